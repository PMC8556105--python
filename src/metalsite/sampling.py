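"""Seeded random undersampling of non-binding windows.

Binding residues are rare (a few percent of a membrane-protein chain), so the
stage-1 training set is rebalanced by keeping every positive window and
drawing ``ratio_n`` negatives per positive uniformly without replacement
(default 1:5).  Undersampling is applied to *training* folds only — validation
stays at natural balance so metrics are not inflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import WindowSample

__all__ = ["SamplingPlan", "undersample"]


@dataclass
class SamplingPlan:
    """Audit record of one undersampling draw."""

    ratio_n: int
    seed: int
    n_positive: int
    n_negative_available: int
    kept_ids: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ratio_n": self.ratio_n,
            "seed": self.seed,
            "n_positive": self.n_positive,
            "n_negative_available": self.n_negative_available,
            "n_kept": len(self.kept_ids),
            "kept_ids": [list(k) for k in self.kept_ids],
        }


def _is_positive(label: object) -> bool:
    if label is None:
        return False
    if isinstance(label, (set, frozenset, list, tuple)):
        return len(label) > 0
    return bool(label)


def undersample(
    samples: Sequence[WindowSample],
    ratio_n: int = 5,
    seed: int = 0,
    return_plan: bool = False,
):
    """Keep all positives and ``min(ratio_n * P, M)`` random negatives.

    The output order is itself shuffled deterministically by ``seed`` so a
    downstream learner never sees positives first.  Raises on zero positives
    or ``ratio_n < 1``; warns when negatives run out before the target ratio.
    """
    if ratio_n < 1:
        raise ValueError(f"ratio_n must be >= 1, got {ratio_n}")
    positives = [s for s in samples if _is_positive(s.label)]
    negatives = [s for s in samples if not _is_positive(s.label)]
    if not positives:
        raise ValueError("undersampling requires at least one positive sample")

    rng = np.random.default_rng(seed)
    target = ratio_n * len(positives)
    if target >= len(negatives):
        if target > len(negatives):
            warnings.warn(
                f"only {len(negatives)} negatives available for target "
                f"{target}; keeping all"
            )
        chosen = negatives
    else:
        idx = rng.choice(len(negatives), size=target, replace=False)
        chosen = [negatives[i] for i in idx]

    kept = positives + chosen
    order = rng.permutation(len(kept))
    kept = [kept[i] for i in order]

    if not return_plan:
        return kept
    plan = SamplingPlan(
        ratio_n,
        seed,
        len(positives),
        len(negatives),
        [s.sample_id for s in kept],
    )
    return kept, plan
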