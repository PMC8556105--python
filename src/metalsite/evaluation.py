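"""Residue-level evaluation: confusion counts, the five metrics, chain-level
10-fold cross-validation, and the sweep harnesses.

The five metrics are accuracy, specificity, sensitivity, the Matthews
correlation coefficient and the area under the ROC curve::

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SPE = TN / (TN + FP)
    SEN = TP / (TP + FN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    AUC = ½ Σ (x_{i+1} − x_i)(y_i + y_{i+1})     (trapezoids over the ROC)

MCC is defined as 0 when any denominator factor vanishes; SPE/SEN with an
empty denominator are reported as missing (None), never as 0.

Cross-validation folds partition *chains*, not residues: windows from one
chain overlap heavily, so residue-level splits would leak.  Undersampling is
applied inside each training fold only, and fold metrics are computed on the
validation chains at their natural class balance; the cross-validated score
is the across-fold mean (with its SD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cascade import (
    CascadeModel,
    predict_cascade,
    train_cascade,
)
from .config import RunConfig
from .curation import ION_CLASSES
from .dataset import Dataset

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ROCCurve",
    "compute_metrics",
    "roc_curve",
    "compute_auc",
    "FoldResult",
    "CVResult",
    "cross_validate",
    "sweep",
    "fold_seed",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @staticmethod
    def from_labels(y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        if t.shape != p.shape:
            raise ValueError("label vectors differ in length")
        return ConfusionCounts(
            TP=int(np.sum((t == 1) & (p == 1))),
            FP=int(np.sum((t == 0) & (p == 1))),
            TN=int(np.sum((t == 0) & (p == 0))),
            FN=int(np.sum((t == 1) & (p == 0))),
        )


@dataclass
class MetricsReport:
    ACC: float
    SPE: float | None
    SEN: float | None
    MCC: float
    AUC: float | None
    counts: ConfusionCounts
    scope: str = "pooled"

    def as_dict(self) -> dict:
        return {
            "ACC": self.ACC,
            "SPE": self.SPE,
            "SEN": self.SEN,
            "MCC": self.MCC,
            "AUC": self.AUC,
        }


def compute_metrics(
    counts: ConfusionCounts, auc: float | None = None, scope: str = "pooled"
) -> MetricsReport:
    """The four threshold metrics from confusion counts (AUC passed through)."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics over zero residues")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    acc = (tp + tn) / counts.total
    spe = tn / (tn + fp) if (tn + fp) > 0 else None
    sen = tp / (tp + fn) if (tp + fn) > 0 else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(acc, spe, sen, mcc, auc, counts, scope)


@dataclass
class ROCCurve:
    """ROC points anchored at (0,0) and (1,1); x (FPR) is non-decreasing."""

    points: np.ndarray  # (m, 2) of (FPR, TPR)
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        x = self.points[:, 0]
        if np.any(np.diff(x) < 0):
            raise ValueError("ROC x-coordinates must be non-decreasing")


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve with tied scores grouped at a single threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score run
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = tps[last] / n_pos
    fpr = fps[last] / n_neg
    points = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])
    if points[-1, 0] != 1.0 or points[-1, 1] != 1.0:
        points = np.vstack([points, [1.0, 1.0]])
    thresholds = np.r_[np.inf, s_sorted[last]]
    return ROCCurve(points, thresholds)


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoidal area under the ROC curve."""
    curve = roc_curve(scores, labels)
    x, y = curve.points[:, 0], curve.points[:, 1]
    return float(0.5 * np.sum((x[1:] - x[:-1]) * (y[1:] + y[:-1])))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def fold_seed(master_seed: int, fold: int) -> int:
    """Per-fold seed derived from the master seed (stays below 2^31)."""
    return int(
        np.random.SeedSequence([master_seed, fold]).generate_state(1)[0] % (2**31)
    )


@dataclass
class FoldResult:
    fold: int
    stage1: MetricsReport
    stage2_macro_acc: float | None
    n_val_residues: int
    val_chains: list[str] = field(default_factory=list)


@dataclass
class CVResult:
    folds: list[FoldResult]
    config: RunConfig

    _METRICS = ("ACC", "SPE", "SEN", "MCC", "AUC")

    def metric_values(self, name: str) -> list[float]:
        if name == "stage2_macro_acc":
            return [f.stage2_macro_acc for f in self.folds
                    if f.stage2_macro_acc is not None]
        return [
            v
            for f in self.folds
            if (v := f.stage1.as_dict()[name]) is not None
        ]

    def summary(self) -> dict[str, tuple[float, float]]:
        """Across-fold (mean, SD) per metric — the cross-validated score."""
        out = {}
        for m in self._METRICS + ("stage2_macro_acc",):
            vals = self.metric_values(m)
            if vals:
                out[m] = (float(np.mean(vals)), float(np.std(vals, ddof=1))
                          if len(vals) > 1 else 0.0)
        return out

    def tidy(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for m, v in f.stage1.as_dict().items():
                if v is not None:
                    rows.append({"fold": f.fold, "metric": m, "value": v})
            if f.stage2_macro_acc is not None:
                rows.append({"fold": f.fold, "metric": "stage2_macro_acc",
                             "value": f.stage2_macro_acc})
        return pd.DataFrame(rows)


def _fold_partition(chain_ids: list[str], k: int, seed: int) -> list[list[str]]:
    if k > len(chain_ids):
        raise ValueError(f"cannot make {k} folds from {len(chain_ids)} chains")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chain_ids))
    return [
        [chain_ids[i] for i in part]
        for part in np.array_split(order, k)
    ]


def _stage2_macro_accuracy(model: CascadeModel, val: Dataset,
                           fms: dict) -> float | None:
    """Macro accuracy of ion-class assignment over true binding residues.

    Each binding residue is scored by the stage-2 bank directly (no stage-1
    gate — this isolates the classification task); a residue counts as
    correct for class c if c is among its true classes and the argmax picks
    c.  Macro = unweighted mean of per-class accuracy over classes present.
    """
    per_class_hits: dict[str, list[int]] = {c: [] for c in ION_CLASSES}
    for chain in val.chains:
        fm = fms[chain.chain_id]
        from .features import extract_windows  # local import avoids cycle at top

        windows = extract_windows(fm, chain.label_sets,
                                  model.layout.window, model.layout.padding)
        binding = [s for s in windows if s.label]
        if not binding:
            continue
        X = np.stack([s.vector for s in binding])
        scores = {
            c: model.stage2[c].predict_proba(X)[:, 1]
            for c in model.enabled_classes
        }
        for j, s in enumerate(binding):
            assigned = max(
                model.enabled_classes,
                key=lambda c: (scores[c][j], -ION_CLASSES.index(c)),
            )
            for cls in s.label:
                per_class_hits[cls].append(1 if assigned == cls else 0)
    accs = [np.mean(v) for v in per_class_hits.values() if v]
    return float(np.mean(accs)) if accs else None


def cross_validate(
    ds: Dataset,
    config: RunConfig | None = None,
    k: int | None = None,
    seed: int | None = None,
    stage2: bool = True,
    factory: Callable | None = None,
) -> CVResult:
    """Chain-level k-fold cross-validation of the full cascade.

    For every fold: train on the other folds' chains (with in-fold
    undersampling at ``config.ratio_n``), then score every residue of the
    validation chains at natural balance.  Stage-1 metrics use the model's
    gate threshold; AUC uses the raw stage-1 probabilities.
    """
    config = config or RunConfig()
    k = k or config.cv_folds
    seed = config.seed if seed is None else seed
    folds = _fold_partition(ds.chain_ids(), k, seed)
    fms = ds.assemble(config.channels)

    results: list[FoldResult] = []
    for i, val_ids in enumerate(folds):
        train_ids = [c for c in ds.chain_ids() if c not in set(val_ids)]
        fs = fold_seed(seed, i)
        model = train_cascade(
            [c for c in ds.chains if c.chain_id in set(train_ids)],
            fms,
            w=config.w,
            padding=config.padding,
            ratio_n=config.ratio_n,
            seed=fs,
            factory=factory or config.factory(),
            threshold=config.threshold,
            stage2_on_predictions=config.stage2_on_predictions,
        )
        val = ds.subset(val_ids)
        preds = predict_cascade(model, [fms[c] for c in val_ids])
        by_chain: dict[str, list] = {}
        for p in preds:
            by_chain.setdefault(p.chain_id, []).append(p)
        y_true, y_pred, probs = [], [], []
        for chain in val.chains:
            truth = chain.binary_labels
            for p in sorted(by_chain[chain.chain_id], key=lambda q: q.position):
                y_true.append(int(truth[p.position]))
                y_pred.append(p.stage1_label)
                probs.append(p.stage1_prob)
        counts = ConfusionCounts.from_labels(y_true, y_pred)
        try:
            auc = compute_auc(probs, y_true)
        except ValueError:
            auc = None
        report = compute_metrics(counts, auc, scope="fold")
        macro = _stage2_macro_accuracy(model, val, fms) if stage2 else None
        results.append(FoldResult(i, report, macro, len(y_true), list(val_ids)))
    return CVResult(results, config)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

_AXES = {
    "ratio_N": "ratio_n",
    "window_w": "w",
    "channels": "channels",
    "classifier": "classifier",
}


def sweep(
    ds: Dataset,
    axis: str,
    grid: Sequence,
    config: RunConfig | None = None,
    k: int | None = None,
    seed: int | None = None,
    factories: dict[str, Callable] | None = None,
    stage2: bool = False,
) -> pd.DataFrame:
    """Cross-validate along one axis; returns a tidy (grid point, fold,
    metric, value) table.

    Axes: ``ratio_N`` (undersampling ratio), ``window_w`` (window length),
    ``channels`` (feature-ablation ladder — grid entries are channel tuples),
    ``classifier`` (grid entries are names into ``factories``).
    """
    if axis not in _AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; choose from {sorted(_AXES)}")
    if not len(grid):
        raise ValueError("sweep grid is empty")
    config = config or RunConfig()
    rows = []
    for point in grid:
        if axis == "classifier":
            if factories is None or point not in factories:
                raise ValueError(f"no factory registered for classifier {point!r}")
            cv = cross_validate(ds, config, k=k, seed=seed, stage2=stage2,
                                factory=factories[point])
            label = point
        else:
            cfg = config.replace(**{_AXES[axis]: point})
            cv = cross_validate(ds, cfg, k=k, seed=seed, stage2=stage2)
            label = "+".join(point) if axis == "channels" else point
        t = cv.tidy()
        t.insert(0, "axis", axis)
        t.insert(1, "point", str(label))
        rows.append(t)
    return pd.concat(rows, ignore_index=True)
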