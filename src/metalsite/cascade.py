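"""The two-stage cascade: binding detection, then ion-class assignment.

Stage 1 is a binary random-forest detector trained on windows labeled
binding-to-any-metal vs non-binding (after 1:5 undersampling).  Stage 2 is a
bank of seven one-vs-rest scorers — one per ion class (K, Ca, Na, Zn, Mg, Hg,
Others) — trained on binding residues only and evaluated only on residues the
stage-1 gate passes (probability ≥ threshold, default 0.5).  The assigned
class maximizes the one-vs-rest scores; exact ties go to the earlier class in
the fixed order.

The classifier is pluggable: any scikit-learn style estimator factory can
stand in for the default random forest (that is how SVM / naïve Bayes /
AdaBoost comparisons are run), but every classifier in one cascade shares a
single feature layout, which the model archive records and prediction
verifies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .curation import ION_CLASSES, ProteinChain
from .features import (
    FeatureLayout,
    FeatureMatrix,
    WindowSample,
    extract_windows,
)
from .sampling import undersample

__all__ = [
    "RFParams",
    "CascadeModel",
    "ResiduePrediction",
    "rf_factory",
    "train_stage1",
    "train_stage2",
    "train_cascade",
    "predict_cascade",
    "predictions_to_records",
    "save_model",
    "load_model",
    "LayoutMismatchError",
]


class LayoutMismatchError(ValueError):
    """Prediction attempted with a feature layout the model was not trained on."""


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters (defaults: 500 trees, unlimited depth,
    √d candidate features per split)."""

    n_trees: int = 500
    max_depth: int | None = None
    max_features: str | float = "sqrt"


def rf_factory(params: RFParams = RFParams()) -> Callable[[int], RandomForestClassifier]:
    """Factory of seeded random forests with vote-fraction probabilities."""

    def make(seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=params.n_trees,
            max_depth=params.max_depth,
            max_features=params.max_features,
            random_state=seed,
            n_jobs=1,
        )

    return make


@dataclass
class CascadeModel:
    stage1: object
    stage2: dict[str, object | None]  # ion class -> fitted scorer or None (disabled)
    layout: FeatureLayout
    threshold: float = 0.5
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.stage2.keys()) != ION_CLASSES:
            raise ValueError(
                f"stage2 must have exactly the seven scorers {ION_CLASSES}, "
                f"got {tuple(self.stage2.keys())}"
            )

    @property
    def enabled_classes(self) -> tuple[str, ...]:
        return tuple(c for c in ION_CLASSES if self.stage2[c] is not None)


@dataclass
class ResiduePrediction:
    chain_id: str
    position: int  # 0-based
    residue: str
    stage1_prob: float
    stage1_label: int
    class_probs: dict[str, float] | None  # None when the gate rejects
    assigned_class: str | None

    def __post_init__(self) -> None:
        if (self.assigned_class is None) != (self.stage1_label == 0):
            raise ValueError(
                "assigned_class must be present exactly when stage1_label is 1"
            )


def _as_xy(samples: Sequence[WindowSample], binary: bool = True):
    X = np.stack([s.vector for s in samples])
    if binary:
        y = np.array(
            [1 if _label_positive(s.label) else 0 for s in samples], dtype=int
        )
        return X, y
    return X, [s.label for s in samples]


def _label_positive(label: object) -> bool:
    if label is None:
        return False
    if isinstance(label, (set, frozenset, list, tuple)):
        return len(label) > 0
    return bool(label)


def _label_classes(label: object) -> frozenset[str]:
    if label is None:
        return frozenset()
    if isinstance(label, str):
        return frozenset([label])
    return frozenset(label)


def train_stage1(
    samples: Sequence[WindowSample],
    factory: Callable[[int], object] | None = None,
    seed: int = 0,
) -> object:
    """Fit the binary binding detector on (already undersampled) windows."""
    factory = factory or rf_factory()
    X, y = _as_xy(samples, binary=True)
    if len(np.unique(y)) < 2:
        raise ValueError("stage-1 training set contains a single class")
    clf = factory(seed)
    clf.fit(X, y)
    return clf


def train_stage2(
    samples: Sequence[WindowSample],
    factory: Callable[[int], object] | None = None,
    seed: int = 0,
) -> dict[str, object | None]:
    """Fit the seven one-vs-rest ion-class scorers on binding windows.

    Each sample's label is its set of ion classes; a residue binding several
    metals is a positive example for each of its classes.  A class with no
    positives — or no negatives — cannot be scored and is disabled with a
    warning; prediction never assigns a disabled class.
    """
    factory = factory or rf_factory()
    X = np.stack([s.vector for s in samples])
    class_sets = [_label_classes(s.label) for s in samples]
    if any(not cs for cs in class_sets):
        raise ValueError("stage-2 samples must all carry at least one ion class")
    scorers: dict[str, object | None] = {}
    for k, cls in enumerate(ION_CLASSES):
        y = np.array([1 if cls in cs else 0 for cs in class_sets], dtype=int)
        if y.sum() < 2 or y.sum() > len(y) - 1:
            warnings.warn(
                f"ion class {cls}: {int(y.sum())} positive of {len(y)} binding "
                "samples; scorer disabled"
            )
            scorers[cls] = None
            continue
        clf = factory(seed + 1 + k)
        clf.fit(X, y)
        scorers[cls] = clf
    return scorers


def train_cascade(
    chains: Sequence[ProteinChain],
    feature_matrices: Mapping[str, FeatureMatrix],
    w: int = 9,
    padding: str = "zero",
    ratio_n: int = 5,
    seed: int = 0,
    factory: Callable[[int], object] | None = None,
    threshold: float = 0.5,
    stage2_on_predictions: bool = False,
) -> CascadeModel:
    """Train the full cascade from labeled chains and their feature matrices.

    Stage 2 trains on true binding residues by default; with
    ``stage2_on_predictions`` it instead trains on residues the freshly
    fitted stage-1 model calls positive (keeping their true class labels),
    coupling the stages the way a deployed gate would see them.
    """
    factory = factory or rf_factory()
    all_windows: list[WindowSample] = []
    for chain in chains:
        fm = feature_matrices[chain.chain_id]
        all_windows.extend(extract_windows(fm, chain.label_sets, w, padding))

    binary = [
        WindowSample(s.chain_id, s.center, s.vector, int(_label_positive(s.label)), s.w)
        for s in all_windows
    ]
    stage1 = train_stage1(
        undersample(binary, ratio_n=ratio_n, seed=seed), factory, seed
    )

    if stage2_on_predictions:
        X = np.stack([s.vector for s in all_windows])
        gate = stage1.predict_proba(X)[:, 1] >= threshold
        pool = [
            s for s, g in zip(all_windows, gate) if g and _label_classes(s.label)
        ]
    else:
        pool = [s for s in all_windows if _label_classes(s.label)]
    if not pool:
        raise ValueError("no binding residues available for stage-2 training")
    stage2 = train_stage2(pool, factory, seed)

    layout = FeatureLayout.of(next(iter(feature_matrices.values())), w, padding)
    return CascadeModel(
        stage1,
        stage2,
        layout,
        threshold,
        config={
            "w": w,
            "padding": padding,
            "ratio_n": ratio_n,
            "seed": seed,
            "stage2_on_predictions": stage2_on_predictions,
        },
    )


def predict_cascade(
    model: CascadeModel,
    feature_matrices: Sequence[FeatureMatrix],
    sequences: Mapping[str, str] | None = None,
    threshold: float | None = None,
) -> list[ResiduePrediction]:
    """Run the cascade over whole chains.

    Stage-2 scorers are evaluated only on residues whose stage-1 probability
    reaches the threshold; everything below the gate gets no class and no
    class probabilities.  Raising the threshold can only shrink the set of
    classed residues.
    """
    thr = model.threshold if threshold is None else threshold
    out: list[ResiduePrediction] = []
    for fm in feature_matrices:
        layout = FeatureLayout.of(fm, model.layout.window, model.layout.padding)
        if layout != model.layout:
            raise LayoutMismatchError(
                f"{fm.chain_id}: feature layout differs from the model's "
                f"({model.layout.diff(layout)})"
            )
        windows = extract_windows(fm, None, model.layout.window, model.layout.padding)
        X = np.stack([s.vector for s in windows])
        p1 = model.stage1.predict_proba(X)[:, 1]
        gated = np.nonzero(p1 >= thr)[0]
        scores = {cls: None for cls in ION_CLASSES}
        if gated.size:
            for cls in model.enabled_classes:
                scores[cls] = model.stage2[cls].predict_proba(X[gated])[:, 1]
        seq = (sequences or {}).get(fm.chain_id)
        gpos = {int(i): j for j, i in enumerate(gated)}
        for i in range(fm.n_residues):
            residue = seq[i] if seq else "X"
            if i in gpos:
                j = gpos[i]
                probs = {
                    cls: float(scores[cls][j])
                    for cls in model.enabled_classes
                }
                # argmax with ties to the earlier class in ION_CLASSES order
                assigned = max(
                    model.enabled_classes,
                    key=lambda c: (probs[c], -ION_CLASSES.index(c)),
                )
                out.append(
                    ResiduePrediction(
                        fm.chain_id, i, residue, float(p1[i]), 1, probs, assigned
                    )
                )
            else:
                out.append(
                    ResiduePrediction(
                        fm.chain_id, i, residue, float(p1[i]), 0, None, None
                    )
                )
    return out


def predictions_to_records(preds: Sequence[ResiduePrediction]) -> list[dict]:
    """Rows for :func:`metalsite.io_formats.write_predictions` (1-based positions)."""
    rows = []
    for p in preds:
        row = {
            "chain": p.chain_id,
            "position": p.position + 1,
            "residue": p.residue,
            "stage1_prob": p.stage1_prob,
            "stage1_label": p.stage1_label,
            "assigned_class": p.assigned_class or "",
        }
        for cls in ION_CLASSES:
            val = None
            if p.class_probs is not None and cls in p.class_probs:
                val = p.class_probs[cls]
            row[f"prob_{cls}"] = val
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------

def save_model(model: CascadeModel, directory: str | Path) -> None:
    """Persist the cascade: 8 classifiers, layout JSON, config snapshot."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.stage1, directory / "stage1.joblib")
    for cls, clf in model.stage2.items():
        if clf is not None:
            joblib.dump(clf, directory / f"stage2_{cls}.joblib")
    meta = {
        "format_version": 1,
        "layout": asdict(model.layout),
        "threshold": model.threshold,
        "config": model.config,
        "enabled_classes": list(model.enabled_classes),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> CascadeModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    if meta.get("format_version") != 1:
        raise LayoutMismatchError(
            f"unsupported model archive version {meta.get('format_version')}"
        )
    layout = FeatureLayout(
        tuple(meta["layout"]["channels"]),
        tuple(meta["layout"]["widths"]),
        meta["layout"]["window"],
        meta["layout"]["padding"],
    )
    stage1 = joblib.load(directory / "stage1.joblib")
    stage2: dict[str, object | None] = {}
    for cls in ION_CLASSES:
        p = directory / f"stage2_{cls}.joblib"
        stage2[cls] = joblib.load(p) if p.exists() else None
    return CascadeModel(stage1, stage2, layout, meta["threshold"], meta["config"])
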