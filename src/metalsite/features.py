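"""Per-residue feature assembly and sliding-window encoding.

Five channels are concatenated per residue, in fixed order:

====== ===== ==========================================================
channel width content
====== ===== ==========================================================
PSSM     20  evolutionary log-odds profile (PSI-BLAST column order)
PCP     553  physicochemical property values of the residue's amino acid
rASA      1  relative solvent accessibility in [0, 1]
Zcoord    1  signed distance to the membrane centre plane (Å)
TOPO      3  one-hot three-state topology (inside / membrane / outside)
====== ===== ==========================================================

giving L×578 for a length-L chain with the full 553-property table.  Any
subset of channels can be assembled (the feature-ablation ladder).  Classifier
samples are odd-length sliding windows centred on each residue, flattened
row-major; positions past the termini are padded (zero rows by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .curation import ProteinChain
from .io_formats import (
    PCPTable,
    PSSMProfile,
    PSSM_ALPHABET,
    ScalarTrack,
    TOPOLOGY_STATES,
    TopologyTrack,
    ValidationError,
)

__all__ = [
    "CHANNELS",
    "CHANNEL_WIDTHS",
    "FeatureMatrix",
    "FeatureLayout",
    "WindowSample",
    "assemble_features",
    "extract_windows",
    "scale_features",
]

#: Channel concatenation order (the ablation ladder's order).
CHANNELS = ("PSSM", "PCP", "rASA", "Zcoord", "TOPO")

#: Widths with the full property table; PCP shrinks with smaller tables.
CHANNEL_WIDTHS = {"PSSM": 20, "PCP": 553, "rASA": 1, "Zcoord": 1, "TOPO": 3}


@dataclass
class FeatureMatrix:
    """L × d per-residue feature block for one chain."""

    chain_id: str
    block: np.ndarray
    column_names: list[str]
    channels: tuple[str, ...]
    scaling_state: str = "none"

    def __post_init__(self) -> None:
        self.block = np.asarray(self.block, dtype=float)
        if self.block.ndim != 2 or self.block.shape[1] != len(self.column_names):
            raise ValidationError(
                f"{self.chain_id}: block shape {self.block.shape} does not "
                f"match {len(self.column_names)} column names"
            )

    @property
    def n_residues(self) -> int:
        return self.block.shape[0]

    @property
    def n_columns(self) -> int:
        return self.block.shape[1]


@dataclass(frozen=True)
class FeatureLayout:
    """Descriptor of a feature space; models refuse mismatched layouts."""

    channels: tuple[str, ...]
    widths: tuple[int, ...]
    window: int
    padding: str

    @property
    def row_width(self) -> int:
        return sum(self.widths)

    @property
    def vector_length(self) -> int:
        return self.window * self.row_width

    def diff(self, other: "FeatureLayout") -> str:
        parts = []
        for name in ("channels", "widths", "window", "padding"):
            a, b = getattr(self, name), getattr(other, name)
            if a != b:
                parts.append(f"{name}: {a} != {b}")
        return "; ".join(parts) or "layouts identical"

    @staticmethod
    def of(fm: FeatureMatrix, window: int, padding: str) -> "FeatureLayout":
        widths = []
        for ch in fm.channels:
            n = sum(1 for c in fm.column_names if c.startswith(f"{ch}_") or c == ch)
            widths.append(n)
        return FeatureLayout(fm.channels, tuple(widths), window, padding)


@dataclass
class WindowSample:
    """One flattened w×d window centred on a residue."""

    chain_id: str
    center: int  # 0-based residue index
    vector: np.ndarray
    label: object  # binary int (stage 1) or ion-class set / name (stage 2)
    w: int

    @property
    def sample_id(self) -> tuple[str, int]:
        return (self.chain_id, self.center)


def assemble_features(
    chain: ProteinChain | str,
    pssm: PSSMProfile | None = None,
    pcp_table: PCPTable | None = None,
    rasa: ScalarTrack | None = None,
    zcoord: ScalarTrack | None = None,
    topo: TopologyTrack | None = None,
    channels: Sequence[str] = CHANNELS,
    chain_id: str | None = None,
) -> FeatureMatrix:
    """Concatenate the requested channels into one L×d matrix.

    Channels not requested may be omitted from the arguments; every supplied
    channel must match the chain length, and a mismatch is reported by
    channel name.  Column order always follows :data:`CHANNELS` regardless of
    the order ``channels`` is given in.
    """
    if isinstance(chain, ProteinChain):
        sequence = chain.sequence
        cid = chain.chain_id
    else:
        sequence = chain
        cid = chain_id or "chain"
    L = len(sequence)
    chan_set = set(channels)
    unknown = chan_set - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")

    blocks: list[np.ndarray] = []
    names: list[str] = []
    for ch in CHANNELS:  # fixed order
        if ch not in chan_set:
            continue
        if ch == "PSSM":
            if pssm is None:
                raise ValueError("PSSM channel requested but no profile given")
            if len(pssm) != L:
                raise ValidationError(
                    f"{cid}: PSSM length {len(pssm)} != chain length {L}"
                )
            blocks.append(pssm.scores.astype(float))
            names.extend(f"PSSM_{aa}" for aa in PSSM_ALPHABET)
        elif ch == "PCP":
            if pcp_table is None:
                raise ValueError("PCP channel requested but no property table given")
            blocks.append(np.stack([pcp_table.vector_for(aa) for aa in sequence]))
            names.extend(f"PCP_{acc}" for acc in pcp_table.accessions)
        elif ch == "rASA":
            if rasa is None:
                raise ValueError("rASA channel requested but no track given")
            if len(rasa) != L:
                raise ValidationError(
                    f"{cid}: rASA length {len(rasa)} != chain length {L}"
                )
            blocks.append(rasa.values[:, None])
            names.append("rASA")
        elif ch == "Zcoord":
            if zcoord is None:
                raise ValueError("Zcoord channel requested but no track given")
            if len(zcoord) != L:
                raise ValidationError(
                    f"{cid}: Zcoord length {len(zcoord)} != chain length {L}"
                )
            blocks.append(zcoord.values[:, None])
            names.append("Zcoord")
        elif ch == "TOPO":
            if topo is None:
                raise ValueError("TOPO channel requested but no track given")
            if len(topo) != L:
                raise ValidationError(
                    f"{cid}: TOPO length {len(topo)} != chain length {L}"
                )
            blocks.append(topo.one_hot())
            names.extend(f"TOPO_{s}" for s in TOPOLOGY_STATES)

    ordered = tuple(ch for ch in CHANNELS if ch in chan_set)
    return FeatureMatrix(cid, np.hstack(blocks), names, ordered)


def extract_windows(
    fm: FeatureMatrix,
    labels: Sequence | None,
    w: int,
    padding: str = "zero",
) -> list[WindowSample]:
    """Cut the feature matrix into L sliding windows of odd size ``w``.

    Sample i covers rows i-(w-1)/2 … i+(w-1)/2; rows past either terminus
    are zero rows (``padding="zero"``) or copies of the terminal row
    (``padding="repeat"``).  The sample's label is residue i's label.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window size must be a positive odd integer, got {w}")
    if padding not in ("zero", "repeat"):
        raise ValueError(f"unknown padding policy {padding!r}")
    L, d = fm.block.shape
    if labels is not None and len(labels) != L:
        raise ValidationError(
            f"{fm.chain_id}: {len(labels)} labels for {L} residues"
        )
    half = (w - 1) // 2
    if padding == "zero":
        padded = np.vstack(
            [np.zeros((half, d)), fm.block, np.zeros((half, d))]
        )
    else:
        padded = np.vstack(
            [np.repeat(fm.block[:1], half, axis=0), fm.block,
             np.repeat(fm.block[-1:], half, axis=0)]
        )
    windows = np.lib.stride_tricks.sliding_window_view(padded, (w, d))[:, 0]
    return [
        WindowSample(
            fm.chain_id,
            i,
            windows[i].reshape(-1).copy(),
            None if labels is None else labels[i],
            w,
        )
        for i in range(L)
    ]


def scale_features(
    train_matrices: Sequence[FeatureMatrix],
    apply_matrices: Sequence[FeatureMatrix] = (),
    method: str = "zscore",
):
    """Fit a per-column scaler on the training chains and apply it everywhere.

    Returns ``(scaled_train, scaled_apply, scaler)``; ``scaler`` is the fitted
    sklearn transformer (or None for ``method="none"``), so the transform can
    be inverted.  Zero-variance columns pass through unchanged with a warning.
    """
    if method == "none":
        return list(train_matrices), list(apply_matrices), None
    if method == "zscore":
        scaler = StandardScaler()
    elif method == "minmax":
        scaler = MinMaxScaler()
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    stacked = np.vstack([fm.block for fm in train_matrices])
    scaler.fit(stacked)
    constant = np.nonzero(stacked.max(axis=0) == stacked.min(axis=0))[0]
    if constant.size:
        names = [train_matrices[0].column_names[i] for i in constant[:5]]
        warnings.warn(
            f"{constant.size} zero-variance column(s) pass through unscaled "
            f"(first: {names})"
        )
        if method == "zscore":
            # true pass-through: identity transform on constant columns
            scaler.mean_[constant] = 0.0
            scaler.scale_[constant] = 1.0

    def _apply(fms: Sequence[FeatureMatrix]) -> list[FeatureMatrix]:
        out = []
        for fm in fms:
            out.append(
                FeatureMatrix(
                    fm.chain_id,
                    scaler.transform(fm.block),
                    list(fm.column_names),
                    fm.channels,
                    scaling_state="fitted",
                )
            )
        return out

    return _apply(train_matrices), _apply(apply_matrices), scaler
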