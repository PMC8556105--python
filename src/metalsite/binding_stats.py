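"""Descriptive statistics of metal binding: amino-acid binding-frequency
profiles per ion class, position-specific frequency matrices around binding
residues, and binding-domain window export for motif tools.

Only the 20 standard amino acids enter the normalized frequencies; other
letters (X and friends) are tallied separately but never analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curation import ION_CLASSES, ProteinChain
from .io_formats import STANDARD_AA, write_fasta

__all__ = [
    "FrequencyProfile",
    "PositionFrequencyMatrix",
    "binding_frequencies",
    "position_frequency_matrix",
    "export_binding_domains",
]

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass
class FrequencyProfile:
    """Binding vs non-binding amino-acid frequencies (percent) for one class."""

    ion_class: str
    binding_freq: np.ndarray  # 20 values, sums to 100
    nonbinding_freq: np.ndarray
    binding_counts: np.ndarray = field(default=None)  # raw counts behind the %
    nonbinding_counts: np.ndarray = field(default=None)
    n_excluded: int = 0  # non-standard letters left out of the normalization

    def __post_init__(self) -> None:
        for name in ("binding_freq", "nonbinding_freq"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (20,) or np.any(v < 0):
                raise ValueError(f"{name} must be 20 non-negative values")
            if abs(v.sum() - 100.0) > 1e-9:
                raise ValueError(f"{name} must sum to 100, got {v.sum()}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "amino_acid": list(STANDARD_AA),
                "binding_pct": self.binding_freq,
                "nonbinding_pct": self.nonbinding_freq,
            }
        )


def _count_letters(letters: Sequence[str]) -> tuple[np.ndarray, int]:
    counts = np.zeros(20, dtype=np.int64)
    excluded = 0
    for aa in letters:
        i = _AA_INDEX.get(aa)
        if i is None:
            excluded += 1
        else:
            counts[i] += 1
    return counts, excluded


def binding_frequencies(
    chains: Sequence[ProteinChain], ion_class: str
) -> FrequencyProfile:
    """Amino-acid composition (percent) of the class's binding residues
    versus all non-binding residues of the same chains."""
    if ion_class not in ION_CLASSES:
        raise ValueError(f"unknown ion class {ion_class!r}")
    binding: list[str] = []
    nonbinding: list[str] = []
    for c in chains:
        for aa, labels in zip(c.sequence, c.label_sets):
            if ion_class in labels:
                binding.append(aa)
            elif not labels:
                nonbinding.append(aa)
    b_counts, b_excl = _count_letters(binding)
    n_counts, n_excl = _count_letters(nonbinding)
    if b_counts.sum() == 0:
        raise ValueError(f"no {ion_class} binding residues in the chain set")
    if n_counts.sum() == 0:
        raise ValueError("no non-binding residues in the chain set")
    return FrequencyProfile(
        ion_class,
        100.0 * b_counts / b_counts.sum(),
        100.0 * n_counts / n_counts.sum(),
        b_counts,
        n_counts,
        b_excl + n_excl,
    )


@dataclass
class PositionFrequencyMatrix:
    """Occurrence counts of the 20 amino acids at each window position
    around the class's binding residues (terminal overhangs excluded)."""

    ion_class: str
    window: int
    counts: np.ndarray  # window × 20
    background: np.ndarray  # dataset letter frequencies, sums to 1
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        half = (self.window - 1) // 2
        df = pd.DataFrame(self.counts, columns=list(STANDARD_AA))
        df.insert(0, "offset", np.arange(-half, half + 1))
        return df


def position_frequency_matrix(
    chains: Sequence[ProteinChain],
    ion_class: str,
    window: int = 21,
) -> PositionFrequencyMatrix:
    """One window contribution per binding residue of the class; positions
    hanging past a terminus contribute nothing at that offset."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    if ion_class not in ION_CLASSES:
        raise ValueError(f"unknown ion class {ion_class!r}")
    half = (window - 1) // 2
    counts = np.zeros((window, 20), dtype=np.int64)
    n_sites = 0
    bg = np.zeros(20, dtype=np.int64)
    for c in chains:
        letters, _ = _count_letters(c.sequence)
        bg += letters
        for i, labels in enumerate(c.label_sets):
            if ion_class not in labels:
                continue
            n_sites += 1
            for off in range(-half, half + 1):
                j = i + off
                if 0 <= j < len(c.sequence):
                    k = _AA_INDEX.get(c.sequence[j])
                    if k is not None:
                        counts[off + half, k] += 1
    if n_sites == 0:
        raise ValueError(f"no {ion_class} binding residues in the chain set")
    background = bg / bg.sum() if bg.sum() else bg.astype(float)
    return PositionFrequencyMatrix(ion_class, window, counts, background, n_sites)


def export_binding_domains(
    chains: Sequence[ProteinChain],
    ion_class: str,
    window: int = 21,
    path: str | Path | None = None,
) -> list[tuple[str, str]]:
    """Centered windows around each binding residue as FASTA records
    (``chain_position`` ids, 1-based positions; terminal overhang padded
    with X so every record has the full window length — motif tools treat
    X as unknown, and the PFM can be rebuilt exactly from the export)."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    half = (window - 1) // 2
    records: list[tuple[str, str]] = []
    for c in chains:
        for i, labels in enumerate(c.label_sets):
            if ion_class not in labels:
                continue
            left = max(0, i - half)
            right = min(len(c.sequence), i + half + 1)
            seq = (
                "X" * (half - (i - left))
                + c.sequence[left:right]
                + "X" * (half - (right - 1 - i))
            )
            records.append((f"{c.chain_id}_{i + 1}", seq))
    if path is not None:
        write_fasta(records, path)
    return records
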