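"""Dataset curation from PDB-format structures.

A chain enters the dataset when it binds at least one of the 24 recognized
metal-ion species and is longer than 50 residues; redundant chains are removed
at 40% pairwise sequence identity (via a CD-HIT ``.clstr`` file when supplied,
or a built-in greedy fallback).  A residue counts as binding when any of its
heavy atoms lies strictly within the contact cutoff (default 3.5 Å — the
first-coordination-shell heuristic) of a metal atom.

Ion species are grouped into seven prediction classes: K, Ca, Na, Zn, Mg, Hg
and Others (the remaining 18 species pooled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import Align

from .io_formats import FormatError

__all__ = [
    "ION_CLASSES",
    "RECOGNIZED_METALS",
    "CurationError",
    "CurationConfig",
    "ProteinChain",
    "group_ion_class",
    "label_binding_residues",
    "apply_chain_filters",
    "deduplicate_by_identity",
    "parse_clstr",
    "pairwise_identity",
    "dataset_manifest",
]

#: The seven prediction classes, in fixed tie-break order.
ION_CLASSES = ("K", "Ca", "Na", "Zn", "Mg", "Hg", "Others")

#: Raw species codes recognized in structures (PDB residue/element codes).
#: FE2 is ferrous iron, CU1 cuprous copper; both group into Others together
#: with their more oxidized counterparts.
RECOGNIZED_METALS = frozenset(
    {
        "K", "CA", "NA", "ZN", "MG", "HG",  # the six named classes
        "CU", "CU1", "W", "CD", "NI", "FE", "FE2", "MN",
        "RB", "AU", "CS", "PB", "PT", "SR", "LI", "CO", "PR", "MO",
    }
)

_NAMED = {"K": "K", "CA": "Ca", "NA": "Na", "ZN": "Zn", "MG": "Mg", "HG": "Hg"}


class CurationError(ValueError):
    """Raised when a structure cannot be curated."""


@dataclass
class CurationConfig:
    """Knobs of the curation pipeline.

    contact_cutoff : Å; a residue binds a metal when any heavy atom is
        strictly closer than this (boundary exclusive).
    min_chain_length : chains must be strictly longer than this.
    max_identity : pairwise identity at or above which two chains are
        considered redundant.
    """

    contact_cutoff: float = 3.5
    min_chain_length: int = 50
    max_identity: float = 0.40

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if not 0 < self.max_identity <= 1:
            raise ValueError("max_identity must be in (0, 1]")


@dataclass
class ProteinChain:
    """A protein chain with per-residue ion-class label sets.

    ``label_sets[i]`` is the (possibly empty) frozenset of ion classes residue
    i binds; ``source_ions[i]`` records the raw species codes behind those
    labels.  A residue may bind several metals — it then carries several
    classes and contributes one stage-2 sample per class.
    """

    chain_id: str
    sequence: str
    label_sets: list[frozenset[str]]
    source_ions: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.label_sets) != len(self.sequence):
            raise ValueError(
                f"{self.chain_id}: {len(self.label_sets)} labels for "
                f"{len(self.sequence)} residues"
            )
        if not self.source_ions:
            self.source_ions = [frozenset() for _ in self.sequence]
        for i, (labels, ions) in enumerate(zip(self.label_sets, self.source_ions)):
            if labels and not ions:
                raise ValueError(
                    f"{self.chain_id}: residue {i} labeled {set(labels)} "
                    "without source ions"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def binary_labels(self) -> np.ndarray:
        """1 where the residue binds any metal, else 0."""
        return np.array([1 if s else 0 for s in self.label_sets], dtype=np.int8)

    @property
    def n_binding(self) -> int:
        return int(self.binary_labels.sum())

    def primary_labels(self) -> list[str | None]:
        """One class per residue (first in :data:`ION_CLASSES` order), or None."""
        out: list[str | None] = []
        for labels in self.label_sets:
            if not labels:
                out.append(None)
            else:
                out.append(next(c for c in ION_CLASSES if c in labels))
        return out


def group_ion_class(element_symbol: str) -> str:
    """Map a raw metal species code to one of the seven prediction classes."""
    code = element_symbol.strip().upper()
    if code not in RECOGNIZED_METALS:
        raise CurationError(
            f"unrecognized metal species {element_symbol!r}; recognized: "
            f"{sorted(RECOGNIZED_METALS)}"
        )
    return _NAMED.get(code, "Others")


def _one_letter(residue_name: str) -> str:
    """Map a residue name to its parent one-letter code; unknown -> 'X'."""
    info = gemmi.find_tabulated_residue(residue_name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _metal_code(residue: gemmi.Residue, atom: gemmi.Atom) -> str | None:
    """Species code for a hetero metal atom, or None if not a tracked metal."""
    name = residue.name.strip().upper()
    if name in RECOGNIZED_METALS:
        return name
    el = atom.element.name.upper()
    if el in RECOGNIZED_METALS and atom.element.is_metal:
        return el
    return None


def label_binding_residues(
    structure_path: str | Path,
    config: CurationConfig | None = None,
) -> list[ProteinChain]:
    """Label metal-binding residues in a PDB-format structure.

    Returns one :class:`ProteinChain` per polymer chain of the first model.
    A residue is labeled binding iff any of its heavy (non-hydrogen) atoms
    lies strictly within ``config.contact_cutoff`` of a recognized metal
    atom; its ``source_ions`` record every such metal.  Residues whose name
    cannot be mapped to a standard letter become ``X`` and never receive a
    positive label.
    """
    config = config or CurationConfig()
    st = gemmi.read_structure(str(structure_path))
    st.setup_entities()
    if len(st) == 0:
        raise CurationError(f"{structure_path}: structure has no models")
    model = st[0]

    metal_codes: list[str] = []
    metal_pos: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            if res.het_flag != "H" or res.name == "HOH":
                continue
            for atom in res:
                code = _metal_code(res, atom)
                if code is not None:
                    metal_codes.append(code)
                    metal_pos.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not metal_pos:
        raise CurationError(
            f"{structure_path}: no recognized metal atoms "
            f"(looked for {sorted(RECOGNIZED_METALS)})"
        )
    metals = np.asarray(metal_pos)

    chains: list[ProteinChain] = []
    for chain in model:
        seq: list[str] = []
        label_sets: list[frozenset[str]] = []
        source_ions: list[frozenset[str]] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa:
                continue
            letter = _one_letter(res.name)
            altlocs = {a.altloc for a in res if a.altloc not in ("", " ", "\0")}
            if altlocs:
                warnings.warn(
                    f"{structure_path}: {chain.name}/{res.seqid.num} has "
                    f"alternate locations {sorted(altlocs)}; using all atoms"
                )
            coords = np.array(
                [
                    (a.pos.x, a.pos.y, a.pos.z)
                    for a in res
                    if a.element != gemmi.Element("H")
                ]
            )
            ions: set[str] = set()
            if coords.size:
                d = np.linalg.norm(
                    coords[:, None, :] - metals[None, :, :], axis=2
                )
                hit = d.min(axis=0) < config.contact_cutoff  # boundary exclusive
                ions = {metal_codes[j] for j in np.nonzero(hit)[0]}
            seq.append(letter)
            if letter == "X":
                # unmappable residues never carry positive labels
                label_sets.append(frozenset())
                source_ions.append(frozenset())
            else:
                label_sets.append(frozenset(group_ion_class(c) for c in ions))
                source_ions.append(frozenset(ions))
        if seq:
            chains.append(
                ProteinChain(
                    f"{st.name or Path(structure_path).stem}_{chain.name}",
                    "".join(seq),
                    label_sets,
                    source_ions,
                )
            )
    return chains


def apply_chain_filters(
    chains: Sequence[ProteinChain], config: CurationConfig | None = None
) -> list[ProteinChain]:
    """Keep chains with >=1 binding residue and length strictly above the
    minimum (a 50-residue chain is removed; 51 passes)."""
    config = config or CurationConfig()
    kept = [
        c
        for c in chains
        if c.n_binding >= 1 and len(c) > config.min_chain_length
    ]
    if not kept:
        warnings.warn("chain filters removed every chain")
    return kept


def parse_clstr(path: str | Path) -> dict[int, list[str]]:
    """Parse a CD-HIT ``.clstr`` file into {cluster index: member ids}."""
    clusters: dict[int, list[str]] = {}
    current: int | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">Cluster"):
            current = int(line.split()[1])
            clusters[current] = []
        elif line.strip():
            if current is None:
                raise FormatError(
                    f"{path}: member line before any cluster header: {line!r}"
                )
            # e.g. "0	123aa, >chain_A... *"
            name = line.split(">", 1)[1].split("...")[0]
            clusters[current].append(name)
    return clusters


_aligner: Align.PairwiseAligner | None = None


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity: matches / length of the shorter
    sequence (CD-HIT's convention)."""
    global _aligner
    if _aligner is None:
        _aligner = Align.PairwiseAligner()
        _aligner.mode = "global"
        _aligner.match_score = 1.0
        _aligner.mismatch_score = -1.0
        _aligner.open_gap_score = -2.0
        _aligner.extend_gap_score = -0.5
    aln = _aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def deduplicate_by_identity(
    chains: Sequence[ProteinChain],
    config: CurationConfig | None = None,
    cluster_file: str | Path | None = None,
) -> list[ProteinChain]:
    """Remove redundant chains at ``config.max_identity``.

    With a CD-HIT ``.clstr`` file, one representative per cluster is kept
    (longest chain, ties by lexicographic id).  Without one, a greedy
    longest-first pass keeps a chain only if its identity to every already
    kept chain is below the threshold.
    """
    config = config or CurationConfig()
    by_id = {c.chain_id: c for c in chains}
    if cluster_file is not None:
        clusters = parse_clstr(cluster_file)
        unknown = [
            m for members in clusters.values() for m in members if m not in by_id
        ]
        if unknown:
            raise CurationError(
                f"{cluster_file}: cluster members not in chain set: {sorted(unknown)}"
            )
        reps = []
        for idx in sorted(clusters):
            members = sorted(
                (by_id[m] for m in clusters[idx]),
                key=lambda c: (-len(c), c.chain_id),
            )
            if members:
                reps.append(members[0])
        return reps

    ordered = sorted(chains, key=lambda c: (-len(c), c.chain_id))
    kept: list[ProteinChain] = []
    for cand in ordered:
        if all(
            pairwise_identity(cand.sequence, k.sequence) < config.max_identity
            for k in kept
        ):
            kept.append(cand)
    # restore input order
    kept_ids = {c.chain_id for c in kept}
    return [c for c in chains if c.chain_id in kept_ids]


def dataset_manifest(chains: Sequence[ProteinChain]) -> pd.DataFrame:
    """Per-chain summary table: length plus binding-residue counts per class."""
    rows = []
    for c in chains:
        row = {"chain": c.chain_id, "length": len(c), "n_binding": c.n_binding}
        for cls in ION_CLASSES:
            row[f"n_{cls}"] = sum(1 for s in c.label_sets if cls in s)
        rows.append(row)
    return pd.DataFrame(rows)
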