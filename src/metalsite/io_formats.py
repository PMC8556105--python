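"""Readers and writers for every file dialect the pipeline touches.

Dialects handled here:

* FASTA (via Biopython);
* PSI-BLAST ASCII position-specific scoring matrices (the ``-out_ascii_pssm``
  dialect: header, then one row per residue with position, residue letter,
  20 log-odds integers and 20 weighted-percentage columns — only the log-odds
  block is retained);
* AAindex1 flat files (H/D/…/I blocks, two rows of ten values in the canonical
  A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V pairing);
* TMHMM-style long-format topology segment lists and per-residue TSV tracks;
* per-residue scalar tracks (relative solvent accessibility, membrane
  Z-coordinate) as two-column TSV;
* the prediction TSV emitted by the cascade.

All on-disk coordinates are 1-based inclusive; everything in memory is
0-based half-open.  Readers reject length-inconsistent input rather than
silently truncating.  ``strict=True`` escalates recoverable warnings
(sequence/PSSM residue mismatches, short AAindex tables) to errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PSSM_ALPHABET",
    "STANDARD_AA",
    "TOPOLOGY_STATES",
    "FormatError",
    "ValidationError",
    "FastaRecord",
    "PSSMProfile",
    "PCPTable",
    "ScalarTrack",
    "TopologyTrack",
    "read_fasta",
    "write_fasta",
    "read_pssm",
    "write_pssm",
    "read_aaindex",
    "write_aaindex",
    "read_topology",
    "write_topology",
    "read_scalar_track",
    "write_scalar_track",
    "write_predictions",
    "read_predictions",
]

#: Fixed amino-acid column order of PSI-BLAST PSSM files.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: The 20 standard amino acids in alphabetical order (internal PCP ordering).
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Letters that appear in sequence databases but are not one of the 20.
NONSTANDARD_LETTERS = frozenset("BJOUXZ")

#: Three-state membrane topology, in one-hot column order.
TOPOLOGY_STATES = ("inside", "membrane", "outside")

_STATE_SYNONYMS = {
    "inside": "inside",
    "i": "inside",
    "in": "inside",
    "tmhelix": "membrane",
    "membrane": "membrane",
    "m": "membrane",
    "h": "membrane",
    "outside": "outside",
    "o": "outside",
    "out": "outside",
}

# AAindex1 I-block layout: two rows of ten values, paired column headers.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a semantic constraint (lengths, ranges…)."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str
    #: 0-based positions of letters outside the 20-letter alphabet.
    nonstandard: tuple[int, ...] = ()


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file; uppercase sequences, flag non-standard letters.

    Raises :class:`FormatError` on an empty file or duplicate identifiers.
    """
    records: list[FastaRecord] = []
    seen: dict[str, int] = {}
    with open(path) as handle:
        parsed = list(SeqIO.parse(handle, "fasta"))
    for rec in parsed:
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {rec.id!r} has an empty sequence")
        flagged = tuple(i for i, aa in enumerate(seq) if aa not in STANDARD_AA)
        bad = [seq[i] for i in flagged if seq[i] not in NONSTANDARD_LETTERS]
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains non-amino-acid letters {sorted(set(bad))}"
            )
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(FastaRecord(rec.id, seq, flagged))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise FormatError(f"duplicate FASTA identifiers: {dupes}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

@dataclass
class PSSMProfile:
    """Log-odds block of a PSI-BLAST ASCII PSSM.

    ``scores`` is an L×20 integer matrix in PSI-BLAST column order
    (:data:`PSSM_ALPHABET`); ``residues`` echoes the file's residue column.
    """

    chain_id: str
    scores: np.ndarray
    residues: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM scores must be L×20, got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.residues):
            raise ValidationError(
                f"PSSM has {self.scores.shape[0]} rows but residue string "
                f"of length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_pssm(
    path: str | Path,
    chain_id: str | None = None,
    sequence: str | None = None,
    strict: bool = False,
) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM, keeping only the 20 log-odds columns.

    If ``sequence`` is given, the file's residue column is compared against
    it position by position; a mismatch warns (or raises under ``strict`` —
    PSI-BLAST may remap selenocysteine and friends, so mismatches are not
    necessarily fatal).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(t in set(PSSM_ALPHABET) for t in toks[:20]):
            header_idx = i
            break
    if header_idx is None:
        raise FormatError(f"{path}: no PSSM column header found")
    header = lines[header_idx].split()
    order = "".join(header[:20])

    residues: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        toks = line.split()
        if not toks:
            break  # blank line terminates the matrix block
        if not toks[0].isdigit():
            break  # footer (K, Lambda …)
        if len(toks) < 22:
            raise FormatError(
                f"{path}:{lineno}: expected at least 22 columns, got {len(toks)}"
            )
        try:
            pos = int(toks[0])
            row = [int(v) for v in toks[2:22]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable row ({exc})") from exc
        if pos != len(residues) + 1:
            raise FormatError(
                f"{path}:{lineno}: position {pos} out of order "
                f"(expected {len(residues) + 1})"
            )
        residues.append(toks[1])
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no PSSM rows parsed")

    scores = np.array(rows, dtype=np.int64)
    # Normalise to the canonical column order should a writer permute it.
    if order != PSSM_ALPHABET:
        perm = [order.index(aa) for aa in PSSM_ALPHABET]
        scores = scores[:, perm]

    residue_str = "".join(residues)
    if sequence is not None:
        if len(sequence) != len(residue_str):
            raise FormatError(
                f"{path}: PSSM has {len(residue_str)} rows but sequence "
                f"has {len(sequence)} residues"
            )
        mismatches = [
            i for i, (a, b) in enumerate(zip(residue_str, sequence)) if a != b
        ]
        if mismatches:
            msg = (
                f"{path}: PSSM residue column differs from sequence at "
                f"{len(mismatches)} position(s), first at {mismatches[0] + 1}"
            )
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg)

    return PSSMProfile(chain_id or path.stem, scores, residue_str)


def write_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (percentage block zeroed)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        cols = "  ".join(PSSM_ALPHABET)
        fh.write("           " + "   ".join(PSSM_ALPHABET) + "   " + cols + "\n")
        for i, (aa, row) in enumerate(zip(profile.residues, profile.scores), start=1):
            logodds = " ".join(f"{int(v):3d}" for v in row)
            pct = " ".join(f"{0:3d}" for _ in range(20))
            fh.write(f"{i:5d} {aa} {logodds}  {pct}  0.00 0.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# AAindex1
# ---------------------------------------------------------------------------

@dataclass
class PCPTable:
    """Physicochemical property table parsed from an AAindex1 flat file.

    ``values`` is an ``n_properties × 20`` array with columns in
    :data:`STANDARD_AA` order.  Properties with missing ("NA") values are
    imputed according to ``imputation_policy`` (default: mean of the defined
    amino acids, which keeps each property on its own scale).
    """

    accessions: list[str]
    descriptions: list[str]
    values: np.ndarray
    imputation_policy: str = "mean"
    imputed: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.accessions), 20):
            raise ValidationError(
                f"PCP table shape {self.values.shape} does not match "
                f"{len(self.accessions)} accessions × 20 amino acids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("PCP table contains undefined values after imputation")
        self._index = {aa: i for i, aa in enumerate(STANDARD_AA)}

    @property
    def n_properties(self) -> int:
        return len(self.accessions)

    def vector_for(self, aa: str) -> np.ndarray:
        """Property vector for one amino acid; non-standard letters get the
        per-property mean (a neutral value on each property's own scale)."""
        i = self._index.get(aa)
        if i is None:
            return self.values.mean(axis=1)
        return self.values[:, i]


def read_aaindex(
    path: str | Path,
    accessions: Sequence[str] | None = None,
    expected_count: int | None = None,
    imputation: str = "mean",
    strict: bool = False,
) -> PCPTable:
    """Parse an AAindex1 flat file into a :class:`PCPTable`.

    ``accessions`` optionally selects (and orders) a subset — this is how a
    curated property list is plugged in.  ``expected_count`` validates the
    size of the retained set (e.g. 553 for the full physicochemical channel);
    a shortfall raises under ``strict`` and warns otherwise.
    """
    path = Path(path)
    entries: list[tuple[str, str, list[float | None]]] = []
    acc = desc = None
    ivals: list[float | None] = []
    in_i = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("H "):
            acc = line[2:].strip()
            desc = ""
            ivals = []
            in_i = False
        elif line.startswith("D "):
            desc = line[2:].strip()
        elif line.startswith("I "):
            in_i = True
        elif line.startswith("//"):
            if acc is not None:
                if len(ivals) != 20:
                    raise FormatError(
                        f"{path}:{lineno}: I block of {acc} has {len(ivals)} "
                        "values, expected 20"
                    )
                entries.append((acc, desc or "", ivals))
            acc = None
            in_i = False
        elif in_i and line[:1].isspace():
            for tok in line.split():
                if tok.upper() in ("NA", "NA."):
                    ivals.append(None)
                else:
                    try:
                        ivals.append(float(tok))
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}:{lineno}: bad I-block value {tok!r}"
                        ) from exc
        else:
            in_i = False
    if not entries:
        raise FormatError(f"{path}: no AAindex entries found")

    by_acc = {a: (a, d, v) for a, d, v in entries}
    if accessions is not None:
        missing = [a for a in accessions if a not in by_acc]
        if missing:
            msg = f"{path}: configured accessions not found: {missing}"
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg)
        entries = [by_acc[a] for a in accessions if a in by_acc]

    kept_acc: list[str] = []
    kept_desc: list[str] = []
    rows: list[np.ndarray] = []
    imputed: dict[str, list[str]] = {}
    # I-block order: row1 = A R N D C Q E G H I, row2 = L K M F P S T W Y V.
    file_order = _AAINDEX_ROW1 + _AAINDEX_ROW2
    for a, d, vals in entries:
        arr = np.array([math.nan if v is None else v for v in vals], dtype=float)
        nas = [file_order[i] for i in range(20) if vals[i] is None]
        if nas:
            if len(nas) == 20 or imputation == "drop":
                warnings.warn(f"{path}: property {a} dropped ({len(nas)} NA values)")
                continue
            if imputation == "mean":
                arr[np.isnan(arr)] = np.nanmean(arr)
                imputed[a] = nas
            else:
                raise ValueError(f"unknown imputation policy {imputation!r}")
        # reorder file layout -> alphabetical STANDARD_AA
        perm = [file_order.index(aa) for aa in STANDARD_AA]
        kept_acc.append(a)
        kept_desc.append(d)
        rows.append(arr[perm])

    if expected_count is not None and len(kept_acc) != expected_count:
        msg = (
            f"{path}: {len(kept_acc)} usable properties, expected {expected_count}"
        )
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg)

    return PCPTable(kept_acc, kept_desc, np.vstack(rows), imputation, imputed)


def write_aaindex(table: PCPTable, path: str | Path) -> None:
    """Write a PCP table back to the AAindex1 dialect."""
    file_order = _AAINDEX_ROW1 + _AAINDEX_ROW2
    perm = [STANDARD_AA.index(aa) for aa in file_order]
    with open(path, "w") as fh:
        for acc, desc, row in zip(table.accessions, table.descriptions, table.values):
            vals = row[perm]
            fh.write(f"H {acc}\n")
            fh.write(f"D {desc}\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     Q/S     "
                     "E/T     G/W     H/Y     I/V\n")
            fh.write("   " + " ".join(f"{v:8.4f}" for v in vals[:10]) + "\n")
            fh.write("   " + " ".join(f"{v:8.4f}" for v in vals[10:]) + "\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class TopologyTrack:
    """Per-residue three-state membrane topology."""

    chain_id: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = sorted({s for s in self.states if s not in TOPOLOGY_STATES})
        if bad:
            raise ValidationError(f"unknown topology states: {bad}")

    def __len__(self) -> int:
        return len(self.states)

    def one_hot(self) -> np.ndarray:
        """L×3 one-hot matrix, columns in :data:`TOPOLOGY_STATES` order."""
        idx = np.array([TOPOLOGY_STATES.index(s) for s in self.states])
        out = np.zeros((len(self.states), 3))
        out[np.arange(len(idx)), idx] = 1.0
        return out


def _normalize_state(raw: str) -> str:
    state = _STATE_SYNONYMS.get(raw.strip().lower())
    if state is None:
        raise FormatError(f"unknown topology state {raw!r}")
    return state


def read_topology(
    path: str | Path,
    dialect: str = "auto",
    chain_id: str | None = None,
) -> TopologyTrack:
    """Read a topology track from TMHMM long-format output or per-residue TSV.

    Long-format segments (1-based inclusive ranges) must tile 1..L exactly;
    gaps, overlaps or out-of-order segments are errors.
    """
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if dialect == "auto":
        body = [l for l in lines if not l.startswith("#")]
        dialect = "tmhmm_long" if body and len(body[0].split()) >= 5 else "tsv"

    if dialect == "tmhmm_long":
        segments: list[tuple[str, int, int]] = []
        cid = chain_id
        for line in lines:
            if line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 5:
                raise FormatError(f"{path}: malformed segment line {line!r}")
            cid = cid or toks[0]
            segments.append((_normalize_state(toks[2]), int(toks[3]), int(toks[4])))
        if not segments:
            raise FormatError(f"{path}: no topology segments found")
        expected_start = 1
        states: list[str] = []
        for state, start, end in segments:
            if start != expected_start:
                kind = "overlap" if start < expected_start else "gap"
                raise FormatError(
                    f"{path}: segment {kind} at position {start} "
                    f"(expected {expected_start})"
                )
            if end < start:
                raise FormatError(f"{path}: segment end {end} before start {start}")
            states.extend([state] * (end - start + 1))
            expected_start = end + 1
        return TopologyTrack(cid or path.stem, tuple(states))

    # per-residue TSV: position <tab> state
    rows: list[tuple[int, str]] = []
    for line in lines:
        if line.startswith("#") or line.lower().startswith("position"):
            continue
        toks = line.split("\t") if "\t" in line else line.split()
        if len(toks) < 2:
            raise FormatError(f"{path}: malformed TSV line {line!r}")
        rows.append((int(toks[0]), _normalize_state(toks[1])))
    rows.sort()
    positions = [p for p, _ in rows]
    if positions != list(range(1, len(rows) + 1)):
        raise FormatError(f"{path}: positions are not a complete 1..L run")
    return TopologyTrack(chain_id or path.stem, tuple(s for _, s in rows))


def write_topology(track: TopologyTrack, path: str | Path) -> None:
    """Write a topology track as per-residue TSV."""
    with open(path, "w") as fh:
        fh.write("position\tstate\n")
        for i, state in enumerate(track.states, start=1):
            fh.write(f"{i}\t{state}\n")


# ---------------------------------------------------------------------------
# Scalar tracks
# ---------------------------------------------------------------------------

@dataclass
class ScalarTrack:
    """Per-residue scalar feature (rASA in [0,1] or membrane Z-coordinate in Å)."""

    chain_id: str
    kind: str  # "rASA" | "Zcoord"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("rASA", "Zcoord"):
            raise ValidationError(f"unknown scalar track kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("scalar track must be one-dimensional")
        if self.kind == "rASA" and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise ValidationError("rASA values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


def read_scalar_track(path: str | Path, kind: str, chain_id: str | None = None) -> ScalarTrack:
    """Read a two-column (position, value) TSV into a :class:`ScalarTrack`."""
    path = Path(path)
    rows: list[tuple[int, float]] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.lower().startswith("position"):
            continue
        toks = line.split("\t") if "\t" in line else line.split()
        if len(toks) < 2:
            raise FormatError(f"{path}: malformed track line {line!r}")
        rows.append((int(toks[0]), float(toks[1])))
    if not rows:
        raise FormatError(f"{path}: empty scalar track")
    rows.sort()
    positions = [p for p, _ in rows]
    if positions != list(range(1, len(rows) + 1)):
        missing = sorted(set(range(1, max(positions) + 1)) - set(positions))
        raise FormatError(f"{path}: positions missing or duplicated (missing {missing[:5]}…)")
    return ScalarTrack(chain_id or path.stem, kind, np.array([v for _, v in rows]))


def write_scalar_track(track: ScalarTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tvalue\n")
        for i, v in enumerate(track.values, start=1):
            fh.write(f"{i}\t{v:.6f}\n")


# ---------------------------------------------------------------------------
# Prediction TSV
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = [
    "chain",
    "position",
    "residue",
    "stage1_prob",
    "stage1_label",
    "assigned_class",
    "prob_K",
    "prob_Ca",
    "prob_Na",
    "prob_Zn",
    "prob_Mg",
    "prob_Hg",
    "prob_Others",
]


def write_predictions(records: Iterable[Mapping], path: str | Path) -> None:
    """Write per-residue cascade predictions as TSV.

    ``records`` are mappings with the :data:`PREDICTION_COLUMNS` keys;
    class probabilities may be ``None`` for residues the stage-1 gate
    rejected (written as empty fields).  Floats are written with fixed
    precision so identical predictions serialize byte-identically.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for rec in records:
            row = []
            for col in PREDICTION_COLUMNS:
                val = rec.get(col)
                if val is None:
                    row.append("")
                elif isinstance(val, float):
                    row.append(f"{val:.6f}")
                else:
                    row.append(str(val))
            fh.write("\t".join(row) + "\n")


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "residue": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: prediction TSV missing columns {missing}")
    return df
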