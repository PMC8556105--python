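"""Synthetic fixtures: complete pipeline inputs with plantable signal.

The generator emits everything the real pipeline consumes — sequences,
PSI-BLAST-dialect PSSMs, an AAindex-dialect property table, rASA / Z-coordinate
/ topology tracks, and per-residue binding labels — with controllable
statistical structure:

* ``binding_rate`` residues are binding, each assigned one of the seven ion
  classes from ``class_mixture``;
* a mean shift of ``effect_size`` background standard deviations is planted
  at binding positions in the chosen ``signal_channels``.  In the PSSM
  channel the shift is added across the whole profile row (so stage 1 can
  detect binding) and doubled again on the binding class's own disjoint pair
  of columns (class k owns columns 2k and 2k+1), giving stage 2 a class
  contrast of ``2·effect_size·σ`` against the rest of the row;
* at ``effect_size = 0`` labels carry no feature information at all — the
  null for permutation-style checks.

Everything is drawn from a single seeded generator; the same spec and seed
reproduce byte-identical files.  A companion helper writes toy PDB structures
with metals at scripted distances for exercising curation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .curation import ION_CLASSES, ProteinChain
from .dataset import Dataset, save_dataset
from .features import CHANNELS
from .io_formats import (
    PCPTable,
    PSSMProfile,
    STANDARD_AA,
    ScalarTrack,
    TOPOLOGY_STATES,
    TopologyTrack,
)

__all__ = ["FixtureSpec", "generate_dataset", "generate_toy_structure",
           "CLASS_SIGNATURE_COLUMNS"]

#: Disjoint PSSM columns carrying each class's planted signal.
CLASS_SIGNATURE_COLUMNS = {cls: (2 * k, 2 * k + 1) for k, cls in enumerate(ION_CLASSES)}

#: Class-preferred amino acids used when signal is planted in the PCP channel
#: (composition bias — the PCP features are deterministic in the letter).
_CLASS_RESIDUES = {"K": "ST", "Ca": "DE", "Na": "GA", "Zn": "CH",
                   "Mg": "DN", "Hg": "CM", "Others": "WY"}

#: Representative raw species code per class, for the label file.
_CLASS_ION = {"K": "K", "Ca": "CA", "Na": "NA", "Zn": "ZN",
              "Mg": "MG", "Hg": "HG", "Others": "FE"}

_PSSM_SIGMA = 2.0   # background log-odds spread
_RASA_SIGMA = 0.15  # rASA shift unit
_CLIP = 16          # PSSM integer clip (wide enough not to truncate signal)


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of a synthetic study.

    Defaults are desk-scale study conditions: 30 membrane-protein-like chains
    of 60–120 residues, 5% binding residues spread uniformly over the seven
    classes, and a 3σ signal planted in the evolutionary (PSSM) channel only.
    """

    n_chains: int = 30
    length_range: tuple[int, int] = (60, 120)
    binding_rate: float = 0.05
    class_mixture: tuple[float, ...] = (1 / 7,) * 7
    effect_size: float = 3.0
    signal_channels: tuple[str, ...] = ("PSSM",)
    n_pcp: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.binding_rate < 1:
            raise ValueError("binding_rate must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if len(self.class_mixture) != 7 or abs(sum(self.class_mixture) - 1) > 1e-9:
            raise ValueError("class_mixture must be 7 proportions summing to 1")
        bad = set(self.signal_channels) - set(CHANNELS)
        if bad:
            raise ValueError(f"unknown signal channels {sorted(bad)}")
        if self.length_range[0] < 3 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length_range")
        if self.n_pcp < 1:
            raise ValueError("n_pcp must be positive")


def _topology_states(L: int, rng: np.random.Generator) -> list[str]:
    """Alternating inside → membrane → outside → membrane → … segments."""
    loop = ["inside", "outside"]
    side = int(rng.integers(2))
    states: list[str] = []
    while len(states) < L:
        states += [loop[side]] * int(rng.integers(5, 16))
        if len(states) >= L:
            break
        states += ["membrane"] * int(rng.integers(15, 26))
        side = 1 - side
    return states[:L]


def _zcoord_from_topology(states: list[str], rng: np.random.Generator) -> np.ndarray:
    """Depths consistent with topology: |Z| < 13 Å inside the membrane,
    inside-side residues negative, outside-side positive."""
    z = np.empty(len(states))
    for i, s in enumerate(states):
        if s == "membrane":
            z[i] = rng.uniform(-13, 13)
        elif s == "inside":
            z[i] = -rng.uniform(13, 40)
        else:
            z[i] = rng.uniform(13, 40)
    return z


def generate_dataset(
    spec: FixtureSpec = FixtureSpec(),
    out_dir: str | Path | None = None,
) -> Dataset:
    """Generate a full synthetic dataset; optionally write it to disk in the
    exact dialects the readers expect."""
    rng = np.random.default_rng(spec.seed)
    eff = spec.effect_size
    p_bias = eff / (eff + 1.0)  # composition/state bias for categorical channels

    # shared property table
    pcp = PCPTable(
        [f"SYN{i + 1:03d}" for i in range(spec.n_pcp)],
        [f"synthetic property {i + 1}" for i in range(spec.n_pcp)],
        rng.normal(0.0, 1.0, size=(spec.n_pcp, 20)),
    )

    chains: list[ProteinChain] = []
    pssms: dict[str, PSSMProfile] = {}
    rasa: dict[str, ScalarTrack] = {}
    zcoord: dict[str, ScalarTrack] = {}
    topo: dict[str, TopologyTrack] = {}
    aa = np.array(list(STANDARD_AA))

    for ci in range(spec.n_chains):
        cid = f"syn{ci:03d}_A"
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        binding = rng.random(L) < spec.binding_rate
        classes = rng.choice(len(ION_CLASSES), size=L, p=spec.class_mixture)

        letters = aa[rng.integers(0, 20, size=L)].tolist()
        states = _topology_states(L, rng)
        r = rng.uniform(0.0, 1.0, size=L)
        scores = rng.normal(0.0, _PSSM_SIGMA, size=(L, 20))

        label_sets: list[frozenset] = []
        ion_sets: list[frozenset] = []
        for i in range(L):
            if not binding[i]:
                label_sets.append(frozenset())
                ion_sets.append(frozenset())
                continue
            cls = ION_CLASSES[classes[i]]
            label_sets.append(frozenset([cls]))
            ion_sets.append(frozenset([_CLASS_ION[cls]]))
            if "PSSM" in spec.signal_channels:
                scores[i, :] += eff * _PSSM_SIGMA  # row-wide: binding signal
                for col in CLASS_SIGNATURE_COLUMNS[cls]:
                    # class signature: contrast of 2·eff·σ against the rest of
                    # the row, so detection and class assignment are comparably
                    # separable at a given effect size
                    scores[i, col] += 2 * eff * _PSSM_SIGMA

            if "PCP" in spec.signal_channels and rng.random() < p_bias:
                letters[i] = _CLASS_RESIDUES[cls][int(rng.integers(2))]
            if "rASA" in spec.signal_channels:
                r[i] = min(1.0, r[i] + eff * _RASA_SIGMA)
            if "TOPO" in spec.signal_channels and rng.random() < p_bias:
                states[i] = "membrane"

        z = _zcoord_from_topology(states, rng)
        if "Zcoord" in spec.signal_channels and eff > 0:
            z[binding] = rng.normal(0.0, 3.0, size=int(binding.sum()))

        seq = "".join(letters)
        chains.append(ProteinChain(cid, seq, label_sets, ion_sets))
        pssms[cid] = PSSMProfile(
            cid, np.clip(np.rint(scores), -_CLIP, _CLIP).astype(np.int64), seq
        )
        rasa[cid] = ScalarTrack(cid, "rASA", r)
        zcoord[cid] = ScalarTrack(cid, "Zcoord", z)
        topo[cid] = TopologyTrack(cid, tuple(states))

    manifest = {
        "generator": "metalsite.synthetic.generate_dataset",
        "spec": {**asdict(spec),
                 "length_range": list(spec.length_range),
                 "class_mixture": list(spec.class_mixture),
                 "signal_channels": list(spec.signal_channels)},
        "n_binding": int(sum(c.n_binding for c in chains)),
        "n_residues": int(sum(len(c) for c in chains)),
    }
    ds = Dataset(chains, pssms, pcp, rasa, zcoord, topo, manifest)
    if out_dir is not None:
        save_dataset(ds, out_dir)
    return ds


# ---------------------------------------------------------------------------
# Toy structures for curation
# ---------------------------------------------------------------------------

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z, element,
              hetatm=False) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    aligned = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:5d} {aligned:<4s}{'':1s}{resname:>3s} {chain:1s}"
        f"{resseq:4d}{'':1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def generate_toy_structure(
    path: str | Path,
    n_residues: int = 60,
    contacts: list[tuple[int, str, float]] | None = None,
    cutoff: float = 3.5,
    seed: int = 0,
) -> dict[int, frozenset[str]]:
    """Write a PDB file with metals at scripted distances; return the
    ground-truth labels.

    ``contacts`` is a list of (0-based residue index, species code, distance
    in Å from that residue's CA).  The default script places three metals
    inside the cutoff (2.0 Å, 2.8 Å, cutoff−0.05) and two decoys just outside
    (cutoff+0.1, cutoff+1.0).  Residues are spaced 6 Å apart with each metal
    on the z-axis of its residue's CA, so the scripted distance *is* the
    minimum heavy-atom distance.  Truth: residue labeled iff distance is
    strictly below the cutoff.
    """
    if contacts is None:
        contacts = [
            (5, "ZN", 2.0),
            (15, "NA", 2.8),
            (25, "CA", cutoff - 0.05),
            (35, "MG", cutoff + 0.1),
            (45, "K", cutoff + 1.0),
        ]
    rng = np.random.default_rng(seed)
    letters = [STANDARD_AA[int(i)] for i in rng.integers(0, 20, size=n_residues)]

    from .curation import group_ion_class

    truth: dict[int, set[str]] = {}
    lines: list[str] = []
    serial = 1
    for i, letter in enumerate(letters):
        x0 = 6.0 * i
        res = _AA3[letter]
        for name, dx, dy, el in (
            ("N", -1.2, 0.8, "N"),
            ("CA", 0.0, 0.0, "C"),
            ("C", 1.2, 0.7, "C"),
            ("O", 1.9, 1.6, "O"),
        ):
            lines.append(
                _pdb_atom(serial, name, res, "A", i + 1, x0 + dx, dy, 0.0, el)
            )
            serial += 1
    lines.append(f"TER   {serial:5d}      {_AA3[letters[-1]]:>3s} A{n_residues:4d}\n")
    serial += 1
    for ri, species, dist in contacts:
        if not 0 <= ri < n_residues:
            raise ValueError(f"contact residue {ri} outside the chain")
        lines.append(
            _pdb_atom(serial, species, species, "M", serial, 6.0 * ri, 0.0,
                      dist, species, hetatm=True)
        )
        serial += 1
        if dist < cutoff:
            truth.setdefault(ri, set()).add(group_ion_class(species))
    lines.append("END\n")
    Path(path).write_text("".join(lines))
    return {i: frozenset(s) for i, s in truth.items()}
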