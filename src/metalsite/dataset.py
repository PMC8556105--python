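"""On-disk dataset bundle: sequences, labels, profiles, tracks, property table.

A dataset directory — written by the synthetic generator or the curation
pipeline, and read by featurize/train/predict — looks like::

    dataset/
      sequences.fasta
      labels.tsv              # chain, position (1-based), classes, ions
      aaindex.txt             # AAindex1 property table
      pssm/<chain>.pssm       # PSI-BLAST ASCII dialect
      tracks/<chain>.rasa.tsv
      tracks/<chain>.zcoord.tsv
      tracks/<chain>.topo.tsv
      manifest.json

Every file uses the dialects of :mod:`metalsite.io_formats`, so a round trip
through this module is exercised by the same parsers real inputs go through.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .curation import ProteinChain
from .features import CHANNELS, FeatureMatrix, assemble_features
from .io_formats import (
    PCPTable,
    PSSMProfile,
    ScalarTrack,
    TopologyTrack,
    read_aaindex,
    read_fasta,
    read_pssm,
    read_scalar_track,
    read_topology,
    write_aaindex,
    write_fasta,
    write_pssm,
    write_scalar_track,
    write_topology,
)

__all__ = ["Dataset", "save_dataset", "load_dataset"]


@dataclass
class Dataset:
    chains: list[ProteinChain]
    pssms: dict[str, PSSMProfile]
    pcp: PCPTable
    rasa: dict[str, ScalarTrack]
    zcoord: dict[str, ScalarTrack]
    topo: dict[str, TopologyTrack]
    manifest: dict = field(default_factory=dict)

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def subset(self, ids: Sequence[str]) -> "Dataset":
        keep = set(ids)
        return Dataset(
            [c for c in self.chains if c.chain_id in keep],
            {k: v for k, v in self.pssms.items() if k in keep},
            self.pcp,
            {k: v for k, v in self.rasa.items() if k in keep},
            {k: v for k, v in self.zcoord.items() if k in keep},
            {k: v for k, v in self.topo.items() if k in keep},
            dict(self.manifest),
        )

    def assemble(self, channels: Sequence[str] = CHANNELS) -> dict[str, FeatureMatrix]:
        """Feature matrices for every chain, one call per chain."""
        out: dict[str, FeatureMatrix] = {}
        for chain in self.chains:
            cid = chain.chain_id
            out[cid] = assemble_features(
                chain,
                pssm=self.pssms.get(cid),
                pcp_table=self.pcp,
                rasa=self.rasa.get(cid),
                zcoord=self.zcoord.get(cid),
                topo=self.topo.get(cid),
                channels=channels,
            )
        return out


def save_dataset(ds: Dataset, directory: str | Path) -> None:
    directory = Path(directory)
    (directory / "pssm").mkdir(parents=True, exist_ok=True)
    (directory / "tracks").mkdir(exist_ok=True)

    write_fasta([(c.chain_id, c.sequence) for c in ds.chains],
                directory / "sequences.fasta")
    with open(directory / "labels.tsv", "w") as fh:
        fh.write("chain\tposition\tclasses\tions\n")
        for c in ds.chains:
            for i, (classes, ions) in enumerate(zip(c.label_sets, c.source_ions)):
                if classes:
                    fh.write(
                        f"{c.chain_id}\t{i + 1}\t{','.join(sorted(classes))}"
                        f"\t{','.join(sorted(ions))}\n"
                    )
    write_aaindex(ds.pcp, directory / "aaindex.txt")
    for cid, pssm in ds.pssms.items():
        write_pssm(pssm, directory / "pssm" / f"{cid}.pssm")
    for cid, tr in ds.rasa.items():
        write_scalar_track(tr, directory / "tracks" / f"{cid}.rasa.tsv")
    for cid, tr in ds.zcoord.items():
        write_scalar_track(tr, directory / "tracks" / f"{cid}.zcoord.tsv")
    for cid, tr in ds.topo.items():
        write_topology(tr, directory / "tracks" / f"{cid}.topo.tsv")
    (directory / "manifest.json").write_text(
        json.dumps(ds.manifest, indent=2, sort_keys=True)
    )


def load_dataset(directory: str | Path, strict: bool = False) -> Dataset:
    directory = Path(directory)
    records = read_fasta(directory / "sequences.fasta")

    labels: dict[str, dict[int, tuple[frozenset, frozenset]]] = {}
    labels_path = directory / "labels.tsv"
    if labels_path.exists():
        for line in labels_path.read_text().splitlines()[1:]:
            if not line.strip():
                continue
            chain, pos, classes, ions = (line.split("\t") + ["", ""])[:4]
            labels.setdefault(chain, {})[int(pos) - 1] = (
                frozenset(classes.split(",")) if classes else frozenset(),
                frozenset(ions.split(",")) if ions else frozenset(),
            )

    chains = []
    pssms: dict[str, PSSMProfile] = {}
    rasa: dict[str, ScalarTrack] = {}
    zcoord: dict[str, ScalarTrack] = {}
    topo: dict[str, TopologyTrack] = {}
    for rec in records:
        per_res = labels.get(rec.id, {})
        label_sets = [per_res.get(i, (frozenset(), frozenset()))[0]
                      for i in range(len(rec.sequence))]
        ion_sets = [per_res.get(i, (frozenset(), frozenset()))[1]
                    for i in range(len(rec.sequence))]
        chains.append(ProteinChain(rec.id, rec.sequence, label_sets, ion_sets))
        pssm_path = directory / "pssm" / f"{rec.id}.pssm"
        if pssm_path.exists():
            pssms[rec.id] = read_pssm(pssm_path, rec.id, rec.sequence, strict=strict)
        for kind, store, suffix in (
            ("rASA", rasa, "rasa"),
            ("Zcoord", zcoord, "zcoord"),
        ):
            p = directory / "tracks" / f"{rec.id}.{suffix}.tsv"
            if p.exists():
                store[rec.id] = read_scalar_track(p, kind, rec.id)
        p = directory / "tracks" / f"{rec.id}.topo.tsv"
        if p.exists():
            topo[rec.id] = read_topology(p, chain_id=rec.id)

    pcp = read_aaindex(directory / "aaindex.txt", strict=strict)
    manifest_path = directory / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    return Dataset(chains, pssms, pcp, rasa, zcoord, topo, manifest)
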