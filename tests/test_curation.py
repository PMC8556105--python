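"""Curation: contact labeling vs a brute-force oracle, filters, grouping,
redundancy removal."""

import math
import random

import pytest

from metalsite.curation import (
    CurationConfig,
    CurationError,
    ProteinChain,
    apply_chain_filters,
    dataset_manifest,
    deduplicate_by_identity,
    group_ion_class,
    label_binding_residues,
    pairwise_identity,
    parse_clstr,
)
from metalsite.synthetic import generate_toy_structure


def brute_force_labels(pdb_path, cutoff=3.5):
    """Independent oracle: hand-parse the PDB text and do an exhaustive
    all-pairs atom-metal distance scan (no gemmi, no numpy)."""
    metals = []
    atoms = []  # (residue_index, x, y, z)
    metal_species = {"K", "CA", "NA", "ZN", "MG", "HG", "CU", "CU1", "W", "CD",
                     "NI", "FE", "FE2", "MN", "RB", "AU", "CS", "PB", "PT",
                     "SR", "LI", "CO", "PR", "MO"}
    for line in open(pdb_path):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        name = line[12:16].strip()
        resname = line[17:20].strip()
        x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
        element = line[76:78].strip()
        if line.startswith("HETATM") and resname in metal_species:
            metals.append((resname, (x, y, z)))
        elif line.startswith("ATOM") and element != "H":
            atoms.append((int(line[22:26]) - 1, (x, y, z)))
    labels = {}
    for ri, (ax, ay, az) in atoms:
        for species, (mx, my, mz) in metals:
            d = math.sqrt((ax - mx) ** 2 + (ay - my) ** 2 + (az - mz) ** 2)
            if d < cutoff:
                labels.setdefault(ri, set()).add(group_ion_class(species))
    return {k: frozenset(v) for k, v in labels.items()}


class TestContactLabeling:
    def test_matches_brute_force_on_default_script(self, tmp_path):
        path = tmp_path / "toy.pdb"
        truth = generate_toy_structure(path, n_residues=60, seed=0)
        (chain,) = label_binding_residues(path)
        got = {i: s for i, s in enumerate(chain.label_sets) if s}
        assert got == truth
        assert got == brute_force_labels(path)

    def test_boundary_is_exclusive(self, tmp_path):
        cutoff = 3.5
        contacts = [
            (3, "ZN", cutoff - 0.01),
            (10, "MG", cutoff),         # exactly at the cutoff: not binding
            (20, "K", cutoff + 0.01),
        ]
        path = tmp_path / "edge.pdb"
        truth = generate_toy_structure(path, n_residues=55, contacts=contacts,
                                       cutoff=cutoff, seed=1)
        (chain,) = label_binding_residues(path, CurationConfig(contact_cutoff=cutoff))
        got = {i: s for i, s in enumerate(chain.label_sets) if s}
        assert set(got) == {3}
        assert got == truth == brute_force_labels(path, cutoff)

    def test_multi_metal_residue_records_both_classes(self, tmp_path):
        contacts = [(7, "NA", 2.0), (7, "ZN", 3.0)]
        path = tmp_path / "multi.pdb"
        generate_toy_structure(path, n_residues=55, contacts=contacts, seed=2)
        (chain,) = label_binding_residues(path)
        assert chain.label_sets[7] == frozenset({"Na", "Zn"})
        assert chain.source_ions[7] == frozenset({"NA", "ZN"})
        assert {i: s for i, s in enumerate(chain.label_sets) if s} == \
            brute_force_labels(path)

    def test_atom_order_permutation_is_irrelevant(self, tmp_path):
        path = tmp_path / "toy.pdb"
        generate_toy_structure(path, n_residues=55, seed=3)
        lines = path.read_text().splitlines(keepends=True)
        # shuffle atom order within each residue and reorder the metal
        # records (residues must stay contiguous for the file to be valid)
        groups: dict[tuple, list[str]] = {}
        order = []
        other = []
        for l in lines:
            if l.startswith(("ATOM", "HETATM")):
                key = (l[21], l[22:26])
                if key not in groups:
                    groups[key] = []
                    order.append(key)
                groups[key].append(l)
            else:
                other.append(l)
        rng = random.Random(0)
        for g in groups.values():
            rng.shuffle(g)
        metal_keys = [k for k in order if k[0] == "M"]
        rng.shuffle(metal_keys)
        protein_keys = [k for k in order if k[0] != "M"]
        shuffled = tmp_path / "shuffled.pdb"
        shuffled.write_text(
            "".join("".join(groups[k]) for k in metal_keys + protein_keys)
            + "".join(other)
        )
        a = label_binding_residues(path)[0]
        b = label_binding_residues(shuffled)[0]
        assert a.label_sets == b.label_sets

    def test_structure_without_metals_rejected(self, tmp_path):
        path = tmp_path / "apo.pdb"
        generate_toy_structure(path, n_residues=55, contacts=[], seed=4)
        with pytest.raises(CurationError, match="no recognized metal"):
            label_binding_residues(path)


class TestIonClassGrouping:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("ZN", "Zn"), ("K", "K"), ("CA", "Ca"), ("NA", "Na"),
            ("MG", "Mg"), ("HG", "Hg"),
            ("FE", "Others"), ("FE2", "Others"), ("CU", "Others"),
            ("CU1", "Others"), ("MO", "Others"), ("SR", "Others"),
        ],
    )
    def test_seven_class_grouping(self, code, expected):
        assert group_ion_class(code) == expected

    def test_unknown_species_lists_recognized(self):
        with pytest.raises(CurationError, match="XX"):
            group_ion_class("XX")


def _chain(cid, length, n_binding):
    labels = [frozenset({"Zn"}) if i < n_binding else frozenset()
              for i in range(length)]
    ions = [frozenset({"ZN"}) if i < n_binding else frozenset()
            for i in range(length)]
    return ProteinChain(cid, "A" * length, labels, ions)


class TestChainFilters:
    def test_length_50_removed_51_kept(self):
        chains = [_chain("a", 50, 3), _chain("b", 51, 3), _chain("c", 200, 1)]
        kept = apply_chain_filters(chains)
        assert [c.chain_id for c in kept] == ["b", "c"]

    def test_zero_binding_removed(self):
        with pytest.warns(UserWarning):
            assert apply_chain_filters([_chain("a", 100, 0)]) == []

    def test_monotone_and_idempotent(self):
        chains = [_chain(f"c{i}", 40 + 5 * i, i % 3) for i in range(10)]
        once = apply_chain_filters(chains)
        assert set(c.chain_id for c in once) <= set(c.chain_id for c in chains)
        assert apply_chain_filters(once) == once


class TestDeduplication:
    def test_identical_sequences_collapse(self):
        a = _chain("a", 60, 2)
        b = _chain("b", 60, 2)
        kept = deduplicate_by_identity([a, b])
        assert len(kept) == 1

    def test_disjoint_alphabet_pair_both_kept(self):
        """Two sequences sharing exactly 30% of positions (disjoint alphabets
        elsewhere) sit below the 40% identity threshold."""
        rng = random.Random(5)
        n = 100
        s1 = [rng.choice("ACDE") for _ in range(n)]
        s2 = [rng.choice("FGHI") for _ in range(n)]
        shared = rng.sample(range(n), 30)
        for i in shared:
            s2[i] = s1[i]
        ident = pairwise_identity("".join(s1), "".join(s2))
        assert ident == pytest.approx(0.30, abs=0.02)
        a = ProteinChain("a", "".join(s1),
                         [frozenset({"Zn"})] + [frozenset()] * (n - 1),
                         [frozenset({"ZN"})] + [frozenset()] * (n - 1))
        b = ProteinChain("b", "".join(s2),
                         [frozenset({"Zn"})] + [frozenset()] * (n - 1),
                         [frozenset({"ZN"})] + [frozenset()] * (n - 1))
        assert len(deduplicate_by_identity([a, b])) == 2

    def test_clstr_representatives(self, tmp_path):
        chains = [_chain(f"c{i}", 60 + i, 1) for i in range(7)]
        clstr = tmp_path / "clusters.clstr"
        clstr.write_text(
            ">Cluster 0\n0\t60aa, >c0... *\n1\t61aa, >c1... at 90%\n"
            ">Cluster 1\n0\t62aa, >c2... *\n1\t63aa, >c3... at 80%\n"
            "2\t64aa, >c4... at 70%\n"
            ">Cluster 2\n0\t65aa, >c5... *\n1\t66aa, >c6... at 95%\n"
        )
        kept = deduplicate_by_identity(chains, cluster_file=clstr)
        # longest member of each cluster wins
        assert sorted(c.chain_id for c in kept) == ["c1", "c4", "c6"]

    def test_clstr_unknown_member_rejected(self, tmp_path):
        clstr = tmp_path / "clusters.clstr"
        clstr.write_text(">Cluster 0\n0\t60aa, >ghost... *\n")
        with pytest.raises(CurationError, match="ghost"):
            deduplicate_by_identity([_chain("a", 60, 1)], cluster_file=clstr)

    def test_parse_clstr_counts(self, tmp_path):
        clstr = tmp_path / "c.clstr"
        clstr.write_text(">Cluster 0\n0\t60aa, >x... *\n>Cluster 1\n0\t9aa, >y... *\n")
        assert parse_clstr(clstr) == {0: ["x"], 1: ["y"]}


def test_manifest_counts_per_class(tmp_path):
    path = tmp_path / "toy.pdb"
    generate_toy_structure(path, n_residues=60, seed=0)
    chains = label_binding_residues(path)
    df = dataset_manifest(chains)
    assert df.loc[0, "length"] == 60
    assert df.loc[0, "n_binding"] == 3
    assert df.loc[0, "n_Zn"] == 1 and df.loc[0, "n_Na"] == 1
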