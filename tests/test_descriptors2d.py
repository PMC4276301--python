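"""E-state values, type sums, AI pair counts, matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from thioqsar import descriptors2d as d2
from thioqsar.compound_data import Compound

from conftest import random_tree_molecule


def estate_bruteforce(mol):
    """Independent per-pair double-loop evaluation of the Kier-Hall E-state."""
    heavy = Chem.RemoveHs(mol)
    pt = Chem.GetPeriodicTable()
    n = heavy.GetNumAtoms()
    I = []
    for atom in heavy.GetAtoms():
        zv = pt.GetNOuterElecs(atom.GetAtomicNum())
        dv = zv - atom.GetTotalNumHs()
        z = atom.GetAtomicNum()
        nq = 1 if z <= 2 else 2 if z <= 10 else 3 if z <= 18 else 4
        I.append(((2.0 / nq) ** 2 * dv + 1.0) / atom.GetDegree())
    D = Chem.GetDistanceMatrix(heavy)
    S = []
    for i in range(n):
        di = sum((I[i] - I[j]) / (D[i, j] + 1.0) ** 2 for j in range(n) if j != i)
        S.append(I[i] + di)
    return np.array(I), np.array(S)


class TestEState:
    def test_ethane_symmetric(self, mols):
        res = d2.estate_values(mols["ethane"])
        assert res.values == pytest.approx([2.0, 2.0])
        assert res.perturbation == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_benzene_all_perturbations_zero(self, mols):
        res = d2.estate_values(mols["benzene"])
        assert np.allclose(res.perturbation, 0.0, atol=1e-12)

    def test_propane_matches_bruteforce(self, mols):
        res = d2.estate_values(mols["propane"])
        _, S = estate_bruteforce(mols["propane"])
        assert res.values == pytest.approx(S, abs=1e-12)

    def test_random_molecules_match_bruteforce_and_conserve(self, rng):
        for _ in range(15):
            mol = random_tree_molecule(rng)
            res = d2.estate_values(mol)
            _, S = estate_bruteforce(mol)
            assert res.values == pytest.approx(S, abs=1e-10)
            assert abs(res.perturbation.sum()) < 1e-9

    def test_matches_rdkit_reference(self, mols):
        # independent reference implementation of the same index
        from rdkit.Chem.EState import EStateIndices

        for name in ("propane", "toluene", "chlorobenzene", "thiophene"):
            mine = d2.estate_values(mols[name]).values
            theirs = np.asarray(EStateIndices(mols[name]))
            assert mine == pytest.approx(theirs, abs=1e-8)

    def test_disconnected_rejected(self):
        # two isolated carbons: degree-0 atoms have no defined intrinsic state
        with pytest.raises(ValueError, match="isolated heavy atom"):
            d2.estate_values(Chem.MolFromSmiles("C.C"))
        # two fragments, both with bonds: disconnected distance matrix
        with pytest.raises(ValueError, match="disconnected"):
            d2.estate_values(Chem.MolFromSmiles("CC.CC"))


class TestTypeSums:
    def test_benzene_has_no_sch3(self, mols):
        assert d2.estate_sum_by_type(mols["benzene"], "sCH3") == 0.0

    def test_thiophene_aas_equals_sulfur_value(self, mols):
        res = d2.estate_values(mols["thiophene"])
        s_idx = [a.GetIdx() for a in mols["thiophene"].GetAtoms()
                 if a.GetSymbol() == "S"][0]
        assert d2.estate_sum_by_type(mols["thiophene"], "aaS") == pytest.approx(
            res.values[s_idx]
        )

    def test_toluene_sch3_single_methyl(self, mols):
        res = d2.estate_values(mols["toluene"])
        methyl = [a.GetIdx() for a in mols["toluene"].GetAtoms()
                  if a.GetSymbol() == "C" and a.GetTotalNumHs() == 3][0]
        assert d2.estate_sum_by_type(mols["toluene"], "sCH3") == pytest.approx(
            res.values[methyl]
        )
        assert d2.count_atoms_of_type(mols["toluene"], "sCH3") == 1

    def test_unknown_type_lists_registry(self, mols):
        with pytest.raises(KeyError, match="aaS"):
            d2.estate_sum_by_type(mols["benzene"], "nope")


def ai_bruteforce(mol, attr_a, attr_b, dist):
    """All-pairs BFS oracle over the explicit-hydrogen graph."""
    import networkx as nx

    mol_h = Chem.AddHs(mol)
    g = nx.Graph()
    g.add_nodes_from(range(mol_h.GetNumAtoms()))
    for b in mol_h.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    sp = dict(nx.all_pairs_shortest_path_length(g))

    def matches(i, attr):
        atom = mol_h.GetAtomWithIdx(i)
        if attr == "2":
            return any(b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds())
        if attr == "3":
            return any(b.GetBondType() == Chem.BondType.TRIPLE for b in atom.GetBonds())
        return atom.GetSymbol() == attr

    n = mol_h.GetNumAtoms()
    if dist == 0:
        return sum(1 for i in range(n) if matches(i, attr_a) and matches(i, attr_b))
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if sp[i].get(j) != dist:
                continue
            if (matches(i, attr_a) and matches(j, attr_b)) or (
                matches(i, attr_b) and matches(j, attr_a)
            ):
                count += 1
    return count


class TestAIPairCounts:
    @pytest.mark.parametrize(
        "name,a,b,d,expected",
        [
            ("chlorobenzene", "C", "Cl", 1, 1),
            ("chlorothiophene", "C", "Cl", 1, 1),
            ("tetrachloromethane", "C", "Cl", 1, 4),
            ("tetrachloromethane", "Cl", "Cl", 2, 6),
        ],
    )
    def test_known_counts(self, mols, name, a, b, d, expected):
        assert d2.ai_pair_count(mols[name], a, b, d) == expected

    def test_symmetry_and_bfs_oracle(self, rng):
        cases = [("C", "H", 2), ("C", "O", 1), ("2", "C", 3), ("N", "S", 4)]
        for _ in range(8):
            mol = random_tree_molecule(rng)
            for a, b, d in cases:
                mine = d2.ai_pair_count(mol, a, b, d)
                assert mine == d2.ai_pair_count(mol, b, a, d)
                assert mine == ai_bruteforce(mol, a, b, d)

    def test_distance_zero_counts_atoms(self, mols):
        # atoms that are both C and double-bonded
        mol = Chem.MolFromSmiles("C=CC")
        assert d2.ai_pair_count(mol, "C", "2", 0) == 2

    def test_range_error(self, mols):
        with pytest.raises(ValueError):
            d2.ai_pair_count(mols["benzene"], "C", "C", 8)
        with pytest.raises(KeyError):
            d2.ai_pair_count(mols["benzene"], "C", "X", 1)


class TestAssembleMatrix:
    def _compounds(self, mols, names):
        return [Compound(id=n, mol=mols[n]) for n in names]

    def test_column_count_formula(self, mols):
        X = d2.assemble_matrix(self._compounds(mols, ["toluene", "anisole"]))
        assert len(X.columns) == d2.expected_column_count()
        # 11 attrs -> 66 unordered pairs x 8 distances
        assert sum(c.startswith("T_") for c in X.columns) == 66 * 8

    def test_external_column_flagged(self, mols):
        ext = pd.DataFrame({"LUMO": [0.0, 0.0]}, index=["toluene", "anisole"])
        X = d2.assemble_matrix(self._compounds(mols, ["toluene", "anisole"]), external=ext)
        assert X.provenance["LUMO"] == "external"
        assert X.provenance["SsCH3_sum"] == "computed"

    def test_external_missing_compound_named(self, mols):
        ext = pd.DataFrame({"LUMO": [0.0]}, index=["toluene"])
        with pytest.raises(ValueError, match="anisole"):
            d2.assemble_matrix(self._compounds(mols, ["toluene", "anisole"]), external=ext)

    def test_same_molecule_identical_rows(self, mols):
        comps = [Compound(id="a", mol=mols["toluene"]),
                 Compound(id="b", mol=mols["toluene"])]
        X = d2.assemble_matrix(comps)
        assert np.array_equal(X.df.loc["a"].to_numpy(), X.df.loc["b"].to_numpy())

    def test_reindexing_invariance(self, rng):
        # descriptor rows must not depend on atom numbering
        for _ in range(5):
            mol = random_tree_molecule(rng)
            perm = list(rng.permutation(mol.GetNumAtoms()))
            perm = [int(p) for p in perm]
            renum = Chem.RenumberAtoms(mol, perm)
            a = d2.assemble_matrix([Compound(id="x", mol=mol)])
            b = d2.assemble_matrix([Compound(id="x", mol=renum)])
            assert np.allclose(a.df.to_numpy(), b.df.to_numpy(), atol=1e-10)

    def test_csv_roundtrip(self, mols, tmp_path):
        X = d2.assemble_matrix(self._compounds(mols, ["toluene", "anisole"]))
        p = tmp_path / "desc.csv"
        X.to_csv(p)
        Y = d2.DescriptorMatrix.from_csv(p)
        assert Y.provenance == X.provenance
        assert np.allclose(X.df.to_numpy(), Y.df.to_numpy())


class TestRemoveInvariant:
    def test_planted_constants_removed(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 90)),
                          columns=[f"c{i}" for i in range(90)])
        for i in range(10):
            df[f"k{i}"] = 3.14
        X = d2.DescriptorMatrix(df=df, provenance={c: "computed" for c in df.columns})
        pruned = d2.remove_invariant_columns(X)
        assert len(pruned.columns) == 90
        assert not any(c.startswith("k") for c in pruned.columns)

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
        df["f"] = 1.0
        X = d2.DescriptorMatrix(df=df, provenance={c: "computed" for c in df.columns})
        once = d2.remove_invariant_columns(X)
        twice = d2.remove_invariant_columns(once)
        assert once.columns == twice.columns

    def test_all_constant_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        X = d2.DescriptorMatrix(df=df, provenance={"a": "computed", "b": "computed"})
        with pytest.raises(ValueError, match="constant"):
            d2.remove_invariant_columns(X)
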