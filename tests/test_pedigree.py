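"""Pedigree ordering, inbreeding and relationship-matrix machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herdblup.pedigree import (PedigreeError, build_a_inverse, compute_inbreeding,
                               pedigree_from_frame, read_pedigree, tabular_a_matrix,
                               write_pedigree)
from _oracles import random_pedigree


def frame(rows):
    return pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id"])


class TestReadAndOrder:
    def test_already_ordered_founder_trio(self):
        ped = pedigree_from_frame(frame([("A", "0", "0"), ("B", "0", "0"),
                                         ("C", "A", "B")]))
        assert ped.animals == ["A", "B", "C"]

    def test_reordering_parents_before_offspring(self):
        ped = pedigree_from_frame(frame([("C", "A", "B"), ("A", "0", "0"),
                                         ("B", "0", "0")]))
        assert ped.animals == ["A", "B", "C"]
        assert ped.sire[2] == 0 and ped.dam[2] == 1

    def test_parent_only_animals_materialized_as_founders(self):
        ped = pedigree_from_frame(frame([("C", "A", "B")]))
        assert set(ped.animals) == {"A", "B", "C"}
        assert ped.founder_mask.sum() == 2

    def test_cycle_detection_names_a_member(self):
        with pytest.raises(PedigreeError, match="cycle.*('A'|'B')"):
            pedigree_from_frame(frame([("A", "B", "0"), ("B", "A", "0")]))

    def test_duplicate_id_rejected(self):
        with pytest.raises(PedigreeError, match="duplicate.*'A'"):
            pedigree_from_frame(frame([("A", "0", "0"), ("A", "0", "0")]))

    def test_self_parent_rejected(self):
        with pytest.raises(PedigreeError, match="own parent"):
            pedigree_from_frame(frame([("A", "A", "0")]))

    def test_id_as_both_sire_and_dam_rejected(self):
        with pytest.raises(PedigreeError, match="both as sire and dam"):
            pedigree_from_frame(frame([("X", "P", "0"), ("Y", "0", "P")]))

    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "ped.csv"
        frame([("C", "A", "B"), ("A", "0", "0"), ("B", "0", "0")]).to_csv(
            path, index=False)
        ped = read_pedigree(path)
        out = tmp_path / "ordered.csv"
        write_pedigree(ped, out)
        back = pd.read_csv(out, dtype=str)
        assert list(back["order"].astype(int)) == [0, 1, 2]
        assert list(back["animal_id"]) == ped.animals


class TestInbreeding:
    def test_founders_have_zero_inbreeding(self):
        ped = pedigree_from_frame(frame([("A", "0", "0"), ("B", "0", "0")]))
        assert np.allclose(compute_inbreeding(ped), 0.0)

    def test_sire_daughter_mating(self):
        # X from sire S and S's daughter D: F_X = 0.25 (tabular oracle)
        ped = pedigree_from_frame(frame([("S", "0", "0"), ("D", "S", "0"),
                                         ("X", "S", "D")]))
        f = compute_inbreeding(ped)
        a = tabular_a_matrix(ped)
        assert np.allclose(f, np.diag(a) - 1.0)
        assert f[ped.index["X"]] == pytest.approx(0.25)

    def test_full_sib_mating(self):
        ped = pedigree_from_frame(frame([
            ("A", "0", "0"), ("B", "0", "0"), ("S1", "A", "B"), ("D1", "A", "B"),
            ("X", "S1", "D1")]))
        f = compute_inbreeding(ped)
        assert f[ped.index["X"]] == pytest.approx(0.25)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 60))
    def test_matches_tabular_diagonal(self, seed, n):
        ped = pedigree_from_frame(random_pedigree(np.random.default_rng(seed), n))
        assert np.allclose(compute_inbreeding(ped),
                           np.diag(tabular_a_matrix(ped)) - 1.0, atol=1e-12)

    def test_invariant_to_input_row_order(self):
        rng = np.random.default_rng(7)
        pf = random_pedigree(rng, 40)
        ped1 = pedigree_from_frame(pf)
        ped2 = pedigree_from_frame(pf.sample(frac=1.0, random_state=1))
        f1 = dict(zip(ped1.animals, compute_inbreeding(ped1)))
        f2 = dict(zip(ped2.animals, compute_inbreeding(ped2)))
        assert f1 == pytest.approx(f2)


class TestAInverse:
    def test_single_founder(self):
        ped = pedigree_from_frame(frame([("A", "0", "0")]))
        assert np.allclose(build_a_inverse(ped).a_inverse.toarray(), [[1.0]])

    def test_non_inbred_trio_closed_form(self):
        # invert tabular A = [[1,0,.5],[0,1,.5],[.5,.5,1]]
        ped = pedigree_from_frame(frame([("A", "0", "0"), ("B", "0", "0"),
                                         ("C", "A", "B")]))
        expect = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        assert build_a_inverse(ped).a_inverse.toarray() == pytest.approx(expect)

    def test_single_parent_relationship(self):
        ped = pedigree_from_frame(frame([("A", "0", "0"), ("C", "A", "0")]))
        a = tabular_a_matrix(ped)
        assert a[0, 1] == pytest.approx(0.5)
        assert a[1, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("use_inbreeding", [True, False])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_inverse_of_reference_a(self, seed, use_inbreeding):
        rng = np.random.default_rng(seed)
        ped = pedigree_from_frame(random_pedigree(rng, 50))
        a_inv = build_a_inverse(ped, use_inbreeding=use_inbreeding).a_inverse
        if use_inbreeding:
            a = tabular_a_matrix(ped)
        else:
            # independent reference via the gene-flow factorization A = T D T'
            # with Mendelian-sampling variances taken at F ≡ 0
            n = len(ped)
            P = np.zeros((n, n))
            d = np.ones(n)
            for i in range(n):
                for p in (ped.sire[i], ped.dam[i]):
                    if p >= 0:
                        P[i, p] = 0.5
                        d[i] -= 0.25
            T = np.linalg.inv(np.eye(n) - P)
            a = T @ np.diag(d) @ T.T
        assert np.abs(a_inv.toarray() @ a - np.eye(len(ped))).max() < 1e-8

    def test_symmetry_and_sparsity(self):
        ped = pedigree_from_frame(random_pedigree(np.random.default_rng(3), 80))
        a_inv = build_a_inverse(ped).a_inverse
        assert (abs(a_inv - a_inv.T)).max() < 1e-12
        assert a_inv.nnz <= 9 * len(ped)

    def test_tabular_positive_definite(self):
        ped = pedigree_from_frame(random_pedigree(np.random.default_rng(11), 150))
        w = np.linalg.eigvalsh(tabular_a_matrix(ped))
        assert w.min() > 0

    def test_tabular_refuses_large_pedigrees(self):
        ped = pedigree_from_frame(random_pedigree(np.random.default_rng(0), 30))
        with pytest.raises(PedigreeError, match="oracle"):
            tabular_a_matrix(ped, dense_limit=10)

    def test_unrelated_founder_leaves_entries_unchanged(self):
        rng = np.random.default_rng(5)
        pf = random_pedigree(rng, 30)
        ped1 = pedigree_from_frame(pf)
        pf2 = pd.concat([pf, pd.DataFrame([("ZZZ", "0", "0")],
                                          columns=pf.columns)], ignore_index=True)
        ped2 = pedigree_from_frame(pf2)
        a1, a2 = tabular_a_matrix(ped1), tabular_a_matrix(ped2)
        idx = [ped2.index[a] for a in ped1.animals]
        assert np.allclose(a2[np.ix_(idx, idx)], a1)
        f2 = dict(zip(ped2.animals, compute_inbreeding(ped2)))
        f1 = dict(zip(ped1.animals, compute_inbreeding(ped1)))
        assert all(f2[a] == pytest.approx(f1[a]) for a in ped1.animals)
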