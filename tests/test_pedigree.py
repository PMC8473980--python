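"""Pedigree parsing, ordering, inbreeding, A, A⁻¹, and race fractions."""

import numpy as np
import pandas as pd
import pytest

from hblup.pedigree import (UNKNOWN_RACE, build_A_inverse, build_A_tabular,
                            group_fraction_matrix, inbreeding_meuwissen_luo,
                            merge_pedigrees, partition_A, read_pedigree,
                            topo_sort_validate)

from conftest import coancestry_oracle, make_pedigree, random_pedigree


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _write_ped(tmp_path, text, name="ped.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadPedigree:
    def test_trio_parse(self, tmp_path):
        path = _write_ped(tmp_path,
                          "id,sire,dam,race\nA,0,0,STRZ\nB,0,0,FURNX\nC,A,B,\n")
        p = read_pedigree(path, "EG1")
        assert p.n == 3
        assert sum(p.founder_mask) == 2
        assert p.parents_of("EG1:C") == ("EG1:A", "EG1:B")

    def test_order_invariance(self, tmp_path):
        forward = read_pedigree(_write_ped(
            tmp_path, "id,sire,dam,race\nA,0,0,STRZ\nC,A,0,\n"), "P")
        reverse = read_pedigree(_write_ped(
            tmp_path, "id,sire,dam,race\nC,A,0,\nA,0,0,STRZ\n", "r.csv"), "P")
        assert forward.ids == reverse.ids
        assert forward.parents_of("P:C") == reverse.parents_of("P:C")

    def test_program_namespacing(self, tmp_path):
        text = "id,sire,dam,race\nP001,0,0,STRZ\n"
        p1 = read_pedigree(_write_ped(tmp_path, text, "a.csv"), "EG1")
        p2 = read_pedigree(_write_ped(tmp_path, text, "b.csv"), "EG2")
        joint = merge_pedigrees(p1, p2)
        assert set(joint.ids) == {"EG1:P001", "EG2:P001"}

    def test_duplicate_id_raises(self, tmp_path):
        path = _write_ped(tmp_path, "id,sire,dam,race\nA,0,0,STRZ\nA,0,0,KI\n")
        with pytest.raises(ValueError, match="A"):
            read_pedigree(path, "P")

    def test_undefined_parent_inserted_as_founder(self, tmp_path):
        path = _write_ped(tmp_path, "id,sire,dam,race\nC,S,0,\n")
        with pytest.warns(UserWarning, match="never defined"):
            p = read_pedigree(path, "P")
        k = p.index_of("P:S")
        assert p.is_founder(k) and p.race[k] == UNKNOWN_RACE

    def test_alias_collapses_shared_founders(self, tmp_path):
        alias = pd.DataFrame({"canonical_id": ["SHARED:F1"],
                              "raw_id_EG1": ["A"], "raw_id_EG2": ["Z"]})
        p1 = read_pedigree(_write_ped(
            tmp_path, "id,sire,dam,race\nA,0,0,STRZ\nC,A,0,\n", "1.csv"),
            "EG1", alias=alias)
        p2 = read_pedigree(_write_ped(
            tmp_path, "id,sire,dam,race\nZ,0,0,STRZ\nD,Z,0,\n", "2.csv"),
            "EG2", alias=alias)
        joint = merge_pedigrees(p1, p2)
        assert joint.ids.count("SHARED:F1") == 1
        A = build_A_tabular(joint)
        # half sibs through the shared founder
        assert A.loc("EG1:C", "EG2:D") == pytest.approx(0.25)


class TestTopoSort:
    def test_idempotent(self, trio):
        again = topo_sort_validate(trio)
        assert again.ids == trio.ids

    def test_reversed_chain(self):
        rows = [(f"I{k}", f"I{k + 1}" if k < 9 else None, None, "R")
                for k in range(10)]
        p = make_pedigree(rows)
        idx = [p.index_of(f"I{k}") for k in range(10)]
        assert idx == sorted(idx, reverse=True)

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            make_pedigree([("A", "B", None, None), ("B", "A", None, None)])


# ---------------------------------------------------------------------------
# inbreeding and A
# ---------------------------------------------------------------------------

class TestInbreeding:
    def test_founders_zero(self):
        p = make_pedigree([(f"F{k}", None, None, "R") for k in range(5)])
        assert np.all(inbreeding_meuwissen_luo(p) == 0.0)

    def test_fullsib_offspring(self, fullsib_mating_pedigree):
        p = fullsib_mating_pedigree
        F = inbreeding_meuwissen_luo(p)
        assert F[p.index_of("E")] == pytest.approx(0.25)

    def test_parent_offspring_mating(self, parent_offspring_mating_pedigree):
        p = parent_offspring_mating_pedigree
        F = inbreeding_meuwissen_luo(p)
        assert F[p.index_of("E")] == pytest.approx(0.25)

    def test_matches_coancestry_of_parents(self):
        rng = np.random.default_rng(42)
        p = random_pedigree(rng, 120)
        F = inbreeding_meuwissen_luo(p)
        f = coancestry_oracle(p)
        for k in range(p.n):
            expected = f(p.sire[k], p.dam[k]) \
                if (p.sire[k] >= 0 and p.dam[k] >= 0) else 0.0
            assert F[k] == pytest.approx(expected, abs=1e-12)


class TestBuildA:
    def test_unrelated_founders_identity(self):
        p = make_pedigree([(f"F{k}", None, None, "R") for k in range(6)])
        A = build_A_tabular(p)
        np.testing.assert_allclose(A.values, np.eye(6))

    def test_trio_coefficients(self, trio):
        A = build_A_tabular(trio)
        assert A.loc("C", "A") == pytest.approx(0.5)
        assert A.loc("C", "C") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_coancestry_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = random_pedigree(rng, 200)
        A = build_A_tabular(p).values
        f = coancestry_oracle(p)
        oracle = np.array([[2.0 * f(i, j) for j in range(p.n)]
                           for i in range(p.n)])
        assert np.max(np.abs(A - oracle)) < 1e-10

    def test_diag_equals_one_plus_F(self):
        rng = np.random.default_rng(3)
        p = random_pedigree(rng, 150)
        A = build_A_tabular(p)
        F = inbreeding_meuwissen_luo(p)
        np.testing.assert_allclose(np.diag(A.values), 1.0 + F, atol=1e-12)

    def test_subset_selection(self):
        rng = np.random.default_rng(4)
        p = random_pedigree(rng, 50)
        ids = [p.ids[i] for i in (3, 10, 20)]
        sub = build_A_tabular(p, subset=ids)
        full = build_A_tabular(p)
        for a in ids:
            for b in ids:
                assert sub.loc(a, b) == full.loc(a, b)

    def test_subset_unknown_id_raises(self, trio):
        with pytest.raises(ValueError, match="NOPE"):
            build_A_tabular(trio, subset=["NOPE"])


class TestAInverse:
    def test_founders_identity(self):
        p = make_pedigree([(f"F{k}", None, None, "R") for k in range(4)])
        Ainv, _ = build_A_inverse(p)
        np.testing.assert_allclose(Ainv.toarray(), np.eye(4))

    @pytest.mark.parametrize("seed,n", [(0, 50), (1, 150), (2, 300)])
    def test_inverts_tabular_A(self, seed, n):
        rng = np.random.default_rng(seed)
        p = random_pedigree(rng, n)
        A = build_A_tabular(p).values
        Ainv, ids = build_A_inverse(p)
        assert ids == p.ids
        err = np.abs(Ainv.toarray() @ A - np.eye(n)).max()
        assert err < 1e-8

    def test_inbred_pedigree(self, fullsib_mating_pedigree):
        p = fullsib_mating_pedigree
        A = build_A_tabular(p).values
        Ainv, _ = build_A_inverse(p)
        err = np.abs(Ainv.toarray() @ A - np.eye(p.n)).max()
        assert err < 1e-10


class TestPartitionA:
    def test_all_genotyped(self, trio):
        A = build_A_tabular(trio)
        blocks = partition_A(A, list(A.ids))
        assert blocks["A11"].n == 0
        np.testing.assert_allclose(blocks["A22"].values, A.values)

    def test_reassembly(self):
        rng = np.random.default_rng(5)
        p = random_pedigree(rng, 40)
        A = build_A_tabular(p)
        genotyped = [p.ids[i] for i in range(0, 40, 3)]
        blocks = partition_A(A, genotyped)
        order = blocks["A11"].ids + genotyped
        n1 = blocks["A11"].n
        rebuilt = np.zeros((40, 40))
        rebuilt[:n1, :n1] = blocks["A11"].values
        rebuilt[:n1, n1:] = blocks["A12"].values
        rebuilt[n1:, :n1] = blocks["A21"]
        rebuilt[n1:, n1:] = blocks["A22"].values
        np.testing.assert_allclose(rebuilt, A.subset(order).values)

    def test_A22_matches_subset_build(self):
        rng = np.random.default_rng(6)
        p = random_pedigree(rng, 50)
        A = build_A_tabular(p)
        genotyped = [p.ids[i] for i in range(40, 50)]
        blocks = partition_A(A, genotyped)
        direct = build_A_tabular(p, subset=genotyped)
        np.testing.assert_allclose(blocks["A22"].values, direct.values,
                                   atol=1e-12)

    def test_empty_genotyped_raises(self, trio):
        with pytest.raises(ValueError, match="empty"):
            partition_A(build_A_tabular(trio), [])


# ---------------------------------------------------------------------------
# race genetic-group fractions
# ---------------------------------------------------------------------------

class TestGroupFractions:
    def test_founder_indicator(self, trio):
        Q = group_fraction_matrix(trio)
        row = Q.to_frame().loc["A"]
        assert row["STRZ"] == 1.0 and row.sum() == pytest.approx(1.0)

    def test_f1_half_and_half(self, trio):
        Q = group_fraction_matrix(trio).to_frame()
        assert Q.loc["C", "STRZ"] == pytest.approx(0.5)
        assert Q.loc["C", "FURNX"] == pytest.approx(0.5)

    def test_rows_sum_to_one_and_order_invariant(self):
        rng = np.random.default_rng(7)
        p = random_pedigree(rng, 80)
        Q = group_fraction_matrix(p).to_frame()
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-12)
        # permute record order: fractions must not change
        perm = rng.permutation(p.n)
        rows = []
        for k in perm:
            s, d = p.parents_of(p.ids[k])
            rows.append((p.ids[k], s, d, p.race[k]))
        p2 = make_pedigree(rows)
        Q2 = group_fraction_matrix(p2).to_frame()
        np.testing.assert_allclose(Q.loc[Q2.index, Q2.columns].values,
                                   Q2.values, atol=1e-12)

    def test_four_generation_gene_drop_expectation(self):
        """Race fractions equal race-label gene-dropping expectations."""
        rows = [("F1", None, None, "STRZ"), ("F2", None, None, "FURNX"),
                ("F3", None, None, "KI"), ("F4", None, None, "STRZ"),
                ("G1", "F1", "F2", None), ("G2", "F3", "F4", None),
                ("H1", "G1", "G2", None), ("H2", "G1", "F4", None),
                ("K1", "H1", "H2", None)]
        p = make_pedigree(rows)
        Q = group_fraction_matrix(p).to_frame()
        rng = np.random.default_rng(123)
        races = sorted(Q.columns)
        n_rep = 20000
        counts = {r: 0.0 for r in races}
        for _ in range(n_rep):
            allele: dict[str, str] = {}
            for k in range(p.n):
                iid = p.ids[k]
                if p.is_founder(k):
                    allele[iid] = p.race[k]
                else:
                    s, d = p.parents_of(iid)
                    pick = s if rng.random() < 0.5 else d
                    allele[iid] = allele[pick]
            counts[allele["K1"]] += 1
        for r in races:
            assert Q.loc["K1", r] == pytest.approx(counts[r] / n_rep,
                                                   abs=0.02)
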