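"""Mixed-model equations: design, assembly, solvers, reliabilities."""

import numpy as np
import pandas as pd
import pytest

from herdblup.mme import (ModelSpec, TraitSpec, VarianceComponents, assemble_mme,
                          build_design, reliabilities, run_evaluation, solve_mme)
from herdblup.pedigree import build_a_inverse, pedigree_from_frame
from conftest import toy_records
from _oracles import dense_mixed_model_oracle, random_pedigree

VC1 = VarianceComponents(["y"], np.array([[1.0]]), np.array([[1.0]]))
SPEC1 = ModelSpec(traits=(TraitSpec("y", False),), varcomp=VC1)


def trio_ped():
    return pedigree_from_frame(pd.DataFrame(
        [("1", "0", "0"), ("2", "0", "0")],
        columns=["animal_id", "sire_id", "dam_id"]))


def two_record_table():
    return pd.DataFrame({
        "animal_id": ["1", "2"], "herd": ["H1", "H1"],
        "hys": ["H1|2000|1", "H1|2000|1"], "y": [10.0, 12.0]})


class TestBuildDesign:
    def test_single_trait_counts_levels_and_constraints(self):
        design = build_design(two_record_table(), trio_ped(), SPEC1)
        assert design.X[0].shape == (2, 2)  # herd level + HYS level
        assert len(design.constrained_fixed[0]) == 1

    def test_pooled_adds_country_factor_with_constrained_level(self):
        rec = two_record_table().assign(country=["KE", "ZA"],
                                        herd=["H1", "H2"],
                                        hys=["H1|2000|1", "H2|2000|1"])
        spec = ModelSpec(traits=(TraitSpec("y", False),), pooled=True, varcomp=VC1)
        design = build_design(rec, trio_ped(), spec)
        labels = design.fixed_labels[0]
        country_cols = [i for i, (e, _) in enumerate(labels) if e == "country"]
        assert len(country_cols) == 2
        assert len(set(country_cols) & design.constrained_fixed[0]) == 1

    def test_afc_has_no_age_column(self):
        vc = VarianceComponents(["my305", "afc"], np.eye(2), np.eye(2))
        spec = ModelSpec(traits=(TraitSpec("my305", True), TraitSpec("afc", False)),
                         varcomp=vc)
        rec = two_record_table().rename(columns={"y": "my305"}).assign(
            afc=[30.0, 31.0], age_months=[28.0, 32.0])
        design = build_design(rec, trio_ped(), spec)
        assert ("age", "slope") in design.fixed_labels[0]
        assert all(e != "age" for e, _ in design.fixed_labels[1])

    def test_unknown_animal_rejected(self):
        rec = two_record_table().assign(animal_id=["1", "zz"])
        with pytest.raises(ValueError, match="zz"):
            build_design(rec, trio_ped(), SPEC1)

    def test_empty_trait_column_rejected(self):
        rec = two_record_table().assign(y=[np.nan, np.nan])
        with pytest.raises(ValueError, match="'y'"):
            build_design(rec, trio_ped(), SPEC1)


class TestAssembleAndSolve:
    def test_toy_shrinkage_against_dense_oracle(self):
        # y = [10, 12] on unrelated animals, one contemporary group, σ²a = σ²e = 1:
        # common mean 11, EBVs ±(y−ȳ)·σ²a/(σ²a+σ²e) = ±0.5
        ped = trio_ped()
        rec = two_record_table()
        res = run_evaluation(rec, ped, SPEC1)
        ebv = res.ebv_series("y")
        assert ebv["1"] == pytest.approx(-0.5, abs=1e-9)
        assert ebv["2"] == pytest.approx(0.5, abs=1e-9)
        herd = res.fixed_effects.query("effect == 'herd'")["estimate"].iloc[0]
        hys = res.fixed_effects.query("effect == 'hys'")["estimate"].iloc[0]
        assert herd + hys == pytest.approx(11.0)
        oracle_ebv, _ = dense_mixed_model_oracle(rec, ped, ["y"], [False],
                                                 VC1.G0, VC1.R0)
        assert np.allclose(ebv[ped.animals], oracle_ebv[:, 0], atol=1e-9)

    def test_vanishing_genetic_variance_shrinks_ebv_to_zero(self):
        vc = VarianceComponents(["y"], np.array([[1e-10]]), np.array([[1.0]]))
        spec = ModelSpec(traits=(TraitSpec("y", False),), varcomp=vc)
        res = run_evaluation(two_record_table(), trio_ped(), spec)
        assert np.abs(res.ebv["ebv"]).max() < 1e-4

    def test_singular_g0_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            VarianceComponents(["a", "b"], np.ones((2, 2)), np.eye(2))

    def test_direct_and_pcg_agree(self):
        rng = np.random.default_rng(2)
        ped = pedigree_from_frame(random_pedigree(rng, 30))
        rec = toy_records(rng, ped)
        design = build_design(rec, ped, SPEC1)
        system = assemble_mme(design, build_a_inverse(ped), VC1)
        x_direct, _ = solve_mme(system, method="direct")
        x_pcg, diag = solve_mme(system, method="pcg", tol=1e-12)
        assert np.allclose(x_direct, x_pcg, atol=1e-6)
        assert diag["relative_residual"] < 1e-8

    def test_pcg_nonconvergence_raises(self):
        rng = np.random.default_rng(2)
        ped = pedigree_from_frame(random_pedigree(rng, 30))
        design = build_design(toy_records(rng, ped), ped, SPEC1)
        system = assemble_mme(design, build_a_inverse(ped), VC1)
        with pytest.raises(RuntimeError, match="did not converge"):
            solve_mme(system, method="pcg", max_iter=1)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_toys_match_dense_oracle(self, seed):
        """EBVs and PEVs agree with the observation-space GLS oracle (1e-6)."""
        rng = np.random.default_rng(100 + seed)
        ped = pedigree_from_frame(random_pedigree(rng, int(rng.integers(8, 30))))
        multi = seed % 2 == 1
        if multi:
            traits = ("u", "v")
            g = np.array([[2.0, 0.5], [0.5, 1.5]])
            r = np.array([[3.0, -0.4], [-0.4, 2.0]])
            uses_age = [True, False]
            tspecs = (TraitSpec("u", True), TraitSpec("v", False))
            missing = 0.25
        else:
            traits = ("u",)
            g, r = np.array([[2.0]]), np.array([[3.0]])
            uses_age = [True]
            tspecs = (TraitSpec("u", True),)
            missing = 0.0
        vc = VarianceComponents(list(traits), g, r)
        spec = ModelSpec(traits=tspecs, varcomp=vc)
        rec = toy_records(rng, ped, traits=traits, missing_rate=missing)
        res = run_evaluation(rec, ped, spec)
        ebv_o, pev_o = dense_mixed_model_oracle(rec, ped, list(traits), uses_age,
                                                g, r)
        for j, t in enumerate(traits):
            ours = res.ebv_series(t)[ped.animals].to_numpy()
            assert np.abs(ours - ebv_o[:, j]).max() < 1e-6
            rel = res.reliability.query("trait == @t").set_index("animal_id")
            pev_ours = rel.loc[ped.animals, "pev"].to_numpy()
            assert np.abs(pev_ours - pev_o[:, j]).max() < 1e-6


class TestReliabilities:
    def test_unconnected_founder_has_zero_reliability(self):
        ped = pedigree_from_frame(pd.DataFrame(
            [("1", "0", "0"), ("2", "0", "0"), ("3", "0", "0")],
            columns=["animal_id", "sire_id", "dam_id"]))
        rec = two_record_table()  # animal 3 has no record, no relatives
        res = run_evaluation(rec, ped, SPEC1)
        rel = res.reliability.set_index("animal_id")
        assert rel.loc["3", "reliability"] == pytest.approx(0.0, abs=1e-9)
        assert rel.loc["3", "pev"] == pytest.approx(1.0, abs=1e-9)

    def test_more_daughters_higher_reliability(self):
        # daughters spread over two contemporary groups that are anchored by
        # unrelated cows, so group effects are not confounded with families
        rows = [("S20", "0", "0"), ("S2", "0", "0")]
        recs = []
        for i in range(20):
            rows.append((f"a{i}", "S20", "0"))
            recs.append((f"a{i}", "H1", f"H1|2012|{i % 2 + 1}", 10.0 + (i % 3)))
        for i in range(2):
            rows.append((f"b{i}", "S2", "0"))
            recs.append((f"b{i}", "H1", f"H1|2012|{i % 2 + 1}", 11.0 + i))
        for i in range(10):
            rows.append((f"u{i}", "0", "0"))
            recs.append((f"u{i}", "H1", f"H1|2012|{i % 2 + 1}", 9.0 + (i % 4)))
        ped = pedigree_from_frame(pd.DataFrame(
            rows, columns=["animal_id", "sire_id", "dam_id"]))
        rec = pd.DataFrame(recs, columns=["animal_id", "herd", "hys", "y"])
        res = run_evaluation(rec, ped, SPEC1)
        acc = res.accuracy_series("y")
        assert acc["S20"] > acc["S2"]
        # cross-check both against the observation-space oracle
        _, pev_o = dense_mixed_model_oracle(rec, ped, ["y"], [False],
                                            VC1.G0, VC1.R0)
        rel = res.reliability.set_index("animal_id")
        assert rel.loc["S20", "pev"] == pytest.approx(
            pev_o[ped.index["S20"], 0], abs=1e-8)
        assert rel.loc["S2", "pev"] == pytest.approx(
            pev_o[ped.index["S2"], 0], abs=1e-8)

    def test_subset_and_unknown_animal(self):
        ped = trio_ped()
        design = build_design(two_record_table(), ped, SPEC1)
        system = assemble_mme(design, build_a_inverse(ped), VC1)
        solve_mme(system)
        sub = reliabilities(system, animals=["2"])
        assert list(sub["animal_id"]) == ["2"]
        with pytest.raises(KeyError, match="zzz"):
            reliabilities(system, animals=["zzz"])

    def test_reliability_invariant_to_shifting_observations(self):
        rng = np.random.default_rng(8)
        ped = pedigree_from_frame(random_pedigree(rng, 25))
        rec = toy_records(rng, ped)
        r1 = run_evaluation(rec, ped, SPEC1).reliability
        rec2 = rec.assign(y=rec["y"] + 100.0)
        r2 = run_evaluation(rec2, ped, SPEC1).reliability
        assert np.allclose(r1["reliability"], r2["reliability"], atol=1e-9)


class TestRunEvaluation:
    def test_requires_variance_components(self):
        spec = ModelSpec(traits=(TraitSpec("y", False),), varcomp=None)
        with pytest.raises(ValueError, match="variance components"):
            run_evaluation(two_record_table(), trio_ped(), spec)

    def test_one_ebv_per_pedigree_animal_per_trait(self, desk_study):
        cfg, sim, data = desk_study
        spec = ModelSpec(varcomp=cfg.varcomp)
        res = run_evaluation(data.records["KE"], data.pedigrees["KE"], spec,
                             reliability_animals=None)
        assert len(res.ebv) == 3 * len(data.pedigrees["KE"])

    def test_record_order_invariance(self):
        rng = np.random.default_rng(21)
        ped = pedigree_from_frame(random_pedigree(rng, 20))
        rec = toy_records(rng, ped)
        res1 = run_evaluation(rec, ped, SPEC1)
        res2 = run_evaluation(rec.sample(frac=1.0, random_state=3), ped, SPEC1)
        assert np.allclose(res1.ebv_series("y")[ped.animals],
                           res2.ebv_series("y")[ped.animals], atol=1e-9)

    def test_diagonal_multitrait_equals_single_trait_solves(self):
        rng = np.random.default_rng(31)
        ped = pedigree_from_frame(random_pedigree(rng, 25))
        rec = toy_records(rng, ped, traits=("u", "v"))
        g = np.diag([2.0, 1.0])
        r = np.diag([3.0, 2.5])
        spec2 = ModelSpec(traits=(TraitSpec("u", False), TraitSpec("v", False)),
                          varcomp=VarianceComponents(["u", "v"], g, r))
        res2 = run_evaluation(rec, ped, spec2)
        for j, t in enumerate(["u", "v"]):
            spec1 = ModelSpec(
                traits=(TraitSpec(t, False),),
                varcomp=VarianceComponents([t], g[j:j+1, j:j+1], r[j:j+1, j:j+1]))
            res1 = run_evaluation(rec, ped, spec1)
            assert np.allclose(res2.ebv_series(t)[ped.animals],
                               res1.ebv_series(t)[ped.animals], atol=1e-8)

    def test_stacked_countries_reproduce_within_solution(self):
        # the same single-country problem duplicated as two countries with a
        # country effect: each block's EBVs equal the single-country EBVs
        rng = np.random.default_rng(17)
        ped_frame = random_pedigree(rng, 15)
        ped = pedigree_from_frame(ped_frame)
        rec = toy_records(rng, ped)
        single = run_evaluation(rec, ped, SPEC1)

        pf2 = ped_frame.copy()
        for col in pf2.columns:
            pf2[col] = pf2[col].map(lambda v: v if v == "0" else "B" + v)
        merged_ped = pedigree_from_frame(pd.concat([ped_frame, pf2],
                                                   ignore_index=True))
        rec_b = rec.copy()
        rec_b["animal_id"] = "B" + rec_b["animal_id"]
        rec_b["herd"] = "B" + rec_b["herd"]
        rec_b["hys"] = "B" + rec_b["hys"]
        pooled_rec = pd.concat([rec.assign(country="KE"),
                                rec_b.assign(country="ZA")], ignore_index=True)
        spec = ModelSpec(traits=(TraitSpec("y", False),), pooled=True, varcomp=VC1)
        pooled = run_evaluation(pooled_rec, merged_ped, spec)
        a = pooled.ebv_series("y")
        b = single.ebv_series("y")
        assert np.allclose(a[ped.animals], b[ped.animals], atol=1e-8)
        assert np.allclose(a[["B" + x for x in ped.animals]],
                           b[ped.animals], atol=1e-8)
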