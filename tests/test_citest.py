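"""Fisher thresholds, partial correlations, verification and comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from helpers import random_correlation, regression_partial_corr
from pcunits.citest import (  # noqa: F401
    TestConfig as VerifyConfig,
    annotation_agreement,
    covariate_comparison,
    dominant_splice,
    fisher_threshold,
    load_gene_list,
    null_model_benchmark,
    partial_correlation,
    subset_enrichment,
    verify_conditions,
)
from pcunits.dyncorr import DynCorrResult
from pcunits.graphs import demo_unit
from pcunits.markov import MarkovCondition, enumerate_markov_conditions


def make_dc(ids, R, layers=None):
    R = np.asarray(R, float)
    return DynCorrResult(
        list(ids), R, R.copy(), np.ones(len(ids)), np.zeros(len(ids)),
        layers or {}, {},
    )


class TestFisherThreshold:
    def test_study_sample_size_gives_theta_near_016(self):
        assert fisher_threshold(147, 0, 0.05) == pytest.approx(0.1619, abs=5e-4)

    def test_one_conditioner(self):
        expect = np.tanh(stats.norm.ppf(0.975) / np.sqrt(143))
        assert fisher_threshold(147, 1, 0.05) == pytest.approx(expect, abs=1e-12)

    def test_alpha_to_one_drives_theta_to_zero(self):
        assert fisher_threshold(147, 0, 1 - 1e-12) < 1e-6

    def test_nonpositive_dof_is_an_error(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            fisher_threshold(5, 3, 0.05)

    def test_threshold_equivalent_to_z_test(self, rng):
        # verified <=> sqrt(N-|C|-3) |atanh(r)| < Phi^-1(1-alpha/2), exactly
        for _ in range(200):
            n = int(rng.integers(10, 300))
            card = int(rng.integers(0, min(5, n - 4)))
            alpha = float(rng.uniform(0.001, 0.3))
            r = float(rng.uniform(-0.99, 0.99))
            theta = fisher_threshold(n, card, alpha)
            z_ok = np.sqrt(n - card - 3) * abs(np.arctanh(r)) < stats.norm.ppf(1 - alpha / 2)
            assert (abs(r) < theta) == z_ok


class TestPartialCorrelation:
    IDS = ["x", "y", "z"]

    def test_triangle_formula_hand_value(self):
        R = np.array([[1, 0.5, 0.6], [0.5, 1, 0.6], [0.6, 0.6, 1]])
        got = partial_correlation(R, self.IDS, "x", "y", ["z"])
        assert got == pytest.approx((0.5 - 0.36) / (1 - 0.36), abs=1e-12)

    def test_empty_conditioning_returns_marginal(self):
        R = np.array([[1, 0.3, 0.0], [0.3, 1, 0.0], [0, 0, 1.0]])
        assert partial_correlation(R, self.IDS, "x", "y", []) == 0.3

    def test_equicorrelated_contracts(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1)
        got = partial_correlation(R, self.IDS, "x", "y", ["z"])
        assert got == pytest.approx(1 / 3, abs=1e-12)

    def test_inversion_matches_triangle_formula_on_random_3x3(self, rng):
        for _ in range(200):
            R = random_correlation(rng, 3)
            got = partial_correlation(R, self.IDS, "x", "y", ["z"])
            rxy, rxz, ryz = R[0, 1], R[0, 2], R[1, 2]
            tri = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            assert got == pytest.approx(tri, abs=1e-12)

    def test_inversion_matches_regression_residual_oracle(self, rng):
        ids = [f"v{i}" for i in range(6)]
        for _ in range(50):
            X = rng.normal(size=(200, 6)) @ rng.normal(size=(6, 6))
            R = np.corrcoef(X, rowvar=False)
            C = list(rng.choice(range(2, 6), size=rng.integers(1, 4), replace=False))
            got = partial_correlation(R, ids, "v0", "v1", [ids[i] for i in C])
            want = regression_partial_corr(X, 0, 1, C)
            assert got == pytest.approx(want, abs=1e-8)

    def test_singular_submatrix_raises(self):
        R = np.array([[1, 1.0, 0.5], [1.0, 1, 0.5], [0.5, 0.5, 1]])
        from pcunits.citest import IllConditionedError

        with pytest.raises(IllConditionedError):
            partial_correlation(R, self.IDS, "x", "z", ["y"])


class TestVerification:
    def records_for(self, alpha):
        dag = demo_unit()
        rng = np.random.default_rng(3)
        R = random_correlation(rng, 6)
        dc = make_dc(sorted(dag.g.nodes), R)
        return verify_conditions(
            enumerate_markov_conditions(dag), dc, VerifyConfig(alpha=alpha)
        )

    def test_verified_iff_partial_below_theta(self):
        rec = self.records_for(0.05)
        ok = rec[~rec.skipped]
        assert (ok.verified == (ok.r_xy_C.abs() < ok.theta)).all()

    def test_monotone_in_threshold(self):
        # larger alpha -> smaller theta: the verified set shrinks
        tight = self.records_for(0.4)
        loose = self.records_for(0.01)
        key = ["x", "y"]
        merged = tight.merge(loose, on=key, suffixes=("_t", "_l"))
        assert (merged.theta_t <= merged.theta_l).all()
        assert (~merged.verified_t | merged.verified_l).all()


class TestDominantSplice:
    def test_noisy_copy_has_clear_dominant(self):
        # s2 is a noisy copy of s1; s1 drives p: conditioning on s1 explains s2
        rng = np.random.default_rng(0)
        n = 400
        s1 = rng.normal(size=n)
        s2 = s1 + 0.3 * rng.normal(size=n)
        p = s1 + 0.1 * rng.normal(size=n)
        a = s1 + 0.5 * rng.normal(size=n)
        X = np.column_stack([a, p, s1, s2])
        ids = ["a1", "P", "s1", "s2"]
        dag = _unit(["a1"], ["s1", "s2"], "P")
        dc = make_dc(ids, np.corrcoef(X, rowvar=False))
        res = dominant_splice(dag, dc, VerifyConfig())
        assert res.dominant == "s1"
        assert res.explained_fraction == 1.0 and res.single_dominant

    def test_independent_equal_drivers_leave_unexplained_siblings(self):
        rng = np.random.default_rng(1)
        n = 2000
        s = rng.normal(size=(n, 3))
        p = s.sum(axis=1) + 0.05 * rng.normal(size=n)
        a = rng.normal(size=n)
        X = np.column_stack([a, p, s])
        ids = ["a1", "P", "s1", "s2", "s3"]
        dag = _unit(["a1"], ["s1", "s2", "s3"], "P")
        dc = make_dc(ids, np.corrcoef(X, rowvar=False))
        res = dominant_splice(dag, dc, VerifyConfig())
        assert res.explained_fraction < 1.0

    def test_tie_breaks_toward_smaller_residual(self):
        # both candidates explain the other; s1 leaves the smaller residual
        R = np.array(
            [
                #      a1     P      s1     s2
                [1.0, 0.10, 0.10, 0.10],
                [0.10, 1.0, 0.90, 0.80],
                [0.10, 0.90, 1.0, 0.85],
                [0.10, 0.80, 0.85, 1.0],
            ]
        )
        ids = ["a1", "P", "s1", "s2"]
        dag = _unit(["a1"], ["s1", "s2"], "P")
        # lenient threshold so both candidates explain their sibling (a tie)
        res = dominant_splice(dag, make_dc(ids, R), VerifyConfig(alpha=1e-9, n_samples=20))
        r_using_s1 = abs(partial_correlation(R, ids, "s2", "P", ["s1"]))
        r_using_s2 = abs(partial_correlation(R, ids, "s1", "P", ["s2"]))
        assert r_using_s1 < r_using_s2
        assert res.dominant == "s1"

    def test_single_splice_unit_rejected(self):
        dag = _unit(["a1"], ["s1"], "P")
        dc = make_dc(["a1", "P", "s1"], np.eye(3))
        with pytest.raises(ValueError, match=">= 2"):
            dominant_splice(dag, dc)


def _unit(peaks, splices, protein):
    from pcunits.graphs import ProteinCodingUnitDAG

    d = ProteinCodingUnitDAG(protein)
    d.add_node(protein, "p", protein)
    for a in peaks:
        d.add_node(a, "a", protein)
    for s in splices:
        d.add_node(s, "s", protein)
        d.add_edge(peaks[0], s)
        d.add_edge(s, protein)
    return d


class TestNullModels:
    def test_too_few_variables_is_an_error(self):
        dc = make_dc(["a", "b"], np.eye(2))
        cond = [MarkovCondition("a", "b", (), "a-a", "D")]
        with pytest.raises(ValueError, match="too few"):
            null_model_benchmark(cond, dc)

    def test_null_sets_preserve_cardinality_and_exclude_x(self, rng):
        R = random_correlation(rng, 12)
        ids = [f"v{i}" for i in range(12)]
        dc = make_dc(ids, R)
        conds = [
            MarkovCondition("v0", "v1", ("v2", "v3"), "s-s", "D"),
            MarkovCondition("v4", "v5", ("v6",), "a->s", "D"),
        ]
        out = null_model_benchmark(conds, dc, VerifyConfig(null_reps=5), rng)
        # cardinality is asserted inside; here check the structure of output
        assert set(out) >= {"true", "null_y", "null_yC"}
        assert len(out["true"]) == 2  # one per distinct x node


class TestSubsetAndCovariates:
    def rec(self, dag_ids, verified):
        return pd.DataFrame(
            {
                "dag_id": dag_ids,
                "x": ["n"] * len(dag_ids),
                "y": ["m"] * len(dag_ids),
                "verified": verified,
                "skipped": [False] * len(dag_ids),
            }
        )

    def test_perfect_separation_matches_hypergeometric(self):
        rec = self.rec(["in"] * 10 + ["out"] * 10, [True] * 10 + [False] * 10)
        table, p = subset_enrichment(rec, ["in"])
        assert table.tolist() == [[10, 0], [0, 10]]
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_equal_proportions_give_p_one(self):
        rec = self.rec(["in", "in", "out", "out"], [True, False, True, False])
        _, p = subset_enrichment(rec, ["in"])
        assert p == 1.0

    def test_empty_margin_warns(self):
        rec = self.rec(["in", "out"], [True, True])
        with pytest.warns(UserWarning, match="margin"):
            _, p = subset_enrichment(rec, ["in"])
        assert p == 1.0

    def test_empty_subset_is_an_error(self):
        with pytest.raises(ValueError):
            subset_enrichment(self.rec(["a"], [True]), [])

    def test_covariate_comparison_detects_shift(self, rng):
        n = 200
        rec = self.rec(["d"] * n, [True] * (n // 2) + [False] * (n // 2))
        rec["x"] = [f"v{i}" for i in range(n)]
        cov = {f"v{i}": (10.0 if i < n // 2 else 0.0) + rng.normal() for i in range(n)}
        out = covariate_comparison(rec, cov)
        assert out["mean_verified"] > out["mean_non_verified"]
        assert out["p"] < 1e-6


class TestAnnotation:
    def test_uniform_ranks_match_random_baseline(self):
        dag = _unit(["a1"], ["s1", "s2", "s3"], "P")
        dom = pd.DataFrame([{"dag_id": "P", "dominant": "s2"}])
        ann = {s: "PRINCIPAL:1" for s in ("s1", "s2", "s3")}
        out = annotation_agreement(dom, ann, [dag])
        assert out["frac_dominant_top_rank"] == out["frac_random_top_rank"] == 1.0

    def test_empty_annotation_degenerates_with_warning(self):
        dag = _unit(["a1"], ["s1", "s2"], "P")
        dom = pd.DataFrame([{"dag_id": "P", "dominant": "s1"}])
        with pytest.warns(UserWarning, match="empty annotation"):
            out = annotation_agreement(dom, {}, [dag])
        assert out["frac_dominant_top_rank"] == 1.0  # everything ties at ABSENT


class TestGeneLists:
    def test_packaged_panels(self):
        th1 = load_gene_list("th1")
        tcell = load_gene_list("tcell")
        assert len(th1) == 34
        assert {"STAT4", "TBX21", "IFNG"} <= set(th1)
        assert set(th1) <= set(tcell)
        assert len(tcell) > 100
        with pytest.raises(ValueError):
            load_gene_list("bcell")
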