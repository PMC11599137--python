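"""Gene prioritization: enrichment, gating, scaling, ranking, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from gscmorph.errors import ValidationError
from gscmorph.prioritize import (
    fit_bimodal_gate,
    hypergeom_upper_tail,
    intersect_gene_sets,
    normalize_symbols,
    prioritize,
    scale_dependency,
    signature_correlation_test,
)
from gscmorph.synth.omics import OmicsSimSpec, generate_omics_tables
from oracles import hypergeom_enumerate


class TestIntersect:
    def test_disjoint_and_identical(self):
        assert intersect_gene_sets(["A", "B"], ["C"]).shared == set()
        res = intersect_gene_sets(["A", "B"], ["b", " a "])
        assert res.shared == {"A", "B"}
        assert res.coverage_a == 1.0

    def test_planted_overlap_recovered_exactly(self):
        shared = {f"SH{i}" for i in range(30)}
        a = shared | {f"A{i}" for i in range(8479)}
        b = shared | {f"B{i}" for i in range(15)}
        res = intersect_gene_sets(a, b)
        assert res.shared == shared
        assert res.coverage_b == pytest.approx(30 / 45)

    def test_normalization_collapses_case_and_whitespace(self):
        assert normalize_symbols(["add3", "ADD3 ", " Add3"]) == {"ADD3"}


class TestHypergeom:
    def test_adducin_family_enrichment_value(self):
        """All three adducins among 30 of 19,396 genes: P = 3.34e-9."""
        res = hypergeom_upper_tail(19396, 3, 30, 3)
        assert res.p_value == pytest.approx(3.34e-9, rel=0.005)

    def test_zero_hits_gives_probability_one(self):
        assert hypergeom_upper_tail(19396, 3, 30, 0).p_value == 1.0

    def test_small_case_equals_exhaustive_third(self):
        # N=10, n=3, k=4: 70 of the 210 draws contain >= 2 successes
        assert hypergeom_upper_tail(10, 3, 4, 2).p_value == pytest.approx(1 / 3)

    def test_matches_enumeration_for_tiny_populations(self):
        for N in (4, 7, 10):
            for n in range(N + 1):
                for k in range(N + 1):
                    for x in range(min(n, k) + 1):
                        expected = hypergeom_enumerate(N, n, k, x)
                        got = hypergeom_upper_tail(N, n, k, x).p_value
                        assert got == pytest.approx(expected, rel=1e-9), (N, n, k, x)

    @given(x=st.integers(min_value=1, max_value=3))
    def test_p_value_monotone_in_hits(self, x):
        lo = hypergeom_upper_tail(100, 5, 10, x).p_value
        hi = hypergeom_upper_tail(100, 5, 10, x - 1).p_value
        assert lo <= hi

    def test_bounds_are_validated(self):
        with pytest.raises(ValidationError):
            hypergeom_upper_tail(10, 3, 4, 4)
        with pytest.raises(ValidationError):
            hypergeom_upper_tail(10, 12, 4, 2)


class TestBimodalGate:
    def test_separated_point_masses(self):
        values = pd.Series(
            [0.0] * 5 + [10.0] * 5, index=[f"G{i}" for i in range(10)]
        )
        fit = fit_bimodal_gate(values, seed=0)
        assert fit.gated_high == {"G5", "G6", "G7", "G8", "G9"}
        assert fit.mean_low == pytest.approx(0.0, abs=0.2)
        assert fit.mean_high == pytest.approx(10.0, abs=0.2)

    def test_recovers_planted_mixture_parameters(self):
        rng = np.random.default_rng(1)
        n = 500
        high = rng.random(n) < 0.6
        vals = np.where(rng.random(n) < 0, 0, 0) + np.where(
            high, rng.normal(6.0, 1.0, n), rng.normal(1.0, 0.25, n)
        )
        fit = fit_bimodal_gate(pd.Series(vals, index=[f"G{i}" for i in range(n)]), seed=1)
        n_high = int(high.sum())
        assert fit.mean_high == pytest.approx(6.0, abs=3 * 1.0 / np.sqrt(n_high))
        assert fit.mean_low == pytest.approx(1.0, abs=3 * 0.25 / np.sqrt(n - n_high))
        gated_fraction = len(fit.gated_high) / n
        assert gated_fraction == pytest.approx(0.6, abs=3 * np.sqrt(0.6 * 0.4 / n))

    def test_gate_membership_invariant_to_location_shift(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(1, 0.3, 100), rng.normal(5, 0.8, 150)])
        idx = [f"G{i}" for i in range(250)]
        base = fit_bimodal_gate(pd.Series(vals, index=idx), seed=3)
        shifted = fit_bimodal_gate(pd.Series(vals + 7.5, index=idx), seed=3)
        assert base.gated_high == shifted.gated_high

    def test_manual_threshold_override(self):
        vals = pd.Series([1.0, 2.0, 6.0, 7.0], index=list("ABCD"))
        fit = fit_bimodal_gate(
            pd.concat([vals, pd.Series(np.linspace(0, 1, 6))]), manual_threshold=4.0
        )
        assert {"C", "D"} <= fit.gated_high

    def test_degenerate_identical_values_raise(self):
        with pytest.raises(ValidationError, match="degenerate"):
            fit_bimodal_gate(pd.Series(np.ones(20)))


class TestScaleDependency:
    @pytest.fixture
    def table(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(20)] + ["ESS1", "ESS2", "NON1", "NON2"]
        return pd.DataFrame(
            rng.normal(-0.3, 0.4, size=(24, 5)),
            index=genes,
            columns=[f"L{j}" for j in range(5)],
        )

    def test_anchor_identities_hold_exactly(self, table):
        sc = scale_dependency(table, ["ESS1", "ESS2"], ["NON1", "NON2"])
        for line in table.columns:
            s = lambda x: (x - sc.m_non[line]) / (sc.m_non[line] - sc.m_ess[line])
            assert s(sc.m_non[line]) == 0.0
            assert s(sc.m_ess[line]) == -1.0
        # brute-force per-line affine map
        for line in table.columns:
            expected = (table[line] - sc.m_non[line]) / (
                sc.m_non[line] - sc.m_ess[line]
            )
            assert np.allclose(sc.scaled[line], expected)

    def test_affine_midpoint(self):
        dep = pd.DataFrame(
            {"L0": [-0.8, 0.0, -0.4]}, index=["ESS", "NON", "GENE"]
        )
        sc = scale_dependency(dep, ["ESS"], ["NON"])
        assert sc.scaled.loc["GENE", "L0"] == pytest.approx(-0.5)
        assert sc.scaled.loc["ESS", "L0"] == pytest.approx(-1.0)

    def test_coincident_anchors_name_the_line(self):
        dep = pd.DataFrame({"LX": [0.5, 0.5, 0.1]}, index=["ESS", "NON", "G"])
        with pytest.raises(ValidationError, match="LX"):
            scale_dependency(dep, ["ESS"], ["NON"])


class TestPrioritize:
    def test_planted_dependent_gene_ranks_first(self):
        t = generate_omics_tables(OmicsSimSpec(seed=5))
        res = prioritize(
            list(t.expression.index),
            t.expression,
            t.dependency,
            t.core_fitness,
            t.truth.essential_anchors,
            t.truth.nonessential_anchors,
            seed=0,
        )
        report = res["report"]
        assert report["gene"].iloc[0] == t.truth.planted_gene
        assert report["argmin_line"].iloc[0] == t.truth.planted_line
        assert report["min_scaled_dep"].iloc[0] <= -1.0
        assert report["context_score"].iloc[0] > 0.5
        assert set(res["core_excluded"]) == t.core_fitness

    def test_all_core_fitness_yields_empty_report(self):
        t = generate_omics_tables(OmicsSimSpec(n_genes=40, seed=6))
        res = prioritize(
            list(t.expression.index),
            t.expression,
            t.dependency,
            set(t.expression.index),  # everything excluded
            t.truth.essential_anchors,
            t.truth.nonessential_anchors,
            seed=0,
        )
        assert len(res["report"]) == 0

    def test_ranking_invariant_to_per_line_affine_transform(self):
        t = generate_omics_tables(OmicsSimSpec(seed=7))
        args = (
            list(t.expression.index),
            t.expression,
        )
        kwargs = dict(
            core_fitness=t.core_fitness,
            essential_anchors=t.truth.essential_anchors,
            nonessential_anchors=t.truth.nonessential_anchors,
            seed=0,
        )
        base = prioritize(*args, dependency=t.dependency, **kwargs)
        warped = t.dependency * 3.0 + 1.2  # same affine map for every line
        alt = prioritize(*args, dependency=warped, **kwargs)
        assert list(base["report"]["gene"]) == list(alt["report"]["gene"])
        assert np.allclose(
            base["report"]["min_scaled_dep"], alt["report"]["min_scaled_dep"]
        )

    def test_missing_genes_reported_not_fatal(self):
        t = generate_omics_tables(OmicsSimSpec(seed=8))
        res = prioritize(
            list(t.expression.index) + ["MGEA5"],
            t.expression,
            t.dependency,
            t.core_fitness,
            t.truth.essential_anchors,
            t.truth.nonessential_anchors,
            seed=0,
        )
        assert res["missing_genes"] == ["MGEA5"]


class TestSignatureCorrelation:
    @pytest.fixture
    def expr(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(60)] + ["FOCAL"]
        return pd.DataFrame(
            rng.normal(size=(61, 48)), index=genes, columns=[f"L{j}" for j in range(48)]
        )

    def test_identical_profile_has_correlation_one(self, expr):
        expr = expr.copy()
        expr.loc["TWIN"] = expr.loc["FOCAL"]
        res = signature_correlation_test(expr, "FOCAL", ["TWIN"])
        assert res.set_correlations["TWIN"] == pytest.approx(1.0)

    def test_independent_genes_center_on_null(self, expr):
        members = [f"G{i}" for i in range(20)]
        res = signature_correlation_test(expr, "FOCAL", members)
        se = 1.0 / np.sqrt(48 - 1)  # sd of a null Pearson r, roughly
        assert abs(res.mean_correlation) <= 3 * se / np.sqrt(len(members))
        assert abs(res.null_mean) < 0.02
        assert res.null_size == 61 * 60 // 2

    def test_planted_correlated_set_is_detected(self, expr):
        rng = np.random.default_rng(10)
        expr = expr.copy()
        focal = expr.loc["FOCAL"].to_numpy()
        target_r = 0.7
        lam = target_r / np.sqrt(1 - target_r**2)
        members = []
        for i in range(15):
            noise = rng.normal(size=focal.size)
            expr.loc[f"UP{i}"] = lam * (focal - focal.mean()) / focal.std() + noise
            members.append(f"UP{i}")
        res = signature_correlation_test(expr, "FOCAL", members)
        se = (1 - target_r**2) / np.sqrt(48 - 1)
        assert res.mean_correlation == pytest.approx(
            target_r, abs=3 * se / np.sqrt(15) + 0.05
        )
        assert res.p_value < 0.01
        assert res.t_statistic > 0

    def test_constant_gene_excluded_with_warning(self, expr):
        expr = expr.copy()
        expr.loc["FLAT"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = signature_correlation_test(expr, "FOCAL", ["FLAT", "G0"])
        assert "FLAT" not in res.set_correlations.index
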