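"""Tertiles, regression models, contingency tests, count reconstruction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from prs_gxe import (
    ModelFitError,
    SimConfig,
    ValidationError,
    adjusted_occurrence,
    assign_tertiles,
    chi_square_2xk,
    fit_interaction_model,
    linear_assoc,
    per_tertile_intervention_or,
    reconstruct_counts,
    simulate_study,
    snp_level_interactions,
)


class TestAssignTertiles:
    def test_cohort_of_529_splits_176_176_177(self):
        rng = np.random.default_rng(0)
        t = assign_tertiles(rng.normal(size=529))
        assert t.sizes == {"low": 176, "medium": 176, "high": 177}

    def test_six_distinct_scores(self):
        t = assign_tertiles([3.0, 1.0, 2.0, 6.0, 5.0, 4.0])
        assert t.sizes == {"low": 2, "medium": 2, "high": 2}
        assert list(t.labels) == ["medium", "low", "low", "high", "high", "medium"]

    def test_boundary_ties_resolved_by_stable_order(self):
        scores = np.zeros(529)  # every score tied
        t1 = assign_tertiles(scores)
        t2 = assign_tertiles(scores)
        assert t1.sizes == {"low": 176, "medium": 176, "high": 177}
        assert (t1.labels == t2.labels).all()
        # stable order: first 176 samples are the low tertile
        assert set(t1.labels[:176]) == {"low"}

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            assign_tertiles([1.0, 2.0])

    @given(n=st.integers(3, 400))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sizes_partition_with_max_min_gap_one(self, n):
        t = assign_tertiles(np.arange(n, dtype=float))
        sizes = list(t.sizes.values())
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1


class TestLinearAssoc:
    def test_noiseless_marker_recovers_exact_slope(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"prs_z": rng.normal(size=50), "age": rng.normal(32, 4, 50)})
        df["marker"] = 2.0 * df["prs_z"]
        res = linear_assoc(df, "marker", covariates=["age"])
        assert res.B == pytest.approx(2.0, abs=1e-10)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-8)

    def test_slope_recovery_within_monte_carlo_error(self):
        rng = np.random.default_rng(2)
        n, b, reps = 500, 0.7, 40
        estimates = []
        for _ in range(reps):
            prs = rng.normal(size=n)
            df = pd.DataFrame(
                {"prs_z": prs, "age": rng.normal(32, 4, n),
                 "marker": b * prs + rng.normal(0, 1, n)}
            )
            estimates.append(linear_assoc(df, "marker").B)
        se = np.std(estimates, ddof=1) / np.sqrt(reps)
        assert np.mean(estimates) == pytest.approx(b, abs=3 * se)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            df = pd.DataFrame(
                {"prs_z": rng.normal(size=150), "age": rng.normal(32, 4, 150),
                 "marker": rng.normal(size=150)}
            )
            pvals.append(linear_assoc(df, "marker").p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"prs_z": rng.normal(size=30)})
        df["copy"] = df["prs_z"]
        df["marker"] = rng.normal(size=30)
        with pytest.raises(ModelFitError, match="singular"):
            linear_assoc(df, "marker", covariates=["copy"])


def _cell_dataset(p):
    """Saturated 2x2x2 dataset: p[(prs, group)] = outcome probability,
    realised as exact cell frequencies with 200 subjects per cell."""
    rows = []
    for (x, g), prob in p.items():
        k = int(round(200 * prob))
        rows += [{"prs_z": x, "group": g, "y": 1}] * k
        rows += [{"prs_z": x, "group": g, "y": 0}] * (200 - k)
    return pd.DataFrame(rows)


class TestInteractionModel:
    def test_saturated_cell_counts_match_closed_form(self):
        p = {(0, 0): 0.30, (1, 0): 0.45, (0, 1): 0.35, (1, 1): 0.25}
        df = _cell_dataset(p)
        res = fit_interaction_model(df, "y", covariates=[])
        logit = lambda q: np.log(q / (1 - q))
        assert res.coefficients["const"] == pytest.approx(logit(0.30), abs=1e-6)
        assert res.coefficients["prs"] == pytest.approx(
            logit(0.45) - logit(0.30), abs=1e-6
        )
        assert res.coefficients["group"] == pytest.approx(
            logit(0.35) - logit(0.30), abs=1e-6
        )
        assert res.coefficients["prs_x_group"] == pytest.approx(
            logit(0.25) - logit(0.35) - logit(0.45) + logit(0.30), abs=1e-6
        )

    def test_score_vector_vanishes_at_optimum(self):
        p = {(0, 0): 0.30, (1, 0): 0.45, (0, 1): 0.35, (1, 1): 0.25}
        res = fit_interaction_model(_cell_dataset(p), "y", covariates=[])
        assert res.converged and res.score_norm < 1e-6

    @pytest.mark.filterwarnings("ignore::UserWarning", "ignore::RuntimeWarning")
    def test_separation_raises_diagnostic(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"prs_z": rng.normal(size=60), "group": rng.integers(0, 2, 60)}
        )
        df["y"] = df["group"]  # outcome perfectly predicted
        with pytest.raises(ModelFitError):
            fit_interaction_model(df, "y", covariates=[])

    def test_booking_exclusion_shrinks_sample(self, small_study):
        from prs_gxe import derive_cohort_phenotypes

        d = derive_cohort_phenotypes(small_study.cohort)
        d["prs_z"] = d["prs_true_z"]
        full = fit_interaction_model(d, "gdm", exclude_booking=False)
        sub = fit_interaction_model(d, "gdm", exclude_booking=True)
        assert sub.n == full.n - int((d["booking_gdm"] == 1).sum())


class TestPerTertileOr:
    def _dataset(self, rng, n, probs_by_tertile):
        prs = rng.normal(size=n)
        t = assign_tertiles(prs)
        g = rng.integers(0, 2, n)
        p = np.empty(n)
        for lab, (p0, p1) in probs_by_tertile.items():
            mask = t.labels == lab
            p[mask] = np.where(g[mask] == 1, p1, p0)
        df = pd.DataFrame({"prs_z": prs, "group": g, "y": rng.binomial(1, p)})
        return df, t

    def test_covariate_free_or_equals_cross_product_ratio(self):
        rng = np.random.default_rng(6)
        df, t = self._dataset(
            rng, 600, {"low": (0.4, 0.4), "medium": (0.4, 0.4), "high": (0.5, 0.3)}
        )
        res = per_tertile_intervention_or(df, t, "y", covariates=[])
        for lab in ("low", "medium", "high"):
            sub = df[t.labels == lab]
            tab = pd.crosstab(sub["group"], sub["y"]).to_numpy()
            cpr = (tab[1, 1] * tab[0, 0]) / (tab[1, 0] * tab[0, 1])
            assert res[lab].odds_ratios["group"][0] == pytest.approx(cpr, rel=1e-6)

    def test_null_arms_give_or_near_one(self):
        rng = np.random.default_rng(7)
        df, t = self._dataset(
            rng, 3000, {k: (0.45, 0.45) for k in ("low", "medium", "high")}
        )
        res = per_tertile_intervention_or(df, t, "y", covariates=[])
        for lab in res:
            o, lo, hi = res[lab].odds_ratios["group"]
            assert lo < 1 < hi

    def test_empty_cell_raises(self):
        rng = np.random.default_rng(8)
        df, t = self._dataset(
            rng, 120, {"low": (0.5, 0.5), "medium": (0.5, 0.5), "high": (0.0, 0.5)}
        )
        with pytest.raises(ModelFitError, match="high"):
            per_tertile_intervention_or(df, t, "y", covariates=[])


class TestAdjustedOccurrence:
    def _dataset(self, rng, n=240):
        prs = rng.normal(size=n)
        t = assign_tertiles(prs)
        df = pd.DataFrame(
            {
                "prs_z": prs,
                "group": rng.integers(0, 2, n),
                "age": rng.normal(32, 4, n),
                "y": rng.binomial(1, 0.4, n),
            }
        )
        return df, t

    def test_no_covariates_equals_raw_cell_proportions(self):
        rng = np.random.default_rng(9)
        df, t = self._dataset(rng)
        occ = adjusted_occurrence(df, t, "y", covariates=[])
        for row in occ.itertuples():
            cell = df[(t.labels == row.tertile) & (df["group"] == row.group)]
            assert row.adjusted == pytest.approx(cell["y"].mean(), abs=1e-10)

    def test_balanced_covariate_changes_nothing(self):
        rng = np.random.default_rng(10)
        df, t = self._dataset(rng)
        df["age"] = 32.0  # identical in every cell
        raw = adjusted_occurrence(df, t, "y", covariates=[])
        adj = adjusted_occurrence(df, t, "y", covariates=["age"])
        np.testing.assert_allclose(
            raw["adjusted"].to_numpy(), adj["adjusted"].to_numpy(), atol=1e-10
        )

    def test_matches_direct_normal_equations(self):
        """Independent least-squares reference: explicit design matrix,
        pseudo-inverse solve, marginal mean at the covariate grand mean."""
        rng = np.random.default_rng(11)
        df, t = self._dataset(rng, n=50)
        occ = adjusted_occurrence(df, t, "y", covariates=["age"])
        labs = ["low", "medium", "high"]
        X = np.zeros((50, 7))
        for i in range(50):
            cell = labs.index(t.labels[i]) * 2 + int(df["group"].iloc[i])
            X[i, cell] = 1.0
        X[:, 6] = df["age"] - df["age"].mean()
        beta = np.linalg.pinv(X) @ df["y"].to_numpy()
        for row in occ.itertuples():
            cell = labs.index(row.tertile) * 2 + row.group
            assert row.adjusted == pytest.approx(beta[cell], abs=1e-8)


class TestChiSquare2xk:
    def test_hand_computed_2x2(self):
        # 10/20 vs 20/20 positives: expected [[15,15],[5,5]], X² = 13.333...
        res = chi_square_2xk([[10, 20], [10, 0]])
        assert res.statistic == pytest.approx(40.0 / 3.0, abs=1e-10)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(40.0 / 3.0, 1))

    def test_equal_proportions_gives_zero_statistic(self):
        res = chi_square_2xk([[30, 60, 90], [70, 140, 210]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2xk([[0, 10], [0, 20]])

    @given(
        counts=st.lists(
            st.tuples(st.integers(1, 80), st.integers(1, 80)),
            min_size=2,
            max_size=5,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_textbook_formula_by_explicit_loop(self, counts):
        table = np.array(counts, dtype=float).T
        res = chi_square_2xk(table)
        total = table.sum()
        acc = 0.0
        for i in range(2):
            for j in range(table.shape[1]):
                e = table[i].sum() * table[:, j].sum() / total
                acc += (table[i, j] - e) ** 2 / e
        assert res.statistic == pytest.approx(acc, abs=1e-10)


class TestReconstructCounts:
    def test_gdm_row_inverts_to_tertile_denominators(self):
        assert reconstruct_counts(516, [66, 87, 97], [38.8, 50.0, 56.4]) == [170, 174, 172]

    def test_obesity_row_matches_tertile_sizes(self):
        assert reconstruct_counts(529, [128, 119, 111], [72.7, 67.6, 62.7]) == [176, 176, 177]

    def test_even_split(self):
        assert reconstruct_counts(200, [50, 50], [50.0, 50.0]) == [100, 100]

    def test_inconsistent_inputs_raise(self):
        with pytest.raises(ValidationError):
            reconstruct_counts(1000, [50, 50], [50.0, 50.0])


class TestSnpLevelInteractions:
    def test_monomorphic_variant_skipped_with_reason(self):
        from .conftest import make_genotypes

        rng = np.random.default_rng(12)
        d = np.column_stack([np.ones(80), rng.integers(0, 3, 80)]).astype(float)
        gm = make_genotypes(d, ids=["mono", "poly"])
        cohort = pd.DataFrame(
            {
                "y": rng.binomial(1, 0.4, 80),
                "group": rng.integers(0, 2, 80),
                "age": rng.normal(32, 4, 80),
            }
        )
        res = snp_level_interactions(gm, cohort, "y").set_index("snp")
        assert res.loc["mono", "status"] == "monomorphic"
        assert res.loc["poly", "status"] == "ok"

    def test_planted_interaction_snp_attains_minimum_p(self):
        """A single SNP with a strong dosage x intervention effect should
        dominate the scan in most replicates."""
        hits = 0
        for rep in range(10):
            cfg = SimConfig(
                n_samples=1000, n_blocks=6, snps_per_block=2, seed=100 + rep,
                missing_rate=0.0,
            )
            study = simulate_study(cfg)
            rng = np.random.default_rng(200 + rep)
            g = rng.integers(0, 2, 1000)
            dose = study.genotypes.dosages[:, 0]
            eta = -0.4 + 1.2 * dose * g
            cohort = pd.DataFrame(
                {
                    "y": rng.binomial(1, 1 / (1 + np.exp(-eta))),
                    "group": g,
                    "age": rng.normal(32, 4, 1000),
                }
            )
            res = snp_level_interactions(study.genotypes, cohort, "y")
            ok = res[res["status"] == "ok"]
            if ok.loc[ok["p"].idxmin(), "snp"] == study.genotypes.variants["id"][0]:
                hits += 1
        assert hits >= 9
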