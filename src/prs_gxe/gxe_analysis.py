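"""Gene-environment statistical stage.

Tertile stratification of the polygenic score, linear PRS-marker
associations, the PRS x intervention logistic interaction model,
per-tertile intervention odds ratios, covariate-adjusted outcome occurrence
(ANCOVA-style estimated marginal means on the binary outcome), Pearson
chi-square contingency tests, and a per-SNP interaction scan.

All regression fits go through statsmodels (OLS / maximum-likelihood
logit); inference is Wald-based, matching standard epidemiological
reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import GenotypeMatrix
from .errors import ComputationError, ModelFitError, ValidationError

__all__ = [
    "TertileAssignment",
    "LinearAssocResult",
    "InteractionResult",
    "ContingencyResult",
    "assign_tertiles",
    "linear_assoc",
    "fit_interaction_model",
    "per_tertile_intervention_or",
    "adjusted_occurrence",
    "chi_square_2xk",
    "reconstruct_counts",
    "snp_level_interactions",
]

log = logging.getLogger(__name__)

TERTILE_LABELS = ("low", "medium", "high")

#: Covariate sets mirrored from standard reporting: age only, or the full
#: background-characteristics adjustment.
COVARIATE_SETS = {
    "age": ["age"],
    "full": ["age", "bmi", "parity", "smoking", "education_years"],
}


@dataclass
class TertileAssignment:
    """Rank-based split of the cohort into genetic-risk thirds."""

    labels: np.ndarray  # per-sample "low"/"medium"/"high"
    cut_points: tuple[float, float]
    sizes: dict[str, int]


@dataclass
class LinearAssocResult:
    """Slope of a glycaemic marker per SD of PRS, with Wald 95% CI."""

    B: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass
class InteractionResult:
    """Logistic-model fit summary.

    ``coefficients``/``se``/``p_values`` are keyed by term name;
    ``odds_ratios`` maps each non-intercept term to (OR, lo, hi). For the
    interaction model the key term is ``prs_x_group``; for per-tertile fits
    it is ``group``.
    """

    coefficients: dict[str, float]
    se: dict[str, float]
    p_values: dict[str, float]
    odds_ratios: dict[str, tuple[float, float, float]]
    n: int
    converged: bool
    score_norm: float

    def or_ci(self, term: str) -> tuple[float, float, float]:
        return self.odds_ratios[term]


@dataclass
class ContingencyResult:
    """Pearson chi-square test of a 2 x k contingency table."""

    table: np.ndarray
    statistic: float
    df: int
    p: float


def assign_tertiles(scores: Sequence[float]) -> TertileAssignment:
    """Split samples into three contiguous rank groups of near-equal size.

    Sizes are ``floor(n/3)`` or ``ceil(n/3)`` with the remainder allocated
    to the highest tertile(s), so n=529 gives 176/176/177. Ties are broken
    by stable input order.
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    if n < 3:
        raise ValidationError(f"need at least 3 samples to form tertiles, got {n}")
    if np.isnan(s).any():
        raise ValidationError("scores contain missing values")
    base, rem = divmod(n, 3)
    sizes = [base, base, base]
    for i in range(rem):  # remainder goes to the top
        sizes[2 - i] += 1
    order = np.argsort(s, kind="stable")
    labels = np.empty(n, dtype=object)
    bounds = np.cumsum([0] + sizes)
    for lab, lo, hi in zip(TERTILE_LABELS, bounds[:-1], bounds[1:]):
        labels[order[lo:hi]] = lab
    cut_points = (
        float(s[order[bounds[1] - 1]]),
        float(s[order[bounds[2] - 1]]),
    )
    return TertileAssignment(
        labels=labels,
        cut_points=cut_points,
        sizes={lab: sz for lab, sz in zip(TERTILE_LABELS, sizes)},
    )


def _design(
    df: pd.DataFrame, cols: Sequence[str], add_const: bool = True
) -> pd.DataFrame:
    X = df[list(cols)].astype(float)
    if add_const:
        X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ModelFitError(f"singular design matrix over columns {list(X.columns)}")
    return X


def _complete_cases(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    return df.dropna(subset=list(cols))


def linear_assoc(
    cohort: pd.DataFrame,
    marker: str,
    covariates: Sequence[str] = ("age",),
    prs_col: str = "prs_z",
) -> LinearAssocResult:
    """OLS of a continuous marker on the standardized PRS plus covariates.

    Returns the PRS slope (change in the marker per SD of PRS), its Wald
    95% CI and two-sided p-value, on complete cases.
    """
    cols = [marker, prs_col, *covariates]
    data = _complete_cases(cohort, cols)
    if len(data) < len(covariates) + 2:
        raise ValidationError(
            f"{len(data)} complete cases are too few for {len(covariates)} covariates"
        )
    X = _design(data, [prs_col, *covariates])
    fit = sm.OLS(data[marker].astype(float), X).fit()
    ci = fit.conf_int().loc[prs_col]
    return LinearAssocResult(
        B=float(fit.params[prs_col]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[prs_col]),
        n=int(fit.nobs),
    )


def _fit_logit(y: pd.Series, X: pd.DataFrame, key_terms: Sequence[str]) -> InteractionResult:
    yv = y.astype(float)
    if not set(np.unique(yv)).issubset({0.0, 1.0}):
        raise ValidationError("outcome must be binary 0/1")
    if yv.nunique() < 2:
        raise ModelFitError("outcome is constant; logistic model undefined")
    model = sm.Logit(yv, X)
    try:
        fit = model.fit(disp=0, maxiter=200, method="newton")
    except (np.linalg.LinAlgError, PerfectSeparationError) as e:
        raise ModelFitError(f"logistic fit failed: {e}") from e
    score_norm = float(np.linalg.norm(model.score(fit.params)))
    if not fit.mle_retvals.get("converged", False) or score_norm > 1e-4:
        raise ModelFitError(
            f"logistic fit did not converge (score norm {score_norm:.2e}); "
            "possible separation"
        )
    if np.abs(fit.params.to_numpy()).max() > 15 or fit.bse.max() > 100:
        raise ModelFitError(
            "implausibly large coefficients or standard errors; quasi-separation"
        )
    conf = fit.conf_int()
    ors = {
        t: (float(np.exp(fit.params[t])), float(np.exp(conf.loc[t, 0])), float(np.exp(conf.loc[t, 1])))
        for t in X.columns
        if t != "const"
    }
    return InteractionResult(
        coefficients={t: float(fit.params[t]) for t in X.columns},
        se={t: float(fit.bse[t]) for t in X.columns},
        p_values={t: float(fit.pvalues[t]) for t in X.columns},
        odds_ratios=ors,
        n=int(fit.nobs),
        converged=True,
        score_norm=score_norm,
    )


def fit_interaction_model(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ("age",),
    prs_col: str = "prs_z",
    group_col: str = "group",
    exclude_booking: bool = False,
) -> InteractionResult:
    """Logistic model ``outcome ~ PRS + group + PRS x group + covariates``.

    With ``exclude_booking`` set, subjects flagged ``booking_gdm`` are
    dropped first (the intervention cannot prevent a diagnosis already made
    at enrolment). The interaction term is reported as ``prs_x_group``.
    """
    df = cohort
    if exclude_booking:
        if "booking_gdm" not in df.columns:
            raise ValidationError("exclude_booking requires a booking_gdm column")
        df = df[df["booking_gdm"] != 1]
    cols = [outcome, prs_col, group_col, *covariates]
    data = _complete_cases(df, cols).copy()
    data["prs_x_group"] = data[prs_col] * data[group_col]
    X = _design(data, [prs_col, group_col, "prs_x_group", *covariates])
    X = X.rename(columns={prs_col: "prs", group_col: "group"})
    return _fit_logit(data[outcome], X, ["prs_x_group"])


def per_tertile_intervention_or(
    cohort: pd.DataFrame,
    tertiles: TertileAssignment,
    outcome: str,
    covariates: Sequence[str] = ("age",),
    group_col: str = "group",
) -> dict[str, InteractionResult]:
    """Intervention odds ratio within each PRS tertile.

    Fits ``outcome ~ group + covariates`` separately per tertile. An empty
    arm x outcome cell inside a tertile makes the OR inestimable and raises
    a diagnostic error naming the tertile.
    """
    if len(tertiles.labels) != len(cohort):
        raise ValidationError("tertile assignment does not match the cohort length")
    results: dict[str, InteractionResult] = {}
    for lab in TERTILE_LABELS:
        sub = cohort[tertiles.labels == lab]
        data = _complete_cases(sub, [outcome, group_col, *covariates])
        cells = pd.crosstab(data[group_col], data[outcome])
        if cells.shape != (2, 2) or (cells.to_numpy() == 0).any():
            raise ModelFitError(
                f"empty arm x outcome cell in tertile {lab!r}: OR inestimable"
            )
        X = _design(data, [group_col, *covariates]).rename(columns={group_col: "group"})
        results[lab] = _fit_logit(data[outcome], X, ["group"])
    return results


def adjusted_occurrence(
    cohort: pd.DataFrame,
    tertiles: TertileAssignment,
    outcome: str,
    covariates: Sequence[str] = ("age",),
    group_col: str = "group",
) -> pd.DataFrame:
    """Covariate-adjusted outcome occurrence per tertile x arm cell.

    Fits a linear probability model with a full tertile x arm cell mean
    structure plus covariates, then evaluates each cell's estimated
    marginal mean with every covariate at its grand mean. Returns a frame
    with columns tertile, group, adjusted, ci_low, ci_high, n.
    """
    if len(tertiles.labels) != len(cohort):
        raise ValidationError("tertile assignment does not match the cohort length")
    df = cohort.copy()
    df["_tertile"] = tertiles.labels
    data = _complete_cases(df, [outcome, group_col, *covariates])
    for lab, grp in product(TERTILE_LABELS, (0, 1)):
        cell = data[(data["_tertile"] == lab) & (data[group_col] == grp)]
        if cell.empty:
            raise ComputationError(f"no complete-case data in cell ({lab}, arm {grp})")

    # Cell-mean coding: one indicator per tertile x arm cell, no intercept.
    cell_cols = []
    X = pd.DataFrame(index=data.index)
    for lab, grp in product(TERTILE_LABELS, (0, 1)):
        col = f"cell_{lab}_{grp}"
        X[col] = ((data["_tertile"] == lab) & (data[group_col] == grp)).astype(float)
        cell_cols.append(col)
    for c in covariates:
        X[c] = data[c].astype(float) - data[c].astype(float).mean()  # centred
    fit = sm.OLS(data[outcome].astype(float), X).fit()

    rows = []
    for lab, grp in product(TERTILE_LABELS, (0, 1)):
        col = f"cell_{lab}_{grp}"
        vec = pd.Series(0.0, index=X.columns)
        vec[col] = 1.0  # covariates centred, so grand mean = 0
        est = float(vec @ fit.params)
        se = float(np.sqrt(vec @ fit.cov_params() @ vec))
        tcrit = stats.t.ppf(0.975, fit.df_resid)
        rows.append(
            {
                "tertile": lab,
                "group": grp,
                "adjusted": est,
                "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se,
                "n": int(X[col].sum()),
            }
        )
    return pd.DataFrame(rows)


def chi_square_2xk(counts: np.ndarray | Sequence[Sequence[float]]) -> ContingencyResult:
    """Pearson chi-square test of a 2 x k table, no continuity correction.

    ``df = k - 1``; the p-value is the upper tail of the chi-square
    distribution. All expected counts must be positive.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValidationError(f"expected a 2 x k table with k >= 2, got {table.shape}")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValidationError("counts must be non-negative integers")
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        raise ValidationError("zero marginal total; chi-square undefined")
    expected = np.outer(row_m, col_m) / table.sum()
    statistic = float(((table - expected) ** 2 / expected).sum())
    df = table.shape[1] - 1
    return ContingencyResult(
        table=table.astype(int),
        statistic=statistic,
        df=df,
        p=float(stats.chi2.sf(statistic, df)),
    )


def reconstruct_counts(
    n_total: int,
    numerators: Sequence[int],
    percentages: Sequence[float],
    decimals: int = 1,
) -> list[int]:
    """Invert printed "n (%)" cells back to per-group denominators.

    For each group, the denominator must reproduce the printed percentage
    at its printed precision; among the feasible combinations the one whose
    denominators sum to ``n_total`` is returned (ties broken by closeness
    to ``numerator / percentage * 100``). Raises when no combination sums
    correctly — the printed numbers would then be mutually inconsistent.
    """
    if len(numerators) != len(percentages):
        raise ValidationError("numerators and percentages differ in length")
    tol = 0.5 * 10.0 ** (-decimals) + 1e-12
    feasible: list[list[int]] = []
    for num, pct in zip(numerators, percentages):
        if not 0 < pct <= 100:
            raise ValidationError(f"percentage {pct} outside (0, 100]")
        target = num / pct * 100.0
        lo = max(num, int(np.floor(target)) - 3)
        hi = int(np.ceil(target)) + 3
        ds = [d for d in range(lo, hi + 1) if abs(100.0 * num / d - pct) <= tol]
        if not ds:
            raise ValidationError(
                f"no denominator reproduces {num} ({pct}%) at {decimals} decimals"
            )
        feasible.append(sorted(ds, key=lambda d: abs(d - target)))
    best: Optional[tuple[float, tuple[int, ...]]] = None
    for combo in product(*feasible):
        if sum(combo) != n_total:
            continue
        dev = sum(
            abs(d - num / pct * 100.0)
            for d, num, pct in zip(combo, numerators, percentages)
        )
        if best is None or dev < best[0]:
            best = (dev, combo)
    if best is None:
        raise ValidationError(
            f"no denominator combination sums to {n_total}; inconsistent inputs"
        )
    return list(best[1])


def snp_level_interactions(
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    age_col: str = "age",
) -> pd.DataFrame:
    """Per-SNP dosage x intervention interaction scan.

    For each variant fits ``outcome ~ dosage + group + dosage x group +
    age`` by maximum likelihood. Monomorphic variants and fits that fail
    (separation, non-convergence) are skipped with the reason recorded,
    never fatal. Returns one row per variant: snp, beta_interaction, se, p,
    n, status.
    """
    if genotypes.n_samples != len(cohort):
        raise ValidationError("genotype and cohort sample counts differ")
    rows = []
    base = cohort[[outcome, group_col, age_col]].reset_index(drop=True)
    for j, snp in enumerate(genotypes.variants["id"]):
        d = genotypes.dosages[:, j]
        data = base.copy()
        data["dosage"] = d
        data = data.dropna()
        if data["dosage"].nunique() < 2:
            rows.append(
                {"snp": snp, "beta_interaction": np.nan, "se": np.nan, "p": np.nan,
                 "n": len(data), "status": "monomorphic"}
            )
            continue
        data["dosage_x_group"] = data["dosage"] * data[group_col]
        try:
            X = _design(data, ["dosage", group_col, "dosage_x_group", age_col])
            res = _fit_logit(data[outcome], X, ["dosage_x_group"])
            rows.append(
                {
                    "snp": snp,
                    "beta_interaction": res.coefficients["dosage_x_group"],
                    "se": res.se["dosage_x_group"],
                    "p": res.p_values["dosage_x_group"],
                    "n": res.n,
                    "status": "ok",
                }
            )
        except (ModelFitError, ValidationError) as e:
            log.info("SNP %s skipped: %s", snp, e)
            rows.append(
                {"snp": snp, "beta_interaction": np.nan, "se": np.nan, "p": np.nan,
                 "n": len(data), "status": "failed"}
            )
    return pd.DataFrame(rows)
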