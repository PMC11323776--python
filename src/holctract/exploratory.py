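"""Exploratory OLS contrasts of outcome prevalence across HOLC grades.

Two families of models, each run crude, region-adjusted, and fully
adjusted (region + the eight 1940 sociodemographics):

* a four-grade model with indicators for grades B, C, D against the
  grade-A reference, all in one model;
* adjacent-pair models restricted to two grades, with a single indicator
  for the less desirable grade.

Estimates are prevalence differences in percentage points with 95%
confidence intervals computed as estimate +/- 1.96 * SE using classical
homoskedastic standard errors (a heteroskedasticity-robust option is
exposed but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import ANALYSIS_GRADES, COVARIATE_COLUMNS, GRADE_PAIRS, REGIONS, DataError

Adjustment = Literal["crude", "region", "region_plus_socio"]
ADJUSTMENTS = ("crude", "region", "region_plus_socio")

#: Normal-approximation 95% multiplier, used throughout for CI half-widths.
Z95 = 1.96


@dataclass(frozen=True)
class ModelSpec:
    """Identifies one regression cell: outcome, contrast, adjustment level."""

    outcome: str
    contrast: Union[str, tuple[str, str]]  # "four_grade" or (lower, higher)
    adjustment: Adjustment

    def __post_init__(self) -> None:
        if self.adjustment not in ADJUSTMENTS:
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        if self.contrast != "four_grade" and tuple(self.contrast) not in GRADE_PAIRS:
            raise ValueError(f"unknown contrast {self.contrast!r}")


@dataclass(frozen=True)
class EffectEstimate:
    """A prevalence difference (percentage points) with its 95% CI."""

    spec: ModelSpec
    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_total: int
    n_lower_grade: int

    def as_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "contrast": self.spec.contrast
            if isinstance(self.spec.contrast, str)
            else f"{self.spec.contrast[0]}_vs_{self.spec.contrast[1]}",
            "adjustment": self.spec.adjustment,
            "term": self.term,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_total": self.n_total,
            "n_lower": self.n_lower_grade,
        }


@dataclass
class LinearFit:
    """OLS fit summary: coefficients, covariance, and basic diagnostics."""

    coef: pd.Series
    cov: pd.DataFrame
    n_used: int
    n_dropped: int
    rss: float
    sigma2: float
    results: object  # underlying statsmodels results, for inspection


def fit_linear_model(
    design: pd.DataFrame,
    response: pd.Series,
    robust: bool = False,
) -> LinearFit:
    """Least-squares fit with classical (or optionally HC1) covariance.

    ``design`` must include an intercept column. Rows with any missing
    value in the used columns are dropped and counted. Rank deficiency is
    an error naming the collinear columns.
    """
    joined = pd.concat([design, response.rename("__y__")], axis=1)
    complete = joined.dropna()
    n_dropped = len(joined) - len(complete)
    X = complete[design.columns]
    y = complete["__y__"]
    n, p = X.shape
    if n <= p:
        raise DataError(f"n={n} <= p={p}: not enough rows to fit")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # QR with pivoting: columns pivoted past the numerical rank are the
        # ones that add no new direction.
        from scipy.linalg import qr

        _, _, piv = qr(X.to_numpy(), pivoting=True, mode="economic")
        collinear = [X.columns[i] for i in piv[rank:]]
        raise DataError(f"design is rank-deficient; collinear columns: {collinear}")

    model = sm.OLS(y.to_numpy(), X.to_numpy())
    res = model.fit(cov_type="HC1") if robust else model.fit()
    coef = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    rss = float(res.ssr)
    return LinearFit(
        coef=coef,
        cov=cov,
        n_used=n,
        n_dropped=n_dropped,
        rss=rss,
        sigma2=rss / (n - p),
        results=res,
    )


def _design_matrix(
    df: pd.DataFrame,
    grade_terms: Sequence[str],
    adjustment: Adjustment,
) -> pd.DataFrame:
    """Intercept + grade indicators (+ region dummies, + 1940 covariates).

    Region reference category is Midwest; covariates enter untransformed
    in their original units.
    """
    cols = {"intercept": np.ones(len(df))}
    for g in grade_terms:
        cols[f"grade_{g}"] = (df["grade"] == g).astype(float).to_numpy()
    if adjustment in ("region", "region_plus_socio"):
        for r in REGIONS[1:]:
            cols[f"region_{r}"] = (df["region"] == r).astype(float).to_numpy()
    if adjustment == "region_plus_socio":
        for c in COVARIATE_COLUMNS:
            cols[c] = df[c].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def _estimate_from_fit(
    fit: LinearFit, term: str, spec: ModelSpec, n_total: int, n_lower: int
) -> EffectEstimate:
    est = float(fit.coef[term])
    se = float(np.sqrt(fit.cov.loc[term, term]))
    return EffectEstimate(
        spec=spec,
        term=term,
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        n_total=n_total,
        n_lower_grade=n_lower,
    )


def fit_four_grade(
    data: pd.DataFrame,
    outcome: str,
    adjustment: Adjustment = "crude",
    robust: bool = False,
) -> list[EffectEstimate]:
    """One model per outcome: B, C, D indicators against the grade-A reference.

    Complete-case on the outcome: rows missing it are dropped first.
    Returns the three grade-indicator estimates in order B, C, D.
    """
    sub = data.dropna(subset=[outcome])
    present = set(sub["grade"].unique())
    missing = [g for g in ANALYSIS_GRADES if g not in present]
    if missing:
        raise DataError(f"grades absent from the {outcome} subset: {missing}")
    design = _design_matrix(sub, grade_terms=["B", "C", "D"], adjustment=adjustment)
    fit = fit_linear_model(design, sub[outcome], robust=robust)
    out = []
    for g in ("B", "C", "D"):
        spec = ModelSpec(outcome=outcome, contrast="four_grade", adjustment=adjustment)
        out.append(
            _estimate_from_fit(
                fit, f"grade_{g}", spec, fit.n_used, int((sub["grade"] == g).sum())
            )
        )
    return out


def fit_pairwise(
    data: pd.DataFrame,
    pair: tuple[str, str],
    outcome: str,
    adjustment: Adjustment = "crude",
    robust: bool = False,
) -> EffectEstimate:
    """Two-grade model: indicator for the less desirable grade of *pair*.

    ``pair`` is (lower, higher), e.g. ("C", "B"); the estimate is the
    prevalence difference lower-minus-higher in percentage points.
    """
    lower, higher = pair
    if (lower, higher) not in GRADE_PAIRS:
        raise ValueError(f"pair {pair!r} is not an adjacent grade pair")
    sub = data[data["grade"].isin([lower, higher])].dropna(subset=[outcome])
    for g in (lower, higher):
        if (sub["grade"] == g).sum() == 0:
            raise DataError(f"grade {g} absent from the {outcome} subset")
    design = _design_matrix(sub, grade_terms=[lower], adjustment=adjustment)
    fit = fit_linear_model(design, sub[outcome], robust=robust)
    spec = ModelSpec(outcome=outcome, contrast=(lower, higher), adjustment=adjustment)
    return _estimate_from_fit(
        fit, f"grade_{lower}", spec, fit.n_used, int((sub["grade"] == lower).sum())
    )


def exploratory_tables(
    data: pd.DataFrame,
    outcomes: Sequence[str] = ("diabetes", "hypertension", "obesity"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full grids of four-grade and pairwise models.

    Returns (four-grade table, pairwise table) as flat DataFrames, one row
    per (outcome, term/pair, adjustment).
    """
    rows4 = []
    rows_pair = []
    for outcome in outcomes:
        for adj in ADJUSTMENTS:
            for est in fit_four_grade(data, outcome, adjustment=adj):
                rows4.append(est.as_dict())
            for pair in GRADE_PAIRS:
                rows_pair.append(
                    fit_pairwise(data, pair, outcome, adjustment=adj).as_dict()
                )
    return pd.DataFrame(rows4), pd.DataFrame(rows_pair)
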