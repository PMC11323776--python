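"""Propensity-score / IPW / marginal-structural-model estimation.

For each adjacent grade pair (B vs A, C vs B, D vs C) the less desirable
grade is the "treatment". The estimator chain is:

1. logit propensity model for treatment given the eight 1940
   sociodemographics and region, fitted by iteratively reweighted least
   squares on internally standardized covariates;
2. trimming to the pooled [alpha, 1 - alpha] propensity-score quantile
   interval (default alpha = 0.025) to remove extreme scores;
3. inverse-probability weights building a pseudo-population in which the
   1940 covariates are balanced across the two grades;
4. a marginal structural model — weighted least squares of prevalence on
   the treatment indicator alone — whose coefficient is the causal
   prevalence difference in percentage points, with an HC0 sandwich
   standard error treating the weights as fixed (optionally a
   nonparametric bootstrap that re-fits the whole chain).

A greedy full-matching estimator on the same propensity scores serves as
the sensitivity analysis.

The estimators follow the scikit-learn protocol (``fit``, ``get_params``,
trailing-underscore fitted attributes); the module-level functions
(`fit_propensity`, `trim_by_propensity`, ...) are thin wrappers over them
operating on the analytic DataFrame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .types import COVARIATE_COLUMNS, REGIONS, DataError

Z95 = 1.96
DEFAULT_SEED = 20240301


# ---------------------------------------------------------------------------
# Logistic regression by IRLS


class PropensityScoreModel(BaseEstimator):
    """Unpenalized logistic regression fitted by IRLS.

    Covariates are standardized internally for numerical conditioning and
    the coefficients are transformed back to the original units, so
    ``coef_`` and ``intercept_`` are on the scale of the inputs.

    Parameters
    ----------
    max_iter : int
        IRLS iteration cap; exceeding it raises rather than returning a
        half-converged model.
    tol : float
        Convergence threshold on the max absolute coefficient change
        (standardized scale).
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, z) -> "PropensityScoreModel":
        X = np.asarray(X, dtype=float)
        z = np.asarray(z, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if set(np.unique(z)) - {0.0, 1.0}:
            raise ValueError("treatment indicator must be 0/1")
        n, p = X.shape
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = np.column_stack([np.ones(n), (X - mu) / sd])

        beta = np.zeros(p + 1)
        zbar = z.mean()
        if not (0 < zbar < 1):
            raise DataError("treatment indicator is constant")
        beta[0] = np.log(zbar / (1 - zbar))

        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = Xs @ beta
            prob = expit(eta)
            w = np.clip(prob * (1 - prob), 1e-12, None)
            # Newton step via weighted normal equations
            XtW = Xs.T * w
            try:
                step = np.linalg.solve(XtW @ Xs, Xs.T @ (z - prob))
            except np.linalg.LinAlgError as exc:
                raise DataError(
                    "propensity logit information matrix is singular "
                    "(collinear covariates or complete separation); inspect "
                    "the covariates"
                ) from exc
            beta = beta + step
            if np.max(np.abs(step)) < self.tol:
                converged = True
                break
        if not converged:
            # under (quasi-)complete separation the ML estimate diverges, so
            # the Newton step never falls below tol: report it as separation
            # rather than returning a half-converged model
            raise DataError(
                f"propensity logit did not converge in {self.max_iter} IRLS "
                "iterations: the two grades are (quasi-)separated by the "
                "covariates; inspect the covariates rather than clamping"
            )
        scores = expit(Xs @ beta)
        # a converged finite MLE is not separation, but a score rounding to
        # exactly 0/1 in floating point would break the downstream inverse
        # weighting; genuinely extreme-but-interior scores are left for the
        # trimming step to remove
        if scores.min() <= 0.0 or scores.max() >= 1.0:
            raise DataError(
                "fitted propensity scores reach 0/1 at floating-point "
                "precision; inspect the extreme covariate profiles rather "
                "than clamping"
            )

        self.n_iter_ = it
        self.converged_ = True
        self.coef_ = beta[1:] / sd
        self.intercept_ = float(beta[0] - np.sum(beta[1:] * mu / sd))
        self.scores_ = scores
        self.n_features_in_ = p
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p1 = expit(self.intercept_ + X @ self.coef_)
        return np.column_stack([1 - p1, p1])


# ---------------------------------------------------------------------------
# Dataclasses mirroring the pipeline's result objects


@dataclass
class PropensityFit:
    """Fitted propensity scores for one grade pair on the analytic data."""

    pair: tuple[str, str]
    tract_ids: np.ndarray
    coefficients: pd.Series  # original-scale, named; includes intercept
    scores: np.ndarray
    treatment: np.ndarray
    converged: bool
    iterations: int


@dataclass
class WeightedSample:
    """Trim bounds, retained tracts and (optionally) their IPW weights."""

    tract_ids: np.ndarray
    trim_lo: float
    trim_hi: float
    n_original: int
    weights: Optional[np.ndarray] = None
    weight_type: str = "unstabilized"
    ess_treated: float = float("nan")
    ess_control: float = float("nan")


@dataclass
class MatchedSets:
    """Greedy full-matching result: set membership and match weights."""

    tract_ids: np.ndarray
    set_ids: np.ndarray
    match_weights: np.ndarray
    n_sets: int


@dataclass
class MSMResult:
    """One causal results cell: pair, outcome, estimate and 95% CI."""

    pair: tuple[str, str]
    outcome: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_trimmed: int
    n_original: int
    weight_type: str = "unstabilized"
    method: str = "ipw"
    bootstrap_ci: Optional[tuple[float, float]] = None

    def as_dict(self) -> dict:
        d = {
            "pair": f"{self.pair[0]}_vs_{self.pair[1]}",
            "outcome": self.outcome,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_trimmed": self.n_trimmed,
            "n_original": self.n_original,
            "method": self.method,
        }
        if self.bootstrap_ci is not None:
            d["boot_ci_low"], d["boot_ci_high"] = self.bootstrap_ci
        return d


# ---------------------------------------------------------------------------
# Design-matrix helper shared with the wrapper functions


def propensity_design(data: pd.DataFrame) -> pd.DataFrame:
    """8 sociodemographics + 3 region indicators (Midwest reference)."""
    cols = {c: data[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS}
    for r in REGIONS[1:]:
        cols[f"region_{r}"] = (data["region"] == r).astype(float).to_numpy()
    return pd.DataFrame(cols, index=data.index)


def fit_propensity(
    data: pd.DataFrame, pair: tuple[str, str], min_arm: int = 25
) -> PropensityFit:
    """Fit the pair's propensity model on the grade-restricted data.

    ``pair`` is (lower, higher); treatment = 1 for the less desirable
    grade. The data frame must already carry ``grade``, ``region`` and the
    eight covariate columns (missing outcomes are fine — the propensity
    stage ignores outcomes).
    """
    lower, higher = pair
    sub = data[data["grade"].isin([lower, higher])]
    z = (sub["grade"] == lower).to_numpy(dtype=float)
    n_t, n_c = int(z.sum()), int((1 - z).sum())
    if min(n_t, n_c) < min_arm:
        raise DataError(
            f"pair {pair}: arm sizes ({n_t} treated, {n_c} control) below "
            f"the minimum of {min_arm}"
        )
    X = propensity_design(sub)
    model = PropensityScoreModel().fit(X.to_numpy(), z)
    coefficients = pd.Series(
        np.concatenate([[model.intercept_], model.coef_]),
        index=["intercept"] + list(X.columns),
    )
    return PropensityFit(
        pair=pair,
        tract_ids=sub["tract_id"].to_numpy()
        if "tract_id" in sub
        else sub.index.to_numpy(),
        coefficients=coefficients,
        scores=model.scores_,
        treatment=z,
        converged=model.converged_,
        iterations=model.n_iter_,
    )


def trim_by_propensity(fit: PropensityFit, alpha: float = 0.025) -> WeightedSample:
    """Retain tracts inside the pooled [alpha, 1-alpha] score quantiles.

    Quantiles use the linear-interpolation definition; bounds are
    inclusive. Retention below 50% signals pathological overlap and is an
    error rather than a silent result.
    """
    if not (0.0 <= alpha < 0.5):
        raise ValueError(f"alpha must be in [0, 0.5), got {alpha}")
    if alpha == 0.0:
        lo, hi = float(fit.scores.min()), float(fit.scores.max())
    else:
        lo, hi = np.quantile(fit.scores, [alpha, 1 - alpha], method="linear")
    keep = (fit.scores >= lo) & (fit.scores <= hi)
    if keep.sum() < 0.5 * len(keep):
        raise DataError(
            f"trimming retained only {int(keep.sum())}/{len(keep)} tracts; "
            "propensity overlap is pathological"
        )
    return WeightedSample(
        tract_ids=fit.tract_ids[keep],
        trim_lo=float(lo),
        trim_hi=float(hi),
        n_original=len(fit.scores),
    )


def compute_ipw_weights(
    fit: PropensityFit,
    sample: WeightedSample,
    weight_type: str = "unstabilized",
) -> WeightedSample:
    """Attach inverse-probability ATE weights to the retained tracts.

    Unstabilized: w = Z/e + (1-Z)/(1-e). Stabilized: arms are multiplied
    by the marginal treated/control fractions and the result is normalized
    to overall mean 1 (a pure rescaling, so point estimates are
    unaffected; only the weight distribution is tamed).
    """
    if weight_type not in ("unstabilized", "stabilized"):
        raise ValueError(f"unknown weight_type {weight_type!r}")
    keep = np.isin(fit.tract_ids, sample.tract_ids)
    e = fit.scores[keep]
    z = fit.treatment[keep]
    if e.min() <= 0.0 or e.max() >= 1.0:
        raise DataError("retained scores must be strictly inside (0, 1)")
    w = z / e + (1 - z) / (1 - e)
    if weight_type == "stabilized":
        p1 = fit.treatment.mean()
        w = np.where(z == 1, p1 * w, (1 - p1) * w)
        w = w / w.mean()

    def ess(x: np.ndarray) -> float:
        return float(x.sum() ** 2 / (x**2).sum()) if len(x) else float("nan")

    return WeightedSample(
        tract_ids=sample.tract_ids,
        trim_lo=sample.trim_lo,
        trim_hi=sample.trim_hi,
        n_original=sample.n_original,
        weights=w,
        weight_type=weight_type,
        ess_treated=ess(w[z == 1]),
        ess_control=ess(w[z == 0]),
    )


# ---------------------------------------------------------------------------
# Weighted difference engine (shared by MSM and matching)


def weighted_difference(
    y: np.ndarray, z: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Weighted mean difference (treated - control) and HC0 sandwich SE.

    Identical to the treatment coefficient of a weighted least-squares
    regression of y on [1, z]; the sandwich treats the weights as fixed:
    (X'WX)^-1 (sum_i w_i^2 e_i^2 x_i x_i') (X'WX)^-1.
    """
    X = np.column_stack([np.ones(len(z)), z])
    XtW = X.T * w
    bread = np.linalg.inv(XtW @ X)
    beta = bread @ (XtW @ y)
    resid = y - X @ beta
    meat = (X.T * (w**2 * resid**2)) @ X
    V = bread @ meat @ bread
    return float(beta[1]), float(np.sqrt(V[1, 1]))


def estimate_msm(
    data: pd.DataFrame,
    fit: PropensityFit,
    weighted: WeightedSample,
    outcome: str,
    n_bootstrap: int = 0,
    seed: int = DEFAULT_SEED,
    trim_alpha: float = 0.025,
) -> MSMResult:
    """Marginal structural model on the pseudo-population for one outcome.

    Rows missing the outcome are dropped *after* trimming, so outcomes
    with different missingness have different Ns from the same trimmed
    sample. ``n_original`` counts the pair tracts with the outcome
    observed before trimming. With ``n_bootstrap`` > 0, a nonparametric
    bootstrap re-fits propensity, trimming and weighting on each resample
    and a percentile CI is attached alongside the sandwich CI.
    """
    if weighted.weights is None:
        raise ValueError("weights not computed; call compute_ipw_weights first")
    sub = data.set_index("tract_id") if "tract_id" in data else data
    y_all = sub[outcome]

    keep_ids = weighted.tract_ids
    y = y_all.reindex(keep_ids).to_numpy(dtype=float)
    keep = np.isin(fit.tract_ids, keep_ids)
    z = fit.treatment[keep]
    w = weighted.weights
    ok = ~np.isnan(y)
    y, z, w = y[ok], z[ok], w[ok]
    if len(y) == 0 or z.min() == z.max():
        raise DataError(
            f"outcome {outcome!r}: one arm empty after trimming and "
            "missing-outcome removal"
        )
    est, se = weighted_difference(y, z, w)

    n_original = int(y_all.reindex(fit.tract_ids).notna().sum())
    boot_ci = None
    if n_bootstrap > 0:
        boot_ci = _bootstrap_msm(
            data, fit.pair, outcome, n_bootstrap, seed, trim_alpha,
            weighted.weight_type,
        )
    return MSMResult(
        pair=fit.pair,
        outcome=outcome,
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        n_trimmed=int(ok.sum()),
        n_original=n_original,
        weight_type=weighted.weight_type,
        method="ipw",
        bootstrap_ci=boot_ci,
    )


def _bootstrap_msm(
    data: pd.DataFrame,
    pair: tuple[str, str],
    outcome: str,
    n_bootstrap: int,
    seed: int,
    trim_alpha: float,
    weight_type: str,
    design_cols: Optional[list[str]] = None,
) -> tuple[float, float]:
    """Percentile CI from resampling tracts and re-fitting the whole chain.

    ``design_cols`` switches the propensity refit to explicit design
    columns (used by the raw-matrix estimator front-end) instead of the
    named covariate + region design.
    """
    rng = np.random.default_rng(seed)
    lower, higher = pair
    sub = data[data["grade"].isin([lower, higher])].reset_index(drop=True)
    estimates = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(sub), size=len(sub))
        boot = sub.iloc[idx].reset_index(drop=True)
        boot = boot.assign(tract_id=[f"b{i}" for i in range(len(boot))])
        try:
            if design_cols is None:
                f = fit_propensity(boot, pair)
            else:
                f = _fit_propensity_raw(boot, design_cols, pair)
            s = trim_by_propensity(f, alpha=trim_alpha)
            ws = compute_ipw_weights(f, s, weight_type=weight_type)
            res = estimate_msm(boot, f, ws, outcome)
        except DataError:
            continue  # degenerate resample; skip
        estimates.append(res.estimate)
    if len(estimates) < max(10, n_bootstrap // 2):
        raise DataError("bootstrap failed on most resamples")
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Greedy full matching


def full_matching(fit: PropensityFit, sample: WeightedSample) -> MatchedSets:
    """Greedy full matching on the trimmed propensity scores.

    Each unit of the minority arm seeds one matched set; every majority-arm
    unit joins the seed nearest in propensity score. Within a set,
    minority units carry weight 1 and majority units 1/(set majority
    count); majority-arm weights are then rescaled so each arm's weights
    sum to its retained size.
    """
    keep = np.isin(fit.tract_ids, sample.tract_ids)
    ids = fit.tract_ids[keep]
    e = fit.scores[keep]
    z = fit.treatment[keep].astype(bool)
    n_t, n_c = int(z.sum()), int((~z).sum())
    if n_t == 0 or n_c == 0:
        raise DataError("both arms must be non-empty after trimming")
    minority_is_treated = n_t <= n_c
    minority = z if minority_is_treated else ~z
    n_sets = int(minority.sum())

    def _nearest(sorted_vals: np.ndarray, queries: np.ndarray) -> np.ndarray:
        """Index into sorted_vals of the value nearest each query."""
        if len(sorted_vals) == 1:
            return np.zeros(len(queries), dtype=int)
        pos = np.clip(np.searchsorted(sorted_vals, queries), 1, len(sorted_vals) - 1)
        left, right = sorted_vals[pos - 1], sorted_vals[pos]
        return np.where(
            np.abs(queries - left) <= np.abs(queries - right), pos - 1, pos
        )

    seed_scores = e[minority]
    order = np.argsort(seed_scores, kind="stable")
    set_ids = np.empty(len(ids), dtype=int)
    set_ids[minority] = np.arange(n_sets)
    maj_idx = np.flatnonzero(~minority)
    set_ids[maj_idx] = order[_nearest(seed_scores[order], e[maj_idx])]

    # a seed left without any majority-arm unit would form a one-arm set;
    # fold its minority unit into the set of its nearest majority unit
    maj_counts = np.bincount(set_ids[maj_idx], minlength=n_sets)
    empty_sets = np.flatnonzero(maj_counts == 0)
    if len(empty_sets) > 0:
        maj_order = np.argsort(e[maj_idx], kind="stable")
        maj_sorted = e[maj_idx][maj_order]
        min_idx = np.flatnonzero(minority)
        for s in empty_sets:
            unit = min_idx[s]
            host = maj_idx[maj_order[_nearest(maj_sorted, e[[unit]])[0]]]
            set_ids[unit] = set_ids[host]

    # weights: minority-arm units 1; majority-arm units carry their set's
    # minority/majority ratio, then are rescaled to the arm's retained size
    weights = np.ones(len(ids))
    min_counts = np.bincount(set_ids[minority], minlength=n_sets)
    maj_counts = np.bincount(set_ids[maj_idx], minlength=n_sets)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(maj_counts > 0, min_counts / np.maximum(maj_counts, 1), 0.0)
    weights[maj_idx] = ratio[set_ids[maj_idx]]
    weights[maj_idx] *= len(maj_idx) / weights[maj_idx].sum()
    n_nonempty = int(np.sum((min_counts > 0) & (maj_counts > 0)))
    return MatchedSets(
        tract_ids=ids,
        set_ids=set_ids,
        match_weights=weights,
        n_sets=n_nonempty,
    )


def matched_estimate(
    data: pd.DataFrame,
    fit: PropensityFit,
    sets: MatchedSets,
    outcome: str,
) -> MSMResult:
    """Prevalence difference in the matched sample (match-weighted, HC0 SE)."""
    sub = data.set_index("tract_id") if "tract_id" in data else data
    y = sub[outcome].reindex(sets.tract_ids).to_numpy(dtype=float)
    keep = np.isin(fit.tract_ids, sets.tract_ids)
    z = fit.treatment[keep]
    ok = ~np.isnan(y)
    y, z, w = y[ok], z[ok], sets.match_weights[ok]
    if len(y) == 0 or z.min() == z.max():
        raise DataError(f"outcome {outcome!r}: one arm empty in matched sample")
    est, se = weighted_difference(y, z, w)
    n_original = int(sub[outcome].reindex(fit.tract_ids).notna().sum())
    return MSMResult(
        pair=fit.pair,
        outcome=outcome,
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        n_trimmed=int(ok.sum()),
        n_original=n_original,
        weight_type="match",
        method="full_matching",
    )


# ---------------------------------------------------------------------------
# Balance diagnostics


def covariate_balance(
    data: pd.DataFrame,
    treatment: np.ndarray,
    weights: Optional[np.ndarray] = None,
    covariates: Sequence[str] = COVARIATE_COLUMNS,
) -> pd.DataFrame:
    """Standardized mean differences, unweighted and weighted.

    The denominator is always the *unweighted* pooled SD
    sqrt((sd_T^2 + sd_C^2)/2), a fixed convention so the weighted and
    unweighted SMDs are on the same scale. A zero pooled SD yields SMD 0
    with ``zero_sd`` flagged.
    """
    z = np.asarray(treatment, dtype=bool)
    if z.sum() < 2 or (~z).sum() < 2:
        raise DataError("need at least 2 units per arm for balance")
    w = np.ones(len(z)) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for c in covariates:
        x = data[c].to_numpy(dtype=float)
        sd_pool = np.sqrt((x[z].std(ddof=1) ** 2 + x[~z].std(ddof=1) ** 2) / 2)
        zero_sd = sd_pool == 0
        if zero_sd:
            warnings.warn(f"covariate {c!r} has zero pooled SD", stacklevel=2)
            smd_u = smd_w = 0.0
        else:
            smd_u = (x[z].mean() - x[~z].mean()) / sd_pool
            mt = np.average(x[z], weights=w[z])
            mc = np.average(x[~z], weights=w[~z])
            smd_w = (mt - mc) / sd_pool
        rows.append(
            {
                "covariate": c,
                "smd_unweighted": smd_u,
                "smd_weighted": smd_w,
                "zero_sd": zero_sd,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scikit-learn front-end over the whole chain


class IPWPrevalenceDifference(BaseEstimator):
    """Propensity-trim-weight-MSM chain as a single sklearn-style estimator.

    ``fit(X, z, y)`` takes the covariate design (original units, no
    intercept column), a 0/1 treatment indicator, and the outcome vector
    (NaN allowed; complete-case after trimming). Fitted attributes carry
    the estimate, sandwich CI, weights and diagnostics.

    Parameters
    ----------
    trim_alpha : float
        Two-tail pooled-quantile trimming fraction (0.025 in the main
        analysis).
    weight_type : {"unstabilized", "stabilized"}
        ATE weight flavour; stabilization rescales, it does not move the
        point estimate.
    n_bootstrap : int
        If > 0, a percentile bootstrap CI re-fitting the whole chain.
    seed : int
        RNG seed for the bootstrap.
    """

    def __init__(
        self,
        trim_alpha: float = 0.025,
        weight_type: str = "unstabilized",
        n_bootstrap: int = 0,
        seed: int = DEFAULT_SEED,
    ):
        self.trim_alpha = trim_alpha
        self.weight_type = weight_type
        self.n_bootstrap = n_bootstrap
        self.seed = seed

    def fit(self, X, z, y) -> "IPWPrevalenceDifference":
        X = pd.DataFrame(np.asarray(X, dtype=float))
        z = np.asarray(z, dtype=float)
        y = np.asarray(y, dtype=float)
        data = X.copy()
        data.columns = [f"x{i}" for i in range(X.shape[1])]
        data["tract_id"] = [f"u{i}" for i in range(len(X))]
        data["grade"] = np.where(z == 1, "C", "B")
        data["__y__"] = y
        # run the chain through the same functions the pipeline uses, with
        # the raw columns standing in for the named covariate design
        fitp = _fit_propensity_raw(data, [c for c in data.columns if c.startswith("x")])
        sample = trim_by_propensity(fitp, alpha=self.trim_alpha)
        weighted = compute_ipw_weights(fitp, sample, weight_type=self.weight_type)
        res = estimate_msm(data, fitp, weighted, "__y__")

        self.propensity_ = fitp
        self.scores_ = fitp.scores
        self.trim_lo_, self.trim_hi_ = weighted.trim_lo, weighted.trim_hi
        self.weights_ = weighted.weights
        self.estimate_ = res.estimate
        self.se_ = res.se
        self.ci_low_, self.ci_high_ = res.ci_low, res.ci_high
        self.n_retained_ = res.n_trimmed
        self.n_original_ = res.n_original
        self.ess_treated_ = weighted.ess_treated
        self.ess_control_ = weighted.ess_control
        if self.n_bootstrap > 0:
            self.bootstrap_ci_ = _bootstrap_msm(
                data, ("C", "B"), "__y__", self.n_bootstrap, self.seed,
                self.trim_alpha, self.weight_type,
                design_cols=[c for c in data.columns if c.startswith("x")],
            )
        return self


def _fit_propensity_raw(
    data: pd.DataFrame, cols: list[str], pair: tuple[str, str] = ("C", "B")
) -> PropensityFit:
    """Propensity fit on explicit design columns (no region machinery)."""
    lower, higher = pair
    sub = data[data["grade"].isin([lower, higher])]
    z = (sub["grade"] == lower).to_numpy(dtype=float)
    model = PropensityScoreModel().fit(sub[cols].to_numpy(), z)
    return PropensityFit(
        pair=pair,
        tract_ids=sub["tract_id"].to_numpy(),
        coefficients=pd.Series(
            np.concatenate([[model.intercept_], model.coef_]),
            index=["intercept"] + cols,
        ),
        scores=model.scores_,
        treatment=z,
        converged=model.converged_,
        iterations=model.n_iter_,
    )


def run_pair_analysis(
    data: pd.DataFrame,
    pair: tuple[str, str],
    outcomes: Sequence[str],
    trim_alpha: float = 0.025,
    weight_type: str = "unstabilized",
    n_bootstrap: int = 0,
    seed: int = DEFAULT_SEED,
    with_matching: bool = True,
) -> tuple[list[MSMResult], list[MSMResult], pd.DataFrame]:
    """Full causal chain for one grade pair across outcomes.

    Returns (IPW results, matched sensitivity results, balance table).
    """
    fitp = fit_propensity(data, pair)
    sample = trim_by_propensity(fitp, alpha=trim_alpha)
    weighted = compute_ipw_weights(fitp, sample, weight_type=weight_type)

    ipw = [
        estimate_msm(
            data, fitp, weighted, o, n_bootstrap=n_bootstrap, seed=seed,
            trim_alpha=trim_alpha,
        )
        for o in outcomes
    ]
    matched: list[MSMResult] = []
    if with_matching:
        sets = full_matching(fitp, sample)
        matched = [matched_estimate(data, fitp, sets, o) for o in outcomes]

    sub = data[data["grade"].isin(pair)]
    sub = sub.set_index("tract_id") if "tract_id" in sub else sub
    keep = np.isin(fitp.tract_ids, weighted.tract_ids)
    bal = covariate_balance(
        sub.reindex(weighted.tract_ids),
        fitp.treatment[keep],
        weights=weighted.weights,
    )
    bal.insert(0, "pair", f"{pair[0]}_vs_{pair[1]}")
    return ipw, matched, bal
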