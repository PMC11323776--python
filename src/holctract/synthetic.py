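"""Synthetic tract data with known ground truth.

Everything the pipeline consumes can be generated here: rectangular
tract/grade geometries whose overlap fractions have closed forms, 1940
sociodemographic covariates whose grade-conditional distributions are
patterned on the published descriptive table for the real study area,
grade assignment from a latent logit on the covariates (confounding by
construction), and continuous tract-level outcome prevalences built as
baseline + covariate effects + a known grade effect + noise.

Most percentages are drawn from truncated normals on [0, 100] whose
parent parameters are calibrated so the generated mean matches the
target exactly and the SD as closely as the family allows (a
left-truncated-at-zero normal cannot have SD much above its mean). The
heavily right-skewed variables — percent Black/non-White, home value,
population density — use right-truncated lognormals instead, with the
mean calibrated exactly and the coefficient of variation preserved.
Within a grade the eight covariates co-move through a one-factor
Gaussian copula, and a fraction of "lookalike" tracts draw their vector
from an adjacent grade, so adjacent grades overlap multivariately the
way real tract samples do.
"""

from __future__ import annotations

import functools
import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from shapely.geometry import box

from .types import (
    ANALYSIS_GRADES,
    COVARIATE_COLUMNS,
    GRADES,
    REGIONS,
    DataError,
    GradedArea,
    TractGeometry,
)

DEFAULT_SEED = 20240301

# ---------------------------------------------------------------------------
# Grade-conditional covariate parameters (mean, sd), patterned on the real
# study area's 1940 descriptives. Home value in k$, density in 1k/km^2.

TABLE1_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "pct_black": {"A": (1.6, 2.4), "B": (1.0, 2.5), "C": (1.6, 6.4), "D": (12.4, 23.8)},
    "pct_nonwhite": {"A": (2.1, 3.5), "B": (1.2, 2.8), "C": (1.8, 6.4), "D": (13.1, 23.9)},
    "pct_foreign_white": {"A": (9.5, 6.7), "B": (13.3, 7.9), "C": (16.2, 9.0), "D": (19.2, 10.8)},
    "median_home_value": {"A": (8.8, 4.1), "B": (6.1, 2.5), "C": (4.3, 1.6), "D": (3.3, 1.8)},
    "pct_college": {"A": (20.9, 7.4), "B": (11.8, 7.0), "C": (6.9, 5.4), "D": (3.8, 3.5)},
    "pct_unemployed": {"A": (5.3, 3.0), "B": (8.9, 3.9), "C": (13.0, 4.9), "D": (20.0, 6.7)},
    "pct_renter": {"A": (39.8, 20.0), "B": (51.8, 20.6), "C": (58.4, 19.0), "D": (68.9, 17.8)},
    "pop_density": {"A": (3.2, 6.8), "B": (6.6, 8.5), "C": (7.1, 7.4), "D": (11.2, 11.4)},
}

#: Grade marginal proportions (counts 330/1337/3390/1924 of 6981).
GRADE_MARGINALS = {"A": 330 / 6981, "B": 1337 / 6981, "C": 3390 / 6981, "D": 1924 / 6981}

#: Region counts by grade (rows: region; from the study area's crosstab).
REGION_BY_GRADE_COUNTS = pd.DataFrame(
    {
        "A": [124, 76, 53, 77],
        "B": [407, 528, 144, 258],
        "C": [1042, 1308, 272, 768],
        "D": [525, 763, 235, 401],
    },
    index=list(REGIONS),
)

#: Lognormal rather than truncated-normal variables (strictly positive,
#: right-skewed in the real data), with upper caps reflecting the range of
#: the 1940 census (home values were topcoded around $20k; tract densities
#: above ~80 k/km^2 did not occur). Draws are from the right-truncated
#: lognormal with the mean calibrated exactly.
LOGNORMAL_CAPS = {"median_home_value": 30.0, "pop_density": 80.0}
LOGNORMAL_COLUMNS = tuple(LOGNORMAL_CAPS)

#: Signed loadings of each covariate on a latent within-grade
#: "disadvantage" factor (Gaussian copula). The 1940 measures co-move
#: strongly in real data — unemployment, tenancy and density rise together
#: while home value and college attainment fall — and independent draws
#: would make the grades far more multivariately separable than any real
#: tract sample, producing propensity-score separation that real data do
#: not show. A loading of +/-0.7 gives pairwise correlations near +/-0.5.
FACTOR_LOADINGS = {
    "pct_black": 0.7,
    "pct_nonwhite": 0.7,
    "pct_foreign_white": 0.5,
    "median_home_value": -0.7,
    "pct_college": -0.7,
    "pct_unemployed": 0.7,
    "pct_renter": 0.7,
    "pop_density": 0.5,
}

#: Outcome intercepts near the pooled study-area means (%).
OUTCOME_BASELINES = {"diabetes": 11.6, "hypertension": 31.2, "obesity": 32.3}

#: Residual noise SDs (%) after covariate effects.
OUTCOME_NOISE_SD = {"diabetes": 3.5, "hypertension": 7.0, "obesity": 7.5}

#: Per-outcome effects of standardized covariates on prevalence (%).
#: Coefficients on the heavy-tailed variables (percent Black, home value)
#: are kept moderate so that clipped prevalences stay below 1% of draws.
OUTCOME_COEFFICIENTS = {
    "diabetes": {"pct_unemployed": 1.8, "pct_black": 0.6, "median_home_value": -0.8},
    "hypertension": {"pct_unemployed": 1.5, "pct_black": 1.0, "median_home_value": -0.8},
    "obesity": {"pct_unemployed": 2.5, "pct_black": 0.8, "median_home_value": -1.2},
}

#: True causal step effects between adjacent grades (A->B, B->C, C->D), in
#: percentage points, used by the descriptive-table-patterned scenario.
GRADE_STEP_EFFECTS = {
    "diabetes": {"B": 0.27, "C": 0.89, "D": -0.24},
    "hypertension": {"B": 0.22, "C": 0.83, "D": 0.03},
    "obesity": {"B": 1.24, "C": 0.90, "D": -0.17},
}

#: Confounded-scenario assignment logit (on standardized covariates).
CONFOUNDED_ASSIGNMENT = {
    "pct_unemployed": 0.9,
    "pct_black": 0.5,
    "median_home_value": -0.6,
}


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind one generated dataset."""

    delta: Union[float, dict]
    assignment_coefficients: dict[str, float]
    outcome_coefficients: dict[str, dict[str, float]]
    baseline: dict[str, float]
    noise_sd: dict[str, float]
    seed: int = DEFAULT_SEED
    hypertension_missing_rate: float = 0.0
    clip_events: int = 0

    def to_json(self) -> str:
        d = dict(self.__dict__)
        return json.dumps(d, indent=2, sort_keys=True, default=float)


# ---------------------------------------------------------------------------
# Marginal calibration under winsorized copula scores

#: Copula scores are winsorized at +/- this many SDs: tracts extreme in all
#: eight covariates at once do not occur in real samples.
WINSOR_LIMIT = 3.0

# fixed quadrature over the winsorized standard-normal score distribution
_WNODES = np.linspace(-WINSOR_LIMIT, WINSOR_LIMIT, 801)
_WSTEP = _WNODES[1] - _WNODES[0]
_WDENS = stats.norm.pdf(_WNODES) * _WSTEP
_WTAIL = float(stats.norm.cdf(-WINSOR_LIMIT))


def _winsorized_mean(transform) -> float:
    """E[transform(s)] for s a winsorized standard normal."""
    vals = transform(_WNODES)
    return float(np.sum(_WDENS * vals) + _WTAIL * (vals[0] + vals[-1]))


@functools.lru_cache(maxsize=512)
def truncnorm_parent_params(
    mean: float, sd: float, lo: float = 0.0, hi: float = 100.0
) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncation has the target mean.

    The SD is matched by least squares first (it may be infeasible for
    strongly skewed targets — a left-truncated-at-zero normal cannot have
    SD much above its mean); the mean is then matched exactly by a 1-D
    root solve in mu, accounting for the winsorized copula scores.
    """
    if not (lo < mean < hi):
        raise ValueError(f"target mean {mean} outside ({lo}, {hi})")

    def moments(mu: float, sigma: float) -> tuple[float, float]:
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return float(m), float(np.sqrt(v))

    def resid(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        m, s = moments(mu, np.exp(log_sigma))
        return np.array([(m - mean) / max(sd, 1.0), (s - sd) / max(sd, 1.0)])

    sol = optimize.least_squares(
        resid,
        x0=np.array([mean, np.log(sd)]),
        bounds=([lo - 50 * sd, np.log(sd * 1e-3)], [hi + 50 * sd, np.log(sd * 50)]),
    )
    sigma = float(np.exp(sol.x[1]))

    def mean_gap(mu: float) -> float:
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return (
            _winsorized_mean(
                lambda s: stats.truncnorm.ppf(
                    stats.norm.cdf(s), a, b, loc=mu, scale=sigma
                )
            )
            - mean
        )

    span = 60 * sigma + (hi - lo)
    mu = optimize.brentq(mean_gap, mean - span, mean + span, xtol=1e-10)
    return float(mu), sigma


def _truncnorm_from_scores(
    scores: np.ndarray, mean: float, sd: float,
    lo: float = 0.0, hi: float = 100.0,
) -> np.ndarray:
    """Map (winsorized) copula scores to the calibrated truncated normal."""
    if sd == 0:
        return np.full(len(scores), mean)
    mu, sigma = truncnorm_parent_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    u = stats.norm.cdf(scores)
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def _draw_truncnorm(
    rng: np.random.Generator, n: int, mean: float, sd: float,
    lo: float = 0.0, hi: float = 100.0,
) -> np.ndarray:
    return _truncnorm_from_scores(rng.standard_normal(n), mean, sd, lo, hi)


@functools.lru_cache(maxsize=512)
def lognorm_trunc_params(mean: float, sd: float, hi: float = 100.0) -> tuple[float, float]:
    """(mu, sigma) of a lognormal truncated above at *hi* with the target mean.

    sigma comes from the untruncated moment match (preserving the target
    coefficient of variation, hence the realistic right skew); mu is then
    solved so the mean under winsorized copula scores equals the target
    exactly.
    """
    sigma = float(np.sqrt(np.log1p((sd / mean) ** 2)))

    def mean_gap(mu: float) -> float:
        cap = stats.norm.cdf((np.log(hi) - mu) / sigma)
        return (
            _winsorized_mean(
                lambda s: np.exp(
                    mu + sigma * stats.norm.ppf(stats.norm.cdf(s) * cap)
                )
            )
            - mean
        )

    mu0 = np.log(mean) - sigma**2 / 2
    mu = optimize.brentq(mean_gap, mu0 - 1.0, np.log(hi) + 6 * sigma, xtol=1e-12)
    return float(mu), sigma


def _lognorm_trunc_from_scores(
    scores: np.ndarray, mean: float, sd: float, hi: float = 100.0
) -> np.ndarray:
    """Copula scores -> right-truncated lognormal (heavy right skew)."""
    if sd == 0:
        return np.full(len(scores), mean)
    mu, sigma = lognorm_trunc_params(mean, sd, hi)
    cap = stats.norm.cdf((np.log(hi) - mu) / sigma)
    u = stats.norm.cdf(scores) * cap
    return np.exp(mu + sigma * stats.norm.ppf(u))


# ---------------------------------------------------------------------------
# Geometry


def generate_geometries(
    n_side: int,
    holc_layout: str = "stripes",
    jitter: float = 0.15,
    seed: int = DEFAULT_SEED,
) -> tuple[list[TractGeometry], list[GradedArea], pd.DataFrame]:
    """Unit-square tract grid plus jittered rectangular graded areas.

    Tracts are the n_side**2 unit squares of an axis-aligned grid. Graded
    areas are rectangles — vertical stripes or a block grid — cycling
    through grades A..E with an ungraded gap every sixth cell, with edges
    offset by ``jitter`` (as a fraction of the nominal cell size) so tract
    and grade boundaries misalign. The exact per-tract overlap fractions
    (closed-form rectangle intersections) are returned as the oracle
    table, one row per tract with one column per grade.
    """
    if n_side < 2:
        raise ValueError("n_side must be >= 2")
    if holc_layout not in ("stripes", "blocks"):
        raise ValueError(f"unknown layout {holc_layout!r}")
    if not (0.0 <= jitter <= 0.4):
        raise ValueError("jitter must be in [0, 0.4]")
    rng = np.random.default_rng(seed)
    side = float(n_side)

    tracts = [
        TractGeometry(tract_id=f"s{i * n_side + j:04d}",
                      geometry=box(j, i, j + 1, i + 1))
        for i in range(n_side)
        for j in range(n_side)
    ]

    cycle = ["A", "B", "C", "D", "E", None]

    def cuts(n_cells: int, w0: float) -> np.ndarray:
        edges = np.arange(n_cells + 1, dtype=float) * w0
        if jitter > 0 and n_cells > 1:
            edges[1:-1] += rng.uniform(-jitter * w0, jitter * w0, size=n_cells - 1)
        edges[-1] = side
        return edges

    rects: list[tuple[str, float, float, float, float]] = []  # grade, x1,y1,x2,y2
    if holc_layout == "stripes":
        n_stripes = 2 * n_side  # nominal width 0.5: every tract sees >=2 stripes
        edges = cuts(n_stripes, side / n_stripes)
        for k in range(n_stripes):
            g = cycle[k % len(cycle)]
            if g is not None:
                rects.append((g, edges[k], 0.0, edges[k + 1], side))
    else:
        n_blocks = n_side  # nominal 1x1 blocks, offset by jitter
        xe = cuts(n_blocks, side / n_blocks)
        ye = cuts(n_blocks, side / n_blocks)
        k = 0
        for bi in range(n_blocks):
            for bj in range(n_blocks):
                g = cycle[k % len(cycle)]
                k += 1
                if g is not None:
                    rects.append((g, xe[bj], ye[bi], xe[bj + 1], ye[bi + 1]))
    if not rects:
        raise DataError("layout produced zero graded coverage")

    areas = [
        GradedArea(area_id=f"h{idx:03d}", grade=g, geometry=box(x1, y1, x2, y2))
        for idx, (g, x1, y1, x2, y2) in enumerate(rects)
    ]

    # closed-form rectangle-intersection oracle
    rows = []
    for t in tracts:
        tx1, ty1, tx2, ty2 = t.geometry.bounds
        fracs = dict.fromkeys(GRADES, 0.0)
        for g, x1, y1, x2, y2 in rects:
            w = max(0.0, min(x2, tx2) - max(x1, tx1))
            h = max(0.0, min(y2, ty2) - max(y1, ty1))
            fracs[g] += w * h  # tract area is exactly 1
        rows.append({"tract_id": t.tract_id, **fracs})
    oracle = pd.DataFrame(rows).set_index("tract_id")
    return tracts, areas, oracle


def oracle_argmax(oracle: pd.DataFrame, threshold: float = 0.25) -> pd.Series:
    """Winning grade per tract from the exact overlap table (ties toward A).

    Tracts below the total-coverage threshold or with zero overlap get
    None, matching the area-overlap linkage rule.
    """
    out = {}
    for tid, row in oracle.iterrows():
        total = row[list(GRADES)].sum()
        best, best_f = None, 0.0
        for g in GRADES:
            if row[g] > best_f:
                best, best_f = g, row[g]
        out[tid] = best if (best is not None and total >= threshold) else None
    return pd.Series(out, name="oracle_grade")


# ---------------------------------------------------------------------------
# Covariates, assignment, outcomes


#: Fraction of tracts whose covariates come from a random grade's
#: conditional distribution instead of their own grade's ("lookalike"
#: neighborhoods: transitional or arguably misgraded areas). This keeps
#: adjacent grades multivariately overlapping, as real tract data are;
#: without it the eight covariates jointly separate the grades almost
#: perfectly at desk-scale n, which no real HOLC sample does.
DEFAULT_MIXING_RATE = 0.10


#: Lookalike tracts draw from a grade adjacent to their own (transitional
#: or arguably misgraded neighborhoods sit at grade boundaries).
ADJACENT_GRADES = {"A": ("B",), "B": ("A", "C"), "C": ("B", "D"), "D": ("C",)}


def _adjusted_targets(
    params: dict[str, dict[str, tuple[float, float]]], rate: float
) -> dict[str, dict[str, tuple[float, float]]]:
    """Adjust per-grade target means so the lookalike mixture restores them.

    With mixing rate r, the observable grade-g mean is
    (1-r) * target_g + r * mean(adjacent targets); the 4x4 linear system
    is solved per covariate so the grade-conditional means of the
    generated data match the stated values exactly. SDs are left at their
    stated values (the mixture inflates spread slightly, which is the
    point).
    """
    if rate == 0:
        return params
    order = list(GRADE_MARGINALS)
    M = np.eye(len(order)) * (1 - rate)
    for i, g in enumerate(order):
        for h in ADJACENT_GRADES[g]:
            M[i, order.index(h)] += rate / len(ADJACENT_GRADES[g])
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for c, by_grade in params.items():
        m = np.array([by_grade[g][0] for g in order])
        t = np.linalg.solve(M, m)
        if (t <= 0).any():
            bad = order[int(np.argmin(t))]
            raise ValueError(
                f"mixing rate {rate} infeasible for {c} grade {bad} "
                f"(adjusted mean {t.min():.3g} <= 0)"
            )
        out[c] = {g: (float(t[i]), by_grade[g][1]) for i, g in enumerate(order)}
    return out


def generate_covariates(
    n: int,
    params: dict[str, dict[str, tuple[float, float]]] = TABLE1_PARAMS,
    seed: int = DEFAULT_SEED,
    grades: Optional[Sequence[Optional[str]]] = None,
    mixing_rate: float = DEFAULT_MIXING_RATE,
) -> pd.DataFrame:
    """Draw grade-conditional 1940 covariates, regions and grade labels.

    If ``grades`` is None, grades are drawn from the study-area marginals;
    otherwise the given labels are used (None entries get a marginal draw
    for the purpose of covariate generation but keep a missing grade
    label). Percent non-White is percent Black plus a non-negative
    increment, so the subset invariant holds by construction. A
    ``mixing_rate`` fraction of tracts are lookalikes drawing their whole
    covariate vector from a random grade's distribution; the grade
    targets are pre-adjusted so grade-conditional means still match
    ``params`` exactly.
    """
    if n < 100:
        raise ValueError("n must be >= 100 for stable covariate distributions")
    if not (0.0 <= mixing_rate < 0.5):
        raise ValueError("mixing_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    grade_names = list(GRADE_MARGINALS)
    probs = np.array(list(GRADE_MARGINALS.values()))
    probs = probs / probs.sum()
    if grades is None:
        grade_arr = rng.choice(grade_names, size=n, p=probs)
        grade_label = grade_arr.copy()
    else:
        grade_label = np.array([g if g is not None else "" for g in grades], dtype=object)
        if len(grade_label) != n:
            raise ValueError("grades length must equal n")
        grade_arr = grade_label.copy()
        missing = grade_arr == ""
        grade_arr[missing] = rng.choice(grade_names, size=int(missing.sum()), p=probs)
        # ungraded/E tracts draw covariates from a marginal grade
        grade_arr = np.where(np.isin(grade_arr, grade_names), grade_arr, "C")

    adj = _adjusted_targets(params, mixing_rate)
    # lookalike tracts: covariates from an adjacent grade, label unchanged
    draw_grade = grade_arr.copy()
    if mixing_rate > 0:
        cont = rng.uniform(size=n) < mixing_rate
        pick = rng.uniform(size=n)
        for g in grade_names:
            gm = cont & (grade_arr == g)
            neigh = ADJACENT_GRADES[g]
            idx = np.minimum((pick[gm] * len(neigh)).astype(int), len(neigh) - 1)
            draw_grade[gm] = np.array(neigh, dtype=object)[idx]

    df = pd.DataFrame({"tract_id": [f"s{i:05d}" for i in range(n)],
                       "grade": grade_label})
    cols = {c: np.empty(n) for c in COVARIATE_COLUMNS}
    region = np.empty(n, dtype=object)
    for g in grade_names:
        mask = draw_grade == g
        m = int(mask.sum())
        if m > 0:
            factor = rng.standard_normal(m)  # shared within-grade disadvantage

            def scores(col: str) -> np.ndarray:
                lam = FACTOR_LOADINGS[col]
                s = lam * factor + np.sqrt(1 - lam**2) * rng.standard_normal(m)
                # winsorize the copula score: joint 4-sigma tracts (extreme in
                # all eight covariates at once) do not occur in real samples
                return np.clip(s, -3.0, 3.0)

            for c in COVARIATE_COLUMNS:
                if c in ("pct_nonwhite", "pct_black"):
                    continue
                mean, sd = adj[c][g]
                if c in LOGNORMAL_COLUMNS:
                    cols[c][mask] = _lognorm_trunc_from_scores(
                        scores(c), mean, sd, hi=LOGNORMAL_CAPS[c]
                    )
                else:
                    cols[c][mask] = _truncnorm_from_scores(scores(c), mean, sd)
            # percent Black is extremely right-skewed in real tracts (many
            # near zero, a long tail); a truncated lognormal keeps the
            # target mean exactly and the skew realistic
            bm, bs = adj["pct_black"][g]
            cols["pct_black"][mask] = _lognorm_trunc_from_scores(
                scores("pct_black"), bm, bs
            )
            nm, ns = adj["pct_nonwhite"][g]
            extra_mean = max(nm - bm, 0.05)
            extra_sd = float(np.sqrt(max(ns**2 - bs**2, 0.25)))
            extra = _lognorm_trunc_from_scores(
                scores("pct_nonwhite"), extra_mean, extra_sd
            )
            cols["pct_nonwhite"][mask] = np.minimum(
                cols["pct_black"][mask] + extra, 100.0
            )
        # region follows the labelled grade, not the lookalike draw
        gmask = grade_arr == g
        if gmask.sum() > 0:
            rprobs = REGION_BY_GRADE_COUNTS[g].to_numpy(dtype=float)
            region[gmask] = rng.choice(
                list(REGIONS), size=int(gmask.sum()), p=rprobs / rprobs.sum()
            )
    for c in COVARIATE_COLUMNS:
        df[c] = cols[c]
    df["region"] = region
    return df


def standardize(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Z-score the named columns against the sample itself."""
    out = {}
    for c in columns:
        x = df[c].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        out[c] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return pd.DataFrame(out, index=df.index)


def generate_assignment(
    covariates: pd.DataFrame,
    assignment_coefficients: dict[str, float],
    seed: int = DEFAULT_SEED,
    intercept: float = 0.0,
    min_arm: int = 25,
) -> np.ndarray:
    """Bernoulli treatment (1 = less desirable grade) from a latent logit.

    Coefficients apply to covariates standardized within the sample, so
    their magnitudes are comparable across variables. This is exactly the
    assignment mechanism the propensity model must undo.
    """
    rng = np.random.default_rng(seed)
    xstd = standardize(covariates, list(assignment_coefficients))
    eta = intercept + sum(
        b * xstd[c].to_numpy() for c, b in assignment_coefficients.items()
    )
    z = (rng.uniform(size=len(covariates)) < expit(eta)).astype(float)
    n_t = int(z.sum())
    if min(n_t, len(z) - n_t) < min_arm:
        raise DataError(
            f"assignment produced an arm with < {min_arm} units; increase n"
        )
    return z


def generate_outcomes(
    covariates: pd.DataFrame,
    treatment: Optional[np.ndarray],
    truth: SimulationTruth,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Continuous tract-level prevalences with a known grade effect.

    outcome = baseline + coefficients . standardized covariates
              + delta * treatment + Normal(0, noise_sd), clipped to
    [0, 100] with clip events counted onto ``truth.clip_events``.

    With ``treatment`` None, the grade column drives cumulative step
    effects instead (delta must then be a per-outcome dict of per-grade
    steps). Hypertension values go missing completely at random at
    ``truth.hypertension_missing_rate``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    xstd = standardize(covariates, COVARIATE_COLUMNS)
    out = pd.DataFrame({"tract_id": covariates["tract_id"].to_numpy()})
    n = len(covariates)
    truth.clip_events = 0
    for outcome, base in truth.baseline.items():
        y = np.full(n, float(base))
        for c, b in truth.outcome_coefficients.get(outcome, {}).items():
            y = y + b * xstd[c].to_numpy()
        if treatment is not None:
            delta = truth.delta[outcome] if isinstance(truth.delta, dict) else truth.delta
            y = y + float(delta) * np.asarray(treatment, dtype=float)
        else:
            steps = truth.delta[outcome]  # per-grade cumulative steps
            cum = {"A": 0.0}
            acc = 0.0
            for g in ("B", "C", "D"):
                acc += steps[g]
                cum[g] = acc
            effect = covariates["grade"].map(lambda g: cum.get(g, 0.0)).to_numpy()
            y = y + effect
        sd = truth.noise_sd[outcome] if isinstance(truth.noise_sd, dict) else truth.noise_sd
        y = y + rng.normal(0.0, float(sd), size=n)
        clipped = np.clip(y, 0.0, 100.0)
        truth.clip_events += int(np.sum(clipped != y))
        if outcome == "hypertension" and truth.hypertension_missing_rate > 0:
            miss = rng.uniform(size=n) < truth.hypertension_missing_rate
            clipped = np.where(miss, np.nan, clipped)
        out[outcome] = clipped
    if truth.clip_events > 0.01 * n * len(truth.baseline):
        warnings.warn(
            f"{truth.clip_events} outcome values clipped to [0, 100] "
            "(> 1% of draws); check baselines and noise SDs",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# Scenarios


@dataclass
class Scenario:
    """A named, fully seeded simulation design with its ground truth."""

    name: str
    n: int
    pair: Optional[tuple[str, str]]
    truth: SimulationTruth
    assignment_intercept: float = 0.0

    def generate(self, seed: Optional[int] = None) -> pd.DataFrame:
        """One analytic-style DataFrame (tract_id, grade, region,
        covariates, outcomes)."""
        base = self.truth.seed if seed is None else seed
        ss = np.random.SeedSequence(base).spawn(3)
        sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
        cov = generate_covariates(self.n, seed=sub[0])
        if self.pair is not None:
            z = generate_assignment(
                cov,
                self.truth.assignment_coefficients,
                seed=sub[1],
                intercept=self.assignment_intercept,
            )
            cov = cov.assign(grade=np.where(z == 1, self.pair[0], self.pair[1]))
            out = generate_outcomes(cov, z, self.truth, seed=sub[2])
        else:
            out = generate_outcomes(cov, None, self.truth, seed=sub[2])
        return cov.merge(out, on="tract_id")


def make_scenarios(n: int = 4000) -> dict[str, Scenario]:
    """The named simulation designs used throughout testing.

    * ``confounded``: pairwise design, true effect delta = 1.0, assignment
      and outcome both loaded on unemployment / percent Black / home value
      so the crude contrast is biased upward by more than +1 point;
    * ``null``: same confounding, delta = 0;
    * ``unconfounded``: random assignment (all logit coefficients 0),
      delta = 1.0;
    * ``table1-like``: all four grades with covariate distributions from
      the descriptive table and small known step effects between adjacent
      grades.
    """
    def pair_truth(delta: float, confounded: bool, seed: int) -> SimulationTruth:
        return SimulationTruth(
            delta=delta,
            assignment_coefficients=dict(CONFOUNDED_ASSIGNMENT) if confounded else {
                c: 0.0 for c in CONFOUNDED_ASSIGNMENT
            },
            outcome_coefficients={"diabetes": dict(OUTCOME_COEFFICIENTS["diabetes"])},
            baseline={"diabetes": OUTCOME_BASELINES["diabetes"]},
            noise_sd={"diabetes": OUTCOME_NOISE_SD["diabetes"]},
            seed=seed,
        )

    scenarios = {
        "confounded": Scenario(
            name="confounded", n=n, pair=("C", "B"),
            truth=pair_truth(1.0, True, DEFAULT_SEED),
        ),
        "null": Scenario(
            name="null", n=n, pair=("C", "B"),
            truth=pair_truth(0.0, True, DEFAULT_SEED + 1),
        ),
        "unconfounded": Scenario(
            name="unconfounded", n=n, pair=("C", "B"),
            truth=pair_truth(1.0, False, DEFAULT_SEED + 2),
        ),
        "table1-like": Scenario(
            name="table1-like", n=n, pair=None,
            truth=SimulationTruth(
                delta={o: dict(s) for o, s in GRADE_STEP_EFFECTS.items()},
                assignment_coefficients={},
                outcome_coefficients={o: dict(c) for o, c in OUTCOME_COEFFICIENTS.items()},
                baseline=dict(OUTCOME_BASELINES),
                noise_sd=dict(OUTCOME_NOISE_SD),
                seed=DEFAULT_SEED + 3,
                hypertension_missing_rate=0.03,
            ),
        ),
    }
    return scenarios


def generate_study_files(
    outdir,
    n_side: int = 24,
    holc_layout: str = "blocks",
    jitter: float = 0.15,
    seed: int = DEFAULT_SEED,
) -> SimulationTruth:
    """Write a complete synthetic study to disk in the pipeline's formats.

    Emits ``tracts.geojson``, ``holc_areas.geojson``, ``covariates.csv``,
    ``outcomes.csv``, the exact-overlap oracle table and a ground-truth
    sidecar JSON. Grades follow the geometry (oracle argmax at the 25%
    threshold); covariates are grade-conditional; outcomes follow the
    descriptive-table-patterned scenario.
    """
    from pathlib import Path

    from .io import write_polygon_layer, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]

    tracts, areas, oracle = generate_geometries(
        n_side, holc_layout=holc_layout, jitter=jitter, seed=sub[0]
    )
    grades = oracle_argmax(oracle, threshold=0.25)
    n = len(tracts)
    grade_seq = [grades[t.tract_id] for t in tracts]
    cov = generate_covariates(n, seed=sub[1], grades=grade_seq)
    cov = cov.assign(tract_id=[t.tract_id for t in tracts])

    truth = make_scenarios(n=n)["table1-like"].truth
    truth.seed = sub[2]
    # grade steps only apply to analyzed grades; E/ungraded stay at baseline
    cov_for_outcomes = cov.assign(
        grade=[g if g in ANALYSIS_GRADES else "" for g in cov["grade"]]
    )
    out = generate_outcomes(cov_for_outcomes, None, truth, seed=sub[2])

    write_polygon_layer(outdir / "tracts.geojson", tracts)
    write_polygon_layer(outdir / "holc_areas.geojson", areas)
    write_table(outdir / "covariates.csv",
                cov[["tract_id", *COVARIATE_COLUMNS, "region"]])
    write_table(outdir / "outcomes.csv", out)
    oracle.reset_index().to_csv(outdir / "overlap_oracle.csv", index=False)
    (outdir / "truth.json").write_text(truth.to_json(), encoding="utf-8")
    return truth
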