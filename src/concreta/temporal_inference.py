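"""Bioindicator and temporal-trend detection.

Four complementary detectors for taxa tied to a condition (here, the
alkali-silica-reaction-prone series) or to time:

* **IndVal.g** — indicator value sqrt(A * B) with group-size-corrected
  specificity A (per-group *means*, so unbalanced groups do not bias
  the statistic) and sensitivity B (fraction of the combination's
  samples containing the taxon); significance by group-label
  permutation of the per-taxon best combination.
* **presence/absence logistic regression** — presence ~ series x
  standardized months; the interaction term asks whether prevalence
  trajectories diverge between series.
* **interval differential abundance** — per-group B-spline fits of
  relative abundance over months; maximal constant-sign runs of the
  difference curve are candidate intervals scored by the area of the
  absolute difference, with a permutation null built from the maximal
  interval area under within-time-point group-label shuffles.
* **seasonal + trend decomposition** — ordinary least squares of
  Hellinger-transformed abundance on harmonic pairs of day-of-year plus
  a linear months term; reports the seasonal-block F test, the months
  slope, and the peak day-of-year of the fitted seasonal component.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# IndVal.g
# ---------------------------------------------------------------------------


@dataclass
class IndicatorResult:
    taxon: str
    combination: tuple
    specificity: float      # A, group-equalized
    sensitivity: float      # B
    indval: float           # sqrt(A * B)
    p: float
    p_adj: float | None = None


def _indval_stats(x: np.ndarray, group_codes: np.ndarray, n_groups: int,
                  combos):
    """Best (A, B, IndVal, combo) over group combinations for one taxon."""
    means = np.array([x[group_codes == g].mean() for g in range(n_groups)])
    sizes = np.array([(group_codes == g).sum() for g in range(n_groups)])
    present = x > 0
    pres_per_group = np.array([present[group_codes == g].sum()
                               for g in range(n_groups)])
    total_mean = means.sum()
    best = (-1.0, None, 0.0, 0.0)
    for combo in combos:
        a = means[list(combo)].sum() / total_mean if total_mean > 0 else 0.0
        b = pres_per_group[list(combo)].sum() / sizes[list(combo)].sum()
        stat = np.sqrt(a * b)
        if stat > best[0]:
            best = (stat, combo, a, b)
    return best


def filter_taxa(counts: pd.DataFrame, min_obs: int = 5, min_samples: int = 5):
    """Keep taxa with more than ``min_obs`` observations in more than
    ``min_samples`` samples (both strict)."""
    keep = [(counts[c] > 0).sum() > min_samples and counts[c].sum() > min_obs
            for c in counts.columns]
    return counts.loc[:, keep]


def indval_g(counts: pd.DataFrame, groups, max_order: int = 1,
             permutations: int = 1000, min_obs: int = 5, min_samples: int = 5,
             seed: int | None = None) -> list[IndicatorResult]:
    """Group-size-corrected indicator species analysis.

    ``counts`` is samples x taxa (agglomerate to the desired taxon level
    first); ``groups`` aligns with its rows. p-values are the
    Laplace-corrected exceedance of the observed best-combination
    statistic under ``permutations`` group-label shuffles; the full
    all-groups combination is excluded (it is uninformative).
    """
    groups = pd.Series(groups, index=counts.index) \
        if not isinstance(groups, pd.Series) else groups.loc[counts.index]
    levels = list(pd.unique(groups))
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if max_order > k:
        raise ValueError("max_order exceeds the number of groups")
    codes = groups.map({g: i for i, g in enumerate(levels)}).to_numpy()
    counts = filter_taxa(counts, min_obs, min_samples)
    combos = [c for r in range(1, max_order + 1)
              for c in itertools.combinations(range(k), r)
              if len(c) < k or k == 1]
    if not combos:  # max_order == k == number of groups, all-set excluded
        combos = [c for r in range(1, max_order)
                  for c in itertools.combinations(range(k), r)]
    rng = np.random.default_rng(seed)
    x_all = counts.to_numpy(dtype=float)
    results = []
    perms = [rng.permutation(codes) for _ in range(permutations)]
    for t, taxon in enumerate(counts.columns):
        x = x_all[:, t]
        stat, combo, a, b = _indval_stats(x, codes, k, combos)
        exceed = 0
        for pc in perms:
            s_p, _, _, _ = _indval_stats(x, pc, k, combos)
            if s_p >= stat - 1e-12:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + permutations)
        results.append(IndicatorResult(
            taxon, tuple(levels[i] for i in combo), a, b, stat, p))
    if results:
        padj = _benjamini_hochberg(np.array([r.p for r in results]))
        for r, q in zip(results, padj):
            r.p_adj = float(q)
    return results


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# presence/absence logistic regression
# ---------------------------------------------------------------------------


def presence_logistic(counts: pd.DataFrame, series, months,
                      min_samples: int = 5) -> pd.DataFrame:
    """Per-taxon logistic fit: presence ~ series + scale(months) + interaction.

    ``series`` is a two-level factor (the reactive series is coded 1 by
    sorted order); months are standardized. Reports the interaction
    log-odds and its two-sided Wald p; non-convergence or separation is
    reported per taxon, not fatal.
    """
    series = pd.Series(series, index=counts.index) \
        if not isinstance(series, pd.Series) else series.loc[counts.index]
    months = pd.Series(months, index=counts.index) \
        if not isinstance(months, pd.Series) else months.loc[counts.index]
    levels = sorted(pd.unique(series))
    if len(levels) != 2:
        raise ValueError("presence_logistic needs exactly two series")
    asr = (series == levels[1]).astype(float).to_numpy()
    mz = (months - months.mean()) / months.std(ddof=0)
    mz = mz.to_numpy()
    design = np.column_stack([np.ones_like(mz), asr, mz, asr * mz])
    rows = []
    for taxon in counts.columns:
        y = (counts[taxon] > 0).astype(float).to_numpy()
        if (y > 0).sum() < min_samples:
            continue
        if y.min() == y.max():
            rows.append((taxon, np.nan, np.nan, "constant_response"))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                    maxiter=100)
            coef = float(fit.params[3])
            p = float(fit.pvalues[3])
            status = "ok"
            if not np.isfinite(p) or abs(coef) > 20:
                status = "separation"
            rows.append((taxon, coef, p, status))
        except Exception as exc:  # pragma: no cover - rare numeric failures
            rows.append((taxon, np.nan, np.nan, f"error:{exc}"))
    return pd.DataFrame(rows, columns=["taxon", "interaction_log_odds", "p",
                                       "status"]).set_index("taxon")


# ---------------------------------------------------------------------------
# interval differential abundance
# ---------------------------------------------------------------------------


@dataclass
class IntervalResult:
    taxon: str
    t_start: float
    t_end: float
    area: float
    p: float
    reaches_end: bool


def _spline_basis(t: np.ndarray, eval_t: np.ndarray, df: int) -> np.ndarray:
    """Cubic least-squares B-spline basis with ``df`` columns."""
    degree = 3
    n_interior = max(df - degree - 1, 0)
    lo, hi = t.min(), t.max()
    if n_interior > 0:
        interior = np.quantile(t, np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    basis = np.empty((len(eval_t), df))
    for k in range(df):
        coef = np.zeros(df)
        coef[k] = 1.0
        basis[:, k] = BSpline(knots, coef, degree, extrapolate=False)(eval_t)
    return np.nan_to_num(basis)


def _fit_difference(rel: np.ndarray, grp: np.ndarray, b_obs: np.ndarray,
                    b_eval: np.ndarray):
    """Fitted group-difference curve at the unique time points.

    ``b_obs``/``b_eval`` are the spline bases at the observed months and
    the evaluation grid (knots depend only on the time design, so they
    are shared across group splits and permutations).
    """
    out = {}
    for g in (0, 1):
        sel = grp == g
        coef, *_ = np.linalg.lstsq(b_obs[sel], rel[sel], rcond=None)
        out[g] = b_eval @ coef
    return out[1] - out[0]


def _sign_runs(diff: np.ndarray, uniq_t: np.ndarray):
    """Maximal constant-sign runs of the difference curve (zeros break)."""
    runs = []
    sign = np.sign(np.where(np.abs(diff) < 1e-12, 0.0, diff))
    start = None
    for i, s in enumerate(sign):
        if s == 0:
            if start is not None:
                runs.append((start, i - 1))
                start = None
            continue
        if start is None:
            start = i
        elif sign[start] != s:
            runs.append((start, i - 1))
            start = i
    if start is not None:
        runs.append((start, len(sign) - 1))
    return runs


def interval_differential(counts: pd.DataFrame, months, groups,
                          spline_df: int = 4, permutations: int = 1000,
                          min_obs: int = 5, min_samples: int = 5,
                          seed: int | None = None) -> list[IntervalResult]:
    """Time intervals where two groups' relative abundances diverge.

    Per taxon, each group's relative abundance is fitted with a cubic
    least-squares B-spline over months; maximal constant-sign runs of
    the fitted difference evaluated at the observed time points are
    candidate intervals, scored by the summed |difference|. The null
    permutes group labels within time points and records the maximal
    interval area; p-values are Laplace-corrected exceedance.
    """
    months = pd.Series(months, index=counts.index) \
        if not isinstance(months, pd.Series) else months.loc[counts.index]
    groups = pd.Series(groups, index=counts.index) \
        if not isinstance(groups, pd.Series) else groups.loc[counts.index]
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("interval_differential needs exactly two groups")
    uniq_t = np.unique(months.to_numpy())
    if len(uniq_t) < spline_df + 1:
        raise ValueError("fewer distinct time points than spline_df + 1")
    counts = filter_taxa(counts, min_obs, min_samples)
    rel = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    mo = months.to_numpy(dtype=float)
    grp = (groups == levels[1]).astype(int).to_numpy()
    rng = np.random.default_rng(seed)

    # permutations of group labels within each time point
    perms = []
    tp_idx = {t: np.where(mo == t)[0] for t in uniq_t}
    for _ in range(permutations):
        gp = grp.copy()
        for idx in tp_idx.values():
            gp[idx] = gp[idx][rng.permutation(len(idx))]
        perms.append(gp)

    b_obs = _spline_basis(mo, mo, spline_df)
    b_eval = _spline_basis(mo, uniq_t, spline_df)
    results = []
    for taxon in counts.columns:
        x = rel[taxon].to_numpy(dtype=float)
        diff = _fit_difference(x, grp, b_obs, b_eval)
        runs = _sign_runs(diff, uniq_t)
        if not runs:
            continue
        null_max = np.empty(permutations)
        for i, gp in enumerate(perms):
            d_p = _fit_difference(x, gp, b_obs, b_eval)
            r_p = _sign_runs(d_p, uniq_t)
            null_max[i] = max((np.abs(d_p[s:e + 1]).sum() for s, e in r_p),
                              default=0.0)
        for s, e in runs:
            area = float(np.abs(diff[s:e + 1]).sum())
            p = float((1.0 + (null_max >= area - 1e-15).sum())
                      / (1.0 + permutations))
            results.append(IntervalResult(
                taxon, float(uniq_t[s]), float(uniq_t[e]), area, p,
                reaches_end=bool(e == len(uniq_t) - 1)))
    return results


# ---------------------------------------------------------------------------
# seasonal + long-term trend
# ---------------------------------------------------------------------------


@dataclass
class SeasonalFit:
    harmonic_coefs: np.ndarray  # (sin1, cos1, sin2, cos2, ...)
    months_slope: float
    months_slope_se: float
    r_squared: float
    seasonal_p: float
    peak_doy: float


def hellinger(abundance: np.ndarray, library_size: np.ndarray | None = None):
    """Square root of relative abundance."""
    x = np.asarray(abundance, dtype=float)
    if library_size is None:
        return np.sqrt(x)
    return np.sqrt(x / np.asarray(library_size, dtype=float))


def seasonal_trend(abundance, day_of_year, months, n_harmonics: int = 2,
                   library_size=None) -> SeasonalFit:
    """Cyclic (harmonic) seasonal fit plus linear long-term trend.

    The response is the Hellinger-transformed abundance (pass
    ``library_size`` to convert counts to relative abundance first).
    The seasonal block (all sin/cos pairs) is tested jointly with an
    F test; the peak day-of-year is the grid argmax of the fitted
    seasonal component over days 1..366.
    """
    y = hellinger(abundance, library_size)
    doy = np.asarray(day_of_year, dtype=float)
    mo = np.asarray(months, dtype=float)
    n = len(y)
    if n < 2 * n_harmonics + 2:
        raise ValueError("too few observations for the harmonic fit")
    cols = [np.ones(n)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * k * doy / DAYS_PER_YEAR))
        cols.append(np.cos(2 * np.pi * k * doy / DAYS_PER_YEAR))
    cols.append(mo)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear design (e.g. all samples share a "
                         "day of year)")
    fit = sm.OLS(y, design).fit()
    k_seas = 2 * n_harmonics
    restriction = np.zeros((k_seas, design.shape[1]))
    for i in range(k_seas):
        restriction[i, 1 + i] = 1.0
    ftest = fit.f_test(restriction)
    coefs = np.asarray(fit.params[1:1 + k_seas])
    grid = np.arange(1.0, 366.5, 0.5)
    seas = np.zeros_like(grid)
    for k in range(1, n_harmonics + 1):
        seas += coefs[2 * (k - 1)] * np.sin(2 * np.pi * k * grid / DAYS_PER_YEAR)
        seas += coefs[2 * k - 1] * np.cos(2 * np.pi * k * grid / DAYS_PER_YEAR)
    return SeasonalFit(
        harmonic_coefs=coefs,
        months_slope=float(fit.params[-1]),
        months_slope_se=float(fit.bse[-1]),
        r_squared=float(fit.rsquared),
        seasonal_p=float(ftest.pvalue),
        peak_doy=float(grid[int(np.argmax(seas))]),
    )
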