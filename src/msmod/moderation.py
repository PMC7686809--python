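"""Moderated regression of trait creativity on microstate parameters.

The statistical layer tests, for each microstate parameter X, whether
self-esteem W moderates its relationship with the creativity total Y,
controlling sex and age:

    Y = b0 + b1*Xc + b2*Wc + b3*Xc*Wc + b4*sex + b5*age + e

with X and W mean-centered before the product is formed. The interaction
is judged by the increment in R^2 when the product term enters,
F(1, n-6) = dR^2 * (n - 6) / (1 - R^2_full), and the family of
interaction p-values is corrected by the Benjamini-Hochberg step-up
procedure. Significant interactions are probed by simple slopes at
W = mean +/- 1 sd and by the Johnson-Neyman region of significance,
solved analytically from the coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

__all__ = [
    "ModerationResult",
    "SimpleSlope",
    "JohnsonNeyman",
    "exclude_outliers",
    "correlation_table",
    "moderated_regression",
    "simple_slopes",
    "johnson_neyman",
    "bh_adjust",
    "run_moderation_battery",
    "BATTERY_ORDER",
]

_MS = ["ms1", "ms2", "ms3", "ms4"]
BATTERY_ORDER: list[str] = (
    [f"duration_{m}" for m in _MS]
    + [f"occurrence_{m}" for m in _MS]
    + [f"contribution_{m}" for m in _MS]
    + [f"transition_{a}_{b}" for a in _MS for b in _MS if a != b]
)


@dataclass
class SimpleSlope:
    w_centered: float
    w_raw: float
    slope: float
    se: float
    t: float
    p: float
    beta: float | None = None     # standardized slope from the z-scored refit


@dataclass
class JohnsonNeyman:
    """Region of significance of the conditional effect of X.

    Boundaries are in raw W units; ``pct_below``/``pct_above`` are the
    percentages of observed W at or beyond each boundary (inclusive).
    ``region`` is "inside", "outside", "everywhere" or "nowhere".
    """

    lower: float | None
    upper: float | None
    pct_below: float | None
    pct_above: float | None
    slope_sign_below: int | None
    slope_sign_above: int | None
    region: str
    alpha: float


@dataclass
class ModerationResult:
    parameter: str
    n: int
    params: np.ndarray            # b0..b5: const, Xc, Wc, Xc*Wc, sex, age
    cov: np.ndarray
    param_names: list[str]
    r2_full: float
    r2_reduced: float
    delta_r2: float
    f_value: float
    df1: int
    df2: int
    p_uncorrected: float
    x_mean: float
    w_mean: float
    w_sd: float
    w_values: np.ndarray          # observed raw W (for J-N percentages)
    beta_x: float                 # standardized refit coefficients
    beta_w: float
    beta_xw: float
    alpha: float = 0.05
    p_fdr: float | None = None
    slopes: list[SimpleSlope] = field(default_factory=list)
    jn: JohnsonNeyman | None = None

    @property
    def b1(self) -> float:
        return float(self.params[1])

    @property
    def b3(self) -> float:
        return float(self.params[3])


def exclude_outliers(
    table: pd.DataFrame, k_sd: float = 3.0, columns: tuple[str, str] = ("wcts_total", "rses")
) -> tuple[pd.DataFrame, list]:
    """Drop subjects whose creativity or self-esteem total deviates more
    than ``k_sd`` standard deviations from the full-sample mean.

    A single pass: means and sds come from the table before any removal.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    mask = np.zeros(len(table), dtype=bool)
    for col in columns:
        v = table[col].to_numpy(dtype=float)
        mu, sd = v.mean(), v.std(ddof=1)
        if sd > 0:
            mask |= np.abs(v - mu) > k_sd * sd
    excluded = table.loc[mask, "subject_id"].tolist() if "subject_id" in table else list(table.index[mask])
    kept = table.loc[~mask].reset_index(drop=True)
    if len(kept) < 10:
        raise ValueError("fewer than 10 subjects remain after outlier exclusion")
    return kept, excluded


def correlation_table(
    table: pd.DataFrame,
    y_col: str = "rses",
    x_cols: tuple[str, ...] = ("risk_taking", "curiosity", "imagination", "challenge", "wcts_total"),
) -> pd.DataFrame:
    """Pearson correlations of self-esteem with the creativity scales.

    Returns one row per scale with r and the two-sided t-based p-value.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 subjects for correlations")
    rows = []
    y = table[y_col].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError(f"zero-variance column: {y_col}")
    for col in x_cols:
        x = table[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"zero-variance column: {col}")
        r, p = sstats.pearsonr(x, y)
        rows.append({"scale": col, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def moderated_regression(
    y: np.ndarray,
    x: np.ndarray,
    w: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    parameter: str = "x",
    alpha: float = 0.05,
) -> ModerationResult:
    """OLS moderation model with mean-centered predictor and moderator.

    Fits the full model (with the Xc*Wc product) and the reduced model
    (without), reports dR^2 and its F(1, df2) test, and refits on
    z-scored Y, X, W (covariates untouched) for standardized betas.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    n = y.size
    if covariates is None:
        cov_arr = np.empty((n, 0))
        cov_names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        cov_arr = covariates.to_numpy(dtype=float)
        cov_names = list(covariates.columns)
    else:
        cov_arr = np.asarray(covariates, dtype=float)
        cov_names = [f"cov{i}" for i in range(cov_arr.shape[1])]
    p_full = 4 + cov_arr.shape[1]
    if n <= p_full:
        raise ValueError("too few observations for the moderation model")

    xc = x - x.mean()
    wc = w - w.mean()

    def design(xs, ws, cov):
        cols = [np.ones(n), xs, ws, xs * ws]
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
        return np.column_stack(cols)

    names = ["const", "x_c", "w_c", "x_c:w_c", *cov_names]
    x_full = design(xc, wc, cov_arr)
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        bad = [
            names[j]
            for j in range(x_full.shape[1])
            if np.linalg.matrix_rank(np.delete(x_full, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")

    full = sm.OLS(y, x_full).fit()
    reduced = sm.OLS(y, np.delete(x_full, 3, axis=1)).fit()
    df2 = n - x_full.shape[1]
    delta = float(full.rsquared - reduced.rsquared)
    resid_frac = 1.0 - full.rsquared
    if resid_frac <= np.finfo(float).eps:      # exact interpolation
        f_value = np.inf if delta > 0 else 0.0
    else:
        f_value = delta * df2 / resid_frac
    p_unc = float(sstats.f.sf(f_value, 1, df2))

    zy = (y - y.mean()) / y.std(ddof=1)
    zx = xc / x.std(ddof=1)
    zw = wc / w.std(ddof=1)
    zfit = sm.OLS(zy, design(zx, zw, cov_arr)).fit()

    return ModerationResult(
        parameter=parameter,
        n=n,
        params=np.asarray(full.params, dtype=float),
        cov=np.asarray(full.cov_params(), dtype=float),
        param_names=names,
        r2_full=float(full.rsquared),
        r2_reduced=float(reduced.rsquared),
        delta_r2=delta,
        f_value=float(f_value),
        df1=1,
        df2=int(df2),
        p_uncorrected=p_unc,
        x_mean=float(x.mean()),
        w_mean=float(w.mean()),
        w_sd=float(w.std(ddof=1)),
        w_values=w.copy(),
        beta_x=float(zfit.params[1]),
        beta_w=float(zfit.params[2]),
        beta_xw=float(zfit.params[3]),
        alpha=alpha,
    )


def _slope_se(res: ModerationResult, wc: float) -> tuple[float, float]:
    b1, b3 = res.params[1], res.params[3]
    s11, s13, s33 = res.cov[1, 1], res.cov[1, 3], res.cov[3, 3]
    slope = b1 + b3 * wc
    se = np.sqrt(s11 + 2 * wc * s13 + wc**2 * s33)
    return float(slope), float(se)


def simple_slopes(
    res: ModerationResult, probe_points: np.ndarray | None = None
) -> list[SimpleSlope]:
    """Conditional effect of X at chosen moderator values.

    ``probe_points`` are centered W values; the default probes are
    mean - 1 sd and mean + 1 sd. The standardized beta at each probe is
    ``beta_x + beta_xw * (w / sd_W)`` from the z-scored refit.
    """
    if probe_points is None:
        probe_points = np.array([-res.w_sd, res.w_sd])
    out = []
    for wc in np.atleast_1d(np.asarray(probe_points, dtype=float)):
        slope, se = _slope_se(res, wc)
        t = slope / se
        p = 2.0 * sstats.t.sf(abs(t), res.df2)
        beta = res.beta_x + res.beta_xw * (wc / res.w_sd)
        out.append(
            SimpleSlope(
                w_centered=float(wc),
                w_raw=float(wc + res.w_mean),
                slope=slope,
                se=se,
                t=float(t),
                p=float(p),
                beta=float(beta),
            )
        )
    return out


def johnson_neyman(
    res: ModerationResult, alpha: float | None = None, w_range: tuple[float, float] | None = None
) -> JohnsonNeyman:
    """Analytic Johnson-Neyman boundaries of the conditional effect.

    Solves |slope(w)| = t_crit * SE(w), i.e. the quadratic
    (b3^2 - t^2 s33) w^2 + 2 (b1 b3 - t^2 s13) w + (b1^2 - t^2 s11) = 0
    on the centered scale, and reports real roots inside the observed
    moderator range in raw units, with the percent of the sample at or
    beyond each boundary.
    """
    if alpha is None:
        alpha = res.alpha
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 0.5]")
    t_crit = float(sstats.t.ppf(1 - alpha / 2, res.df2))
    b1, b3 = res.params[1], res.params[3]
    s11, s13, s33 = res.cov[1, 1], res.cov[1, 3], res.cov[3, 3]
    a = b3**2 - t_crit**2 * s33
    b = 2 * (b1 * b3 - t_crit**2 * s13)
    c = b1**2 - t_crit**2 * s11

    wvals = res.w_values
    if w_range is None:
        lo_raw, hi_raw = float(wvals.min()), float(wvals.max())
    else:
        lo_raw, hi_raw = map(float, w_range)
    lo_c, hi_c = lo_raw - res.w_mean, hi_raw - res.w_mean

    scale = max(abs(b3), abs(b1), t_crit * np.sqrt(abs(s33)), 1e-30)
    roots: list[float]
    if abs(a) < 1e-12 * scale**2:
        roots = [-c / b] if abs(b) > 0 else []
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            roots = []
        else:
            sq = np.sqrt(disc)
            roots = sorted([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    inside = [r for r in roots if lo_c <= r <= hi_c]

    def significant(wc: float) -> bool:
        slope, se = _slope_se(res, wc)
        return abs(slope / se) > t_crit

    def sign_at(wc: float) -> int:
        slope, _ = _slope_se(res, wc)
        return int(np.sign(slope))

    if not inside:
        region = "everywhere" if significant((lo_c + hi_c) / 2) else "nowhere"
        return JohnsonNeyman(None, None, None, None, None, None, region, alpha)

    if len(inside) == 1:
        r = inside[0]
        sig_low = significant((lo_c + r) / 2)
        sig_high = significant((r + hi_c) / 2)
        if sig_low and not sig_high:
            pct_below = 100.0 * np.mean(wvals <= r + res.w_mean)
            return JohnsonNeyman(
                float(r + res.w_mean), None, float(pct_below), None,
                sign_at((lo_c + r) / 2), None, "below-lower", alpha,
            )
        if sig_high and not sig_low:
            pct_above = 100.0 * np.mean(wvals >= r + res.w_mean)
            return JohnsonNeyman(
                None, float(r + res.w_mean), None, float(pct_above),
                None, sign_at((r + hi_c) / 2), "above-upper", alpha,
            )
        # root grazes the critical line without changing significance
        region = "everywhere" if sig_low else "nowhere"
        return JohnsonNeyman(None, None, None, None, None, None, region, alpha)

    lo_r, hi_r = inside[0], inside[1]
    mid_sig = significant((lo_r + hi_r) / 2)
    region = "inside" if mid_sig else "outside"
    pct_below = 100.0 * np.mean(wvals <= lo_r + res.w_mean)
    pct_above = 100.0 * np.mean(wvals >= hi_r + res.w_mean)
    return JohnsonNeyman(
        float(lo_r + res.w_mean),
        float(hi_r + res.w_mean),
        float(pct_below),
        float(pct_above),
        sign_at((lo_c + lo_r) / 2),
        sign_at((hi_r + hi_c) / 2),
        region,
        alpha,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} p_(j) * m / j over the sorted values,
    capped at 1 and mapped back to the input order; equal inputs receive
    equal adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    raw = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def run_moderation_battery(
    stats_table: pd.DataFrame,
    behavior: pd.DataFrame,
    alpha: float = 0.05,
    parameters: list[str] | None = None,
    probe_sds: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, ModerationResult]]:
    """Run the full 24-test moderation family and BH-correct it.

    ``stats_table`` holds one row per subject with the 24 microstate
    parameters; ``behavior`` the creativity/self-esteem/sex/age columns.
    Tables are aligned on ``subject_id`` and must match exactly. Simple
    slopes (mean +/- 1 sd) and the Johnson-Neyman region are computed for
    every parameter whose corrected p is below ``alpha``.

    Returns the report table (one row per parameter, battery order) and
    the full per-parameter results.
    """
    if parameters is None:
        parameters = [p for p in BATTERY_ORDER if p in stats_table.columns]
    a = set(stats_table["subject_id"])
    b = set(behavior["subject_id"])
    if a != b:
        raise ValueError("subject ids of statistics and behavior tables differ")
    merged = behavior.merge(stats_table, on="subject_id", validate="one_to_one")
    y = merged["wcts_total"].to_numpy(dtype=float)
    w = merged["rses"].to_numpy(dtype=float)
    covs = merged[["sex", "age"]]

    results: dict[str, ModerationResult] = {}
    for name in parameters:
        results[name] = moderated_regression(
            y, merged[name].to_numpy(dtype=float), w, covs, parameter=name, alpha=alpha
        )
    p_fdr = bh_adjust([results[n].p_uncorrected for n in parameters])
    rows = []
    for name, q in zip(parameters, p_fdr):
        res = results[name]
        res.p_fdr = float(q)
        if q < alpha:
            probes = np.array([-probe_sds * res.w_sd, probe_sds * res.w_sd])
            res.slopes = simple_slopes(res, probe_points=probes)
            res.jn = johnson_neyman(res)
        rows.append(
            {
                "parameter": name,
                "delta_r2": res.delta_r2,
                "df1": res.df1,
                "df2": res.df2,
                "f_value": res.f_value,
                "p_uncorrected": res.p_uncorrected,
                "p_fdr": res.p_fdr,
                "significant": q < alpha,
            }
        )
    return pd.DataFrame(rows), results
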