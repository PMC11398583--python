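"""Population filtering, summaries, Hill dose-response fits and LOAEL.

Per-worm endpoint values are cleaned with Tukey fences (1.5 x IQR on body
length and on autofluorescence; a worm outside either fence is dropped
entirely), summarized per well (mean, SD, SEM, CV = sigma/mu), and fitted
with a 4-parameter variable-slope Hill function

    Y = Bottom + (Top - Bottom) / (1 + (X / EC50)^h)

to obtain the effective concentration for a 10% change,
``ECf = (f/(100-f))^(1/|h|) * EC50`` with f = 10 ("ECanything" transform).
For body endpoints Bottom is constrained to 0; for autofluorescence all four
parameters are free.  95% confidence intervals for EC10 come from profile
likelihood (F-based sum-of-squares profiling) with a parametric bootstrap
fallback.  The LOAEL is the smallest dose whose endpoint departs from the
solvent control at adjusted p < 0.05 under Welch's ANOVA with Dunnett's T3
post-hoc comparisons (Welch t statistics with Satterthwaite degrees of
freedom; studentized-maximum-modulus adjustment); Shapiro-Wilk normality
p-values are reported alongside but do not change the chosen test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "WellSummary", "DoseResponseFit", "LoaelResult", "tukey_filter",
    "summarize_well", "hill_curve", "hill_fit", "ec_anything", "welch_anova",
    "dunnett_t3", "loael", "control_cv",
]


# ---------------------------------------------------------------------------
# filtering and summaries
# ---------------------------------------------------------------------------

def tukey_filter(values, k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, removed) by Tukey fences Q1/Q3 ± k*IQR.

    Quartiles use linear interpolation between order statistics (numpy's
    default convention).  Fewer than 4 values pass through unfiltered with
    a warning.  Idempotent on its own output for any sample where the
    fences do not tighten after removal of the flagged points.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 values: Tukey filter passes all through",
                      stacklevel=2)
        return x, np.empty(0)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = (x >= lo) & (x <= hi)
    return x[keep], x[~keep]


@dataclass
class WellSummary:
    """Per-well endpoint summary after outlier filtering."""

    well_id: str
    dose_um: float
    n_worms_raw: int
    n_worms_kept: int
    stats: dict[str, dict[str, float]] = field(default_factory=dict)
    # stats[endpoint] = {"mean": mu, "sd": sigma, "sem": ..., "cv": ...}
    flags: list[str] = field(default_factory=list)


def summarize_well(
    endpoint_values: dict[str, np.ndarray],
    well_id: str = "",
    dose_um: float = float("nan"),
    filter_endpoints: tuple[str, ...] = ("length_um", "af_per_length"),
) -> WellSummary:
    """Tukey-filter and summarize one well's per-worm endpoint values.

    ``endpoint_values`` maps endpoint name -> per-worm array (equal
    lengths).  Worms falling outside the Tukey fences of *any* endpoint in
    ``filter_endpoints`` are removed from every endpoint.  Returns sample
    mean, SD (ddof=1), SEM = sd/sqrt(n) and CV = sd/mean per endpoint.
    """
    names = list(endpoint_values)
    arrays = {k: np.asarray(v, dtype=float) for k, v in endpoint_values.items()}
    n_raw = len(arrays[names[0]])
    if any(len(a) != n_raw for a in arrays.values()):
        raise ValueError("endpoint arrays must have equal length")
    keep = np.ones(n_raw, dtype=bool)
    for ep in filter_endpoints:
        if ep not in arrays or n_raw < 4:
            continue
        x = arrays[ep]
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        keep &= (x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)
    summary = WellSummary(well_id=well_id, dose_um=dose_um,
                          n_worms_raw=n_raw, n_worms_kept=int(keep.sum()))
    if summary.n_worms_kept == 0:
        summary.flags.append("empty_after_filtering")
        return summary
    for name, x in arrays.items():
        xk = x[keep]
        mu = float(xk.mean())
        sd = float(xk.std(ddof=1)) if len(xk) > 1 else 0.0
        summary.stats[name] = dict(
            mean=mu, sd=sd, sem=sd / np.sqrt(len(xk)),
            cv=sd / mu if mu != 0 else float("nan"),
        )
    return summary


def control_cv(control_well_means: dict[str, np.ndarray] | np.ndarray
               ) -> dict[str, float] | float:
    """Coefficient of variance of control-well means across replicates.

    Accepts one array of per-replicate control means (returns a float) or a
    mapping endpoint -> array (returns a mapping).
    """
    def cv(x):
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ValueError("need >= 2 control wells for a CV")
        return float(x.std(ddof=1) / x.mean())

    if isinstance(control_well_means, dict):
        return {k: cv(v) for k, v in control_well_means.items()}
    return cv(control_well_means)


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

def hill_curve(x, bottom, top, ec50, slope):
    """``Y = Bottom + (Top - Bottom)/(1 + (X/EC50)^h)`` (vectorized)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ec50) ** slope)


def ec_anything(ec50: float, slope: float, f: float = 10.0) -> float:
    """ECf transform: concentration of an f% change along the Hill curve.

    ``ECf = (f/(100-f))^(1/|h|) * EC50``; with f = 50 this is EC50 for any
    slope.  The magnitude of the slope is used, so the transform applies on
    the appropriate branch for rising (h < 0) and falling (h > 0) curves
    alike.
    """
    return float((f / (100.0 - f)) ** (1.0 / abs(slope)) * ec50)


@dataclass
class DoseResponseFit:
    endpoint: str
    bottom: float
    top: float
    ec50: float
    hill_slope: float
    ec10: float
    ec10_ci: tuple[float, float]
    constraint_mode: str
    converged: bool
    message: str
    sse: float
    n: int
    ci_method: str = "profile"


def _substitute_control_dose(doses: np.ndarray) -> np.ndarray:
    """Map dose 0 to min_positive/100 so controls anchor Top on a log axis."""
    out = np.array(doses, dtype=float)
    pos = out[out > 0]
    if pos.size and np.any(out == 0):
        out[out == 0] = pos.min() / 100.0
    return out


def _fit_ss(xs, ys, constraint_mode, slope_sign):
    """Least-squares Hill fit; returns (params, sse, success)."""
    y_lo, y_hi = float(np.min(ys)), float(np.max(ys))
    span = max(y_hi - y_lo, 1e-12)
    x_mid = float(np.sqrt(np.min(xs) * np.max(xs)))
    free_bottom = constraint_mode != "body"

    def unpack(p):
        if free_bottom:
            bottom, top, lec50, slope = p
        else:
            top, lec50, slope = p
            bottom = 0.0
        return bottom, top, np.exp(lec50), slope

    def resid(p):
        b, t, e, h = unpack(p)
        return hill_curve(xs, b, t, e, h) - ys

    slope0 = 1.5 * slope_sign
    if free_bottom:
        p0 = [y_lo, y_hi, np.log(x_mid), slope0]
        lb = [y_lo - 2 * span, y_lo - 2 * span, np.log(np.min(xs)) - 5,
              -20.0]
        ub = [y_hi + 2 * span, y_hi + 2 * span, np.log(np.max(xs)) + 5,
              20.0]
    else:
        p0 = [y_hi, np.log(x_mid), slope0]
        lb = [0.0, np.log(np.min(xs)) - 5, -20.0]
        ub = [y_hi + 2 * span, np.log(np.max(xs)) + 5, 20.0]
    res = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf")
    return unpack(res.x), float(2 * res.cost), res.success


def hill_fit(
    doses,
    responses,
    constraint_mode: str = "body",
    endpoint: str = "",
    ci_method: str = "profile",
    n_boot: int = 300,
    rng: np.random.Generator | None = None,
) -> DoseResponseFit:
    """Fit the 4-parameter variable-slope Hill model and derive EC10 + CI.

    ``constraint_mode='body'`` fixes Bottom = 0 (length/area/volume);
    ``'af'`` leaves all four parameters free (autofluorescence).  Control
    doses (0) are substituted by min_positive/100 before fitting so they
    anchor the zero-dose asymptote.  The slope sign is chosen by the data
    (falling vs rising trend) and EC10 follows the ECanything transform.

    The 95% CI uses sum-of-squares profiling of log EC10 against the
    F(1, n-p) threshold; ``ci_method='bootstrap'`` draws ``n_boot``
    parametric resamples instead.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must align")
    if len(np.unique(doses)) < 4:
        raise ValueError("need >= 4 distinct doses for a 4-parameter fit")
    xs = _substitute_control_dose(doses)
    lo_mean = responses[xs <= np.median(xs)].mean()
    hi_mean = responses[xs > np.median(xs)].mean()
    slope_sign = 1.0 if lo_mean >= hi_mean else -1.0

    (bottom, top, ec50, slope), sse, ok = _fit_ss(
        xs, responses, constraint_mode, slope_sign
    )
    if not ok or not np.isfinite(sse):
        return DoseResponseFit(
            endpoint=endpoint, bottom=np.nan, top=np.nan, ec50=np.nan,
            hill_slope=np.nan, ec10=np.nan, ec10_ci=(np.nan, np.nan),
            constraint_mode=constraint_mode, converged=False,
            message="least-squares fit did not converge", sse=np.nan,
            n=len(xs), ci_method=ci_method,
        )
    ec10 = ec_anything(ec50, slope, f=10.0)
    n = len(xs)
    n_par = 3 if constraint_mode == "body" else 4
    if ci_method == "profile":
        ci = _profile_ci_ec10(xs, responses, constraint_mode, slope_sign,
                              ec10, slope, sse, n, n_par)
    elif ci_method == "bootstrap":
        ci = _bootstrap_ci_ec10(xs, responses, constraint_mode, slope_sign,
                                bottom, top, ec50, slope, sse, n, n_par,
                                n_boot, rng or np.random.default_rng(0))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return DoseResponseFit(
        endpoint=endpoint, bottom=float(bottom), top=float(top),
        ec50=float(ec50), hill_slope=float(slope), ec10=float(ec10),
        ec10_ci=ci, constraint_mode=constraint_mode, converged=True,
        message="", sse=sse, n=n, ci_method=ci_method,
    )


def _fit_ss_fixed_ec10(xs, ys, constraint_mode, slope_sign, log_ec10):
    """Refit with EC10 held fixed (EC50 reparametrized through the slope)."""
    y_lo, y_hi = float(np.min(ys)), float(np.max(ys))
    span = max(y_hi - y_lo, 1e-12)
    free_bottom = constraint_mode != "body"
    ratio = 10.0 / 90.0

    def unpack(p):
        if free_bottom:
            bottom, top, slope = p
        else:
            top, slope = p
            bottom = 0.0
        ec50 = np.exp(log_ec10) * ratio ** (-1.0 / abs(slope))
        return bottom, top, ec50, slope

    def resid(p):
        b, t, e, h = unpack(p)
        return hill_curve(xs, b, t, e, h) - ys

    slope0 = 1.5 * slope_sign
    if free_bottom:
        p0 = [y_lo, y_hi, slope0]
        lb = [y_lo - 2 * span, y_lo - 2 * span, -20.0]
        ub = [y_hi + 2 * span, y_hi + 2 * span, 20.0]
    else:
        p0 = [y_hi, slope0]
        lb = [0.0, -20.0]
        ub = [y_hi + 2 * span, 20.0]
    res = optimize.least_squares(resid, p0, bounds=(lb, ub), method="trf")
    return float(2 * res.cost)


def _profile_ci_ec10(xs, ys, mode, slope_sign, ec10, slope, sse, n, n_par,
                     level=0.95):
    """F-based sum-of-squares profile interval for log EC10."""
    dof = n - n_par
    if dof <= 0:
        return (np.nan, np.nan)
    if sse <= 1e-10 * float(np.sum(ys**2)):
        # zero-residual (noiseless) fit: the profile interval degenerates
        return (ec10, ec10)
    fcrit = stats.f.ppf(level, 1, dof)
    threshold = sse * (1.0 + fcrit / dof)
    log0 = np.log(ec10)

    def excess(le):
        return _fit_ss_fixed_ec10(xs, ys, mode, slope_sign, le) - threshold

    if excess(log0) > 0:  # numerical edge: refit at the MLE not below SSR
        return (ec10, ec10)

    def search(direction):
        step = 0.1
        prev = log0
        for _ in range(60):
            cur = prev + direction * step
            if excess(cur) > 0:
                return optimize.brentq(excess, min(prev, cur),
                                       max(prev, cur), xtol=1e-4)
            prev = cur
            step *= 1.5
        return direction * np.inf  # profile never crossed: unbounded side

    lo = search(-1.0)
    hi = search(+1.0)
    return (float(np.exp(lo)) if np.isfinite(lo) else 0.0,
            float(np.exp(hi)) if np.isfinite(hi) else np.inf)


def _bootstrap_ci_ec10(xs, ys, mode, slope_sign, bottom, top, ec50, slope,
                       sse, n, n_par, n_boot, rng, level=0.95):
    """Parametric bootstrap: resample residual noise around the fit."""
    sigma = np.sqrt(sse / max(n - n_par, 1))
    fitted = hill_curve(xs, bottom, top, ec50, slope)
    out = []
    for _ in range(n_boot):
        yb = fitted + rng.normal(0.0, sigma, size=n)
        try:
            (b, t, e, h), _, ok = _fit_ss(xs, yb, mode, slope_sign)
            if ok:
                out.append(ec_anything(e, h, 10.0))
        except Exception:
            continue
    if len(out) < max(20, n_boot // 4):
        return (np.nan, np.nan)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(out, [a, 1.0 - a])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Welch ANOVA + Dunnett T3
# ---------------------------------------------------------------------------

def welch_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns (F, df1, df2, p).  Implements Welch's F with weights
    ``w_i = n_i / s_i^2`` and Satterthwaite-style denominator degrees of
    freedom; for two groups F equals the squared Welch t statistic.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    n = np.array([len(g) for g in groups], dtype=float)
    if np.any(n < 2):
        raise ValueError("every group needs >= 2 observations")
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    if np.any(v == 0):
        v = np.maximum(v, 1e-300)
    w = n / v
    w_sum = w.sum()
    mw = (w * m).sum() / w_sum
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = np.sum((1 - w / w_sum) ** 2 / (n - 1))
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f_stat = a / b
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * lam) if lam > 0 else np.inf
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), float(df1), float(df2), p


def _smm_sf(t_abs: float, df: float, k: int) -> float:
    """Survival function of the studentized maximum modulus.

    P(max_i |T_i| > t) for k independent t(df) variates — the standard
    tabulated SMM distribution used by Dunnett's T3 adjustment.
    """
    per = 2.0 * stats.t.sf(t_abs, df)
    return float(1.0 - (1.0 - per) ** k)


def dunnett_t3(groups: dict[float, np.ndarray], control_key: float = 0.0,
               n_mc: int = 0, rng: np.random.Generator | None = None
               ) -> dict[float, dict[str, float]]:
    """Dunnett's T3 pairwise comparisons of every group against the control.

    Each comparison uses the Welch t statistic with Satterthwaite degrees
    of freedom; the family-wise adjustment evaluates the statistic against
    the studentized maximum modulus over the k comparisons.  With
    ``n_mc > 0`` the SMM tail is estimated by seeded Monte Carlo that
    preserves the correlation induced by the shared control sample;
    otherwise the standard (independence) SMM distribution is used.
    """
    if control_key not in groups:
        raise ValueError(f"control group {control_key!r} missing")
    ctrl = np.asarray(groups[control_key], dtype=float)
    others = {d: np.asarray(g, float) for d, g in groups.items()
              if d != control_key}
    too_small = [d for d, g in list(others.items()) + [(control_key, ctrl)]
                 if len(g) < 3]
    if too_small:
        raise ValueError(f"groups too small (<3) for T3: {sorted(too_small)}")
    k = len(others)
    n0, m0, v0 = len(ctrl), ctrl.mean(), ctrl.var(ddof=1)
    results: dict[float, dict[str, float]] = {}
    stats_t, dfs = {}, {}
    for d, g in others.items():
        ni, mi, vi = len(g), g.mean(), g.var(ddof=1)
        se2 = vi / ni + v0 / n0
        se2 = max(se2, 1e-300)
        t = (mi - m0) / np.sqrt(se2)
        df = se2**2 / (
            (vi / ni) ** 2 / (ni - 1) + (v0 / n0) ** 2 / (n0 - 1)
        ) if se2 > 0 else 1.0
        stats_t[d], dfs[d] = t, df
    if n_mc > 0:
        rng = rng or np.random.default_rng(0)
        # joint null: shared control draw induces correlation between
        # comparisons; simulate the max modulus of the Welch statistics
        maxmod = np.zeros(n_mc)
        sims = []
        for d, g in others.items():
            ni = len(g)
            zi = rng.standard_normal((n_mc, ni))
            sims.append((d, zi))
        z0 = rng.standard_normal((n_mc, n0))
        for d, zi in sims:
            ni = zi.shape[1]
            vi = zi.var(axis=1, ddof=1)
            vc = z0.var(axis=1, ddof=1)
            t = (zi.mean(axis=1) - z0.mean(axis=1)) / np.sqrt(
                vi / ni + vc / n0
            )
            maxmod = np.maximum(maxmod, np.abs(t))
        for d in others:
            p_adj = float(np.mean(maxmod >= abs(stats_t[d])))
            results[d] = dict(t=stats_t[d], df=dfs[d], p_adj=p_adj)
    else:
        for d in others:
            results[d] = dict(
                t=stats_t[d], df=dfs[d],
                p_adj=_smm_sf(abs(stats_t[d]), dfs[d], k),
            )
    return results


@dataclass
class LoaelResult:
    loael_dose_um: float | None
    p_values: dict[float, float]
    normality_p: dict[float, float]
    welch_f: float
    welch_p: float
    test_used: str = "welch_anova+dunnett_t3"


def loael(values_by_dose: dict[float, np.ndarray], alpha: float = 0.05,
          n_mc: int = 0, rng: np.random.Generator | None = None
          ) -> LoaelResult:
    """Lowest observable adverse effect level across a dose series.

    ``values_by_dose`` maps dose (uM, control = 0 required) to per-worm
    endpoint values.  Shapiro-Wilk normality p-values are recorded per
    group; Welch's ANOVA is computed across all groups; each treated dose
    is compared to the control with Dunnett's T3 and the LOAEL is the
    smallest dose with adjusted p < alpha (None when no dose reaches
    significance).
    """
    if 0.0 not in values_by_dose:
        raise ValueError("control group (dose 0) required")
    if len(values_by_dose) < 2:
        raise ValueError("need >= 2 dose groups including the control")
    small = {d: len(np.asarray(v)) for d, v in values_by_dose.items()
             if len(np.asarray(v)) < 3}
    if small:
        raise ValueError(f"groups with < 3 worms: {small}")
    normality = {}
    for d, v in values_by_dose.items():
        v = np.asarray(v, dtype=float)
        normality[d] = float(stats.shapiro(v).pvalue) if len(v) >= 3 else np.nan
    f_stat, _, _, welch_p = welch_anova(list(values_by_dose.values()))
    t3 = dunnett_t3(values_by_dose, control_key=0.0, n_mc=n_mc, rng=rng)
    p_values = {d: r["p_adj"] for d, r in sorted(t3.items())}
    sig = sorted(d for d, p in p_values.items() if p < alpha)
    return LoaelResult(
        loael_dose_um=sig[0] if sig else None,
        p_values=p_values,
        normality_p=normality,
        welch_f=f_stat,
        welch_p=welch_p,
    )
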