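"""Survival analysis: Kaplan–Meier, log-rank, Cox PH and diagnostics.

The Cox proportional hazards model is fitted by Newton–Raphson
maximization of the partial likelihood with either Efron (default) or
Breslow handling of tied event times.  Diagnostics follow the standard
workflow for clinical cohorts: martingale and deviance residuals, a
leave-one-out influence screen, a Kolmogorov-type supremum test of the
proportional-hazards assumption based on multiplier resampling of the
standardized cumulative score process, and a simulation-based post-hoc
power calculation for a single density covariate.

Covariate categorization into low/moderate/high groups cuts at the 34th
and 66th percentiles (linear-interpolation quantiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, EstimationError, ParameterError

__all__ = [
    "km_estimate",
    "logrank",
    "LogrankResult",
    "tertile_categorize",
    "CoxFit",
    "fit_cox",
    "build_design",
    "loo_influence",
    "ph_supremum_test",
    "posthoc_power",
]


# ---------------------------------------------------------------------------
# Kaplan–Meier


def _km_one_group(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq = np.unique(t[e == 1])
    n = len(t)
    rows = []
    surv = 1.0
    var_sum = 0.0  # Greenwood accumulator sum d/(n(n-d))
    for tk in uniq:
        n_risk = int(np.sum(t >= tk))
        d = int(np.sum((t == tk) & (e == 1)))
        surv *= 1.0 - d / n_risk
        if n_risk > d:
            var_sum += d / (n_risk * (n_risk - d))
            var = surv**2 * var_sum
        else:
            var = 0.0
        rows.append(
            {"time": tk, "n_risk": n_risk, "n_event": d, "survival": surv,
             "variance": var}
        )
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "survival", "variance"])


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate with Greenwood variance per group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ParameterError("times and events must have equal length")
    if np.any(times < 0):
        raise ParameterError("times must be nonnegative")
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise EstimationError(f"empty group {g!r}")
        out[str(g)] = _km_one_group(times[sel], events[sel])
    return out


# ---------------------------------------------------------------------------
# Log-rank test


class LogrankResult(NamedTuple):
    chi2: float
    p_value: float
    df: int


def logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> LogrankResult:
    """k-sample log-rank test (observed minus expected, df = k - 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = len(labels)
    if k < 2:
        raise ParameterError("log-rank test needs at least 2 groups")
    gidx = np.searchsorted(np.sort(labels.astype(str)), groups.astype(str))
    # re-map to stable integer codes
    codes = pd.Categorical(groups.astype(str)).codes
    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for tk in event_times:
        at_risk = times >= tk
        n = at_risk.sum()
        d = int(np.sum((times == tk) & (events == 1)))
        n_g = np.bincount(codes[at_risk], minlength=k).astype(float)
        d_g = np.bincount(
            codes[(times == tk) & (events == 1)], minlength=k
        ).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            c = d * (n - d) / (n - 1)
            p = n_g / n
            V += c * (np.diag(p) - np.outer(p, p))
    u = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(u @ np.linalg.solve(Vsub, u))
    except np.linalg.LinAlgError:
        chi2 = float(u @ np.linalg.pinv(Vsub) @ u)
    df = k - 1
    return LogrankResult(chi2, float(stats.chi2.sf(chi2, df)), df)


# ---------------------------------------------------------------------------
# Tertile categorization


def tertile_categorize(x: Sequence[float]) -> pd.Categorical:
    """Cut a covariate at its 34th/66th percentiles into low/moderate/high.

    Quantiles use linear interpolation.  Values strictly below the 34th
    percentile are "low", above the 66th "high", the rest "moderate".
    All-equal input collapses to a single category with a warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ParameterError("need at least 3 values to categorize")
    p34, p66 = np.percentile(x, [34.0, 66.0])
    if np.ptp(x) == 0:
        warnings.warn("all values equal: single category 'low'", stacklevel=2)
        labels = np.full(len(x), "low", dtype=object)
    else:
        labels = np.where(x < p34, "low", np.where(x > p66, "high", "moderate"))
    return pd.Categorical(labels, categories=["low", "moderate", "high"], ordered=True)


# ---------------------------------------------------------------------------
# Cox proportional hazards


def build_design(
    df: pd.DataFrame,
    covariates: Sequence[str],
    stage_levels: Sequence[str] = ("I", "II", "III", "IV"),
    grade_levels: Sequence[str] = ("1", "2", "3", "NA"),
) -> pd.DataFrame:
    """Numeric design matrix; stage/grade expand to treatment dummies.

    Factor dummies are emitted only for levels observed in the data;
    the first observed level is the reference.
    """
    cols = {}
    for cov in covariates:
        if cov in ("stage", "grade"):
            all_levels = stage_levels if cov == "stage" else grade_levels
            vals = df[cov].astype(str)
            observed = [lvl for lvl in all_levels if (vals == lvl).any()]
            for lvl in observed[1:]:
                cols[f"{cov}_{lvl}"] = (vals == lvl).astype(float)
        else:
            cols[cov] = df[cov].astype(float)
    return pd.DataFrame(cols, index=df.index)


def _cox_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, gradient and (negative) Hessian.

    Data must be pre-sorted by time ascending.  Risk-set sums are
    accumulated as suffix cumulative sums; tied event times use the
    Efron or Breslow adjustment.
    """
    if ties not in ("efron", "breslow"):
        raise ParameterError(f"unknown ties method {ties!r}")
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; cancels in all ratios
    # extreme trial steps can underflow risk sums; the resulting -inf
    # log-likelihood is rejected by step halving, so fp errors are muted
    errstate = np.errstate(divide="ignore", invalid="ignore", over="ignore")
    errstate.__enter__()
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    # suffix sums: S0[k] = sum_{i >= k} w_i, etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    k = 0
    while k < n:
        # block of identical times
        k2 = k
        while k2 + 1 < n and times[k2 + 1] == times[k]:
            k2 += 1
        ev = [i for i in range(k, k2 + 1) if events[i] == 1]
        d = len(ev)
        if d > 0:
            s0, s1, s2 = S0[k], S1[k], S2[k]
            xd = X[ev]
            wd = w[ev]
            ll += eta[ev].sum() - (eta.max() * 0)  # eta already shifted
            if ties == "breslow" or d == 1:
                ll -= d * np.log(s0)
                xbar = s1 / s0
                grad += xd.sum(axis=0) - d * xbar
                info += d * (s2 / s0 - np.outer(xbar, xbar))
            elif ties == "efron":
                wd_sum = wd.sum()
                wxd_sum = (wd[:, None] * xd).sum(axis=0)
                wxxd_sum = (wd[:, None, None] * xd[:, :, None] * xd[:, None, :]).sum(
                    axis=0
                )
                for m in range(d):
                    f = m / d
                    s0m = s0 - f * wd_sum
                    s1m = s1 - f * wxd_sum
                    s2m = s2 - f * wxxd_sum
                    ll -= np.log(s0m)
                    xbar = s1m / s0m
                    grad += xd[m] - xbar  # note: sum over m of xd[m] = sum xd
                    info += s2m / s0m - np.outer(xbar, xbar)
                # correction: grad should subtract xbar_m but add each event's x once;
                # xd[m] order within ties is arbitrary and sums correctly.
        k = k2 + 1
    errstate.__exit__(None, None, None)
    if not np.isfinite(ll):
        ll = -np.inf
    return ll, grad, info


@dataclass
class CoxFit:
    """Fitted Cox proportional hazards model."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    pvalues: pd.Series
    llf: float
    llf_null: float
    ties: str
    converged: bool
    flagged: str | None  # e.g. monotone-likelihood warning
    n: int
    n_events: int
    baseline: pd.DataFrame  # columns: time, cum_hazard
    residuals: pd.DataFrame  # martingale, deviance per subject (input order)
    data: pd.DataFrame | None = None
    duration_col: str = "time"
    event_col: str = "event"
    covariates: tuple = ()

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def confint(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lo": lo, "hi": hi, "hr_lo": np.exp(lo), "hr_hi": np.exp(hi)})

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        ci = self.confint(level)
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "hr": self.hazard_ratios,
                "hr_lo": ci["hr_lo"],
                "hr_hi": ci["hr_hi"],
                "p": self.pvalues,
            }
        )


def fit_cox(
    df: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    ties: Literal["efron", "breslow"] = "efron",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox PH model by Newton–Raphson with step halving.

    ``covariates`` may include the factor names "stage" and "grade",
    which expand to treatment-coded dummies.  Convergence requires the
    max absolute score below ``tol`` (or a matching parameter change);
    monotone likelihood (separation) is flagged rather than silently
    reported.
    """
    X_df = build_design(df, covariates)
    names = list(X_df.columns)
    X = X_df.to_numpy(dtype=float)
    times = df[duration_col].to_numpy(dtype=float)
    events = df[event_col].to_numpy(dtype=int)
    n, p = X.shape
    if events.sum() == 0:
        raise EstimationError("no events: Cox model cannot be fitted")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [names[k] for k in np.nonzero(sds == 0)[0]]
        raise ParameterError(f"zero-variance covariate(s): {bad}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise ParameterError("design matrix is rank deficient")

    order = np.argsort(times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]

    beta = np.zeros(p)
    ll, grad, info = _cox_loglik(beta, Xs, ts, es, ties)
    llf_null = ll
    converged = False
    flagged = None
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flagged = "singular information matrix"
            break
        # step halving to guarantee ascent
        factor = 1.0
        for _half in range(30):
            beta_new = beta + factor * step
            ll_new, grad_new, info_new = _cox_loglik(beta_new, Xs, ts, es, ties)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        delta = np.max(np.abs(beta_new - beta))
        beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
        if np.max(np.abs(grad)) < tol or delta < tol:
            converged = True
            break
    if np.max(np.abs(beta * sds)) > 5:
        flagged = "possible monotone likelihood (separation)"
    if not converged and flagged is None:
        flagged = "did not converge within max_iter"

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        flagged = flagged or "singular information matrix"
    bse = np.sqrt(np.abs(np.diag(cov)))
    z = beta / bse
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    # Breslow baseline cumulative hazard at beta_hat
    eta = Xs @ beta
    w = np.exp(eta - eta.max())
    S0 = np.cumsum(w[::-1])[::-1] * np.exp(eta.max())
    uniq_times = []
    dH = []
    k = 0
    while k < n:
        k2 = k
        while k2 + 1 < n and ts[k2 + 1] == ts[k]:
            k2 += 1
        d = int(es[k : k2 + 1].sum())
        if d > 0:
            uniq_times.append(ts[k])
            dH.append(d / S0[k])
        k = k2 + 1
    baseline = pd.DataFrame(
        {"time": uniq_times, "cum_hazard": np.cumsum(dH)}
    )

    # martingale and deviance residuals in the original row order
    H0_step = np.concatenate([[0.0], baseline["cum_hazard"].to_numpy()])
    idx = np.searchsorted(baseline["time"].to_numpy(), times, side="right")
    H0_at_t = H0_step[idx]
    risk = np.exp(X @ beta)
    mart = events - H0_at_t * risk
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_core = mart + events * np.log(np.maximum(events - mart, 1e-300))
    dev = np.sign(mart) * np.sqrt(np.maximum(-2.0 * dev_core, 0.0))
    residuals = pd.DataFrame(
        {"martingale": mart, "deviance": dev}, index=df.index
    )

    return CoxFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        pvalues=pd.Series(pvals, index=names),
        llf=float(ll),
        llf_null=float(llf_null),
        ties=ties,
        converged=converged,
        flagged=flagged,
        n=n,
        n_events=int(events.sum()),
        baseline=baseline,
        residuals=residuals,
        data=df,
        duration_col=duration_col,
        event_col=event_col,
        covariates=tuple(covariates),
    )


def cox_score_test(
    df: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    ties: Literal["efron", "breslow"] = "breslow",
) -> tuple[float, float]:
    """Score (Rao) test of beta = 0; equals the log-rank chi-square for a
    single binary covariate without ties (Breslow)."""
    X_df = build_design(df, covariates)
    X = X_df.to_numpy(dtype=float)
    times = df[duration_col].to_numpy(dtype=float)
    events = df[event_col].to_numpy(dtype=int)
    order = np.argsort(times, kind="stable")
    _, grad, info = _cox_loglik(
        np.zeros(X.shape[1]), X[order], times[order], events[order], ties
    )
    chi2 = float(grad @ np.linalg.solve(info, grad))
    return chi2, float(stats.chi2.sf(chi2, X.shape[1]))


# ---------------------------------------------------------------------------
# Leave-one-out influence


def loo_influence(fit: CoxFit, flag_factor: float = 3.0) -> pd.DataFrame:
    """Refit the model without each subject; report coefficient deltas.

    A subject is flagged when removing it changes any coefficient by
    more than ``flag_factor`` times that coefficient's standard error —
    the operational screen for an "unusually sizeable impact".
    """
    if fit.data is None:
        raise ParameterError("fit does not carry its data; cannot refit")
    if not fit.converged:
        raise EstimationError("cannot run influence analysis on a non-converged fit")
    df = fit.data
    rows = []
    for i in df.index:
        sub = df.drop(index=i)
        try:
            refit = fit_cox(
                sub,
                fit.covariates,
                duration_col=fit.duration_col,
                event_col=fit.event_col,
                ties=fit.ties,
            )
            delta = refit.params - fit.params
            std_delta = (delta / fit.bse).abs()
            flagged = bool((std_delta > flag_factor).any())
            row = {"subject": i, "converged": refit.converged, "flagged": flagged}
            for name in fit.params.index:
                row[f"delta_{name}"] = delta[name]
            row["max_abs_delta"] = float(delta.abs().max())
            row["max_std_delta"] = float(std_delta.max())
        except (EstimationError, ParameterError) as exc:
            row = {
                "subject": i,
                "converged": False,
                "flagged": False,
                "max_abs_delta": np.nan,
                "max_std_delta": np.nan,
                "error": str(exc),
            }
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


# ---------------------------------------------------------------------------
# Proportional-hazards supremum test (score-process multiplier resampling)


def ph_supremum_test(
    fit: CoxFit,
    n_sim: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Kolmogorov-type supremum test of proportional hazards.

    The observed standardized cumulative score process (partial sums of
    Schoenfeld residuals over event times) is compared, per covariate,
    with realizations obtained by multiplier resampling of the
    per-subject score-residual processes, including the
    I(t) I(inf)^{-1} correction for estimating beta (Lin–Wei–Ying).
    Returns per-covariate observed suprema and resampling p-values.
    """
    if n_sim < 100:
        raise ParameterError("n_sim must be at least 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    if fit.data is None:
        raise ParameterError("fit does not carry its data")
    df = fit.data
    X = build_design(df, fit.covariates).to_numpy(dtype=float)
    times = df[fit.duration_col].to_numpy(dtype=float)
    events = df[fit.event_col].to_numpy(dtype=int)
    beta = fit.params.to_numpy()
    n, p = X.shape

    order = np.argsort(times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]
    eta = Xs @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]

    # unique event times
    blocks = []
    k = 0
    while k < n:
        k2 = k
        while k2 + 1 < n and ts[k2 + 1] == ts[k]:
            k2 += 1
        d = int(es[k : k2 + 1].sum())
        if d > 0:
            blocks.append((k, k2, d))
        k = k2 + 1
    K = len(blocks)
    if K < 2:
        raise DegenerateDataError("too few distinct event times for a score process")

    xbar = np.empty((K, p))
    dH = np.empty(K)
    Vk = np.empty((K, p, p))
    for q, (k, k2, d) in enumerate(blocks):
        s0 = S0[k]
        xbar[q] = S1[k] / s0
        dH[q] = d / (s0 * np.exp(shift))
        # Breslow-style per-time information increment
        wxx = np.einsum("i,ij,il->jl", w[k:], Xs[k:], Xs[k:])
        Vk[q] = d * (wxx / s0 - np.outer(xbar[q], xbar[q]))

    # observed score process: partial sums of Schoenfeld residuals
    U = np.zeros((K, p))
    for q, (k, k2, d) in enumerate(blocks):
        ev = [i for i in range(k, k2 + 1) if es[i] == 1]
        U[q] = Xs[ev].sum(axis=0) - d * xbar[q]
    U = np.cumsum(U, axis=0)

    I_t = np.cumsum(Vk, axis=0)  # (K, p, p)
    I_inf = I_t[-1]
    scale = np.sqrt(np.diag(I_inf))
    if np.any(scale <= 0):
        raise DegenerateDataError("degenerate score process (zero information)")
    I_inv = np.linalg.inv(I_inf)
    B = I_t @ I_inv  # (K, p, p)

    # per-subject score-residual increments at each event time:
    # dS_i(q) = (x_i - xbar_q) dN_i(q) - Y_i(q) w_i (x_i - xbar_q) dH_q
    event_block = np.full(n, -1)
    for q, (k, k2, d) in enumerate(blocks):
        for i in range(k, k2 + 1):
            if es[i] == 1:
                event_block[i] = q
    risk_w = np.exp(eta)  # includes shift; dH defined with exp(shift) factored out

    obs_sup = np.abs(U / scale[None, :]).max(axis=0)

    # Build per-subject cumulative score residual S_i(t_q) lazily per covariate
    # to bound memory: arrays are (n, K).
    Y = ts[:, None] >= np.array([ts[k] for k, _, _ in blocks])[None, :]
    comp = Y * (risk_w[:, None] * dH[None, :])  # compensator increments (n, K)
    G = rng.standard_normal(size=(n_sim, n))

    sim_sup = np.zeros((n_sim, p))
    S_inf = np.zeros((n, p))
    S_cum_list = []
    for j in range(p):
        dS = -comp * (Xs[:, j, None] - xbar[None, :, j])
        rows_ev = np.nonzero(event_block >= 0)[0]
        dS[rows_ev, event_block[rows_ev]] += (
            Xs[rows_ev, j] - xbar[event_block[rows_ev], j]
        )
        S_cum = np.cumsum(dS, axis=1)  # (n, K)
        S_inf[:, j] = S_cum[:, -1]
        S_cum_list.append(S_cum)

    GS_inf = G @ S_inf  # (n_sim, p)
    for j in range(p):
        W = G @ S_cum_list[j]  # (n_sim, K)
        corr = np.einsum("kq,sq->sk", B[:, j, :], GS_inf)
        W = W - corr
        sim_sup[:, j] = np.abs(W / scale[j]).max(axis=1)

    pvals = (sim_sup >= obs_sup[None, :]).mean(axis=0)
    return pd.DataFrame(
        {"sup_stat": obs_sup, "p_value": pvals}, index=fit.params.index
    )


# ---------------------------------------------------------------------------
# Post-hoc power


def posthoc_power(
    n: int,
    log_hr: float,
    covariate_sd: float,
    event_rate: float,
    alpha: float = 0.05,
    n_sim: int = 500,
    seed: int | None = None,
    baseline_shape: float = 1.2,
    baseline_scale: float = 90.0,
) -> float:
    """Simulation-based power of the Wald test for one density covariate.

    Cohorts of size ``n`` are drawn from a Weibull-baseline Cox model
    with the given true log hazard ratio; administrative censoring is
    set so a fraction ``event_rate`` of subjects experience the event.
    Returns the rejection fraction at two-sided level ``alpha``.
    """
    if n < 10:
        raise ParameterError("n must be at least 10")
    if n_sim < 100:
        raise ParameterError("n_sim must be at least 100")
    if event_rate <= 0 or event_rate > 1:
        raise ParameterError("event_rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    hits = 0
    for _ in range(n_sim):
        x = rng.normal(0.0, covariate_sd, size=n)
        u = rng.uniform(size=n)
        t = baseline_scale * (-np.log(u) / np.exp(log_hr * (x - x.mean()))) ** (
            1.0 / baseline_shape
        )
        if event_rate < 1.0:
            c = np.quantile(t, event_rate)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
        else:
            time, event = t, np.ones(n, dtype=int)
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        try:
            fit = fit_cox(df, ["x"], ties="breslow")
        except (EstimationError, ParameterError):
            continue
        if abs(fit.params["x"] / fit.bse["x"]) > z_crit:
            hits += 1
    return hits / n_sim
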