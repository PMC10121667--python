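"""Core-level (non-spatial) association between CAIX and CD8.

Spearman rank correlation with nonparametric bootstrap confidence
intervals, plus count-regression models for CD8 cell counts: negative
binomial and zero-inflated Poisson with a log(area) offset, a TMA-slide
indicator and a CAIX × TMA interaction to absorb slide/batch effects.
Model choice is by AIC; slide-conditional CAIX effects are reported with
Wald confidence intervals from the coefficient covariance.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.discrete.count_model import ZeroInflatedPoisson
from statsmodels.discrete.discrete_model import NegativeBinomial

from .exceptions import DegenerateDataError, EstimationError, ParameterError
from .spatial import MarkedPointPattern

__all__ = [
    "spearman",
    "bootstrap_ci",
    "BootstrapCI",
    "summarize_cores",
    "CountModelFit",
    "fit_count_model",
    "compare_aic",
    "conditional_effect",
]

log = logging.getLogger(__name__)

# CAIX densities (cells/µm²) are rescaled internally so the optimizer
# sees O(1) covariates; coefficients are reported on the original scale.
CAIX_INTERNAL_SCALE = 1e4


# ---------------------------------------------------------------------------
# Spearman correlation


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of ranks (ties-safe Spearman rho)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with two-sided p-value.

    Ties receive average ranks.  For n <= 9 the p-value is exact,
    computed by enumerating all n! rank orders; otherwise the
    large-sample t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ParameterError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero-variance input: correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n <= 9:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        rhos = (ry_c[perms] * rx_c).sum(axis=1) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        # t approximation, guarding |rho| = 1
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# Bootstrap confidence interval


class BootstrapCI(NamedTuple):
    lo: float
    hi: float


def _spearman_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho for (B, n) resample matrices."""
    rx = stats.rankdata(xs, axis=1)
    ry = stats.rankdata(ys, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    return (rx * ry).sum(axis=1) / denom


def bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CI for the Spearman correlation.

    Units (cores) are resampled in pairs with replacement.  Degenerate
    resamples with zero variance in either coordinate are redrawn; the
    number of redraws is logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ParameterError("bootstrap needs at least 4 paired observations")
    if B < 200:
        raise ParameterError("B must be at least 200")
    if not 0 < level < 1:
        raise ParameterError("level must lie in (0, 1)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero-variance input: correlation undefined")
    if rng is None:
        rng = np.random.default_rng(seed)

    idx = rng.integers(0, n, size=(B, n))
    xs, ys = x[idx], y[idx]
    n_redraws = 0
    for _ in range(1000):
        bad = (np.ptp(xs, axis=1) == 0) | (np.ptp(ys, axis=1) == 0)
        if not bad.any():
            break
        n_redraws += int(bad.sum())
        idx_new = rng.integers(0, n, size=(int(bad.sum()), n))
        xs[bad] = x[idx_new]
        ys[bad] = y[idx_new]
    if n_redraws:
        log.info("bootstrap_ci: redrew %d degenerate resample(s)", n_redraws)
    rhos = _spearman_rows(xs, ys)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(rhos, [a, 1.0 - a])
    return BootstrapCI(float(lo), float(hi))


# ---------------------------------------------------------------------------
# Core summaries


def summarize_cores(
    patterns: Iterable[MarkedPointPattern],
    type_i: str = "CD8",
    type_j: str = "CAIX",
    subject_ids: Mapping[tuple, str] | None = None,
) -> pd.DataFrame:
    """Per-core areas, counts and densities, overall and by compartment."""
    rows = []
    for p in patterns:
        areas = dict(p.compartment_areas or {})
        row = {
            "core_id": p.core_id,
            "tma": p.tma_id,
            "subject_id": (subject_ids or {}).get((p.tma_id, p.core_id), p.core_id),
            "area_all": p.window.area,
            "area_tumor": areas.get("tumor", np.nan),
            "area_stroma": areas.get("stroma", np.nan),
        }
        for label, mark in (("cd8", type_i), ("caix", type_j)):
            row[f"{label}_all"] = p.count(mark)
            for comp in ("tumor", "stroma"):
                if p.compartments is not None:
                    row[f"{label}_{comp}"] = p.count(mark, comp)
                else:
                    row[f"{label}_{comp}"] = np.nan
        for label in ("cd8", "caix"):
            for comp in ("all", "tumor", "stroma"):
                area = row[f"area_{comp}"]
                cnt = row[f"{label}_{comp}"]
                row[f"{label}_density_{comp}"] = (
                    cnt / area if area and area > 0 else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Count regression


@dataclass
class CountModelFit:
    """Fitted count-regression model for CD8 counts."""

    family: str
    params: pd.Series  # original (per cells/µm²) scale
    bse: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    llf: float
    aic: float
    n_params: int
    converged: bool
    dispersion: float | None  # NB theta
    inflation: float | None  # ZIP inflation intercept (logit scale)
    design: dict = field(default_factory=dict)
    endog: np.ndarray | None = None

    def wald_ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        est, se = self.params[term], self.bse[term]
        return est - z * se, est + z * se


def _build_count_design(
    summaries: pd.DataFrame,
    compartment: str,
    terms: Sequence[str] = ("caix", "tma", "interaction"),
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, dict]:
    need = [f"cd8_{compartment}", f"caix_{compartment}", f"area_{compartment}", "tma"]
    for c in need:
        if c not in summaries.columns:
            raise ParameterError(f"summaries lack required column {c!r}")
    df = summaries.dropna(subset=need).copy()
    y = df[f"cd8_{compartment}"].to_numpy()
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ParameterError("response must be nonnegative integer counts")
    area = df[f"area_{compartment}"].to_numpy(dtype=float)
    if np.any(area <= 0):
        raise ParameterError("compartment areas must be positive")
    caix_density = df[f"caix_{compartment}"].to_numpy(dtype=float) / area
    tma_levels = sorted(df["tma"].unique())
    cols = {"const": np.ones(len(df))}
    if "caix" in terms:
        cols["caix"] = caix_density * CAIX_INTERNAL_SCALE
    for lvl in tma_levels[1:]:
        ind = (df["tma"] == lvl).astype(float).to_numpy()
        if "tma" in terms:
            cols[f"tma[{lvl}]"] = ind
        if "interaction" in terms and "caix" in terms:
            cols[f"caix:tma[{lvl}]"] = cols["caix"] * ind
    X = pd.DataFrame(cols, index=df.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name aliased columns via QR
        q, r = np.linalg.qr(X.to_numpy())
        aliased = [X.columns[k] for k in range(X.shape[1]) if abs(r[k, k]) < 1e-8]
        raise ParameterError(f"design matrix is rank deficient; aliased: {aliased}")
    meta = {
        "compartment": compartment,
        "tma_levels": tma_levels,
        "offset": f"log(area_{compartment})",
        "caix_internal_scale": CAIX_INTERNAL_SCALE,
    }
    return y.astype(float), X, np.log(area), meta


def _rescale_caix(params: pd.Series, cov: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Convert CAIX-related coefficients back to the per cells/µm² scale."""
    scale = pd.Series(1.0, index=params.index)
    for name in params.index:
        if name == "caix" or name.startswith("caix:"):
            scale[name] = CAIX_INTERNAL_SCALE
    params2 = params * scale
    cov2 = cov.mul(scale, axis=0).mul(scale, axis=1)
    return params2, cov2


def _fit_with_fallback(
    model, methods: Sequence[str] = ("newton", "bfgs", "nm")
) -> tuple:
    """Fit a statsmodels discrete model, falling back across optimizers.

    Boundary solutions (e.g. NB dispersion alpha -> 0 on Poisson-like
    data) can leave the Hessian singular; in that case the covariance is
    recovered from the Moore–Penrose pseudo-inverse of the observed
    information.
    """
    res = None
    for method in methods:
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = model.fit(disp=0, method=method, maxiter=500)
        except Exception:  # noqa: BLE001 - try the next optimizer
            continue
        res = cand
        if res.mle_retvals.get("converged", False):
            break
    if res is None:
        raise EstimationError("count-model fit failed with every optimizer")
    converged = bool(res.mle_retvals.get("converged", False))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(cov)):
            raise ValueError
    except Exception:  # noqa: BLE001 - singular information fallback
        if hasattr(model, "_transparams"):
            model._transparams = False  # params are on the natural scale
        with np.errstate(all="ignore"):
            hess = model.hessian(res.params)
        cov = np.linalg.pinv(-hess)
        log.warning(
            "count-model information matrix singular at the optimum; "
            "using pseudo-inverse covariance"
        )
    return res, cov, converged


def fit_count_model(
    summaries: pd.DataFrame,
    family: Literal["negative_binomial", "zero_inflated_poisson"] = "negative_binomial",
    compartment: Literal["all", "tumor", "stroma"] = "all",
    terms: Sequence[str] = ("caix", "tma", "interaction"),
) -> CountModelFit:
    """Fit a count model for CD8 counts with a CAIX × TMA design.

    Log link; linear predictor = intercept + CAIX density + TMA
    indicator + CAIX×TMA interaction, with offset log(compartment area).
    The negative binomial dispersion theta is estimated by maximum
    likelihood; the zero-inflated Poisson uses an intercept-only
    inflation component.
    """
    y, X, offset, meta = _build_count_design(summaries, compartment, terms)
    exog = X.to_numpy()
    names = list(X.columns)

    if family == "negative_binomial":
        model = NegativeBinomial(y, exog, offset=offset, loglike_method="nb2")
        res, full_cov, converged = _fit_with_fallback(model)
        alpha = float(res.params[-1])
        params = pd.Series(res.params[:-1], index=names)
        cov = pd.DataFrame(full_cov[:-1, :-1], index=names, columns=names)
        dispersion = 1.0 / alpha if alpha > 0 else np.inf
        inflation = None
        n_params = len(res.params)
    elif family == "zero_inflated_poisson":
        model = ZeroInflatedPoisson(
            y, exog, exog_infl=np.ones((len(y), 1)), offset=offset
        )
        res, full_cov, converged = _fit_with_fallback(model, methods=("bfgs", "nm"))
        # statsmodels orders params as [inflate_const, beta...]
        params = pd.Series(res.params[1:], index=names)
        cov = pd.DataFrame(full_cov[1:, 1:], index=names, columns=names)
        dispersion = None
        inflation = float(res.params[0])
        n_params = len(res.params)
    else:
        raise ParameterError(f"unknown family {family!r}")
    if not converged:
        log.warning("%s fit did not converge; results flagged", family)
    params, cov = _rescale_caix(params, cov)
    bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
    z = params / bse
    pvalues = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=names)
    llf = float(res.llf)
    return CountModelFit(
        family=family,
        params=params,
        bse=bse,
        pvalues=pvalues,
        cov=cov,
        llf=llf,
        aic=-2.0 * llf + 2.0 * n_params,
        n_params=n_params,
        converged=converged,
        dispersion=dispersion,
        inflation=inflation,
        design=meta,
        endog=y,
    )


def compare_aic(fits: Sequence[CountModelFit]) -> pd.DataFrame:
    """Rank fits of the same response by AIC (ascending), with delta AIC."""
    fits = list(fits)
    if not fits:
        raise ParameterError("no fits to compare")
    y0 = fits[0].endog
    for f in fits[1:]:
        if f.endog is None or y0 is None or not np.array_equal(f.endog, y0):
            raise ParameterError("fits were made on different responses")
    order = np.argsort([f.aic for f in fits], kind="stable")
    rows = [
        {
            "family": fits[k].family,
            "aic": fits[k].aic,
            "llf": fits[k].llf,
            "n_params": fits[k].n_params,
        }
        for k in order
    ]
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out


class ConditionalEffect(NamedTuple):
    estimate: float
    lo: float
    hi: float


def conditional_effect(
    fit: CountModelFit, tma_level: str, level: float = 0.95
) -> ConditionalEffect:
    """CAIX effect on CD8 conditional on one TMA slide, with Wald CI.

    For the reference slide this is the CAIX coefficient itself; for any
    other slide it is beta_caix + beta_{caix x tma}, with variance from
    the linear combination of the coefficient covariance.
    """
    if fit.cov is None or "caix" not in fit.params.index:
        raise ParameterError("fit lacks a CAIX term or its covariance")
    names = list(fit.params.index)
    L = np.zeros(len(names))
    L[names.index("caix")] = 1.0
    inter = f"caix:tma[{tma_level}]"
    levels = fit.design.get("tma_levels", [])
    if tma_level not in levels:
        raise ParameterError(f"unknown TMA level {tma_level!r}; have {levels}")
    if inter in names:
        L[names.index(inter)] = 1.0
    est = float(L @ fit.params.to_numpy())
    var = float(L @ fit.cov.to_numpy() @ L)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(var)
    return ConditionalEffect(est, est - z * se, est + z * se)
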