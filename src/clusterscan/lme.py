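"""Hierarchical linear mixed models for cluster-scan thickness data.

One model per participant:

    thickness ~ Timepoint * ROI + motion,
    random intercepts for scans nested in sessions nested in days,
    residual variance stratified (heteroscedastic) across ROI x Timepoint cells.

The model is fit by restricted maximum likelihood (REML).  Writing the
marginal covariance as  V = sigma^2 * V0(theta)  with

    V0 = gamma_day Zd Zd' + gamma_sess Zs Zs' + gamma_scan Zk Zk' + diag(w^2),

gamma_l the random-intercept variances relative to sigma^2 and w the
per-stratum residual weight multipliers (reference stratum = 1), sigma^2 is
profiled out analytically and the remaining parameters are optimized on the
log scale.  Fixed effects are the GLS solution at the optimum.

Downstream summaries follow the estimated-marginal-means workflow: cell
means of the Timepoint x ROI grid with motion held at its sample mean,
pairwise timepoint contrasts within ROI (family of 6, Bonferroni),
difference-in-decline interaction contrasts (family of 3), percent change
relative to the reference timepoint, and Wald F tests per fixed term.
Denominator degrees of freedom use a containment-style heuristic: terms
varying only between scans are tested against (n_scans - q_between), terms
varying within scans against (n_obs - n_scans - q_within).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from clusterscan.io import ClusterScanDataset, ValidationError

SINGULAR_TOL = 1e-6  # relative variance below this is a boundary estimate
_LOG_GAMMA_BOUNDS = (np.log(1e-8), np.log(1e4))
_LOG_W_BOUNDS = (np.log(1e-3), np.log(1e3))


class ConvergenceError(RuntimeError):
    """REML optimization failed after restarts; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class LMEModelSpec:
    """Model structure: fixed terms, random-intercept levels, residual strata.

    ``random``: ``"nested"`` (day/session/scan), ``"scan"`` (scans only) or
    ``"none"`` (fixed effects only).  ``strata``: tuple of grouping columns
    defining residual-variance strata, e.g. ``("roi", "timepoint")`` (the
    default six weights), ``("roi",)``, or ``()`` for homoscedastic.
    """

    include_timepoint: bool = True
    include_roi: bool = True
    include_motion: bool = True
    random: str = "nested"
    strata: tuple[str, ...] = ("roi", "timepoint")
    reference_roi: str = "core"
    df_method: str = "containment"  # containment | residual | normal

    def __post_init__(self):
        if self.random not in ("nested", "scan", "none"):
            raise ValidationError(f"unknown random structure {self.random!r}")
        if self.df_method not in ("containment", "residual", "normal"):
            raise ValidationError(f"unknown df method {self.df_method!r}")
        if self.include_roi is False and "roi" in self.strata:
            raise ValidationError("cannot stratify on roi without the roi factor")


@dataclass
class LMEFit:
    """Fitted model: estimates, variance components, and design metadata."""

    beta: np.ndarray
    cov: np.ndarray  # covariance of beta
    columns: list[str]
    sigma2: float
    varcomp: dict  # sigma2_day / sigma2_session / sigma2_scan (absolute)
    weights: dict  # stratum -> residual weight multiplier (reference = 1)
    loglik_reml: float
    n_obs: int
    n_scans: int
    converged: bool
    singular: bool
    spec: LMEModelSpec = None
    tp_levels: tuple = ()
    roi_levels: tuple = ()
    motion_mean: float = 0.0
    df_between: float = 0.0
    df_within: float = 0.0
    within_cols: frozenset = frozenset()
    data_fingerprint: str = ""
    optimizer_trace: list = field(default_factory=list, repr=False)
    whitened_X: np.ndarray = field(default=None, repr=False)
    whitened_y: np.ndarray = field(default=None, repr=False)

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])


@dataclass
class EMMTable:
    """Estimated marginal means of the Timepoint x ROI grid (motion at its mean)."""

    table: pd.DataFrame  # columns: timepoint, roi, emm, se, df, ci_lo, ci_hi

    def emm(self, timepoint: str, roi: str | None = None) -> float:
        t = self.table
        m = t["timepoint"] == timepoint
        if roi is not None:
            m &= t["roi"] == roi
        sel = t[m]
        if len(sel) != 1:
            raise KeyError(f"no unique EMM cell ({timepoint}, {roi})")
        return float(sel["emm"].iloc[0])


@dataclass
class ContrastResult:
    label: str
    delta: float
    se: float
    ci_lo: float
    ci_hi: float
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    family_size: int


# ---------------------------------------------------------------------------
# design construction

def _prepare_frame(data, include_roi: bool) -> pd.DataFrame:
    if isinstance(data, ClusterScanDataset):
        df = data.table
        df = df[df["unit_type"] == "roi"].copy()
        df = df.rename(columns={"unit": "roi", "thickness_mm": "thickness"})
    else:
        df = data.copy()
        if "thickness" not in df.columns and "thickness_mm" in df.columns:
            df = df.rename(columns={"thickness_mm": "thickness"})
    needed = ["timepoint", "day", "session", "scan", "rmspm", "thickness"]
    if include_roi:
        needed.append("roi")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"model data missing column(s): {missing}")
    if df["rmspm"].isna().any():
        raise ValidationError("missing motion scores in model data")
    df["scan_unit"] = (df["timepoint"].astype(str) + "/" + df["day"].astype(str)
                       + "/" + df["session"].astype(str) + "/" + df["scan"].astype(str))
    df["sess_unit"] = (df["timepoint"].astype(str) + "/" + df["day"].astype(str)
                       + "/" + df["session"].astype(str))
    df["day_unit"] = df["timepoint"].astype(str) + "/" + df["day"].astype(str)
    return df


def _tp_levels(df: pd.DataFrame) -> tuple[str, ...]:
    tp = df["timepoint"]
    if isinstance(tp.dtype, pd.CategoricalDtype):
        return tuple(str(c) for c in tp.cat.categories if (tp == c).any())
    return tuple(pd.unique(tp.astype(str)))


def _design_matrix(df: pd.DataFrame, spec: LMEModelSpec):
    tp_levels = _tp_levels(df)
    tp = df["timepoint"].astype(str).to_numpy()
    cols: list[str] = ["Intercept"]
    X = [np.ones(len(df))]
    if spec.include_timepoint:
        if len(tp_levels) < 2:
            raise ValidationError("need >= 2 timepoints to model longitudinal change")
        for l in tp_levels[1:]:
            cols.append(f"tp[{l}]")
            X.append((tp == l).astype(float))
    roi_levels: tuple[str, ...] = ()
    if spec.include_roi:
        rois = sorted(df["roi"].astype(str).unique())
        if len(rois) != 2:
            raise ValidationError(f"full model needs both ROIs, found {rois}")
        if spec.reference_roi not in rois:
            raise ValidationError(f"reference ROI {spec.reference_roi!r} not in data")
        other = [r for r in rois if r != spec.reference_roi][0]
        roi_levels = (spec.reference_roi, other)
        roi_ind = (df["roi"].astype(str) == other).to_numpy().astype(float)
        cols.append(f"roi[{other}]")
        X.append(roi_ind)
        for l in tp_levels[1:]:
            cols.append(f"tp[{l}]:roi[{other}]")
            X.append((tp == l).astype(float) * roi_ind)
    if spec.include_motion:
        cols.append("motion")
        X.append(df["rmspm"].to_numpy(dtype=float))
    return np.column_stack(X), cols, tp_levels, roi_levels


def _indicator(codes: pd.Series) -> np.ndarray:
    cats, inv = np.unique(codes.to_numpy(), return_inverse=True)
    Z = np.zeros((len(inv), len(cats)))
    Z[np.arange(len(inv)), inv] = 1.0
    return Z


# ---------------------------------------------------------------------------
# REML machinery

def _reml_neg2(theta, ZZt_list, strat_idx, n_strata, X, y, n, p,
               want_grad: bool = False):
    """Profiled -2 restricted log-likelihood (and its gradient) at log-params."""
    k = len(ZZt_list)
    gammas = np.exp(theta[:k])
    w = np.ones(n_strata)
    if n_strata > 1:
        w[1:] = np.exp(theta[k:])
    V0 = np.zeros((n, n))
    for g, ZZt in zip(gammas, ZZt_list):
        V0 += g * ZZt
    d = (w ** 2)[strat_idx]
    V0[np.diag_indices(n)] += d
    try:
        c, low = linalg.cho_factor(V0, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return (np.inf, None, None) if want_grad else (np.inf, None)
    logdetV0 = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
    Vi_y = linalg.cho_solve((c, low), y, check_finite=False)
    XtViX = X.T @ Vi_X
    XtViy = X.T @ Vi_y
    try:
        cx = linalg.cho_factor(XtViX, check_finite=False)
    except linalg.LinAlgError:
        return (np.inf, None, None) if want_grad else (np.inf, None)
    beta = linalg.cho_solve(cx, XtViy, check_finite=False)
    logdetXtViX = 2.0 * np.sum(np.log(np.diag(cx[0])))
    rss0 = float(y @ Vi_y - XtViy @ beta)
    rss0 = max(rss0, 1e-300)
    sigma2 = rss0 / (n - p)
    neg2 = ((n - p) * (1.0 + np.log(2.0 * np.pi * sigma2))
            + logdetV0 + logdetXtViX)
    aux = (beta, sigma2, XtViX, c, low)
    if not want_grad:
        return neg2, aux
    # gradient of the profiled objective: for a variance parameter alpha,
    #   d(-2l)/dalpha = tr(P dV0) - (n-p)/rss0 * (Py)' dV0 (Py)
    # with P = V0^-1 - V0^-1 X (X'V0^-1 X)^-1 X'V0^-1
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    P = Vi - Vi_X @ linalg.cho_solve(cx, Vi_X.T, check_finite=False)
    Py = Vi_y - Vi_X @ beta
    scale = (n - p) / rss0
    grad = np.empty(len(theta))
    for j, (g, ZZt) in enumerate(zip(gammas, ZZt_list)):
        grad[j] = g * (np.sum(P * ZZt) - scale * float(Py @ ZZt @ Py))
    diagP = np.diag(P)
    for s in range(1, n_strata):
        mask = strat_idx == s
        dw = 2.0 * w[s] ** 2
        grad[k + s - 1] = dw * (diagP[mask].sum() - scale * float(np.sum(Py[mask] ** 2)))
    return neg2, aux, grad


def _degenerate_fit(df, X, y, beta, cols, tp_levels, roi_levels,
                    spec: LMEModelSpec) -> "LMEFit":
    n, p = X.shape
    n_scans = df["scan_unit"].nunique()
    within = frozenset(c for c in cols if "roi[" in c)
    fp = hashlib.sha256(np.ascontiguousarray(np.round(y, 12)).tobytes()).hexdigest()[:16]
    levels = {"nested": ["day", "session", "scan"], "scan": ["scan"], "none": []}[spec.random]
    if spec.random == "none":
        df_between = df_within = float(n - p)
    else:
        df_between = float(n_scans - (p - len(within)))
        df_within = float(max(n - n_scans - len(within), 1))
    return LMEFit(beta=beta, cov=np.zeros((p, p)), columns=cols, sigma2=0.0,
                  varcomp={f"sigma2_{l}": 0.0 for l in levels}, weights={"all": 1.0},
                  loglik_reml=np.inf, n_obs=n, n_scans=int(n_scans),
                  converged=True, singular=bool(levels), spec=spec,
                  tp_levels=tp_levels, roi_levels=roi_levels,
                  motion_mean=float(df["rmspm"].mean()) if spec.include_motion else 0.0,
                  df_between=df_between, df_within=df_within, within_cols=within,
                  data_fingerprint=fp, whitened_X=X, whitened_y=y)


def fit_lme(data, spec: LMEModelSpec | None = None,
            fixed_theta: np.ndarray | None = None,
            max_restarts: int = 3, seed: int = 0) -> LMEFit:
    """Fit the mixed model by REML.

    Parameters
    ----------
    data
        A :class:`ClusterScanDataset` (its ROI rows are used) or a long
        DataFrame with columns timepoint/day/session/scan/rmspm/thickness
        (plus roi when ``spec.include_roi``).
    spec
        Model structure; defaults to the full nested heteroscedastic model.
    fixed_theta
        Optional log-parameter vector (log relative variances then log
        stratum weights) to evaluate at without optimizing — used when
        variance components are known.
    """
    if spec is None:
        spec = LMEModelSpec()
    df = _prepare_frame(data, spec.include_roi)
    X, cols, tp_levels, roi_levels = _design_matrix(df, spec)
    y = df["thickness"].to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("fixed-effects design matrix is rank deficient")

    # exactly (or machine-precision) noise-free data: the REML objective is
    # unbounded below, so return the interpolating OLS fit with every
    # variance component at the boundary
    beta_ols, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss_ols = float(np.sum((y - X @ beta_ols) ** 2))
    if rss_ols <= n * (1e-10 ** 2) * max(1.0, float(np.mean(y ** 2))):
        return _degenerate_fit(df, X, y, beta_ols, cols, tp_levels, roi_levels, spec)

    level_names = {"nested": ["day", "session", "scan"], "scan": ["scan"], "none": []}
    unit_cols = {"day": "day_unit", "session": "sess_unit", "scan": "scan_unit"}
    levels = level_names[spec.random]
    ZZt_list = []
    for l in levels:
        Z = _indicator(df[unit_cols[l]])
        ZZt_list.append(Z @ Z.T)

    if spec.strata:
        strat_codes = df[list(spec.strata)].astype(str).agg("|".join, axis=1)
        strat_names, strat_idx = np.unique(strat_codes.to_numpy(), return_inverse=True)
    else:
        strat_names, strat_idx = np.array(["all"]), np.zeros(n, dtype=int)
    n_strata = len(strat_names)
    k = len(ZZt_list)
    n_theta = k + max(n_strata - 1, 0)

    trace: list = []
    if n_theta == 0:
        neg2, aux = _reml_neg2(np.empty(0), ZZt_list, strat_idx, n_strata, X, y, n, p)
        theta_hat, converged = np.empty(0), True
    elif fixed_theta is not None:
        theta_hat = np.asarray(fixed_theta, dtype=float)
        neg2, aux = _reml_neg2(theta_hat, ZZt_list, strat_idx, n_strata, X, y, n, p)
        converged = True
    else:
        bounds = [_LOG_GAMMA_BOUNDS] * k + [_LOG_W_BOUNDS] * (n_strata - 1)
        rng = np.random.default_rng(seed)
        best = None
        start = np.zeros(n_theta)
        start[:k] = np.log(0.5)
        def fun_and_grad(th):
            f, _, g = _reml_neg2(th, ZZt_list, strat_idx, n_strata, X, y, n, p,
                                 want_grad=True)
            if not np.isfinite(f):
                return np.inf, np.zeros_like(th)
            return f, g

        finished = []
        for attempt in range(max_restarts + 1):
            x0 = start if attempt == 0 else start + rng.normal(0, 1.5, size=n_theta)
            res = optimize.minimize(fun_and_grad, x0, jac=True, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"maxiter": 1000, "ftol": 1e-14,
                                             "gtol": 1e-10})
            trace.append({"attempt": attempt, "success": bool(res.success),
                          "fun": float(res.fun), "message": str(res.message)})
            if np.isfinite(res.fun):
                finished.append(res)
            if res.success and np.isfinite(res.fun):
                best = res
                break
            # line search can abort (ABNORMAL) once the objective is flat to
            # machine precision; accept when two independent starts agree
            if len(finished) >= 2:
                finished.sort(key=lambda r: r.fun)
                if (finished[1].fun - finished[0].fun
                        < 1e-5 * max(1.0, abs(finished[0].fun))):
                    best = finished[0]
                    break
        if best is None:
            raise ConvergenceError("REML optimization failed after restarts", trace)
        theta_hat, converged = best.x, True
        neg2, aux = _reml_neg2(theta_hat, ZZt_list, strat_idx, n_strata, X, y, n, p)

    if aux is None:
        raise ConvergenceError("REML objective not finite at optimum", trace)
    beta, sigma2, XtViX, c, low = aux
    cov = sigma2 * np.linalg.inv(XtViX)
    gammas = np.exp(theta_hat[:k])
    weights = {str(strat_names[0]): 1.0}
    for i, name in enumerate(strat_names[1:]):
        weights[str(name)] = float(np.exp(theta_hat[k + i]))
    varcomp = {f"sigma2_{l}": float(sigma2 * g) for l, g in zip(levels, gammas)}
    at_bound = bool(k) and bool(np.any(theta_hat[:k] <= _LOG_GAMMA_BOUNDS[0] + 1e-8))
    singular = bool(k) and (bool(np.any(gammas < SINGULAR_TOL)) or at_bound)

    n_scans = df["scan_unit"].nunique()
    within = frozenset(cname for cname in cols if "roi[" in cname)
    q_within = len(within)
    q_between = p - q_within
    if spec.random == "none":
        df_between = df_within = float(n - p)
    else:
        df_between = float(n_scans - q_between)
        df_within = float(max(n - n_scans - q_within, 1))
    fp = hashlib.sha256(np.ascontiguousarray(np.round(y, 12)).tobytes()).hexdigest()[:16]
    wX = linalg.solve_triangular(c, X, lower=low, check_finite=False)
    wy = linalg.solve_triangular(c, y, lower=low, check_finite=False)
    return LMEFit(beta=beta, cov=cov, columns=cols, sigma2=float(sigma2),
                  varcomp=varcomp, weights=weights,
                  loglik_reml=float(-0.5 * neg2), n_obs=n, n_scans=int(n_scans),
                  converged=converged, singular=singular, spec=spec,
                  tp_levels=tp_levels, roi_levels=roi_levels,
                  motion_mean=float(df["rmspm"].mean()) if spec.include_motion else 0.0,
                  df_between=df_between, df_within=df_within, within_cols=within,
                  data_fingerprint=fp, optimizer_trace=trace,
                  whitened_X=wX, whitened_y=wy)


# ---------------------------------------------------------------------------
# inference helpers

def _contrast_df(fit: LMEFit, L: np.ndarray) -> float:
    method = fit.spec.df_method if fit.spec else "containment"
    if method == "normal":
        return np.inf
    if method == "residual":
        return float(fit.n_obs - len(fit.columns))
    uses_within = any(abs(L[i]) > 1e-12 and fit.columns[i] in fit.within_cols
                      for i in range(len(fit.columns)))
    return fit.df_within if uses_within else fit.df_between


def _emm_row(fit: LMEFit, timepoint: str, roi: str | None) -> np.ndarray:
    L = np.zeros(len(fit.columns))
    for i, cname in enumerate(fit.columns):
        if cname == "Intercept":
            L[i] = 1.0
        elif cname == f"tp[{timepoint}]":
            L[i] = 1.0
        elif roi is not None and cname == f"roi[{roi}]":
            L[i] = 1.0
        elif roi is not None and cname == f"tp[{timepoint}]:roi[{roi}]":
            L[i] = 1.0
        elif cname == "motion":
            L[i] = fit.motion_mean
    return L


def estimated_marginal_means(fit: LMEFit, conf_level: float = 0.95) -> EMMTable:
    """Cell means of the Timepoint (x ROI) grid with motion at its sample mean."""
    if not fit.converged:
        raise ValidationError("cannot compute EMMs from a non-converged fit")
    rows = []
    rois = list(fit.roi_levels) if fit.roi_levels else [None]
    for tp in fit.tp_levels:
        for roi in rois:
            # reference-ROI rows must not pick up the roi dummy
            roi_for_L = None if (roi is not None and roi == fit.roi_levels[0]) else roi
            L = _emm_row(fit, tp, roi_for_L)
            est = float(L @ fit.beta)
            se = float(np.sqrt(L @ fit.cov @ L))
            dof = _contrast_df(fit, L)
            tcrit = stats.t.ppf(0.5 + conf_level / 2, dof) if np.isfinite(dof) \
                else stats.norm.ppf(0.5 + conf_level / 2)
            rows.append({"timepoint": tp, "roi": roi if roi is not None else "",
                         "emm": est, "se": se, "df": dof,
                         "ci_lo": est - tcrit * se, "ci_hi": est + tcrit * se})
    return EMMTable(pd.DataFrame(rows))


def _contrast(fit: LMEFit, L: np.ndarray, label: str, family_size: int,
              conf_level: float = 0.95) -> ContrastResult:
    delta = float(L @ fit.beta)
    se = float(np.sqrt(L @ fit.cov @ L))
    dof = _contrast_df(fit, L)
    if se > 0:
        tval = delta / se
    else:  # noise-free fit: any non-zero difference is exact
        tval = np.inf * np.sign(delta) if abs(delta) > 1e-12 else 0.0
    if np.isfinite(dof):
        p = 2 * stats.t.sf(abs(tval), dof)
        tcrit = stats.t.ppf(0.5 + conf_level / 2, dof)
    else:
        p = 2 * stats.norm.sf(abs(tval))
        tcrit = stats.norm.ppf(0.5 + conf_level / 2)
    return ContrastResult(label=label, delta=delta, se=se,
                          ci_lo=delta - tcrit * se, ci_hi=delta + tcrit * se,
                          t=float(tval), df=float(dof), p_raw=float(p),
                          p_adjusted=float(min(1.0, family_size * p)),
                          family_size=family_size)


def timepoint_pairs(tp_levels) -> list[tuple[str, str]]:
    """All (earlier, later) pairs in chronological order."""
    return [(tp_levels[i], tp_levels[j])
            for i in range(len(tp_levels)) for j in range(i + 1, len(tp_levels))]


def pairwise_contrasts(fit: LMEFit, family_size: int | None = None
                       ) -> list[ContrastResult]:
    """Earlier-minus-later timepoint differences within each ROI.

    Positive delta = thinning.  The default family is every timepoint pair
    in every ROI (3 pairs x 2 ROIs = 6), Bonferroni-adjusted.
    """
    pairs = timepoint_pairs(fit.tp_levels)
    rois = list(fit.roi_levels) if fit.roi_levels else [None]
    if family_size is None:
        family_size = len(pairs) * len(rois)
    out = []
    for roi in rois:
        roi_for_L = None if (roi is not None and roi == fit.roi_levels[0]) else roi
        for earlier, later in pairs:
            L = _emm_row(fit, earlier, roi_for_L) - _emm_row(fit, later, roi_for_L)
            label = f"{earlier}-{later}" + (f" | {roi}" if roi is not None else "")
            out.append(_contrast(fit, L, label, family_size))
    return out


def interaction_contrasts(fit: LMEFit, family_size: int | None = None
                          ) -> list[ContrastResult]:
    """Per timepoint pair: (decline in core) minus (decline in control)."""
    if not fit.roi_levels:
        raise ValidationError("interaction contrasts need the ROI factor")
    ref, other = fit.roi_levels
    pairs = timepoint_pairs(fit.tp_levels)
    if family_size is None:
        family_size = len(pairs)
    out = []
    for earlier, later in pairs:
        L_ref = _emm_row(fit, earlier, None) - _emm_row(fit, later, None)
        L_other = _emm_row(fit, earlier, other) - _emm_row(fit, later, other)
        L = L_ref - L_other
        out.append(_contrast(fit, L, f"{earlier}-{later} | {ref} vs {other}",
                             family_size))
    return out


def percent_change(emms: EMMTable, pair: tuple[str, str], roi: str | None = None,
                   ndigits: int | None = 1) -> float:
    """100 x (later - reference) / reference; thinning is negative.

    ``ndigits=1`` (default) rounds to one decimal for report output; pass
    ``None`` for the raw value.
    """
    reference = emms.emm(pair[0], roi)
    later = emms.emm(pair[1], roi)
    if reference <= 0:
        raise ValidationError("reference EMM must be positive")
    pct = 100.0 * (later - reference) / reference
    return round(pct, ndigits) if ndigits is not None else pct


def bonferroni_threshold(alpha: float, family_size: int) -> float:
    """Per-test significance threshold alpha / family_size."""
    if family_size < 1:
        raise ValidationError("family_size must be >= 1")
    return alpha / family_size


# ---------------------------------------------------------------------------
# F tests and LRT

_TERM_ORDER = ["timepoint", "roi", "motion", "timepoint:roi"]


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _term_columns(fit: LMEFit) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {t: [] for t in _TERM_ORDER}
    for i, cname in enumerate(fit.columns):
        if cname == "Intercept":
            continue
        if cname == "motion":
            groups["motion"].append(i)
        elif cname.startswith("tp[") and ":" not in cname:
            groups["timepoint"].append(i)
        elif cname.startswith("roi["):
            groups["roi"].append(i)
        else:
            groups["timepoint:roi"].append(i)
    return {t: ix for t, ix in groups.items() if ix}


def anova_fixed_effects(fit: LMEFit, mode: str = "marginal") -> pd.DataFrame:
    """Wald F test per fixed term (Timepoint, ROI, Motion, Timepoint x ROI).

    ``marginal`` (default) tests each term's coefficient block in the full
    model; ``sequential`` tests terms in order via incremental generalized
    least squares sums of squares.
    """
    groups = _term_columns(fit)
    rows = []
    if mode == "marginal":
        for term, ix in groups.items():
            b = fit.beta[ix]
            C = fit.cov[np.ix_(ix, ix)]
            # an exactly interpolating (zero-residual) fit has a zero
            # covariance block: the data are noise-free, so any non-zero
            # effect is infinitely significant
            if np.all(np.abs(C) < 1e-300):
                F = np.inf if np.any(np.abs(b) > 1e-12) else 0.0
            else:
                F = float(b @ np.linalg.solve(C, b) / len(ix))
            L = np.zeros(len(fit.columns))
            L[ix] = 1.0
            dfd = _contrast_df(fit, L)
            rows.append({"term": term, "df_num": len(ix), "df_den": dfd, "F": F,
                         "p": float(stats.f.sf(F, len(ix), dfd))})
    elif mode == "sequential":
        # GLS Type-I: incremental residual-sum-of-squares drops on the
        # whitened (V0^{-1/2}-transformed) design, term by term in order.
        wX, wy = fit.whitened_X, fit.whitened_y
        if wX is None:
            raise ValidationError("fit lacks the whitened design (refit required)")
        order = [t for t in _TERM_ORDER if t in groups]
        done: list[int] = [fit.columns.index("Intercept")]
        rss_prev = _ols_rss(wX[:, done], wy)
        for term in order:
            ix = groups[term]
            done = done + ix
            rss_new = _ols_rss(wX[:, done], wy)
            k = len(ix)
            F = float((rss_prev - rss_new) / (k * fit.sigma2))
            rss_prev = rss_new
            L = np.zeros(len(fit.columns))
            L[ix] = 1.0
            dfd = _contrast_df(fit, L)
            rows.append({"term": term, "df_num": k, "df_den": dfd, "F": F,
                         "p": float(stats.f.sf(F, k, dfd))})
    else:
        raise ValidationError(f"unknown anova mode {mode!r}")
    return pd.DataFrame(rows)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float
    retain_simple: bool


def lrt_random_structure(full: LMEFit, simple: LMEFit,
                         alpha: float = 0.05) -> LRTResult:
    """Likelihood ratio test of nested day/session/scan vs scan-only intercepts.

    Valid on REML fits because the fixed effects are identical.  The
    statistic is referred to chi-square with 2 df (the two dropped variance
    components); the boundary-null chi-bar-square refinement would be more
    conservative but the plain chi-square reference is the default.  The
    simple model is retained when p > alpha.
    """
    if full.data_fingerprint != simple.data_fingerprint:
        raise ValidationError("LRT models were fit to different data")
    if full.columns != simple.columns:
        raise ValidationError("LRT models must share identical fixed effects")
    if np.isinf(full.loglik_reml) and np.isinf(simple.loglik_reml):
        stat = 0.0  # both interpolate exactly: no evidence either way
    else:
        stat = max(0.0, 2.0 * (full.loglik_reml - simple.loglik_reml))
    p = float(stats.chi2.sf(stat, df=2))
    return LRTResult(statistic=float(stat), df=2, p=p, retain_simple=p > alpha)
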