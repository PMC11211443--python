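"""Linear mixed-effects growth models with AR1 within-fish errors.

The model for log relative growth of fish *f* at increment *t* is

    y_ft = x_ft' beta + b0_f + b1_f * (t - center) + e_ft

with independent fish-level random intercepts b0 and slopes b1 and a
stationary AR1 process for e within fish.  Estimation maximizes the
profiled marginal (ML or REML) log-likelihood over the variance ratios
and the autocorrelation with a Nelder-Mead search; statsmodels' MixedLM
does not support AR1 residual correlation, hence the dedicated fitter.

Also provides covariate standardization, a three-step AIC model-selection
ladder (random structure, fixed-effect subsets, error structure), and
marginal means on the response scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = [
    "ScalingInfo",
    "ModelFit",
    "scale_predictors",
    "fit_lmm",
    "select_model",
    "marginal_means",
]


# ---------------------------------------------------------------------------
# covariate scaling


@dataclass
class ScalingInfo:
    means: dict[str, float]
    sds: dict[str, float]


def scale_predictors(
    obs: pd.DataFrame, columns: list[str], ddof: int = 1
) -> tuple[pd.DataFrame, ScalingInfo]:
    """Standardize continuous covariates: (x - mean) / sd (sample SD).

    Returns a copy with the named columns replaced and the constants
    needed to back-transform.  Zero-variance columns are rejected.
    """
    out = obs.copy()
    means, sds = {}, {}
    for col in columns:
        x = out[col].to_numpy(float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=ddof))
        if sd == 0.0:
            raise ValueError(f"covariate {col!r} has zero variance")
        out[col] = (x - mu) / sd
        means[col], sds[col] = mu, sd
    return out, ScalingInfo(means=means, sds=sds)


# ---------------------------------------------------------------------------
# design assembly


def _class_levels(s: pd.Series) -> list[str]:
    preferred = ["Before", "Between", "Heatwave", "During"]
    present = list(pd.unique(s))
    ordered = [c for c in preferred if c in present]
    return ordered + sorted(set(present) - set(ordered))


def _build_design(
    data: pd.DataFrame,
    fixed: list[str],
    class_col: str | None,
    class_levels: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix with intercept, continuous terms,
    treatment-coded class dummies, and ':'-separated interactions."""
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    dummies: dict[str, np.ndarray] = {}
    if class_col is not None and class_col in data.columns:
        levels = class_levels or _class_levels(data[class_col])
        for lev in levels[1:]:
            dummies[f"{class_col}[{lev}]"] = (
                (data[class_col] == lev).to_numpy(float)
            )

    def term_columns(term: str) -> dict[str, np.ndarray]:
        if class_col is not None and term == class_col:
            return dict(dummies)
        return {term: data[term].to_numpy(float)}

    for term in fixed:
        parts = term.split(":")
        pieces = [term_columns(p) for p in parts]
        for combo in itertools.product(*[list(p.items()) for p in pieces]):
            name = ":".join(k for k, _ in combo)
            col = np.ones(n)
            for _, v in combo:
                col = col * v
            cols.append(col)
            names.append(name)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ModelFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df: pd.Series
    sigma2: float
    var_intercept: float
    var_slope: float
    ar1_phi: float
    loglik: float
    aic: float
    n_params: int
    r2_marginal: float
    r2_conditional: float
    converged: bool
    method: str
    fixed: list[str] = field(default_factory=list)
    response: str = ""
    group_col: str = ""
    class_col: str | None = None
    class_levels: list[str] = field(default_factory=list)
    slope_center: float = 11.0
    random_slope: bool = True
    ar1: bool = True
    n_obs: int = 0
    n_groups: int = 0
    scaling: ScalingInfo | None = None
    cov_params: np.ndarray | None = None

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "std_error": self.bse,
                "df": self.df,
                "t_value": self.tvalues,
                "p_value": self.pvalues,
            }
        )


def _ar1_corr(n: int, phi: float) -> np.ndarray:
    idx = np.arange(n)
    return phi ** np.abs(idx[:, None] - idx[None, :])


class _Blocks:
    """Per-fish data grouped by identical (length, z-vector) patterns so
    the within-group covariance factorization is done once per pattern."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray, z: np.ndarray):
        order = np.argsort(groups, kind="stable")
        Xs, ys, zs, gs = X[order], y[order], z[order], groups[order]
        bounds = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1], True])
        by_key: dict[tuple, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
        for a, b in zip(bounds[:-1], bounds[1:]):
            zi = zs[a:b]
            key = (b - a, tuple(np.round(zi, 9)))
            by_key.setdefault(key, []).append((Xs[a:b], ys[a:b], zi))
        self.patterns: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for items in by_key.values():
            Xstack = np.stack([it[0] for it in items])  # (m, n_i, p)
            ystack = np.stack([it[1] for it in items])  # (m, n_i)
            self.patterns.append((Xstack, ystack, items[0][2]))
        self.n_obs = len(y)
        self.p = X.shape[1]


def _profiled_nll(
    theta: np.ndarray,
    blocks: _Blocks,
    random_slope: bool,
    ar1: bool,
    reml: bool,
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Negative profiled log-likelihood; returns (nll, beta, sigma2, XtWiX)."""
    k = 0
    g_int = np.exp(theta[k]); k += 1
    g_slope = 0.0
    if random_slope:
        g_slope = np.exp(theta[k]); k += 1
    phi = np.tanh(theta[k]) if ar1 else 0.0

    p = blocks.p
    XtWiX = np.zeros((p, p))
    XtWiy = np.zeros(p)
    logdet = 0.0
    whitened: list[tuple[np.ndarray, np.ndarray]] = []
    for Xs, ys, zi in blocks.patterns:
        m, n_i = ys.shape
        Z = np.column_stack([np.ones(n_i), zi]) if random_slope else np.ones((n_i, 1))
        G = np.diag([g_int, g_slope][: Z.shape[1]])
        W = Z @ G @ Z.T + (_ar1_corr(n_i, phi) if ar1 else np.eye(n_i))
        try:
            L = np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(p), np.nan, XtWiX
        logdet += 2.0 * m * np.log(np.diag(L)).sum()
        Xw = solve_triangular(
            L, Xs.transpose(1, 0, 2).reshape(n_i, m * p), lower=True
        ).reshape(n_i, m, p).transpose(1, 0, 2).reshape(m * n_i, p)
        yw = solve_triangular(L, ys.T, lower=True).T.reshape(m * n_i)
        XtWiX += Xw.T @ Xw
        XtWiy += Xw.T @ yw
        whitened.append((Xw, yw))

    try:
        beta = np.linalg.solve(XtWiX, XtWiy)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(p), np.nan, XtWiX
    rss = 0.0
    for Xw, yw in whitened:
        r = yw - Xw @ beta
        rss += float(r @ r)
    N = blocks.n_obs
    denom = N - p if reml else N
    sigma2 = rss / denom
    if not np.isfinite(sigma2) or sigma2 <= 0:
        return np.inf, beta, sigma2, XtWiX
    nll = 0.5 * (denom * np.log(2 * np.pi * sigma2) + logdet + denom)
    if reml:
        sign, ld = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return np.inf, beta, sigma2, XtWiX
        nll += 0.5 * ld
    return nll, beta, sigma2, XtWiX


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    group_col: str = "fish_id",
    increment_col: str = "increment_index",
    class_col: str | None = "class",
    random_slope: bool = True,
    ar1: bool = True,
    reml: bool = False,
    slope_center: float = 11.0,
    start: np.ndarray | None = None,
    maxiter: int = 2000,
) -> ModelFit:
    """Fit the mixed model by maximizing the profiled marginal likelihood.

    ``fixed`` lists fixed-effect terms by column name; the class column
    expands to treatment-coded dummies and ':' builds interactions.  The
    random slope is on the increment index centered at ``slope_center``.
    Uses a Nelder-Mead search over (log variance ratios, atanh phi).
    """
    levels = (
        _class_levels(data[class_col])
        if class_col is not None and class_col in data.columns
        else []
    )
    X, names = _build_design(data, fixed, class_col, levels or None)
    y = data[response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    groups = data[group_col].to_numpy()
    z = data[increment_col].to_numpy(float) - slope_center
    blocks = _Blocks(X, y, groups, z)
    n_groups = len(pd.unique(data[group_col]))
    if ar1 and pd.Series(groups).value_counts().min() < 2:
        raise ValueError("AR1 errors need >=2 observations per fish")

    n_theta = 1 + int(random_slope) + int(ar1)
    if start is None:
        start = np.zeros(n_theta)
        start[0] = np.log(0.5)
        if random_slope:
            start[1] = np.log(0.01)

    def obj(theta: np.ndarray) -> float:
        return _profiled_nll(theta, blocks, random_slope, ar1, reml)[0]

    res = optimize.minimize(
        obj,
        start,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-7, "fatol": 1e-9},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"mixed-model fit failed to converge: {res.message}")
    nll, beta, sigma2, XtWiX = _profiled_nll(res.x, blocks, random_slope, ar1, reml)
    k = 0
    g_int = float(np.exp(res.x[k])); k += 1
    g_slope = 0.0
    if random_slope:
        g_slope = float(np.exp(res.x[k])); k += 1
    phi = float(np.tanh(res.x[k])) if ar1 else 0.0

    cov = sigma2 * np.linalg.inv(XtWiX)
    bse = np.sqrt(np.diag(cov))
    tvals = beta / bse
    df_vals = _term_dfs(X, groups, n_groups)
    pvals = 2 * stats.t.sf(np.abs(tvals), df_vals)

    n_params = len(beta) + n_theta + 1
    loglik = -nll
    aic = 2 * n_params - 2 * loglik

    var_f = float(np.var(X @ beta))
    var_r = sigma2 * (g_int + g_slope * float(np.mean(z**2)))
    var_e = sigma2  # AR1 correlation has unit marginal variance
    r2m = var_f / (var_f + var_r + var_e)
    r2c = (var_f + var_r) / (var_f + var_r + var_e)

    idx = pd.Index(names)
    return ModelFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(bse, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        df=pd.Series(df_vals, index=idx),
        sigma2=float(sigma2),
        var_intercept=g_int * sigma2,
        var_slope=g_slope * sigma2,
        ar1_phi=phi,
        loglik=float(loglik),
        aic=float(aic),
        n_params=n_params,
        r2_marginal=float(r2m),
        r2_conditional=float(r2c),
        converged=bool(res.success),
        method="REML" if reml else "ML",
        fixed=list(fixed),
        response=response,
        group_col=group_col,
        class_col=class_col,
        class_levels=levels,
        slope_center=slope_center,
        random_slope=random_slope,
        ar1=ar1,
        n_obs=len(y),
        n_groups=n_groups,
        cov_params=cov,
    )


def _term_dfs(X: np.ndarray, groups: np.ndarray, n_groups: int) -> np.ndarray:
    """Residual-style df: columns constant within fish get group-level df,
    others observation-level df (coefficient-table approximation)."""
    N, p = X.shape
    order = np.argsort(groups, kind="stable")
    gs = groups[order]
    bounds = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1], True])
    between = np.empty(p, bool)
    for j in range(p):
        col = X[order, j]
        between[j] = all(
            np.ptp(col[a:b]) < 1e-12 for a, b in zip(bounds[:-1], bounds[1:])
        )
    n_between = int(between.sum())
    dfs = np.where(between, n_groups - n_between, N - p)
    return np.maximum(dfs, 1)


# ---------------------------------------------------------------------------
# model selection


def select_model(
    data: pd.DataFrame,
    response: str,
    global_fixed: list[str],
    group_col: str = "fish_id",
    increment_col: str = "increment_index",
    class_col: str | None = "class",
    max_candidates: int = 64,
    reml_refit: bool = True,
    **fit_kwargs,
) -> tuple[ModelFit, pd.DataFrame]:
    """Three-step AIC selection: random structure, fixed-effect subsets,
    then error structure; ML for all comparisons, REML refit of the
    winner.  Non-convergent candidates are logged in the ladder and
    excluded; AIC ties go to the simpler model.
    """
    rows: list[dict] = []

    def try_fit(step, fixed, random_slope, ar1):
        try:
            f = fit_lmm(
                data, response, list(fixed),
                group_col=group_col, increment_col=increment_col,
                class_col=class_col, random_slope=random_slope,
                ar1=ar1, reml=False, **fit_kwargs,
            )
            rows.append({"step": step, "fixed": "+".join(fixed) or "(intercept)",
                         "random_slope": random_slope, "ar1": ar1,
                         "aic": f.aic, "status": "ok"})
            return f
        except Exception as exc:  # noqa: BLE001 - candidates may fail freely
            rows.append({"step": step, "fixed": "+".join(fixed) or "(intercept)",
                         "random_slope": random_slope, "ar1": ar1,
                         "aic": np.nan, "status": f"failed: {exc}"})
            return None

    # step 1: random structure under the global fixed effects
    fits1 = [
        (f.aic, int(rs), rs, f)
        for rs in (False, True)
        if (f := try_fit(1, global_fixed, rs, False)) is not None
    ]
    if not fits1:
        raise RuntimeError("no random-structure candidate converged")
    fits1.sort(key=lambda t: (round(t[0], 6), t[1]))
    best_rs = fits1[0][2]

    # step 2: all fixed-effect subsets (intercept always retained)
    subsets: list[tuple[str, ...]] = []
    for r in range(len(global_fixed) + 1):
        subsets.extend(itertools.combinations(global_fixed, r))
    if len(subsets) > max_candidates:
        subsets = subsets[-max_candidates:]
    fits2 = [
        (f.aic, len(sub), sub, f)
        for sub in subsets
        if (f := try_fit(2, sub, best_rs, False)) is not None
    ]
    fits2.sort(key=lambda t: (round(t[0], 6), t[1]))
    best_fixed = list(fits2[0][2])

    # step 3: error structure
    fits3 = [
        (f.aic, int(ar), ar, f)
        for ar in (False, True)
        if (f := try_fit(3, best_fixed, best_rs, ar)) is not None
    ]
    fits3.sort(key=lambda t: (round(t[0], 6), t[1]))
    best_ar, best = fits3[0][2], fits3[0][3]

    if reml_refit:
        best = fit_lmm(
            data, response, best_fixed,
            group_col=group_col, increment_col=increment_col,
            class_col=class_col, random_slope=best_rs, ar1=best_ar,
            reml=True, **fit_kwargs,
        )
    return best, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marginal means


def marginal_means(
    fit: ModelFit,
    data: pd.DataFrame,
    focal: dict[str, list],
    back_transform: bool = True,
) -> pd.DataFrame:
    """Model predictions over a focal grid with non-focal continuous
    covariates held at their data means and non-focal class levels
    averaged with equal weight; exponentiated back to the response scale
    for a log-transformed response.
    """
    base_terms: set[str] = set()
    for term in fit.fixed:
        base_terms.update(term.split(":"))
    for name in focal:
        if name not in base_terms:
            raise ValueError(f"focal term {name!r} not in the fitted model")

    class_col = fit.class_col
    class_in_model = class_col is not None and class_col in base_terms
    levels = fit.class_levels or (
        _class_levels(data[class_col]) if class_in_model else []
    )
    grid = [dict(zip(focal, combo)) for combo in itertools.product(*focal.values())]
    records = []
    for cell in grid:
        avg_levels = (
            [cell[class_col]] if class_in_model and class_col in cell
            else (levels if class_in_model else [None])
        )
        rows = []
        for lev in avg_levels:
            row = {}
            for t in base_terms:
                if class_in_model and t == class_col:
                    row[t] = lev
                elif t in cell:
                    row[t] = cell[t]
                else:
                    row[t] = float(np.mean(data[t].to_numpy(float)))
            rows.append(row)
        frame = pd.DataFrame(rows)
        X, names = _build_design(
            frame, fit.fixed, class_col if class_in_model else None, levels or None
        )
        assert names == list(fit.params.index), "design misalignment"
        xbar = np.mean(X, axis=0)
        eta = float(xbar @ fit.params.to_numpy())
        se = float(np.sqrt(xbar @ fit.cov_params @ xbar))
        rec = dict(cell)
        rec["linear_predictor"] = eta
        rec["se"] = se
        if back_transform:
            rec["mean"] = float(np.exp(eta))
            rec["lower"] = float(np.exp(eta - 1.96 * se))
            rec["upper"] = float(np.exp(eta + 1.96 * se))
        else:
            rec["mean"] = eta
            rec["lower"] = eta - 1.96 * se
            rec["upper"] = eta + 1.96 * se
        records.append(rec)
    return pd.DataFrame(records)
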