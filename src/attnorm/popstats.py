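"""Population-level statistics over pair-index tables.

Centres on the interaction regression

    attention_modulation = selectivity*b1 + suppression*b2
                           + selectivity*suppression*b3 + error

whose interaction term b3 captures the central claim that selectivity and
stimulus-induced suppression jointly, not additively, control attention
modulation.  Supporting tools: slope comparisons across receptive-field
configurations, a Bayes factor asking whether configuration adds anything
to the regression, sign-flip permutation tests, and the binned summaries
behind the population figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import integrate

INDEX_COLS = ["selectivity", "suppression", "attention_modulation"]


def _clean(table: pd.DataFrame, cols=INDEX_COLS, require_included=True) -> pd.DataFrame:
    df = table.copy()
    if require_included and "pair_included" in df.columns:
        df = df[df["pair_included"]]
    return df.dropna(subset=list(cols))


@dataclass
class RegressionResult:
    """Coefficients and tests of the interaction regression."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    n: int
    r_squared: float
    model: object  # fitted statsmodels results, for diagnostics

    def __getitem__(self, term: str) -> float:
        return float(self.params[term])


_FORMULA = "attention_modulation ~ selectivity + suppression + selectivity:suppression"


def interaction_regression(
    table: pd.DataFrame, include_intercept: bool = True
) -> RegressionResult:
    """OLS of attention modulation on selectivity, suppression and their product.

    With the product term present, the suppression main effect is the
    contribution of suppression at zero selectivity (and vice versa).  The
    intercept is optional: the canonical written model has none, but an
    intercept guards against mean offsets and is the default.
    """
    df = _clean(table)
    if len(df) < 10:
        raise ValueError("need at least 10 rows with finite indices")
    formula = _FORMULA if include_intercept else _FORMULA + " - 1"
    res = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        bad = ", ".join(res.model.exog_names)
        raise ValueError(f"rank-deficient design (collinear columns among: {bad})")
    return RegressionResult(
        params=res.params, bse=res.bse, tvalues=res.tvalues, pvalues=res.pvalues,
        conf_int=res.conf_int(), n=int(res.nobs), r_squared=res.rsquared, model=res,
    )


def compare_slopes(
    table: pd.DataFrame,
    group: str = "rf_configuration",
    include_intercept: bool = True,
    terms: str = "all",
) -> tuple[float, object]:
    """Test whether the regression differs across receptive-field configurations.

    Fits the interaction regression with all terms crossed by the group
    factor.  ``terms='all'`` returns the joint F-test p over every
    group-involving term; ``terms='three_way'`` the p of the
    group x selectivity x suppression coefficient alone.  A large p says
    one set of coefficients serves both configurations.  Also returns the
    fitted model.
    """
    df = _clean(table, INDEX_COLS + [group])
    levels = df[group].unique()
    if len(levels) < 2:
        raise ValueError("both receptive-field configurations must be present")
    base = "selectivity + suppression + selectivity:suppression"
    formula = f"attention_modulation ~ ({base}) * C({group})"
    if not include_intercept:
        formula += " - 1"
    res = smf.ols(formula, data=df).fit()
    group_terms = [name for name in res.params.index if group in name]
    if not group_terms:
        raise ValueError("no group terms in the design")
    if terms == "three_way":
        sel = [t for t in group_terms if "selectivity" in t and "suppression" in t]
        if len(df[group].unique()) == 2 and len(sel) == 1:
            return float(res.pvalues[sel[0]]), res
        ftest = res.f_test([f"{t} = 0" for t in sel])
        return float(ftest.pvalue), res
    if terms != "all":
        raise ValueError("terms must be 'all' or 'three_way'")
    ftest = res.f_test([f"{t} = 0" for t in group_terms])
    return float(ftest.pvalue), res


def _jzs_log_bf_vs_null(r2: float, n: int, p: int, r_scale: float) -> float:
    """Log JZS Bayes factor of a linear model against the intercept-only null.

    Zellner-Siow mixture of g-priors: BF = integral over g of
    (1+g)^((n-1-p)/2) (1+g(1-R^2))^(-(n-1)/2) pi(g) dg with pi(g) the
    scaled inverse-chi^2 density induced by a Cauchy(r_scale) prior.
    Computed in log space (the integrand peak can overflow at large n R^2).
    """
    if p == 0:
        return 0.0
    a = n * r_scale**2 / 2.0

    def log_f(g):
        return (
            (n - 1 - p) / 2.0 * np.log1p(g)
            - (n - 1) / 2.0 * np.log1p(g * (1.0 - r2))
            + 0.5 * np.log(a / np.pi)
            - 1.5 * np.log(g)
            - a / g
        )

    grid = np.logspace(-8, 10, 600)
    peak = float(np.max(log_f(grid)))

    def scaled(g):
        return np.exp(log_f(g) - peak)

    val, _ = integrate.quad(scaled, 0, np.inf, limit=400)
    return peak + float(np.log(max(val, 1e-300)))


def _design_matrices(table: pd.DataFrame, group: str):
    df = _clean(table, INDEX_COLS + [group]).reset_index(drop=True)
    y = df["attention_modulation"].to_numpy()
    base = df[["selectivity", "suppression"]].copy()
    base["interaction"] = base["selectivity"] * base["suppression"]
    g = pd.get_dummies(df[group], drop_first=True).astype(float)
    with_cfg = base.copy()
    for col in g.columns:
        with_cfg[f"cfg_{col}"] = g[col]
        for b in ["selectivity", "suppression", "interaction"]:
            with_cfg[f"cfg_{col}:{b}"] = g[col] * base[b]
    return y, base.to_numpy(), with_cfg.to_numpy()


def bayes_factor_config(
    table: pd.DataFrame,
    group: str = "rf_configuration",
    method: str = "jzs",
    r_scale: float = float(np.sqrt(2) / 4),
) -> float:
    """Bayes factor for dropping receptive-field configuration from the regression.

    Compares the marginal likelihood of the interaction regression without
    the configuration factor to the model with configuration (main effect
    plus all interactions).  BF > 1 favours the configuration-free model,
    i.e. one common rule across cRF and surround.  ``method='jzs'`` uses a
    default-prior g-prior Bayes factor; ``method='bic'`` the BIC
    approximation exp((BIC_config - BIC_free)/2).
    """
    y, X_free, X_cfg = _design_matrices(table, group)
    n = len(y)
    if n <= X_cfg.shape[1] + 2:
        raise ValueError("degenerate design: too few rows")
    if method == "bic":
        bics = []
        for X in (X_free, X_cfg):
            bics.append(sm.OLS(y, sm.add_constant(X)).fit().bic)
        return float(np.exp((bics[1] - bics[0]) / 2.0))
    if method != "jzs":
        raise ValueError(f"unknown method {method!r}")
    log_bfs = []
    for X in (X_free, X_cfg):
        res = sm.OLS(y, sm.add_constant(X)).fit()
        log_bfs.append(_jzs_log_bf_vs_null(res.rsquared, n, X.shape[1], r_scale))
    return float(np.exp(log_bfs[0] - log_bfs[1]))


def _t_stat(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        m = d.mean()
        return 0.0 if m == 0 else np.inf * np.sign(m)
    return d.mean() / (sd / np.sqrt(len(d)))


def paired_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> float:
    """Two-sided paired permutation t-test by sign-flipping the differences.

    When 2^n <= n_perm all sign assignments are enumerated and the p value
    is exact; otherwise ``n_perm`` random flips are drawn and the add-one
    corrected estimate (b+1)/(m+1) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d arrays (n >= 2)")
    d = x - y
    if np.all(d == 0):
        return 1.0
    t_obs = abs(_t_stat(d))
    n = len(d)
    tol = 1e-12
    if 2**n <= n_perm:
        codes = np.arange(2**n)
        signs = ((codes[:, None] >> np.arange(n)) & 1) * 2.0 - 1.0
        flipped = signs * d
        m = flipped.mean(axis=1)
        sd = flipped.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.abs(np.where(sd > 0, m / (sd / np.sqrt(n)),
                                     np.where(m == 0, 0.0, np.inf)))
        return float(np.mean(t_perm >= t_obs - tol))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        flipped = d * rng.choice([-1.0, 1.0], size=n)
        if abs(_t_stat(flipped)) >= t_obs - tol:
            hits += 1
    return float((hits + 1) / (n_perm + 1))


def one_sample_permutation_test(
    x: np.ndarray, n_perm: int = 10_000, seed: int | None = 0
) -> float:
    """Permutation t-test of a mean against zero (sign-flip null)."""
    x = np.asarray(x, dtype=float)
    return paired_permutation_test(x, np.zeros_like(x), n_perm=n_perm, seed=seed)


@dataclass
class BinnedCurve:
    """Per-bin mean +/- SEM summary of y against x."""

    bin_centers: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": self.bin_centers, "mean": self.mean,
             "sem": self.sem, "count": self.count}
        )


def binned_summary(x, y, bins=10) -> BinnedCurve:
    """Mean, SEM and count of y in bins of x; empty bins are omitted."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    edges = np.histogram_bin_edges(x, bins=bins)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    centers, means, sems, counts = [], [], [], []
    for b in range(len(edges) - 1):
        sel = y[idx == b]
        if len(sel) == 0:
            continue
        centers.append((edges[b] + edges[b + 1]) / 2)
        means.append(sel.mean())
        sems.append(sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else 0.0)
        counts.append(len(sel))
    return BinnedCurve(np.array(centers), np.array(means), np.array(sems),
                       np.array(counts, dtype=int))


def alpha_L_vs_distance(
    fit_results: list,
    geometries: list,
    design,
    metric: str = "degrees",
    bins=4,
) -> tuple[BinnedCurve, BinnedCurve]:
    """Normalized suppressive (alpha) and excitatory (L) drive vs distance.

    For every fitted neuron, the three locations' alpha values and
    orientation-averaged L values are normalized by their per-neuron
    maxima, paired with the distance of each location from the fitted
    receptive-field center (``metric='degrees'`` or ``'mahalanobis'``), and
    pooled across neurons into binned curves (alpha curve, L curve).
    Neurons whose geometry fit failed are skipped.
    """
    if metric not in ("degrees", "mahalanobis"):
        raise ValueError("metric must be 'degrees' or 'mahalanobis'")
    dist_all, a_all, l_all = [], [], []
    for fr, geo in zip(fit_results, geometries):
        if geo is None or getattr(geo, "fit_failed", False):
            continue
        p = fr.params
        alpha = p.alpha
        l_mean = p.L.mean(axis=1)
        if alpha.max() <= 0 or l_mean.max() <= 0:
            continue
        for i, loc in enumerate(sorted(design.locations)):
            xy = design.location_xy(loc)
            if metric == "degrees":
                dist = float(np.linalg.norm(xy - geo.center))
            else:
                dist = geo.mahalanobis(xy)
            dist_all.append(dist)
            a_all.append(alpha[i] / alpha.max())
            l_all.append(l_mean[i] / l_mean.max())
    edges = np.histogram_bin_edges(np.asarray(dist_all, dtype=float), bins=bins)
    return (
        binned_summary(dist_all, a_all, bins=edges),
        binned_summary(dist_all, l_all, bins=edges),
    )


def attention_surface(
    table: pd.DataFrame,
    grid_size: int = 25,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed mean attention modulation over (suppression, selectivity).

    A Gaussian-kernel local mean (Nadaraya-Watson) on a regular grid — a
    smooth gridded interpolant standing in for figure-rendering smoothers.
    Returns (suppression grid, selectivity grid, surface).
    """
    df = _clean(table)
    if len(df) < 50:
        raise ValueError("need at least 50 index points for a surface")
    x = df["suppression"].to_numpy()
    y = df["selectivity"].to_numpy()
    z = df["attention_modulation"].to_numpy()
    if bandwidth is None:
        bandwidth = 0.15 * max(np.ptp(x), np.ptp(y), 1e-6)
    gx = np.linspace(x.min(), x.max(), grid_size)
    gy = np.linspace(y.min(), y.max(), grid_size)
    GX, GY = np.meshgrid(gx, gy)
    dx = (GX.ravel()[:, None] - x[None, :]) / bandwidth
    dy = (GY.ravel()[:, None] - y[None, :]) / bandwidth
    w = np.exp(-0.5 * (dx**2 + dy**2))
    surf = (w @ z) / np.maximum(w.sum(axis=1), 1e-300)
    return GX, GY, surf.reshape(GX.shape)
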