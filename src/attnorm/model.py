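"""Spatially-tuned divisive normalization model of attention.

The response of a neuron to a set of Gabor stimuli is modelled as pooled
excitatory drive divided by pooled suppressive drive plus a semisaturation
constant.  For a pair at locations 1 and 2 with attention away::

    R_12 = (L_1 + L_2) / (alpha_1 + alpha_2 + sigma)

Each stimulated receptive-field location i contributes an excitatory drive
``L_ij`` (dependent on the orientation j shown there) to the numerator and a
location-specific, orientation-independent suppressive weight ``alpha_i`` to
the denominator — the "spatial tuning" of normalization.  Directing
attention to a location multiplies both its L and its alpha by a single gain
``beta`` (attend location 1: ``(beta L_1 + L_2) / (beta alpha_1 + alpha_2 +
sigma)``); attention away means ``beta = 1``.  ``alpha_1`` is fixed at 1 to
set the scale, and every parameter is constrained nonnegative.

Fitting minimises the sum of squared errors between per-condition mean
spike counts and model predictions with a Nelder-Mead simplex in an
absolute-value reparameterised space (which enforces nonnegativity while
keeping the simplex family).  Goodness of fit is the squared Pearson
correlation between predictions and held-out condition means under
two-fold cross-validation repeated five times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .task import AWAY, Condition

N_LOCATIONS = 3
N_ORIENTATIONS = 2

VARIANTS = ("full", "fixed_beta", "fixed_alpha", "no_sigma", "single_L")


@dataclass
class ModelParams:
    """Parameter set of the spatially-tuned normalization model.

    ``L`` is a (3, 2) array of excitatory drives (expected spike counts per
    window) for location i, orientation j; ``alpha2``/``alpha3`` are the
    suppressive weights of locations 2 and 3 relative to location 1 (whose
    weight is fixed at 1); ``sigma`` is the baseline (semisaturation)
    suppression; ``beta`` the multiplicative attention gain.
    """

    L: np.ndarray
    alpha2: float = 1.0
    alpha3: float = 1.0
    sigma: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (N_LOCATIONS, N_ORIENTATIONS):
            raise ValueError("L must have shape (3, 2)")
        if np.any(self.L < 0) or min(self.alpha2, self.alpha3) < 0:
            raise ValueError("L and alpha must be nonnegative")
        if self.sigma < 0 or self.beta < 0:
            raise ValueError("sigma and beta must be nonnegative")

    @property
    def alpha(self) -> np.ndarray:
        """Suppressive weights per location, alpha_1 fixed at 1."""
        return np.array([1.0, self.alpha2, self.alpha3])

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.L.ravel(), [self.alpha2, self.alpha3, self.sigma, self.beta]])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ModelParams":
        v = np.asarray(v, dtype=float)
        return cls(L=v[:6].reshape(3, 2), alpha2=v[6], alpha3=v[7], sigma=v[8], beta=v[9])


def response(
    L: np.ndarray,
    alpha: np.ndarray,
    sigma: float,
    beta: float,
    stimuli: tuple[tuple[int, int], ...],
    attention: int | str,
) -> float:
    """Evaluate the normalization equation for one condition.

    Blank presentations return 0 (the model has no spontaneous-rate term).
    Attention to an unstimulated location has no effect because only
    stimulated locations contribute drive.
    """
    if len(stimuli) == 0:
        return 0.0
    num = 0.0
    den = float(sigma)
    for loc, ori in stimuli:
        gain = beta if attention == loc else 1.0
        num += gain * L[loc - 1, ori - 1]
        den += gain * alpha[loc - 1]
    if den <= 0:
        return np.inf if num > 0 else 0.0
    return num / den


def predict(params: ModelParams, condition: Condition) -> float:
    """Model-predicted mean spike count for one condition."""
    return response(
        params.L, params.alpha, params.sigma, params.beta,
        condition.stimuli, condition.attention,
    )


class ConditionDesign:
    """Precomputed index matrices for vectorised prediction over conditions.

    For C conditions and the 6 L-parameters / 3 alpha-parameters, stores
    membership masks and attended-parameter masks so that predictions for a
    full parameter vector are two matrix products.
    """

    def __init__(self, conditions: list[Condition]):
        self.conditions = list(conditions)
        C = len(self.conditions)
        self.W_L = np.zeros((C, 6))
        self.A_L = np.zeros((C, 6), dtype=bool)
        self.W_a = np.zeros((C, 3))
        self.A_a = np.zeros((C, 3), dtype=bool)
        for c, cond in enumerate(self.conditions):
            for loc, ori in cond.stimuli:
                k = (loc - 1) * 2 + (ori - 1)
                self.W_L[c, k] = 1.0
                self.W_a[c, loc - 1] = 1.0
                if cond.attention == loc:
                    self.A_L[c, k] = True
                    self.A_a[c, loc - 1] = True
        self.is_blank = np.array([c.is_blank for c in self.conditions])

    def predict_vector(self, params: ModelParams) -> np.ndarray:
        Lv = params.L.ravel()
        av = params.alpha
        b = params.beta
        num = (self.W_L * np.where(self.A_L, b, 1.0)) @ Lv
        den = (self.W_a * np.where(self.A_a, b, 1.0)) @ av + params.sigma
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        out[self.is_blank] = 0.0
        return out


@dataclass
class FitResult:
    """Outcome of one least-squares model fit."""

    params: ModelParams
    sse: float
    variant: str
    n_free: int
    converged: bool
    n_restarts: int
    n_iterations: int
    cv_explained_variance: float | None = None
    notes: dict = field(default_factory=dict)


def _variant_pack(variant: str, fixed_beta_value: float | None):
    """Free-parameter layout per model variant.

    Returns (n_free, unpack) where unpack maps a free vector (already made
    nonnegative) to a ModelParams.
    """
    if variant == "full":
        return 10, lambda v: ModelParams.from_vector(v)
    if variant == "fixed_beta":
        if fixed_beta_value is None:
            raise ValueError("fixed_beta variant requires fixed_beta_value")
        b = float(fixed_beta_value)
        return 9, lambda v: ModelParams(
            L=v[:6].reshape(3, 2), alpha2=v[6], alpha3=v[7], sigma=v[8], beta=b
        )
    if variant == "fixed_alpha":
        return 8, lambda v: ModelParams(
            L=v[:6].reshape(3, 2), alpha2=1.0, alpha3=1.0, sigma=v[6], beta=v[7]
        )
    if variant == "no_sigma":
        return 9, lambda v: ModelParams(
            L=v[:6].reshape(3, 2), alpha2=v[6], alpha3=v[7], sigma=0.0, beta=v[8]
        )
    if variant == "single_L":
        return 5, lambda v: ModelParams(
            L=np.full((3, 2), v[0]), alpha2=v[1], alpha3=v[2], sigma=v[3], beta=v[4]
        )
    raise ValueError(f"unknown variant {variant!r}")


def _initial_free(variant: str, conditions: list[Condition], y: np.ndarray) -> np.ndarray:
    """Data-informed starting point: L from single-stimulus attend-away means."""
    sigma0 = 0.1
    L0 = np.full((3, 2), np.nan)
    for cond, obs in zip(conditions, y):
        if len(cond.stimuli) == 1 and cond.attention == AWAY:
            (loc, ori), = cond.stimuli
            L0[loc - 1, ori - 1] = obs * (1.0 + sigma0)
    fallback = np.nanmean(L0) if np.any(np.isfinite(L0)) else max(float(np.mean(y)), 0.1)
    L0 = np.where(np.isfinite(L0), L0, fallback)
    L0 = np.maximum(L0, 1e-3)
    if variant == "full":
        return np.concatenate([L0.ravel(), [1.0, 1.0, sigma0, 1.0]])
    if variant == "fixed_beta":
        return np.concatenate([L0.ravel(), [1.0, 1.0, sigma0]])
    if variant == "fixed_alpha":
        return np.concatenate([L0.ravel(), [sigma0, 1.0]])
    if variant == "no_sigma":
        return np.concatenate([L0.ravel(), [1.0, 1.0, 1.0]])
    if variant == "single_L":
        return np.array([float(np.mean(L0)), 1.0, 1.0, sigma0, 1.0])
    raise ValueError(variant)


def fit(
    mean_responses: np.ndarray,
    conditions: list[Condition],
    variant: str = "full",
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = 0,
    fixed_beta_value: float | None = None,
    maxfev: int = 50_000,
) -> FitResult:
    """Fit the normalization model to per-condition mean spike counts.

    Parameters are constrained nonnegative by optimising in an
    absolute-value-transformed space with a Nelder-Mead simplex; the best of
    ``n_restarts`` jittered starts (by SSE) is returned, each polished by
    restarting the simplex from its own solution until the SSE improvement
    is below 1e-12 (at most three rounds).

    Variants: ``full`` (10 free parameters); ``fixed_beta`` (beta clamped to
    ``fixed_beta_value``, e.g. a population mean); ``fixed_alpha`` (alpha_2 =
    alpha_3 = 1, removing spatial tuning); ``no_sigma`` (sigma = 0);
    ``single_L`` (one shared excitatory drive for all stimuli).
    """
    y = np.asarray(mean_responses, dtype=float)
    if y.shape != (len(conditions),):
        raise ValueError("mean_responses length must match conditions")
    if not np.all(np.isfinite(y)):
        raise ValueError("mean responses must be finite")
    n_free, unpack = _variant_pack(variant, fixed_beta_value)
    if len(conditions) < n_free:
        raise ValueError("need at least as many conditions as free parameters")
    design = ConditionDesign(conditions)
    rng = np.random.default_rng(seed)

    # raw objective avoiding per-evaluation ModelParams construction
    W_L, A_L, W_a, A_a = design.W_L, design.A_L, design.W_a, design.A_a
    blank = design.is_blank

    def raw_unpack(free: np.ndarray):
        if variant == "full":
            return free[:6], free[6], free[7], free[8], free[9]
        if variant == "fixed_beta":
            return free[:6], free[6], free[7], free[8], fixed_beta_value
        if variant == "fixed_alpha":
            return free[:6], 1.0, 1.0, free[6], free[7]
        if variant == "no_sigma":
            return free[:6], free[6], free[7], 0.0, free[8]
        return np.repeat(free[0], 6), free[1], free[2], free[3], free[4]

    def sse_of(free: np.ndarray) -> float:
        Lv, a2, a3, sg, b = raw_unpack(np.abs(free))
        av = np.array([1.0, a2, a3])
        num = (W_L * np.where(A_L, b, 1.0)) @ Lv
        den = (W_a * np.where(A_a, b, 1.0)) @ av + sg
        with np.errstate(divide="ignore", invalid="ignore"):
            pred = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        pred[blank] = 0.0
        r = pred - y
        return float(r @ r)

    x0 = _initial_free(variant, conditions, y)
    best: tuple[float, np.ndarray] | None = None
    total_iter = 0
    any_converged = False
    for k in range(max(n_restarts, 1)):
        start = x0 if k == 0 else x0 * rng.lognormal(0.0, 0.25, size=x0.shape)
        prev = np.inf
        x = start
        converged = False
        for _ in range(3):  # polish loop: simplex restarted from incumbent
            # stop on relative SSE change < 1e-9 (fatol is absolute in scipy)
            fatol = max(1e-9 * sse_of(x), 1e-12)
            res = optimize.minimize(
                sse_of, x, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": fatol, "maxfev": maxfev,
                         "maxiter": maxfev},
            )
            total_iter += res.nit
            x = res.x
            converged = converged or bool(res.success)
            if prev - res.fun < 1e-12:
                break
            prev = res.fun
        val = sse_of(x)
        any_converged = any_converged or converged
        if best is None or val < best[0]:
            best = (val, x)
    sse, xbest = best
    params = unpack(np.abs(xbest))
    result = FitResult(
        params=params,
        sse=sse,
        variant=variant,
        n_free=n_free,
        converged=any_converged,
        n_restarts=max(n_restarts, 1),
        n_iterations=total_iter,
    )
    if variant != "fixed_beta":
        # a gain wandering to non-physical magnitude signals a flat SSE
        # direction: beta is not identified by this neuron's responses
        result.notes["beta_identified"] = bool(0.02 <= params.beta <= 50.0)
    return result


def explained_variance(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Squared Pearson correlation between predictions and observations.

    Returns NaN when either vector is constant (correlation undefined).
    Note the deliberate asymmetry with SSE: a prediction that is a linear
    transform of the observations scores 1 even if offset or inverted.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("need >= 3 paired conditions")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        return np.nan
    r = np.corrcoef(predicted, observed)[0, 1]
    return float(r * r)


def _split_half_means(
    trials: pd.DataFrame, conditions: list[Condition], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[Condition]]:
    """Random within-condition half-split; returns fold means and the kept conditions."""
    kept, m1, m2 = [], [], []
    by_cond = trials.groupby("condition_id")["count"]
    groups = {cid: g.to_numpy() for cid, g in by_cond}
    for cond in conditions:
        counts = groups.get(cond.condition_id)
        if counts is None or len(counts) < 2:
            continue
        perm = rng.permutation(len(counts))
        half = len(counts) // 2
        a, b = counts[perm[:half]], counts[perm[half:]]
        kept.append(cond)
        m1.append(a.mean())
        m2.append(b.mean())
    return np.array(m1), np.array(m2), kept


def cross_validate(
    trials: pd.DataFrame,
    conditions: list[Condition],
    variant: str = "full",
    n_repeats: int = 5,
    seed: int | None = 0,
    n_restarts: int = 3,
    fixed_beta_value: float | None = None,
) -> FitResult:
    """Two-fold cross-validated explained variance, averaged over repeats.

    Each repeat randomly halves the trials within every condition, fits the
    model to one half's condition means and scores the squared correlation
    against the held-out half's means; both fold directions are scored, and
    the mean over ``n_repeats`` x 2 folds is reported.  The returned
    ``FitResult`` carries the fit to all trials plus ``cv_explained_variance``.
    """
    rng = np.random.default_rng(seed)
    fittable = [c for c in conditions if not c.is_blank]
    evs = []
    n_skipped = 0
    for _ in range(n_repeats):
        mA, mB, kept = _split_half_means(trials, fittable, rng)
        n_skipped = len(fittable) - len(kept)
        for train, test in ((mA, mB), (mB, mA)):
            fr = fit(
                train, kept, variant=variant, n_restarts=n_restarts,
                seed=int(rng.integers(2**31)), fixed_beta_value=fixed_beta_value,
            )
            des = ConditionDesign(kept)
            evs.append(explained_variance(des.predict_vector(fr.params), test))
    full_means = (
        trials.groupby("condition_id")["count"].mean()
        .reindex([c.condition_id for c in fittable])
    )
    ok = full_means.notna().to_numpy()
    kept_all = [c for c, keep in zip(fittable, ok) if keep]
    final = fit(
        full_means.to_numpy()[ok], kept_all, variant=variant,
        n_restarts=n_restarts, seed=int(rng.integers(2**31)),
        fixed_beta_value=fixed_beta_value,
    )
    final.cv_explained_variance = float(np.nanmean(evs))
    final.notes["n_conditions_skipped"] = n_skipped
    return final


@dataclass
class FTestResult:
    f: float
    p: float
    df_num: int
    df_den: int
    flagged: bool = False


def nested_f_test(full: FitResult, reduced: FitResult, n_conditions: int) -> FTestResult:
    """Sequential F-test between a model and a nested constrained variant."""
    if reduced.n_free >= full.n_free:
        raise ValueError("reduced model must have fewer free parameters")
    df_num = full.n_free - reduced.n_free
    df_den = n_conditions - full.n_free
    if df_den <= 0:
        raise ValueError("not enough conditions for the F-test")
    flagged = reduced.sse < full.sse - 1e-10  # optimizer failure on the full model
    num = max(reduced.sse - full.sse, 0.0) / df_num
    den = full.sse / df_den if full.sse > 0 else np.nan
    if not np.isfinite(den) or den == 0:
        f_stat = np.inf if num > 0 else 0.0
    else:
        f_stat = num / den
    p = float(stats.f.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else 0.0
    return FTestResult(f=float(f_stat), p=p, df_num=df_num, df_den=df_den, flagged=flagged)


def suppression_index_from_params(
    params: ModelParams,
    pair: tuple[tuple[int, int], tuple[int, int]],
) -> float:
    """Closed-form stimulus-induced suppression index implied by the model.

    For a pair with preferred component (loc_P, ori_P) and non-preferred
    component (loc_N, ori_N), the index (P - PN)/(P + PN) evaluates to::

        [L_P/(a_P + s) - (L_P + L_N)/(a_P + a_N + s)]
        -----------------------------------------------
        [L_P/(a_P + s) + (L_P + L_N)/(a_P + a_N + s)]

    showing that observed suppression mixes excitatory (L) and suppressive
    (alpha) drive and is therefore distinct from alpha itself.
    """
    (loc_p, ori_p), (loc_n, ori_n) = pair
    a = params.alpha
    L_P = params.L[loc_p - 1, ori_p - 1]
    L_N = params.L[loc_n - 1, ori_n - 1]
    a_P, a_N, s = a[loc_p - 1], a[loc_n - 1], params.sigma
    if a_P + s <= 0 or a_P + a_N + s <= 0:
        return np.nan
    p_alone = L_P / (a_P + s)
    pn = (L_P + L_N) / (a_P + a_N + s)
    if p_alone + pn == 0:
        return np.nan
    return (p_alone - pn) / (p_alone + pn)


def mean_beta(fit_results: list[FitResult]) -> float:
    """Population mean attention gain, used to clamp the fixed-beta variant.

    Fits whose gain was flagged non-identified (flat SSE direction) are
    skipped; their wandering values carry no information.
    """
    vals = [
        fr.params.beta for fr in fit_results
        if fr.notes.get("beta_identified", True)
    ]
    if not vals:
        raise ValueError("no identified attention gains to average")
    return float(np.mean(vals))
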