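"""Ground-truth neuron populations and seeded Poisson trial simulation.

Neurons are parameterised directly in the normalization model's terms
(excitatory drives L, suppressive weights alpha, baseline suppression
sigma, attention gain beta) plus a planar Gaussian receptive field.  The
population priors mimic the receptive-field structure seen in visual
cortex: both excitation and suppression fall off with a stimulus
location's distance from the receptive-field center, but excitation is
more spatially concentrated — L decays on a shorter spatial scale than
alpha.  Spike counts in the analysis window are Poisson around the model
mean (plus an optional additive baseline rate, default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, response
from .rf import RFMap
from .task import AWAY, Condition, TaskDesign, blank_condition

TRIAL_COLUMNS = ["neuron_id", "condition_id", "stimuli", "attention", "trial", "count"]


@dataclass
class GroundTruthNeuron:
    """A simulated neuron with known normalization-model parameters.

    L is in expected spike counts per analysis window; alpha is
    dimensionless with alpha[0] (location 1) fixed at 1; rf_center/rf_cov
    define the planar Gaussian receptive field in visual degrees.
    ``baseline`` is an optional additive spontaneous count per window
    (default 0; the normalization model itself has no baseline term) and
    ``map_amplitude`` scales the mapping-grid response.
    """

    neuron_id: int
    L: np.ndarray
    alpha: np.ndarray
    sigma: float
    beta: float
    rf_center: np.ndarray
    rf_cov: np.ndarray
    baseline: float = 0.0
    map_amplitude: float = 10.0

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.rf_center = np.asarray(self.rf_center, dtype=float)
        self.rf_cov = np.asarray(self.rf_cov, dtype=float)
        if self.L.shape != (3, 2) or self.alpha.shape != (3,):
            raise ValueError("L must be (3,2), alpha (3,)")
        if np.any(self.L < 0) or np.any(self.alpha < 0):
            raise ValueError("drives must be nonnegative")
        if abs(self.alpha[0] - 1.0) > 1e-12:
            raise ValueError("alpha at location 1 must equal 1")
        if self.sigma < 0 or self.beta < 0 or self.baseline < 0:
            raise ValueError("sigma, beta and baseline must be nonnegative")
        if np.any(np.linalg.eigvalsh(self.rf_cov) <= 0):
            raise ValueError("rf_cov must be positive definite")

    @property
    def params(self) -> ModelParams:
        return ModelParams(
            L=self.L, alpha2=float(self.alpha[1]), alpha3=float(self.alpha[2]),
            sigma=self.sigma, beta=self.beta,
        )


def expected_count(neuron: GroundTruthNeuron, condition: Condition) -> float:
    """Model-mean spike count per window for one condition (blank -> 0)."""
    return response(
        neuron.L, neuron.alpha, neuron.sigma, neuron.beta,
        condition.stimuli, condition.attention,
    )


@dataclass
class PopulationPriors:
    """Distributional assumptions for sampling ground-truth neurons.

    ``l_scale`` and ``alpha_scale`` are the Gaussian/exponential spatial
    decay scales (degrees) of excitation and suppression; ``alpha_scale``
    must exceed ``l_scale`` so that suppression extends beyond excitation.
    ``l_peak_*`` set the log-normal peak excitatory drive (counts/window);
    ``beta_*`` the log-normal attention gain (centred near 1.5);
    ``sigma_mean`` the exponential mean of the baseline suppression, a
    small-sigma regime; ``rf_scatter`` the s.d. of receptive-field centres
    around the stimulus-array centroid; ``rf_sd_range`` the uniform range
    of receptive-field Gaussian widths (degrees).
    """

    l_peak_log_mean: float = float(np.log(12.0))
    l_peak_log_sd: float = 0.35
    l_scale: float = 1.0
    alpha_scale: float = 2.8
    l_jitter_sd: float = 0.15
    alpha_jitter_sd: float = 0.55
    ori_selectivity_a: float = 2.0
    ori_selectivity_b: float = 2.0
    beta_log_mean: float = float(np.log(1.8))
    beta_log_sd: float = 0.25
    sigma_mean: float = 0.15
    rf_scatter: float = 1.8
    rf_sd_range: tuple[float, float] = (0.8, 1.6)
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_scale <= self.l_scale:
            raise ValueError("alpha must decay more slowly than L (alpha_scale > l_scale)")
        if self.l_scale <= 0 or self.sigma_mean < 0 or self.baseline < 0:
            raise ValueError("invalid prior specification")
        lo, hi = self.rf_sd_range
        if not (0 < lo <= hi):
            raise ValueError("invalid rf_sd_range")


def sample_population(
    n_neurons: int,
    design: TaskDesign,
    priors: PopulationPriors | None = None,
    seed: int | np.random.Generator = 0,
) -> list[GroundTruthNeuron]:
    """Draw a reproducible population of ground-truth neurons.

    Excitatory drive at each stimulus location falls off as a Gaussian of
    the location's distance from the receptive-field centre with scale
    ``l_scale``; suppressive drive falls off exponentially with the longer
    scale ``alpha_scale`` and is renormalised so location 1 has weight 1.
    Because receptive-field centres scatter around the stimulus array, some
    neurons see all locations inside the classical receptive field
    (cRF-cRF pairs) while for others the flanking location is in the
    silent, purely suppressive surround (sRF-cRF pairs).
    """
    if n_neurons < 0:
        raise ValueError("n_neurons must be >= 0")
    priors = priors or PopulationPriors()
    rng = np.random.default_rng(seed)
    loc_xy = np.array([design.location_xy(l) for l in (1, 2, 3)])
    centroid = loc_xy.mean(axis=0)
    neurons = []
    for nid in range(n_neurons):
        center = centroid + rng.normal(0.0, priors.rf_scatter, size=2)
        d = np.linalg.norm(loc_xy - center, axis=1)

        l_peak = rng.lognormal(priors.l_peak_log_mean, priors.l_peak_log_sd)
        spatial = np.exp(-0.5 * (d / priors.l_scale) ** 2)
        sel = rng.beta(priors.ori_selectivity_a, priors.ori_selectivity_b)
        pref = rng.integers(2)
        ori_gain = np.ones(2)
        ori_gain[1 - pref] = 1.0 - sel
        L = (
            l_peak
            * spatial[:, None]
            * ori_gain[None, :]
            * rng.lognormal(0.0, priors.l_jitter_sd, size=(3, 2))
        )

        a_raw = np.exp(-d / priors.alpha_scale) * rng.lognormal(
            0.0, priors.alpha_jitter_sd, size=3
        )
        alpha = a_raw / a_raw[0]  # location-1 weight defines the scale

        sd = rng.uniform(*priors.rf_sd_range, size=2)
        theta = rng.uniform(0, np.pi)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        cov = R @ np.diag(sd**2) @ R.T

        neurons.append(
            GroundTruthNeuron(
                neuron_id=nid,
                L=L,
                alpha=alpha,
                sigma=float(rng.exponential(priors.sigma_mean)),
                beta=float(rng.lognormal(priors.beta_log_mean, priors.beta_log_sd)),
                rf_center=center,
                rf_cov=cov,
                baseline=priors.baseline,
                map_amplitude=float(l_peak),
            )
        )
    return neurons


def simulate_trials(
    neuron: GroundTruthNeuron,
    conditions: list[Condition],
    n_trials: int,
    seed: int | np.random.Generator = 0,
    include_blank: bool = True,
    split_away: bool = False,
) -> pd.DataFrame:
    """Poisson trial table for one neuron across conditions.

    Counts are drawn independently per trial with mean
    ``expected_count + baseline``; a blank condition (mean = baseline) is
    appended by default so inclusion tests have a reference distribution.

    ``split_away=True`` emits the attend-away trials as two equal far-locus
    replicates (``away1``/``away2``, identical means), which the
    neurometrics layer averages per locus; model fitting expects the
    pooled single-``away`` representation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    conds = list(conditions)
    if include_blank and not any(c.is_blank for c in conds):
        conds = conds + [blank_condition()]
    rows = []
    for cond in conds:
        mu = expected_count(neuron, cond) + neuron.baseline
        stim = "+".join(f"l{l}o{o}" for l, o in cond.stimuli) or "blank"
        if split_away and cond.attention == AWAY:
            labels = ["away1"] * (n_trials // 2) + ["away2"] * (n_trials - n_trials // 2)
        else:
            labels = [str(cond.attention)] * n_trials
        counts = rng.poisson(mu, size=n_trials)
        trial_idx: dict[str, int] = {}
        for lab, c in zip(labels, counts):
            t = trial_idx.get(lab, 0)
            trial_idx[lab] = t + 1
            cid = cond.condition_id if lab == str(cond.attention) else (
                f"{stim}_att{lab}"
            )
            rows.append((neuron.neuron_id, cid, stim, lab, t, int(c)))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_population_trials(
    neurons: list[GroundTruthNeuron],
    conditions: list[Condition],
    n_trials: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Concatenated trial tables for a population, one derived seed per neuron."""
    rng = np.random.default_rng(seed)
    tables = [
        simulate_trials(nrn, conditions, n_trials, seed=int(rng.integers(2**31)))
        for nrn in neurons
    ]
    if not tables:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def mapping_grid(
    azimuth: tuple[float, float] = (-1.0, 8.0),
    elevation: tuple[float, float] = (2.5, -8.0),
    n: int = 8,
) -> np.ndarray:
    """The 8x8 receptive-field mapping grid (positions in degrees), (n*n, 2)."""
    az = np.linspace(*azimuth, n)
    el = np.linspace(*elevation, n)
    A, E = np.meshgrid(az, el, indexing="xy")
    return np.column_stack([A.ravel(), E.ravel()])


def simulate_rf_map(
    neuron: GroundTruthNeuron,
    grid: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    n_trials: int = 10,
    noise: str = "poisson",
) -> RFMap:
    """Mean mapping responses on a position grid.

    The mean at each position is the neuron's planar Gaussian (peak
    ``map_amplitude`` counts) evaluated there; with ``noise='poisson'`` the
    recorded value is the mean of ``n_trials`` Poisson draws, with
    ``noise='none'`` it is exact.
    """
    grid = mapping_grid() if grid is None else np.asarray(grid, dtype=float)
    dx = grid - neuron.rf_center
    prec = np.linalg.inv(neuron.rf_cov)
    quad = np.einsum("ni,ij,nj->n", dx, prec, dx)
    mu = neuron.map_amplitude * np.exp(-0.5 * quad) + neuron.baseline
    if noise == "none":
        resp = mu
    elif noise == "poisson":
        rng = np.random.default_rng(seed)
        resp = rng.poisson(mu[:, None], size=(len(mu), n_trials)).mean(axis=1)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return RFMap(positions=grid, responses=resp)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"attention": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df
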