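"""Spike-count neurometrics: inclusion rules, cRF/surround classification,
and the selectivity / suppression / attention-modulation indices.

All quantities are computed from mean spike counts in the analysis window
(50-300 ms after stimulus onset), with attention directed away from the
receptive field unless an index explicitly contrasts attention conditions.
For each Gabor pair the component evoking the stronger response alone is
"preferred" (P) and the other "non-preferred" (N) — except that a stimulus
in the silent surround, which by definition evokes no response alone, is
always assigned N.  The three indices are

* selectivity        (P - N) / (P + N)           in [0, 1]
* suppression        (P - PN) / (P + PN)         negative when the pair
  exceeds the preferred component alone
* attention          (PattN - PNatt) / (PattN + PNatt)  positive when
  attending the preferred component raises the response

where PN is the pair response with attention away, and PattN / PNatt the
pair response with attention on the preferred / non-preferred component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .task import AWAY, Condition, TaskDesign

ALPHA_LEVEL = 0.05
PAIR_MIN_MEAN_COUNT = 1.0

CRF = "crf"
SURROUND = "surround"
UNRESPONSIVE = "unresponsive"


class MissingDataError(ValueError):
    """No trials available for a required condition."""


class UndefinedIndexError(ValueError):
    """Index denominator is zero."""


def _stim_token(stimuli: tuple[tuple[int, int], ...]) -> str:
    return "+".join(f"l{l}o{o}" for l, o in stimuli) or "blank"


def _select(trials: pd.DataFrame, stimuli, attention) -> pd.DataFrame:
    tok = _stim_token(tuple(stimuli))
    sel = trials[trials["stimuli"] == tok]
    if attention == AWAY:
        return sel[sel["attention"].str.startswith(AWAY)]
    return sel[sel["attention"] == str(attention)]


def mean_response(
    trials: pd.DataFrame,
    condition: Condition | tuple,
    attention: int | str | None = None,
) -> float:
    """Mean spike count for one condition.

    ``condition`` may be a :class:`Condition` or a tuple of stimuli with
    ``attention`` given separately.  Attend-away responses average the
    per-locus means when the table distinguishes the two far attention loci
    (``away1``/``away2``), matching the convention of averaging rather than
    pooling their trials.
    """
    if isinstance(condition, Condition):
        stimuli, attention = condition.stimuli, condition.attention
    else:
        stimuli = tuple(condition)
        if attention is None:
            raise ValueError("attention required when passing raw stimuli")
    sel = _select(trials, stimuli, attention)
    if sel.empty:
        raise MissingDataError(
            f"no trials for {_stim_token(tuple(stimuli))} / att={attention}"
        )
    if attention == AWAY:
        return float(sel.groupby("attention")["count"].mean().mean())
    return float(sel["count"].mean())


def baseline_counts(trials: pd.DataFrame) -> np.ndarray:
    """Spike counts from blank presentations (the baseline distribution)."""
    sel = trials[trials["stimuli"] == "blank"]
    if sel.empty:
        raise MissingDataError("no blank presentations for baseline")
    return sel["count"].to_numpy()


def _significantly_above(baseline: np.ndarray, counts: np.ndarray,
                         alpha: float = ALPHA_LEVEL) -> bool:
    """One-way ANOVA of stimulus vs blank counts, requiring a positive shift."""
    if len(counts) == 0:
        return False
    if np.ptp(baseline) == 0 and np.ptp(counts) == 0:
        return False  # degenerate: no variance anywhere
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.f_oneway(baseline, counts)
    return bool(np.isfinite(p) and p < alpha and counts.mean() > baseline.mean())


def _single_away_counts(trials: pd.DataFrame, loc: int, ori: int) -> np.ndarray:
    return _select(trials, ((loc, ori),), AWAY)["count"].to_numpy()


def include_neuron(trials: pd.DataFrame, design: TaskDesign,
                   alpha: float = ALPHA_LEVEL) -> bool:
    """Global inclusion: any single Gabor (attend away) drives the neuron
    significantly above the blank baseline.  Neurons only suppressed below
    baseline are excluded by the directional requirement."""
    base = baseline_counts(trials)
    for loc in sorted(design.locations):
        for ori in design.orientations:
            if _significantly_above(base, _single_away_counts(trials, loc, ori), alpha):
                return True
    return False


def classify_location(
    trials: pd.DataFrame,
    location: int,
    design: TaskDesign,
    alpha: float = ALPHA_LEVEL,
    geometry=None,
    min_surround_mahalanobis: float | None = None,
) -> str:
    """Classify a stimulus location as cRF, surround or unresponsive.

    cRF: either single Gabor at the location (attend away) drives the
    neuron significantly above baseline.  Surround: neither does, while the
    neuron passes global inclusion (i.e. responds at some other, cRF,
    location).  Optionally a stricter surround criterion additionally
    requires the location to lie more than ``min_surround_mahalanobis``
    s.d. contours from the fitted receptive-field center.
    """
    base = baseline_counts(trials)
    for ori in design.orientations:
        counts = _single_away_counts(trials, location, ori)
        if len(counts) == 0:
            raise MissingDataError(f"no single-stimulus trials at location {location}")
        if _significantly_above(base, counts, alpha):
            return CRF
    if not include_neuron(trials, design, alpha):
        return UNRESPONSIVE
    if min_surround_mahalanobis is not None:
        if geometry is None:
            raise ValueError("geometry required for the Mahalanobis surround criterion")
        dist = geometry.mahalanobis(design.location_xy(location))
        if not dist > min_surround_mahalanobis:
            return UNRESPONSIVE
    return SURROUND


def include_pair(trials: pd.DataFrame, pair_stimuli) -> bool:
    """Pair inclusion: mean attend-away response to the pair >= 1 spike/window."""
    return mean_response(trials, tuple(pair_stimuli), AWAY) >= PAIR_MIN_MEAN_COUNT


def assign_preference(
    resp_a: float,
    resp_b: float,
    keys: tuple | None = None,
    surround_component: int | None = None,
) -> tuple[int, int]:
    """Return indices (preferred, non-preferred) over components (0, 1).

    ``surround_component`` forces that component to be non-preferred (a
    surround stimulus evokes no response alone by definition, whatever its
    measured mean).  Exact ties break deterministically by the components'
    ``keys`` (e.g. (location, orientation) tuples), lower key preferred.
    """
    if surround_component is not None:
        p = 1 - surround_component
        return p, surround_component
    if resp_a > resp_b:
        return 0, 1
    if resp_b > resp_a:
        return 1, 0
    if keys is not None and keys[1] < keys[0]:
        return 1, 0
    return 0, 1


def selectivity_index(P: float, N: float) -> float:
    """(P - N)/(P + N): 0 = unselective, 1 = completely selective.

    In [0, 1] when P is assigned by the stronger mean response; mildly
    negative values can arise when a surround stimulus is force-assigned
    non-preferred yet its measured mean exceeds the cRF component's.
    """
    if min(P, N) < 0:
        raise ValueError("responses must be nonnegative")
    if P + N <= 0:
        raise UndefinedIndexError("P + N = 0")
    return (P - N) / (P + N)


def suppression_index(P: float, PN: float, N: float | None = None,
                      alternate: bool = False) -> float:
    """Stimulus-induced suppression: (P - PN)/(P + PN).

    Negative when adding the non-preferred stimulus increases the response.
    ``alternate=True`` uses (P + N - PN)/(P + N + PN), which requires N.
    """
    if alternate:
        if N is None:
            raise ValueError("alternate definition requires N")
        if P + N + PN <= 0:
            raise UndefinedIndexError("P + N + PN = 0")
        return (P + N - PN) / (P + N + PN)
    if P + PN <= 0:
        raise UndefinedIndexError("P + PN = 0")
    return (P - PN) / (P + PN)


def attention_index(P_attN: float, PN_att: float) -> float:
    """(PattN - PNatt)/(PattN + PNatt): positive when attending P helps."""
    if P_attN + PN_att <= 0:
        raise UndefinedIndexError("PattN + PNatt = 0")
    return (P_attN - PN_att) / (P_attN + PN_att)


def compute_psth(
    spike_times: list[np.ndarray] | np.ndarray,
    t_start: float = 0.0,
    t_stop: float = 0.5,
    bin_width: float = 0.001,
    smooth_sigma: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Peri-stimulus time histogram: 1 ms bins, Gaussian-smoothed (sigma 5 ms).

    ``spike_times`` is a list of per-trial spike-time arrays (seconds).
    Returns (bin centers, rate in spikes/s); smoothing preserves total area.
    """
    if isinstance(spike_times, np.ndarray) and spike_times.ndim == 1:
        spike_times = [spike_times]
    edges = np.arange(t_start, t_stop + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    n_trials = max(len(spike_times), 1)
    counts = np.zeros(len(centers))
    for st in spike_times:
        counts += np.histogram(np.asarray(st), bins=edges)[0]
    rate = counts / (n_trials * bin_width)
    if smooth_sigma > 0:
        rate = gaussian_filter1d(rate, smooth_sigma / bin_width, mode="constant")
    return centers, rate


@dataclass
class PairIndices:
    neuron_id: int
    pair_id: str
    rf_configuration: str
    selectivity: float
    suppression: float
    attention_modulation: float
    P: float
    N: float
    PN: float
    pair_included: bool


def compute_pair_indices(
    trials: pd.DataFrame,
    design: TaskDesign,
    alpha: float = ALPHA_LEVEL,
    alternate_suppression: bool = False,
) -> pd.DataFrame:
    """Index table for one neuron: one row per Gabor pair (up to 8).

    Rows carry the receptive-field configuration of the location pair
    (cRF-cRF or sRF-cRF; pairs involving an unresponsive neuron or two
    surround locations are labelled 'other' and excluded), the pair
    inclusion flag (>= 1 spike/window attend away) and the three indices.
    Undefined indices (zero denominators) propagate as NaN.
    """
    neuron_ids = trials["neuron_id"].unique()
    if len(neuron_ids) != 1:
        raise ValueError("compute_pair_indices expects a single neuron's trials")
    nid = int(neuron_ids[0])
    included = include_neuron(trials, design, alpha)
    cls = {
        loc: classify_location(trials, loc, design, alpha) if included else UNRESPONSIVE
        for loc in sorted(design.locations)
    }
    rows = []
    for loc_a, loc_b in design.location_pairs:
        for ori_a in design.orientations:
            for ori_b in design.orientations:
                comp = ((loc_a, ori_a), (loc_b, ori_b))
                pair_id = _stim_token(comp)
                ca, cb = cls[loc_a], cls[loc_b]
                if ca == CRF and cb == CRF:
                    config, sur = "crf-crf", None
                elif {ca, cb} == {CRF, SURROUND}:
                    config = "srf-crf"
                    sur = 0 if ca == SURROUND else 1
                else:
                    config, sur = "other", None
                try:
                    resp = [mean_response(trials, (c,), AWAY) for c in comp]
                    pi, ni = assign_preference(
                        resp[0], resp[1], keys=comp, surround_component=sur
                    )
                    P, N = resp[pi], resp[ni]
                    PN = mean_response(trials, comp, AWAY)
                    P_attN = mean_response(trials, comp, comp[pi][0])
                    PN_att = mean_response(trials, comp, comp[ni][0])
                except MissingDataError:
                    continue
                def _safe(fn, *args, **kw):
                    try:
                        return fn(*args, **kw)
                    except UndefinedIndexError:
                        return np.nan
                rows.append(
                    PairIndices(
                        neuron_id=nid,
                        pair_id=pair_id,
                        rf_configuration=config,
                        selectivity=_safe(selectivity_index, P, N),
                        suppression=_safe(
                            suppression_index, P, PN, N, alternate_suppression
                        ),
                        attention_modulation=_safe(attention_index, P_attN, PN_att),
                        P=P, N=N, PN=PN,
                        pair_included=PN >= PAIR_MIN_MEAN_COUNT,
                    ).__dict__
                )
    return pd.DataFrame(rows)


def population_indices(
    trials: pd.DataFrame, design: TaskDesign, **kwargs
) -> pd.DataFrame:
    """Pair-index table for every neuron in a population trial table."""
    parts = [
        compute_pair_indices(g, design, **kwargs)
        for _, g in trials.groupby("neuron_id")
    ]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)
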