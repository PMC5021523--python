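"""Task design and condition enumeration for the spatial-attention paradigm.

The paradigm presents Gabor stimuli at three receptive-field locations
(a fixed middle location plus a clockwise and a counterclockwise neighbour),
in two orthogonal orientations, singly or in location pairs, while attention
is directed to one of the near locations or to a location on the opposite
side of fixation ("away").  Enumerating every stimulus x attention
combination that enters the model fit yields 36 conditions:

* 12 single-stimulus conditions: 3 locations x 2 orientations x
  {attend the stimulus location, attend away}
* 24 paired-stimulus conditions: 2 tested location pairs x 4 orientation
  combinations x {attend component A, attend component B, attend away}

Blank presentations are represented separately (they anchor the baseline
for inclusion tests) and are never fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

AWAY = "away"

#: number of stimulus x attention combinations entering the model fit
N_CONDITIONS = 36


@dataclass(frozen=True)
class Condition:
    """One stimulus x attention combination.

    Parameters
    ----------
    stimuli
        Tuple of ``(location, orientation)`` pairs, each location in
        ``{1, 2, 3}`` and orientation in ``{1, 2}``; size 0 (blank), 1 or 2.
        At most one stimulus per location.
    attention
        ``1``, ``2`` or ``3`` (a near location) or ``"away"``.
    """

    stimuli: tuple[tuple[int, int], ...]
    attention: int | str = AWAY

    def __post_init__(self) -> None:
        locs = [loc for loc, _ in self.stimuli]
        if len(set(locs)) != len(locs):
            raise ValueError("at most one stimulus per location")
        if self.attention != AWAY and self.attention not in (1, 2, 3):
            raise ValueError(f"invalid attention locus {self.attention!r}")
        # canonical ordering makes conditions hashable/comparable
        object.__setattr__(self, "stimuli", tuple(sorted(self.stimuli)))

    @property
    def is_blank(self) -> bool:
        return len(self.stimuli) == 0

    @property
    def locations(self) -> tuple[int, ...]:
        return tuple(loc for loc, _ in self.stimuli)

    @property
    def condition_id(self) -> str:
        if self.is_blank:
            stim = "blank"
        else:
            stim = "+".join(f"l{loc}o{ori}" for loc, ori in self.stimuli)
        return f"{stim}_att{self.attention}"

    def __str__(self) -> str:  # pragma: no cover - debugging nicety
        return self.condition_id


def _default_locations(
    eccentricity: float = 3.6, pair_separation: float = 2.3
) -> dict[int, tuple[float, float]]:
    """Place the three near locations on an iso-eccentric arc.

    Location 1 is the fixed middle location; 2 and 3 flank it clockwise and
    counterclockwise at the requested centre-to-centre separation, all at the
    same eccentricity in the lower-right visual quadrant.
    """
    base = math.radians(-40.0)
    half = 2.0 * math.asin(pair_separation / (2.0 * eccentricity))
    out = {}
    for loc, ang in ((1, base), (2, base - half), (3, base + half)):
        out[loc] = (eccentricity * math.cos(ang), eccentricity * math.sin(ang))
    return out


@dataclass
class TaskDesign:
    """Geometry and repetition structure of the attention task.

    Attributes
    ----------
    locations
        Mapping from location label (1, 2, 3) to planar coordinates in
        visual degrees.  Location 1 is the middle location common to both
        tested pairs.
    orientations
        The two orthogonal Gabor orientation labels.
    location_pairs
        The two tested pairings; the middle location appears in both.
    trials_per_condition
        Repetitions per condition in a simulated session.
    count_window
        Spike-count window duration in seconds (50-300 ms post onset).
    """

    locations: dict[int, tuple[float, float]] = field(
        default_factory=_default_locations
    )
    orientations: tuple[int, int] = (1, 2)
    location_pairs: tuple[tuple[int, int], ...] = ((1, 2), (1, 3))
    trials_per_condition: int = 40
    count_window: float = 0.25

    def __post_init__(self) -> None:
        if sorted(self.locations) != [1, 2, 3]:
            raise ValueError("design requires exactly locations 1, 2, 3")
        if len(self.location_pairs) != 2 or any(
            1 not in pair for pair in self.location_pairs
        ):
            raise ValueError(
                "the middle location (1) must appear in both location pairs"
            )
        if len(self.orientations) != 2:
            raise ValueError("exactly two orientations required")
        if self.count_window <= 0:
            raise ValueError("count_window must be positive")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")

    def location_xy(self, loc: int) -> np.ndarray:
        return np.asarray(self.locations[loc], dtype=float)


def enumerate_conditions(design: TaskDesign) -> list[Condition]:
    """Enumerate the 36 fittable stimulus x attention combinations."""
    conds: list[Condition] = []
    for loc in sorted(design.locations):
        for ori in design.orientations:
            stim = ((loc, ori),)
            conds.append(Condition(stim, attention=loc))
            conds.append(Condition(stim, attention=AWAY))
    for loc_a, loc_b in design.location_pairs:
        for ori_a in design.orientations:
            for ori_b in design.orientations:
                stim = ((loc_a, ori_a), (loc_b, ori_b))
                for att in (loc_a, loc_b, AWAY):
                    conds.append(Condition(stim, attention=att))
    if len(conds) != N_CONDITIONS or len(set(conds)) != N_CONDITIONS:
        raise RuntimeError("condition enumeration is inconsistent")
    return conds


def blank_condition() -> Condition:
    """The no-stimulus presentation used as the response baseline."""
    return Condition((), attention=AWAY)


def design_to_json(design: TaskDesign, path) -> None:
    """Write a TaskDesign sidecar as JSON."""
    import json

    payload = {
        "locations": {str(k): list(v) for k, v in design.locations.items()},
        "orientations": list(design.orientations),
        "location_pairs": [list(p) for p in design.location_pairs],
        "trials_per_condition": design.trials_per_condition,
        "count_window": design.count_window,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def design_from_json(path) -> TaskDesign:
    """Read a TaskDesign sidecar written by :func:`design_to_json`."""
    import json

    with open(path) as fh:
        raw = json.load(fh)
    return TaskDesign(
        locations={int(k): tuple(v) for k, v in raw["locations"].items()},
        orientations=tuple(raw["orientations"]),
        location_pairs=tuple(tuple(p) for p in raw["location_pairs"]),
        trials_per_condition=raw["trials_per_condition"],
        count_window=raw["count_window"],
    )


def conditions_frame(conditions: list[Condition]):
    """Tabulate conditions as a DataFrame (one row per condition)."""
    import pandas as pd

    rows = []
    for c in conditions:
        rows.append(
            {
                "condition_id": c.condition_id,
                "n_stimuli": len(c.stimuli),
                "stimuli": "+".join(f"l{l}o{o}" for l, o in c.stimuli) or "blank",
                "attention": str(c.attention),
            }
        )
    return pd.DataFrame(rows)
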