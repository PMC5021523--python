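"""Receptive-field geometry: mapping grids, center of mass, Gaussian fits.

The receptive field of each neuron is characterised from an 8x8 grid of
mapping responses: the center of mass of the raw (unfitted) responses
defines the receptive-field center, and a bivariate Gaussian least-squares
fit provides a covariance under which distances can be expressed in
Mahalanobis units (number of standard-deviation contours from the center).
Fits explaining 80% of the response variance or less are flagged as
unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

EV_RELIABLE = 0.80


@dataclass
class RFMap:
    """Gridded mapping responses: positions (n, 2) in degrees, responses (n,)."""

    positions: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if len(self.responses) != len(self.positions):
            raise ValueError("positions and responses must align")


@dataclass
class RFGeometry:
    """Center of mass, Gaussian fit, and Mahalanobis metric for one map."""

    center_of_mass: np.ndarray
    amplitude: float
    center: np.ndarray
    cov: np.ndarray
    explained_variance: float
    reliable: bool
    fit_failed: bool = False

    def mahalanobis(self, point) -> float:
        """Distance of a point from the fitted center in s.d. units."""
        if self.fit_failed:
            return np.nan
        dx = np.asarray(point, dtype=float) - self.center
        return float(np.sqrt(dx @ np.linalg.inv(self.cov) @ dx))


def center_of_mass(rf_map: RFMap) -> np.ndarray:
    """Response-weighted mean position of the unfitted map.

    Negative responses (possible after baseline subtraction) are clipped to
    zero so the weighting stays a convex combination.
    """
    w = np.clip(rf_map.responses, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("map has no positive response mass")
    return (w[:, None] * rf_map.positions).sum(axis=0) / total


def _gauss2d(pos: np.ndarray, amp, mx, my, log_sx, log_sy, rho_z) -> np.ndarray:
    sx, sy = np.exp(log_sx), np.exp(log_sy)
    rho = np.tanh(rho_z)
    dx = (pos[:, 0] - mx) / sx
    dy = (pos[:, 1] - my) / sy
    q = (dx**2 - 2 * rho * dx * dy + dy**2) / (1 - rho**2)
    return amp * np.exp(-0.5 * q)


def fit_gaussian(rf_map: RFMap) -> RFGeometry:
    """Least-squares bivariate Gaussian fit to a mapping grid.

    Parameterised by amplitude, center, log axis s.d.s and an atanh-mapped
    correlation so the covariance stays positive definite; initialised from
    the center of mass and response-weighted second moments.
    """
    y = rf_map.responses
    pos = rf_map.positions
    if np.ptp(y) <= 0:
        return RFGeometry(
            center_of_mass=pos.mean(axis=0), amplitude=0.0,
            center=pos.mean(axis=0), cov=np.eye(2),
            explained_variance=np.nan, reliable=False, fit_failed=True,
        )
    com = center_of_mass(rf_map)
    w = np.clip(y, 0, None)
    w = w / w.sum()
    dx = pos - com
    second = np.einsum("n,ni,nj->ij", w, dx, dx)
    sx0 = max(np.sqrt(second[0, 0]), 1e-2)
    sy0 = max(np.sqrt(second[1, 1]), 1e-2)
    x0 = np.array([y.max(), com[0], com[1], np.log(sx0), np.log(sy0), 0.0])

    def resid(theta):
        return _gauss2d(pos, *theta) - y

    try:
        sol = optimize.least_squares(resid, x0, max_nfev=20_000)
    except Exception:
        return RFGeometry(
            center_of_mass=com, amplitude=np.nan, center=com, cov=np.eye(2),
            explained_variance=np.nan, reliable=False, fit_failed=True,
        )
    amp, mx, my, lsx, lsy, rz = sol.x
    sx, sy, rho = np.exp(lsx), np.exp(lsy), np.tanh(rz)
    cov = np.array([[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]])
    ss_res = float(sol.fun @ sol.fun)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ev = max(0.0, 1.0 - ss_res / ss_tot)
    return RFGeometry(
        center_of_mass=com, amplitude=float(amp), center=np.array([mx, my]),
        cov=cov, explained_variance=ev, reliable=ev > EV_RELIABLE,
    )


def rf_geometry(rf_map: RFMap) -> RFGeometry:
    """Center of mass plus Gaussian fit of a mapping grid (see fit_gaussian)."""
    return fit_gaussian(rf_map)
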