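"""Core mathematics of the 2-state switching first-difference correlated random walk.

The movement process operates on displacements ``d_t = x_t - x_{t-1}`` of a
track of true (unobserved) planar locations ``x_t`` (km) on a regular time
grid.  Each displacement is centred on a rotated, damped copy of the previous
one,

    d_t | d_{t-1}, b_t  ~  N2( gamma[b_t] * T(theta[b_t]) @ d_{t-1}, Sigma ),

where ``b_t`` in {1, 2} is a latent behavioural state (1 = transient: fast,
directionally persistent travel; 2 = area-restricted search: slow movement
with frequent course reversals), ``gamma`` in [0, 1] is the move persistence,
``T(theta)`` a rotation matrix of the mean turn angle and ``Sigma`` the 2-D
process covariance shared by both states.  The state sequence follows a
first-order Markov chain with a 2x2 row-stochastic transition matrix
``alpha``.

Observation models supported:

* ``none``  -- observations equal the true locations exactly,
* ``gps``   -- bivariate-Normal error with covariance ``Omega`` (GPS-like),
* ``argos`` -- per-axis location-scale t errors with class-specific scale
  ``tau_q`` and degrees of freedom ``nu_q`` (heavy-tailed, Argos-like), with
  an optional per-individual rescale factor ``psi`` applied to the scales.

Everything in this module is a pure deterministic function; simulation and
inference are layered on top.  Angles are radians; ``T(theta)`` is the
counter-clockwise rotation of the previous displacement (results are
invariant to the sign convention as long as simulation and inference share
it, which they do by construction here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ProcessParams",
    "ObsParams",
    "LatentPath",
    "build_turn_matrix",
    "process_mean",
    "process_logdensity",
    "build_transition_matrix",
    "stationary_distribution",
    "obs_logdensity_gaussian",
    "obs_logdensity_t",
    "interpolate_position",
    "lonlat_to_km",
    "km_to_lonlat",
]

TRANSIENT = 1
ARS = 2

_LOG_2PI = float(np.log(2.0 * np.pi))


def _as_vec2(v, name: str) -> np.ndarray:
    out = np.asarray(v, dtype=float)
    if out.shape != (2,):
        raise ValueError(f"{name} must be a length-2 vector, got shape {out.shape}")
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{name} must be finite")
    return out


def _as_cov2(m, name: str, require_pd: bool = True) -> np.ndarray:
    out = np.asarray(m, dtype=float)
    if out.shape != (2, 2):
        raise ValueError(f"{name} must be a 2x2 matrix, got shape {out.shape}")
    if not np.allclose(out, out.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(out)
    if require_pd and eigvals.min() <= 0:
        raise np.linalg.LinAlgError(f"{name} must be positive definite")
    if not require_pd and eigvals.min() < -1e-12:
        raise ValueError(f"{name} must be positive semi-definite")
    return out


@dataclass(frozen=True)
class ProcessParams:
    """Behavioural movement parameters of the switching CRW.

    Parameters
    ----------
    gamma
        Per-state move persistence ``(gamma_1, gamma_2)``, each in [0, 1].
        State 1 (transient) must be at least as persistent as state 2 (ARS);
        this ordering is the label-identifiability convention used throughout.
    theta
        Per-state mean turn angle in radians ``(theta_1, theta_2)``.
    sigma
        2x2 symmetric positive-definite process covariance, km^2, shared by
        both states.
    alpha
        2x2 row-stochastic state transition matrix.  ``alpha[0, 0]`` is the
        probability of remaining transient; ``alpha[1, 0]`` the probability
        of switching from ARS to transient.
    """

    gamma: tuple[float, float]
    theta: tuple[float, float]
    sigma: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        gamma = tuple(float(g) for g in self.gamma)
        theta = tuple(float(t) for t in self.theta)
        if len(gamma) != 2 or len(theta) != 2:
            raise ValueError("gamma and theta must each have two entries")
        for g in gamma:
            if not (0.0 <= g <= 1.0):
                raise ValueError(f"gamma entries must lie in [0, 1], got {g}")
        if gamma[0] < gamma[1]:
            raise ValueError(
                "identifiability requires gamma[transient] >= gamma[ARS]; "
                f"got {gamma}"
            )
        if not all(np.isfinite(theta)):
            raise ValueError("theta entries must be finite")
        sigma = _as_cov2(self.sigma, "sigma")
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.shape != (2, 2):
            raise ValueError("alpha must be 2x2")
        if np.any(alpha < 0) or np.any(alpha > 1):
            raise ValueError("alpha entries must lie in [0, 1]")
        if not np.allclose(alpha.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of alpha must sum to 1")
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "alpha", alpha)


@dataclass(frozen=True)
class ObsParams:
    """Observation-error model specification.

    ``regime`` selects among ``none`` (error-free identity observation),
    ``gps`` (bivariate Normal with covariance ``omega``) and ``argos``
    (per-axis location-scale t with per-quality-class scale pairs ``tau``
    (km) and degrees of freedom ``nu``, all rescaled by a per-individual
    positive factor ``psi``).
    """

    regime: str = "none"
    omega: np.ndarray | None = None
    tau: dict[str, tuple[float, float]] | None = None
    nu: dict[str, float] | None = None
    psi: float = 1.0

    def __post_init__(self):
        if self.regime not in ("none", "gps", "argos"):
            raise ValueError(f"unknown observation regime {self.regime!r}")
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        if self.regime == "gps":
            if self.omega is None:
                raise ValueError("gps regime requires omega")
            object.__setattr__(
                self, "omega", _as_cov2(self.omega, "omega", require_pd=False)
            )
        if self.regime == "argos":
            if not self.tau or not self.nu:
                raise ValueError("argos regime requires tau and nu tables")
            for q, pair in self.tau.items():
                if any(t <= 0 for t in pair):
                    raise ValueError(f"tau for class {q!r} must be positive")
            for q, v in self.nu.items():
                if v <= 0:
                    raise ValueError(f"nu for class {q!r} must be positive")
            if set(self.tau) != set(self.nu):
                raise ValueError("tau and nu must cover the same classes")


@dataclass
class LatentPath:
    """True locations and behavioural states on a regular time grid.

    ``x`` has shape (T, 2) in km, ``b`` shape (T,) with values in {1, 2},
    and ``dt`` is the grid spacing in hours.
    """

    x: np.ndarray
    b: np.ndarray
    dt: float = 1.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.b = np.asarray(self.b, dtype=int)
        if self.x.ndim != 2 or self.x.shape[1] != 2:
            raise ValueError("x must have shape (T, 2)")
        if self.b.shape != (self.x.shape[0],):
            raise ValueError("b must have the same length as x")
        if self.x.shape[0] < 3:
            raise ValueError("a path needs at least 3 locations")
        if not np.all(np.isin(self.b, (TRANSIENT, ARS))):
            raise ValueError("states must be 1 (transient) or 2 (ARS)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.x.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Hours from track start for each grid point."""
        return np.arange(len(self)) * self.dt


def build_turn_matrix(theta: float) -> np.ndarray:
    """Rotation matrix ``T(theta)`` applied to the previous displacement.

    Counter-clockwise convention::

        [[cos t, -sin t],
         [sin t,  cos t]]
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def process_mean(d_prev, state: int, params: ProcessParams) -> np.ndarray:
    """Expected next displacement ``gamma_b T(theta_b) d_prev`` (km)."""
    d_prev = _as_vec2(d_prev, "d_prev")
    if state not in (TRANSIENT, ARS):
        raise ValueError(f"state must be 1 or 2, got {state}")
    g = params.gamma[state - 1]
    return g * (build_turn_matrix(params.theta[state - 1]) @ d_prev)


def process_logdensity(x_t, x_prev, x_prev2, state: int, params: ProcessParams) -> float:
    """Log density of ``x_t`` under the switching CRW process step.

    The displacement ``d_t = x_t - x_prev`` is bivariate Normal about
    ``process_mean(x_prev - x_prev2, state)`` with covariance ``Sigma``.
    """
    x_t = _as_vec2(x_t, "x_t")
    x_prev = _as_vec2(x_prev, "x_prev")
    x_prev2 = _as_vec2(x_prev2, "x_prev2")
    mean = process_mean(x_prev - x_prev2, state, params)
    d = x_t - x_prev
    return _mvn2_logpdf(d, mean, params.sigma)


def _mvn2_logpdf(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError("covariance is singular")
    r = y - mean
    quad = r @ np.linalg.solve(cov, r)
    return float(-_LOG_2PI - 0.5 * logdet - 0.5 * quad)


def build_transition_matrix(alpha1: float, alpha2: float) -> np.ndarray:
    """Assemble the 2x2 behavioural transition matrix.

    ``alpha1`` = P(stay transient), ``alpha2`` = P(ARS -> transient);
    row i gives the distribution of the next state given current state i+1.
    """
    for name, a in (("alpha1", alpha1), ("alpha2", alpha2)):
        if not (0.0 <= a <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {a}")
    return np.array([[alpha1, 1.0 - alpha1], [alpha2, 1.0 - alpha2]])


def stationary_distribution(alpha: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 2-state row-stochastic chain.

    Closed form: with switch rates a12 = 1 - alpha[0,0] and a21 = alpha[1,0],
    pi = (a21, a12) / (a12 + a21).  Requires an irreducible chain.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (2, 2):
        raise ValueError("alpha must be 2x2")
    a12 = alpha[0, 1]
    a21 = alpha[1, 0]
    if a12 <= 0 or a21 <= 0:
        raise ValueError("chain is reducible: both off-diagonal entries must be > 0")
    pi = np.array([a21, a12]) / (a12 + a21)
    return pi


def obs_logdensity_gaussian(y, x, omega) -> float:
    """Bivariate-Normal log density of an observed location about the truth."""
    y = _as_vec2(y, "y")
    x = _as_vec2(x, "x")
    omega = _as_cov2(omega, "omega", require_pd=False)
    return _mvn2_logpdf(y, x, omega)


def obs_logdensity_t(y, x, tau, nu: float, psi: float = 1.0) -> float:
    """Heavy-tailed Argos-style observation log density.

    The two coordinate axes are independent location-scale t variates centred
    on the true location with scales ``psi * tau`` and common degrees of
    freedom ``nu``.
    """
    y = _as_vec2(y, "y")
    x = _as_vec2(x, "x")
    tau = np.asarray(tau, dtype=float)
    if tau.shape == ():
        tau = np.array([float(tau), float(tau)])
    if tau.shape != (2,) or np.any(tau <= 0):
        raise ValueError("tau must be a positive scalar or positive pair")
    if nu <= 0:
        raise ValueError("nu must be positive")
    if psi <= 0:
        raise ValueError("psi must be positive")
    scale = psi * tau
    return float(np.sum(stats.t.logpdf(y, df=nu, loc=x, scale=scale)))


def interpolate_position(x_prev, x_curr, j: float) -> np.ndarray:
    """Straight-line position a fraction ``j`` of the way from x_prev to x_curr."""
    if not (0.0 <= j <= 1.0):
        raise ValueError(f"interpolation fraction must lie in [0, 1], got {j}")
    x_prev = _as_vec2(x_prev, "x_prev")
    x_curr = _as_vec2(x_curr, "x_curr")
    return (1.0 - j) * x_prev + j * x_curr


_KM_PER_DEG = 111.32  # km per degree of latitude (spherical Earth)


def lonlat_to_km(lon, lat, origin: tuple[float, float] | None = None):
    """Equirectangular projection of lon/lat degrees to planar km.

    Projects about ``origin`` (defaults to the track centroid); returns
    ``(xy, origin)`` where ``xy`` has shape (n, 2).  Adequate for regional
    tracks; all core model math is projection-agnostic.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if origin is None:
        origin = (float(np.mean(lon)), float(np.mean(lat)))
    lon0, lat0 = origin
    x = (lon - lon0) * _KM_PER_DEG * np.cos(np.deg2rad(lat0))
    y = (lat - lat0) * _KM_PER_DEG
    return np.column_stack([x, y]), origin


def km_to_lonlat(xy, origin: tuple[float, float]):
    """Inverse of :func:`lonlat_to_km` for the same projection origin."""
    xy = np.asarray(xy, dtype=float)
    lon0, lat0 = origin
    lon = lon0 + xy[..., 0] / (_KM_PER_DEG * np.cos(np.deg2rad(lat0)))
    lat = lat0 + xy[..., 1] / _KM_PER_DEG
    return lon, lat
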