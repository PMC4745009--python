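"""Bayesian MCMC estimation for the switching CRW state-space model.

Two model forms share one code path:

* ``ssm``  -- movement parameters estimated separately per individual
  (independent fits, run batched for speed);
* ``hssm`` -- joint estimation: a single set of movement parameters
  (gamma, theta, alpha, Sigma) shared across individuals, while the state
  and location sequences (and the Argos error rescale ``psi``) remain
  individual-level.

Observations may be regular (one per latent time step) or irregularly
timed; irregular observations are regularised onto the latent grid by
straight-line interpolation between the two bracketing latent locations.

The sampler is Metropolis-within-Gibbs with exact forward-filtering
backward-sampling for the discrete states; see ``_sampler`` for details.
Default priors (all overridable through :class:`Priors`): Beta(1,1) on the
transition probabilities; gamma1 ~ U(0,1) with gamma2 = gamma1*u,
u ~ U(0,1) (enforcing the gamma1 > gamma2 labelling); theta1 ~
U(-pi/2, pi/2), theta2 ~ U(pi/2, 3pi/2); per-axis half-t(3) process SDs
with U(-1,1) correlation; psi ~ U(0, 10).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _sampler
from ._sampler import GibbsSampler, Priors, StackedTracks, attach_obs_model, stack_tracks
from .io import Track
from .model_core import ARS, TRANSIENT, LatentPath, ObsParams, ProcessParams

__all__ = [
    "FitConfig",
    "Priors",
    "PosteriorDraws",
    "RegularisedObsMap",
    "map_observations_to_steps",
    "filter_gaps",
    "joint_log_posterior",
    "sample_states_conditional",
    "initialize_chain",
    "fit",
]

PARAM_NAMES = (
    "gamma1",
    "gamma2",
    "theta1",
    "theta2",
    "alpha1",
    "alpha2",
    "sigma_x",
    "sigma_y",
    "rho",
)


@dataclass
class FitConfig:
    """MCMC protocol and model-form configuration.

    The reference protocol is 2 chains of 60 000 iterations, 40 000 burn-in
    and thinning by 20, retaining 1 000 draws per chain (2 000 total).  The
    default time step is 1 h (simulator-resolution data); seal-like
    irregular Argos data are typically fit with a 6 h step.
    """

    model_form: str = "hssm"
    time_step: float = 1.0  # hours
    n_chains: int = 2
    n_iter: int = 60_000
    n_burnin: int = 40_000
    thin: int = 20
    seed: int = 0
    priors: Priors = field(default_factory=Priors)
    monitor: tuple[str, ...] = PARAM_NAMES + ("psi", "b", "x")
    estimate_psi: bool = True

    def __post_init__(self):
        if self.model_form not in ("ssm", "hssm"):
            raise ValueError("model_form must be 'ssm' or 'hssm'")
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (required for R-hat)")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    @property
    def retained_per_chain(self) -> int:
        """floor((n_iter - n_burnin) / thin) retained draws per chain."""
        return (self.n_iter - self.n_burnin) // self.thin

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain


@dataclass
class RegularisedObsMap:
    """Mapping of irregular observation times onto the latent grid.

    ``interval`` is 1-based: observation i falls ``frac[i]`` of the way
    through latent interval ``interval[i]``, i.e. between latent locations
    with 0-based indices ``interval[i] - 1`` and ``interval[i]``...  in
    0-based grid coordinates the interpolated mean is
    ``(1 - frac) * x[k] + frac * x[k + 1]`` with ``k = interval - 1``.
    """

    interval: np.ndarray
    frac: np.ndarray

    @property
    def k(self) -> np.ndarray:
        """0-based index of the latent location starting each interval."""
        return self.interval - 1


def map_observations_to_steps(
    obs_times, start_time: float, time_step: float
) -> RegularisedObsMap:
    """Assign each observation to a latent interval and elapsed fraction.

    ``interval = 1 + floor((t - start) / step)`` and ``frac`` is the
    fractional remainder in [0, 1).
    """
    t = np.asarray(obs_times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("obs_times must be sorted ascending")
    rel = (t - start_time) / time_step
    if np.any(rel < -1e-9):
        raise ValueError("observations precede start_time")
    k = np.floor(rel + 1e-9).astype(int)
    frac = rel - k
    frac[np.abs(frac) < 1e-9] = 0.0
    return RegularisedObsMap(interval=k + 1, frac=frac)


def filter_gaps(track: Track, max_gap: float = 4.0) -> Track:
    """Retain the longest contiguous run with inter-observation gaps <= max_gap days.

    Returns a new Track; the number of dropped observations is recorded on
    the result as ``n_dropped``.
    """
    gaps_days = np.diff(track.times) / 24.0
    breaks = np.flatnonzero(gaps_days > max_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(track)]])
    lengths = ends - starts
    best = int(np.argmax(lengths))
    s, e = int(starts[best]), int(ends[best])
    if e - s < 3:
        raise ValueError(
            f"track {track.ident!r}: longest gap-free run has {e - s} "
            f"observations (< 3)"
        )
    out = Track(
        ident=track.ident,
        times=track.times[s:e] - track.times[s],
        y=track.y[s:e],
        lc=None if track.lc is None else track.lc[s:e],
        origin=track.origin,
    )
    out.n_dropped = len(track) - (e - s)
    return out


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with chain/iteration structure preserved.

    ``params[name]`` has shape (n_chains, n_draws) for shared parameters or
    (n_chains, n_draws, n_ind) for per-individual ones; ``b`` has shape
    (n_chains, n_draws, n_ind, T) with states coded 1/2 and padded entries 0;
    ``x`` (optional) has shape (n_chains, n_draws, n_ind, T, 2).
    """

    model_form: str
    track_ids: list[str]
    t_len: np.ndarray
    params: dict[str, np.ndarray]
    b: np.ndarray | None
    x: np.ndarray | None
    meta: dict

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def get(self, name: str, individual: int | None = None) -> np.ndarray:
        """Draws of one scalar parameter, shape (n_chains, n_draws)."""
        arr = self.params[name]
        if arr.ndim == 2:
            return arr
        if individual is None:
            if arr.shape[2] == 1:
                return arr[:, :, 0]
            raise ValueError(f"{name} is per-individual; pass individual=")
        return arr[:, :, individual]

    def states_for(self, individual: int) -> np.ndarray:
        """State draws for one track, shape (n_chains, n_draws, T_i)."""
        T = int(self.t_len[individual])
        return self.b[:, :, individual, :T]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view of the scalar parameter draws."""
        rows = []
        for name, arr in self.params.items():
            a = arr if arr.ndim == 3 else arr[:, :, None]
            n_chains, n_draws, n_ind = a.shape
            for c in range(n_chains):
                for i in range(n_ind):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iteration": np.arange(n_draws),
                                "parameter": name,
                                "individual": i if arr.ndim == 3 else -1,
                                "value": a[c, :, i],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# log posterior (reference implementation, used by tests and diagnostics)
# --------------------------------------------------------------------------


def _support_violation(p: dict, priors: Priors) -> bool:
    g1, g2 = p["gamma1"], p["gamma2"]
    if not (0 <= g2 <= g1 <= 1):
        return True
    if not (priors.theta1_range[0] <= p["theta1"] <= priors.theta1_range[1]):
        return True
    if not (priors.theta2_range[0] <= p["theta2"] <= priors.theta2_range[1]):
        return True
    if not (0 <= p["alpha1"] <= 1 and 0 <= p["alpha2"] <= 1):
        return True
    if p["sigma_x"] <= 0 or p["sigma_y"] <= 0 or not (-1 < p["rho"] < 1):
        return True
    if not (0 < p.get("psi", 1.0) < priors.psi_max):
        return True
    return False


def _params_to_dict(params) -> dict:
    if isinstance(params, dict):
        return dict(params)
    if isinstance(params, ProcessParams):
        return {
            "gamma1": params.gamma[0],
            "gamma2": params.gamma[1],
            "theta1": params.theta[0],
            "theta2": params.theta[1],
            "alpha1": params.alpha[0, 0],
            "alpha2": params.alpha[1, 0],
            "sigma_x": math.sqrt(params.sigma[0, 0]),
            "sigma_y": math.sqrt(params.sigma[1, 1]),
            "rho": params.sigma[0, 1]
            / math.sqrt(params.sigma[0, 0] * params.sigma[1, 1]),
        }
    raise TypeError("params must be a dict or ProcessParams")


def joint_log_posterior(
    latents,
    params,
    tracks,
    config: FitConfig,
    obs: ObsParams | None = None,
) -> float:
    """Joint log posterior of latents and parameters given the tracks.

    ``latents`` is a sequence of :class:`LatentPath` (one per track);
    ``params`` a single parameter set (dict or ProcessParams, shared /
    hssm form) or one per track (ssm form).  Parameters outside the prior
    support yield ``-inf`` rather than raising.  Terms: process densities,
    state-transition log probabilities (with the stationary distribution as
    the initial-state prior), observation densities (with straight-line
    interpolation for irregular times), vague Gaussian anchors on the first
    two locations, and the log priors.
    """
    obs = obs if obs is not None else ObsParams(regime="none")
    pr = config.priors
    n = len(tracks)
    if isinstance(params, (dict, ProcessParams)):
        psets = [_params_to_dict(params)] * n
        shared = True
    else:
        psets = [_params_to_dict(p) for p in params]
        shared = False
    if len(psets) != n or len(latents) != n:
        raise ValueError("latents, params and tracks must align")

    psis = _psi_vector(obs, n)
    for p, psi in zip(psets, psis):
        p.setdefault("psi", psi)
    unique = psets[:1] if shared else psets
    for p in unique:
        if _support_violation(p, pr):
            return -math.inf

    total = 0.0
    for p in unique:
        total += _log_prior(p, pr, include_psi=not shared and obs.regime == "argos")
    if shared and obs.regime == "argos":
        for p in psets:
            total += -math.log(pr.psi_max)

    for lat, p, tr in zip(latents, psets, tracks):
        total += _track_loglik(lat, p, tr, config, obs, pr)
    return float(total)


def _psi_vector(obs: ObsParams, n: int) -> list[float]:
    psi = obs.psi
    if np.ndim(psi) == 0:
        return [float(psi)] * n
    return [float(v) for v in psi]


def _log_prior(p: dict, pr: Priors, include_psi: bool) -> float:
    # gamma1 ~ U(0,1), u ~ U(0,1)  =>  density 1/gamma1 on the ordered pair
    lp = -math.log(max(p["gamma1"], 1e-300))
    lp -= math.log(pr.theta1_range[1] - pr.theta1_range[0])
    lp -= math.log(pr.theta2_range[1] - pr.theta2_range[0])
    lp += float(_sampler._half_t_logpdf(p["sigma_x"], pr.sigma_df, pr.sigma_scale))
    lp += float(_sampler._half_t_logpdf(p["sigma_y"], pr.sigma_df, pr.sigma_scale))
    lp -= math.log(2.0)  # rho ~ U(-1, 1)
    # alpha ~ Beta(1,1): 0
    if include_psi:
        lp -= math.log(pr.psi_max)
    return lp


def _track_loglik(
    lat: LatentPath, p: dict, tr: Track, config: FitConfig, obs: ObsParams, pr: Priors
) -> float:
    from .model_core import (
        build_transition_matrix,
        obs_logdensity_gaussian,
        obs_logdensity_t,
        process_logdensity,
        stationary_distribution,
    )

    params = ProcessParams(
        gamma=(p["gamma1"], p["gamma2"]),
        theta=(p["theta1"], p["theta2"]),
        sigma=_sigma_from(p),
        alpha=build_transition_matrix(p["alpha1"], p["alpha2"]),
    )
    x, b = lat.x, lat.b
    total = 0.0
    # state chain
    pi = stationary_distribution(params.alpha)
    total += math.log(pi[b[0] - 1])
    for t in range(1, len(b)):
        total += math.log(params.alpha[b[t - 1] - 1, b[t] - 1])
    # process
    for t in range(2, len(b)):
        total += process_logdensity(x[t], x[t - 1], x[t - 2], b[t], params)
    # anchors on the first two locations
    for s in range(2):
        r = x[s] - tr.y[0]
        total += -_norm_const(pr.anchor_sd) - float(r @ r) / (2 * pr.anchor_sd**2)
    # observations
    if obs.regime != "none":
        m = map_observations_to_steps(tr.times, tr.times[0], config.time_step)
        for i in range(len(tr.times)):
            k, j = int(m.k[i]), float(m.frac[i])
            mu = (1 - j) * x[k] + j * x[min(k + 1, len(b) - 1)]
            if obs.regime == "gps":
                total += obs_logdensity_gaussian(tr.y[i], mu, obs.omega)
            else:
                q = str(tr.lc[i])
                total += obs_logdensity_t(
                    tr.y[i], mu, obs.tau[q], obs.nu[q], p.get("psi", 1.0)
                )
    return total


def _norm_const(sd: float) -> float:
    return math.log(2 * math.pi) + 2 * math.log(sd)


def _sigma_from(p: dict) -> np.ndarray:
    sx, sy, rho = p["sigma_x"], p["sigma_y"], p["rho"]
    return np.array(
        [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]]
    )


# --------------------------------------------------------------------------
# conditional state sampling (public single-track surface over FFBS)
# --------------------------------------------------------------------------


def sample_states_conditional(
    x: np.ndarray,
    params: ProcessParams,
    obs=None,
    rng: np.random.Generator | None = None,
    n_draws: int = 1,
) -> np.ndarray:
    """Draw state sequences from their exact conditional given locations.

    Emissions are the process densities; observation terms do not involve
    the states and therefore drop out of this conditional.  Returns states
    coded 1/2 with shape (T,) or (n_draws, T).
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(x, dtype=float)[None, :, :]
    T = x.shape[1]
    p = _params_to_dict(params)
    ps = _sampler.ParamState(
        gamma1=np.array([p["gamma1"]]),
        u=np.array([p["gamma2"] / p["gamma1"] if p["gamma1"] > 0 else 0.0]),
        theta1=np.array([p["theta1"]]),
        theta2=np.array([p["theta2"]]),
        sx=np.array([p["sigma_x"]]),
        sy=np.array([p["sigma_y"]]),
        rho=np.array([p["rho"]]),
        alpha1=np.array([p["alpha1"]]),
        alpha2=np.array([p["alpha2"]]),
        psi=np.ones(1),
    )
    pind = np.zeros(1, dtype=int)
    valid = np.ones((1, T - 2), dtype=bool)
    t_len = np.array([T])
    emiss = _sampler.state_emissions(x, ps, pind, valid)
    if np.any(~np.isfinite(emiss)):
        raise FloatingPointError("degenerate (zero-probability) emissions")
    draws = np.empty((n_draws, T), dtype=np.int8)
    for d in range(n_draws):
        draws[d] = _sampler.ffbs(emiss, ps, pind, t_len, rng)[0] + 1
    return draws[0] if n_draws == 1 else draws


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _chain_rng(seed: int, chain_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, chain_index]))


def initialize_chain(
    tracks, config: FitConfig, chain_index: int, obs: ObsParams | None = None
):
    """Build a sampler with the over-dispersed initialisation of one chain.

    Deterministic given (config.seed, chain_index): parameters are drawn
    from their priors, latent locations from the interpolated observations
    plus jitter, and initial states by thresholding step lengths at their
    median.  Returns the initialised :class:`GibbsSampler`.
    """
    obs = obs if obs is not None else ObsParams(regime="none")
    stacked, lcs = stack_tracks(tracks, config.time_step)
    attach_obs_model(stacked, lcs, obs)
    sampler = GibbsSampler(
        stacked,
        shared=config.model_form == "hssm",
        priors=config.priors,
        estimate_psi=config.estimate_psi,
    )
    sampler.initialize(_chain_rng(config.seed, chain_index))
    return sampler


def fit(tracks, config: FitConfig, obs: ObsParams | None = None) -> PosteriorDraws:
    """Run the full MCMC protocol and return retained, thinned draws.

    Chains run sequentially with independent over-dispersed initialisations;
    proposal-scale adaptation is active only during burn-in.
    """
    obs = obs if obs is not None else ObsParams(regime="none")
    n_keep = config.retained_per_chain
    if n_keep < 1:
        raise ValueError("protocol retains no draws; increase n_iter or reduce thin")
    n_ind = len(tracks)
    first = initialize_chain(tracks, config, 0, obs)
    t_len = first.st.t_len
    t_max = first.st.t_max
    shared = config.model_form == "hssm"
    p_shape = (config.n_chains, n_keep) if shared else (config.n_chains, n_keep, n_ind)

    params_store = {name: np.empty(p_shape) for name in PARAM_NAMES}
    if first.estimate_psi:
        params_store["psi"] = np.empty((config.n_chains, n_keep, n_ind))
    keep_b = "b" in config.monitor
    keep_x = "x" in config.monitor and first.sample_locations
    b_store = (
        np.zeros((config.n_chains, n_keep, n_ind, t_max), dtype=np.int8)
        if keep_b
        else None
    )
    x_store = (
        np.empty((config.n_chains, n_keep, n_ind, t_max, 2), dtype=np.float32)
        if keep_x
        else None
    )

    start = time.time()
    meta = {"config": {**config.__dict__, "priors": config.priors.__dict__}, "chains": []}
    for c in range(config.n_chains):
        sampler = first if c == 0 else initialize_chain(tracks, config, c, obs)
        rng = _chain_rng(config.seed, 10_000 + c)
        kept = 0
        for it in range(config.n_iter):
            if it == config.n_burnin:
                sampler.adapting = False
            sampler.sweep(rng)
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                if kept < n_keep:
                    _store_draw(sampler, params_store, b_store, x_store, c, kept, shared)
                    kept += 1
        meta["chains"].append(
            {
                "chain": c,
                "retained": kept,
                "loc_scale": math.exp(sampler.scales.loc),
            }
        )
    meta["runtime_s"] = time.time() - start
    return PosteriorDraws(
        model_form=config.model_form,
        track_ids=[tr.ident for tr in tracks],
        t_len=t_len,
        params=params_store,
        b=b_store,
        x=x_store,
        meta=meta,
    )


def _store_draw(sampler, params_store, b_store, x_store, c, k, shared):
    ps = sampler.params
    vals = {
        "gamma1": ps.gamma1,
        "gamma2": ps.gamma2,
        "theta1": ps.theta1,
        "theta2": ps.theta2,
        "alpha1": ps.alpha1,
        "alpha2": ps.alpha2,
        "sigma_x": ps.sx,
        "sigma_y": ps.sy,
        "rho": ps.rho,
    }
    for name, v in vals.items():
        params_store[name][c, k] = v[0] if shared else v
    if "psi" in params_store:
        params_store["psi"][c, k] = ps.psi
    if b_store is not None:
        b = sampler.b + 1
        b = np.where(sampler.st.site_mask, b, 0)
        b_store[c, k] = b
    if x_store is not None:
        x_store[c, k] = sampler.x
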