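"""Metropolis-within-Gibbs engine for the switching CRW state-space model.

The sampler operates on a stack of tracks padded to a common latent length
so that every update is vectorised across individuals:

* behavioural states ``b`` -- exact draws from their full conditional via
  forward-filtering backward-sampling (FFBS) over the 2-state chain, with
  the process densities as emissions;
* latent locations ``x`` -- single-site random-walk Metropolis, updated in
  three interleaved colour classes (sites 3 apart are conditionally
  independent under the second-order process dependence), each class
  vectorised over sites and tracks;
* continuous movement parameters -- adaptive random-walk Metropolis on
  unconstrained or box-constrained scales, with adaptation frozen at the end
  of burn-in to preserve detailed balance;
* transition probabilities ``alpha`` -- independence MH with the conjugate
  Beta full-conditional (given the transition counts) as proposal; the
  acceptance ratio reduces to the stationary-distribution prior on the
  initial states.

Parameter sharing: in joint-estimation form ("hssm") there is a single
parameter vector shared by all tracks; in per-individual form ("ssm") each
track has its own, and because no likelihood term couples tracks the batched
run is mathematically identical to independent per-track fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .model_core import stationary_distribution

_LOG_2PI = math.log(2.0 * math.pi)


# --------------------------------------------------------------------------
# stacked data container
# --------------------------------------------------------------------------


@dataclass
class StackedTracks:
    """Observation data for all tracks, padded to a common grid length."""

    n_ind: int
    t_len: np.ndarray  # (I,) latent steps per track
    t_max: int
    regime: str  # none | gps | argos
    # concatenated observations across tracks
    obs_ind: np.ndarray  # (N,) individual index
    obs_k: np.ndarray  # (N,) 0-based interval start index
    obs_j: np.ndarray  # (N,) fraction in [0, 1)
    obs_y: np.ndarray  # (N, 2)
    obs_tau: np.ndarray | None  # (N, 2) argos scales
    obs_nu: np.ndarray | None  # (N,)
    omega_inv: np.ndarray | None  # (2, 2) gps
    omega_logdet: float | None
    x_obs_grid: np.ndarray  # (I, Tmax, 2) obs interpolated onto the grid
    anchor: np.ndarray  # (I, 2) first-observation anchor for x1/x2 priors

    @property
    def site_mask(self) -> np.ndarray:
        return np.arange(self.t_max)[None, :] < self.t_len[:, None]


def stack_tracks(tracks, time_step: float) -> StackedTracks:
    """Map observations of each track onto its regular latent grid."""
    n_ind = len(tracks)
    t_len = np.empty(n_ind, dtype=int)
    ks, js, ys, inds, lcs = [], [], [], [], []
    for i, tr in enumerate(tracks):
        t = np.asarray(tr.times, dtype=float) - float(tr.times[0])
        k = np.floor(t / time_step + 1e-9).astype(int)
        j = t / time_step - k
        j[np.abs(j) < 1e-9] = 0.0
        T = int(k[-1] + (2 if j[-1] > 0 else 1))
        T = max(T, 3)
        t_len[i] = T
        ks.append(k)
        js.append(j)
        ys.append(np.asarray(tr.y, dtype=float))
        inds.append(np.full(len(t), i))
        lcs.append(tr.lc if tr.lc is not None else [None] * len(t))
    t_max = int(t_len.max())
    obs_k = np.concatenate(ks)
    obs_j = np.concatenate(js)
    obs_y = np.vstack(ys)
    obs_ind = np.concatenate(inds)

    # interpolate observations onto each grid for initialisation
    x_grid = np.zeros((n_ind, t_max, 2))
    anchor = np.zeros((n_ind, 2))
    for i, tr in enumerate(tracks):
        grid = np.arange(t_len[i]) * time_step
        tt = np.asarray(tr.times, dtype=float) - float(tr.times[0])
        for a in (0, 1):
            x_grid[i, : t_len[i], a] = np.interp(grid, tt, tr.y[:, a])
            x_grid[i, t_len[i]:, a] = x_grid[i, t_len[i] - 1, a]
        anchor[i] = tr.y[0]
    return StackedTracks(
        n_ind=n_ind,
        t_len=t_len,
        t_max=t_max,
        regime="none",
        obs_ind=obs_ind,
        obs_k=obs_k,
        obs_j=obs_j,
        obs_y=obs_y,
        obs_tau=None,
        obs_nu=None,
        omega_inv=None,
        omega_logdet=None,
        x_obs_grid=x_grid,
        anchor=anchor,
    ), lcs


def attach_obs_model(stacked: StackedTracks, lcs, obs_params) -> None:
    """Attach the observation-error regime to a stacked container."""
    stacked.regime = obs_params.regime
    if obs_params.regime == "gps":
        omega = np.asarray(obs_params.omega, dtype=float)
        sign, logdet = np.linalg.slogdet(omega)
        if sign <= 0:
            raise np.linalg.LinAlgError("omega must be positive definite for fitting")
        stacked.omega_inv = np.linalg.inv(omega)
        stacked.omega_logdet = float(logdet)
    elif obs_params.regime == "argos":
        flat_lc = [q for track_lc in lcs for q in track_lc]
        if any(q is None for q in flat_lc):
            raise ValueError("argos regime requires a quality class on every row")
        tau = np.array([obs_params.tau[str(q)] for q in flat_lc], dtype=float)
        nu = np.array([obs_params.nu[str(q)] for q in flat_lc], dtype=float)
        stacked.obs_tau = tau
        stacked.obs_nu = nu


# --------------------------------------------------------------------------
# parameter state
# --------------------------------------------------------------------------


@dataclass
class ParamState:
    """Current values of all continuous parameters.

    Vectors have length P = 1 (shared, joint-estimation form) or
    P = n_ind (per-individual form); ``psi`` is always per individual.
    ``u`` is the ratio gamma2/gamma1 used to enforce the identifiability
    ordering gamma1 > gamma2.
    """

    gamma1: np.ndarray
    u: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    sx: np.ndarray
    sy: np.ndarray
    rho: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    psi: np.ndarray

    @property
    def gamma2(self) -> np.ndarray:
        return self.gamma1 * self.u

    def sigma_inv_terms(self):
        """Per-parameter-set (Sinv_xx, Sinv_xy, Sinv_yy, logdet)."""
        var_x = self.sx**2
        var_y = self.sy**2
        cov = self.rho * self.sx * self.sy
        det = var_x * var_y - cov**2
        return var_y / det, -cov / det, var_x / det, np.log(det)


@dataclass
class Priors:
    """Hyper-parameters of the default prior set (all user-overridable)."""

    sigma_scale: float = 10.0  # half-t scale for per-axis process SDs, km
    sigma_df: float = 3.0
    psi_max: float = 10.0
    anchor_sd: float = 50.0  # vague Gaussian SD on the first two locations, km
    theta1_range: tuple[float, float] = (-np.pi / 2, np.pi / 2)
    theta2_range: tuple[float, float] = (np.pi / 2, 3 * np.pi / 2)


# --------------------------------------------------------------------------
# likelihood pieces (all vectorised over individuals and time)
# --------------------------------------------------------------------------


def process_terms(
    x: np.ndarray,
    b: np.ndarray,
    ps: ParamState,
    pind: np.ndarray,
    valid: np.ndarray,
) -> np.ndarray:
    """Per-step process log densities, shape (I, T-2); padded terms are 0.

    ``b`` holds internal 0/1 state codes; term ``s`` (0-based displacement
    time ``s = it + 2``) is the density of d_s given d_{s-1} and b_s.
    """
    d = x[:, 1:, :] - x[:, :-1, :]
    dprev = d[:, :-1, :]
    dcur = d[:, 1:, :]
    bb = b[:, 2:]
    g = np.where(bb == 0, ps.gamma1[pind][:, None], ps.gamma2[pind][:, None])
    th = np.where(bb == 0, ps.theta1[pind][:, None], ps.theta2[pind][:, None])
    c, s = np.cos(th), np.sin(th)
    mx = g * (c * dprev[..., 0] - s * dprev[..., 1])
    my = g * (s * dprev[..., 0] + c * dprev[..., 1])
    rx = dcur[..., 0] - mx
    ry = dcur[..., 1] - my
    ia, ib, ic, logdet = ps.sigma_inv_terms()
    quad = (
        ia[pind][:, None] * rx**2
        + 2.0 * ib[pind][:, None] * rx * ry
        + ic[pind][:, None] * ry**2
    )
    ll = -_LOG_2PI - 0.5 * logdet[pind][:, None] - 0.5 * quad
    return np.where(valid, ll, 0.0)


def state_emissions(
    x: np.ndarray, ps: ParamState, pind: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Process log densities under both candidate states, (I, T-2, 2)."""
    d = x[:, 1:, :] - x[:, :-1, :]
    dprev = d[:, :-1, :]
    dcur = d[:, 1:, :]
    ia, ib, ic, logdet = ps.sigma_inv_terms()
    out = np.empty(dprev.shape[:2] + (2,))
    for s_idx, (gv, tv) in enumerate(
        ((ps.gamma1, ps.theta1), (ps.gamma2, ps.theta2))
    ):
        g = gv[pind][:, None]
        th = tv[pind][:, None]
        c, s = np.cos(th), np.sin(th)
        mx = g * (c * dprev[..., 0] - s * dprev[..., 1])
        my = g * (s * dprev[..., 0] + c * dprev[..., 1])
        rx = dcur[..., 0] - mx
        ry = dcur[..., 1] - my
        quad = (
            ia[pind][:, None] * rx**2
            + 2.0 * ib[pind][:, None] * rx * ry
            + ic[pind][:, None] * ry**2
        )
        out[..., s_idx] = -_LOG_2PI - 0.5 * logdet[pind][:, None] - 0.5 * quad
    return np.where(valid[..., None], out, 0.0)


def obs_terms(st: StackedTracks, x: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Per-observation log densities, shape (N,)."""
    if st.regime == "none":
        return np.zeros(len(st.obs_k))
    kp1 = np.minimum(st.obs_k + 1, st.t_max - 1)
    j = st.obs_j[:, None]
    mu = (1.0 - j) * x[st.obs_ind, st.obs_k] + j * x[st.obs_ind, kp1]
    r = st.obs_y - mu
    if st.regime == "gps":
        oi = st.omega_inv
        quad = oi[0, 0] * r[:, 0] ** 2 + 2 * oi[0, 1] * r[:, 0] * r[:, 1] + oi[1, 1] * r[:, 1] ** 2
        return -_LOG_2PI - 0.5 * st.omega_logdet - 0.5 * quad
    scale = psi[st.obs_ind][:, None] * st.obs_tau
    nu = st.obs_nu[:, None]
    z = r / scale
    ll = (
        gammaln((nu + 1) / 2)
        - gammaln(nu / 2)
        - 0.5 * np.log(nu * np.pi)
        - np.log(scale)
        - (nu + 1) / 2 * np.log1p(z**2 / nu)
    )
    return ll.sum(axis=1)


def sum_by_individual(values: np.ndarray, ind: np.ndarray, n_ind: int) -> np.ndarray:
    return np.bincount(ind, weights=values, minlength=n_ind)


# --------------------------------------------------------------------------
# FFBS state update
# --------------------------------------------------------------------------


def ffbs(
    emiss: np.ndarray,
    ps: ParamState,
    pind: np.ndarray,
    t_len: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact draw of the state sequences given locations and parameters.

    ``emiss`` is (I, T-2, 2); returns internal 0/1 codes of shape (I, T).
    The initial state prior is the stationary distribution of alpha.
    """
    n_ind, tm2, _ = emiss.shape
    T = tm2 + 2
    a1 = ps.alpha1[pind]
    a2 = ps.alpha2[pind]
    with np.errstate(divide="ignore"):
        logA = np.log(
            np.stack(
                [
                    np.stack([a1, 1.0 - a1], axis=-1),
                    np.stack([a2, 1.0 - a2], axis=-1),
                ],
                axis=1,
            )
        )  # (I, from, to)
        switch = (1.0 - a1) + a2
        pi1 = np.where(switch > 0, a2 / np.where(switch > 0, switch, 1.0), 0.5)
        logpi = np.log(np.stack([pi1, 1.0 - pi1], axis=-1))

    logf = np.empty((n_ind, T, 2))
    logf[:, 0] = logpi
    for t in range(1, T):
        pred = np.logaddexp(
            logf[:, t - 1, 0, None] + logA[:, 0, :],
            logf[:, t - 1, 1, None] + logA[:, 1, :],
        )
        if t >= 2:
            pred = pred + emiss[:, t - 2, :]
        # guard against joint underflow on long padded stretches
        pred -= pred.max(axis=1, keepdims=True)
        logf[:, t] = pred

    b = np.zeros((n_ind, T), dtype=np.int8)
    rows = np.arange(n_ind)
    us = rng.random((n_ind, T))
    for t in range(T - 1, -1, -1):
        logp = logf[:, t, :].copy()
        has_next = t < t_len - 1
        if has_next.any():
            nxt = b[:, t + 1].astype(int)
            logp += np.where(has_next[:, None], logA[rows, :, nxt], 0.0)
        p0 = expit(logp[:, 0] - logp[:, 1])
        draw = (us[:, t] >= p0).astype(np.int8)
        active = t <= t_len - 1
        b[:, t] = np.where(active, draw, 0)
    return b


# --------------------------------------------------------------------------
# the Gibbs sampler
# --------------------------------------------------------------------------


@dataclass
class AdaptiveScales:
    gamma1: np.ndarray
    u: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    sigma: np.ndarray
    psi: np.ndarray
    loc: float

    @classmethod
    def fresh(cls, n_par: int, n_ind: int, loc_scale: float) -> "AdaptiveScales":
        return cls(
            gamma1=np.full(n_par, math.log(0.05)),
            u=np.full(n_par, math.log(0.1)),
            theta1=np.full(n_par, math.log(0.1)),
            theta2=np.full(n_par, math.log(0.1)),
            sigma=np.full(n_par, math.log(0.1)),
            psi=np.full(n_ind, math.log(0.2)),
            loc=math.log(loc_scale),
        )


class GibbsSampler:
    """One-chain sampler over stacked tracks.

    Parameters are shared across tracks when ``shared`` is true
    (joint-estimation / hSSM form) and per-track otherwise (SSM form).
    """

    TARGET_SCALAR = 0.44
    TARGET_BLOCK = 0.30

    def __init__(
        self,
        stacked: StackedTracks,
        shared: bool,
        priors: Priors,
        estimate_psi: bool = True,
        sample_locations: bool | None = None,
    ):
        self.st = stacked
        self.shared = shared
        self.priors = priors
        self.n_ind = stacked.n_ind
        self.n_par = 1 if shared else stacked.n_ind
        self.pind = (
            np.zeros(self.n_ind, dtype=int) if shared else np.arange(self.n_ind)
        )
        # number of valid process terms per parameter set (for bookkeeping)
        self.valid = (
            np.arange(stacked.t_max - 2)[None, :] + 2 < stacked.t_len[:, None]
        )
        self.estimate_psi = estimate_psi and stacked.regime == "argos"
        if sample_locations is None:
            sample_locations = stacked.regime != "none"
        self.sample_locations = sample_locations
        loc_scale = 0.1
        if stacked.regime == "argos" and stacked.obs_tau is not None:
            loc_scale = float(np.median(stacked.obs_tau))
        self.scales = AdaptiveScales.fresh(self.n_par, self.n_ind, loc_scale)
        self._adapt_count = 0
        self.adapting = True
        self.accept_stats: dict[str, list] = {}

    # -- initialisation ----------------------------------------------------

    def initialize(self, rng: np.random.Generator):
        """Over-dispersed initial values: parameters drawn from their priors.

        Latent locations start at the observations interpolated onto the
        grid plus a small jitter; initial states are assigned by
        thresholding empirical step lengths at their median so that both
        states are represented.
        """
        pr = self.priors
        P = self.n_par
        sd_draw = np.abs(
            pr.sigma_scale * rng.standard_t(df=pr.sigma_df, size=(2, P))
        )
        sd_draw = np.clip(sd_draw, 0.05, 100.0)
        self.params = ParamState(
            gamma1=rng.uniform(0.0, 1.0, P),
            u=rng.uniform(0.0, 1.0, P),
            theta1=rng.uniform(*pr.theta1_range, P),
            theta2=rng.uniform(*pr.theta2_range, P),
            sx=sd_draw[0],
            sy=sd_draw[1],
            rho=rng.uniform(-1.0, 1.0, P),
            alpha1=rng.beta(1.0, 1.0, P),
            alpha2=rng.beta(1.0, 1.0, P),
            psi=rng.uniform(0.0, pr.psi_max, self.n_ind)
            if self.estimate_psi
            else np.ones(self.n_ind),
        )
        self.x = self.st.x_obs_grid.copy()
        if self.sample_locations:
            self.x += 0.1 * rng.standard_normal(self.x.shape)
        # step-length threshold initial states
        d = np.linalg.norm(self.x[:, 1:, :] - self.x[:, :-1, :], axis=-1)
        self.b = np.zeros((self.n_ind, self.st.t_max), dtype=np.int8)
        for i in range(self.n_ind):
            steps = d[i, : self.st.t_len[i] - 1]
            med = np.median(steps)
            self.b[i, 1 : self.st.t_len[i]] = (steps < med).astype(np.int8)
            self.b[i, 0] = self.b[i, 1]

    # -- likelihood caches -------------------------------------------------

    def _pll_by_set(self, x=None, b=None, ps=None) -> np.ndarray:
        """Process loglik summed per parameter set, shape (P,)."""
        x = self.x if x is None else x
        b = self.b if b is None else b
        ps = self.params if ps is None else ps
        terms = process_terms(x, b, ps, self.pind, self.valid)
        by_ind = terms.sum(axis=1)
        if self.shared:
            return np.array([by_ind.sum()])
        return by_ind

    def _oll_by_ind(self, x=None, psi=None) -> np.ndarray:
        x = self.x if x is None else x
        psi = self.params.psi if psi is None else psi
        vals = obs_terms(self.st, x, psi)
        return sum_by_individual(vals, self.st.obs_ind, self.n_ind)

    # -- adaptation --------------------------------------------------------

    def _adapt(self, name: str, accepted, target: float):
        if not self.adapting:
            return
        rate = min(0.25, 5.0 / max(self._adapt_count, 20))
        cur = getattr(self.scales, name)
        if np.isscalar(cur) or np.ndim(cur) == 0:
            setattr(self.scales, name, cur + rate * (float(np.mean(accepted)) - target))
        else:
            setattr(self.scales, name, cur + rate * (accepted.astype(float) - target))

    # -- parameter updates -------------------------------------------------

    def _mh_scalar(self, name: str, lo, hi, rng, extra_logprior=None):
        """Random-walk MH on one box-constrained parameter vector (P,)."""
        ps = self.params
        cur = getattr(ps, name)
        step = np.exp(getattr(self.scales, name))
        prop = cur + step * rng.standard_normal(self.n_par)
        ok = (prop > lo) & (prop < hi)
        cand = np.where(ok, prop, cur)
        trial = ParamState(**{**ps.__dict__, name: cand})
        pll_cur = self._pll_by_set()
        pll_new = self._pll_by_set(ps=trial)
        delta = pll_new - pll_cur
        if extra_logprior is not None:
            delta = delta + extra_logprior(cand) - extra_logprior(cur)
        accept = ok & (np.log(rng.random(self.n_par)) < delta)
        setattr(ps, name, np.where(accept, cand, cur))
        self._adapt(name, accept, self.TARGET_SCALAR)
        return accept

    def update_movement_params(self, rng: np.random.Generator):
        self._mh_scalar("gamma1", 0.0, 1.0, rng)
        self._mh_scalar("u", 0.0, 1.0, rng)
        self._mh_scalar("theta1", *self.priors.theta1_range, rng)
        self._mh_scalar("theta2", *self.priors.theta2_range, rng)
        self._update_sigma(rng)
        self._update_alpha(rng)
        if self.estimate_psi:
            self._update_psi(rng)

    def _update_sigma(self, rng):
        ps = self.params
        pr = self.priors
        step = np.exp(self.scales.sigma)
        z = np.arctanh(np.clip(ps.rho, -0.999999, 0.999999))
        prop = np.stack([np.log(ps.sx), np.log(ps.sy), z]) + step * rng.standard_normal(
            (3, self.n_par)
        )
        sx_new = np.exp(prop[0])
        sy_new = np.exp(prop[1])
        rho_new = np.tanh(prop[2])
        trial = ParamState(**{**ps.__dict__, "sx": sx_new, "sy": sy_new, "rho": rho_new})
        delta = self._pll_by_set(ps=trial) - self._pll_by_set()
        # half-t prior on the SDs plus log-scale Jacobian; uniform prior on
        # rho plus tanh Jacobian
        def logp(sx, sy, rho):
            lp = _half_t_logpdf(sx, pr.sigma_df, pr.sigma_scale) + np.log(sx)
            lp += _half_t_logpdf(sy, pr.sigma_df, pr.sigma_scale) + np.log(sy)
            lp += np.log1p(-rho**2)
            return lp

        delta += logp(sx_new, sy_new, rho_new) - logp(ps.sx, ps.sy, ps.rho)
        accept = np.log(rng.random(self.n_par)) < delta
        ps.sx = np.where(accept, sx_new, ps.sx)
        ps.sy = np.where(accept, sy_new, ps.sy)
        ps.rho = np.where(accept, rho_new, ps.rho)
        self._adapt("sigma", accept, self.TARGET_BLOCK)

    def _update_alpha(self, rng):
        """Conjugate-proposal independence MH for the transition probabilities.

        Beta(1 + transitions) proposals are exact for the conditional given
        the transition counts; the MH correction accounts for the
        alpha-dependent stationary prior on the initial states.
        """
        ps = self.params
        b = self.b
        counts = np.zeros((self.n_par, 2, 2))
        b0 = np.empty(self.n_ind, dtype=int)
        for i in range(self.n_ind):
            T = self.st.t_len[i]
            frm = b[i, : T - 1]
            to = b[i, 1:T]
            p = self.pind[i]
            np.add.at(counts[p], (frm.astype(int), to.astype(int)), 1)
            b0[i] = b[i, 0]
        a1_new = rng.beta(1.0 + counts[:, 0, 0], 1.0 + counts[:, 0, 1])
        a2_new = rng.beta(1.0 + counts[:, 1, 0], 1.0 + counts[:, 1, 1])

        def log_pi0(a1, a2):
            switch = (1.0 - a1) + a2
            pi1 = np.where(switch > 0, a2 / np.where(switch > 0, switch, 1.0), 0.5)
            pi = np.stack([pi1, 1.0 - pi1], axis=-1)
            with np.errstate(divide="ignore"):
                lp = np.log(np.clip(pi, 1e-300, None))
            out = np.zeros(self.n_par)
            np.add.at(out, self.pind, lp[self.pind, b0])
            return out

        delta = log_pi0(a1_new, a2_new) - log_pi0(ps.alpha1, ps.alpha2)
        accept = np.log(rng.random(self.n_par)) < delta
        ps.alpha1 = np.where(accept, a1_new, ps.alpha1)
        ps.alpha2 = np.where(accept, a2_new, ps.alpha2)

    def _update_psi(self, rng):
        ps = self.params
        step = np.exp(self.scales.psi)
        prop = ps.psi + step * rng.standard_normal(self.n_ind)
        ok = (prop > 0) & (prop < self.priors.psi_max)
        cand = np.where(ok, prop, ps.psi)
        delta = self._oll_by_ind(psi=cand) - self._oll_by_ind()
        accept = ok & (np.log(rng.random(self.n_ind)) < delta)
        ps.psi = np.where(accept, cand, ps.psi)
        self._adapt("psi", accept, self.TARGET_SCALAR)

    # -- latent updates ----------------------------------------------------

    def update_states(self, rng):
        emiss = state_emissions(self.x, self.params, self.pind, self.valid)
        self.b = ffbs(emiss, self.params, self.pind, self.st.t_len, rng)

    def update_locations(self, rng):
        if not self.sample_locations:
            return
        st = self.st
        T = st.t_max
        scale = math.exp(self.scales.loc)
        site_mask = st.site_mask
        acc_rates = []
        pr = self.priors
        for c in range(3):
            color = np.zeros(T, dtype=bool)
            color[c::3] = True
            upd = site_mask & color[None, :]
            prop = self.x + np.where(
                upd[..., None], scale * rng.standard_normal(self.x.shape), 0.0
            )
            cur_t = process_terms(self.x, self.b, self.params, self.pind, self.valid)
            new_t = process_terms(prop, self.b, self.params, self.pind, self.valid)
            dterm = new_t - cur_t  # (I, T-2), term s at index s-2
            # term s involves sites s, s-1, s-2; exactly one is in the colour
            # class, namely u = s - ((s - c) mod 3).  Equivalently site u
            # collects terms u, u+1, u+2.
            padded = np.zeros((self.n_ind, T + 2))
            padded[:, 2:T] = dterm
            site_delta = padded[:, :T] + padded[:, 1 : T + 1] + padded[:, 2 : T + 2]
            delta = np.where(upd, site_delta, -np.inf)
            # observation terms
            if st.regime != "none":
                cur_o = obs_terms(st, self.x, self.params.psi)
                new_o = obs_terms(st, prop, self.params.psi)
                k = st.obs_k
                kp1 = np.minimum(k + 1, T - 1)
                touch = np.where(
                    color[k], k, np.where(color[kp1] & (st.obs_j > 0), kp1, -1)
                )
                sel = touch >= 0
                np.add.at(
                    delta, (st.obs_ind[sel], touch[sel]), (new_o - cur_o)[sel]
                )
            # vague anchors on the first two latent locations
            for s0 in range(2):
                if color[s0]:
                    r_new = prop[:, s0, :] - st.anchor
                    r_cur = self.x[:, s0, :] - st.anchor
                    danch = (
                        (r_cur**2).sum(axis=1) - (r_new**2).sum(axis=1)
                    ) / (2.0 * pr.anchor_sd**2)
                    delta[:, s0] += danch
            accept = np.log(rng.random((self.n_ind, T))) < delta
            accept &= upd
            self.x = np.where(accept[..., None], prop, self.x)
            acc_rates.append(accept.sum() / max(upd.sum(), 1))
        self._adapt("loc", np.mean(acc_rates), self.TARGET_SCALAR)

    # -- one full sweep ----------------------------------------------------

    def sweep(self, rng):
        self._adapt_count += 1
        self.update_states(rng)
        self.update_locations(rng)
        self.update_movement_params(rng)


def _half_t_logpdf(x, df, scale):
    return (
        math.log(2.0)
        + gammaln((df + 1) / 2)
        - gammaln(df / 2)
        - 0.5 * np.log(df * np.pi * scale**2)
        - (df + 1) / 2 * np.log1p((x / scale) ** 2 / df)
    )
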