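"""Tests of regularisation, the joint posterior, state sampling and fitting."""

import math

import numpy as np
import pytest
from scipy import stats

from switchssm.evaluation import hpdi, summarise_states, state_rmse
from switchssm.inference import (
    FitConfig,
    filter_gaps,
    fit,
    initialize_chain,
    joint_log_posterior,
    map_observations_to_steps,
    sample_states_conditional,
)
from switchssm.io import Track
from switchssm.model_core import (
    LatentPath,
    ObsParams,
    ProcessParams,
    build_transition_matrix,
    obs_logdensity_gaussian,
    process_logdensity,
    stationary_distribution,
)
from switchssm.simulator import simulate_scenario, table_scenario


def tracks_from_simulated(sim_tracks):
    return [Track(ident=t.track_id, times=t.times, y=t.y, lc=t.lc) for t in sim_tracks]


class TestRegularisation:
    def test_grid_time_maps_to_interval_start(self):
        m = map_observations_to_steps([0.0, 6.0, 12.0], 0.0, 6.0)
        assert np.array_equal(m.interval, [1, 2, 3])
        assert np.allclose(m.frac, 0.0)

    def test_midpoint_of_fourth_interval(self):
        # 3 h into interval 4 at a 6 h step
        m = map_observations_to_steps([21.0], 0.0, 6.0)
        assert m.interval[0] == 4
        assert np.isclose(m.frac[0], 0.5)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            map_observations_to_steps([3.0, 1.0], 0.0, 6.0)

    def test_seal_like_rate_two_obs_per_step(self, rng):
        """8.5 locations/day at a 6 h step gives about two obs per interval."""
        duration_h = 50 * 24.0
        n = rng.poisson(8.5 * 50)
        times = np.sort(rng.uniform(0, duration_h, n))
        m = map_observations_to_steps(times, 0.0, 6.0)
        per_step = len(times) / m.interval.max()
        assert 1.6 < per_step < 2.7  # nominal 8.5/24*6 = 2.125


class TestFilterGaps:
    def make_track(self, gap_days):
        times = np.concatenate([[0.0], np.cumsum(np.asarray(gap_days) * 24.0)])
        y = np.column_stack([np.arange(len(times)), np.zeros(len(times))])
        return Track(ident="t", times=times, y=y)

    def test_no_gap_unchanged(self):
        tr = self.make_track([1, 1, 1, 1])
        out = filter_gaps(tr, max_gap=4.0)
        assert len(out) == 5 and out.n_dropped == 0

    def test_single_gap_keeps_longer_side(self):
        tr = self.make_track([1, 1, 5, 1, 1, 1])
        out = filter_gaps(tr, max_gap=4.0)
        assert len(out) == 4
        assert np.allclose(out.y[:, 0], [3, 4, 5, 6])

    def test_enumerated_runs_keep_six_point_tail(self):
        tr = self.make_track([1, 1, 1, 5, 1, 1, 1, 1, 1])
        out = filter_gaps(tr, max_gap=4.0)
        assert len(out) == 6
        assert out.n_dropped == 4
        assert out.times[0] == 0.0  # re-zeroed

    def test_everything_gapped_rejected(self):
        tr = self.make_track([5, 6, 7])
        with pytest.raises(ValueError):
            filter_gaps(tr, max_gap=4.0)


class TestRetainedDrawArithmetic:
    @pytest.mark.parametrize(
        "n_iter, n_burnin, thin, expected_per_chain",
        [(60_000, 40_000, 20, 1000), (1000, 400, 7, 85), (11, 10, 1, 1)],
    )
    def test_floor_rule(self, n_iter, n_burnin, thin, expected_per_chain):
        cfg = FitConfig(n_iter=n_iter, n_burnin=n_burnin, thin=thin)
        assert cfg.retained_per_chain == expected_per_chain
        assert cfg.retained_total == 2 * expected_per_chain

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            FitConfig(thin=0)
        with pytest.raises(ValueError):
            FitConfig(n_chains=1)


def toy_setup(T=4, seed=0, regime="gps"):
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(0, 2, size=(T, 2)), axis=0)
    b = np.array([1, 2, 1, 1])[:T]
    lat = LatentPath(x=x, b=b)
    y = x + rng.normal(0, 0.05, size=(T, 2))
    track = Track(ident="toy", times=np.arange(T, dtype=float), y=y)
    params = {
        "gamma1": 0.8,
        "gamma2": 0.2,
        "theta1": 0.1,
        "theta2": 3.0,
        "alpha1": 0.85,
        "alpha2": 0.15,
        "sigma_x": 2.0,
        "sigma_y": 1.5,
        "rho": 0.2,
    }
    obs = (
        ObsParams(regime="gps", omega=np.eye(2) * 0.05**2)
        if regime == "gps"
        else ObsParams(regime="none")
    )
    return lat, params, track, obs


class TestJointLogPosterior:
    def test_term_by_term_oracle(self):
        """Hand-summed process + chain + obs + anchor + prior terms on T=4."""
        lat, p, track, obs = toy_setup()
        cfg = FitConfig(n_iter=10, n_burnin=5)
        got = joint_log_posterior([lat], p, [track], cfg, obs=obs)

        pp = ProcessParams(
            gamma=(p["gamma1"], p["gamma2"]),
            theta=(p["theta1"], p["theta2"]),
            sigma=np.array(
                [
                    [p["sigma_x"] ** 2, p["rho"] * p["sigma_x"] * p["sigma_y"]],
                    [p["rho"] * p["sigma_x"] * p["sigma_y"], p["sigma_y"] ** 2],
                ]
            ),
            alpha=build_transition_matrix(p["alpha1"], p["alpha2"]),
        )
        pi = stationary_distribution(pp.alpha)
        expected = math.log(pi[lat.b[0] - 1])
        for t in range(1, 4):
            expected += math.log(pp.alpha[lat.b[t - 1] - 1, lat.b[t] - 1])
        for t in range(2, 4):
            expected += process_logdensity(lat.x[t], lat.x[t - 1], lat.x[t - 2], lat.b[t], pp)
        for t in range(4):
            expected += obs_logdensity_gaussian(track.y[t], lat.x[t], obs.omega)
        pr = cfg.priors
        for s in range(2):
            r = lat.x[s] - track.y[0]
            expected += stats.multivariate_normal(
                mean=track.y[0], cov=np.eye(2) * pr.anchor_sd**2
            ).logpdf(lat.x[s])
        # priors: 1/gamma1 (ordered-pair density), uniform thetas, half-t SDs,
        # uniform rho; Beta(1,1) alphas contribute 0
        expected += -math.log(p["gamma1"])
        expected += -math.log(np.pi) * 2
        for sd in (p["sigma_x"], p["sigma_y"]):
            expected += math.log(2) + stats.t.logpdf(sd, df=3, scale=pr.sigma_scale)
        expected += -math.log(2)
        assert np.isclose(got, expected, rtol=1e-10)

    def test_additivity_over_individuals(self):
        lat1, p, tr1, obs = toy_setup(seed=1)
        lat2, _, tr2, _ = toy_setup(seed=2)
        cfg = FitConfig(n_iter=10, n_burnin=5)
        lp1 = joint_log_posterior([lat1], p, [tr1], cfg, obs=obs)
        lp2 = joint_log_posterior([lat2], p, [tr2], cfg, obs=obs)
        lp12 = joint_log_posterior([lat1, lat2], p, [tr1, tr2], cfg, obs=obs)
        # adding an individual adds exactly its likelihood contribution
        # (the shared prior is charged once)
        assert np.isclose(lp12 - lp1, lp2 - _prior_only(p, cfg), rtol=1e-10)

    def test_singleton_ssm_equals_hssm(self):
        lat, p, tr, obs = toy_setup(seed=3)
        cfg = FitConfig(n_iter=10, n_burnin=5)
        shared = joint_log_posterior([lat], p, [tr], cfg, obs=obs)
        per_ind = joint_log_posterior([lat], [p], [tr], cfg, obs=obs)
        assert np.isclose(shared, per_ind)

    @pytest.mark.parametrize(
        "bad",
        [
            {"gamma1": 0.2, "gamma2": 0.8},  # ordering violated
            {"alpha1": 1.4},
            {"sigma_x": -1.0},
            {"rho": 1.5},
            {"theta1": 2.0},  # outside transient prior range
        ],
    )
    def test_out_of_support_is_minus_inf(self, bad):
        lat, p, tr, obs = toy_setup()
        p.update(bad)
        cfg = FitConfig(n_iter=10, n_burnin=5)
        assert joint_log_posterior([lat], p, [tr], cfg, obs=obs) == -np.inf


def _prior_only(p, cfg):
    """Prior terms as charged by joint_log_posterior for a shared set."""
    pr = cfg.priors
    lp = -math.log(p["gamma1"]) - 2 * math.log(np.pi) - math.log(2)
    for sd in (p["sigma_x"], p["sigma_y"]):
        lp += math.log(2) + stats.t.logpdf(sd, df=3, scale=pr.sigma_scale)
    return lp


class TestStateConditional:
    def params(self, **over):
        kw = dict(
            gamma=(0.9, 0.2),
            theta=(0.0, np.pi),
            sigma=np.eye(2) * 2,
            alpha=build_transition_matrix(0.85, 0.2),
        )
        kw.update(over)
        return ProcessParams(**kw)

    def test_uninformative_emissions_recover_prior_marginals(self, rng):
        """Identical movement in both states: marginals equal the chain prior."""
        p = self.params(gamma=(0.5, 0.5), theta=(0.3, 0.3))
        x = np.cumsum(rng.normal(0, 1, (8, 2)), axis=0)
        draws = sample_states_conditional(x, p, rng=rng, n_draws=4000)
        # stationary marginal of the asymmetric chain
        pi1 = stationary_distribution(p.alpha)[0]
        freq = (draws == 1).mean(axis=0)
        assert np.all(np.abs(freq - pi1) < 0.04)

    def test_absorbing_chain_constant_sequences(self, rng):
        p = self.params(alpha=np.eye(2))
        x = np.cumsum(rng.normal(0, 1, (6, 2)), axis=0)
        draws = sample_states_conditional(x, p, rng=rng, n_draws=200)
        assert np.all(draws.min(axis=1) == draws.max(axis=1))

    def test_matches_enumeration_on_toy_track(self, rng):
        """Monte Carlo marginals vs exact 2^T enumeration, T = 6."""
        from itertools import product

        p = self.params()
        T = 6
        x = np.cumsum(rng.normal(0, 1.5, (T, 2)), axis=0)
        pi = stationary_distribution(p.alpha)
        seqs = list(product([1, 2], repeat=T))
        logps = []
        for seq in seqs:
            lp = math.log(pi[seq[0] - 1])
            for t in range(1, T):
                lp += math.log(p.alpha[seq[t - 1] - 1, seq[t] - 1])
            for t in range(2, T):
                lp += process_logdensity(x[t], x[t - 1], x[t - 2], seq[t], p)
            logps.append(lp)
        w = np.exp(np.array(logps) - max(logps))
        w /= w.sum()
        exact = np.array(
            [sum(wi for wi, s in zip(w, seqs) if s[t] == 2) for t in range(T)]
        )
        draws = sample_states_conditional(x, p, rng=rng, n_draws=10_000)
        mc = (draws == 2).mean(axis=0)
        assert np.max(np.abs(mc - exact)) < 0.02


class TestInitialisation:
    def test_deterministic_given_seed_and_chain(self, errorfree_tracks):
        _, tracks, scen = errorfree_tracks
        cfg = FitConfig(n_iter=100, n_burnin=50, seed=9)
        a = initialize_chain(tracks, cfg, 0, obs=scen.obs)
        b = initialize_chain(tracks, cfg, 0, obs=scen.obs)
        assert a.params.gamma1 == b.params.gamma1
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.b, b.b)

    def test_chains_overdispersed(self, errorfree_tracks):
        _, tracks, scen = errorfree_tracks
        cfg = FitConfig(n_iter=100, n_burnin=50, seed=9)
        a = initialize_chain(tracks, cfg, 0, obs=scen.obs)
        b = initialize_chain(tracks, cfg, 1, obs=scen.obs)
        assert not np.isclose(a.params.gamma1[0], b.params.gamma1[0])

    def test_both_states_initially_represented(self, errorfree_tracks):
        _, tracks, scen = errorfree_tracks
        cfg = FitConfig(n_iter=100, n_burnin=50, seed=9)
        s = initialize_chain(tracks, cfg, 0, obs=scen.obs)
        for i in range(len(tracks)):
            states = s.b[i, : s.st.t_len[i]]
            assert {0, 1} <= set(states.tolist())


class TestFit:
    def test_bookkeeping_and_shapes(self, errorfree_tracks):
        _, tracks, scen = errorfree_tracks
        cfg = FitConfig(
            model_form="hssm", n_iter=60, n_burnin=20, thin=4, seed=2
        )
        draws = fit(tracks, cfg, obs=scen.obs)
        assert draws.n_chains == 2
        assert draws.n_draws == cfg.retained_per_chain == 10
        assert draws.get("gamma1").shape == (2, 10)
        b = draws.states_for(0)
        assert b.shape == (2, 10, 80)
        assert set(np.unique(b)) <= {1, 2}

    def test_errorfree_recovery_smoke(self, errorfree_tracks):
        """Posterior concentrates near the simulating values (loose bands)."""
        sim, tracks, scen = errorfree_tracks
        cfg = FitConfig(model_form="hssm", n_iter=900, n_burnin=400, thin=2, seed=5)
        draws = fit(tracks, cfg, obs=scen.obs)
        assert abs(draws.get("gamma1").mean() - 0.95) < 0.15
        assert abs(draws.get("gamma2").mean() - 0.10) < 0.15
        rmse = state_rmse(summarise_states(draws, 0), sim[0].truth.b)
        assert rmse < 0.45

    def test_ssm_singleton_matches_hssm(self, errorfree_tracks):
        """One individual: per-individual and joint forms share a posterior."""
        sim, tracks, scen = errorfree_tracks
        intervals = {}
        for form in ("ssm", "hssm"):
            cfg = FitConfig(model_form=form, n_iter=900, n_burnin=400, thin=2, seed=3)
            draws = fit(tracks[:1], cfg, obs=scen.obs)
            intervals[form] = hpdi(draws.get("gamma1", individual=None
                                             if form == "hssm" else 0), 0.95)
        lo = max(intervals["ssm"][0], intervals["hssm"][0])
        hi = min(intervals["ssm"][1], intervals["hssm"][1])
        assert lo < hi  # overlapping 95% HPDIs

    def test_irregular_time_fit_runs(self, rng):
        """Irregularly timed observations fit on a 6 h latent grid."""
        from switchssm.simulator import irregularize, simulate_path
        from switchssm.simulator import table_scenario

        scen = table_scenario("large", "gps", n_tracks=1, track_length=120, seed=21)
        path = simulate_scenario_path(scen, rng)
        times, xs = irregularize(path, mean_rate=8.5, rng=rng)
        y = xs + rng.normal(0, 0.05, xs.shape)
        track = Track(ident="irr", times=times, y=y)
        cfg = FitConfig(
            model_form="hssm", time_step=6.0, n_iter=200, n_burnin=100, thin=2, seed=4
        )
        draws = fit([track], cfg, obs=scen.obs)
        expected_T = int(np.floor(times[-1] / 6.0)) + 1 + (
            1 if (times[-1] / 6.0) % 1 > 0 else 0
        )
        assert draws.states_for(0).shape[-1] == expected_T
        assert np.isfinite(draws.get("gamma1")).all()

    def test_psi_concentrates_near_one(self):
        """Argos data simulated with the packaged, un-rescaled tau table."""
        scen = table_scenario("large", "argos", n_tracks=3, track_length=100, seed=13)
        sim = simulate_scenario(scen)
        tracks = tracks_from_simulated(sim)
        cfg = FitConfig(model_form="hssm", n_iter=1200, n_burnin=600, thin=3, seed=6)
        draws = fit(tracks, cfg, obs=scen.obs)
        psi_mean = draws.params["psi"].mean()
        assert 0.6 < psi_mean < 1.5


def simulate_scenario_path(scen, rng):
    from switchssm.simulator import simulate_path

    return simulate_path(scen.track_length, scen.params, rng=rng)
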