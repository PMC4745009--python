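# switchssm

Switching correlated-random-walk state-space models for animal movement
telemetry: simulate two-state movement tracks with realistic location error,
fit them by Bayesian MCMC either per individual (SSM) or jointly across
individuals (hSSM), and score behavioural-state estimates against known
truth.

## The problem

Electronic tags record animal locations, not behaviour.  Behavioural
switching models recover behaviour by assuming movement alternates between
discrete states with different dynamics — here a fast, directionally
persistent *transient* state and a slow, frequently reversing
*area-restricted search* (ARS) state, the classic signature of foraging.
Location data range from near-exact GPS fixes to Argos satellite fixes with
heavy-tailed, quality-class-dependent errors and irregular timing, so the
movement process and the observation process must be modelled jointly.

The package exists to make one methodological point measurable: estimating
movement parameters *jointly* across individuals (identical-parameter
pooling, the hSSM) sharpens behavioural-state inference relative to fitting
each track alone (the SSM), and the gain is largest when location errors
are heavy-tailed.

## The model

True locations x_t on a regular time grid move through their displacements
d_t = x_t − x_{t−1}:

    d_t | d_{t−1}, b_t ~ N₂( γ_{b_t} T(θ_{b_t}) d_{t−1}, Σ )

with per-state move persistence γ ∈ [0, 1] and turn-angle rotation T(θ);
the state sequence b_t ∈ {transient, ARS} follows a first-order Markov
chain with transition matrix α.  Observations are exact, Gaussian
(y_t ~ N₂(x_t, Ω), GPS-like) or per-axis location-scale t with
class-specific scale τ_q and df ν_q rescaled by a per-individual factor ψ
(Argos-like); irregularly timed fixes are tied to the grid by straight-line
interpolation between bracketing latent locations.  Inference is
Metropolis-within-Gibbs with exact forward-filtering backward-sampling for
the states.  Accuracy is summarised by the RMSE between per-time posterior
mean states (continuous in [1, 2], carrying uncertainty) and simulated
truth; Cohen's kappa on posterior-median states is also provided.  See
`docs/methods.md` for priors, sampler details and design choices.

## Worked example

```python
import numpy as np
from switchssm import FitConfig, Track, fit, state_rmse, summarise_states, table_scenario
from switchssm.simulator import simulate_scenario

scenario = table_scenario("large", "gps", n_tracks=5, track_length=100, seed=42)
sim = simulate_scenario(scenario)
tracks = [Track(ident=t.track_id, times=t.times, y=t.y) for t in sim]

config = FitConfig(model_form="hssm", n_iter=4000, n_burnin=2000, thin=4, seed=7)
draws = fit(tracks, config, obs=scenario.obs)

for name, truth in [("gamma1", 0.95), ("gamma2", 0.10), ("alpha1", 0.90), ("alpha2", 0.10)]:
    post = draws.get(name)
    print(f"{name}: posterior mean {post.mean():.3f} (truth {truth})")
rmse = [state_rmse(summarise_states(draws, i), sim[i].truth.b) for i in range(len(sim))]
print(f"behavioural-state RMSE per track: {np.round(rmse, 3)}")
```

Output (about a minute on one core):

```
gamma1: posterior mean 0.965 (truth 0.95)
gamma2: posterior mean 0.066 (truth 0.1)
alpha1: posterior mean 0.923 (truth 0.9)
alpha2: posterior mean 0.084 (truth 0.1)
behavioural-state RMSE per track: [0.218 0.173 0.184 0.281 0.284]
```

The movement parameters are recovered from five 100-step GPS tracks, and
the per-track RMSE (0 = perfect state recovery, 0.5 = pure uncertainty)
shows the states are well resolved under the large persistence contrast.

A command-line surface wraps the same machinery:

```bash
switchssm simulate --config scenario.yaml --out sim/ --seed 3
switchssm fit --model hssm --tracks sim/tracks.csv --out fit/ --seed 1
switchssm evaluate --fits fit/ --truth sim/truth.csv --out rmse.csv
switchssm reproduce-study --scale desk --out study/ --seed 0
```

`reproduce-study` runs the six-scenario comparison (persistence contrast
Δγ ∈ {0.55, 0.85} × error ∈ {none, GPS, Argos}) with hSSM and SSM arms and
writes tidy per-track RMSE tables plus boxplots; `--scale desk` uses the
documented scaled-down protocol, `--scale paper` the full 50-track design
(days of CPU).

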