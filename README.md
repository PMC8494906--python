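# opencamscr

Spatial capture–recapture (SCR) toolkit for grid-based camera-trap
surveys of individually identifiable carnivores, built around the design
of a decade-long Eurasian lynx (*Lynx lynx*) monitoring programme in the
Bohemian Forest Ecosystem: a 2.7 × 2.7 km grid with a paired-camera site
in every second cell, yearly 100-day sampling sessions with daily
occasions, and auxiliary records of unmarked prey and mesopredator
species.

The package is aimed at wildlife ecologists who want to estimate
**density, survival, recruitment and population growth** from photo
identification data, and at methodologists who want a transparent,
fully seeded implementation of the underlying models to simulate and
stress-test.

## What it implements

- **Data model and I/O** (`capture_data`): detector/effort/capture CSVs,
  robust-design detection histories (individual × site × day × year,
  at most one detection per site per day), 5-day occasion collapsing for
  closed-model sessions, plain-text history interchange.
- **Habitat mask** (`statespace`): rectangular buffered state space with
  exact area bookkeeping and the 3σ buffer-width check.
- **Synthetic survey generator** (`simulate`): open-population SCR
  process with sex-specific half-normal detection
  (p = g₀·exp(−d²/2σ²) per day), yearly survival φ and per-capita
  recruitment γ per sex, Markovian activity-centre relocation, effort
  masking, and unmarked-species photo streams. Defaults reproduce the
  survey's reported parameter values and design dimensions.
- **Open-population Bayesian SCR** (`scr_open`): data augmentation to a
  super-population of size M, exact-enumeration updates of contiguous
  alive runs (no revival), latent sexes, truncated-bivariate-normal
  movement, numba-compiled Metropolis-within-Gibbs; derived abundance
  N_t, density D_t, realised growth λ_t = N_{t+1}/N_t and sex ratio per
  posterior draw; posterior-mode point estimates and 95% HPD intervals.
- **Closed-population maximum-likelihood SCR** (`scr_closed`): full
  (Poisson-n) likelihood over the mask for proximity detectors with
  effort-compounded occasions, null and sex-mixture (hybrid `pmix`)
  model structures, AICc selection and Akaike-weight model averaging of
  density.
- **Convergence diagnostics** (`diagnostics`): Gelman–Rubin PSRF with
  97.5% upper confidence limits (pass rule: upper < 1.1), numerically
  matching the standard R implementation.
- **Relative abundance index** (`rai`): 10-minute rolling-gap event
  de-duplication and a one-camera-per-site bootstrap (5,000 replicates)
  of events per trap night.
- **Demography** (`demography`): juvenile/independent/floater status
  rules on the May-1 "lynx year", generation time (mean age of resident
  reproducing females at first documented reproduction), mean number of
  recruits, and the age pyramid.
- **CLI** (`opencamscr simulate|fit-open|fit-closed|diagnose|rai|demog|fixtures|run`)
  with a single global seed and labelled sub-seeds per stage.

## Worked example

Simulate a reduced-scale survey at the reported parameter values and fit
the open model:

```python
import opencamscr as oc

array = oc.make_grid_design(10, 11)              # 55 paired-camera sites
mask = oc.build_mask(array, buffer_width=18_000, spacing=1_000)
params = oc.SimulationParams(n_primary=5, n_secondary=50,
                             N_initial=38, seed=3)
traj = oc.simulate_population(params, mask)
history = oc.simulate_detections(traj, array, params)
history = oc.apply_sex_missingness(history, 0.18, seed=4)

config = oc.OpenModelConfig(M=150, n_chains=3, n_iter=20_000,
                            burn_in=5_000, thin=5, seed=5)
posterior = oc.run_mcmc(history, mask, config)
print(oc.scr_open.parameter_summary(posterior))
```

This run printed (posterior mode and 95% HPD; generating values in
brackets):

```
 parameter     mode  hpd_low  hpd_high
      g0_F    0.006    0.003     0.009   [0.01]
      g0_M    0.008    0.005     0.011   [0.01]
   sigma_F 4156.269 3314.653  5383.428   [3960 m]
   sigma_M 4115.575 3476.519  4919.444   [4070 m]
     phi_F    0.868    0.620     0.977   [0.82]
     phi_M    0.982    0.818     1.000   [0.90]
sigma_move 3963.170 2641.603  5612.891   [4750 m]
```

i.e. the detection scales are recovered to within a few hundred metres
and the survival and movement HPDs cover the generating values (with 27
detected individuals over five periods the data are deliberately
sparse). A companion closed-model fit of the first session is

```python
closed = oc.collapse_occasions(history, days_per_occasion=5, period=0)
fit = oc.fit_closed(closed, mask, oc.ClosedModelSpec("M0"))
print(fit.density_per_100km2)   # 1.181 individuals / 100 km^2
```

For the unmarked-species index, `published_session_table()` carries the
survey's printed per-session event counts and effective trap nights;
`compute_rai(events, trap_nights)` reproduces, for example, a red fox
RAI of 401/2865 = 0.14 events per trap night.

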