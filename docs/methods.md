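# Methods

## Observation model

Detection is a daily Bernoulli proximity process. An individual with
activity centre **s** is photographed at a camera site at distance
d = ‖x_site − s‖ on an active day with probability

    p(d) = g0 · exp(−d² / (2σ²)),

with baseline probability g₀ and spatial scale σ (metres) specific to
sex. Multiple photographs of one individual at one site on one day are
collapsed to a single detection, so within a primary period the daily
detections at a site are exchangeable given effort; all likelihoods use
the sufficient statistics (detection-day counts per individual × site ×
period, active-day counts per site × period). Site-level effort is the
union of the site's cameras: a site-day is active if at least one of its
one or two cameras was active.

## Open-population model

The observed individuals are embedded in an augmented super-population
of fixed size M (data augmentation). Each augmented row i carries

* a latent sex (female with probability ψ),
* a contiguous alive run across the L yearly primary periods — a single
  entry and a single exit with no revival,
* an activity-centre path s_{i,1..L} over the rectangular habitat mask.

Initial inclusion is Bernoulli(ψ₁). At each transition t → t+1,
alive individuals of sex s survive with probability φ_s, and entrants
are drawn from the never-yet-alive pool of that sex with a per-member
entry probability calibrated so the expected number of entrants equals
γ_s·N_t, where N_t is total abundance (both sexes) — matching the
definition of per-capita recruitment as individuals of each sex added
per total abundance per year. Movement is first-order Markov: s_{i,t+1}
is bivariate normal around s_{i,t} with per-coordinate scale σ_move
(shared across sexes), truncated to the mask rectangle with an exact
erf-product normaliser; the first-period distribution is uniform.

Priors are bounded uniform: g₀, φ, γ, ψ, ψ₁ ~ U(0,1); σ ~ U(0, 20 km);
σ_move ~ U(0, 30 km). ψ₁ is an auxiliary inclusion parameter required
by the augmentation and is not a demographic quantity.

### Sampler

A numba-compiled Metropolis-within-Gibbs chain:

* **Alive runs** are updated by exact categorical draws over the
  enumerable set of contiguous runs consistent with each individual's
  detections (at most L(L+1)/2 + 1 candidates), so the no-revival
  constraint holds at every iteration. The empty run contributes to the
  entry pool like any never-alive row; its candidate weight includes
  that pool term. For never-yet-alive augmented rows the process-prior
  categorical (identical across rows of a sex, cached and rebuilt when
  the demographic counts change) serves as an independence-Metropolis
  proposal with the non-detection likelihood as the acceptance term —
  an exact but much cheaper update, since "stay empty" proposals carry
  no observation work. The tiny-M behaviour of these updates is checked
  against full enumeration of the process prior in the test suite.
* **Latent sexes** of unsexed rows are Bernoulli draws combining ψ, the
  sex-specific observation terms and the sex-specific demographic terms;
  observed sexes are never updated (their posterior is degenerate).
* **φ, ψ, ψ₁** have conjugate Beta full conditionals (Gibbs); **γ** is
  drawn exactly from its one-dimensional conditional on a 256-cell grid
  (inverse-CDF with within-cell jitter), which avoids random-walk
  stickiness in the recruitment rate; **σ_move** uses random-walk
  Metropolis on the log scale (three proposals per iteration — its
  collapsed conditional is cheap); **(g₀, σ)** are updated as a per-sex
  joint random-walk block. Because the per-capita entry probability
  couples the recruitment rate to the augmented never-yet-alive pool,
  the demographic scalars are additionally refreshed at intervals
  *inside* the alive-state sweep, and the sweep runs twice per
  iteration (detected individuals only in the first pass), so the
  entrant counts and rates equilibrate jointly rather than by a slow
  alternating walk.
* **Activity centres** use random-walk Metropolis with the observation
  and movement terms. Paths with no observation constraint are redrawn
  exactly from the movement prior (never-alive rows: whole path;
  dead-tail segments: joint forward draw), and those segments are
  correspondingly integrated out of the σ_move conditional — a
  partially collapsed update that removes the prior-feedback
  autocorrelation that otherwise makes σ_move mix very slowly.
* Proposal scales adapt toward a 20–45% acceptance rate during burn-in
  only, preserving detailed balance afterwards.

Observation terms truncate the half-normal at 5σ (a per-day probability
below 4·10⁻⁶·g₀) except at sites where the individual was detected;
the truncation is part of the model definition, not an approximation
toggle.

Chains are independent given sub-seeds spawned from the configuration
seed; identical seeds give bit-identical draws. The default desk-scale
run is 3 chains × 20,000 iterations (burn-in 5,000, thin 5) with
M = 150–400; `OpenModelConfig.survey_preset()` gives the full-scale
10 × 100,000, M = 400 configuration.

### Derived quantities

Per retained draw: abundance N_t (and per sex) is the count of alive
rows; density D_t = N_t/A × 100 per 100 km², with A the mask area;
realised growth λ_t = N_{t+1}/N_t (flagged undefined when N_t = 0); sex
ratio = N_{F,t}/N_t. Point estimates are posterior modes (histogram
with Freedman–Diaconis bin width; integer mode for counts; median
fallback below 100 draws) and intervals are 95% highest-posterior-
density intervals (shortest interval over sorted draws); equal-tailed
quantile intervals are available as an option since the two are often
conflated in applied reports.

## Closed-population model

Per session, daily occasions are collapsed into 5-day blocks; an
occasion's usage is its count of active days u, compounding detection
as p_occ = 1 − (1 − p_day)^u. Density is a homogeneous Poisson
intensity D over the mask and the fit maximises the full unconditional
likelihood: with Λ = D·a·Σ_x Σ_c w_c·p·(x,c) over mask cells x and sex
classes c,

    log L = Σ_i log( D·a·Σ_c w_ic Σ_x P_i(x,c) ) − Λ − log n!,

where P_i is the Bernoulli product of individual i's history and w the
class weights (pmix for females; known sexes contribute their class
only — the hybrid mixture). The full-likelihood route (rather than the
conditional likelihood with a Horvitz–Thompson density estimator) keeps
one coherent estimator for model averaging; in small samples it can
differ slightly from conditional-likelihood software.

Three structures are fitted: M0 (K = 3), sex on σ (K = 5) and sex on
both g₀ and σ (K = 6). Estimation is quasi-Newton on transformed
parameters (log D, logit g₀, log σ, logit pmix) with a Nelder–Mead
polish; standard errors come from the inverse numerical Hessian with
delta-method back-transformation, and 95% CIs are Wald intervals on the
link scale. AICc uses n = number of detected individuals (the
conventional SCR choice); models with ΔAICc < 2 are averaged with
renormalised Akaike weights, and the unconditional SE combines within-
model variance and between-model spread. Fits without spatial
recaptures (σ unidentifiable) or with degenerate Hessians are flagged,
never silently reported.

## State space

The mask is the detector bounding box expanded by a buffer width on
every side (default 18,000 m) and gridded at 1,000 m; total area is
exactly n_cells × spacing². A 3σ rule check warns when the buffer is
too narrow for a fitted σ. With σ ≈ 4 km, 1 km spacing is fine enough
that density estimates are stable to spacing refinements; the suite
checks likelihood invariance under equivalent-area regriddings. The
area used to convert abundance to density always accompanies the
estimate, since density scales inversely with the chosen buffer.

## Synthetic data generator

The generator emulates the survey design: a checkerboard of 55 paired-
camera sites on a 2.7 km grid (10 × 11 cells), ten 100-day autumn
sessions with daily occasions, sex-specific detection/survival/
recruitment at the reported posterior modes (g₀ = 0.01/day,
σ = 3.96/4.07 km, φ = 0.82/0.90, γ = 0.12/0.09 for females/males,
ψ = 0.53, σ_move = 4.75 km, 38 initial individuals, 18% unknown sexes).
Recruit counts are Poisson with expectation γ_s·N_t; recruits receive
uniform centres (no natal philopatry); survivors' centres move by a
bivariate normal reflected at the mask boundary. Reflection (simulator)
versus truncation (inference) differ negligibly when σ_move is small
relative to the mask extent, as here. Whether per-capita recruitment is
relative to total or sex-specific abundance is configurable; the
default is total abundance.

What the generator does **not** emulate: within-session camera
relocations, juvenile (kitten) detections, behavioural responses to
cameras, spatially heterogeneous density or habitat, and mortality-
cause structure. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
these real-data features.

## Convergence

The Gelman–Rubin potential scale reduction factor with its 97.5%
sampling-distribution upper limit follows the classical construction
(df-adjusted PSRF and an F-quantile upper limit); the implementation
reproduces the standard R implementation to ten decimals on frozen
chains. The report covers the scalar parameters and the N_t series —
not per-individual latent indicators — and passes when every upper
limit is below 1.1. A parameter with zero variance across all draws is
reported as exactly converged with a note.

## Relative abundance index

Photos of one species at one camera chain into a single event while the
rolling gap to the previous photo is under 10 minutes; a gap equal to
the threshold starts a new event. Because paired cameras double-count
passes, the RAI is bootstrapped by selecting one camera per site
uniformly per replicate (default 5,000) and recomputing events and the
selected cameras' trap nights; the reported index is the mean of the
per-replicate ratios with its bootstrap SD. When all cameras at a site
share identical effort the replicate trap nights are constant and the
mean RAI equals mean events divided by trap nights exactly; with
heterogeneous camera effort the two differ slightly. The bootstrap mean
is validated against exact enumeration of the camera-choice product
measure on small arrays.

## Demographic summaries

Ages increment on May 1 (the kitten birth pulse). Status per
individual-year: juvenile (with mother, under one year), independent
(over one year or with proof of independence — an input flag, since
"proof" cannot be inferred from images alone), unknown (excluded from
SCR). Independents are flagged floaters when they are previous-year
juveniles in their second year or unknown-age first appearances of
unknown origin. Generation time is the mean age of known-age resident
reproducing females at their first documented reproduction; it accepts
an explicit exclusion list (e.g. for late-detected first reproductions
flagged as outliers) and excludes nothing by default. The mean number
of recruits averages kitten counts at the onset of winter over all
reproduction records regardless of the female's age being known.

## Problem sizes used in testing

Parameter-recovery studies run at a reduced scale chosen to exercise
every model component with useful statistical power: closed-model
recovery uses 20 single-session replicates (55 sites, 20 five-day
occasions, true density 1.2/100 km²); open-model recovery uses 10
replicates of 5 primary × 50 secondary occasions with M = 150 and
3 chains × 20,000 iterations. Tiny enumerable instances (≤ 3 sites,
≤ 16 mask cells, M ≤ 3) back the exact oracles.

## Known limitations

* Apparent survival and recruitment include emigration and immigration;
  the movement model cannot reliably separate them at array sizes much
  smaller than dispersal distances.
* The closed-model full likelihood and Wald intervals can be
  optimistic with very few detected individuals (n < ~10).
* The per-capita entry construction (entry probability γ·N_t divided
  over the never-yet-alive pool) admits rare self-reinforcing
  "entry-cascade" excursions of the recruitment rate: a tail draw of γ
  raises the entry probability, entrants raise N and deplete the pool,
  and the γ conditional shifts up until the excursion decays. These are
  genuine low-mass posterior features (about 2% of draws at
  stationarity in the recovery studies), but a chain takes a few
  thousand iterations to pass through one, so short runs (3 × 20,000)
  can fail the Gelman–Rubin threshold on γ even though parameter
  coverage is unaffected; 3 × 60,000 iterations converge cleanly on the
  same data. Chains several-fold longer than feel necessary — as in the
  original survey's 100,000-iteration runs — are advisable.
* Homogeneous density over a rectangular mask; no habitat covariates.
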