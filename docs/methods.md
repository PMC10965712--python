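# Methods

## Model

Sensor data inside a half-open analysis window [t₀, t₁) are modeled as

    y(t) = Σᵢ₌₁ᴺ G(rᵢ) qᵢ(t) + ε(t),   ε(t) ~ N(0, σ_ε² I)

with an unknown number N of current dipoles at unknown source-space
vertices rᵢ. The number and locations are constant over the window; only
the moments qᵢ(t) vary. Moments carry a Gaussian prior N(0, σ_q² I) — an
independent draw per analyzed sample — so each sample is marginally
y_t ~ N(0, σ_q² G_R G_Rᵀ + σ_ε² I) and samples are conditionally
independent given (N, R, σ_q). The marginal likelihood is evaluated with
the Woodbury identity on the k×k Gram matrix (k = N · n_comp), so its cost
does not grow with the sensor count cubed; σ_ε > 0 guarantees a
well-conditioned covariance. The conditional posterior of the moments is
the standard ridge-form Gaussian with precision GᵀG/σ_ε² + I/σ_q², shared
across samples.

Orientation handling: free-orientation source spaces use 3 lead-field
columns per vertex with an isotropic moment prior; fixed-orientation
(cortically constrained) spaces use one signed column along the vertex
normal.

### Priors

* Number of dipoles: truncated Poisson with mean 0.25 on {0, …, n_max}
  (default n_max = 10). The truth is only known to be small; the mild
  sparsity prior keeps the prior mass decreasing in N and is overridable.
* Locations: a configuration is an unordered set of distinct vertices.
  Its prior is defined exactly as N i.i.d. draws from the per-vertex weight
  map conditioned on distinctness:
  p({r₁…r_N} | N) = Πᵢ w(rᵢ) / e_N(w), with e_N the N-th elementary
  symmetric polynomial of the weights (computed once by Newton's
  identities). This closed form makes the prior-sampling routine (rejection
  on duplicates), the Metropolis–Hastings acceptance ratios and the
  brute-force enumeration oracle target the identical distribution. Zero
  weights implement excluded search regions; non-uniform weights implement
  a-priori high/low-probability regions.
* Moment scale: either fixed, or a log-uniform hyper-prior on
  [σ_q^min, 10³ σ_q^min] with density 1/(σ_q ln 10³), shared by the whole
  configuration (one σ_q per particle, not per dipole).

### Hyper-parameter defaults

* σ_ε: 20% of the peak absolute signal in the window — a deliberately
  conservative rule absorbing both measurement noise and forward-model
  error. A baseline-window estimate (pooled std over [T0, T1)) is also
  available via `--noise-std baseline:T0:T1`.
* σ_q: 15 · max|y| / max_v ‖G_v‖_F, i.e. a dipole of this strength at the
  most sensitive vertex comfortably explains the data peak. The estimate is
  degree-1 homogeneous in the data and degree −1 in the lead field, so the
  implied strength is unit-free. In hyper mode this value seeds
  σ_q^min = σ_q/√10³ so the point estimate sits mid-support on the log
  scale.

## Sampler

Adaptive tempered SMC targeting π_γ ∝ p(y|N,R,σ_q)^γ p(N)p(R)p(σ_q):

1. Initialize I particles from the prior (rejection sampling gives exact
   draws), equal weights, γ = 0.
2. Per iteration: one MH sweep per particle; choose the next γ by bisection
   (tolerance 10⁻⁶) so the post-reweight effective sample size equals 0.99
   of the current one, capped at γ = 1; reweight
   wᵢ ∝ wᵢ exp((γ′−γ)·log p(y|θᵢ)); systematic resampling when
   ESS < I/2.
3. Stop at γ = 1 (optional extra post-burn sweeps decorrelate the final
   population); an iteration log records γ, ESS and per-move acceptance
   rates so mixing can be assessed. Exceeding `max_iterations` (default
   1000; a fast 50-iteration preset is available) raises a convergence
   error carrying the partial state.

MH moves (probabilities ⅓/⅓/⅓): **birth** proposes a new dipole at a
vertex drawn from the prior weight map (auto-rejected beyond n_max or onto
an occupied or zero-weight vertex); **death** removes a uniformly chosen
dipole; **update** random-walks one dipole over a precomputed spatial
kernel — transition probabilities ∝ exp(−d²/2s²) over vertices within 3s
(s = 1 cm by default), with the 6 nearest vertices always included so the
proposal graph stays connected on sparse grids — and, in hyper mode,
simultaneously perturbs σ_q by a Gaussian random walk in log σ_q (scale
0.1), with the Jacobian in the acceptance ratio. Forward and reverse
proposal densities enter every acceptance ratio; asymmetric neighbor pairs
(reverse probability 0) are rejected outright, which is valid if slightly
wasteful. Marginal-likelihood values are memoized per (configuration, σ_q),
which makes repeated evaluations on small state spaces nearly free.

Estimates: p(N=k|y) is the weight mass on k-dipole particles; the
conditional location map renormalizes the N = N̂ particles and assigns each
dipole weight/N̂ to its vertex; N̂ maximizes p(N|y) with ties broken toward
smaller N (parsimony). Peaks are extracted greedily with a 2 cm exclusion
radius; each peak's credibility is the map mass it suppressed. Time courses
are the conditional-posterior mean at the peak configuration with σ_q set
to the posterior-weighted mean conditioned on N = N̂. Alternative solutions
are reported for every N with mass ≥ 0.1 (matching the spirit of a 60/40
split between one- and two-dipole models being worth showing the user).

## Metrics

* GOF = 1 − ‖y − ŷ‖²_F / ‖y‖²_F (1 iff perfect fit).
* OSPA(X, Y; c, p): optimal-subpattern-assignment distance with cutoff
  c = 3 cm and order p = 1; assignment solved exactly
  (scipy `linear_sum_assignment`); penalizes both localization error and
  cardinality mismatch, bounded by c.
* SD = √(Σ_v map_v · d(v, nearest estimated dipole)²) — the
  probability-weighted spread of the map, 0 iff all mass sits on dipole
  vertices.
* MLD = mean distance from each true dipole to the nearest map peak
  (ground-truth studies only).

GOF, SD and MLD are implemented with these standard definitions, chosen
and documented here as this package's conventions.

## Synthetic studies

The generator emulates a complete M/EEG acquisition: radially oriented
sensors quasi-uniformly covering a hemispherical cap (radius 12 cm),
volumetric (ball, radius 8 cm, free orientation) or shell (fixed outward
orientation) source spaces, and a free-space magnetic-dipole forward model
B(r) = (μ₀/4π) q × (r−r₀)/‖r−r₀‖³ projected on sensor orientations.
This forward model is linear in q and analytically checkable, which is
what testing an inverse algorithm requires; it is **not** a physiological
volume-conductor model (no conductor boundaries, no EEG potentials), so
passing tests demonstrate correctness of the inference machinery, not
fidelity to real head geometries — real analyses supply their own lead
field. Simulated moments are smooth Gaussian pulses peaking at 10 nA·m
(a typical evoked-response strength), staggered in time, with a random
fixed orientation per dipole in free mode.

Study conditions (also used by `scripts/acceptance.py`):

* *Oracle equivalence*: 20 tiny problems (8–12 vertices, 4–8 sensors,
  n_max = 2, one simulated dipole at SNR 3 — a moderate regime where the
  posterior genuinely spreads), I = 2000 particles with 5 post-burn sweeps,
  fixed-σ_q mode; compared against exact enumeration within 3 binomial
  Monte Carlo standard errors.
* *Recovery*: 200-vertex volume, 32 sensors, 2 dipoles ≥ 4 cm apart at
  SNR 10 (SNR = ‖GQ‖_F/(σ_ε√(#entries))), 20 time samples, I = 100.
  Recovery experiments condition on the *known* simulated noise level —
  the natural setting when ground truth is available; the 20%-of-peak
  default is intentionally conservative and tends to drop the weaker
  source (exactly the σ_ε effect described above). Success = modal N̂ = 2
  and OSPA below the grid's median nearest-neighbor spacing (≈ 2 cm).
* *Noise sweep*: one fixed two-dipole dataset, σ_ε ∈ {0.065, 0.2, 0.65} ×
  data peak; the enumerated posterior mean of N is non-increasing across
  this data-dominated regime. (At even larger σ_ε the likelihood flattens
  and the mean creeps back up toward the prior mean ≈ 0.25 — a real
  prior-pull effect, which is why the sweep stops at 0.65.)
* *Enumeration oracle*: all configurations up to n_max (guarded at 10⁴);
  hyper-mode σ_q integrated by 200-point midpoint quadrature, uniform in
  log σ_q.

Problem sizes were chosen so the full validation suite runs in a few
minutes on a single CPU; the sampler itself scales linearly in the number
of particles (measured log-log slope ≈ 0.95).

## Numerical choices and degenerate inputs

* Marginal likelihood is exactly permutation-invariant: configurations are
  canonicalized (sorted vertex order) before the linear algebra.
* All-zero data make the σ_ε and σ_q estimators error out (a zero noise
  level is invalid); an all-zero lead-field vertex block is rejected at
  construction.
* γ increments: if even γ′ = 1 keeps ESS above the decay target the
  sampler jumps straight to 1 (happens when all particles explain the data
  equally well).
* Systematic resampling is used for its minimal variance; expected copy
  counts equal I·wᵢ exactly.
* Free-orientation caveat: with radially oriented sensors the free-space
  dipole law leaves one moment direction nearly silent, so full moment
  vectors are not identifiable even from noiseless data (their *fields*
  are). Exact time-course recovery is therefore only guaranteed in
  fixed-orientation mode; in free mode the per-dipole amplitude ‖q‖(t) is
  reported alongside the components.

## Known limitations

* The forward model shipped for synthesis is free-space magnetics; no BEM/
  FEM head modeling, no EEG volume conduction.
* Gaussian, homoscedastic, spatially white noise; no temporal correlation
  in moments or noise.
* One shared σ_q per configuration (not per dipole).
* Single-threaded; cost grows non-linearly with the estimated number of
  sources (more dipoles → larger Gram matrices and slower mixing).
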