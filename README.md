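# dipsmc

Bayesian multi-dipole source localization for MEG/EEG with full posterior
uncertainty, for researchers and clinicians who need to know not just
*where* the active sources are but *how sure* the data allow them to be.

## The problem and the model

M/EEG sensor data are modeled as the superposition of a small, unknown
number of equivalent current dipoles plus Gaussian noise:

    y(t) = Σᵢ₌₁ᴺ G(rᵢ) qᵢ(t) + ε(t),      ε(t) ~ N(0, σ_ε² I)

where `G(rᵢ)` is the lead-field block of a dipole at source-space vertex
`rᵢ` and `qᵢ(t)` its moment. Within the analysis window N and the locations
R = {rᵢ} are fixed; only the moments vary. With a Gaussian prior
N(0, σ_q² I) on the moments the model is conditionally linear Gaussian, so
the posterior factorizes as

    p(N, R, Q | y) = p(Q | N, R, y) · p(N, R | y)

The first factor is a closed-form Gaussian (used to recover source time
courses); the second — a trans-dimensional distribution over "how many
dipoles, and where" — is sampled by an adaptive sequential Monte Carlo
(SMC) sampler: a population of weighted particles is moved from the prior
(tempering exponent γ = 0) to the posterior (γ = 1) through the bridging
distributions π_γ ∝ p(y|N, R, σ_q)^γ p(N) p(R) p(σ_q), with
birth/death/move Metropolis–Hastings kernels, adaptive γ increments keyed
to the effective sample size, and systematic resampling. The moment scale
σ_q can be fixed, estimated from data and lead field, or given a
log-uniform hyper-prior over three orders of magnitude and sampled along
with the dipoles.

The output is the posterior itself: p(N|y), per-vertex location probability
maps conditioned on the estimated N̂, peak dipoles with per-dipole
credibility mass, posterior-mean time courses, goodness of fit (GOF),
spatial dispersion (SD), and every alternative dipole count whose posterior
mass exceeds 10%.

## Worked example

Simulate a two-dipole dataset at SNR 10 on a 200-vertex volumetric source
space, then localize:

```sh
dipsmc simulate --n-sensors 32 --n-vertices 200 --n-dipoles 2 \
    --snr 10 --seed 7 --out demo
dipsmc run --leadfield demo/leadfield.h5 --data demo/data.h5 \
    --source-space demo/source_space.h5 --noise-std auto \
    --dip-mom-std hyper --n-particles 100 --seed 1 --output demo/result.h5
```

which prints

```
number of sources: 1  [p(N=1)=0.986, p(N=2)=0.014]
  dipole at vertex 188  credibility 1.000
GOF = 0.9213   SD = 0.00 cm
```

The simulated truth is dipoles at vertices 188 and 125. With the default
noise level (`auto` = 20% of the data peak, a deliberately conservative
rule of thumb) the sampler keeps only the stronger source: a high σ_ε tells
the algorithm that coarse data fits are acceptable, so it prefers simpler
models. Re-running with the noise level set near the true simulated value
(`--noise-std 2.5e-15`, in the same tesla units as the data):

```
number of sources: 2  [p(N=2)=1.000]
  dipole at vertex 125  credibility 0.500
  dipole at vertex 188  credibility 0.500
GOF = 0.9924   SD = 0.00 cm
```

Both dipoles are recovered exactly, with full posterior probability on the
two-dipole model, near-perfect goodness of fit and a location map so
focused that its spatial dispersion rounds to zero. `dipsmc inspect
demo/result.h5` re-prints the stored summaries; everything (particles,
resolved parameters, seed) lives in the self-describing HDF5 result file,
so any run can be reproduced from its output alone. `dipsmc oracle`
computes the exact posterior by brute-force enumeration on tiny source
spaces — the reference the sampler is tested against.

The same pipeline is available as a library: `dipsmc.Model` bundles the
lead field, data, noise level and priors; `dipsmc.run_smc` returns the
particle population; `dipsmc.summarize` condenses it into the posterior
summaries above.

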