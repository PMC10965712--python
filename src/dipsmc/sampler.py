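"""Adaptive sequential Monte Carlo sampler over multi-dipole configurations.

The sampler targets the posterior p(N, R, sigma_q | y) by tempering: a
population of weighted particles is moved through the bridging distributions

    pi_gamma ∝ p(y | N, R, sigma_q)^gamma · p(N) p(R) p(sigma_q)

from the prior (gamma = 0) to the posterior (gamma = 1).  Each iteration
applies one trans-dimensional Metropolis-Hastings sweep (dipole birth /
death / spatial update plus a log-random-walk on sigma_q), adapts the next
tempering exponent so the effective sample size decays at a controlled
rate, reweights by importance sampling, and resamples systematically when
the effective sample size falls below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DipoleConfig, Model

__all__ = [
    "Particle",
    "ParticleSet",
    "SamplerSettings",
    "ConvergenceError",
    "initialize_particles",
    "ess",
    "next_exponent",
    "reweight",
    "resample",
    "mcmc_move",
    "run_smc",
]


@dataclass
class Particle:
    """One weighted candidate solution: (N, R), sigma_q and its weight."""

    config: DipoleConfig
    sigma_q: float
    log_weight: float
    cached_logml: float


class ParticleSet:
    """Weighted particle population at tempering exponent ``gamma``."""

    def __init__(self, particles: list[Particle], gamma: float = 0.0, iteration: int = 0):
        if len(particles) < 2:
            raise ValueError("a particle set needs at least 2 particles")
        self.particles = particles
        self.gamma = float(gamma)
        self.iteration = int(iteration)

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def log_weights(self) -> np.ndarray:
        return np.array([p.log_weight for p in self.particles])

    @property
    def weights(self) -> np.ndarray:
        lw = self.log_weights
        lw = lw - lw.max()
        w = np.exp(lw)
        return w / w.sum()

    @property
    def logml(self) -> np.ndarray:
        return np.array([p.cached_logml for p in self.particles])

    def set_weights(self, w: np.ndarray) -> None:
        w = np.asarray(w, dtype=float)
        w = w / w.sum()
        with np.errstate(divide="ignore"):
            lw = np.log(w)
        for p, v in zip(self.particles, lw):
            p.log_weight = float(v)

    def ess(self) -> float:
        return ess(self.weights)


@dataclass
class SamplerSettings:
    """Tuning knobs of the sampler; defaults suit most problems.

    ``n_particles`` trades accuracy for time (cost is linear in it).
    ``ess_decay_target`` sets how aggressively the tempering exponent grows:
    each reweighting step is chosen so the effective sample size shrinks to
    this fraction of its current value.  ``fast_preset`` (50 iterations) is
    available by setting ``max_iterations=50``.
    """

    n_particles: int = 100
    ess_resample_frac: float = 0.5
    ess_decay_target: float = 0.99
    max_iterations: int = 1000
    post_burn_iterations: int = 0
    move_probabilities: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    hyper_walk_scale: float = 0.1
    neighbor_kernel_scale_m: float = 0.01
    sweeps_per_iteration: int = 1
    bisect_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.move_probabilities) - 1.0) > 1e-12:
            raise ValueError("move probabilities must sum to 1")
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        for name in ("hyper_walk_scale", "neighbor_kernel_scale_m", "bisect_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


class ConvergenceError(RuntimeError):
    """Raised when gamma fails to reach 1 within max_iterations."""

    def __init__(self, message: str, particles: ParticleSet, log: list[dict]):
        super().__init__(message)
        self.particles = particles
        self.log = log


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def initialize_particles(
    settings: SamplerSettings, model: Model, rng: np.random.Generator
) -> ParticleSet:
    """Draw the initial population from the prior, with equal weights."""
    if model.n_vertices == 0:
        raise ValueError("empty source space")
    I = settings.n_particles
    particles = []
    for _ in range(I):
        config = model.source_prior.sample_config(rng)
        sigma_q = model.moment_prior.sample_sigma_q(rng)
        logml = model.log_marginal(config, sigma_q)
        particles.append(Particle(config, sigma_q, -np.log(I), logml))
    return ParticleSet(particles, gamma=0.0, iteration=0)


def ess(weights: np.ndarray) -> float:
    """Effective sample size 1 / sum(w_i^2) of normalized weights."""
    w = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(w**2))


def _ess_after(w: np.ndarray, logml: np.ndarray, delta: float) -> float:
    lw = np.log(w) + delta * logml
    lw -= lw.max()
    wn = np.exp(lw)
    wn /= wn.sum()
    return ess(wn)


def next_exponent(particles: ParticleSet, settings: SamplerSettings) -> float:
    """Adaptive choice of the next tempering exponent.

    Bisects the increment so the post-reweight effective sample size equals
    ``ess_decay_target`` times the current one; capped at gamma = 1.
    """
    gamma = particles.gamma
    if gamma >= 1.0:
        raise ValueError("gamma already at 1")
    w = particles.weights
    logml = particles.logml
    target = settings.ess_decay_target * ess(w)
    hi = 1.0 - gamma
    if _ess_after(w, logml, hi) >= target:
        return 1.0
    lo = 0.0
    while hi - lo > settings.bisect_tol:
        mid = 0.5 * (lo + hi)
        if _ess_after(w, logml, mid) >= target:
            lo = mid
        else:
            hi = mid
    return gamma + 0.5 * (lo + hi)


def reweight(particles: ParticleSet, gamma_new: float) -> ParticleSet:
    """Importance-sampling weight update for the move gamma -> gamma_new."""
    if gamma_new < particles.gamma:
        raise ValueError("gamma must not decrease")
    delta = gamma_new - particles.gamma
    lw = particles.log_weights + delta * particles.logml
    lw -= lw.max()
    w = np.exp(lw)
    particles.set_weights(w / w.sum())
    particles.gamma = float(gamma_new)
    return particles


def resample(particles: ParticleSet, rng: np.random.Generator) -> ParticleSet:
    """Systematic resampling; resets weights to 1/I, keeps population size."""
    I = len(particles)
    w = particles.weights
    positions = (rng.random() + np.arange(I)) / I
    cum = np.cumsum(w)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, positions, side="right")
    new = []
    for i in idx:
        p = particles.particles[int(i)]
        new.append(Particle(p.config, p.sigma_q, -np.log(I), p.cached_logml))
    out = ParticleSet(new, gamma=particles.gamma, iteration=particles.iteration)
    return out


# ---------------------------------------------------------------------------
# Metropolis-Hastings kernel
# ---------------------------------------------------------------------------


def _propose_sigma_q(
    particle_sigma: float, model: Model, settings: SamplerSettings, rng: np.random.Generator
) -> tuple[float, float]:
    """Log-space random walk on sigma_q (hyper mode only).

    Returns (proposed sigma_q, log proposal-asymmetry correction), the
    correction being the log-Jacobian term log(sigma') - log(sigma) that
    makes the sigma-space acceptance ratio exact.
    """
    if model.moment_prior.mode != "hyper":
        return particle_sigma, 0.0
    xi = rng.normal(0.0, settings.hyper_walk_scale)
    prop = particle_sigma * float(np.exp(xi))
    return prop, float(np.log(prop) - np.log(particle_sigma))


def mcmc_move(
    particle: Particle,
    gamma: float,
    model: Model,
    settings: SamplerSettings,
    rng: np.random.Generator,
) -> tuple[Particle, str, bool]:
    """One Metropolis-Hastings move targeting pi_gamma.

    Picks birth / death / update by ``move_probabilities``.  Birth proposes
    a new dipole at a vertex drawn from the prior vertex weights (rejected
    outright if occupied or beyond n_max); death removes a uniformly chosen
    dipole; update random-walks one dipole over the spatial neighbor kernel
    and, in hyper mode, also perturbs sigma_q.  Returns the (possibly
    unchanged) particle, the move name and the acceptance flag.
    """
    p_birth, p_death, _ = settings.move_probabilities
    u = rng.random()
    move = "birth" if u < p_birth else ("death" if u < p_birth + p_death else "update")
    prior = model.source_prior
    config = particle.config
    n = config.n_dipoles

    if move == "birth":
        if n >= prior.n_max:
            return particle, move, False
        v = prior.sample_vertex(rng)
        if v in config.vertices:
            return particle, move, False
        new_config = config.with_added(v)
        log_q_fwd = float(np.log(p_birth) + prior._log_w[v])
        log_q_rev = float(np.log(p_death) - np.log(n + 1))
        new_sigma, log_jac = particle.sigma_q, 0.0
    elif move == "death":
        if n == 0:
            return particle, move, False
        idx = int(rng.integers(n))
        v = config.vertices[idx]
        new_config = config.with_removed(idx)
        log_q_fwd = float(np.log(p_death) - np.log(n))
        log_q_rev = float(np.log(p_birth) + prior._log_w[v])
        new_sigma, log_jac = particle.sigma_q, 0.0
    else:  # update: spatial walk on one dipole + sigma_q walk (hyper mode)
        new_sigma, log_jac = _propose_sigma_q(particle.sigma_q, model, settings, rng)
        if n == 0:
            if model.moment_prior.mode != "hyper":
                return particle, move, False
            new_config = config
            log_q_fwd = log_q_rev = 0.0
        else:
            space = model.source_space
            if space is None or not space.neighbors:
                raise ValueError("update move requires a source space with a neighbor kernel")
            idx = int(rng.integers(n))
            v = config.vertices[idx]
            v_new = space.sample_neighbor(v, rng)
            if v_new in config.vertices:
                return particle, move, False
            new_config = config.with_moved(idx, v_new)
            fwd = space.transition_prob(v, v_new)
            rev = space.transition_prob(v_new, v)
            if rev == 0.0:
                return particle, move, False
            log_q_fwd = float(np.log(fwd))
            log_q_rev = float(np.log(rev))

    log_t_new = model.log_target(new_config, new_sigma, gamma)
    if log_t_new == -np.inf:
        return particle, move, False
    log_t_old = model.log_target(config, particle.sigma_q, gamma)
    log_alpha = log_t_new - log_t_old + log_q_rev - log_q_fwd + log_jac
    if np.log(rng.random()) < log_alpha:
        new = Particle(
            new_config,
            new_sigma,
            particle.log_weight,
            model.log_marginal(new_config, new_sigma),
        )
        return new, move, True
    return particle, move, False


def _sweep(
    particles: ParticleSet,
    model: Model,
    settings: SamplerSettings,
    rng: np.random.Generator,
) -> dict[str, float]:
    """One MH sweep over every particle; returns per-move acceptance rates."""
    counts = {"birth": 0, "death": 0, "update": 0}
    accepts = {"birth": 0, "death": 0, "update": 0}
    for _ in range(settings.sweeps_per_iteration):
        for i, p in enumerate(particles.particles):
            new, move, accepted = mcmc_move(p, particles.gamma, model, settings, rng)
            counts[move] += 1
            if accepted:
                accepts[move] += 1
                particles.particles[i] = new
    return {
        m: (accepts[m] / counts[m] if counts[m] else float("nan")) for m in counts
    }


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def run_smc(model: Model, settings: SamplerSettings) -> tuple[ParticleSet, list[dict]]:
    """Run the full sampler: prior -> posterior via adaptive tempering.

    Returns the final particle set (gamma = 1) and an iteration log with
    one record per iteration: gamma, effective sample size, whether a
    resampling step fired, and the per-move acceptance rates.  Fully
    deterministic given ``settings.seed``.
    """
    rng = np.random.default_rng(settings.seed)
    particles = initialize_particles(settings, model, rng)
    log: list[dict] = []
    while particles.gamma < 1.0:
        if particles.iteration >= settings.max_iterations:
            raise ConvergenceError(
                f"gamma = {particles.gamma:.6f} after "
                f"{settings.max_iterations} iterations",
                particles,
                log,
            )
        particles.iteration += 1
        acc = _sweep(particles, model, settings, rng)
        gamma_new = next_exponent(particles, settings)
        reweight(particles, gamma_new)
        resampled = False
        if particles.ess() < settings.ess_resample_frac * len(particles):
            particles = resample(particles, rng)
            resampled = True
        log.append(
            {
                "iteration": particles.iteration,
                "gamma": particles.gamma,
                "ess": particles.ess(),
                "resampled": resampled,
                "acceptance": acc,
            }
        )
    for _ in range(settings.post_burn_iterations):
        particles.iteration += 1
        acc = _sweep(particles, model, settings, rng)
        log.append(
            {
                "iteration": particles.iteration,
                "gamma": particles.gamma,
                "ess": particles.ess(),
                "resampled": False,
                "acceptance": acc,
            }
        )
    return particles, log
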