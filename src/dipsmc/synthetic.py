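"""Synthetic M/EEG studies with known ground truth.

Generates sensor arrays on a hemispherical cap, volumetric or shell source
spaces, free-space magnetic-dipole lead fields, multi-dipole datasets with
additive Gaussian sensor noise, and — for small source spaces — the exact
posterior by brute-force enumeration of every dipole configuration, which
serves as the reference the sampler is validated against.

The forward model is the free-space magnetic-dipole law

    B(r) = (mu0 / 4 pi) * q x (r - r0) / ||r - r0||^3

projected on the sensor orientations.  It is deliberately simple — linear
in q and analytically checkable — and is not a physiological
volume-conductor model: real analyses supply their own lead field.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model import (
    DipoleConfig,
    LeadField,
    MEEGData,
    Model,
    SourceSpace,
    build_gain,
    log_prior_config,
)

__all__ = [
    "GroundTruth",
    "ExactPosterior",
    "make_sensor_array",
    "make_source_space",
    "dipole_leadfield",
    "gaussian_pulse_moments",
    "simulate_dataset",
    "sigma_eps_for_snr",
    "enumerate_posterior",
    "tiny_inverse_problem",
    "recovery_problem",
]

MU0_OVER_4PI = 1e-7  # T·m/A


@dataclass
class GroundTruth:
    """True source configuration behind a simulated dataset."""

    config: DipoleConfig
    moments: np.ndarray  # (n_dipoles * n_comp, n_times), A·m
    sigma_eps_true: float
    seed: int


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the upper hemisphere (z >= 0)."""
    i = np.arange(n)
    z = (i + 0.5) / n  # z in (0, 1)
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_sensor_array(
    n_sensors: int, radius_m: float = 0.12, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Radially-oriented sensors on a hemispherical cap of given radius.

    Returns ``(positions, orientations)``; the quasi-uniform layout is
    rotated about z by a seeded angle so distinct seeds give distinct but
    equally regular arrays.
    """
    if n_sensors < 3:
        raise ValueError("need at least 3 sensors")
    rng = np.random.default_rng(seed)
    units = _fibonacci_hemisphere(n_sensors) @ _rot_z(rng.uniform(0, 2 * np.pi)).T
    return radius_m * units, units.copy()


def make_source_space(
    n_vertices: int,
    radius_m: float = 0.08,
    mode: str = "volume",
    seed: int = 0,
    kernel_scale_m: float = 0.01,
) -> SourceSpace:
    """Volumetric ball grid or spherical-shell source space.

    ``volume`` scatters vertices quasi-uniformly inside the ball (free
    orientation); ``shell`` places them on the sphere with outward unit
    orientations, a fixed-orientation stand-in for a cortical surface.
    The spatial neighbor kernel is prebuilt with scale ``kernel_scale_m``.
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    rng = np.random.default_rng(seed)
    if mode == "volume":
        u = rng.standard_normal((n_vertices, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = radius_m * rng.random(n_vertices) ** (1.0 / 3.0)
        positions = u * r[:, None]
        orientations = None
    elif mode == "shell":
        units = _fibonacci_hemisphere(n_vertices) @ _rot_z(rng.uniform(0, 2 * np.pi)).T
        positions = radius_m * units
        orientations = units.copy()
    else:
        raise ValueError("mode must be 'volume' or 'shell'")
    space = SourceSpace(positions=positions, orientations=orientations)
    space.build_neighbor_kernel(scale_m=kernel_scale_m)
    return space


def dipole_leadfield(
    space: SourceSpace,
    sensor_positions: np.ndarray,
    sensor_orientations: np.ndarray,
) -> LeadField:
    """Free-space magnetic-dipole lead field projected on sensor orientations.

    Free-orientation spaces get 3 columns per vertex (unit moments along
    x, y, z); fixed-orientation spaces get 1 signed column along the vertex
    orientation.
    """
    sens = np.asarray(sensor_positions, dtype=float)
    ori = np.asarray(sensor_orientations, dtype=float)
    m = sens.shape[0]
    V = space.n_vertices
    d = sens[:, None, :] - space.positions[None, :, :]  # (m, V, 3)
    dist = np.linalg.norm(d, axis=2)
    if np.any(dist < 1e-9):
        raise ValueError("a sensor coincides with a source vertex")
    inv3 = dist**-3
    if space.orientations is None:
        cols = np.empty((m, V, 3))
        for k, e in enumerate(np.eye(3)):
            # B = mu0/4pi * (e x d) / |d|^3, projected on sensor orientation
            cross = np.cross(np.broadcast_to(e, d.shape), d)
            cols[:, :, k] = MU0_OVER_4PI * inv3 * np.einsum("mvi,mi->mv", cross, ori)
        matrix = cols.reshape(m, V * 3)
        return LeadField(matrix=matrix, n_comp=3)
    q = np.broadcast_to(space.orientations[None, :, :], d.shape)
    cross = np.cross(q, d)
    matrix = MU0_OVER_4PI * inv3 * np.einsum("mvi,mi->mv", cross, ori)
    return LeadField(matrix=matrix, n_comp=1)


def gaussian_pulse_moments(
    n_dipoles: int,
    n_comp: int,
    n_times: int,
    peak_moment: float = 1e-8,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Smooth single-pulse time courses, one Gaussian bump per dipole.

    Peak moment defaults to 10 nA·m, a typical evoked-response dipole
    strength.  Pulse centers are staggered across the window; in free
    orientation each dipole gets a random fixed unit direction.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    t = np.linspace(0.0, 1.0, n_times)
    Q = np.zeros((n_dipoles * n_comp, n_times))
    for i in range(n_dipoles):
        center = (i + 1) / (n_dipoles + 1)
        pulse = peak_moment * np.exp(-((t - center) ** 2) / (2 * 0.15**2))
        if n_comp == 1:
            Q[i] = pulse
        else:
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            Q[3 * i : 3 * i + 3] = u[:, None] * pulse[None, :]
    return Q


def sigma_eps_for_snr(
    leadfield: LeadField, config: DipoleConfig, moments: np.ndarray, snr: float
) -> float:
    """Noise level giving ||G Q||_F / (sigma_eps * sqrt(#entries)) = snr."""
    clean = build_gain(config, leadfield) @ moments
    signal = float(np.linalg.norm(clean))
    if signal == 0.0:
        raise ValueError("zero signal; SNR undefined")
    return signal / (snr * np.sqrt(clean.size))


def simulate_dataset(
    truth: GroundTruth,
    leadfield: LeadField,
    n_times: int | None = None,
    sample_rate: float = 100.0,
) -> MEEGData:
    """Forward-simulate sensor data: y = G_R Q + Gaussian noise.

    Noise is i.i.d. N(0, sigma_eps_true^2) per entry, seeded from
    ``truth.seed``; with sigma_eps_true = 0 the data equal G_R Q exactly.
    """
    if n_times is None:
        n_times = truth.moments.shape[1] if truth.moments.size else 1
    G = build_gain(truth.config, leadfield)
    if truth.config.n_dipoles == 0:
        clean = np.zeros((leadfield.sensor_count, n_times))
    else:
        if truth.moments.shape != (G.shape[1], n_times):
            raise ValueError("moments shape inconsistent with config/lead field")
        clean = G @ truth.moments
    values = clean
    if truth.sigma_eps_true > 0:
        rng = np.random.default_rng(truth.seed)
        values = clean + truth.sigma_eps_true * rng.standard_normal(clean.shape)
    times = np.arange(n_times) / sample_rate
    return MEEGData(values=values, sample_times=times)


# ---------------------------------------------------------------------------
# canned study problems
# ---------------------------------------------------------------------------


def tiny_inverse_problem(
    seed: int,
    snr: float = 3.0,
    n_true: int = 1,
    n_max: int = 2,
    moment_mode: str = "fixed",
) -> tuple[Model, DipoleConfig]:
    """A small enumerable inverse problem: 8-12 vertices, 4-8 sensors.

    Simulates ``n_true`` dipole(s) at the given signal-to-noise ratio and
    conditions the model on the true noise level (the natural setting for
    validating the sampler against the exact enumerated posterior).
    Returns the model and the true configuration.
    """
    from .model import MomentPrior, NoiseModel, SourcePrior, estimate_dip_mom_std

    rng = np.random.default_rng(seed)
    n_vertices = 8 + seed % 5
    n_sensors = 4 + seed % 5
    sens_pos, sens_ori = make_sensor_array(n_sensors, seed=seed)
    space = make_source_space(n_vertices, seed=seed, kernel_scale_m=0.03)
    leadfield = dipole_leadfield(space, sens_pos, sens_ori)
    config = DipoleConfig(tuple(rng.choice(n_vertices, size=n_true, replace=False)))
    moments = gaussian_pulse_moments(n_true, leadfield.n_comp, 5, rng=rng)
    sigma_eps = sigma_eps_for_snr(leadfield, config, moments, snr)
    truth = GroundTruth(config, moments, sigma_eps, seed)
    data = simulate_dataset(truth, leadfield)
    sigma_q = estimate_dip_mom_std(leadfield, data)
    if moment_mode == "fixed":
        moment_prior = MomentPrior(mode="fixed", sigma_q=sigma_q)
    else:
        moment_prior = MomentPrior(mode="hyper", sigma_q_min=sigma_q / np.sqrt(1000.0))
    model = Model(
        leadfield,
        data,
        NoiseModel(sigma_eps),
        SourcePrior(n_vertices=n_vertices, n_max=n_max),
        moment_prior,
        space,
    )
    return model, config


def recovery_problem(
    seed: int,
    n_dipoles: int = 2,
    snr: float = 10.0,
    n_vertices: int = 200,
    n_sensors: int = 32,
    n_times: int = 20,
    min_separation_m: float = 0.04,
) -> tuple[Model, DipoleConfig]:
    """A volumetric parameter-recovery experiment with well-separated dipoles.

    The noise model is conditioned on the known simulated noise level; the
    moment prior uses the log-uniform hyper-prior seeded from the data and
    lead field.  Returns the model and the true configuration.
    """
    from .model import (
        MomentPrior,
        NoiseModel,
        SourcePrior,
        estimate_dip_mom_std,
    )

    rng = np.random.default_rng(seed)
    sens_pos, sens_ori = make_sensor_array(n_sensors, seed=seed)
    space = make_source_space(n_vertices, seed=seed)
    leadfield = dipole_leadfield(space, sens_pos, sens_ori)
    if n_dipoles > 0:
        while True:
            verts = rng.choice(n_vertices, size=n_dipoles, replace=False)
            pos = space.positions[verts]
            if n_dipoles == 1:
                break
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            if d[np.triu_indices(n_dipoles, 1)].min() >= min_separation_m:
                break
        config = DipoleConfig(tuple(int(v) for v in verts))
        moments = gaussian_pulse_moments(n_dipoles, leadfield.n_comp, n_times, rng=rng)
        sigma_eps = sigma_eps_for_snr(leadfield, config, moments, snr)
    else:
        config = DipoleConfig(())
        moments = np.zeros((0, n_times))
        sigma_eps = 0.2e-8 * float(np.abs(leadfield.matrix).max())
    truth = GroundTruth(config, moments, sigma_eps, seed)
    data = simulate_dataset(truth, leadfield, n_times)
    sigma_q = estimate_dip_mom_std(leadfield, data)
    model = Model(
        leadfield,
        data,
        NoiseModel(sigma_eps),
        SourcePrior(n_vertices=n_vertices),
        MomentPrior(mode="hyper", sigma_q_min=sigma_q / np.sqrt(1000.0)),
        space,
    )
    return model, config


# ---------------------------------------------------------------------------
# exact posterior by enumeration (small source spaces only)
# ---------------------------------------------------------------------------


@dataclass
class ExactPosterior:
    """Brute-force posterior over every dipole configuration."""

    n_pmf: np.ndarray
    conditional_maps: dict[int, np.ndarray]
    log_evidence: float
    config_log_probs: dict[DipoleConfig, float]

    @property
    def mean_n(self) -> float:
        return float(np.sum(np.arange(len(self.n_pmf)) * self.n_pmf))


def enumerate_posterior(
    model: Model, max_configs: int = 10_000, n_quad: int = 200
) -> ExactPosterior:
    """Exact posterior p(N, R | y) by enumerating all configurations.

    Each configuration's marginal likelihood is combined with its prior
    mass; in hyper mode sigma_q is integrated out by ``n_quad``-point
    quadrature over the log-uniform hyper-prior (midpoint rule, uniform in
    log sigma_q).  Guarded to ``max_configs`` configurations.
    """
    prior = model.source_prior
    V = model.n_vertices
    support = [v for v in range(V) if prior.vertex_weights[v] > 0]
    configs: list[DipoleConfig] = []
    for n in range(prior.n_max + 1):
        if prior.n_prior_pmf[n] == 0:
            continue
        for verts in itertools.combinations(support, n):
            configs.append(DipoleConfig(verts))
            if len(configs) > max_configs:
                raise ValueError(
                    f"more than {max_configs} configurations; "
                    "enumeration is limited to tiny source spaces"
                )

    mp = model.moment_prior
    if mp.mode == "hyper":
        theta = np.log(mp.sigma_q_min) + (np.arange(n_quad) + 0.5) / n_quad * np.log(
            mp.range_factor
        )
        sigmas = np.exp(theta)
    else:
        sigmas = np.array([mp.sigma_q])

    log_joint = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        lp = log_prior_config(cfg, prior)
        lls = np.array([model.log_marginal(cfg, s) for s in sigmas])
        # marginal over sigma_q: mean over quadrature nodes (uniform in log)
        log_joint[i] = lp + logsumexp(lls) - np.log(len(sigmas))

    log_Z = float(logsumexp(log_joint))
    probs = np.exp(log_joint - log_Z)
    n_pmf = np.zeros(prior.n_max + 1)
    maps: dict[int, np.ndarray] = {}
    for cfg, p in zip(configs, probs):
        n = cfg.n_dipoles
        n_pmf[n] += p
        if n > 0:
            m = maps.setdefault(n, np.zeros(V))
            for v in cfg.vertices:
                m[v] += p / n
    for n, m in maps.items():
        if n_pmf[n] > 0:
            maps[n] = m / n_pmf[n]
    return ExactPosterior(
        n_pmf=n_pmf,
        conditional_maps=maps,
        log_evidence=log_Z,
        config_log_probs={c: float(lj - log_Z) for c, lj in zip(configs, log_joint)},
    )
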