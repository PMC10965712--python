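"""Probabilistic model for multi-dipole M/EEG source analysis.

The measurement model is the standard equivalent-current-dipole (ECD)
superposition: at every time sample the sensor vector is

    y(t) = sum_i G(r_i) q_i(t) + eps(t)

where ``G(r_i)`` is the lead-field block of the dipole at vertex ``r_i``,
``q_i(t)`` its moment and ``eps(t)`` i.i.d. Gaussian sensor noise with
standard deviation ``sigma_eps``.  Within the analysis window the number of
dipoles and their locations are fixed; only the moments vary over time.

With a Gaussian prior N(0, sigma_q^2 I) on the moments the model is
conditionally linear-Gaussian: the moments integrate out analytically,
leaving a closed-form marginal likelihood p(y | N, R, sigma_q) that the
trans-dimensional sampler in :mod:`dipsmc.sampler` explores, and a
closed-form Gaussian conditional posterior p(Q | N, R, y) used to recover
source time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SourceSpace",
    "LeadField",
    "MEEGData",
    "NoiseModel",
    "SourcePrior",
    "MomentPrior",
    "DipoleConfig",
    "Model",
    "build_gain",
    "log_marginal_likelihood",
    "log_prior_config",
    "log_hyperprior",
    "conditional_moment_posterior",
    "estimate_noise_std",
    "estimate_dip_mom_std",
    "truncated_poisson_pmf",
]

LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SourceSpace:
    """Discrete set of candidate dipole locations.

    Parameters
    ----------
    positions : (V, 3) float array
        Vertex coordinates in meters.
    orientations : (V, 3) float array or None
        Unit dipole orientations for fixed-orientation (cortically
        constrained) analyses; ``None`` for free orientation.
    neighbors : list of int arrays
        For each vertex, ids of its neighbors (used by the spatial
        random-walk proposal).
    neighbor_probs : list of float arrays
        Transition probabilities aligned with ``neighbors``; each row sums
        to 1.
    """

    positions: np.ndarray
    orientations: np.ndarray | None = None
    neighbors: list[np.ndarray] = field(default_factory=list)
    neighbor_probs: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (V, 3)")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float)
            if self.orientations.shape != self.positions.shape:
                raise ValueError("orientations must match positions shape")
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("orientations must have unit norm")
        if self.neighbors and len(self.neighbors) != self.n_vertices:
            raise ValueError("neighbor table length mismatch")
        for probs in self.neighbor_probs:
            if abs(float(np.sum(probs)) - 1.0) > 1e-12:
                raise ValueError("neighbor probability rows must sum to 1")
        self._cum_probs: list[np.ndarray] | None = None

    @property
    def n_vertices(self) -> int:
        return self.positions.shape[0]

    def build_neighbor_kernel(self, scale_m: float = 0.01, k_min: int = 6) -> None:
        """Precompute the Gaussian spatial proposal kernel.

        Transition probabilities are proportional to ``exp(-d^2 / 2 s^2)``
        over vertices within ``3 s`` of the current vertex (``s`` =
        ``scale_m``).  The ``k_min`` nearest vertices are always included so
        the proposal graph stays connected on sparse grids.
        """
        pos = self.positions
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        s2 = float(scale_m) ** 2
        cutoff2 = (3.0 * scale_m) ** 2
        neighbors: list[np.ndarray] = []
        probs: list[np.ndarray] = []
        k = min(k_min + 1, self.n_vertices)
        for v in range(self.n_vertices):
            row = d2[v]
            near = np.flatnonzero(row <= cutoff2)
            knn = np.argpartition(row, k - 1)[:k]
            ids = np.union1d(near, knn)
            ids = ids[ids != v]
            if ids.size == 0:  # isolated single-vertex space
                ids = np.array([v])
            w = np.exp(-row[ids] / (2.0 * s2))
            if w.sum() <= 0:
                w = np.ones_like(w)
            w = w / w.sum()
            neighbors.append(ids.astype(np.intp))
            probs.append(w)
        self.neighbors = neighbors
        self.neighbor_probs = probs
        self._cum_probs = None

    def transition_prob(self, src: int, dst: int) -> float:
        """Proposal probability of a spatial step ``src -> dst`` (0 if not adjacent)."""
        ids = self.neighbors[src]
        hits = np.flatnonzero(ids == dst)
        if hits.size == 0:
            return 0.0
        return float(self.neighbor_probs[src][hits[0]])

    def sample_neighbor(self, v: int, rng: np.random.Generator) -> int:
        if self._cum_probs is None:
            self._cum_probs = [np.cumsum(p) for p in self.neighbor_probs]
        cum = self._cum_probs[v]
        j = int(np.searchsorted(cum, rng.random(), side="right"))
        j = min(j, len(cum) - 1)
        return int(self.neighbors[v][j])


@dataclass
class LeadField:
    """Linear map from unit dipole moments to sensor readings.

    ``matrix`` has one block of ``n_comp`` columns per source-space vertex,
    in vertex order: 3 columns in free-orientation mode, 1 signed column in
    fixed-orientation mode.
    """

    matrix: np.ndarray
    n_comp: int = 3

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("lead field must be a 2-D matrix")
        if self.n_comp not in (1, 3):
            raise ValueError("n_comp must be 1 or 3")
        if self.matrix.shape[1] % self.n_comp != 0:
            raise ValueError("column count not divisible by n_comp")
        if not np.isfinite(self.matrix).all():
            raise ValueError("lead field entries must be finite")

    @property
    def sensor_count(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[1] // self.n_comp

    def vertex_block(self, v: int) -> np.ndarray:
        """Columns of vertex ``v`` — shape (n_sensors, n_comp)."""
        if not 0 <= v < self.n_vertices:
            raise IndexError(f"vertex id {v} out of range [0, {self.n_vertices})")
        c = self.n_comp
        return self.matrix[:, v * c : (v + 1) * c]


@dataclass
class MEEGData:
    """Sensor data restricted to a half-open analysis window [t_start, t_end)."""

    values: np.ndarray
    sample_times: np.ndarray
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("data must be (n_sensors, n_times)")
        if self.sample_times.shape != (self.values.shape[1],):
            raise ValueError("sample_times length must match data columns")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.window is None:
            # default window covers every sample
            t = self.sample_times
            self.window = (float(t[0]), np.nextafter(float(t[-1]), np.inf))
        mask = self.window_mask()
        if not mask.any():
            raise ValueError("analysis window contains no samples")

    def window_mask(self) -> np.ndarray:
        t0, t1 = self.window
        return (self.sample_times >= t0) & (self.sample_times < t1)

    def analyzed(self) -> np.ndarray:
        """Data submatrix inside the analysis window, shape (n_sensors, T_w)."""
        return self.values[:, self.window_mask()]

    def analyzed_times(self) -> np.ndarray:
        return self.sample_times[self.window_mask()]

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]


@dataclass
class NoiseModel:
    """Gaussian sensor-noise level; also absorbs forward-modeling error."""

    sigma_eps: float

    def __post_init__(self) -> None:
        self.sigma_eps = float(self.sigma_eps)
        if not self.sigma_eps > 0:
            raise ValueError("sigma_eps must be > 0")


def truncated_poisson_pmf(mean: float, n_max: int) -> np.ndarray:
    """Poisson(mean) pmf truncated to {0, ..., n_max} and renormalized."""
    k = np.arange(n_max + 1)
    pmf = stats.poisson.pmf(k, mean)
    return pmf / pmf.sum()


@dataclass
class SourcePrior:
    """Prior over the number of dipoles and their locations.

    The number of dipoles follows ``n_prior_pmf`` on {0, ..., n_max}
    (default: truncated Poisson with mean 0.25, a mild sparsity prior).
    Locations are drawn from ``vertex_weights``; non-uniform weights encode
    a-priori high/low-probability search regions, and zero-weight vertices
    are excluded from the support entirely.

    A configuration is an unordered set of distinct vertices.  Its prior
    mass is defined as that of i.i.d. weighted draws conditioned on
    distinctness:  p({r_1..r_N} | N) = prod_i w_{r_i} / e_N(w), where
    e_N is the N-th elementary symmetric polynomial of the weights.
    """

    n_vertices: int
    n_max: int = 10
    n_prior_pmf: np.ndarray | None = None
    vertex_weights: np.ndarray | None = None
    poisson_mean: float = 0.25

    def __post_init__(self) -> None:
        if self.n_prior_pmf is None:
            self.n_prior_pmf = truncated_poisson_pmf(self.poisson_mean, self.n_max)
        self.n_prior_pmf = np.asarray(self.n_prior_pmf, dtype=float)
        if self.n_prior_pmf.shape != (self.n_max + 1,):
            raise ValueError("n_prior_pmf must have length n_max + 1")
        if abs(float(self.n_prior_pmf.sum()) - 1.0) > 1e-12:
            raise ValueError("n_prior_pmf must sum to 1")
        if self.vertex_weights is None:
            self.vertex_weights = np.full(self.n_vertices, 1.0 / self.n_vertices)
        self.vertex_weights = np.asarray(self.vertex_weights, dtype=float)
        if self.vertex_weights.shape != (self.n_vertices,):
            raise ValueError("vertex_weights must have one entry per vertex")
        if np.any(self.vertex_weights < 0):
            raise ValueError("vertex_weights must be non-negative")
        total = float(self.vertex_weights.sum())
        if total <= 0:
            raise ValueError("vertex_weights must not be all zero")
        self.vertex_weights = self.vertex_weights / total
        self._log_esym = _log_elementary_symmetric(self.vertex_weights, self.n_max)
        with np.errstate(divide="ignore"):
            self._log_w = np.log(self.vertex_weights)
        self._cum_w = np.cumsum(self.vertex_weights)

    def log_esym(self, n: int) -> float:
        """log e_n(vertex_weights); normalizer of the unordered location prior."""
        return float(self._log_esym[n])

    def sample_vertex(self, rng: np.random.Generator) -> int:
        j = int(np.searchsorted(self._cum_w, rng.random(), side="right"))
        return min(j, self.n_vertices - 1)

    def sample_config(self, rng: np.random.Generator) -> "DipoleConfig":
        """Draw (N, R) from the prior (rejection on duplicate vertices)."""
        n = int(rng.choice(self.n_max + 1, p=self.n_prior_pmf))
        while True:
            verts = [self.sample_vertex(rng) for _ in range(n)]
            if len(set(verts)) == n:
                return DipoleConfig(tuple(verts))


def _log_elementary_symmetric(w: np.ndarray, n_max: int) -> np.ndarray:
    """log of e_0..e_n_max of the weights, by Newton's identities."""
    w = np.asarray(w, dtype=float)
    p = np.array([np.sum(w**k) for k in range(1, n_max + 1)])
    e = np.zeros(n_max + 1)
    e[0] = 1.0
    for k in range(1, n_max + 1):
        acc = 0.0
        for i in range(1, k + 1):
            acc += (-1.0) ** (i - 1) * e[k - i] * p[i - 1]
        e[k] = acc / k
    out = np.full(n_max + 1, -np.inf)
    pos = e > 0
    out[pos] = np.log(e[pos])
    return out


@dataclass
class MomentPrior:
    """Gaussian prior on dipole moments, N(0, sigma_q^2 I).

    ``fixed`` mode pins sigma_q; ``hyper`` mode treats it as unknown with a
    log-uniform hyper-prior on [sigma_q_min, range_factor * sigma_q_min]
    (default range spans three orders of magnitude).
    """

    mode: str = "fixed"
    sigma_q: float | None = None
    sigma_q_min: float | None = None
    range_factor: float = 1000.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "hyper"):
            raise ValueError("mode must be 'fixed' or 'hyper'")
        if self.mode == "fixed":
            if self.sigma_q is None or not self.sigma_q > 0:
                raise ValueError("fixed mode requires sigma_q > 0")
        else:
            if self.sigma_q_min is None or not self.sigma_q_min > 0:
                raise ValueError("hyper mode requires sigma_q_min > 0")
            if not self.range_factor > 1:
                raise ValueError("range_factor must be > 1")

    @property
    def sigma_q_max(self) -> float:
        if self.mode != "hyper":
            raise ValueError("sigma_q_max defined only in hyper mode")
        return float(self.sigma_q_min * self.range_factor)

    def sample_sigma_q(self, rng: np.random.Generator) -> float:
        if self.mode == "fixed":
            return float(self.sigma_q)
        lo, hi = np.log(self.sigma_q_min), np.log(self.sigma_q_max)
        return float(np.exp(rng.uniform(lo, hi)))


class DipoleConfig:
    """An unordered set of distinct dipole vertices (a candidate solution).

    Order of the vertex list is non-semantic: two configurations with
    permuted lists compare equal and hash identically.
    """

    __slots__ = ("vertices", "_key")

    def __init__(self, vertices: Sequence[int] = ()):
        verts = tuple(int(v) for v in vertices)
        if any(v < 0 for v in verts):
            raise ValueError("vertex ids must be non-negative")
        if len(set(verts)) != len(verts):
            raise ValueError("duplicate vertices are forbidden in a configuration")
        self.vertices = verts
        self._key = tuple(sorted(verts))

    @property
    def n_dipoles(self) -> int:
        return len(self.vertices)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DipoleConfig) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        return f"DipoleConfig(vertices={list(self.vertices)})"

    def with_added(self, v: int) -> "DipoleConfig":
        return DipoleConfig(self.vertices + (int(v),))

    def with_removed(self, idx: int) -> "DipoleConfig":
        verts = list(self.vertices)
        del verts[idx]
        return DipoleConfig(tuple(verts))

    def with_moved(self, idx: int, v: int) -> "DipoleConfig":
        verts = list(self.vertices)
        verts[idx] = int(v)
        return DipoleConfig(tuple(verts))


# ---------------------------------------------------------------------------
# closed-form pieces of the model
# ---------------------------------------------------------------------------


def build_gain(config: DipoleConfig, leadfield: LeadField) -> np.ndarray:
    """Gain matrix of a configuration: its lead-field blocks side by side.

    Realizes the linear superposition of dipole contributions; shape is
    (n_sensors, n_dipoles * n_comp), with 0 columns for the empty
    configuration.
    """
    m = leadfield.sensor_count
    if config.n_dipoles == 0:
        return np.zeros((m, 0))
    return np.hstack([leadfield.vertex_block(v) for v in config.vertices])


def log_marginal_likelihood(
    config: DipoleConfig,
    sigma_q: float,
    data: MEEGData,
    leadfield: LeadField,
    noise: NoiseModel,
) -> float:
    """Marginal log-likelihood log p(y | N, R, sigma_q), moments integrated out.

    With an independent N(0, sigma_q^2 I) moment draw per analyzed sample,
    each sample is marginally y_t ~ N(0, sigma_q^2 G G^T + sigma_eps^2 I);
    samples are conditionally independent.  Evaluated via the Woodbury
    identity on the small k x k Gram matrix (k = n_dipoles * n_comp).
    """
    if not sigma_q > 0:
        raise ValueError("sigma_q must be > 0")
    Y = data.analyzed()
    m, T = Y.shape
    if m != leadfield.sensor_count:
        raise ValueError("data/lead-field sensor mismatch")
    s2e = noise.sigma_eps**2
    yy = float(np.sum(Y * Y))
    if config.n_dipoles == 0:
        return -0.5 * (T * m * (LOG_2PI + np.log(s2e)) + yy / s2e)
    # canonical vertex order makes the value exactly permutation-invariant
    G = build_gain(DipoleConfig(config._key), leadfield)
    k = G.shape[1]
    ratio = sigma_q**2 / s2e
    # M = I_k + (sq^2/se^2) G^T G ;  Sigma^-1 = (I - G Minv G^T sq^2/se^2)/se^2
    M = np.eye(k) + ratio * (G.T @ G)
    L = np.linalg.cholesky(M)
    logdet_sigma = m * np.log(s2e) + 2.0 * float(np.sum(np.log(np.diag(L))))
    GtY = G.T @ Y
    Z = np.linalg.solve(L, GtY)
    quad = (yy - ratio * float(np.sum(Z * Z))) / s2e
    return -0.5 * (T * (m * LOG_2PI + logdet_sigma) + quad)


def log_prior_config(config: DipoleConfig, prior: SourcePrior) -> float:
    """log p(N, R) for an unordered configuration of distinct vertices.

    Returns -inf when N exceeds n_max or any vertex carries zero prior
    weight; exactly permutation-invariant.
    """
    n = config.n_dipoles
    if n > prior.n_max:
        return -np.inf
    lp = float(np.log(prior.n_prior_pmf[n])) if prior.n_prior_pmf[n] > 0 else -np.inf
    for v in config._key:  # canonical order: exactly permutation-invariant
        lp += float(prior._log_w[v])
    if n > 0:
        lp -= prior.log_esym(n)
    return lp


def log_hyperprior(sigma_q: float, prior: MomentPrior) -> float:
    """Log-density of the log-uniform hyper-prior on sigma_q."""
    if prior.mode != "hyper":
        raise ValueError("log_hyperprior requires a hyper-mode MomentPrior")
    lo, hi = prior.sigma_q_min, prior.sigma_q_max
    if not (lo <= sigma_q <= hi):
        return -np.inf
    return float(-np.log(sigma_q) - np.log(np.log(prior.range_factor)))


def conditional_moment_posterior(
    config: DipoleConfig,
    sigma_q: float,
    data: MEEGData,
    leadfield: LeadField,
    noise: NoiseModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian posterior of the dipole moments given (N, R, sigma_q).

    Returns ``(mean, covariance)`` where ``mean`` has shape
    (n_dipoles*n_comp, T) — one column per analyzed sample — and the
    posterior covariance (G^T G / se^2 + I / sq^2)^-1 is shared across
    samples.
    """
    if config.n_dipoles == 0:
        raise ValueError("conditional moment posterior undefined for 0 dipoles")
    if not sigma_q > 0:
        raise ValueError("sigma_q must be > 0")
    Y = data.analyzed()
    G = build_gain(config, leadfield)
    k = G.shape[1]
    s2e = noise.sigma_eps**2
    prec = G.T @ G / s2e + np.eye(k) / sigma_q**2
    cov = np.linalg.inv(prec)
    cov = 0.5 * (cov + cov.T)
    mean = np.linalg.solve(prec, G.T @ Y / s2e)
    return mean, cov


def estimate_noise_std(data: MEEGData) -> float:
    """Default noise level: 20% of the peak absolute signal in the window."""
    peak = float(np.max(np.abs(data.analyzed())))
    if peak == 0.0:
        raise ValueError("cannot estimate noise level from all-zero data")
    return 0.2 * peak


def estimate_dip_mom_std(leadfield: LeadField, data: MEEGData) -> float:
    """Data/lead-field driven scale for the dipole-moment prior.

    sigma_q = 15 * max|y| / max_v ||G_v||_F : a dipole of this strength at
    the most sensitive vertex comfortably explains the data peak.  The
    estimate is homogeneous of degree 1 in the data and -1 in the lead
    field, so the implied source strength is unit-free.
    """
    peak = float(np.max(np.abs(data.analyzed())))
    if peak == 0.0:
        raise ValueError("cannot estimate moment scale from all-zero data")
    c = leadfield.n_comp
    blocks = leadfield.matrix.reshape(leadfield.sensor_count, -1, c)
    norms = np.sqrt((blocks**2).sum(axis=(0, 2)))
    gmax = float(norms.max())
    if gmax == 0.0:
        raise ValueError("cannot estimate moment scale from an all-zero lead field")
    return 15.0 * peak / gmax


# ---------------------------------------------------------------------------
# model bundle with marginal-likelihood cache
# ---------------------------------------------------------------------------


class Model:
    """Bundle of the model ingredients with a marginal-likelihood cache.

    The sampler evaluates p(y | N, R, sigma_q) for the same configuration
    many times; results are memoized on (sorted vertices, sigma_q).
    """

    def __init__(
        self,
        leadfield: LeadField,
        data: MEEGData,
        noise: NoiseModel,
        source_prior: SourcePrior,
        moment_prior: MomentPrior,
        source_space: SourceSpace | None = None,
    ):
        if data.n_sensors != leadfield.sensor_count:
            raise ValueError(
                f"data has {data.n_sensors} sensors, lead field "
                f"{leadfield.sensor_count}"
            )
        if source_prior.n_vertices != leadfield.n_vertices:
            raise ValueError("source prior / lead field vertex count mismatch")
        self.leadfield = leadfield
        self.data = data
        self.noise = noise
        self.source_prior = source_prior
        self.moment_prior = moment_prior
        self.source_space = source_space
        self._cache: dict[tuple, float] = {}

    @property
    def n_vertices(self) -> int:
        return self.leadfield.n_vertices

    def log_marginal(self, config: DipoleConfig, sigma_q: float) -> float:
        key = (config._key, sigma_q)
        val = self._cache.get(key)
        if val is None:
            val = log_marginal_likelihood(
                config, sigma_q, self.data, self.leadfield, self.noise
            )
            self._cache[key] = val
        return val

    def log_prior(self, config: DipoleConfig, sigma_q: float) -> float:
        lp = log_prior_config(config, self.source_prior)
        if self.moment_prior.mode == "hyper":
            lp += log_hyperprior(sigma_q, self.moment_prior)
        return lp

    def log_target(self, config: DipoleConfig, sigma_q: float, gamma: float) -> float:
        """Log of the tempered target pi_gamma ∝ likelihood^gamma * prior."""
        lp = self.log_prior(config, sigma_q)
        if lp == -np.inf:
            return -np.inf
        if gamma == 0.0:
            return lp
        return gamma * self.log_marginal(config, sigma_q) + lp
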