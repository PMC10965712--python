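"""File formats: matrices (TSV / HDF5), source spaces, datasets and results.

Result files are self-describing HDF5 with three groups:

* ``/config``    — every resolved parameter of the run, including the seed,
  so any run is re-executable from its output alone;
* ``/posterior`` — the raw particle population (per-particle dipole count,
  concatenated vertex lists with offsets, sigma_q, weights) plus the
  tempering schedule and effective-sample-size log;
* ``/estimates`` — the posterior summaries (number-of-sources pmf,
  location map, estimated dipoles, time courses, GOF, SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import yaml

from .estimates import PosteriorSummary
from .model import DipoleConfig
from .sampler import Particle, ParticleSet

__all__ = [
    "FormatError",
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "save_result",
    "load_result",
    "save_source_space",
    "load_source_space",
    "save_dataset",
    "load_dataset",
]

FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised on malformed or incompatible input files."""


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5", ".hdf")


def read_matrix(path: str | Path, dataset: str = "matrix") -> np.ndarray:
    """Read a real matrix from delimited text or an HDF5 dataset.

    Text files are whitespace/tab delimited, row-major, with ``#`` comment
    lines; HDF5 files read the named dataset.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise FormatError(f"{path}: missing dataset '{dataset}'")
            return np.asarray(f[dataset], dtype=float)
    rows: list[list[float]] = []
    width: int | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        try:
            row = [float(x) for x in stripped.split()]
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise FormatError(
                f"{path}: line {lineno} has {len(row)} columns, expected {width}"
            )
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def write_matrix(matrix: np.ndarray, path: str | Path, dataset: str = "matrix") -> None:
    """Write a real matrix as TSV or an HDF5 dataset (by file extension)."""
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=matrix)
        return
    header = f"shape: {matrix.shape[0]} x {matrix.shape[1]}"
    np.savetxt(path, matrix, delimiter="\t", header=header)


# ---------------------------------------------------------------------------
# source spaces, lead fields and datasets
# ---------------------------------------------------------------------------


def save_leadfield(leadfield, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_comp"] = leadfield.n_comp
        f.create_dataset("matrix", data=leadfield.matrix)


def load_leadfield(path: str | Path, n_comp: int | None = None):
    from .model import LeadField

    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            _check_version(f, path)
            matrix = np.asarray(f["matrix"])
            n_comp = int(f.attrs.get("n_comp", n_comp or 3))
        return LeadField(matrix=matrix, n_comp=n_comp)
    return LeadField(matrix=read_matrix(path), n_comp=n_comp or 3)


def save_source_space(space, path: str | Path, kernel_scale_m: float = 0.01) -> None:
    from .model import SourceSpace  # local to avoid import cycle at module load

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kernel_scale_m"] = kernel_scale_m
        f.create_dataset("positions", data=space.positions)
        if space.orientations is not None:
            f.create_dataset("orientations", data=space.orientations)


def load_source_space(path: str | Path):
    from .model import SourceSpace

    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        positions = np.asarray(f["positions"])
        orientations = np.asarray(f["orientations"]) if "orientations" in f else None
        scale = float(f.attrs.get("kernel_scale_m", 0.01))
    space = SourceSpace(positions=positions, orientations=orientations)
    space.build_neighbor_kernel(scale_m=scale)
    return space


def save_dataset(data, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("values", data=data.values)
        f.create_dataset("sample_times", data=data.sample_times)
        f.attrs["window"] = list(data.window)


def load_dataset(path: str | Path, window: tuple[float, float] | None = None):
    from .model import MEEGData

    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        values = np.asarray(f["values"])
        times = np.asarray(f["sample_times"])
        stored = tuple(f.attrs["window"]) if "window" in f.attrs else None
    return MEEGData(values=values, sample_times=times, window=window or stored)


def _check_version(f: h5py.File, path: Path) -> None:
    version = int(f.attrs.get("format_version", FORMAT_VERSION))
    if version > FORMAT_VERSION:
        raise FormatError(
            f"{path}: format version {version} is newer than supported "
            f"({FORMAT_VERSION})"
        )


# ---------------------------------------------------------------------------
# result files
# ---------------------------------------------------------------------------


def save_result(
    summary: PosteriorSummary,
    particles: ParticleSet,
    config: dict[str, Any],
    path: str | Path,
    iteration_log: list[dict] | None = None,
) -> None:
    """Save a completed analysis (summaries + raw particles + parameters)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        g = f.create_group("config")
        for key, val in config.items():
            if val is None:
                continue
            g.attrs[key] = val
        g = f.create_group("posterior")
        ns = np.array([p.config.n_dipoles for p in particles.particles])
        verts = np.concatenate(
            [np.asarray(p.config.vertices, dtype=np.int64) for p in particles.particles]
        ) if ns.sum() else np.zeros(0, dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(ns)])
        g.create_dataset("n_dipoles", data=ns)
        g.create_dataset("vertices", data=verts)
        g.create_dataset("offsets", data=offsets)
        g.create_dataset("sigma_q", data=np.array([p.sigma_q for p in particles.particles]))
        g.create_dataset("weights", data=particles.weights)
        g.attrs["gamma"] = particles.gamma
        if iteration_log:
            g.create_dataset("gamma_schedule", data=np.array([r["gamma"] for r in iteration_log]))
            g.create_dataset("ess_log", data=np.array([r["ess"] for r in iteration_log]))
        g = f.create_group("estimates")
        g.create_dataset("n_pmf", data=summary.n_pmf)
        g.create_dataset("location_map", data=summary.location_map)
        g.create_dataset("dipole_vertices", data=np.asarray(summary.estimated_dipoles, dtype=np.int64))
        g.create_dataset("dipole_credibility", data=np.asarray(summary.dipole_credibility))
        g.create_dataset("time_courses", data=summary.time_courses)
        if summary.amplitudes is not None:
            g.create_dataset("amplitudes", data=summary.amplitudes)
        g.attrs["n_hat"] = summary.n_hat
        g.attrs["gof"] = summary.gof
        g.attrs["sd"] = summary.sd
        g.attrs["sigma_q_hat"] = summary.sigma_q_hat
        g.attrs["units_positions"] = "m"
        g.attrs["units_time_courses"] = "A*m"


def load_result(path: str | Path) -> dict[str, Any]:
    """Load a result file; returns config dict, particle set and estimates."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        _check_version(f, path)
        for group in ("config", "posterior", "estimates"):
            if group not in f:
                raise FormatError(f"{path}: missing group '/{group}'")
        config = dict(f["config"].attrs)
        g = f["posterior"]
        ns = np.asarray(g["n_dipoles"])
        verts = np.asarray(g["vertices"])
        offsets = np.asarray(g["offsets"])
        sigma_q = np.asarray(g["sigma_q"])
        weights = np.asarray(g["weights"])
        gamma = float(g.attrs["gamma"])
        particles = []
        for i in range(len(ns)):
            vv = tuple(int(v) for v in verts[offsets[i] : offsets[i + 1]])
            particles.append(
                Particle(DipoleConfig(vv), float(sigma_q[i]), float(np.log(weights[i])), np.nan)
            )
        pset = ParticleSet(particles, gamma=gamma)
        pset.set_weights(weights)
        extra = {}
        if "gamma_schedule" in g:
            extra["gamma_schedule"] = np.asarray(g["gamma_schedule"])
            extra["ess_log"] = np.asarray(g["ess_log"])
        g = f["estimates"]
        summary = PosteriorSummary(
            n_pmf=np.asarray(g["n_pmf"]),
            n_hat=int(g.attrs["n_hat"]),
            location_map=np.asarray(g["location_map"]),
            estimated_dipoles=[int(v) for v in g["dipole_vertices"]],
            dipole_credibility=[float(v) for v in g["dipole_credibility"]],
            time_courses=np.asarray(g["time_courses"]),
            amplitudes=np.asarray(g["amplitudes"]) if "amplitudes" in g else None,
            gof=float(g.attrs["gof"]),
            sd=float(g.attrs["sd"]),
            sigma_q_hat=float(g.attrs["sigma_q_hat"]),
            alternatives=[],
        )
    return {"config": config, "particles": pset, "summary": summary, **extra}


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved inputs of one analysis run; mirrors the CLI flags.

    ``noise_std`` is ``"auto"`` (20% of the window peak), a number, or
    ``"baseline:T0:T1"`` (pooled std over a baseline window).
    ``dip_mom_std`` is ``"auto"`` (fixed sigma_q from data and lead field),
    ``"hyper"`` (log-uniform hyper-prior seeded from the same estimate), or
    a number.
    """

    leadfield: str
    data: str
    source_space: str
    output: str
    window: tuple[float, float] | None = None
    noise_std: str | float = "auto"
    dip_mom_std: str | float = "hyper"
    n_particles: int = 100
    n_max: int = 10
    seed: int = 0
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: expected a mapping of run options")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown options {sorted(unknown)}")
        if "window" in raw and raw["window"] is not None:
            raw["window"] = tuple(float(x) for x in raw["window"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if data["window"] is not None:
            data["window"] = list(data["window"])
        Path(path).write_text(yaml.safe_dump(data))
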