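"""Observables, trajectory logging, file export, configuration and logging —
the run-facing shell of the simulator.

Per-iteration observables (piston height, collision counts, compartment work,
peak membrane height, contact area, bond counts) accumulate in a
:class:`TrajectoryLog`; logs export to CSV with a stable column order and
mesh snapshots export as numbered OBJ frames that any mesh viewer loads.
"""

from __future__ import annotations

import json
import logging
import math
from collections import namedtuple
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mesh_core import TriMesh, save_obj, ParameterError

logger = logging.getLogger("membranemc")


def setup_run_logging(level=logging.INFO) -> logging.Logger:
    """Structured, leveled run logging (idempotent)."""
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s"))
        logger.addHandler(h)
    logger.setLevel(level)
    return logger


def echo_config(config, seed) -> None:
    """Log the resolved configuration and seed at run start (provenance)."""
    logger.info("run start: seed=%s config=%s", seed, config)


class NaNObservableError(RuntimeError):
    """A non-finite number reached the trajectory log; the run is aborted."""


class TrajectoryLog:
    """Per-iteration observable records plus a mesh-snapshot manifest.

    Records are keyed by a strictly increasing iteration index; every value
    must be finite — a NaN anywhere aborts the run with a clear error.
    """

    def __init__(self):
        self.records: list[dict] = []
        self.snapshots: list[tuple[int, TriMesh]] = []
        self._last_iteration = None

    def add(self, iteration: int, **observables) -> None:
        if self._last_iteration is not None and iteration <= self._last_iteration:
            raise ValueError("iteration indices must be strictly increasing")
        for key, val in observables.items():
            if isinstance(val, (int, float, np.floating, np.integer)):
                if not math.isfinite(float(val)):
                    raise NaNObservableError(
                        f"non-finite observable {key}={val} at iteration "
                        f"{iteration}; aborting")
        self.records.append({"iteration": iteration, **observables})
        self._last_iteration = iteration

    def snapshot(self, iteration: int, mesh: TriMesh) -> None:
        self.snapshots.append((iteration, mesh.copy()))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def dataframe(self) -> pd.DataFrame:
        if not self.records:
            return pd.DataFrame(columns=["iteration"])
        return pd.DataFrame(self.records)

    def series(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.records])


def export_csv(log: TrajectoryLog, path) -> None:
    """One CSV row per iteration, stable column order; floats round-trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    log.dataframe.to_csv(path, index=False)


def load_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_mesh_frames(log: TrajectoryLog, outdir) -> list[Path]:
    """Write snapshot meshes as OBJ files named by zero-padded iteration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for iteration, mesh in log.snapshots:
        p = outdir / f"frame_{iteration:06d}.obj"
        save_obj(mesh, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# observables

def contact_area(mesh: TriMesh, plane_z: float, proximity_delta: float = 0.05) -> float:
    """Total area of faces all of whose vertices lie within ``proximity_delta``
    of the plane z = plane_z (µm²) — the spreading readout."""
    if proximity_delta <= 0:
        raise ParameterError("proximity_delta must be positive")
    close = np.abs(mesh.vertices[:, 2] - plane_z) <= proximity_delta
    face_close = close[mesh.faces].all(axis=1)
    if not face_close.any():
        return 0.0
    from .mesh_core import triangle_areas
    return float(triangle_areas(mesh.vertices, mesh.faces[face_close]).sum())


def contact_area_to_mesh(mesh: TriMesh, other: TriMesh,
                         proximity_delta: float = 0.05) -> float:
    """Contact area against another (e.g. rigid) mesh: faces whose vertices
    all lie within ``proximity_delta`` of the other mesh's vertices."""
    from scipy.spatial import cKDTree
    d, _ = cKDTree(other.vertices).query(mesh.vertices)
    close = d <= proximity_delta
    face_close = close[mesh.faces].all(axis=1)
    if not face_close.any():
        return 0.0
    from .mesh_core import triangle_areas
    return float(triangle_areas(mesh.vertices, mesh.faces[face_close]).sum())


def peak_height(mesh: TriMesh, reference_z: float = 0.0) -> float:
    """Maximum vertex z minus the reference plane (µm)."""
    return float(mesh.vertices[:, 2].max() - reference_z)


def normalized_series(series) -> np.ndarray:
    """Series divided by its final value (e.g. normalized contact area or
    cumulative interactions, as plotted for spreading time courses)."""
    x = np.asarray(series, dtype=float)
    if len(x) == 0 or x[-1] == 0:
        return x.copy()
    return x / x[-1]


def scaled_time(log: TrajectoryLog, scale: float = 1.0,
                timestep: float = 1.0) -> np.ndarray:
    """Iteration axis in physical time, times a user-supplied scale factor.

    Comparison of simulated spreading curves with experimental ones uses a
    single multiplicative rescaling of the time axis; no fitting is done.
    """
    return log.series("iteration") * timestep * scale


DiffusionFit = namedtuple("DiffusionFit", ["D", "r_squared", "slope"])


def estimate_diffusion_coefficient(series, dt: float) -> DiffusionFit:
    """Diffusion coefficient from the MSD slope of a 1D trajectory ensemble.

    ``series``: (T,) single trajectory or (R, T) ensemble of z positions (µm)
    sampled every ``dt`` µs.  The mean-squared displacement, averaged over
    the ensemble and over all time origins (the standard overlapping-window
    MSD estimator), is fit by least squares over short lag times (up to 5% of
    the series length, at least 25 lags), where the estimator's relative
    error is smallest; long lags carry strongly correlated noise and would
    dominate the fit.  D = slope/2 (one-dimensional walk) is reported in
    nm²/µs together with the fit R² as a linearity diagnostic (a drifting,
    ballistic series gives a quadratic MSD and a poor R²).
    """
    z = np.atleast_2d(np.asarray(series, dtype=float))
    if z.shape[1] < 100:
        raise ParameterError("need at least 100 samples to estimate D")
    n_fit = min(max(z.shape[1] // 20, 25), z.shape[1] - 1)
    msd = np.empty(n_fit)
    msd[0] = 0.0
    for lag in range(1, n_fit):
        d = z[:, lag:] - z[:, :-lag]
        msd[lag] = float(np.mean(d * d))             # µm²
    t = np.arange(n_fit) * dt                        # µs
    y = msd
    if np.allclose(y, 0.0):
        return DiffusionFit(0.0, 1.0, 0.0)
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    d_um2_per_us = slope / 2.0
    return DiffusionFit(d_um2_per_us * 1e6, r2, slope)  # µm² = 1e6 nm²


# ---------------------------------------------------------------------------
# configuration files

def load_config(path) -> dict:
    """Read a scenario configuration mapping from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: configuration must be a mapping")
    return data


def rolling_mean(x, window: int) -> np.ndarray:
    """Simple trailing-window smoothing used for monotonicity readouts."""
    x = np.asarray(x, dtype=float)
    if window <= 1 or len(x) < window:
        return x.copy()
    c = np.cumsum(np.insert(x, 0, 0.0))
    return (c[window:] - c[:-window]) / window


def smoothed_growth_is_monotone(series, window: int = 200,
                                drawdown_fraction: float = 0.05) -> bool:
    """Whether a growing observable (contact area, bond count) increases
    monotonically at the resolution of its own fluctuations.

    The series is window-averaged and the maximum drawdown (retreat below
    the running maximum) of the smoothed curve must not exceed
    ``drawdown_fraction`` of its net growth.  The default 200-iteration
    window matches the breathing correlation time of the desk-scale contact
    readout (a few thousand molecules); with the full-scale molecule counts
    a much shorter window suffices.  A genuine collapse of the contact
    (sustained decline) fails this test at any window.
    """
    s = rolling_mean(series, window)
    growth = float(s[-1] - s[0])
    if growth <= 0:
        return bool((np.diff(s) >= 0).all())
    drawdown = float((np.maximum.accumulate(s) - s).max())
    return drawdown <= drawdown_fraction * growth


def smoothed_relaxation_is_monotone(series, window: int = 25,
                                    band_sigmas: float = 3.0) -> bool:
    """Whether a relaxing observable decays monotonically at the resolution
    of its own thermal fluctuations.

    The series is window-averaged; the stationary fluctuation scale is taken
    from the last quarter of the smoothed series, and the decay is monotone
    if no smoothed step increases by more than ``band_sigmas`` standard
    deviations of that scale before the series first enters the stationary
    band (tail mean + band_sigmas·std).
    """
    s = rolling_mean(series, window)
    tail = s[-max(len(s) // 4, 2):]
    scale = float(tail.std())
    band = float(tail.mean()) + band_sigmas * scale
    inband = np.nonzero(s <= band)[0]
    stop = int(inband[0]) if len(inband) else len(s)
    if stop < 2:
        return True
    return bool((np.diff(s[:stop]) <= band_sigmas * scale).all())
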