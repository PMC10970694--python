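"""HOLE-style pore radius/diameter profile along a fixed axis.

At each station along the (known, straight) pore axis the maximal inscribed
sphere is found in the perpendicular plane: the centre maximising
``min over atoms of (|c − atom| − r_vdw)``, located by a grid search followed
by a local simplex polish.  Unlike HOLE's connected Monte-Carlo walk, the
per-station maximisation is independent and deterministic — adequate for
near-straight paracellular pores whose axis is known, and reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .errors import ConfigError, GeometryError
from .model import Frame, Selection, Topology, Trajectory, resolve_window

__all__ = ["PoreAxisSpec", "PoreProfile", "pore_radius_at_station", "pore_profile"]

SLAB_HALF_WIDTH = 10.0  # Å; atoms farther along the axis cannot bind the sphere
REFINE_TOL = 0.01  # Å


@dataclass(frozen=True)
class PoreAxisSpec:
    """Axis and search parameters for the profiler.

    ``axis`` need not be +x; coordinates are rotated into an axis-aligned
    frame internally.  ``search_radius`` bounds the lateral offset of the
    sphere centre; ``grid_step`` is the coarse search resolution (the local
    polish refines to 0.01 Å).
    """

    x_min: float
    x_max: float
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    station_spacing: float = 0.5
    search_radius: float = 15.0
    grid_step: float = 0.25

    def __post_init__(self) -> None:
        if self.x_min >= self.x_max:
            raise ConfigError("x_min must be below x_max")
        if self.station_spacing <= 0 or self.grid_step <= 0:
            raise ConfigError("spacings must be positive")

    def basis(self) -> np.ndarray:
        """Orthonormal basis (rows) with the pore axis first."""
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ConfigError("axis must be a nonzero vector")
        a = a / n
        helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(a, helper)
        u /= np.linalg.norm(u)
        v = np.cross(a, u)
        return np.vstack([a, u, v])

    def stations(self) -> np.ndarray:
        n = int(np.floor((self.x_max - self.x_min) / self.station_spacing + 1e-9)) + 1
        return self.x_min + self.station_spacing * np.arange(n)


@dataclass
class StationResult:
    center: np.ndarray  # original coordinates
    radius: float
    blocked: bool


@dataclass
class PoreProfile:
    """Mean/SD pore diameter per station over a trajectory window."""

    stations: np.ndarray
    mean_diameter: np.ndarray
    sd_diameter: np.ndarray
    blocked: np.ndarray  # True where the sphere radius was negative in any frame
    masked: np.ndarray  # True where no atoms were in range
    per_frame_diameter: np.ndarray | None = None  # (n_frames, n_stations)

    @property
    def min_mean_diameter(self) -> float:
        valid = ~self.masked
        return float(np.nanmin(self.mean_diameter[valid]))

    @property
    def min_station(self) -> float:
        valid = np.where(~self.masked)[0]
        k = valid[np.nanargmin(self.mean_diameter[valid])]
        return float(self.stations[k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_A": self.stations,
                "mean_diameter_A": self.mean_diameter,
                "sd_A": self.sd_diameter,
                "blocked": self.blocked,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _radius_fn(slab_coords: np.ndarray, slab_radii: np.ndarray):
    def radius(c: np.ndarray) -> float:
        d = np.linalg.norm(slab_coords - c, axis=1) - slab_radii
        return float(d.min())
    return radius


def pore_radius_at_station(
    frame: Frame,
    topology: Topology,
    station: float,
    spec: PoreAxisSpec,
    exclude: Selection | None = None,
) -> StationResult:
    """Maximal inscribed sphere in the plane through *station* ⊥ axis.

    Returns the centre (original coordinates), the radius, and a ``blocked``
    flag when even the best centre overlaps an atom (negative radius,
    reported as-is).
    """
    B = spec.basis()
    coords = frame.coords @ B.T  # axis-aligned frame: column 0 is the axis
    keep = np.ones(topology.n_atoms, dtype=bool)
    if exclude is not None:
        import warnings
        from .errors import EmptySelectionWarning
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptySelectionWarning)
            keep[exclude.resolve(topology)] = False
    slab = keep & (np.abs(coords[:, 0] - station) <= SLAB_HALF_WIDTH)
    if not np.any(slab):
        raise GeometryError(f"no atoms within range of station {station:g} Å")
    slab_coords = coords[slab]
    slab_radii = topology.vdw_radii[slab]

    # coarse grid in the station plane, centred on the slab's lateral centroid
    cy, cz = slab_coords[:, 1].mean(), slab_coords[:, 2].mean()
    g = np.arange(-spec.search_radius, spec.search_radius + 1e-9, spec.grid_step)
    gy, gz = np.meshgrid(g + cy, g + cz, indexing="ij")
    lateral_ok = (gy - cy) ** 2 + (gz - cz) ** 2 <= spec.search_radius**2
    cand = np.column_stack(
        [np.full(lateral_ok.sum(), station), gy[lateral_ok], gz[lateral_ok]]
    )
    d = cdist(cand, slab_coords) - slab_radii[None, :]
    rad = d.min(axis=1)
    best = int(np.argmax(rad))

    # local polish (2D Nelder–Mead in the plane), deterministic start
    fn = _radius_fn(slab_coords, slab_radii)

    def neg(yz: np.ndarray) -> float:
        # keep the polish inside the lateral search disc
        if (yz[0] - cy) ** 2 + (yz[1] - cz) ** 2 > spec.search_radius**2:
            return 1e9
        return -fn(np.array([station, yz[0], yz[1]]))

    res = minimize(
        neg,
        x0=cand[best, 1:],
        method="Nelder-Mead",
        options={"xatol": REFINE_TOL, "fatol": REFINE_TOL / 10, "maxiter": 200},
    )
    yz = res.x if -res.fun >= rad[best] else cand[best, 1:]
    radius = max(-res.fun, float(rad[best]))
    center_axis = np.array([station, yz[0], yz[1]])
    return StationResult(center=center_axis @ B, radius=radius, blocked=radius < 0)


def pore_profile(
    traj: Trajectory,
    spec: PoreAxisSpec,
    window=None,
    exclude: Selection | None = None,
    keep_per_frame: bool = False,
) -> PoreProfile:
    """Per-station mean and SD of the pore diameter (2 × inscribed radius)
    over a trajectory window.  Stations with no atoms in range are masked."""
    win = resolve_window(window, traj.n_frames)
    stations = spec.stations()
    diam = np.full((len(win), len(stations)), np.nan)
    blocked = np.zeros(len(stations), dtype=bool)
    masked = np.zeros(len(stations), dtype=bool)
    for k, fi in enumerate(win):
        frame = traj.frames[fi]
        for s, st in enumerate(stations):
            if masked[s]:
                continue
            try:
                r = pore_radius_at_station(frame, traj.topology, float(st), spec, exclude)
            except GeometryError:
                masked[s] = True
                continue
            diam[k, s] = 2.0 * r.radius
            blocked[s] |= r.blocked
    mean = np.nanmean(np.where(np.isnan(diam), np.nan, diam), axis=0)
    sd = np.nanstd(diam, axis=0)
    mean[masked] = np.nan
    sd[masked] = np.nan
    return PoreProfile(
        stations=stations,
        mean_diameter=mean,
        sd_diameter=sd,
        blocked=blocked,
        masked=masked,
        per_frame_diameter=diam if keep_per_frame else None,
    )
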