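"""Model domain, idealized Bohai bathymetry, and synthetic inputs.

The domain is the Bohai Sea box (37-41N, 117.5-122.5E) on a regular
lon/lat lattice with a small number of z-layers.  Everything real-world
(ROMS currents, NCEP temperature, WOA nitrate) is replaced by smooth
parametric generators so every experiment runs offline; externally
supplied NetCDF fields can be substituted through :mod:`npzdvar.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelGrid",
    "ForcingFields",
    "TruthField",
    "make_bohai_grid",
    "make_synthetic_forcing",
    "make_truth_ie1",
    "make_truth_ie2",
    "surface_to_3d",
    "idealized_bathymetry",
]

LON_MIN, LON_MAX = 117.5, 122.5
LAT_MIN, LAT_MAX = 37.0, 41.0
EARTH_RADIUS = 6_371_000.0  # m

DEFAULT_LAYERS = (5.0, 10.0, 10.0, 20.0, 25.0, 25.0)

#: vertical e-folding scale (m) used to extend surface patterns downward
PROFILE_SCALE = 20.0

#: minimum water depth (m) on wet cells; keeps the surface layer active
MIN_WET_DEPTH = 6.0

# Idealized geography in normalized coordinates x=(lon-117.5)/5, y=(lat-37)/4:
# one central basin plus the three bays (west, north-east, south).
# Each entry: (cx, cy, semi_x, semi_y, max_depth_m).
BASIN_ELLIPSE = (0.55, 0.50, 0.28, 0.30, 70.0)
BAY_ELLIPSES = {
    "bohai_bay": (0.18, 0.55, 0.18, 0.18, 22.0),
    "liaodong_bay": (0.78, 0.78, 0.14, 0.20, 25.0),
    "laizhou_bay": (0.62, 0.15, 0.20, 0.14, 18.0),
}


@dataclass
class ModelGrid:
    """Structured lon/lat grid with z-layers and a land/sea mask.

    Parameters
    ----------
    lon_edges, lat_edges : ndarray
        Cell edge coordinates in degrees, lengths nx+1 and ny+1.
    layer_thickness : ndarray
        Layer thicknesses in metres, surface first.
    mask : ndarray of bool, shape (ny, nx)
        True on wet cells.
    depth : ndarray, shape (ny, nx)
        Water depth in metres (0 on land).
    """

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    layer_thickness: np.ndarray
    mask: np.ndarray
    depth: np.ndarray

    # derived, filled in __post_init__
    active: np.ndarray = field(init=False, repr=False)
    cell_index: np.ndarray = field(init=False, repr=False)
    n_active: int = field(init=False)

    def __post_init__(self) -> None:
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.layer_thickness = np.asarray(self.layer_thickness, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.layer_thickness.ndim != 1 or self.layer_thickness.size == 0:
            raise ValueError("layer_thickness must be a non-empty 1-D sequence")
        if np.any(self.layer_thickness <= 0):
            raise ValueError("layer thicknesses must be strictly positive")
        if self.mask.shape != (self.ny, self.nx):
            raise ValueError("mask shape does not match grid extent")
        if self.depth.shape != self.mask.shape:
            raise ValueError("depth shape does not match mask")
        if np.any(self.depth[self.mask] <= 0):
            raise ValueError("wet cells must have positive depth")
        # layer k is active where the layer top lies above the sea bed
        z_top = self.z_interfaces[:-1]
        self.active = self.mask[None, :, :] & (self.depth[None, :, :] > z_top[:, None, None])
        self.cell_index = np.full(self.active.shape, -1, dtype=np.int64)
        self.cell_index[self.active] = np.arange(int(self.active.sum()))
        self.n_active = int(self.active.sum())

    # ------------------------------------------------------------------ sizes
    @property
    def nx(self) -> int:
        return self.lon_edges.size - 1

    @property
    def ny(self) -> int:
        return self.lat_edges.size - 1

    @property
    def nz(self) -> int:
        return self.layer_thickness.size

    # ------------------------------------------------------------- geometry
    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def z_interfaces(self) -> np.ndarray:
        """Depths of layer interfaces, surface (0) to bottom, length nz+1."""
        return np.concatenate([[0.0], np.cumsum(self.layer_thickness)])

    @property
    def z_mid(self) -> np.ndarray:
        zi = self.z_interfaces
        return 0.5 * (zi[:-1] + zi[1:])

    @property
    def dx(self) -> float:
        """Zonal cell size in metres (uniform, taken at mid-latitude)."""
        dlon = np.deg2rad(self.lon_edges[1] - self.lon_edges[0])
        midlat = np.deg2rad(0.5 * (self.lat_edges[0] + self.lat_edges[-1]))
        return float(EARTH_RADIUS * np.cos(midlat) * dlon)

    @property
    def dy(self) -> float:
        dlat = np.deg2rad(self.lat_edges[1] - self.lat_edges[0])
        return float(EARTH_RADIUS * dlat)

    @property
    def cell_volumes(self) -> np.ndarray:
        """Volume (m^3) of every active cell, flat ordering."""
        vol3 = np.broadcast_to(
            (self.dx * self.dy) * self.layer_thickness[:, None, None],
            self.active.shape,
        )
        return vol3[self.active]

    # ------------------------------------------------------------- indexing
    def flatten(self, field3d: np.ndarray) -> np.ndarray:
        """Extract active-cell values from an (nz, ny, nx) array."""
        return np.asarray(field3d, dtype=float)[self.active]

    def unflatten(self, flat: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a flat active-cell vector back to (nz, ny, nx)."""
        out = np.full(self.active.shape, fill, dtype=float)
        out[self.active] = flat
        return out

    def surface_flatten(self, field2d: np.ndarray) -> np.ndarray:
        """Extract wet-cell values from an (ny, nx) surface array."""
        return np.asarray(field2d, dtype=float)[self.mask]

    def surface_unflatten(self, flat: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = flat
        return out

    @property
    def n_wet(self) -> int:
        return int(self.mask.sum())


@dataclass
class ForcingFields:
    """Physical forcing on a :class:`ModelGrid`.

    Velocities live on cell faces so the finite-volume transport sees an
    exactly non-divergent flow: ``u`` has shape (nz, ny, nx+1) and ``v``
    has shape (nz, ny+1, nx).  ``sst`` and ``surface_irradiance`` carry one
    entry per model time level (6-h cadence by default).
    """

    u: np.ndarray
    v: np.ndarray
    sst: np.ndarray
    surface_irradiance: np.ndarray
    horizontal_diffusivity: float
    vertical_diffusivity: float
    step_hours: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.sst = np.asarray(self.sst, dtype=float)
        self.surface_irradiance = np.asarray(self.surface_irradiance, dtype=float)
        if not np.all(np.isfinite(self.sst)):
            raise ValueError("sst must be finite")
        if np.any(self.surface_irradiance < 0):
            raise ValueError("surface irradiance must be non-negative")
        if self.sst.shape[0] != self.surface_irradiance.shape[0]:
            raise ValueError("sst and irradiance time axes differ")

    @property
    def n_times(self) -> int:
        return self.sst.shape[0]

    def u_centered(self) -> np.ndarray:
        """Cell-centered zonal velocity (average of the two x-faces)."""
        return 0.5 * (self.u[:, :, :-1] + self.u[:, :, 1:])

    def v_centered(self) -> np.ndarray:
        return 0.5 * (self.v[:, :-1, :] + self.v[:, 1:, :])


@dataclass
class TruthField:
    """Prescribed phytoplankton distribution used as twin-experiment truth."""

    values: np.ndarray  # (nz, ny, nx), mmol N m^-3, 0 on dry cells
    label: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("truth field must be non-negative")

    @property
    def surface(self) -> np.ndarray:
        return self.values[0]


# ---------------------------------------------------------------------------
# idealized geography
# ---------------------------------------------------------------------------

def _ellipse_r2(xn: np.ndarray, yn: np.ndarray, ell) -> np.ndarray:
    cx, cy, sx, sy, _ = ell
    return ((xn - cx) / sx) ** 2 + ((yn - cy) / sy) ** 2


def idealized_bathymetry(lon_centers: np.ndarray, lat_centers: np.ndarray):
    """Idealized Bohai mask and depth: central basin plus three bay lobes.

    Returns (mask, depth).  The outermost ring of cells is always land so
    the basin is closed.
    """
    xn = (lon_centers[None, :] - LON_MIN) / (LON_MAX - LON_MIN)
    yn = (lat_centers[:, None] - LAT_MIN) / (LAT_MAX - LAT_MIN)
    xn, yn = np.broadcast_arrays(xn, yn)

    depth = np.zeros_like(xn)
    wet = np.zeros(xn.shape, dtype=bool)
    for ell in (BASIN_ELLIPSE, *BAY_ELLIPSES.values()):
        r2 = _ellipse_r2(xn, yn, ell)
        inside = r2 < 1.0
        wet |= inside
        depth = np.maximum(depth, np.where(inside, ell[4] * (1.0 - r2), 0.0))

    # closed domain: land ring at the edge
    wet[0, :] = wet[-1, :] = False
    wet[:, 0] = wet[:, -1] = False
    depth = np.where(wet, np.maximum(depth, MIN_WET_DEPTH), 0.0)
    return wet, depth


def basin_centroid_lonlat() -> tuple[float, float]:
    """Lon/lat of the central-basin centre of the idealized geography."""
    cx, cy = BASIN_ELLIPSE[0], BASIN_ELLIPSE[1]
    return LON_MIN + cx * (LON_MAX - LON_MIN), LAT_MIN + cy * (LAT_MAX - LAT_MIN)


def bay_centers_lonlat() -> dict[str, tuple[float, float]]:
    out = {}
    for name, (cx, cy, *_rest) in BAY_ELLIPSES.items():
        out[name] = (LON_MIN + cx * (LON_MAX - LON_MIN), LAT_MIN + cy * (LAT_MAX - LAT_MIN))
    return out


def make_bohai_grid(
    resolution_arcmin: float = 4.0,
    layer_thicknesses=DEFAULT_LAYERS,
    bathymetry: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> ModelGrid:
    """Build the Bohai-box grid at the requested resolution.

    Parameters
    ----------
    resolution_arcmin : float
        Horizontal spacing in arc-minutes; must divide the 5 deg x 4 deg
        extent into whole cells.
    layer_thicknesses : sequence of float
        Layer thicknesses in metres, surface first.
    bathymetry, mask : ndarray, optional
        User-supplied depth (m) and wet mask on the cell lattice; the
        idealized geography is used when omitted.
    """
    thick = np.asarray(layer_thicknesses, dtype=float)
    if thick.ndim != 1 or thick.size == 0 or np.any(thick <= 0):
        raise ValueError("layer thicknesses must be a non-empty positive sequence")
    deg = resolution_arcmin / 60.0
    nx_f = (LON_MAX - LON_MIN) / deg
    ny_f = (LAT_MAX - LAT_MIN) / deg
    nx, ny = round(nx_f), round(ny_f)
    if abs(nx_f - nx) > 1e-9 or abs(ny_f - ny) > 1e-9:
        raise ValueError(
            f"resolution {resolution_arcmin}' does not divide the domain into whole cells"
        )
    lon_edges = np.linspace(LON_MIN, LON_MAX, nx + 1)
    lat_edges = np.linspace(LAT_MIN, LAT_MAX, ny + 1)
    lonc = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    latc = 0.5 * (lat_edges[:-1] + lat_edges[1:])

    if bathymetry is None:
        wet, depth = idealized_bathymetry(lonc, latc)
    else:
        depth = np.asarray(bathymetry, dtype=float)
        wet = depth > 0 if mask is None else np.asarray(mask, dtype=bool)
        depth = np.where(wet, np.maximum(depth, MIN_WET_DEPTH), 0.0)
    return ModelGrid(lon_edges, lat_edges, thick, wet, depth)


# ---------------------------------------------------------------------------
# synthetic forcing
# ---------------------------------------------------------------------------

def _gyre_face_velocities(grid: ModelGrid, max_speed: float) -> tuple[np.ndarray, np.ndarray]:
    """Streamfunction-derived face velocities, exactly non-divergent.

    The streamfunction lives on cell corners and vanishes on corners that
    touch any dry cell, which closes the flow at the coast.  Amplitude
    decays with depth.
    """
    ny, nx, nz = grid.ny, grid.nx, grid.nz
    # corner coordinates, normalized
    xe = (grid.lon_edges - LON_MIN) / (LON_MAX - LON_MIN)
    ye = (grid.lat_edges - LAT_MIN) / (LAT_MAX - LAT_MIN)
    psi_raw = np.sin(np.pi * xe[None, :]) * np.sin(np.pi * ye[:, None])  # (ny+1, nx+1)

    decay = np.exp(-grid.z_mid / 30.0)  # weaker flow at depth
    u = np.zeros((nz, ny, nx + 1))
    v = np.zeros((nz, ny + 1, nx))
    for k in range(nz):
        # a corner carries streamfunction only when all four neighbouring
        # cells are active at this layer; faces touching inactive cells then
        # get zero velocity and each layer stays exactly non-divergent
        padded = np.zeros((ny + 2, nx + 2), dtype=bool)
        padded[1:-1, 1:-1] = grid.active[k]
        interior = (
            padded[:-1, :-1] & padded[:-1, 1:] & padded[1:, :-1] & padded[1:, 1:]
        )
        psi = np.where(interior, psi_raw, 0.0)
        u[k] = -decay[k] * (psi[1:, :] - psi[:-1, :]) / grid.dy
        v[k] = decay[k] * (psi[:, 1:] - psi[:, :-1]) / grid.dx

    peak = max(np.abs(u).max(), np.abs(v).max())
    scale = 0.0 if peak == 0 else max_speed / peak
    return scale * u, scale * v


def make_synthetic_forcing(
    grid: ModelGrid,
    days: float = 30.0,
    step_hours: float = 6.0,
    seed: int = 0,
    max_speed: float = 0.1,
    horizontal_diffusivity: float = 50.0,
    vertical_diffusivity: float = 1e-4,
    irradiance_peak: float = 100.0,
    sst_mean: float = 22.0,
) -> ForcingFields:
    """Generate gyre circulation, SST and irradiance time series.

    The circulation is steady and layerwise non-divergent; SST combines a
    warm-shallow/cool-deep spatial pattern, a diurnal cycle, a slow trend
    and a seeded smooth perturbation; irradiance is a truncated diurnal
    sinusoid peaking at local noon.  Deterministic for a fixed seed.
    """
    if days <= 0:
        raise ValueError("days must be positive")
    if step_hours <= 0 or 24.0 % step_hours != 0:
        raise ValueError("step_hours must be positive and divide 24")
    n_steps = int(round(days * 24.0 / step_hours))
    hours = np.arange(n_steps + 1) * step_hours

    u, v = _gyre_face_velocities(grid, max_speed) if max_speed > 0 else (
        np.zeros((grid.nz, grid.ny, grid.nx + 1)),
        np.zeros((grid.nz, grid.ny + 1, grid.nx)),
    )

    rng = np.random.default_rng(seed)
    yn = (grid.lat_centers[:, None] - LAT_MIN) / (LAT_MAX - LAT_MIN)
    depth_n = grid.depth / max(grid.depth.max(), 1.0)
    # warm in the south and in the shallow bays, cool over the deep basin
    pattern = sst_mean + 1.5 * (1.0 - yn) - 3.0 * depth_n
    # seeded large-scale perturbation keeps runs distinguishable by seed
    phase = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.1, 0.3)
    xn = (grid.lon_centers[None, :] - LON_MIN) / (LON_MAX - LON_MIN)
    pattern = pattern + amp * np.sin(np.pi * xn + phase) * np.sin(np.pi * yn)

    diurnal = 0.5 * np.sin(2 * np.pi * (hours % 24.0 - 9.0) / 24.0)
    trend = 0.02 * hours / 24.0
    sst = pattern[None, :, :] + (diurnal + trend)[:, None, None]
    sst = np.where(grid.mask[None, :, :], sst, 0.0)

    hod = hours % 24.0
    irradiance = irradiance_peak * np.maximum(0.0, np.sin(np.pi * (hod - 6.0) / 12.0))

    return ForcingFields(
        u=u,
        v=v,
        sst=sst,
        surface_irradiance=irradiance,
        horizontal_diffusivity=horizontal_diffusivity,
        vertical_diffusivity=vertical_diffusivity,
        step_hours=step_hours,
    )


# ---------------------------------------------------------------------------
# truth fields
# ---------------------------------------------------------------------------

def surface_to_3d(grid: ModelGrid, surface: np.ndarray) -> np.ndarray:
    """Extend a surface pattern downward with an exponential profile.

    The surface layer carries the pattern unchanged; deeper layers are
    attenuated by exp(-(z - z_surface)/20 m).  Inactive cells are zero.
    """
    zm = grid.z_mid
    profile = np.exp(-(zm - zm[0]) / PROFILE_SCALE)
    out = profile[:, None, None] * np.asarray(surface, dtype=float)[None, :, :]
    out[~grid.active] = 0.0
    return out


def vertical_profile(grid: ModelGrid) -> np.ndarray:
    zm = grid.z_mid
    return np.exp(-(zm - zm[0]) / PROFILE_SCALE)


def make_truth_ie1(grid: ModelGrid, peak: float = 3.0, floor: float = 0.5) -> TruthField:
    """Paraboloid truth: low over the central basin, high toward the bays."""
    if not peak > floor >= 0:
        raise ValueError("require peak > floor >= 0")
    lon0, lat0 = basin_centroid_lonlat()
    # radial distance in scaled degrees so the paraboloid is round in the box
    dx = (grid.lon_centers[None, :] - lon0) / (LON_MAX - LON_MIN)
    dy = (grid.lat_centers[:, None] - lat0) / (LAT_MAX - LAT_MIN)
    r2 = dx**2 + dy**2
    r2_max = r2[grid.mask].max()
    surface = floor + (peak - floor) * r2 / r2_max
    surface = np.where(grid.mask, surface, 0.0)
    return TruthField(surface_to_3d(grid, surface), label="IE1")


def make_truth_ie2(
    grid: ModelGrid,
    forcing: ForcingFields,
    p_ref: float = 1.5,
    slope: float = 0.2,
) -> TruthField:
    """Temperature-driven truth: affine in time-mean SST, clipped at zero."""
    if forcing.sst.shape[1:] != grid.mask.shape:
        raise ValueError("forcing does not cover the grid")
    sst_mean = forcing.sst.mean(axis=0)
    ref = sst_mean[grid.mask].mean()
    surface = np.clip(p_ref + slope * (sst_mean - ref), 0.0, None)
    surface = np.where(grid.mask, surface, 0.0)
    return TruthField(surface_to_3d(grid, surface), label="IE2")
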