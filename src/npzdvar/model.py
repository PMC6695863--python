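"""Nitrogen-based NPZD model: biology kinetics, transport, forward runs.

The four compartments (nutrient N, phytoplankton P, zooplankton Z,
detritus D, all mmol N m^-3) evolve under operator splitting: a linear
finite-volume transport step (first-order upwind advection, centered
diffusion, vertical sinking) followed by forward-Euler biology.  The
transport operator is materialized as a sparse matrix so the adjoint can
use its exact transpose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, asdict

import numpy as np
import scipy.sparse as sp

from .grid import ForcingFields, ModelGrid, TruthField, vertical_profile

__all__ = [
    "EcoParameters",
    "EcoState",
    "CFLError",
    "temperature_factor",
    "nutrient_limitation",
    "light_limitation",
    "grazing_rate",
    "biological_tendencies",
    "build_transport_matrix",
    "transport_step",
    "NPZDModel",
    "Trajectory",
    "run_forward",
    "spin_up",
]

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0


class CFLError(RuntimeError):
    """Transport stability condition violated for the requested time step."""


@dataclass(frozen=True)
class EcoParameters:
    """Ecological constants (defaults are the standard coastal set).

    Units: rates day^-1, Kext m^-1, Io W m^-2, sinking m day^-1,
    Ks mmol m^-3, f_ivlev m^3 (mmol N)^-1; Q10 factors, gamma and theta
    dimensionless.
    """

    Vm: float = 1.0        # max phytoplankton growth
    Gm: float = 0.5        # max zooplankton grazing
    Dp: float = 0.1        # phytoplankton mortality
    Dz: float = 0.2        # zooplankton mortality
    e: float = 0.05        # detritus remineralization
    AQ10: float = 2.08     # phytoplankton growth Q10
    BQ10: float = 3.10     # zooplankton grazing Q10
    gamma: float = 0.75    # assimilated fraction of grazing
    theta: float = 0.03    # excreted fraction of grazing
    Kext: float = 1.0      # light attenuation
    Io: float = 100.0      # optimum irradiance
    wp: float = 0.73       # phytoplankton sinking
    wd: float = 1.00       # detritus sinking
    Ks: float = 1.0        # nutrient half-saturation
    f_ivlev: float = 0.2   # Ivlev grazing constant

    def __post_init__(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if v < 0:
                raise ValueError(f"parameter {f_.name} must be non-negative, got {v}")
        if self.gamma > 1:
            raise ValueError("gamma must be <= 1")
        if self.theta > 1:
            raise ValueError("theta must be <= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EcoState:
    """Concentrations of the four compartments on active cells."""

    N: np.ndarray
    P: np.ndarray
    Z: np.ndarray
    D: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.N, self.P, self.Z, self.D])

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "EcoState":
        return cls(N=arr[0], P=arr[1], Z=arr[2], D=arr[3])


# ---------------------------------------------------------------------------
# biology kinetics
# ---------------------------------------------------------------------------

def temperature_factor(T, Q10):
    """Q10 temperature response, Q10 ** ((T - 10) / 10)."""
    if np.any(np.asarray(Q10) <= 0):
        raise ValueError("Q10 must be positive")
    return np.power(Q10, (np.asarray(T, dtype=float) - 10.0) / 10.0)


def nutrient_limitation(N, Ks):
    """Michaelis-Menten nutrient limitation N / (Ks + N)."""
    if np.any(np.asarray(Ks) <= 0):
        raise ValueError("Ks must be positive")
    n = np.asarray(N, dtype=float)
    if np.any(n < 0):
        raise ValueError("N must be non-negative")
    return n / (Ks + n)


def light_limitation(I, Io):
    """Steele light response (I/Io) * exp(1 - I/Io), peaking at I = Io."""
    if np.any(np.asarray(Io) <= 0):
        raise ValueError("Io must be positive")
    i = np.asarray(I, dtype=float)
    if np.any(i < 0):
        raise ValueError("irradiance must be non-negative")
    r = i / Io
    return r * np.exp(1.0 - r)


def grazing_rate(P, Gm, f_ivlev, T, BQ10):
    """Ivlev grazing rate per unit zooplankton, day^-1."""
    p = np.asarray(P, dtype=float)
    if np.any(p < 0):
        raise ValueError("P must be non-negative")
    return Gm * (1.0 - np.exp(-f_ivlev * p)) * temperature_factor(T, BQ10)


def _tendencies_raw(N, P, Z, D, T, I, params: EcoParameters, surface_source=0.0):
    """Compartment tendencies (mmol N m^-3 day^-1); no input validation."""
    p = params
    L = p.Vm * np.power(p.AQ10, (T - 10.0) / 10.0) * light_limitation(np.maximum(I, 0.0), p.Io)
    uptake = L * (N / (p.Ks + N)) * P
    graze = p.Gm * np.power(p.BQ10, (T - 10.0) / 10.0) * (1.0 - np.exp(-p.f_ivlev * P)) * Z
    dN = -uptake + p.theta * graze + p.e * D + surface_source
    dP = uptake - graze - p.Dp * P
    dZ = p.gamma * graze - p.theta * graze - p.Dz * Z
    dD = (1.0 - p.gamma) * graze + p.Dp * P + p.Dz * Z - p.e * D
    return dN, dP, dZ, dD


def biological_tendencies(state: EcoState, T, I, params: EcoParameters,
                          surface_source=0.0):
    """Rates of change of N, P, Z, D in mmol N m^-3 day^-1.

    Uptake uses Q10 x Michaelis-Menten x Steele limitation; grazing is
    Ivlev with its own Q10; the unassimilated grazing fraction goes to
    detritus so the four tendencies sum to zero when no external nitrogen
    source is configured.
    """
    for name, arr in (("N", state.N), ("P", state.P), ("Z", state.Z), ("D", state.D)):
        if np.any(np.asarray(arr) < 0):
            raise ValueError(f"negative {name} concentration")
    return _tendencies_raw(state.N, state.P, state.Z, state.D,
                           np.asarray(T, dtype=float), np.asarray(I, dtype=float),
                           params, surface_source)


def _bio_jacobian_T_apply(N, P, Z, D, T, I, params: EcoParameters, lam):
    """Return J(state)^T @ lam for the biology tendencies, per cell."""
    p = params
    L = p.Vm * np.power(p.AQ10, (T - 10.0) / 10.0) * light_limitation(np.maximum(I, 0.0), p.Io)
    mm = N / (p.Ks + N)
    U_N = L * P * p.Ks / (p.Ks + N) ** 2
    U_P = L * mm
    Gb = p.Gm * np.power(p.BQ10, (T - 10.0) / 10.0)
    Ei = np.exp(-p.f_ivlev * P)
    G_P = Gb * p.f_ivlev * Ei * Z
    G_Z = Gb * (1.0 - Ei)
    lN, lP, lZ, lD = lam
    out = np.empty_like(lam)
    out[0] = U_N * (lP - lN)
    out[1] = ((-U_P + p.theta * G_P) * lN + (U_P - G_P - p.Dp) * lP
              + (p.gamma - p.theta) * G_P * lZ + ((1.0 - p.gamma) * G_P + p.Dp) * lD)
    out[2] = (p.theta * G_Z * lN - G_Z * lP
              + ((p.gamma - p.theta) * G_Z - p.Dz) * lZ
              + ((1.0 - p.gamma) * G_Z + p.Dz) * lD)
    out[3] = p.e * (lN - lD)
    return out


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

def build_transport_matrix(
    grid: ModelGrid,
    forcing: ForcingFields,
    sinking_speed: float,
    dt_seconds: float,
    check_cfl: bool = True,
) -> sp.csr_matrix:
    """One-step transport operator A with c_new = A @ c on active cells.

    First-order upwind advection on cell faces, centered horizontal and
    vertical diffusion, downward sinking with no flux through the coast or
    the sea bed.  The flux form makes the step exactly mass-conserving on
    the closed domain.
    """
    nz, ny, nx = grid.nz, grid.ny, grid.nx
    idx = grid.cell_index
    dx, dy = grid.dx, grid.dy
    dz = grid.layer_thickness
    kh = forcing.horizontal_diffusivity
    kv = forcing.vertical_diffusivity
    w_sink = sinking_speed / SECONDS_PER_DAY  # m/s, positive downward

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=float))

    for k in range(nz):
        act = grid.active[k]
        # ---- x faces between (j, i-1) and (j, i)
        fx = act[:, :-1] & act[:, 1:]
        jj, ii = np.nonzero(fx)
        if jj.size:
            a = idx[k, jj, ii]        # west cell
            b = idx[k, jj, ii + 1]    # east cell
            u = forcing.u[k, jj, ii + 1]  # face i+1 separates cells i and i+1
            up = np.where(u >= 0, a, b)  # upwind donor
            r_adv = u / dx               # rate, s^-1 (uniform dx, dy, dz)
            add(a, up, -r_adv)
            add(b, up, r_adv)
            r_dif = kh / dx**2
            add(a, a, np.full(a.size, -r_dif)); add(a, b, np.full(a.size, r_dif))
            add(b, b, np.full(a.size, -r_dif)); add(b, a, np.full(a.size, r_dif))
        # ---- y faces between (j-1, i) and (j, i)
        fy = act[:-1, :] & act[1:, :]
        jj, ii = np.nonzero(fy)
        if jj.size:
            a = idx[k, jj, ii]        # south cell
            b = idx[k, jj + 1, ii]    # north cell
            v = forcing.v[k, jj + 1, ii]
            up = np.where(v >= 0, a, b)
            r_adv = v / dy
            add(a, up, -r_adv)
            add(b, up, r_adv)
            r_dif = kh / dy**2
            add(a, a, np.full(a.size, -r_dif)); add(a, b, np.full(a.size, r_dif))
            add(b, b, np.full(a.size, -r_dif)); add(b, a, np.full(a.size, r_dif))

    # ---- vertical faces between layer k (upper) and k+1 (lower)
    for k in range(nz - 1):
        both = grid.active[k] & grid.active[k + 1]
        jj, ii = np.nonzero(both)
        if jj.size == 0:
            continue
        a = idx[k, jj, ii]       # upper
        b = idx[k + 1, jj, ii]   # lower
        if w_sink > 0:
            add(a, a, np.full(a.size, -w_sink / dz[k]))
            add(b, a, np.full(a.size, w_sink / dz[k + 1]))
        dzc = 0.5 * (dz[k] + dz[k + 1])
        add(a, a, np.full(a.size, -kv / (dzc * dz[k])))
        add(a, b, np.full(a.size, kv / (dzc * dz[k])))
        add(b, b, np.full(a.size, -kv / (dzc * dz[k + 1])))
        add(b, a, np.full(a.size, kv / (dzc * dz[k + 1])))

    n = grid.n_active
    if rows:
        m = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
    else:
        m = sp.csr_matrix((n, n))

    if check_cfl:
        cfl = float(-m.diagonal().min() * dt_seconds) if n else 0.0
        if cfl > 1.0 + 1e-12:
            raise CFLError(
                f"transport CFL number {cfl:.3f} > 1 for dt = {dt_seconds:.0f} s; "
                "reduce the time step, velocities or diffusivities"
            )
    return (sp.identity(n, format="csr") + dt_seconds * m).tocsr()


def transport_step(
    field3d: np.ndarray,
    grid: ModelGrid,
    forcing: ForcingFields,
    sinking_speed: float = 0.0,
    dt_seconds: float = 21600.0,
) -> np.ndarray:
    """Advance one tracer field (nz, ny, nx) through a single transport step."""
    a = build_transport_matrix(grid, forcing, sinking_speed, dt_seconds)
    return grid.unflatten(a @ grid.flatten(field3d))


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Stored forward states: stack shape (n_times, 4, n_active), N P Z D order."""

    states: np.ndarray
    step_hours: float
    grid: ModelGrid
    surface_index: np.ndarray
    clipped_mass: float = 0.0

    @property
    def n_times(self) -> int:
        return self.states.shape[0]

    @property
    def surface_p(self) -> np.ndarray:
        """Surface-layer phytoplankton, shape (n_times, n_wet)."""
        return self.states[:, 1, self.surface_index]

    def final_state(self) -> EcoState:
        return EcoState.from_stack(self.states[-1])


class NPZDModel:
    """Forward NPZD stepper bound to one grid/forcing/parameter set.

    Precomputes the per-tracer transport matrices (and their transposes,
    used by the adjoint) plus the cell-wise temperature and light lookup.
    """

    def __init__(
        self,
        grid: ModelGrid,
        forcing: ForcingFields,
        params: EcoParameters | None = None,
        step_hours: float | None = None,
        bio_substeps: int = 1,
        n_surface_source: float = 0.0,
        check_cfl: bool = True,
    ) -> None:
        self.grid = grid
        self.forcing = forcing
        self.params = params or EcoParameters()
        self.step_hours = float(step_hours if step_hours is not None else forcing.step_hours)
        self.bio_substeps = int(bio_substeps)
        self.n_surface_source = float(n_surface_source)
        self.dt_seconds = self.step_hours * 3600.0
        self.dt_days = self.step_hours / 24.0

        p = self.params
        self.A_plain = build_transport_matrix(grid, forcing, 0.0, self.dt_seconds, check_cfl)
        self.A_sink_p = build_transport_matrix(grid, forcing, p.wp, self.dt_seconds, check_cfl)
        self.A_sink_d = build_transport_matrix(grid, forcing, p.wd, self.dt_seconds, check_cfl)
        self.AT_plain = self.A_plain.T.tocsr()
        self.AT_sink_p = self.A_sink_p.T.tocsr()
        self.AT_sink_d = self.A_sink_d.T.tocsr()

        kk, jj, ii = np.nonzero(grid.active)
        self._act_k, self._act_j, self._act_i = kk, jj, ii
        self._light_atten = np.exp(-p.Kext * grid.z_mid[kk])
        self._is_surface = kk == 0
        #: flat active indices of surface wet cells, mask scan order
        self.surface_index = grid.cell_index[0][grid.mask]
        self.clipped_mass = 0.0

    # ------------------------------------------------------------- forcing
    def bio_env(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Temperature and irradiance per active cell at time index k."""
        k = min(k, self.forcing.n_times - 1)
        t_cell = self.forcing.sst[k][self._act_j, self._act_i]
        i_cell = self.forcing.surface_irradiance[k] * self._light_atten
        return t_cell, i_cell

    # ------------------------------------------------------------- stepping
    def _apply_transport(self, s: np.ndarray) -> np.ndarray:
        out = np.empty_like(s)
        out[0] = self.A_plain @ s[0]
        out[1] = self.A_sink_p @ s[1]
        out[2] = self.A_plain @ s[2]
        out[3] = self.A_sink_d @ s[3]
        return out

    def _apply_transport_T(self, lam: np.ndarray) -> np.ndarray:
        out = np.empty_like(lam)
        out[0] = self.AT_plain @ lam[0]
        out[1] = self.AT_sink_p @ lam[1]
        out[2] = self.AT_plain @ lam[2]
        out[3] = self.AT_sink_d @ lam[3]
        return out

    def _bio_substates(self, transported: np.ndarray, k: int) -> list[np.ndarray]:
        """All biology substep states, first entry = transported input."""
        t_cell, i_cell = self.bio_env(k)
        h = self.dt_days / self.bio_substeps
        src = np.where(self._is_surface, self.n_surface_source, 0.0) \
            if self.n_surface_source else 0.0
        states = [transported]
        s = transported
        for _ in range(self.bio_substeps):
            dN, dP, dZ, dD = _tendencies_raw(s[0], s[1], s[2], s[3], t_cell, i_cell,
                                             self.params, src)
            s = s + h * np.stack([dN, dP, dZ, dD])
            states.append(s)
        return states

    def _clip(self, s: np.ndarray) -> np.ndarray:
        """Conservative positivity clip: deficits in P, Z, D drawn from N."""
        out = s.copy()
        neg_total = np.zeros_like(s[0])
        for c in (1, 2, 3):
            neg = np.minimum(out[c], 0.0)
            neg_total += neg
            out[c] -= neg
        out[0] += neg_total
        lost = np.minimum(out[0], 0.0)
        if np.any(neg_total < 0) or np.any(lost < 0):
            vol = self.grid.cell_volumes
            self.clipped_mass += float(-(neg_total * vol).sum() - (lost * vol).sum())
        out[0] -= lost  # non-conservative floor on N itself, logged above
        return out

    def step(self, state: np.ndarray, k: int) -> np.ndarray:
        """Advance the stacked state (4, n_active) from time index k to k+1."""
        transported = self._apply_transport(state)
        s = self._bio_substates(transported, k)[-1]
        return self._clip(s)

    def adjoint_step(self, lam: np.ndarray, state_k: np.ndarray, k: int) -> np.ndarray:
        """Transpose of :meth:`step` linearized about the stored state at k."""
        substates = self._bio_substates(self._apply_transport(state_k), k)
        pre_clip = substates[-1]
        t_cell, i_cell = self.bio_env(k)
        h = self.dt_days / self.bio_substeps

        # clip transpose
        lam = lam.copy()
        n_clipped = (pre_clip[1:].clip(max=0.0).sum(axis=0) + pre_clip[0]) < 0
        lam[0] = np.where(n_clipped, 0.0, lam[0])
        for c in (1, 2, 3):
            lam[c] = np.where(pre_clip[c] < 0, lam[0], lam[c])

        # biology substeps, reverse order
        for s in reversed(substates[:-1]):
            lam = lam + h * _bio_jacobian_T_apply(s[0], s[1], s[2], s[3],
                                                  t_cell, i_cell, self.params, lam)
        return self._apply_transport_T(lam)

    # ----------------------------------------------------------------- runs
    def run(self, state0: np.ndarray, n_steps: int) -> Trajectory:
        states = np.empty((n_steps + 1, 4, self.grid.n_active))
        states[0] = state0
        self.clipped_mass = 0.0
        for k in range(n_steps):
            states[k + 1] = self.step(states[k], k)
            if not np.all(np.isfinite(states[k + 1])):
                raise FloatingPointError(f"non-finite state at step {k + 1}")
        return Trajectory(states, self.step_hours, self.grid, self.surface_index,
                          clipped_mass=self.clipped_mass)

    def initial_state(self, initial_P, initial_N=6.0, initial_Z=0.1,
                      initial_D=0.1) -> np.ndarray:
        """Assemble a stacked initial state from fields or scalars."""
        g = self.grid

        def to_flat(x):
            x = x.values if isinstance(x, TruthField) else x
            x = np.asarray(x, dtype=float)
            if x.ndim == 0:
                return np.full(g.n_active, float(x))
            if x.shape == g.active.shape:
                return g.flatten(x)
            if x.shape == (g.n_active,):
                return x.copy()
            raise ValueError(f"cannot interpret initial field of shape {x.shape}")

        return np.stack([to_flat(initial_N), to_flat(initial_P),
                         to_flat(initial_Z), to_flat(initial_D)])


def run_forward(
    initial_P,
    grid: ModelGrid,
    forcing: ForcingFields,
    params: EcoParameters | None = None,
    days: float = 30.0,
    step_hours: float = 6.0,
    initial_N=6.0,
    initial_Z=0.1,
    initial_D=0.1,
    bio_substeps: int = 1,
    n_surface_source: float = 0.0,
) -> Trajectory:
    """Integrate the NPZD model and record every state (surface P included).

    ``initial_P`` may be a :class:`TruthField`, an (nz, ny, nx) array, a
    flat active vector or a scalar.  ``days=0`` returns a trajectory that
    contains only the initial state.
    """
    model = NPZDModel(grid, forcing, params, step_hours,
                      bio_substeps=bio_substeps, n_surface_source=n_surface_source)
    state0 = model.initial_state(initial_P, initial_N, initial_Z, initial_D)
    n_steps = int(round(days * 24.0 / step_hours))
    traj = model.run(state0, n_steps)
    total = float((np.abs(traj.states[0]) * model.grid.cell_volumes).sum())
    if total > 0 and traj.clipped_mass / total > 1e-3:
        logger.warning("clipped mass fraction %.2e exceeds 0.1%%", traj.clipped_mass / total)
    return traj


def spin_up(
    grid: ModelGrid,
    forcing: ForcingFields,
    params: EcoParameters | None = None,
    days: float = 10.0,
    step_hours: float = 6.0,
    initial_P: float = 1.0,
    initial_N: float = 6.0,
    initial_Z: float = 0.1,
    initial_D: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Free run to generate initial Z and D fields from the model itself."""
    traj = run_forward(initial_P, grid, forcing, params, days, step_hours,
                       initial_N, initial_Z, initial_D)
    final = traj.final_state()
    return final.Z, final.D
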