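"""Cost function, discrete adjoint and the assimilation loop.

The gradient of the observation misfit with respect to the initial
phytoplankton field is obtained by sweeping the exact transpose of the
operator-split forward step backwards through the stored trajectory, then
chained through the vertical profile and the independent-point expansion.
Minimization is plain steepest descent with an infinity-norm-normalized
step, halving on cost increase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import ForcingFields, ModelGrid, vertical_profile
from .ips import IndependentPointSet
from .metrics import MetricBundle
from .model import EcoParameters, NPZDModel, Trajectory

__all__ = [
    "ObservationSet",
    "AssimilationResult",
    "StepPolicy",
    "cost",
    "adjoint_sweep",
    "project_to_independent_points",
    "steepest_descent",
    "assimilate",
]

logger = logging.getLogger(__name__)


@dataclass
class ObservationSet:
    """Surface phytoplankton observations on (time, wet cell).

    ``weights`` is the availability mask: exactly 1 where an observation
    exists and 0 elsewhere.
    """

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights shapes differ")
        if not np.all((self.weights == 0.0) | (self.weights == 1.0)):
            raise ValueError("weights must be exactly 0 or 1")
        if not np.all(np.isfinite(self.values[self.weights == 1.0])):
            raise ValueError("observed values must be finite where weighted")

    @classmethod
    def full_coverage(cls, surface_p: np.ndarray) -> "ObservationSet":
        """Observations available at every time and wet cell (twin setting)."""
        return cls(values=surface_p.copy(), weights=np.ones_like(surface_p))


@dataclass
class AssimilationResult:
    """Output of one assimilation run."""

    ncf_history: np.ndarray       # starts at 1, one entry per accepted state
    j_history: np.ndarray
    final_control: np.ndarray
    final_field: np.ndarray       # recovered initial surface P, (ny, nx)
    iterations_run: int
    stalled: bool = False
    metrics: MetricBundle | None = None

    @property
    def final_ncf(self) -> float:
        return float(self.ncf_history[-1])


def cost(p_model: np.ndarray, obs: ObservationSet) -> float:
    """J = 1/2 * sum over time x space of W * (P - P_o)^2."""
    p = np.asarray(p_model, dtype=float)
    if p.shape != obs.values.shape:
        raise ValueError(f"shape mismatch: model {p.shape} vs obs {obs.values.shape}")
    diff = np.where(obs.weights == 1.0, p - obs.values, 0.0)
    return float(0.5 * np.sum(diff * diff))


def _misfit(p_model: np.ndarray, obs: ObservationSet) -> np.ndarray:
    return obs.weights * (p_model - obs.values)


def adjoint_sweep(
    trajectory: Trajectory,
    obs: ObservationSet,
    grid: ModelGrid | None = None,
    forcing: ForcingFields | None = None,
    params: EcoParameters | None = None,
    model: NPZDModel | None = None,
    full: bool = False,
) -> np.ndarray:
    """Gradient of the cost with respect to the initial state.

    Backward sweep of the discrete adjoint with the misfit W*(P - P_o)
    injected at every observation time, including t=0.  Returns
    dJ/dP(t=0) on active cells; with ``full=True`` the complete
    (4, n_active) adjoint state (N, P, Z, D components) is returned.
    """
    if model is None:
        if grid is None or forcing is None:
            raise ValueError("provide either a model or grid+forcing")
        model = NPZDModel(grid, forcing, params, trajectory.step_hours)
    n_steps = trajectory.n_times - 1
    if obs.values.shape[0] != trajectory.n_times:
        raise ValueError(
            f"observation time levels ({obs.values.shape[0]}) do not match "
            f"trajectory ({trajectory.n_times})"
        )
    surf = model.surface_index
    misfit = _misfit(trajectory.surface_p, obs)

    lam = np.zeros((4, model.grid.n_active))
    lam[1, surf] += misfit[n_steps]
    for k in range(n_steps - 1, -1, -1):
        lam = model.adjoint_step(lam, trajectory.states[k], k)
        lam[1, surf] += misfit[k]
    return lam if full else lam[1]


def project_to_independent_points(grid_gradient: np.ndarray,
                                  ips: IndependentPointSet) -> np.ndarray:
    """Chain rule through the expansion: g_n = sum_cells kappa[cell, n] * grad."""
    g = np.asarray(grid_gradient, dtype=float).ravel()
    if g.size != ips.kappa.shape[0]:
        raise ValueError(
            f"gradient length {g.size} does not match kappa rows {ips.kappa.shape[0]}"
        )
    return ips.kappa.T @ g


@dataclass
class StepPolicy:
    """Steepest-descent step control.

    ``alpha0`` is the initial step length applied to the infinity-norm
    normalized gradient (when None: 2% of the control range at start);
    the step is halved on cost increase and grown on acceptance.
    """

    alpha0: float | None = None
    normalize: bool = True
    growth: float = 1.2
    max_halvings: int = 5


def steepest_descent(control: np.ndarray, gradient: np.ndarray,
                     alpha: float, normalize: bool = True) -> np.ndarray:
    """One descent update: control - alpha * g / ||g||_inf (or raw g)."""
    control = np.asarray(control, dtype=float)
    g = np.asarray(gradient, dtype=float)
    if control.shape != g.shape:
        raise ValueError("control and gradient lengths differ")
    gmax = np.max(np.abs(g))
    if gmax == 0.0:
        return control.copy()
    direction = g / gmax if normalize else g
    return control - alpha * direction


def _surface_gradient(model: NPZDModel, lam_p0: np.ndarray,
                      clip_mask: np.ndarray) -> np.ndarray:
    """Collapse dJ/dP0 (active cells) onto the surface pattern.

    The initial P field is the surface pattern times a fixed vertical
    profile, so the pattern gradient is the profile-weighted sum over
    layers; cells whose expanded value was clipped at zero pass no
    gradient.
    """
    g3 = model.grid.unflatten(lam_p0)
    profile = vertical_profile(model.grid)
    gsurf = np.tensordot(profile, g3, axes=(0, 0))[model.grid.mask]
    gsurf[clip_mask] = 0.0
    return gsurf


def assimilate(
    grid: ModelGrid,
    forcing: ForcingFields,
    obs: ObservationSet,
    ips: IndependentPointSet,
    initial_control: np.ndarray,
    params: EcoParameters | None = None,
    days: float = 30.0,
    step_hours: float = 6.0,
    initial_N=6.0,
    initial_Z=0.1,
    initial_D=0.1,
    max_iterations: int = 100,
    ncf_threshold: float = 5e-4,
    step_policy: StepPolicy | None = None,
    bio_substeps: int = 1,
) -> AssimilationResult:
    """Steepest-descent assimilation of surface P observations.

    Loop: expand control -> forward run -> cost -> adjoint -> project ->
    update, until the iteration cap or the NCF threshold is reached.
    Deterministic for fixed inputs.
    """
    from .grid import surface_to_3d  # local import avoids a cycle at module load

    policy = step_policy or StepPolicy()
    model = NPZDModel(grid, forcing, params, step_hours, bio_substeps=bio_substeps)
    n_steps = int(round(days * 24.0 / step_hours))

    def evaluate(control):
        raw = ips.kappa @ control
        clip_mask = raw < 0.0
        surface = grid.surface_unflatten(np.maximum(raw, 0.0))
        p0 = surface_to_3d(grid, surface)
        state0 = model.initial_state(p0, initial_N, initial_Z, initial_D)
        traj = model.run(state0, n_steps)
        return cost(traj.surface_p, obs), traj, clip_mask, surface

    control = np.asarray(initial_control, dtype=float).copy()
    j, traj, clip_mask, surface = evaluate(control)
    j0 = j
    j_history = [j]
    if j0 == 0.0:
        return AssimilationResult(
            ncf_history=np.array([1.0]), j_history=np.array([0.0]),
            final_control=control, final_field=surface, iterations_run=0)

    crange = float(np.ptp(control))
    if crange == 0.0:
        crange = max(float(np.max(np.abs(control))), 1.0)
    alpha = policy.alpha0 if policy.alpha0 is not None else 0.02 * crange

    iterations = 0
    stalled = False
    for it in range(1, max_iterations + 1):
        lam_p0 = adjoint_sweep(traj, obs, model=model)
        gsurf = _surface_gradient(model, lam_p0, clip_mask)
        g = project_to_independent_points(gsurf, ips)
        if np.max(np.abs(g)) == 0.0:
            logger.info("iteration %d: zero gradient, stopping", it)
            break

        accepted = False
        for _ in range(policy.max_halvings + 1):
            trial = steepest_descent(control, g, alpha, policy.normalize)
            j_trial, traj_trial, clip_trial, surf_trial = evaluate(trial)
            if j_trial < j:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            logger.info("iteration %d: no descent after %d halvings (alpha=%.3e), "
                        "stopping", it, policy.max_halvings, alpha)
            stalled = True
            break

        control, j, traj, clip_mask, surface = trial, j_trial, traj_trial, clip_trial, surf_trial
        j_history.append(j)
        iterations += 1
        alpha *= policy.growth
        logger.info("iteration %d: J=%.6e NCF=%.3e alpha=%.3e", it, j, j / j0, alpha)
        if j / j0 < ncf_threshold:
            break

    jh = np.asarray(j_history)
    return AssimilationResult(
        ncf_history=jh / j0,
        j_history=jh,
        final_control=control,
        final_field=surface,
        iterations_run=iterations,
        stalled=stalled,
    )
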