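"""1-D reaction-diffusion model of competitive multi-spine structural plasticity.

Two molecular resources evolve on a dendritic segment after quasi-simultaneous
stimulation of a set of spines:

* ``C`` — a fast-diffusing, fast-degrading potentiating resource (calcium and
  related molecules), seeded at stimulation sites as narrow Gaussians whose
  amplitude ``C_s + C_d * D_i`` combines a spine-specific store with a share
  ``D_i`` of the common dendritic pool (see :mod:`spinecomp.layout`).
* ``P`` — a slow dual-role resource, produced from an inactive precursor
  ``P_in`` by the action of ``C`` and degraded slowly.  ``P`` potentiates
  spines smaller than the threshold ``nu`` and depresses larger ones through
  the smooth decision function ``F(S) = -tanh(phi * (S - nu))``.

The normalised spine size field ``S`` integrates both influences,

    dS/dt = zeta1 * C + zeta2 * P * F(S),

with ``S(x, 0) = 1`` (sizes are normalised to the pre-stimulation baseline).
Time is in minutes from the end of the stimulation train, space in μm;
concentrations carry arbitrary units fixed by the fit.

The integrator uses Strang splitting: an implicit Crank-Nicolson step for the
diffusion terms (finite-volume Laplacian, no-flux boundaries, exact mass
conservation) wrapped by explicit midpoint (RK2) half-steps for the local
reactions, giving second-order accuracy in ``dt``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace, asdict

import numpy as np
from scipy.linalg import cholesky_banded, cho_solve_banded

from .layout import SpineLayout, CompetitionFactors, compute_competition

__all__ = [
    "ModelParameters",
    "REFERENCE_PARAMS",
    "Grid",
    "FieldState",
    "SimulationResult",
    "IntegrationError",
    "initial_C",
    "initial_Pin",
    "decision_F",
    "integrate",
    "simulate",
    "check_convergence",
]

#: Names of the 13 parameters the fitting procedure may vary (the Gaussian
#: kernel coefficient g_eff is a fixed geometric constant, not fitted).
FITTABLE_PARAMS = (
    "C_s", "C_d", "lam", "alpha1", "alpha2", "beta1", "beta2",
    "gamma", "rho", "phi", "nu", "zeta1", "zeta2",
)

_DEFAULT_G_EFF = -4.0 * math.log(2.0)  # kernel FWHM = 1 μm


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the resource-competition model.

    Attributes
    ----------
    C_s, C_d : float
        Spine-specific and shared-dendritic amounts of the fast resource
        (arbitrary concentration units).
    lam : float
        Competition exponent shaping the saturating distance terms d_i (>0).
    g_eff : float
        Gaussian kernel coefficient (μm^-2, < 0); default gives FWHM = 1 μm.
        Fixed, not fitted.
    alpha1, alpha2 : float
        Diffusion (μm^2/min) and degradation (1/min) rates of C.
    beta1, beta2 : float
        Diffusion rate of P and P_in (μm^2/min) and activation rate of
        P_in -> P by C (per concentration per min).
    gamma : float
        Degradation rate of P (1/min).
    rho : float
        Baseline level of the inactive precursor P_in.
    phi : float
        Steepness of the potentiation/depression switch (>0).
    nu : float
        Normalised-size threshold of the switch (>0).
    zeta1, zeta2 : float
        Susceptibility of spine size to C and to P.
    """

    C_s: float = 0.1
    C_d: float = 1.0
    lam: float = 40.0
    g_eff: float = _DEFAULT_G_EFF
    alpha1: float = 0.5
    alpha2: float = 2.0
    beta1: float = 0.4
    beta2: float = 1.0
    gamma: float = 0.03
    rho: float = 1.0
    phi: float = 4.0
    nu: float = 1.05
    zeta1: float = 2.0
    zeta2: float = 0.25

    def __post_init__(self):
        for name in ("C_s", "C_d", "alpha1", "alpha2", "beta1", "beta2",
                     "gamma", "rho", "zeta1", "zeta2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("lam", "phi", "nu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.g_eff >= 0:
            raise ValueError("g_eff must be < 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def as_vector(self, names=FITTABLE_PARAMS) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    @classmethod
    def from_vector(cls, vec, names=FITTABLE_PARAMS, base: "ModelParameters" = None):
        base = base if base is not None else cls()
        return base.replace(**dict(zip(names, map(float, vec))))


#: Reference parameter set used for model-property demonstrations and as the
#: default ground truth of the synthetic-data generator.  Tuned once to
#: reproduce the qualitative multi-spine behaviours (single-spine overshoot
#: and decay toward ~1.3, 1/N early-potentiation ordering, late edge>middle
#: divergence, distributed-spine decoupling); see docs/methods.md.
REFERENCE_PARAMS = ModelParameters()


@dataclass(frozen=True)
class Grid:
    """Uniform 1-D spatial grid (μm)."""

    x_min: float
    x_max: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 2 or self.x_max <= self.x_min:
            raise ValueError("invalid grid extent")

    @property
    def spacing(self) -> float:
        return (self.x_max - self.x_min) / (self.n_points - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_points)

    @classmethod
    def for_layout(cls, layout: SpineLayout, g_eff: float = _DEFAULT_G_EFF,
                   pad: float = 20.0, dx: float = 0.125) -> "Grid":
        """Grid covering the layout with ``pad`` μm margins and spacing
        fine enough to resolve the Gaussian kernel (>=8 points per FWHM)."""
        fwhm = 2.0 * math.sqrt(math.log(2.0) / -g_eff)
        if dx > fwhm / 8.0 + 1e-12:
            raise ValueError(
                f"dx={dx} too coarse for kernel FWHM {fwhm:.3g} μm (need <= {fwhm / 8:.3g})"
            )
        lo = float(layout.position.min()) - pad
        hi = float(layout.position.max()) + pad
        n = int(math.ceil((hi - lo) / dx)) + 1
        return cls(lo, lo + (n - 1) * dx, n)

    def nearest_index(self, x: float) -> int:
        return int(round((x - self.x_min) / self.spacing))

    def interp_weights(self, positions) -> tuple[np.ndarray, np.ndarray]:
        """Left node index and right-node weight for linear interpolation."""
        s = (np.asarray(positions, dtype=float) - self.x_min) / self.spacing
        j = np.clip(np.floor(s).astype(int), 0, self.n_points - 2)
        return j, s - j


@dataclass
class FieldState:
    """Spatial profiles of the model fields at one time point."""

    t: float
    C: np.ndarray
    P_in: np.ndarray
    P: np.ndarray
    S: np.ndarray
    grid: Grid


@dataclass
class SimulationResult:
    """Spine-size trajectories sampled at spine positions."""

    times: np.ndarray                 # snapshot times (min), strictly increasing
    sizes: np.ndarray                 # (n_spines, n_times) normalised sizes
    layout: SpineLayout
    competition: CompetitionFactors | None = None
    fields: list | None = None        # optional FieldState snapshots

    @property
    def stim_sizes(self) -> np.ndarray:
        return self.sizes[self.layout.stimulated]

    def mean_stim_trajectory(self) -> np.ndarray:
        return self.stim_sizes.mean(axis=0)


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Initial conditions


def _gaussians(grid_x: np.ndarray, centres: np.ndarray, g_eff: float) -> np.ndarray:
    """(n_centres, n_x) matrix of kernel profiles exp(g_eff * (x - x_i)^2)."""
    dx2 = (grid_x[None, :] - centres[:, None]) ** 2
    return np.exp(g_eff * dx2)


def initial_C(grid: Grid, layout: SpineLayout, params: ModelParameters,
              comp: CompetitionFactors) -> np.ndarray:
    """C(x, 0) = sum_i (C_s + C_d * D_i) exp(g_eff (x - x_i)^2)."""
    G = _gaussians(grid.x, layout.stim_positions, params.g_eff)
    amps = params.C_s + params.C_d * comp.D
    return amps @ G


def initial_Pin(grid: Grid, layout: SpineLayout, params: ModelParameters,
                comp: CompetitionFactors) -> np.ndarray:
    """P_in(x, 0) = rho * (1 - sum_i (1 - D_i) exp(g_eff (x - x_i)^2)), clamped at 0.

    The precursor pool is depleted at stimulation sites in proportion to the
    dendritic C drawn there; overlapping depletion troughs from tight
    clusters are clamped at zero because concentrations cannot be negative.
    """
    if params.rho < 0:
        raise ValueError("rho must be >= 0")
    G = _gaussians(grid.x, layout.stim_positions, params.g_eff)
    depletion = (1.0 - comp.D) @ G
    return params.rho * np.clip(1.0 - depletion, 0.0, None)


def decision_F(S, phi: float, nu: float):
    """Dual-role switch F(S) = -tanh(phi (S - nu)); growth for S < nu."""
    if phi <= 0:
        raise ValueError("phi must be > 0")
    return -np.tanh(phi * (np.asarray(S, dtype=float) - nu))


# ---------------------------------------------------------------------------
# Integrator


def laplacian_apply(v: np.ndarray) -> np.ndarray:
    """Finite-volume no-flux Laplacian stencil (units of 1/dx^2 applied outside)."""
    out = np.empty_like(v)
    out[..., 1:-1] = v[..., :-2] - 2.0 * v[..., 1:-1] + v[..., 2:]
    out[..., 0] = v[..., 1] - v[..., 0]
    out[..., -1] = v[..., -2] - v[..., -1]
    return out


class DiffusionOp:
    """Crank-Nicolson half of the split step for one diffusion coefficient.

    Solves (I - r/2 L) v_new = (I + r/2 L) v_old with r = kappa dt / dx^2 and
    L the symmetric finite-volume no-flux Laplacian; the ones-vector is a
    left null vector of L so total mass is conserved exactly.
    """

    def __init__(self, kappa: float, dt: float, dx: float, n: int):
        self.kappa, self.dt, self.dx, self.n = kappa, dt, dx, n
        self.r = kappa * dt / dx ** 2
        # upper banded storage for the symmetric tridiagonal A = I - r/2 L
        ab = np.zeros((2, n))
        ab[0, 1:] = -self.r / 2.0          # superdiagonal
        ab[1, :] = 1.0 + self.r            # diagonal (interior)
        ab[1, 0] = 1.0 + self.r / 2.0      # boundary rows of L have one neighbour
        ab[1, -1] = 1.0 + self.r / 2.0
        self._cho = cholesky_banded(ab) if kappa > 0 else None

    def apply_B(self, v: np.ndarray) -> np.ndarray:
        return v + (self.r / 2.0) * laplacian_apply(v)

    def solve_A(self, b: np.ndarray) -> np.ndarray:
        if self._cho is None:
            return b
        if b.ndim == 1:
            return cho_solve_banded((self._cho, False), b)
        return cho_solve_banded((self._cho, False), b.T).T

    def step(self, v: np.ndarray) -> np.ndarray:
        if self.kappa == 0.0:
            return v
        return self.solve_A(self.apply_B(v))


def _reaction_rhs(u: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Local reaction terms for the stacked state u = (C, P_in, P, S)."""
    C, Pin, P, S = u
    F = -np.tanh(p.phi * (S - p.nu))
    return np.stack([
        -p.alpha2 * C,
        -p.beta2 * Pin * C,
        p.beta2 * C * Pin - p.gamma * P,
        p.zeta1 * C + p.zeta2 * P * F,
    ])


def _reaction_half(u: np.ndarray, p: ModelParameters, h: float) -> np.ndarray:
    """Explicit midpoint (RK2) step of size h for the local reactions."""
    um = u + (h / 2.0) * _reaction_rhs(u, p)
    return u + h * _reaction_rhs(um, p)


class Stepper:
    """Strang-split stepper; also exposes the sub-stage states for the adjoint."""

    def __init__(self, params: ModelParameters, dt: float, dx: float, n: int):
        self.params, self.dt, self.dx, self.n = params, dt, dx, n
        self.opC = DiffusionOp(params.alpha1, dt, dx, n)
        self.opP = DiffusionOp(params.beta1, dt, dx, n)

    def step(self, u: np.ndarray) -> np.ndarray:
        ua = _reaction_half(u, self.params, self.dt / 2.0)
        ub = ua.copy()
        ub[0] = self.opC.step(ua[0])
        ub[1:3] = self.opP.step(ua[1:3])
        return _reaction_half(ub, self.params, self.dt / 2.0)

    def step_stages(self, u: np.ndarray):
        ua = _reaction_half(u, self.params, self.dt / 2.0)
        ub = ua.copy()
        ub[0] = self.opC.step(ua[0])
        ub[1:3] = self.opP.step(ua[1:3])
        return ua, ub, _reaction_half(ub, self.params, self.dt / 2.0)


def _pack(state: FieldState) -> np.ndarray:
    return np.stack([state.C, state.P_in, state.P, state.S])


def integrate(state: FieldState, params: ModelParameters, t_end: float,
              dt: float = 0.02, record_times=None) -> list[FieldState]:
    """Advance the coupled system from ``state.t`` to ``state.t + t_end``.

    Returns FieldState snapshots at ``record_times`` (measured from the
    initial state's time; defaults to the final time only).  Recording times
    are rounded to the nearest integer step.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    n_steps = int(round(t_end / dt))
    dt = t_end / n_steps
    if record_times is None:
        record_times = [t_end]
    rec_steps = {}
    for t in record_times:
        k = int(round(t / dt))
        if not (0 <= k <= n_steps):
            raise ValueError(f"record time {t} outside [0, {t_end}]")
        rec_steps.setdefault(k, t)

    stepper = Stepper(params, dt, state.grid.spacing, state.grid.n_points)
    u = _pack(state)
    out = []

    def record(k):
        if k in rec_steps:
            if not np.all(np.isfinite(u)):
                raise IntegrationError(
                    f"non-finite field values at t = {state.t + k * dt:.4g} min"
                )
            out.append(FieldState(state.t + k * dt, u[0].copy(), u[1].copy(),
                                  u[2].copy(), u[3].copy(), state.grid))

    record(0)
    for k in range(1, n_steps + 1):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                u = stepper.step(u)
        except ValueError as err:
            raise IntegrationError(
                f"non-finite field values at t = {state.t + k * dt:.4g} min"
            ) from err
        if not np.all(np.isfinite(u)):
            raise IntegrationError(f"non-finite field values at t = {state.t + k * dt:.4g} min")
        record(k)
    return out


# ---------------------------------------------------------------------------
# High-level simulation


def build_initial_state(grid: Grid, layout: SpineLayout, params: ModelParameters,
                        comp: CompetitionFactors) -> FieldState:
    n = grid.n_points
    return FieldState(
        t=0.0,
        C=initial_C(grid, layout, params, comp),
        P_in=initial_Pin(grid, layout, params, comp),
        P=np.zeros(n),
        S=np.ones(n),
        grid=grid,
    )


def simulate(layout: SpineLayout, params: ModelParameters, snapshot_times,
             dt: float = 0.02, dx: float = 0.125, pad: float = 20.0,
             n_hat: int | None = None, nhat_radius: float = 2.0,
             readout: str = "interp", keep_fields: bool = False) -> SimulationResult:
    """Forward-simulate a stimulation paradigm and sample S at every spine.

    ``t = 0`` is the end of the 1-min stimulation train; the first two
    minutes lie inside the stimulation-region validity gap, so model-data
    comparisons conventionally start at +2 min.  The sham paradigm carries
    zero initial resources and returns S = 1 identically.

    ``readout='interp'`` (default) linearly interpolates S at the exact spine
    position (sub-grid accurate, so trajectories converge under grid
    refinement); ``readout='node'`` samples the nearest grid node;
    ``readout='window'`` averages S over ±0.5 μm around each spine.
    """
    times = np.asarray(snapshot_times, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one snapshot time")
    if np.any(np.diff(times) <= 0):
        raise ValueError("snapshot times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("snapshot times must be >= 0 (post-stimulation)")

    if layout.paradigm == "sham":
        sizes = np.ones((layout.n_spines, times.size))
        return SimulationResult(times=times, sizes=sizes, layout=layout)

    comp = compute_competition(layout, params.lam, radius=nhat_radius, n_hat=n_hat)
    grid = Grid.for_layout(layout, params.g_eff, pad=pad, dx=dx)
    state0 = build_initial_state(grid, layout, params, comp)
    snaps = integrate(state0, params, t_end=float(times[-1]) if times[-1] > 0 else dt,
                      dt=dt, record_times=list(times))

    sizes = np.empty((layout.n_spines, times.size))
    half_w = max(1, int(round(0.5 / grid.spacing)))
    jdx, wts = grid.interp_weights(layout.position)
    for j, st in enumerate(snaps):
        if readout == "interp":
            sizes[:, j] = st.S[jdx] * (1.0 - wts) + st.S[jdx + 1] * wts
            continue
        for k, x in enumerate(layout.position):
            i = grid.nearest_index(float(x))
            if readout == "window":
                lo, hi = max(0, i - half_w), min(grid.n_points, i + half_w + 1)
                sizes[k, j] = st.S[lo:hi].mean()
            else:
                sizes[k, j] = st.S[i]
    return SimulationResult(times=times, sizes=sizes, layout=layout,
                            competition=comp,
                            fields=snaps if keep_fields else None)


def check_convergence(layout: SpineLayout, params: ModelParameters, snapshot_times,
                      dt: float = 0.02, dx: float = 0.125, **kw) -> dict:
    """dt-halving and grid-doubling sup-norm changes of the sampled trajectories."""
    base = simulate(layout, params, snapshot_times, dt=dt, dx=dx, **kw)
    half_dt = simulate(layout, params, snapshot_times, dt=dt / 2.0, dx=dx, **kw)
    half_dx = simulate(layout, params, snapshot_times, dt=dt, dx=dx / 2.0, **kw)
    return {
        "dt_halving_sup": float(np.abs(base.sizes - half_dt.sizes).max()),
        "grid_doubling_sup": float(np.abs(base.sizes - half_dx.sizes).max()),
    }
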