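"""Finite-difference integrator for one masked two-species system.

The tissue patch is the rectangle [0, width_x] x [0, width_y] with periodic
boundaries top/bottom (y) and zero-flux boundaries left/right (x) -- the
rectangle stands for a small window of a much larger skin domain.  Fields
live on a uniform cell-centered grid; the Laplacian is the standard 5-point
stencil with a wrap in y and mirror ghost cells in x.

Time stepping is semi-implicit (IMEX): diffusion is treated implicitly via
a fast transform that diagonalizes the stencil exactly (DCT-II along x for
the mirror symmetry, real FFT along y for the wrap), while the competence-
gated kinetics are explicit.  Diffusion is applied everywhere; the reaction
terms are multiplied by the binary competence mask, so morphogens diffuse
freely through already-patterned tissue but no longer react there.  An
explicit Euler scheme is provided as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as spfft

from .kinetics import KineticParameters, evaluate_kinetics, homogeneous_steady_state

__all__ = [
    "Grid",
    "ScalarField",
    "SolverSettings",
    "RunResult",
    "make_initial_condition",
    "laplacian",
    "step",
    "run_to_stationarity",
    "Stepper",
]

NEGATIVE_TOL = 1e-9  # explicit kinetics may undershoot zero by rounding


class IntegrationError(RuntimeError):
    """Raised when a step produces NaN/Inf or significantly negative values."""


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centered grid on [0, width_x] x [0, width_y].

    x is the zero-flux (left/right) direction, y the periodic (top/bottom)
    one; arrays are indexed ``[iy, ix]``.  Cell centers sit at
    ``(i + 1/2) * spacing``.
    """

    width_x: float = 15.0
    width_y: float = 25.0
    n_x: int = 120
    n_y: int = 200

    def __post_init__(self) -> None:
        if self.width_x <= 0 or self.width_y <= 0:
            raise ValueError("domain extents must be positive")
        if self.n_x < 8 or self.n_y < 8:
            raise ValueError(f"grid must be at least 8x8, got {self.n_x}x{self.n_y}")

    @property
    def dx(self) -> float:
        return self.width_x / self.n_x

    @property
    def dy(self) -> float:
        return self.width_y / self.n_y

    @property
    def spacing(self) -> tuple[float, float]:
        return (self.dx, self.dy)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.n_x) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.n_y) + 0.5) * self.dy


@dataclass
class ScalarField:
    """One morphogen concentration field of one system on a Grid."""

    grid: Grid
    values: np.ndarray
    species: str = "activator"  # "activator" (u) or "inhibitor" (v)
    system_index: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy(), self.species, self.system_index)


@dataclass(frozen=True)
class SolverSettings:
    dt: float = 0.05
    duration: float = 500.0
    scheme: str = "imex"  # "imex" or "explicit"
    stationarity_tol: float = 1e-5
    record_every: float = 10.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.stationarity_tol < 0:
            raise ValueError("stationarity_tol must be >= 0")
        if self.scheme not in ("imex", "explicit"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class RunResult:
    """Outcome of integrating one system for a fixed duration."""

    u: ScalarField
    v: ScalarField
    trace_times: np.ndarray
    trace_rates: np.ndarray  # max |field change| / dt at each trace time
    converged: bool
    snapshot_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    snapshots_u: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 0)))


def make_initial_condition(
    grid: Grid,
    p: KineticParameters,
    amplitude: float = 0.01,
    seed: int = 0,
    noise_grid: Grid | None = None,
) -> tuple[ScalarField, ScalarField]:
    """Randomly perturbed homogeneous steady state, the Turing initial condition.

    ``u = u* (1 + amplitude * eta_u)`` and likewise for v, with eta i.i.d.
    uniform on [-1, 1] per cell, reproducible from ``seed``.

    When ``noise_grid`` is given (a coarser grid whose cell counts divide
    those of ``grid``), the noise is drawn on the coarse grid and block-
    replicated, so refinement studies share one noise realization.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    u_star, v_star = homogeneous_steady_state(p)
    rng = np.random.default_rng(seed)
    src = noise_grid if noise_grid is not None else grid
    eta_u = rng.uniform(-1.0, 1.0, size=src.shape)
    eta_v = rng.uniform(-1.0, 1.0, size=src.shape)
    if noise_grid is not None:
        if grid.n_x % src.n_x or grid.n_y % src.n_y:
            raise ValueError("noise_grid cell counts must divide the grid's")
        eta_u = np.repeat(np.repeat(eta_u, grid.n_y // src.n_y, axis=0), grid.n_x // src.n_x, axis=1)
        eta_v = np.repeat(np.repeat(eta_v, grid.n_y // src.n_y, axis=0), grid.n_x // src.n_x, axis=1)
    u = ScalarField(grid, u_star * (1.0 + amplitude * eta_u), "activator")
    v = ScalarField(grid, v_star * (1.0 + amplitude * eta_v), "inhibitor")
    return u, v


def laplacian_values(vals: np.ndarray, grid: Grid) -> np.ndarray:
    """5-point Laplacian; y wraps, x uses mirror (zero-flux) ghost cells."""
    if grid.n_x < 3 or grid.n_y < 3:
        raise ValueError("laplacian needs at least 3 cells per direction")
    out = (np.roll(vals, 1, axis=0) + np.roll(vals, -1, axis=0) - 2.0 * vals) / grid.dy**2
    xx = np.empty_like(vals)
    xx[:, 1:-1] = vals[:, 2:] + vals[:, :-2] - 2.0 * vals[:, 1:-1]
    xx[:, 0] = vals[:, 1] - vals[:, 0]  # mirror ghost: u[-1] = u[0]
    xx[:, -1] = vals[:, -2] - vals[:, -1]
    out += xx / grid.dx**2
    return out


def laplacian(fld: ScalarField) -> ScalarField:
    return ScalarField(fld.grid, laplacian_values(fld.values, fld.grid), fld.species, fld.system_index)


class Stepper:
    """Time stepper with precomputed spectral symbols for one (grid, dt, p).

    The implicit diffusion solve divides each transform coefficient by
    ``1 - dt * D * (lambda_x + lambda_y)``, where lambda are the exact
    eigenvalues of the 5-point stencil under DCT-II (x) and DFT (y).
    """

    def __init__(self, grid: Grid, p: KineticParameters, settings: SolverSettings):
        self.grid = grid
        self.p = p
        self.settings = settings
        dt = settings.dt
        if settings.scheme == "explicit":
            dmax = max(p.D_u, p.D_v)
            dt_stable = 0.5 / (dmax * (1.0 / grid.dx**2 + 1.0 / grid.dy**2))
            if dt > dt_stable:
                raise ValueError(
                    f"explicit scheme needs dt <= {dt_stable:.3g}, got {dt}"
                )
            self._denom_u = self._denom_v = None
        else:
            lam_x = -(2.0 - 2.0 * np.cos(np.pi * np.arange(grid.n_x) / grid.n_x)) / grid.dx**2
            jy = np.arange(grid.n_y // 2 + 1)
            lam_y = -(2.0 - 2.0 * np.cos(2.0 * np.pi * jy / grid.n_y)) / grid.dy**2
            lam = lam_y[:, None] + lam_x[None, :]
            self._denom_u = 1.0 - dt * p.D_u * lam
            self._denom_v = 1.0 - dt * p.D_v * lam

    def _implicit_diffuse(self, rhs: np.ndarray, denom: np.ndarray) -> np.ndarray:
        hat = spfft.rfft(spfft.dct(rhs, type=2, axis=1), axis=0)
        hat /= denom
        return spfft.idct(spfft.irfft(hat, n=self.grid.n_y, axis=0), type=2, axis=1)

    def advance(
        self, u: np.ndarray, v: np.ndarray, mask: np.ndarray, t: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """One dt; raises IntegrationError on NaN/Inf or values < -1e-9."""
        p, dt = self.p, self.settings.dt
        uuv = u * u * v
        fu = (p.a - u + uuv) * mask
        gv = (p.b - uuv) * mask
        if self.settings.scheme == "explicit":
            un = u + dt * (p.D_u * laplacian_values(u, self.grid) + fu)
            vn = v + dt * (p.D_v * laplacian_values(v, self.grid) + gv)
        else:
            un = self._implicit_diffuse(u + dt * fu, self._denom_u)
            vn = self._implicit_diffuse(v + dt * gv, self._denom_v)
        for name, arr in (("u", un), ("v", vn)):
            mn = arr.min()
            if not np.isfinite(mn) or not np.isfinite(arr.max()) or mn < -NEGATIVE_TOL:
                iy, ix = np.unravel_index(
                    int(np.nanargmin(np.where(np.isfinite(arr), arr, np.inf))), arr.shape
                )
                raise IntegrationError(
                    f"integration failure in {name} at t={t + dt:.4g}, "
                    f"cell (iy={iy}, ix={ix}): value {arr[iy, ix]}"
                )
        return un, vn


def _mask_values(mask, grid: Grid) -> np.ndarray:
    if mask is None:
        return np.ones(grid.shape)
    vals = getattr(mask, "values", mask)
    return np.asarray(vals, dtype=float)


def step(
    u: ScalarField,
    v: ScalarField,
    mask,
    p: KineticParameters,
    settings: SolverSettings,
) -> tuple[ScalarField, ScalarField]:
    """Advance one dt.  Diffusion everywhere; kinetics only where mask = 1."""
    if u.grid != v.grid:
        raise ValueError("u and v must share one grid")
    stepper = Stepper(u.grid, p, settings)
    un, vn = stepper.advance(u.values, v.values, _mask_values(mask, u.grid), 0.0)
    return (
        ScalarField(u.grid, un, "activator", u.system_index),
        ScalarField(v.grid, vn, "inhibitor", v.system_index),
    )


def run_to_stationarity(
    u0: ScalarField,
    v0: ScalarField,
    mask,
    p: KineticParameters,
    settings: SolverSettings,
    record_snapshots: bool = False,
) -> RunResult:
    """Integrate for ``settings.duration`` and report the change-rate trace.

    ``converged`` is True when the final max |field change|/dt falls below
    ``settings.stationarity_tol``.  Snapshot recording (activator only) at
    ``record_every`` intervals is optional to keep memory modest.
    """
    grid = u0.grid
    mask_vals = _mask_values(mask, grid)
    stepper = Stepper(grid, p, settings)
    dt = settings.dt
    n_steps = int(round(settings.duration / dt))
    every = max(1, int(round(settings.record_every / dt)))

    u, v = u0.values.copy(), v0.values.copy()
    times, rates = [], []
    snap_t, snaps = [], []

    def change_rate(ua, va, ub, vb) -> float:
        return max(np.abs(ub - ua).max(), np.abs(vb - va).max()) / dt

    if n_steps == 0:
        un, vn = stepper.advance(u, v, mask_vals, 0.0)
        rate = change_rate(u, v, un, vn)
        return RunResult(
            u0.copy(), v0.copy(), np.array([0.0]), np.array([rate]),
            bool(rate < settings.stationarity_tol),
        )

    rate = np.inf
    for n in range(n_steps):
        t = n * dt
        un, vn = stepper.advance(u, v, mask_vals, t)
        if (n + 1) % every == 0 or n == n_steps - 1:
            rate = change_rate(u, v, un, vn)
            times.append(t + dt)
            rates.append(rate)
            if record_snapshots:
                snap_t.append(t + dt)
                snaps.append(un.copy())
        u, v = un, vn

    return RunResult(
        u=ScalarField(grid, u, "activator", u0.system_index),
        v=ScalarField(grid, v, "inhibitor", v0.system_index),
        trace_times=np.asarray(times),
        trace_rates=np.asarray(rates),
        converged=bool(rate < settings.stationarity_tol),
        snapshot_times=np.asarray(snap_t),
        snapshots_u=np.asarray(snaps) if snaps else np.empty((0, *grid.shape)),
    )
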