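"""Synthetic fixture fields with machine-readable ground truth.

Everything the test suite needs is generated here at run time: perturbed
homogeneous initial states, fields with condensations planted at known
positions, hexagonal spot lattices for spacing statistics, and single
Fourier eigenmodes of the mixed periodic/zero-flux rectangle for
solver-versus-dispersion checks.  Bumps are isotropic Gaussians truncated
at 4 sigma, so their support is effectively compact and their geometry is
exactly known to downstream oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticParameters, homogeneous_steady_state
from .metrics import Spot, SpotSet
from .solver import Grid, ScalarField

__all__ = ["FixtureSpec", "generate", "hex_lattice_spots", "bump_field"]

KINDS = ("perturbed_homogeneous", "planted_bumps", "hex_lattice", "single_mode")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic field; every fixture is reproducible from it."""

    kind: str
    grid: Grid = Grid()
    seed: int = 0
    amplitude: float = 0.01  # perturbation or mode amplitude
    # planted_bumps
    centers: tuple[tuple[float, float], ...] = ()
    bump_amplitude: float = 2.0
    bump_sigma: float = 0.8
    # hex_lattice
    lattice_spacing: float = 5.0
    # single_mode: cos(pi * mode_x * x / Lx) * cos(2 pi * mode_y * y / Ly)
    mode_x: int = 0
    mode_y: int = 1

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        for cx, cy in self.centers:
            if not 0 <= cx <= self.grid.width_x:
                raise ValueError(f"bump center x={cx} outside the domain")


def bump_field(
    grid: Grid,
    centers,
    amplitude: float,
    sigma: float,
    background: float = 0.0,
) -> np.ndarray:
    """Sum of isotropic Gaussian bumps (truncated at 4 sigma, periodic in y)."""
    vals = np.full(grid.shape, background)
    X = grid.x_centers[None, :]
    Y = grid.y_centers[:, None]
    for cx, cy in centers:
        dy = (Y - cy + grid.width_y / 2) % grid.width_y - grid.width_y / 2
        r2 = (X - cx) ** 2 + dy**2
        bump = amplitude * np.exp(-0.5 * r2 / sigma**2)
        bump[r2 > (4.0 * sigma) ** 2] = 0.0
        vals += bump
    return vals


def generate(
    spec: FixtureSpec, p: KineticParameters = KineticParameters()
) -> tuple[ScalarField, dict]:
    """Build the fixture field and its ground-truth metadata.

    Returns the activator-like ScalarField plus a dict carrying whatever an
    oracle needs: steady state, bump centers, the mode's wavenumber, or the
    lattice truth SpotSet.
    """
    grid = spec.grid
    u_star, v_star = homogeneous_steady_state(p)
    truth: dict = {"kind": spec.kind, "u_star": u_star, "v_star": v_star}

    if spec.kind == "perturbed_homogeneous":
        rng = np.random.default_rng(spec.seed)
        eta = rng.uniform(-1.0, 1.0, size=grid.shape)
        vals = u_star * (1.0 + spec.amplitude * eta)
        truth["amplitude"] = spec.amplitude

    elif spec.kind == "planted_bumps":
        if not spec.centers:
            raise ValueError("planted_bumps needs at least one center")
        vals = bump_field(
            grid, spec.centers, spec.bump_amplitude, spec.bump_sigma, background=u_star
        )
        truth["centers"] = [(cx, cy % grid.width_y) for cx, cy in spec.centers]
        truth["bump_sigma"] = spec.bump_sigma
        truth["bump_amplitude"] = spec.bump_amplitude

    elif spec.kind == "hex_lattice":
        fld, spot_set, s_adj = hex_lattice_spots(grid, spec.lattice_spacing)
        truth["spot_set"] = spot_set
        truth["adjusted_spacing"] = s_adj
        return fld, truth

    elif spec.kind == "single_mode":
        if spec.mode_x != int(spec.mode_x) or spec.mode_x < 0:
            raise ValueError(
                "mode_x must be a nonnegative integer: x modes are cosines "
                "with zero slope at the zero-flux boundaries"
            )
        if spec.mode_y != int(spec.mode_y):
            raise ValueError(
                "mode_y must be an integer: y modes must close on the periodic boundary"
            )
        kx = np.pi * spec.mode_x / grid.width_x
        ky = 2.0 * np.pi * spec.mode_y / grid.width_y
        X = grid.x_centers[None, :]
        Y = grid.y_centers[:, None]
        mode = np.cos(kx * X) * np.cos(ky * Y)
        vals = u_star + spec.amplitude * mode
        truth.update(kx=kx, ky=ky, k=float(np.hypot(kx, ky)), mode=mode)

    return ScalarField(grid, vals, "activator"), truth


def hex_lattice_spots(
    grid: Grid, spacing: float
) -> tuple[ScalarField, SpotSet, float]:
    """Triangular lattice of bumps commensurate with the periodic y direction.

    Rows run along x, stacked in y.  The row count is quantized to an even
    integer so the lattice closes on the period; the in-row spacing is then
    re-derived to keep the lattice equilateral, and the adjusted spacing is
    returned alongside the field and the ground-truth SpotSet.
    """
    if spacing <= 2 * max(grid.dx, grid.dy):
        raise ValueError("lattice spacing must exceed 2 cells")
    row_sep_target = spacing * np.sqrt(3.0) / 2.0
    n_rows = max(2, 2 * round(grid.width_y / (2.0 * row_sep_target)))
    row_sep = grid.width_y / n_rows
    s_adj = 2.0 * row_sep / np.sqrt(3.0)  # keeps the triangles equilateral
    centers: list[tuple[float, float]] = []
    for r in range(n_rows):
        y = (r + 0.5) * row_sep
        x0 = s_adj / 4.0 + (r % 2) * s_adj / 2.0  # alternate rows shift by s/2
        x = x0
        while x < grid.width_x:
            centers.append((x, y))
            x += s_adj
    sigma = min(s_adj, spacing) / 6.0
    vals = bump_field(grid, centers, amplitude=1.0, sigma=sigma)
    fld = ScalarField(grid, vals, "activator")
    spots = [Spot(c, np.pi * sigma**2, 1, 1.0) for c in centers]
    spot_set = SpotSet(spots, 0, grid)
    return fld, spot_set, float(s_adj)
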