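"""Competence regions: where the reaction kinetics are switched on.

Each system i reacts only inside its competence region Omega_i, encoded as
a binary field S_i(x, y).  The sequential rule is purely geometric: tissue
already occupied by an activator condensation (plus a safety margin) loses
competence, so Omega shrinks monotonically as buds appear.  This module
extracts condensations from a stationary activator field, carves them out
of a mask, and builds the horseshoe (crescent) geometry used to confine
late buds around the primary one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kinetics import KineticParameters, homogeneous_steady_state
from .solver import Grid, ScalarField

__all__ = [
    "CompetenceMask",
    "CondensationRegion",
    "extract_condensations",
    "shrink_competence",
    "horseshoe_mask",
    "compose_scenario_mask",
    "full_mask",
    "periodic_label",
]

# condensations shallower than this fraction of u* above the steady state
# are treated as numerical ripple, not pattern
MIN_AMPLITUDE_FRACTION = 0.05


@dataclass
class CompetenceMask:
    """Binary field S_i: 1 where system ``system_index`` may react."""

    grid: Grid
    values: np.ndarray
    system_index: int = 1

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.values = vals.astype(np.uint8)

    def copy(self) -> "CompetenceMask":
        return CompetenceMask(self.grid, self.values.copy(), self.system_index)


@dataclass
class CondensationRegion:
    """One connected above-threshold activator peak (a bud)."""

    cells: np.ndarray  # (n, 2) array of (iy, ix) indices
    centroid: tuple[float, float]  # (x, y), y wrapped into [0, width_y)
    area: float  # cell count * cell area
    peak_value: float
    system_index: int = 1

    def __post_init__(self) -> None:
        if len(self.cells) == 0 or self.area <= 0:
            raise ValueError("condensation must occupy at least one cell")


def full_mask(grid: Grid, system_index: int = 1) -> CompetenceMask:
    return CompetenceMask(grid, np.ones(grid.shape, dtype=np.uint8), system_index)


def periodic_label(binary: np.ndarray) -> tuple[np.ndarray, int]:
    """4-connected component labeling with wrap-around along axis 0 (y).

    Labels with ``scipy.ndimage.label`` and then unions components that touch
    across the y seam.
    """
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return labels, 0
    # union-find over seam adjacencies
    parent = np.arange(n + 1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    top, bot = labels[0, :], labels[-1, :]
    for a, b in zip(top, bot):
        if a and b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = np.array([find(i) for i in range(n + 1)])
    # compress to consecutive labels 1..m
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots[labels]], len(uniq)


def _periodic_centroid(cells: np.ndarray, grid: Grid) -> tuple[float, float]:
    xs = (cells[:, 1] + 0.5) * grid.dx
    theta = 2.0 * np.pi * (cells[:, 0] + 0.5) * grid.dy / grid.width_y
    ybar = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    y = (ybar * grid.width_y / (2.0 * np.pi)) % grid.width_y
    return float(xs.mean()), float(y)


def extract_condensations(
    u: ScalarField,
    p: KineticParameters,
    threshold_fraction: float = 0.5,
    min_area_cells: int = 4,
    within: CompetenceMask | None = None,
    min_amplitude_fraction: float = MIN_AMPLITUDE_FRACTION,
) -> list[CondensationRegion]:
    """Group above-threshold activator cells into condensation regions.

    Cells with ``u > u* + threshold_fraction * (max(u) - u*)`` are labeled
    into 4-connected components (wrapping across the periodic y boundary);
    components smaller than ``min_area_cells`` are discarded.  A field whose
    excess over u* is below ``min_amplitude_fraction * u*`` everywhere is
    considered unpatterned and yields an empty list.  ``within`` optionally
    restricts candidate cells to a competence region: a condensation is
    patterned tissue, which in this model only arises where the kinetics
    were active.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    grid = u.grid
    u_star, _ = homogeneous_steady_state(p)
    vals = u.values
    excess_max = vals.max() - u_star
    if excess_max <= min_amplitude_fraction * u_star:
        return []
    threshold = u_star + threshold_fraction * excess_max
    binary = vals > threshold
    if within is not None:
        binary &= within.values.astype(bool)
    labels, n = periodic_label(binary)
    regions: list[CondensationRegion] = []
    for lbl in range(1, n + 1):
        cells = np.argwhere(labels == lbl)
        if len(cells) < min_area_cells:
            continue
        regions.append(
            CondensationRegion(
                cells=cells,
                centroid=_periodic_centroid(cells, grid),
                area=len(cells) * grid.cell_area,
                peak_value=float(vals[cells[:, 0], cells[:, 1]].max()),
                system_index=u.system_index,
            )
        )
    return regions


def _disc_structure(grid: Grid, margin: float) -> np.ndarray | None:
    """Elliptical footprint covering a physical disc of radius ``margin``."""
    ry = int(np.floor(margin / grid.dy))
    rx = int(np.floor(margin / grid.dx))
    if rx == 0 and ry == 0:
        return None
    oy, ox = np.mgrid[-ry : ry + 1, -rx : rx + 1]
    return (oy * grid.dy) ** 2 + (ox * grid.dx) ** 2 <= margin**2


def condensation_footprint(
    grid: Grid, condensations: list[CondensationRegion], margin: float = 0.0
) -> np.ndarray:
    """Boolean field of all condensation cells dilated by a disc of radius margin.

    The dilation wraps across the periodic y boundary; beyond the zero-flux
    x boundaries there is simply no tissue.
    """
    excl = np.zeros(grid.shape, dtype=bool)
    for region in condensations:
        excl[region.cells[:, 0], region.cells[:, 1]] = True
    if margin > 0 and excl.any():
        struct = _disc_structure(grid, margin)
        if struct is not None:
            ry = struct.shape[0] // 2
            padded = np.pad(excl, ((ry, ry), (0, 0)), mode="wrap")
            padded = ndimage.binary_dilation(padded, structure=struct)
            excl = padded[ry : ry + grid.n_y, :] if ry else padded
    return excl


def shrink_competence(
    prev_mask: CompetenceMask,
    condensations: list[CondensationRegion],
    margin: float = 0.5,
) -> CompetenceMask:
    """Remove dilated condensations from the competent region.

    The result is a subset of ``prev_mask`` (monotone shrinkage) and the
    operation is idempotent for a fixed condensation list.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    excl = condensation_footprint(prev_mask.grid, condensations, margin)
    new_vals = prev_mask.values.astype(bool) & ~excl
    return CompetenceMask(
        prev_mask.grid, new_vals.astype(np.uint8), prev_mask.system_index + 1
    )


def horseshoe_mask(
    grid: Grid,
    center: tuple[float, float],
    r_inner: float,
    r_outer: float,
    opening_half_angle: float = 60.0,
    opening_direction: float = 180.0,
) -> CompetenceMask:
    """Annulus around ``center`` with an angular opening (a horseshoe).

    Bearings are measured in degrees from the anterior direction (-y),
    positive toward +x; ``opening_direction = 180`` opens the ring toward
    the posterior.  Distances wrap across the periodic y boundary, so the
    annulus may not exceed half the periodic extent.
    """
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    if not 0 <= opening_half_angle <= 180:
        raise ValueError("opening_half_angle must lie in [0, 180]")
    if r_outer > grid.width_y / 2:
        raise ValueError(
            f"r_outer={r_outer} exceeds half the periodic extent "
            f"({grid.width_y / 2}); the ring would overlap itself"
        )
    cx, cy = center
    X = grid.x_centers[None, :] - cx
    dyv = grid.y_centers[:, None] - cy
    Y = (dyv + grid.width_y / 2) % grid.width_y - grid.width_y / 2
    r = np.hypot(X, Y)
    bearing = np.degrees(np.arctan2(X, -Y))  # 0 = anterior (-y), +90 = +x
    sep = np.abs((bearing - opening_direction + 180.0) % 360.0 - 180.0)
    if opening_half_angle >= 180.0:  # wedge swallows the whole ring
        ring = np.zeros(grid.shape, dtype=bool)
    else:
        ring = (r >= r_inner) & (r <= r_outer) & (sep >= opening_half_angle)
    return CompetenceMask(grid, ring.astype(np.uint8))


def compose_scenario_mask(
    base: CompetenceMask, scenario_overlay: CompetenceMask | None
) -> CompetenceMask:
    """Elementwise AND of the competence mask with a scenario overlay."""
    if scenario_overlay is None:
        return base.copy()
    if scenario_overlay.grid != base.grid:
        raise ValueError("masks must share one grid")
    return CompetenceMask(
        base.grid, (base.values & scenario_overlay.values), base.system_index
    )
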