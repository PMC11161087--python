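"""Quantification and spatial classification of simulated bud patterns.

Ectopic buds are named by where they sit relative to the primary bud:
spot 2 in the interbud region (far from any primary bud), spot 3 anterior,
spots 4/4' lateral right/left, spots 5/5' posterior-lateral right/left.
Bearings are measured from the anterior direction (0 deg = -y), positive
toward +x (the animal's right); a posterior wedge is deliberately left
unclassified because no buds are observed immediately posterior to the
primary bud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .masks import extract_condensations
from .orchestrator import SequentialResult
from .solver import Grid

__all__ = [
    "Spot",
    "SpotSet",
    "PositionClass",
    "SectorConfig",
    "detect_spots",
    "classify_positions",
    "spacing_statistics",
    "combination_code",
    "periodic_distance",
]

CLASS_ORDER = ("1", "2", "3", "4", "4'", "5", "5'", "unclassified")


@dataclass(frozen=True)
class Spot:
    centroid: tuple[float, float]  # (x, y)
    area: float
    system_index: int
    peak_value: float


@dataclass
class SpotSet:
    """Detected condensations of a whole sequence, with the primary bud."""

    spots: list[Spot]
    primary_index: int
    grid: Grid

    def __post_init__(self) -> None:
        if not 0 <= self.primary_index < len(self.spots):
            raise ValueError("primary_index out of range")
        if self.spots[self.primary_index].system_index != 1:
            raise ValueError("primary spot must come from system 1")

    @property
    def primary(self) -> Spot:
        return self.spots[self.primary_index]


@dataclass(frozen=True)
class PositionClass:
    label: str  # one of CLASS_ORDER
    bearing_deg: float  # from anterior (-y), positive toward +x
    distance: float  # periodic distance from the primary centroid

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {self.label!r}")


@dataclass(frozen=True)
class SectorConfig:
    """Angular sectors (degrees from anterior, half-open) and the interbud rule.

    ``interbud_radius`` of None triggers the automatic rule: 0.6x the
    nearest-neighbor spacing among system-1 spots, or 0.6x half the smaller
    domain extent when system 1 produced a single spot.
    """

    anterior_half_angle: float = 30.0
    lateral_bound: float = 90.0
    posterior_lateral_bound: float = 150.0
    interbud_radius: float | None = None
    interbud_factor: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.anterior_half_angle < self.lateral_bound < self.posterior_lateral_bound <= 180:
            raise ValueError("sector bounds must increase within (0, 180]")


def periodic_distance(
    a: tuple[float, float], b: tuple[float, float], grid: Grid
) -> float:
    """Euclidean distance with the y coordinate wrapped on the period."""
    dx = a[0] - b[0]
    dy = (a[1] - b[1] + grid.width_y / 2) % grid.width_y - grid.width_y / 2
    return float(np.hypot(dx, dy))


def detect_spots(
    result: SequentialResult, detection_threshold: float = 0.5
) -> SpotSet:
    """Union of per-system condensations; primary = largest system-1 spot."""
    spots: list[Spot] = []
    for i in range(1, result.n_systems + 1):
        regions = extract_condensations(
            result.fields_u[i - 1],
            result.schedule.params_for(i),
            detection_threshold,
            within=result.masks[i - 1],
        )
        for r in regions:
            spots.append(Spot(r.centroid, r.area, i, r.peak_value))
    sys1 = [(j, s) for j, s in enumerate(spots) if s.system_index == 1]
    if not sys1:
        raise RuntimeError("system 1 produced no spot: no primary bud to reference")
    primary_index = max(sys1, key=lambda js: js[1].area)[0]
    return SpotSet(spots, primary_index, result.grid)


def _interbud_radius(spot_set: SpotSet, cfg: SectorConfig) -> float:
    if cfg.interbud_radius is not None:
        return cfg.interbud_radius
    primaries = [s for s in spot_set.spots if s.system_index == 1]
    if len(primaries) >= 2:
        dists = [
            min(
                periodic_distance(a.centroid, b.centroid, spot_set.grid)
                for b in primaries
                if b is not a
            )
            for a in primaries
        ]
        return cfg.interbud_factor * float(np.mean(dists))
    g = spot_set.grid
    return cfg.interbud_factor * min(g.width_x, g.width_y) / 2


def classify_positions(
    spot_set: SpotSet, sector_config: SectorConfig = SectorConfig()
) -> list[PositionClass]:
    """Assign each spot a position class relative to the primary bud.

    The primary spot is class 1.  Any other spot farther than the interbud
    radius is class 2 regardless of bearing; nearer spots fall into angular
    sectors: anterior -> 3, lateral -> 4 (right, +x) / 4' (left),
    posterior-lateral -> 5/5', and the remaining posterior wedge is
    unclassified.
    """
    cfg = sector_config
    g = spot_set.grid
    px, py = spot_set.primary.centroid
    r_interbud = _interbud_radius(spot_set, cfg)
    out: list[PositionClass] = []
    for j, s in enumerate(spot_set.spots):
        dx = s.centroid[0] - px
        dy = (s.centroid[1] - py + g.width_y / 2) % g.width_y - g.width_y / 2
        dist = float(np.hypot(dx, dy))
        bearing = float(np.degrees(np.arctan2(dx, -dy)))  # 0 = anterior
        if j == spot_set.primary_index:
            out.append(PositionClass("1", bearing, dist))
            continue
        if dist > r_interbud:
            out.append(PositionClass("2", bearing, dist))
            continue
        mag, right = abs(bearing), bearing >= 0
        if mag < cfg.anterior_half_angle:
            label = "3"
        elif mag < cfg.lateral_bound:
            label = "4" if right else "4'"
        elif mag < cfg.posterior_lateral_bound:
            label = "5" if right else "5'"
        else:
            label = "unclassified"
        out.append(PositionClass(label, bearing, dist))
    return out


def spacing_statistics(spot_set: SpotSet) -> tuple[float, float, int]:
    """(mean nearest-neighbor distance, min pairwise distance, spot count).

    Distances use the periodic-y metric.  Needs at least two spots.
    """
    n = len(spot_set.spots)
    if n < 2:
        raise ValueError("spacing statistics need at least 2 spots")
    cents = [s.centroid for s in spot_set.spots]
    nn = []
    dmin = np.inf
    for i in range(n):
        best = min(
            periodic_distance(cents[i], cents[j], spot_set.grid)
            for j in range(n)
            if j != i
        )
        nn.append(best)
        dmin = min(dmin, best)
    return float(np.mean(nn)), float(dmin), n


def combination_code(classes: list[PositionClass]) -> str:
    """Canonical '+'-joined string of the distinct classes present.

    The primary class 1 is always included; unclassified spots are ignored
    in the code (they have no named position).
    """
    present = {c.label for c in classes if c.label != "unclassified"}
    present.add("1")
    return "+".join(lbl for lbl in CLASS_ORDER[:-1] if lbl in present)
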