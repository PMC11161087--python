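"""Run the consecutive Turing systems, each gated to unpatterned tissue.

Five independent morphogen pairs (u_i, v_i) share one domain and interact
identically; the only coupling between them is geometric: system i may
react only where systems 1..i-1 left no condensation.  Three scenarios are
supported:

``full``
    The plain consecutive scheme: each new competence region is the
    previous one minus the previous system's (dilated) condensations.
``remove_bud2``
    System 2 still runs, but its condensations are never excluded from
    later competence regions -- only systems 1, 3, 4, ... restrict space.
``horseshoe``
    From system 3 on, competence is the intersection of "not patterned by
    system 1" with a horseshoe ring around the primary bud, mimicking the
    crescent-shaped competent area seen around the primary bud base; the
    ring is independent of system 2.

Each system starts from its own freshly perturbed homogeneous state; the
morphogen pairs are separate species, coupled only through geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import KineticParameters, homogeneous_steady_state
from .masks import (
    CompetenceMask,
    CondensationRegion,
    compose_scenario_mask,
    condensation_footprint,
    extract_condensations,
    full_mask,
    horseshoe_mask,
)
from .solver import (
    Grid,
    RunResult,
    ScalarField,
    SolverSettings,
    make_initial_condition,
    run_to_stationarity,
)

__all__ = [
    "SCENARIOS",
    "SimulationSchedule",
    "MaskParams",
    "HorseshoeParams",
    "SequentialResult",
    "run_sequence",
    "apply_scenario",
    "merge_patterns",
    "derive_system_seed",
]

SCENARIOS = ("full", "remove_bud2", "horseshoe")

PAPER_DURATIONS = (500.0, 1000.0, 1000.0, 1000.0, 1000.0)


@dataclass(frozen=True)
class HorseshoeParams:
    """Geometry of the crescent competence region (scenario ``horseshoe``).

    ``r_inner`` defaults to 1.2x the primary spot's equivalent radius and
    ``r_outer`` to ``r_inner + 2.5`` length units; the 60-degree half-angle
    opening faces the posterior (+y), where no ectopic buds are observed
    immediately behind the primary bud.
    """

    r_inner: float | None = None
    r_outer: float | None = None
    opening_half_angle: float = 60.0
    opening_direction: float = 180.0


@dataclass(frozen=True)
class MaskParams:
    threshold_fraction: float = 0.5
    margin: float = 0.5  # dilation radius around condensations, length units
    min_area_cells: int = 4
    horseshoe: HorseshoeParams = HorseshoeParams()


@dataclass(frozen=True)
class SimulationSchedule:
    """Ordered per-system durations, scenario variant and master seed."""

    n_systems: int = 5
    durations: tuple[float, ...] = PAPER_DURATIONS
    scenario: str = "full"
    params: KineticParameters | tuple[KineticParameters, ...] = KineticParameters()
    seed: int = 0
    amplitude: float = 0.01  # initial perturbation, fraction of steady state

    def __post_init__(self) -> None:
        if self.n_systems < 1:
            raise ValueError("n_systems must be >= 1")
        if len(self.durations) != self.n_systems:
            raise ValueError(
                f"need one duration per system: got {len(self.durations)} "
                f"durations for {self.n_systems} systems"
            )
        if any(d <= 0 for d in self.durations):
            raise ValueError("all durations must be > 0")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")

    def params_for(self, i: int) -> KineticParameters:
        """Kinetic parameters of system i (1-based)."""
        if isinstance(self.params, KineticParameters):
            return self.params
        if len(self.params) != self.n_systems:
            raise ValueError("per-system parameter list length must equal n_systems")
        return self.params[i - 1]


@dataclass
class SequentialResult:
    grid: Grid
    schedule: SimulationSchedule
    fields_u: list[ScalarField] = field(default_factory=list)
    fields_v: list[ScalarField] = field(default_factory=list)
    masks: list[CompetenceMask] = field(default_factory=list)
    condensations: list[list[CondensationRegion]] = field(default_factory=list)
    run_results: list[RunResult] = field(default_factory=list)
    system_seeds: list[int] = field(default_factory=list)
    horseshoe: CompetenceMask | None = None
    event_log: list[str] = field(default_factory=list)

    @property
    def n_systems(self) -> int:
        return len(self.fields_u)


def derive_system_seed(master_seed: int, i: int) -> int:
    """Independent, reproducible per-system seed (below 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), int(i)])
    return int(ss.generate_state(1)[0] % 2**31)


def _primary_region(result: SequentialResult) -> CondensationRegion:
    sys1 = result.condensations[0]
    if not sys1:
        raise RuntimeError("system 1 produced no condensation; no primary bud")
    return max(sys1, key=lambda r: r.area)


def _horseshoe_for(result: SequentialResult, mp: MaskParams) -> CompetenceMask:
    """Build (once) the horseshoe ring around the system-1 primary spot."""
    if result.horseshoe is not None:
        return result.horseshoe
    primary = _primary_region(result)
    hp = mp.horseshoe
    r_primary = float(np.sqrt(primary.area / np.pi))
    r_inner = hp.r_inner if hp.r_inner is not None else 1.2 * r_primary
    r_outer = hp.r_outer if hp.r_outer is not None else r_inner + 2.5
    ring = horseshoe_mask(
        result.grid,
        primary.centroid,
        r_inner,
        r_outer,
        hp.opening_half_angle,
        hp.opening_direction,
    )
    result.horseshoe = ring
    result.event_log.append(
        f"horseshoe ring: center={primary.centroid}, r_inner={r_inner:.3f}, "
        f"r_outer={r_outer:.3f}"
    )
    return ring


def apply_scenario(
    scenario: str,
    i: int,
    mask_candidate: CompetenceMask,
    context: SequentialResult,
    mask_params: MaskParams = MaskParams(),
) -> CompetenceMask:
    """Scenario-specific rewrite of the candidate competence mask for system i.

    ``full`` is the identity.  ``remove_bud2`` rebuilds the mask for i >= 3
    from the condensations of systems 1 and 3..i-1, dropping system 2's
    influence.  ``horseshoe`` intersects, for i >= 3, the system-1-only
    exclusion with the horseshoe ring.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if i < 2:
        raise ValueError("scenarios apply from system 2 onward")
    if scenario == "full" or i == 2:
        return mask_candidate
    grid = context.grid
    if scenario == "remove_bud2":
        keep = [
            region
            for j, regions in enumerate(context.condensations[: i - 1], start=1)
            if j != 2
            for region in regions
        ]
        excl = condensation_footprint(grid, keep, mask_params.margin)
        return CompetenceMask(grid, (~excl).astype(np.uint8), i)
    # horseshoe: exclusion from system 1 only, intersected with the ring
    excl = condensation_footprint(grid, context.condensations[0], mask_params.margin)
    base = CompetenceMask(grid, (~excl).astype(np.uint8), i)
    return compose_scenario_mask(base, _horseshoe_for(context, mask_params))


def run_sequence(
    schedule: SimulationSchedule,
    grid: Grid = Grid(),
    settings: SolverSettings = SolverSettings(),
    mask_params: MaskParams = MaskParams(),
    noise_grid: Grid | None = None,
    record_snapshots: bool = False,
) -> SequentialResult:
    """Integrate the consecutive systems and collect fields, masks and buds.

    System 1 is competent everywhere; system i inherits the previous mask
    minus the previous system's dilated condensations, modified by the
    scenario.  Every system starts from a freshly perturbed homogeneous
    state whose seed derives deterministically from ``schedule.seed``.
    A system that produces no condensation is logged as a warning but does
    not abort the sequence.
    """
    result = SequentialResult(grid=grid, schedule=schedule)
    mask = full_mask(grid, 1)
    for i in range(1, schedule.n_systems + 1):
        if i >= 2:
            candidate = CompetenceMask(
                grid,
                (
                    mask.values.astype(bool)
                    & ~condensation_footprint(
                        grid, result.condensations[i - 2], mask_params.margin
                    )
                ).astype(np.uint8),
                i,
            )
            mask = apply_scenario(schedule.scenario, i, candidate, result, mask_params)
        p = schedule.params_for(i)
        seed_i = derive_system_seed(schedule.seed, i)
        u0, v0 = make_initial_condition(
            grid, p, schedule.amplitude, seed_i, noise_grid=noise_grid
        )
        run_settings = replace(settings, duration=schedule.durations[i - 1])
        try:
            run = run_to_stationarity(
                u0, v0, mask, p, run_settings, record_snapshots=record_snapshots
            )
        except Exception as exc:
            raise RuntimeError(f"solver failure in system {i}: {exc}") from exc
        run.u.system_index = run.v.system_index = i
        conds = extract_condensations(
            run.u,
            p,
            mask_params.threshold_fraction,
            mask_params.min_area_cells,
            within=mask,
        )
        result.fields_u.append(run.u)
        result.fields_v.append(run.v)
        result.masks.append(mask)
        result.condensations.append(conds)
        result.run_results.append(run)
        result.system_seeds.append(seed_i)
        result.event_log.append(
            f"system {i}: seed={seed_i}, duration={schedule.durations[i - 1]}, "
            f"converged={run.converged}, condensations={len(conds)}, "
            f"competent_fraction={mask.values.mean():.3f}"
        )
        if not conds:
            result.event_log.append(f"warning: system {i} produced no condensation")
    return result


def merge_patterns(result: SequentialResult) -> tuple[ScalarField, np.ndarray]:
    """Composite pattern: per-cell max of normalized activator excess.

    Each system's activator excess over its steady state is normalized by
    its own maximum excess (flat systems contribute zeros) and clipped at
    zero; the merged field takes the per-cell maximum.  The accompanying
    integer label field records which system dominates each cell (0 where
    no system exceeds its steady state).
    """
    if result.n_systems == 0:
        raise ValueError("empty result")
    grid = result.grid
    stack = np.zeros((result.n_systems, *grid.shape))
    for j, u in enumerate(result.fields_u):
        u_star, _ = homogeneous_steady_state(result.schedule.params_for(j + 1))
        excess = np.clip(u.values - u_star, 0.0, None)
        m = excess.max()
        if m > 0:
            stack[j] = excess / m
    merged = stack.max(axis=0)
    labels = np.where(merged > 0, stack.argmax(axis=0) + 1, 0)
    return ScalarField(grid, merged, "activator", 0), labels
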