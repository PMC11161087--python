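"""Readers and writers for fields, masks, spot tables and run manifests.

Field stacks travel in a self-describing netCDF container (via xarray, one
``system`` layer per reaction-diffusion system, dims ``(system, y, x)``)
together with the grid geometry and the kinetic constants as attributes.
Spot tables and combination summaries are plain CSV with stable headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .kinetics import KineticParameters
from .masks import CompetenceMask
from .metrics import PositionClass, SpotSet, classify_positions, spacing_statistics
from .orchestrator import SequentialResult, SimulationSchedule, merge_patterns
from .solver import Grid, ScalarField

__all__ = [
    "write_fields",
    "read_fields",
    "spots_table",
    "write_spot_tables",
    "write_merged_png",
    "write_manifest",
]

SPOT_COLUMNS = [
    "spot_id", "system", "x", "y", "area", "peak", "class", "bearing_deg", "distance",
]


def result_to_dataset(result: SequentialResult) -> xr.Dataset:
    grid = result.grid
    n = result.n_systems
    u = np.stack([f.values for f in result.fields_u])
    v = np.stack([f.values for f in result.fields_v])
    m = np.stack([mk.values for mk in result.masks]).astype(np.int8)
    merged, labels = merge_patterns(result)
    sched = result.schedule
    params = [sched.params_for(i) for i in range(1, n + 1)]
    ds = xr.Dataset(
        {
            "u": (("system", "y", "x"), u),
            "v": (("system", "y", "x"), v),
            "mask": (("system", "y", "x"), m),
            "merged": (("y", "x"), merged.values),
            "dominant_system": (("y", "x"), labels.astype(np.int32)),
        },
        coords={
            "system": np.arange(1, n + 1),
            "x": grid.x_centers,
            "y": grid.y_centers,
        },
        attrs={
            "width_x": grid.width_x,
            "width_y": grid.width_y,
            "n_x": grid.n_x,
            "n_y": grid.n_y,
            "scenario": sched.scenario,
            "seed": sched.seed,
            "amplitude": sched.amplitude,
            "durations": list(sched.durations),
            "a": [p.a for p in params],
            "b": [p.b for p in params],
            "D_u": [p.D_u for p in params],
            "D_v": [p.D_v for p in params],
        },
    )
    return ds


def write_fields(result: SequentialResult, path: str | Path) -> Path:
    """Write the per-system field/mask stack as a netCDF container."""
    path = Path(path)
    result_to_dataset(result).to_netcdf(path, engine="scipy")
    return path


def read_fields(path: str | Path) -> SequentialResult:
    """Rebuild a SequentialResult (fields, masks, schedule) from a container.

    Condensation lists are not stored; downstream analysis re-extracts them
    from the fields, which keeps re-analysis under different thresholds
    possible.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no field container at {path}")
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    at = ds.attrs
    grid = Grid(float(at["width_x"]), float(at["width_y"]), int(at["n_x"]), int(at["n_y"]))
    n = ds.sizes["system"]

    def _aslist(key):
        val = at[key]
        return list(np.atleast_1d(val))

    a, b, Du, Dv = (_aslist(k) for k in ("a", "b", "D_u", "D_v"))
    params = tuple(
        KineticParameters(float(a[i]), float(b[i]), float(Du[i]), float(Dv[i]))
        for i in range(n)
    )
    schedule = SimulationSchedule(
        n_systems=n,
        durations=tuple(float(d) for d in _aslist("durations")),
        scenario=str(at["scenario"]),
        params=params,
        seed=int(at["seed"]),
        amplitude=float(at["amplitude"]),
    )
    result = SequentialResult(grid=grid, schedule=schedule)
    for i in range(n):
        result.fields_u.append(
            ScalarField(grid, ds["u"].values[i], "activator", i + 1)
        )
        result.fields_v.append(
            ScalarField(grid, ds["v"].values[i], "inhibitor", i + 1)
        )
        result.masks.append(
            CompetenceMask(grid, ds["mask"].values[i].astype(np.uint8), i + 1)
        )
        result.condensations.append([])
    return result


def spots_table(spot_set: SpotSet, classes: list[PositionClass]) -> pd.DataFrame:
    rows = []
    for j, (s, c) in enumerate(zip(spot_set.spots, classes)):
        rows.append(
            {
                "spot_id": j,
                "system": s.system_index,
                "x": s.centroid[0],
                "y": s.centroid[1],
                "area": s.area,
                "peak": s.peak_value,
                "class": c.label,
                "bearing_deg": c.bearing_deg,
                "distance": c.distance,
            }
        )
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def write_spot_tables(
    spot_set: SpotSet,
    classes: list[PositionClass],
    combination: str,
    out_dir: str | Path,
    seed: int,
    scenario: str,
) -> tuple[Path, Path]:
    """Write spots.csv and the one-row combination.csv summary."""
    out_dir = Path(out_dir)
    spots_path = out_dir / "spots.csv"
    spots_table(spot_set, classes).to_csv(spots_path, index=False, float_format="%.6f")
    mean_nn, dmin, count = (
        spacing_statistics(spot_set) if len(spot_set.spots) >= 2 else (np.nan, np.nan, len(spot_set.spots))
    )
    combo_path = out_dir / "combination.csv"
    pd.DataFrame(
        [
            {
                "seed": seed,
                "scenario": scenario,
                "combination": combination,
                "n_spots": count,
                "mean_nn_distance": mean_nn,
                "min_distance": dmin,
            }
        ]
    ).to_csv(combo_path, index=False, float_format="%.6f")
    return spots_path, combo_path


def write_merged_png(result: SequentialResult, path: str | Path) -> Path:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    merged, _ = merge_patterns(result)
    path = Path(path)
    plt.imsave(path, merged.values, cmap="magma", origin="lower")
    return path


def write_field_png(values: np.ndarray, path: str | Path, cmap: str = "magma") -> Path:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    plt.imsave(path, values, cmap=cmap, origin="lower")
    return path


def write_manifest(
    out_dir: str | Path,
    config_dict: dict,
    result: SequentialResult | None,
    outputs: list[str],
    success: bool,
) -> Path:
    from . import __version__

    manifest = {
        "package": "turingbuds",
        "version": __version__,
        "numpy_version": np.__version__,
        "config": config_dict,
        "system_seeds": result.system_seeds if result is not None else [],
        "event_log": result.event_log if result is not None else [],
        "outputs": outputs,
        "success": success,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
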