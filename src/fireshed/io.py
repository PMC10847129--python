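"""Readers/writers for the pipeline's file formats.

Grids go to single- or multi-band TIFF (integer layers bit-exact, continuous
layers float32) with a JSON sidecar legend for categorical layers; tabular
data (plots, cohorts, stands, ledgers, transition tables) to CSV; manifests
and summaries to JSON; and initial-communities layers to a simple text
format of ``MapCode N`` blocks followed by ``species age1 age2 ...`` lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imputation import InitialCommunitiesLayer
from .landscape import (
    Cohort,
    PlotRecord,
    SPECIES_NAMES,
    StandTable,
)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Grids


def write_grid(path: str | Path, grid: np.ndarray,
               legend: dict[int, str] | None = None) -> None:
    """Write a 2-D grid or a (bands, rows, cols) stack as TIFF; integer
    arrays are preserved bit-exactly, floats stored as float32."""
    arr = np.asarray(grid)
    if arr.ndim not in (2, 3):
        raise FormatError("grid must be 2-D or a (bands, rows, cols) stack")
    if not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr)
    if legend is not None:
        sidecar = Path(str(path) + ".json")
        sidecar.write_text(json.dumps({str(k): v for k, v in legend.items()},
                                      indent=2))


def read_grid(path: str | Path) -> tuple[np.ndarray, dict[int, str] | None]:
    try:
        arr = tifffile.imread(str(path))
    except Exception as err:  # malformed file
        raise FormatError(f"cannot read grid {path}: {err}") from err
    legend = None
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return arr, legend


# ---------------------------------------------------------------------------
# Plots / stands tables


def write_plot_tables(out_dir: str | Path, plots: list[PlotRecord],
                      stands: StandTable | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"plot_id": p.plot_id, "stand_id": p.stand_id, "x": p.x, "y": p.y,
          "source": p.source, "forest_type": p.forest_type} for p in plots]
    ).to_csv(out / "plots.csv", index=False)
    pd.DataFrame(
        [{"plot_id": p.plot_id, "species_id": c.species_id,
          "species": SPECIES_NAMES[c.species_id], "age": c.age,
          "agc_mg_ha": c.agc}
         for p in plots for c in p.cohorts]
    ).to_csv(out / "cohorts.csv", index=False)
    if stands is not None:
        pd.DataFrame(
            [{"stand_id": s, "x": stands.centroids[s][0],
              "y": stands.centroids[s][1],
              "n_plots": len(stands.plot_ids[s])} for s in stands.stand_ids]
        ).to_csv(out / "stands.csv", index=False)


def read_plot_tables(in_dir: str | Path) -> list[PlotRecord]:
    in_path = Path(in_dir)
    plots_df = pd.read_csv(in_path / "plots.csv")
    cohorts_df = pd.read_csv(in_path / "cohorts.csv")
    grouped = {pid: g for pid, g in cohorts_df.groupby("plot_id")}
    plots = []
    for row in plots_df.itertuples():
        g = grouped.get(row.plot_id)
        cohorts = [] if g is None else [
            Cohort(int(r.species_id), int(r.age), float(r.agc_mg_ha))
            for r in g.itertuples()]
        stand = None if pd.isna(row.stand_id) else int(row.stand_id)
        plots.append(PlotRecord(plot_id=int(row.plot_id), x=float(row.x),
                                y=float(row.y), source=str(row.source),
                                cohorts=cohorts, forest_type=str(row.forest_type),
                                stand_id=stand))
    return plots


# ---------------------------------------------------------------------------
# Initial-communities text format


def write_initial_communities_text(path: str | Path,
                                   layer: InitialCommunitiesLayer) -> None:
    """Blocks of ``MapCode N`` followed by one ``species age...`` line per
    species present in the code's cohort list."""
    lines = ["LandisData \"Initial Communities\"", ""]
    for code in sorted(layer.code_cohorts):
        lines.append(f"MapCode {code}")
        by_species: dict[int, list[int]] = {}
        for c in layer.code_cohorts[code]:
            by_species.setdefault(c.species_id, []).append(c.age)
        for sp in sorted(by_species):
            ages = " ".join(str(a) for a in sorted(by_species[sp]))
            lines.append(f"{SPECIES_NAMES[sp]} {ages}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_manifest_json(path: str | Path, manifest) -> None:
    data = [{"layer_id": r.layer_id, "climate_id": r.climate_id,
             "scenario": r.scenario, "replicate": r.replicate, "seed": r.seed}
            for r in manifest.runs]
    Path(path).write_text(json.dumps(data, indent=2))
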