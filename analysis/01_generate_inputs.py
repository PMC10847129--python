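"""Generate the synthetic fireshed and its two inventory designs.

Builds the 100 m landscape (elevation, TRASP, spectral bands, forest types,
18 ecoregions, 3 fire regions), a 68-plot exact-coordinate network spanning
the whole grid, and 111 stand-exam stands (3-31 plots each, centroid
coordinates only) clustered in the northern uplands.  Writes the rasters,
plot/cohort/stand tables, and the per-plot sampling-intensity table under
results/inputs/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import fireshed as fs
from fireshed import io as fio
from fireshed.experiments import build_campaign_inputs
from fireshed.imputation import compute_sampling_intensity
from fireshed.landscape import COVER_LABELS

SEED = 20240
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    cfg = fs.validate_config()
    landscape, fia, stands, cse = build_campaign_inputs(cfg, SEED)
    OUT.mkdir(parents=True, exist_ok=True)

    fio.write_grid(OUT / "elevation.tif", landscape.covariates.elevation)
    fio.write_grid(OUT / "trasp.tif", landscape.covariates.trasp)
    fio.write_grid(OUT / "slope.tif", landscape.zones.slope)
    fio.write_grid(OUT / "forest_type.tif",
                   landscape.forest_type.astype(np.int16),
                   legend=dict(enumerate(COVER_LABELS)))
    fio.write_grid(OUT / "ecoregion.tif",
                   landscape.zones.ecoregion.astype(np.int16))
    fio.write_plot_tables(OUT, fia + cse, stands)

    table = compute_sampling_intensity(fia + cse, landscape)
    rows = [{"plot_id": pid, "forest_type": ftype, "represented_area_ha": ha}
            for pid, (ftype, ha) in table.per_plot.items()]
    pd.DataFrame(rows).to_csv(OUT / "sampling_intensity.csv", index=False)

    areas = landscape.type_areas_ha()
    summary = {
        "grid": list(landscape.grid.shape),
        "total_area_ha": landscape.grid.n_cells * landscape.grid.cell_area_ha,
        "forest_type_areas_ha": areas,
        "n_fia_plots": len(fia),
        "n_cse_plots": len(cse),
        "n_stands": len(stands.stand_ids),
        "plots_per_stand_min": min(len(stands.plot_ids[s])
                                   for s in stands.stand_ids),
        "plots_per_stand_max": max(len(stands.plot_ids[s])
                                   for s in stands.stand_ids),
        "ecoregion_classes": int(len(np.unique(landscape.zones.ecoregion))),
        "uncovered_types": table.uncovered_types,
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"Landscape: {summary['total_area_ha']:.0f} ha, "
          f"{summary['ecoregion_classes']} ecoregions")
    print(f"Inventories: {len(fia)} exact-coordinate plots, "
          f"{len(cse)} stand-exam plots in {len(stands.stand_ids)} stands "
          f"({summary['plots_per_stand_min']}-{summary['plots_per_stand_max']} "
          f"plots/stand)")
    for ftype, ha in areas.items():
        n = sum(1 for r in rows if r["forest_type"] == ftype)
        per = ha / n if n else float("nan")
        print(f"  {ftype:>16}: {ha:6.0f} ha, {n:4d} plots, "
              f"{per:7.1f} ha represented per plot")


if __name__ == "__main__":
    main()
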