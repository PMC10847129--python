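"""Uncertainty experiments and campaign orchestration.

Two experiments probe how inventory design propagates into the initial
vegetation layer: (1) the within-stand experiment redraws the
one-plot-per-stand selection to bound the uncertainty from plots that share
a stand centroid; (2) the sampling-intensity experiment rebuilds the layer
from nested halvings of the plot pool (and from the sparse exact-coordinate
network alone).  The management campaign runs paired no-management /
management ensembles, maps conditional high-severity probability, zones
treatments, and accounts net ecosystem carbon balance (NECB = photosynthesis
gain minus wildfire, thinning and prescribed-burn losses), relativized to
the no-management scenario.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import CampaignConfig
from .imputation import (
    InitialCommunitiesLayer,
    build_layer,
    select_one_plot_per_stand,
    subsample_proportional,
)
from .landscape import (
    FOREST_TYPES,
    COVER_CODE,
    Landscape,
    LandscapeConfig,
    PlotRecord,
    StandTable,
    generate_landscape,
    sample_cse_like_stands,
    sample_fia_like_plots,
)
from .risk import (
    SeverityProbabilityMap,
    TreatmentMap,
    build_treatment_map,
    high_severity_probability,
)
from .simulator import (
    ClimateForcing,
    FluxLedger,
    SimulationOutput,
    SimulatorConfig,
    default_climates,
    run_simulation,
)


class ManifestError(ValueError):
    pass


class StatisticsError(ValueError):
    pass


def derive_seed(master: int, *keys: int | str) -> int:
    """Deterministic per-run seed (< 2^31) from a master seed and run identity."""
    ints = [int(master) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Manifests and comparisons


@dataclass(frozen=True)
class RunSpec:
    layer_id: str
    climate_id: str
    scenario: str  # "no_mgmt" | "mgmt"
    replicate: int
    seed: int


@dataclass
class ExperimentManifest:
    runs: list[RunSpec]

    def __post_init__(self) -> None:
        seeds = [r.seed for r in self.runs]
        if len(set(seeds)) != len(seeds):
            raise ManifestError("run seeds are not unique")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def simulation_years(self, years: int) -> int:
        return self.n_runs * years


@dataclass
class LayerComparison:
    """Reference-minus-alternative AGC difference and its summaries."""

    difference: np.ndarray  # Mg C/ha, reference - alternative
    median: float
    iqr: float
    exceedance_area_ha: float  # |difference| > threshold
    threshold: float
    by_forest_type: dict[str, np.ndarray]  # alternative-layer AGC per type


def compare_layers(reference_agc: np.ndarray, alternative_agc: np.ndarray,
                   landscape: Landscape,
                   threshold: float = 20.0) -> LayerComparison:
    """Difference statistics over forested cells (reference - alternative)."""
    mask = landscape.forested_mask()
    diff = reference_agc - alternative_agc
    vals = diff[mask]
    q25, q75 = np.percentile(vals, [25, 75])
    exceed = float(np.sum(np.abs(diff[mask]) > threshold)
                   * landscape.grid.cell_area_ha)
    by_type = {}
    for ftype in FOREST_TYPES:
        tmask = landscape.forest_type == COVER_CODE[ftype]
        by_type[ftype] = alternative_agc[tmask]
    return LayerComparison(difference=diff, median=float(np.median(vals)),
                           iqr=float(q75 - q25), exceedance_area_ha=exceed,
                           threshold=threshold, by_forest_type=by_type)


# ---------------------------------------------------------------------------
# Within-stand experiment


@dataclass
class WithinStandResult:
    manifest: ExperimentManifest
    reference_layer: InitialCommunitiesLayer
    layers: list[InitialCommunitiesLayer]
    comparison: LayerComparison  # reference vs mean over replicate layers
    year1_totals_tg: list[float]  # per scheduled run (layer x climate)


def within_stand_experiment(
    stands: StandTable,
    cse_plots: list[PlotRecord],
    fia_plots: list[PlotRecord],
    landscape: Landscape,
    climates: list[ClimateForcing],
    seed: int,
    simulate: bool = False,
    sim_config: SimulatorConfig = SimulatorConfig(),
    exceedance_threshold: float = 20.0,
) -> WithinStandResult:
    """Bound the uncertainty from stand-centroid-only plot coordinates.

    Builds as many one-plot-per-stand layers as the largest stand holds
    plots (each draw pooled with the exact-coordinate plots), schedules one
    run per layer x climate, and compares year-1 AGC of a designated
    reference draw against the mean over the replicate layers.  With
    ``simulate`` off, year-1 AGC is taken from the imputed layers directly
    (the comparison the layer statistics need); runs are still scheduled in
    the manifest.
    """
    if not stands.stand_ids:
        raise ManifestError("no stands supplied")
    n_layers = max(len(stands.plot_ids[s]) for s in stands.stand_ids)

    reference_sel = select_one_plot_per_stand(stands, cse_plots,
                                              derive_seed(seed, "reference"))
    reference_layer = build_layer(reference_sel + fia_plots, landscape)

    layers = []
    runs = []
    for i in range(n_layers):
        sel = select_one_plot_per_stand(stands, cse_plots,
                                        derive_seed(seed, "draw", i))
        layers.append(build_layer(sel + fia_plots, landscape))
        for climate in climates:
            runs.append(RunSpec(layer_id=f"within_stand_{i+1}",
                                climate_id=climate.name, scenario="no_mgmt",
                                replicate=1,
                                seed=derive_seed(seed, "run", i, climate.name)))
    manifest = ExperimentManifest(runs=runs)

    year1_totals = []
    cell_tg = landscape.grid.cell_area_ha / 1e6
    if simulate:
        year1_grids = []
        for i, layer in enumerate(layers):
            for j, climate in enumerate(climates):
                run = runs[i * len(climates) + j]
                out = run_simulation(layer, landscape, climate, None, 1,
                                     run.seed, sim_config)
                year1_grids.append(out.agc[0])
                year1_totals.append(float(out.agc[0].sum()) * cell_tg)
        mean_year1 = np.mean(np.stack(year1_grids), axis=0)
        ref_grid = reference_layer.agc_grid()
    else:
        grids = [layer.agc_grid() for layer in layers]
        for g in grids:
            for _ in climates:
                year1_totals.append(float(g.sum()) * cell_tg)
        mean_year1 = np.mean(np.stack(grids), axis=0)
        ref_grid = reference_layer.agc_grid()

    comparison = compare_layers(ref_grid, mean_year1, landscape,
                                exceedance_threshold)
    return WithinStandResult(manifest=manifest, reference_layer=reference_layer,
                             layers=layers, comparison=comparison,
                             year1_totals_tg=year1_totals)


# ---------------------------------------------------------------------------
# Sampling-intensity experiment


@dataclass
class IntensityLevelResult:
    label: str
    n_cse_plots: int
    layer: InitialCommunitiesLayer
    comparison: LayerComparison
    plots: list[PlotRecord] = field(default_factory=list)  # donors incl. FIA

    def donor_agc_range(self, forest_type: str) -> float:
        """Attainable AGC span of this level's donor pool for one type.
        By donor closure the imputed cell values lie inside this span."""
        from .imputation import classify_plot

        vals = [p.total_agc for p in self.plots
                if classify_plot(p) == forest_type]
        return float(max(vals) - min(vals)) if vals else 0.0


@dataclass
class IntensityResult:
    reference_layer: InitialCommunitiesLayer
    levels: list[IntensityLevelResult]


def sampling_intensity_experiment(
    fia_plots: list[PlotRecord],
    cse_plots: list[PlotRecord],
    landscape: Landscape,
    levels: list[int] | None = None,
    seed: int = 0,
    exceedance_threshold: float = 20.0,
) -> IntensityResult:
    """Rebuild the layer from nested halvings of the stand-exam plot pool.

    The reference uses all CSE plots plus the exact-coordinate plots.  Each
    level subsamples the PREVIOUS level's plots proportionally to forest-type
    area (so donor pools are nested and their AGC ranges shrink
    monotonically), and a final level uses the exact-coordinate plots alone.
    """
    if levels is None:
        levels = [len(cse_plots) // 2, len(cse_plots) // 4,
                  len(cse_plots) // 8, len(cse_plots) // 16]
    if any(lv > len(cse_plots) for lv in levels):
        raise ManifestError("a level exceeds the available plots")
    areas = landscape.type_areas_ha()

    reference_layer = build_layer(cse_plots + fia_plots, landscape)
    ref_grid = reference_layer.agc_grid()

    out_levels = []
    current = cse_plots
    for i, lv in enumerate(levels):
        subset = subsample_proportional(current, lv, areas,
                                        derive_seed(seed, "level", i))
        layer = build_layer(subset + fia_plots, landscape)
        comp = compare_layers(ref_grid, layer.agc_grid(), landscape,
                              exceedance_threshold)
        out_levels.append(IntensityLevelResult(label=str(lv), n_cse_plots=lv,
                                               layer=layer, comparison=comp,
                                               plots=subset + fia_plots))
        current = subset

    fia_layer = build_layer(fia_plots, landscape)
    comp = compare_layers(ref_grid, fia_layer.agc_grid(), landscape,
                          exceedance_threshold)
    out_levels.append(IntensityLevelResult(label="fia_only", n_cse_plots=0,
                                           layer=fia_layer, comparison=comp,
                                           plots=list(fia_plots)))
    return IntensityResult(reference_layer=reference_layer, levels=out_levels)


def halving_levels(n_plots: int, n_levels: int = 4) -> list[int]:
    """Successive halvings of a plot count (1072 -> 536, 268, 134, 67)."""
    out = []
    n = n_plots
    for _ in range(n_levels):
        n //= 2
        out.append(n)
    return out


# ---------------------------------------------------------------------------
# Per-cell significance testing


def percent_significant(
    agc_runs_a: np.ndarray,
    agc_runs_b: np.ndarray,
    mask: np.ndarray | None = None,
    interval_years: int = 10,
    alpha: float = 0.01,
    welch: bool = False,
    extra_years: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Percent of (forested) area with significantly different AGC.

    Inputs are (replicates, years, n_rows, n_cols) ensembles.  At every
    ``interval_years``-th year (plus ``extra_years``, 1-indexed) an
    independent two-sample t-test compares replicates cell by cell; cells
    where the statistic is undefined (zero variance both sides, or zero
    difference) count as not significant.
    """
    if agc_runs_a.ndim != 4 or agc_runs_b.ndim != 4:
        raise StatisticsError("expected (replicates, years, rows, cols) arrays")
    if agc_runs_a.shape[1:] != agc_runs_b.shape[1:]:
        raise StatisticsError("ensembles have mismatched grids or horizons")
    if agc_runs_a.shape[0] < 2 or agc_runs_b.shape[0] < 2:
        raise StatisticsError("need at least 2 replicates per side")
    years = agc_runs_a.shape[1]
    if mask is None:
        mask = np.ones(agc_runs_a.shape[2:], dtype=bool)
    sample_years = sorted(set(range(interval_years, years + 1, interval_years))
                          | {y for y in extra_years if 1 <= y <= years})
    rows = []
    for y in sample_years:
        A = agc_runs_a[:, y - 1][:, mask]
        B = agc_runs_b[:, y - 1][:, mask]
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            # cells with (near-)identical replicates yield an undefined
            # statistic; they are counted as not significant below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(A, B, axis=0, equal_var=not welch)
        sig = np.nan_to_num(res.pvalue, nan=1.0) < alpha
        rows.append({"year": y,
                     "percent_significant": 100.0 * sig.sum() / mask.sum()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NECB


@dataclass
class NecbSeries:
    necb: pd.Series  # Tg C per year
    cumulative: pd.Series
    relative_cumulative: pd.Series  # management - no-management, cumulative
    crossover_year: int | None


def necb(ledger_mgmt: FluxLedger, ledger_nomgmt: FluxLedger) -> NecbSeries:
    """NECB(t) = gain(t) - [wildfire(t) + thinning(t) + rx_burn(t)], with the
    management series relativized to no-management and the first recovery
    year (relative cumulative >= 0 after being < 0) reported as crossover."""
    a, b = ledger_mgmt.table, ledger_nomgmt.table
    if not a.index.equals(b.index):
        raise StatisticsError("ledgers cover different horizons")

    def series(df: pd.DataFrame) -> pd.Series:
        return (df["photosynthesis_gain"] - df["wildfire_loss"]
                - df["thinning_loss"] - df["rx_burn_loss"])

    n_m = series(a)
    n_n = series(b)
    cum_m = n_m.cumsum()
    cum_n = n_n.cumsum()
    rel = cum_m - cum_n
    crossover = None
    was_negative = False
    for year, v in rel.items():
        if v < 0:
            was_negative = True
        elif was_negative and v >= 0:
            crossover = int(year)
            break
    return NecbSeries(necb=n_m, cumulative=cum_m, relative_cumulative=rel,
                      crossover_year=crossover)


# ---------------------------------------------------------------------------
# Full campaign


@dataclass
class CampaignResult:
    landscape: Landscape
    fia_plots: list[PlotRecord]
    stands: StandTable
    cse_plots: list[PlotRecord]
    reference_layer: InitialCommunitiesLayer
    manifest: ExperimentManifest
    no_mgmt_runs: list[SimulationOutput] = field(default_factory=list)
    mgmt_runs: list[SimulationOutput] = field(default_factory=list)
    prob_no_mgmt: SeverityProbabilityMap | None = None
    prob_mgmt: SeverityProbabilityMap | None = None
    treatment_map: TreatmentMap | None = None
    necb_series: NecbSeries | None = None
    agc_diff_year_end: np.ndarray | None = None  # mgmt - no_mgmt, Mg C/ha


def _mean_ledger(runs: list[SimulationOutput]) -> FluxLedger:
    tables = [r.ledger.table for r in runs]
    mean = sum(tables[1:], tables[0].copy()) / len(tables)
    return FluxLedger(table=mean)


def landscape_config_from(config: CampaignConfig) -> LandscapeConfig:
    L = config.landscape
    return LandscapeConfig(
        n_rows=L.n_rows, n_cols=L.n_cols, cell_size=L.cell_size,
        elevation_range=(L.elevation_min, L.elevation_max),
        n_soils=L.n_soils, n_spectral=L.n_spectral,
        aspen_fraction=L.aspen_fraction,
        nonforest_fraction=L.nonforest_fraction,
        shrub_fraction=L.shrub_fraction,
        measurement_noise_sigma=L.measurement_noise_sigma,
    )


def simulator_config_from(config: CampaignConfig) -> SimulatorConfig:
    S = config.simulator
    return SimulatorConfig(
        growth_rate=S.growth_rate, mortality_fraction=S.mortality_fraction,
        ignition_rate=S.ignition_rate,
        fire_size_median_cells=S.fire_size_median_cells,
        fire_size_sigma=S.fire_size_sigma,
        high_severity_kill=S.high_severity_kill,
        thin_fraction=S.thin_fraction,
    )


def build_campaign_inputs(config: CampaignConfig, seed: int
                          ) -> tuple[Landscape, list[PlotRecord], StandTable,
                                     list[PlotRecord]]:
    """Generate the landscape and both inventory designs for a campaign."""
    lcfg = landscape_config_from(config)
    landscape = generate_landscape(lcfg, derive_seed(seed, "landscape"))
    fia = sample_fia_like_plots(landscape, config.plots.n_fia,
                                derive_seed(seed, "fia"),
                                noise_sigma=lcfg.measurement_noise_sigma)
    stands, cse = sample_cse_like_stands(
        landscape, config.plots.n_stands,
        (config.plots.plots_per_stand_min, config.plots.plots_per_stand_max),
        seed=derive_seed(seed, "cse"),
        noise_sigma=lcfg.measurement_noise_sigma,
    )
    return landscape, fia, stands, cse


def build_campaign_manifest(config: CampaignConfig, seed: int,
                            climates: list[ClimateForcing] | None = None
                            ) -> ExperimentManifest:
    """Schedule the paired no-management / management ensembles.

    Replicate seeds are PAIRED across scenarios (identical stochastic draws
    with and without treatment), so run identity is (scenario, seed)."""
    E = config.experiment
    if climates is None:
        climates = default_climates(E.years, E.n_climates)
    runs: list[RunSpec] = []
    for scenario in ("no_mgmt", "mgmt"):
        for climate in climates:
            for rep in range(1, E.replicates + 1):
                runs.append(RunSpec(
                    layer_id="reference", climate_id=climate.name,
                    scenario=scenario, replicate=rep,
                    seed=derive_seed(seed, "sim", climate.name, rep)))
    manifest = ExperimentManifest.__new__(ExperimentManifest)
    manifest.runs = runs
    keys = {(r.scenario, r.seed) for r in runs}
    if len(keys) != len(runs):
        raise ManifestError("duplicate run identity in manifest")
    return manifest


def run_campaign(config: CampaignConfig, seed: int,
                 climates: list[ClimateForcing] | None = None) -> CampaignResult:
    """Execute the management campaign end to end.

    No-management ensemble -> conditional high-severity probability map ->
    treatment zoning -> management ensemble with PAIRED per-run seeds ->
    post-treatment probability map, end-of-horizon AGC difference, and the
    relativized cumulative NECB series.
    """
    E = config.experiment
    sim_cfg = simulator_config_from(config)
    if climates is None:
        climates = default_climates(E.years, E.n_climates)
    landscape, fia, stands, cse = build_campaign_inputs(config, seed)

    ref_sel = select_one_plot_per_stand(stands, cse, derive_seed(seed, "reference"))
    reference_layer = build_layer(
        ref_sel + fia, landscape,
        select_covariates=config.imputation.select_covariates)

    manifest = build_campaign_manifest(config, seed, climates)
    runs = manifest.runs

    result = CampaignResult(landscape=landscape, fia_plots=fia, stands=stands,
                            cse_plots=cse, reference_layer=reference_layer,
                            manifest=manifest)

    no_mgmt = [r for r in runs if r.scenario == "no_mgmt"]
    climate_by_name = {c.name: c for c in climates}
    for r in no_mgmt:
        out = run_simulation(reference_layer, landscape,
                             climate_by_name[r.climate_id], None, E.years,
                             r.seed, sim_cfg)
        result.no_mgmt_runs.append(out)

    result.prob_no_mgmt = high_severity_probability(
        [o.severity for o in result.no_mgmt_runs])
    Z = config.zoning
    result.treatment_map = build_treatment_map(
        result.prob_no_mgmt, landscape.zones.slope, reference_layer,
        prob_threshold=Z.prob_threshold, slope_max_percent=Z.slope_max_percent,
        composition_min=Z.composition_min,
        codominance_threshold=Z.codominance_threshold,
        intervals=(Z.burn_interval_short, Z.burn_interval_long))

    plan = result.treatment_map.to_plan()
    for r in (r for r in runs if r.scenario == "mgmt"):
        out = run_simulation(reference_layer, landscape,
                             climate_by_name[r.climate_id], plan, E.years,
                             r.seed, sim_cfg)
        result.mgmt_runs.append(out)

    result.prob_mgmt = high_severity_probability(
        [o.severity for o in result.mgmt_runs])
    result.necb_series = necb(_mean_ledger(result.mgmt_runs),
                              _mean_ledger(result.no_mgmt_runs))
    end_m = np.mean(np.stack([o.agc[-1] for o in result.mgmt_runs]), axis=0)
    end_n = np.mean(np.stack([o.agc[-1] for o in result.no_mgmt_runs]), axis=0)
    result.agc_diff_year_end = end_m - end_n
    return result
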