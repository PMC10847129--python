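"""Cohort forest-growth / wildfire / treatment simulator with a closed
carbon ledger.

A deliberately simple yearly engine standing in for a full landscape
disturbance-and-succession model: logistic cohort growth toward an
ecoregion-specific carrying capacity scaled by a climate modifier,
background mortality feeding a surface-fuel pool, stochastic ignitions that
grow contiguous burn patches with sizes drawn from a lognormal, a 5-class
fire-severity scale that is a monotone function of fuel+biomass load and a
decadal fire-weather draw (classes 4-5 remove the overstory), plus
management: a one-time thin-from-below removing an exact biomass fraction
youngest cohorts first, and recurring prescribed burns on a fixed return
interval.  Every flux is booked so that the change in total aboveground
carbon equals gains minus losses to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import COVER_CODE, FOREST_TYPES, Cohort, Landscape
from .imputation import InitialCommunitiesLayer

MG_PER_TG = 1e6


class PlanError(ValueError):
    pass


@dataclass
class CellState:
    """Stand-alone cell state for the unit-level treatment operations."""

    cohorts: list[Cohort]
    surface_fuel: float = 0.0
    ecoregion: int = 1

    @property
    def total_agc(self) -> float:
        return float(sum(c.agc for c in self.cohorts))


@dataclass(frozen=True)
class ClimateForcing:
    """One named forcing series: a yearly growth modifier and decadal
    fire-weather lognormal parameters (median and sigma of the weather
    multiplier; the median steps once per decade)."""

    name: str
    growth_modifier: np.ndarray  # (years,), unitless > 0
    weather_median: np.ndarray  # (n_decades,)
    weather_sigma: float = 0.35

    def weather_params(self, year_index: int) -> tuple[float, float]:
        d = min(year_index // 10, len(self.weather_median) - 1)
        return float(self.weather_median[d]), self.weather_sigma


def default_climates(years: int = 50, n: int = 5) -> list[ClimateForcing]:
    """Five synthetic forcing series spanning cool-wet to hot-dry futures.

    Growth modifiers trend away from 1 over the horizon; fire-weather
    medians step up each decade, faster for the hotter-drier members.
    """
    trends = [0.10, 0.04, 0.00, -0.05, -0.10][:n]
    weather0 = [0.85, 0.95, 1.00, 1.10, 1.20][:n]
    weather_growth = [0.02, 0.04, 0.05, 0.07, 0.09][:n]
    names = [f"climate_{i+1}" for i in range(n)]
    t = np.arange(years) / max(years - 1, 1)
    n_dec = max(1, math.ceil(years / 10))
    out = []
    for name, a, w0, g in zip(names, trends, weather0, weather_growth):
        growth = 1.0 + a * t + 0.03 * np.sin(2 * np.pi * np.arange(years) / 10.0)
        med = w0 * (1.0 + g * np.arange(n_dec))
        out.append(ClimateForcing(name=name, growth_modifier=growth,
                                  weather_median=med))
    return out


@dataclass(frozen=True)
class SimulatorConfig:
    """All engine constants, with defaults emulating dense, fire-excluded
    southwestern conifer forest near carrying capacity."""

    growth_rate: float = 0.12  # logistic rate, 1/yr
    mortality_fraction: float = 0.008  # AGC -> surface fuel, 1/yr
    fuel_decomposition: float = 0.03  # surface-fuel decay, 1/yr (slow: dry climate)
    init_fuel_fraction: float = 0.25  # initial fuel = fraction x initial AGC
    shrub_fuel: float = 6.0  # Mg/ha on shrub cells
    #: carrying capacity (Mg C/ha) by elevation zone 1..3; soils scale it
    capacity_by_zone: tuple[float, float, float] = (45.0, 95.0, 130.0)
    capacity_soil_span: float = 0.15
    ignition_rate: float = 1.2  # Poisson mean ignitions / fire region / yr
    fire_size_median_cells: float = 40.0
    fire_size_sigma: float = 0.9
    #: surface fuel counts this many times its mass in the severity load
    #: (ladder/surface fuels, not standing biomass, drive severity)
    fuel_weight: float = 3.0
    #: thresholds on weather x (fuel_weight x surface_fuel + AGC), classes 1..5
    severity_thresholds: tuple[float, float, float, float] = (50.0, 90.0, 140.0, 200.0)
    high_severity_kill: float = 0.8  # fraction of cohort AGC emitted, classes 4-5
    high_severity_fuel_consumption: float = 0.9
    low_severity_agc_fraction: float = 0.03  # classes 1-3
    low_severity_fuel_consumption: float = 0.6
    rx_fuel_consumption: float = 0.8
    rx_agc_fraction: float = 0.02
    thin_fraction: float = 0.30


@dataclass
class FluxLedger:
    """Yearly landscape totals in Tg C.  ``fuel_consumed`` is the surface
    fuel burned by wildfire; it lives outside the AGC closure identity."""

    table: pd.DataFrame  # columns: year, photosynthesis_gain, wildfire_loss,
    #                      thinning_loss, rx_burn_loss, mortality_loss,
    #                      fuel_consumed

    @classmethod
    def empty(cls, years: int) -> "FluxLedger":
        cols = ["photosynthesis_gain", "wildfire_loss", "thinning_loss",
                "rx_burn_loss", "mortality_loss", "fuel_consumed"]
        df = pd.DataFrame(0.0, index=pd.RangeIndex(1, years + 1, name="year"),
                          columns=cols)
        return cls(table=df)

    def total_losses(self) -> pd.Series:
        return self.table[["wildfire_loss", "thinning_loss", "rx_burn_loss",
                           "mortality_loss"]].sum(axis=1)


@dataclass
class SimulationOutput:
    severity: np.ndarray  # (years, n_rows, n_cols), int8, 0 = no fire
    agc: np.ndarray  # (years, n_rows, n_cols), float32, Mg C/ha (year end)
    ledger: FluxLedger
    initial_agc_tg: float
    final_agc_tg: float


# ---------------------------------------------------------------------------
# Unit-level treatment operations


def apply_thinning(cell: CellState, fraction: float = 0.30) -> tuple[CellState, float]:
    """Thin from below: remove exactly ``fraction`` of the cell's AGC,
    taking whole cohorts in ascending age order and splitting the cohort
    that crosses the target."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    total = cell.total_agc
    if total <= 0:
        return CellState([Cohort(c.species_id, c.age, c.agc) for c in cell.cohorts],
                         cell.surface_fuel, cell.ecoregion), 0.0
    target = fraction * total
    order = sorted(range(len(cell.cohorts)),
                   key=lambda i: (cell.cohorts[i].age, i))
    removed = 0.0
    new = [Cohort(c.species_id, c.age, c.agc) for c in cell.cohorts]
    for i in order:
        if removed >= target - 1e-12:
            break
        take = min(new[i].agc, target - removed)
        new[i] = Cohort(new[i].species_id, new[i].age, new[i].agc - take)
        removed += take
    new = [c for c in new if c.agc > 1e-12]
    return CellState(new, cell.surface_fuel, cell.ecoregion), removed


def apply_prescribed_burn(cell: CellState,
                          config: SimulatorConfig = SimulatorConfig()
                          ) -> tuple[CellState, float]:
    """Low-intensity broadcast burn: consumes most surface fuel plus a small
    AGC fraction; never produces severity classes 4-5."""
    new_fuel = cell.surface_fuel * (1.0 - config.rx_fuel_consumption)
    removed = 0.0
    new = []
    for c in cell.cohorts:
        loss = c.agc * config.rx_agc_fraction
        removed += loss
        new.append(Cohort(c.species_id, c.age, c.agc - loss))
    return CellState(new, new_fuel, cell.ecoregion), removed


def severity_class(load: np.ndarray | float, weather: float,
                   config: SimulatorConfig = SimulatorConfig()) -> np.ndarray | int:
    """Discretize weather x load into severity classes 1-5 (burned cells).

    Monotone non-decreasing in ``load`` for fixed ``weather``."""
    score = np.asarray(load, dtype=float) * weather
    cls = 1 + np.searchsorted(np.asarray(config.severity_thresholds), score,
                              side="right")
    if np.isscalar(load):
        return int(cls)
    return cls.astype(np.int8)


# ---------------------------------------------------------------------------
# Engine


def _capacity_grid(landscape: Landscape, config: SimulatorConfig) -> np.ndarray:
    z = landscape.zones.elevation_zone
    soil = landscape.zones.soil
    base = np.asarray(config.capacity_by_zone)[z - 1]
    n_soils = int(soil.max())
    span = config.capacity_soil_span
    soil_factor = 1.0 + span * (2.0 * (soil - 1) / max(n_soils - 1, 1) - 1.0)
    return base * soil_factor


def _flatten_layer(layer: InitialCommunitiesLayer
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flat cohort arrays (cell_index, species, age, agc) from a layer."""
    cells, species, ages, agcs = [], [], [], []
    nr, nc = layer.grid_shape
    flat_code = layer.map_code.ravel()
    for idx in range(nr * nc):
        for c in layer.code_cohorts.get(int(flat_code[idx]), []):
            cells.append(idx)
            species.append(c.species_id)
            ages.append(c.age)
            agcs.append(c.agc)
    return (np.asarray(cells, dtype=np.int64), np.asarray(species, dtype=np.int16),
            np.asarray(ages, dtype=np.int32), np.asarray(agcs, dtype=float))


def _grow_patch(start: int, target: int, burnable: np.ndarray,
                burned: np.ndarray, shape: tuple[int, int],
                rng: np.random.Generator) -> list[int]:
    """Contiguous random patch growth (4-neighbour stochastic fill)."""
    nr, nc = shape
    patch = [start]
    in_patch = {start}
    frontier: list[int] = []

    def push_neighbors(i: int) -> None:
        r, c = divmod(i, nc)
        for (rr, cc) in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < nr and 0 <= cc < nc:
                j = rr * nc + cc
                if burnable[j] and not burned[j] and j not in in_patch:
                    frontier.append(j)

    push_neighbors(start)
    while len(patch) < target and frontier:
        k = int(rng.integers(len(frontier)))
        j = frontier.pop(k)
        if j in in_patch:
            continue
        patch.append(j)
        in_patch.add(j)
        push_neighbors(j)
    return patch


def run_simulation(
    layer: InitialCommunitiesLayer,
    landscape: Landscape,
    climate: ClimateForcing,
    plan: "TreatmentPlan | None",
    years: int,
    seed: int,
    config: SimulatorConfig = SimulatorConfig(),
) -> SimulationOutput:
    """Run one seeded simulation and return severity, AGC, and the ledger.

    Yearly order per the engine contract: growth, aging, mortality, fire,
    then management (thinning once in year 1, prescribed burns on each
    zone's return interval starting year 1).
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    nr, nc = landscape.grid.shape
    if layer.grid_shape != (nr, nc):
        raise PlanError("layer does not cover the landscape grid")
    n_cells = nr * nc
    rng = np.random.default_rng(seed)

    cell_idx, species, ages, agc = _flatten_layer(layer)
    K = _capacity_grid(landscape, config).ravel()
    flat_cover = landscape.forest_type.ravel()
    fire_region = landscape.zones.fire_region.ravel()

    surface_fuel = np.zeros(n_cells)
    init_total = np.bincount(cell_idx, weights=agc, minlength=n_cells)
    surface_fuel += config.init_fuel_fraction * init_total
    shrub = np.isin(flat_cover, [COVER_CODE["shrub_resprout"],
                                 COVER_CODE["shrub_nonresprout"]])
    surface_fuel[shrub] += config.shrub_fuel
    burnable = (flat_cover < len(FOREST_TYPES)) | shrub

    if plan is not None and plan.zone.shape != (nr, nc):
        raise PlanError("treatment plan grid does not match the landscape")

    cell_area_ha = landscape.grid.cell_area_ha
    to_tg = cell_area_ha / MG_PER_TG  # Mg/ha on 1 cell -> Tg

    ledger = FluxLedger.empty(years)
    led = ledger.table
    severity = np.zeros((years, n_cells), dtype=np.int8)
    agc_out = np.zeros((years, n_cells), dtype=np.float32)
    initial_agc_tg = float(init_total.sum() * to_tg)

    thin_cells = burn_cells = None
    burn_interval = None
    if plan is not None:
        zflat = plan.zone.ravel()
        thin_cells = np.nonzero(zflat == 2)[0]  # thin_and_burn
        burn_cells = np.nonzero(zflat >= 1)[0]  # burn_only or thin_and_burn
        burn_interval = plan.burn_interval.ravel()

    for t in range(years):
        mod = float(climate.growth_modifier[min(t, len(climate.growth_modifier) - 1)])

        # 1. growth (logistic on cell totals, distributed over cohorts)
        total = np.bincount(cell_idx, weights=agc, minlength=n_cells)
        inc = config.growth_rate * mod * total * (1.0 - total / K)
        np.maximum(inc, 0.0, out=inc)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(total > 0, inc / total, 0.0)
        agc *= 1.0 + factor[cell_idx]
        led.iloc[t, led.columns.get_loc("photosynthesis_gain")] += inc.sum() * to_tg

        # 2. aging
        ages += 1

        # 3. background mortality: AGC -> surface fuel
        dm = config.mortality_fraction * agc
        agc -= dm
        surface_fuel += np.bincount(cell_idx, weights=dm, minlength=n_cells)
        led.iloc[t, led.columns.get_loc("mortality_loss")] += dm.sum() * to_tg
        surface_fuel *= 1.0 - config.fuel_decomposition

        # 4. wildfire
        total = np.bincount(cell_idx, weights=agc, minlength=n_cells)
        burned_this_year = np.zeros(n_cells, dtype=bool)
        w_med, w_sig = climate.weather_params(t)
        for region in (1, 2, 3):
            rmask = (fire_region == region) & burnable
            candidates = np.nonzero(rmask & ~burned_this_year)[0]
            if len(candidates) == 0:
                continue
            n_ign = int(rng.poisson(config.ignition_rate))
            for _ in range(n_ign):
                candidates = np.nonzero(rmask & ~burned_this_year)[0]
                if len(candidates) == 0:
                    break
                start = int(candidates[rng.integers(len(candidates))])
                size = int(round(rng.lognormal(
                    math.log(config.fire_size_median_cells), config.fire_size_sigma)))
                size = max(1, size)
                patch = _grow_patch(start, size, burnable, burned_this_year,
                                    (nr, nc), rng)
                patch_arr = np.asarray(patch)
                weather = float(rng.lognormal(math.log(w_med), w_sig))
                load = (config.fuel_weight * surface_fuel[patch_arr]
                        + total[patch_arr])
                cls = severity_class(load, weather, config)
                severity[t, patch_arr] = cls
                burned_this_year[patch_arr] = True

        if burned_this_year.any():
            sev_t = severity[t]
            kill = np.zeros(n_cells)
            cons = np.zeros(n_cells)
            high = sev_t >= 4
            low = (sev_t >= 1) & (sev_t < 4)
            kill[high] = config.high_severity_kill
            kill[low] = config.low_severity_agc_fraction
            cons[high] = config.high_severity_fuel_consumption
            cons[low] = config.low_severity_fuel_consumption
            dfire = agc * kill[cell_idx]
            agc -= dfire
            led.iloc[t, led.columns.get_loc("wildfire_loss")] += dfire.sum() * to_tg
            consumed = surface_fuel * cons
            surface_fuel -= consumed
            led.iloc[t, led.columns.get_loc("fuel_consumed")] += consumed.sum() * to_tg

        # 5. management
        if plan is not None:
            if t == 0 and len(thin_cells) > 0:
                removed = _thin_cells_vectorized(cell_idx, ages, agc, thin_cells,
                                                 config.thin_fraction)
                led.iloc[t, led.columns.get_loc("thinning_loss")] += removed * to_tg
            due = burn_cells[(t % burn_interval[burn_cells]) == 0]
            if len(due) > 0:
                drx = agc * np.isin(cell_idx, due) * config.rx_agc_fraction
                agc -= drx
                led.iloc[t, led.columns.get_loc("rx_burn_loss")] += drx.sum() * to_tg
                surface_fuel[due] *= 1.0 - config.rx_fuel_consumption

        agc_out[t] = np.bincount(cell_idx, weights=agc,
                                 minlength=n_cells).astype(np.float32)

    final_total = np.bincount(cell_idx, weights=agc, minlength=n_cells)
    return SimulationOutput(
        severity=severity.reshape(years, nr, nc),
        agc=agc_out.reshape(years, nr, nc),
        ledger=ledger,
        initial_agc_tg=initial_agc_tg,
        final_agc_tg=float(final_total.sum() * to_tg),
    )


def _thin_cells_vectorized(cell_idx: np.ndarray, ages: np.ndarray,
                           agc: np.ndarray, cells: np.ndarray,
                           fraction: float) -> float:
    """In-place youngest-first thinning of the given cells; returns the total
    removed (Mg/ha summed over cells)."""
    cellset = np.zeros(int(cell_idx.max(initial=0)) + 1, dtype=bool)
    cellset[cells[cells < len(cellset)]] = True
    mask = cellset[cell_idx]
    idxs = np.nonzero(mask)[0]
    removed_total = 0.0
    # group cohort rows by cell
    order = idxs[np.lexsort((ages[idxs], cell_idx[idxs]))]
    i = 0
    while i < len(order):
        j = i
        cid = cell_idx[order[i]]
        while j < len(order) and cell_idx[order[j]] == cid:
            j += 1
        rows = order[i:j]  # this cell's cohorts, youngest first
        total = agc[rows].sum()
        target = fraction * total
        removed = 0.0
        for r in rows:
            if removed >= target - 1e-12:
                break
            take = min(agc[r], target - removed)
            agc[r] -= take
            removed += take
        removed_total += removed
        i = j
    return removed_total


@dataclass
class TreatmentPlan:
    """Per-cell treatment zoning used by the engine: zone 0 = none,
    1 = burn_only, 2 = thin_and_burn; ``burn_interval`` in years (ignored
    where zone is 0)."""

    zone: np.ndarray  # int8 (n_rows, n_cols)
    burn_interval: np.ndarray  # int16 (n_rows, n_cols)
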