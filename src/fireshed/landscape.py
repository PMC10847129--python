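"""Synthetic landscape, inventory-design, and covariate generation.

Produces seeded stand-ins for the data a fireshed-scale landscape simulation
consumes: a 100 m grid with elevation, aspect (and its TRASP heat-load
transform), spectral covariates, generalized forest types, ecoregions
(elevation zone x soil class) and fire regions (elevation zones), a ground
truth per-cell cohort surface, and two inventory designs layered on top of
it — a sparse landscape-wide plot network with exact coordinates (FIA-like)
and a dense, regionally clustered stand-exam set in which individual plots
carry only their stand's centroid coordinate (CSE-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

# ---------------------------------------------------------------------------
# Species / forest-type vocabulary

PINYON = 1
JUNIPER = 2
PONDEROSA = 3
DOUGLAS_FIR = 4
SPRUCE = 5
LIMBER_PINE = 6
ASPEN = 7
SHRUB_RESPROUT = 8
SHRUB_NONRESPROUT = 9

SPECIES_NAMES = {
    PINYON: "pinyon",
    JUNIPER: "juniper",
    PONDEROSA: "ponderosa",
    DOUGLAS_FIR: "douglas_fir",
    SPRUCE: "spruce",
    LIMBER_PINE: "limber_pine",
    ASPEN: "aspen",
    SHRUB_RESPROUT: "shrub_resprout",
    SHRUB_NONRESPROUT: "shrub_nonresprout",
}

#: Generalized forest categories, in the fixed tie-break order used by plot
#: classification, followed by the non-tree cover labels.
FOREST_TYPES = ("pinyon_juniper", "ponderosa", "mixed_conifer", "aspen")
COVER_LABELS = FOREST_TYPES + ("shrub_resprout", "shrub_nonresprout", "nonforest")

#: Integer codes for the cover map (0-based index into COVER_LABELS).
COVER_CODE = {name: i for i, name in enumerate(COVER_LABELS)}

#: Species membership of each generalized category.  Douglas-fir, spruce and
#: limber pine are grouped into a general mixed-conifer category.
TYPE_SPECIES = {
    "pinyon_juniper": (PINYON, JUNIPER),
    "ponderosa": (PONDEROSA,),
    "mixed_conifer": (DOUGLAS_FIR, SPRUCE, LIMBER_PINE),
    "aspen": (ASPEN,),
}

SPECIES_TO_TYPE = {
    sp: ftype for ftype, sps in TYPE_SPECIES.items() for sp in sps
}


class ConfigurationError(ValueError):
    """Raised for invalid landscape-generation configuration."""


class SamplingError(ValueError):
    """Raised when an inventory design cannot be drawn from the landscape."""


# ---------------------------------------------------------------------------
# Grid and layer containers


@dataclass(frozen=True)
class GridSpec:
    """Abstract planar grid; with the default 100 m cell each cell is 1 ha."""

    n_rows: int
    n_cols: int
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_ha(self) -> float:
        return (self.cell_size / 100.0) ** 2

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 + (row + 0.5) * self.cell_size)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        return (int((y - y0) // self.cell_size), int((x - x0) // self.cell_size))


@dataclass
class CovariateStack:
    """Continuous per-cell predictors shared by all imputation models."""

    elevation: np.ndarray  # m
    aspect: np.ndarray  # degrees [0, 360)
    trasp: np.ndarray  # unitless [0, 1]
    spectral: np.ndarray  # (k, n_rows, n_cols), unitless

    def as_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Return an (n_cells, p) covariate matrix and covariate names."""
        layers = [self.elevation.ravel(), self.trasp.ravel()]
        names = ["elevation", "trasp"]
        for k in range(self.spectral.shape[0]):
            layers.append(self.spectral[k].ravel())
            names.append(f"spectral_{k}")
        return np.column_stack(layers), names


@dataclass
class ZoneMaps:
    """Categorical strata: ecoregions, fire regions, and their factors."""

    ecoregion: np.ndarray  # 1..18
    fire_region: np.ndarray  # 1..3, equals elevation_zone
    soil: np.ndarray  # 1..6
    elevation_zone: np.ndarray  # 1..3
    slope: np.ndarray  # percent


@dataclass
class Cohort:
    species_id: int
    age: int
    agc: float  # Mg C / ha


@dataclass
class PlotRecord:
    plot_id: int
    x: float
    y: float
    source: str  # "fia_like" | "cse_like"
    cohorts: list[Cohort]
    forest_type: str
    stand_id: int | None = None

    @property
    def total_agc(self) -> float:
        return float(sum(c.agc for c in self.cohorts))


@dataclass
class StandTable:
    """Stand centroids and membership; provenance records which true cell
    each plot was measured on (used only by recovery tests)."""

    stand_ids: list[int]
    centroids: dict[int, tuple[float, float]]
    plot_ids: dict[int, list[int]]
    plot_cells: dict[int, tuple[int, int]] = field(default_factory=dict)


@dataclass
class Landscape:
    """Bundle of all generated layers (ground truth included)."""

    grid: GridSpec
    covariates: CovariateStack
    forest_type: np.ndarray  # integer cover codes, see COVER_CODE
    zones: ZoneMaps
    truth: list[list[Cohort]]  # per cell (row-major), [] for non-forest

    def cover_name(self, row: int, col: int) -> str:
        return COVER_LABELS[int(self.forest_type[row, col])]

    def forested_mask(self) -> np.ndarray:
        return self.forest_type < len(FOREST_TYPES)

    def truth_agc_grid(self) -> np.ndarray:
        agc = np.array([sum(c.agc for c in cell) for cell in self.truth])
        return agc.reshape(self.grid.shape)

    def type_areas_ha(self) -> dict[str, float]:
        """Area of each generalized forest type in hectares."""
        out = {}
        for ftype in FOREST_TYPES:
            n = int(np.sum(self.forest_type == COVER_CODE[ftype]))
            out[ftype] = n * self.grid.cell_area_ha
        return out


# ---------------------------------------------------------------------------
# Generation config


@dataclass(frozen=True)
class LandscapeConfig:
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 100.0
    elevation_range: tuple[float, float] = (1900.0, 3700.0)
    #: Elevation thresholds splitting the range into 3 zones (fractions of range).
    zone_breaks: tuple[float, float] = (0.33, 0.66)
    n_soils: int = 6
    n_spectral: int = 3
    #: Lognormal (median, sigma) of per-cell total AGC by forest type, Mg C/ha.
    agc_median: dict[str, float] = field(
        default_factory=lambda: {
            "pinyon_juniper": 25.0,
            "ponderosa": 65.0,
            "mixed_conifer": 95.0,
            "aspen": 55.0,
        }
    )
    agc_sigma: dict[str, float] = field(
        default_factory=lambda: {
            "pinyon_juniper": 0.55,
            "ponderosa": 0.40,
            "mixed_conifer": 0.40,
            "aspen": 0.50,
        }
    )
    #: Strength of the elevation effect on within-type AGC (fraction of the
    #: median per standardized elevation unit); makes elevation a genuinely
    #: informative covariate for imputation.
    agc_elevation_effect: float = 0.25
    nonforest_fraction: float = 0.12
    shrub_fraction: float = 0.08
    aspen_fraction: float = 0.03  # of forested area; rare and patchy
    spectral_noise: float = 0.3
    measurement_noise_sigma: float = 0.1  # lognormal sigma on cohort agc
    terrain_smooth_cells: float = 6.0


def compute_trasp(aspect: np.ndarray | float) -> np.ndarray | float:
    """Topographic Radiation Aspect Index: (1 - cos((aspect - 30) deg)) / 2.

    0 at the coolest aspect (30 deg, NNE) and 1 at the hottest (210 deg, SSW).
    """
    a = np.asarray(aspect, dtype=float)
    if np.any((a < 0) | (a >= 360)):
        raise ValueError("aspect must lie in [0, 360)")
    t = (1.0 - np.cos(np.radians(a - 30.0))) / 2.0
    if np.isscalar(aspect):
        return float(t)
    return t


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  smooth: float) -> np.ndarray:
    """Standardized spatially-correlated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), smooth, mode="nearest")
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def _slope_percent(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    # np.gradient uses central differences inside and one-sided at borders
    dzdy, dzdx = np.gradient(elevation, cell_size)
    return 100.0 * np.hypot(dzdx, dzdy)


def _aspect_degrees(elevation: np.ndarray, cell_size: float,
                    rng: np.random.Generator) -> np.ndarray:
    dzdy, dzdx = np.gradient(elevation, cell_size)
    # downslope direction; flat cells get a random aspect
    asp = np.degrees(np.arctan2(-dzdx, dzdy)) % 360.0
    flat = np.hypot(dzdx, dzdy) < 1e-12
    asp[flat] = rng.uniform(0.0, 360.0, size=int(flat.sum()))
    return asp


def _draw_cohorts(ftype: str, total_agc: float, elev_z: float,
                  rng: np.random.Generator, config: LandscapeConfig) -> list[Cohort]:
    """Split a cell's total AGC into 1-3 species-age cohorts of its type."""
    species_pool = TYPE_SPECIES[ftype]
    n = int(rng.integers(1, min(3, len(species_pool) + 1) + 1)) if len(species_pool) > 1 \
        else int(rng.integers(1, 3))
    n = max(1, min(n, 3))
    shares = rng.dirichlet(np.ones(n) * 2.0)
    age_lo, age_hi = {"pinyon_juniper": (40, 160), "ponderosa": (20, 140),
                      "mixed_conifer": (30, 180), "aspen": (10, 80)}[ftype]
    cohorts = []
    for s in shares:
        sp = int(rng.choice(species_pool))
        age = int(rng.integers(age_lo, age_hi + 1))
        cohorts.append(Cohort(sp, age, float(total_agc * s)))
    return cohorts


def generate_landscape(config: LandscapeConfig, seed: int) -> Landscape:
    """Generate a seeded synthetic landscape.

    Forest types follow elevation bands (pinyon-juniper low, ponderosa mid,
    mixed-conifer high) perturbed by a smooth noise field; aspen occurs as
    rare patches; shrub and non-forest cells carry no cohorts.  Ground-truth
    per-cell cohort lists are drawn from type-specific lognormal AGC
    distributions modulated by elevation, and the spectral covariates are
    noisy transforms of the true AGC (a stand-in for tasseled-cap bands).
    """
    lo, hi = config.elevation_range
    if hi <= lo:
        raise ConfigurationError("elevation_range must be increasing")
    if not (0 < config.zone_breaks[0] < config.zone_breaks[1] < 1):
        raise ConfigurationError("zone_breaks must be increasing fractions in (0,1)")
    grid = GridSpec(config.n_rows, config.n_cols, config.cell_size)
    rng = np.random.default_rng(seed)
    shape = grid.shape

    # --- terrain: a broad ramp rising to the north (row 0) plus correlated
    # relief; the northern uplands carry the mixed-conifer and ponderosa
    # belts, the southern lowlands the pinyon-juniper woodland
    rows = np.linspace(1.0, 0.0, config.n_rows)[:, None]
    ramp = np.broadcast_to(rows, shape)
    relief = _smooth_field(shape, rng, config.terrain_smooth_cells)
    raw = 0.75 * ramp + 0.25 * (relief - relief.min()) / max(np.ptp(relief), 1e-9)
    elevation = lo + (hi - lo) * (raw - raw.min()) / max(np.ptp(raw), 1e-9)
    slope = _slope_percent(elevation, grid.cell_size)
    aspect = _aspect_degrees(elevation, grid.cell_size, rng)
    trasp = np.asarray(compute_trasp(aspect))

    # --- zones
    b1 = lo + config.zone_breaks[0] * (hi - lo)
    b2 = lo + config.zone_breaks[1] * (hi - lo)
    elevation_zone = np.digitize(elevation, [b1, b2]) + 1  # 1..3
    soil_field = _smooth_field(shape, rng, config.terrain_smooth_cells * 1.5)
    soil_edges = np.quantile(soil_field, np.linspace(0, 1, config.n_soils + 1)[1:-1])
    soil = np.digitize(soil_field, soil_edges) + 1  # 1..n_soils
    ecoregion = (elevation_zone - 1) * config.n_soils + soil  # 1..3*n_soils
    fire_region = elevation_zone.copy()
    zones = ZoneMaps(ecoregion=ecoregion, fire_region=fire_region, soil=soil,
                     elevation_zone=elevation_zone, slope=slope)

    # --- cover types
    jitter = _smooth_field(shape, rng, config.terrain_smooth_cells / 2.0)
    band_val = (elevation - lo) / (hi - lo) + 0.08 * jitter
    cover = np.full(shape, COVER_CODE["pinyon_juniper"], dtype=np.int8)
    cover[band_val >= config.zone_breaks[0]] = COVER_CODE["ponderosa"]
    cover[band_val >= config.zone_breaks[1]] = COVER_CODE["mixed_conifer"]

    # non-forest and shrub from an independent smooth field
    open_field = _smooth_field(shape, rng, config.terrain_smooth_cells / 2.0)
    q_nf = np.quantile(open_field, 1.0 - config.nonforest_fraction)
    q_sh = np.quantile(open_field, 1.0 - config.nonforest_fraction - config.shrub_fraction)
    shrub_mask = (open_field >= q_sh) & (open_field < q_nf)
    shrub_kind = _smooth_field(shape, rng, 2.0) > 0
    cover[shrub_mask & shrub_kind] = COVER_CODE["shrub_resprout"]
    cover[shrub_mask & ~shrub_kind] = COVER_CODE["shrub_nonresprout"]
    cover[open_field >= q_nf] = COVER_CODE["nonforest"]

    # aspen: small patches in the mid/high elevations
    forested = cover < len(FOREST_TYPES)
    n_aspen = int(round(config.aspen_fraction * forested.sum()))
    if n_aspen > 0:
        eligible = forested & (elevation_zone >= 2)
        er, ec = np.nonzero(eligible)
        placed = 0
        while placed < n_aspen and len(er) > 0:
            i = rng.integers(len(er))
            r0, c0 = int(er[i]), int(ec[i])
            patch = int(rng.integers(3, 13))
            rr = slice(max(0, r0 - 1), min(config.n_rows, r0 + 2))
            cc = slice(max(0, c0 - patch // 3 - 1), min(config.n_cols, c0 + patch // 3 + 2))
            block = eligible[rr, cc]
            cover[rr, cc][block] = COVER_CODE["aspen"]
            placed += int(block.sum())
            eligible = forested & (elevation_zone >= 2) & (cover != COVER_CODE["aspen"])
            er, ec = np.nonzero(eligible)

    # --- ground-truth cohorts
    elev_std = (elevation - elevation.mean()) / max(elevation.std(), 1e-9)
    truth: list[list[Cohort]] = []
    flat_cover = cover.ravel()
    flat_elev_z = elev_std.ravel()
    for idx in range(grid.n_cells):
        code = int(flat_cover[idx])
        if code >= len(FOREST_TYPES):
            truth.append([])
            continue
        ftype = FOREST_TYPES[code]
        med = config.agc_median[ftype]
        med_cell = med * max(0.1, 1.0 + config.agc_elevation_effect * flat_elev_z[idx])
        total = float(rng.lognormal(math.log(med_cell), config.agc_sigma[ftype]))
        truth.append(_draw_cohorts(ftype, total, flat_elev_z[idx], rng, config))

    # --- spectral bands: noisy transforms of true AGC (tasseled-cap stand-in)
    agc_grid = np.array([sum(c.agc for c in cell) for cell in truth]).reshape(shape)
    agc_n = (agc_grid - agc_grid.mean()) / max(agc_grid.std(), 1e-9)
    bands = []
    for k in range(config.n_spectral):
        w = [0.9, -0.6, 0.4][k % 3]
        band = w * agc_n + config.spectral_noise * rng.standard_normal(shape)
        bands.append(band)
    spectral = np.stack(bands)

    covs = CovariateStack(elevation=elevation, aspect=aspect, trasp=trasp,
                          spectral=spectral)
    return Landscape(grid=grid, covariates=covs, forest_type=cover, zones=zones,
                     truth=truth)


# ---------------------------------------------------------------------------
# Inventory designs


def _noisy_copy(cohorts: list[Cohort], sigma: float,
                rng: np.random.Generator) -> list[Cohort]:
    if sigma <= 0:
        return [replace(c) for c in cohorts]
    return [replace(c, agc=float(c.agc * rng.lognormal(0.0, sigma)))
            for c in cohorts]


def _plot_type(cohorts: list[Cohort]) -> str:
    totals = {f: 0.0 for f in FOREST_TYPES}
    for c in cohorts:
        totals[SPECIES_TO_TYPE[c.species_id]] += c.agc
    # plurality with the fixed category order as tie-break
    return max(FOREST_TYPES, key=lambda f: (totals[f], -FOREST_TYPES.index(f)))


def sample_fia_like_plots(landscape: Landscape, n: int, seed: int,
                          noise_sigma: float | None = None) -> list[PlotRecord]:
    """Draw n plots at exact cell coordinates, quasi-uniformly spread.

    The grid is partitioned into roughly n blocks and one forested cell is
    drawn per block (remaining plots fall back to a simple random draw), so
    the network spans the whole landscape like a national inventory grid.
    """
    if n < 1:
        raise SamplingError("n must be >= 1")
    cfg_sigma = noise_sigma
    if cfg_sigma is None:
        cfg_sigma = 0.1
    rng = np.random.default_rng(seed)
    forested = landscape.forested_mask()
    fr, fc = np.nonzero(forested)
    if n > len(fr):
        raise SamplingError(f"requested {n} plots but only {len(fr)} forested cells")

    m = max(1, int(math.ceil(math.sqrt(n))))
    row_edges = np.linspace(0, landscape.grid.n_rows, m + 1)
    col_edges = np.linspace(0, landscape.grid.n_cols, m + 1)
    blocks = [(i, j) for i in range(m) for j in range(m)]
    rng.shuffle(blocks)
    chosen: list[tuple[int, int]] = []
    used = set()
    for (i, j) in blocks:
        if len(chosen) >= n:
            break
        in_block = ((fr >= row_edges[i]) & (fr < row_edges[i + 1])
                    & (fc >= col_edges[j]) & (fc < col_edges[j + 1]))
        idxs = np.nonzero(in_block)[0]
        idxs = [k for k in idxs if (fr[k], fc[k]) not in used]
        if idxs:
            k = idxs[int(rng.integers(len(idxs)))]
            chosen.append((int(fr[k]), int(fc[k])))
            used.add((int(fr[k]), int(fc[k])))
    while len(chosen) < n:
        k = int(rng.integers(len(fr)))
        cell = (int(fr[k]), int(fc[k]))
        if cell not in used:
            chosen.append(cell)
            used.add(cell)

    plots = []
    for pid, (r, c) in enumerate(chosen, start=1):
        cohorts = _noisy_copy(landscape.truth[r * landscape.grid.n_cols + c],
                              cfg_sigma, rng)
        x, y = landscape.grid.cell_center(r, c)
        plots.append(PlotRecord(plot_id=pid, x=x, y=y, source="fia_like",
                                cohorts=cohorts, forest_type=_plot_type(cohorts)))
    return plots


def sample_cse_like_stands(
    landscape: Landscape,
    n_stands: int,
    plots_per_stand_range: tuple[int, int] = (3, 31),
    region_bias: tuple[int, int, int, int] | None = None,
    seed: int = 0,
    noise_sigma: float = 0.1,
    stand_radius_cells: int = 3,
    plot_id_start: int = 10_000,
) -> tuple[StandTable, list[PlotRecord]]:
    """Draw stand-exam-like stands inside a biased sub-rectangle.

    Stands sit mostly on ponderosa / mixed-conifer cells; each stand holds a
    uniform number of plots in ``plots_per_stand_range``, measured on cells
    within ``stand_radius_cells`` of the centroid, but every plot carries the
    stand centroid as its coordinate (the georeferencing limitation the
    uncertainty analysis studies).  ``region_bias`` is (row0, row1, col0,
    col1); default is the northern half of the grid.
    """
    lopp, hipp = plots_per_stand_range
    if not (3 <= lopp <= hipp <= 31):
        raise SamplingError("plots_per_stand_range must lie within [3, 31]")
    rng = np.random.default_rng(seed)
    nr, nc = landscape.grid.shape
    if region_bias is None:
        region_bias = (0, max(1, nr // 2), 0, nc)
    r0, r1, c0, c1 = region_bias

    forested = landscape.forested_mask()
    preferred = np.isin(landscape.forest_type,
                        [COVER_CODE["ponderosa"], COVER_CODE["mixed_conifer"]])
    region = np.zeros_like(forested)
    region[r0:r1, c0:c1] = True
    elig_pref = np.nonzero(region & preferred)
    elig_any = np.nonzero(region & forested)
    if len(elig_any[0]) == 0:
        raise SamplingError("biased region contains no forested cells")

    centroid_cells: list[tuple[int, int]] = []
    used = set()
    attempts = 0
    while len(centroid_cells) < n_stands:
        attempts += 1
        if attempts > 50 * n_stands:
            raise SamplingError("could not place the requested number of stands")
        pool = elig_pref if (rng.random() < 0.9 and len(elig_pref[0]) > 0) else elig_any
        k = int(rng.integers(len(pool[0])))
        cell = (int(pool[0][k]), int(pool[1][k]))
        if cell in used:
            continue
        used.add(cell)
        centroid_cells.append(cell)

    stand_ids = list(range(1, n_stands + 1))
    centroids: dict[int, tuple[float, float]] = {}
    plot_ids: dict[int, list[int]] = {}
    plot_cells: dict[int, tuple[int, int]] = {}
    plots: list[PlotRecord] = []
    pid = plot_id_start
    for sid, (cr, cc) in zip(stand_ids, centroid_cells):
        cx, cy = landscape.grid.cell_center(cr, cc)
        centroids[sid] = (cx, cy)
        n_plots = int(rng.integers(lopp, hipp + 1))
        # candidate measurement cells: forested cells within the stand radius
        rr0, rr1 = max(0, cr - stand_radius_cells), min(nr, cr + stand_radius_cells + 1)
        cc0, cc1 = max(0, cc - stand_radius_cells), min(nc, cc + stand_radius_cells + 1)
        cand = [(r, c) for r in range(rr0, rr1) for c in range(cc0, cc1)
                if forested[r, c]]
        if not cand:
            cand = [(cr, cc)]
        ids = []
        for _ in range(n_plots):
            pid += 1
            r, c = cand[int(rng.integers(len(cand)))]
            cohorts = _noisy_copy(landscape.truth[r * nc + c], noise_sigma, rng)
            if not cohorts:  # forested-by-mask but empty cohort list cannot occur;
                cohorts = _noisy_copy(landscape.truth[cr * nc + cc], noise_sigma, rng)
            plots.append(PlotRecord(plot_id=pid, x=cx, y=cy, source="cse_like",
                                    cohorts=cohorts,
                                    forest_type=_plot_type(cohorts),
                                    stand_id=sid))
            plot_cells[pid] = (r, c)
            ids.append(pid)
        plot_ids[sid] = ids

    table = StandTable(stand_ids=stand_ids, centroids=centroids,
                       plot_ids=plot_ids, plot_cells=plot_cells)
    return table, plots
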