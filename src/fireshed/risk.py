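"""High-severity fire probability and optimized treatment placement.

The conditional probability of high-severity fire is, per cell, the number
of replicate-years that burned at severity 4-5 divided by the number of
replicate-years that burned at all (pooled across an ensemble of
no-management runs).  Treatment zoning then follows three eligibility
rules: probability above a threshold (default 0.3), stand composition at
least 65% ponderosa + Douglas-fir carbon, and mechanical thinning only on
slopes below 30%; prescribed-burn return interval is 10 years for
ponderosa-dominated cells and 15 years where Douglas-fir co-dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import DOUGLAS_FIR, PONDEROSA, Landscape
from .imputation import InitialCommunitiesLayer
from .simulator import TreatmentPlan

ZONE_NONE, ZONE_BURN_ONLY, ZONE_THIN_AND_BURN = 0, 1, 2
ZONE_NAMES = {ZONE_NONE: "none", ZONE_BURN_ONLY: "burn_only",
              ZONE_THIN_AND_BURN: "thin_and_burn"}


class ShapeError(ValueError):
    pass


@dataclass
class SeverityProbabilityMap:
    """Per-cell conditional probability; NaN where no fire was observed."""

    prob: np.ndarray  # float, NaN = undefined
    fire_years: np.ndarray  # denominator (replicate-years with fire)
    high_years: np.ndarray  # numerator

    @property
    def defined(self) -> np.ndarray:
        return self.fire_years >= 1


@dataclass
class TreatmentMap:
    zone: np.ndarray  # int8, ZONE_* codes
    burn_interval: np.ndarray  # int16, years; 0 where zone is none

    def to_plan(self) -> TreatmentPlan:
        return TreatmentPlan(zone=self.zone, burn_interval=self.burn_interval)

    def zone_areas_ha(self, cell_area_ha: float = 1.0) -> dict[str, float]:
        return {name: float(np.sum(self.zone == code) * cell_area_ha)
                for code, name in ZONE_NAMES.items()}


def high_severity_probability(stacks: list[np.ndarray],
                              high_threshold: int = 4,
                              per_replicate_mean: bool = False
                              ) -> SeverityProbabilityMap:
    """Pool severity stacks (years, n_rows, n_cols; 0 = no fire) into a
    conditional high-severity probability map.

    With ``per_replicate_mean`` the per-replicate probabilities are averaged
    over replicates where defined, instead of pooling all replicate-years
    into one numerator/denominator (the default, which matches the statistic
    as worded).
    """
    if not stacks:
        raise ShapeError("at least one severity stack required")
    shape = stacks[0].shape[1:]
    for s in stacks:
        if s.shape[1:] != shape:
            raise ShapeError("severity stacks have mismatched grids")
    if per_replicate_mean:
        probs = []
        fire_tot = np.zeros(shape)
        high_tot = np.zeros(shape)
        for s in stacks:
            fire = (s >= 1).sum(axis=0)
            high = (s >= high_threshold).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                probs.append(np.where(fire >= 1, high / fire, np.nan))
            fire_tot += fire
            high_tot += high
        prob = np.nanmean(np.stack(probs), axis=0)
        return SeverityProbabilityMap(prob=prob, fire_years=fire_tot,
                                      high_years=high_tot)
    fire = np.zeros(shape)
    high = np.zeros(shape)
    for s in stacks:
        fire += (s >= 1).sum(axis=0)
        high += (s >= high_threshold).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(fire >= 1, high / fire, np.nan)
    return SeverityProbabilityMap(prob=prob, fire_years=fire, high_years=high)


def _composition_grids(layer: InitialCommunitiesLayer
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell (total agc, ponderosa agc, douglas-fir agc) from the layer."""
    max_code = max(layer.code_cohorts, default=0)
    tot = np.zeros(max_code + 1)
    pond = np.zeros(max_code + 1)
    doug = np.zeros(max_code + 1)
    for code, cohorts in layer.code_cohorts.items():
        for c in cohorts:
            tot[code] += c.agc
            if c.species_id == PONDEROSA:
                pond[code] += c.agc
            elif c.species_id == DOUGLAS_FIR:
                doug[code] += c.agc
    mc = layer.map_code
    return tot[mc], pond[mc], doug[mc]


def build_treatment_map(
    prob: SeverityProbabilityMap,
    slope: np.ndarray,
    layer: InitialCommunitiesLayer,
    prob_threshold: float = 0.3,
    slope_max_percent: float = 30.0,
    composition_min: float = 0.65,
    codominance_threshold: float = 0.2,
    intervals: tuple[int, int] = (10, 15),
) -> TreatmentMap:
    """Apply the eligibility rules to zone the landscape for treatment.

    Eligible cells have a defined probability above ``prob_threshold`` and
    ponderosa+Douglas-fir at least ``composition_min`` of total AGC (on the
    initial layer).  Eligible cells below the slope limit are zoned
    thin_and_burn, the rest burn_only.  The return interval is the shorter
    one where Douglas-fir holds less than ``codominance_threshold`` of the
    pair's carbon (ponderosa-dominated), the longer one where co-dominated.
    Cells with undefined probability are never treated.
    """
    if slope is None:
        raise ValueError("slope layer required")
    if slope.shape != prob.prob.shape or layer.map_code.shape != slope.shape:
        raise ShapeError("probability, slope and layer grids must match")
    tot, pond, doug = _composition_grids(layer)
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_share = np.where(tot > 0, (pond + doug) / tot, 0.0)
        doug_share = np.where(pond + doug > 0, doug / (pond + doug), 0.0)
    eligible = (prob.defined & (np.nan_to_num(prob.prob) > prob_threshold)
                & (pair_share >= composition_min))
    zone = np.zeros(slope.shape, dtype=np.int8)
    zone[eligible & (slope < slope_max_percent)] = ZONE_THIN_AND_BURN
    zone[eligible & (slope >= slope_max_percent)] = ZONE_BURN_ONLY
    interval = np.zeros(slope.shape, dtype=np.int16)
    short, long = intervals
    interval[(zone > 0) & (doug_share < codominance_threshold)] = short
    interval[(zone > 0) & (doug_share >= codominance_threshold)] = long
    return TreatmentMap(zone=zone, burn_interval=interval)


def treatment_transition(map_a: TreatmentMap, map_b: TreatmentMap,
                         cell_area_ha: float = 1.0
                         ) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Cross-tabulate two treatment maps.

    Returns (table of hectares with map_a zones as rows and map_b zones as
    columns, per-cell transition-category grid encoded 3*a+b, net change in
    thinned area in hectares: b minus a).
    """
    if map_a.zone.shape != map_b.zone.shape:
        raise ShapeError("treatment maps have mismatched grids")
    names = [ZONE_NAMES[z] for z in (ZONE_NONE, ZONE_BURN_ONLY, ZONE_THIN_AND_BURN)]
    table = pd.DataFrame(0.0, index=names, columns=names)
    grid = (3 * map_a.zone + map_b.zone).astype(np.int8)
    for a in range(3):
        for b in range(3):
            n = int(np.sum((map_a.zone == a) & (map_b.zone == b)))
            table.iloc[a, b] = n * cell_area_ha
    thin_a = float(np.sum(map_a.zone == ZONE_THIN_AND_BURN) * cell_area_ha)
    thin_b = float(np.sum(map_b.zone == ZONE_THIN_AND_BURN) * cell_area_ha)
    return table, grid, thin_b - thin_a
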