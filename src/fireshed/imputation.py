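"""Donor-based imputation of initial vegetation from inventory plots.

Each forested grid cell receives the full cohort record of its most similar
measured plot (nearest neighbour in a standardized covariate space, within
the cell's generalized forest-type stratum).  An optional greedy backward
covariate elimination mimics per-type parsimonious model selection by
minimizing leave-one-out donor-prediction error on plot aboveground carbon.
Also implements plot classification, plot sampling-intensity accounting, and
the two subsampling schemes used by the uncertainty experiments (one plot
per stand; proportional-to-area subsampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .landscape import (
    COVER_CODE,
    FOREST_TYPES,
    SPECIES_TO_TYPE,
    Cohort,
    Landscape,
    PlotRecord,
    StandTable,
)


class ClassificationError(ValueError):
    pass


class ImputationError(ValueError):
    pass


def classify_plot(plot: PlotRecord) -> str:
    """Generalized forest category holding the plurality of plot AGC.

    Douglas-fir, spruce-like, and limber-pine-like species are grouped into
    mixed-conifer.  Exact ties go to the category earlier in the fixed order
    (pinyon_juniper, ponderosa, mixed_conifer, aspen).
    """
    if not plot.cohorts:
        raise ClassificationError(f"plot {plot.plot_id} has no cohorts")
    totals = dict.fromkeys(FOREST_TYPES, 0.0)
    for c in plot.cohorts:
        totals[SPECIES_TO_TYPE[c.species_id]] += c.agc
    best = FOREST_TYPES[0]
    for f in FOREST_TYPES:
        if totals[f] > totals[best]:
            best = f
    return best


@dataclass
class SamplingIntensityTable:
    """Hectares of its forest type each plot represents (type area / plots)."""

    per_plot: dict[int, tuple[str, float]]  # plot_id -> (forest_type, ha)
    uncovered_types: list[str]  # types with area > 0 but no plots

    def represented_area(self, plot_id: int) -> float:
        return self.per_plot[plot_id][1]


def compute_sampling_intensity(plots: list[PlotRecord],
                               landscape: Landscape) -> SamplingIntensityTable:
    areas = landscape.type_areas_ha()
    by_type: dict[str, list[int]] = {f: [] for f in FOREST_TYPES}
    for p in plots:
        by_type[classify_plot(p)].append(p.plot_id)
    per_plot = {}
    uncovered = []
    for f in FOREST_TYPES:
        if areas[f] > 0 and not by_type[f]:
            uncovered.append(f)
            continue
        if not by_type[f]:
            continue
        share = areas[f] / len(by_type[f])
        for pid in by_type[f]:
            per_plot[pid] = (f, share)
    return SamplingIntensityTable(per_plot=per_plot, uncovered_types=uncovered)


# ---------------------------------------------------------------------------
# Imputation model


@dataclass
class TypeModel:
    donors: list[PlotRecord]  # sorted by plot_id (tie-break order)
    covariate_names: list[str]  # selected subset
    center: np.ndarray  # per selected covariate, over the type's cells
    scale: np.ndarray
    donor_features: np.ndarray  # (n_donors, n_selected), standardized


@dataclass
class ImputationModel:
    per_type: dict[str, TypeModel]
    all_covariates: list[str]


def _plot_cell_features(plots: list[PlotRecord], landscape: Landscape,
                        cov_matrix: np.ndarray) -> np.ndarray:
    """Covariates read at each plot's recorded coordinate (stand centroid for
    CSE-like plots — the georeferencing limitation enters here)."""
    rows = []
    nc = landscape.grid.n_cols
    for p in plots:
        r, c = landscape.grid.cell_of(p.x, p.y)
        rows.append(cov_matrix[r * nc + c])
    return np.asarray(rows)


def _loo_error(features: np.ndarray, agc: np.ndarray, cols: list[int]) -> float:
    """Leave-one-out 1-NN prediction RMSE of plot AGC in the given columns."""
    X = features[:, cols]
    n = len(X)
    if n < 2:
        return 0.0
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    nearest = np.argmin(d2, axis=1)  # first minimum = smallest plot_id (sorted)
    return float(np.sqrt(np.mean((agc - agc[nearest]) ** 2)))


def fit_imputation(plots: list[PlotRecord], landscape: Landscape,
                   select_covariates: bool = False) -> ImputationModel:
    """Fit per-forest-type nearest-donor models.

    Covariates are standardized over each type's landscape cells.  With
    ``select_covariates`` a greedy backward elimination drops covariates as
    long as the leave-one-out donor-prediction RMSE of plot AGC does not
    increase, keeping at least one covariate.  A type with a single donor
    keeps all covariates (the model is constant anyway).
    """
    cov_matrix, names = landscape.covariates.as_matrix()
    flat_type = landscape.forest_type.ravel()

    by_type: dict[str, list[PlotRecord]] = {f: [] for f in FOREST_TYPES}
    for p in plots:
        by_type[classify_plot(p)].append(p)

    per_type: dict[str, TypeModel] = {}
    for f in FOREST_TYPES:
        donors = sorted(by_type[f], key=lambda p: p.plot_id)
        if not donors:
            continue
        cells = np.nonzero(flat_type == COVER_CODE[f])[0]
        if len(cells) == 0:
            continue
        center = cov_matrix[cells].mean(axis=0)
        scale = cov_matrix[cells].std(axis=0)
        scale[scale == 0] = 1.0
        feats = (_plot_cell_features(donors, landscape, cov_matrix) - center) / scale

        cols = list(range(len(names)))
        if select_covariates and len(donors) > 1:
            agc = np.array([p.total_agc for p in donors])
            best_err = _loo_error(feats, agc, cols)
            improved = True
            while improved and len(cols) > 1:
                improved = False
                trial_errs = []
                for j in cols:
                    reduced = [c for c in cols if c != j]
                    trial_errs.append((_loo_error(feats, agc, reduced), j))
                err, drop = min(trial_errs)  # deterministic: ties on err -> smaller j
                if err <= best_err + 1e-12:
                    cols = [c for c in cols if c != drop]
                    best_err = err
                    improved = True
        per_type[f] = TypeModel(
            donors=donors,
            covariate_names=[names[c] for c in cols],
            center=center[cols],
            scale=scale[cols],
            donor_features=feats[:, cols],
        )
    return ImputationModel(per_type=per_type, all_covariates=names)


@dataclass
class InitialCommunitiesLayer:
    """Per-cell donor assignment and materialized cohorts.

    ``donor_id`` is -1 for cells without a donor (non-forest, shrub, or an
    uncovered forest type); ``map_code`` is 0 there.  Cells sharing a
    map_code hold identical cohort lists.
    """

    grid_shape: tuple[int, int]
    donor_id: np.ndarray  # int, (n_rows, n_cols)
    map_code: np.ndarray  # int, (n_rows, n_cols); 0 = no vegetation
    code_cohorts: dict[int, list[Cohort]]
    uncovered_types: list[str] = field(default_factory=list)

    def cohorts_at(self, row: int, col: int) -> list[Cohort]:
        return self.code_cohorts.get(int(self.map_code[row, col]), [])

    def agc_grid(self) -> np.ndarray:
        totals = {code: sum(c.agc for c in chs)
                  for code, chs in self.code_cohorts.items()}
        totals[0] = 0.0
        lut = np.zeros(max(totals) + 1)
        for code, v in totals.items():
            lut[code] = v
        return lut[self.map_code]


def _cohort_key(cohorts: list[Cohort]) -> tuple:
    return tuple(sorted((c.species_id, c.age, round(c.agc, 9)) for c in cohorts))


def impute_layer(model: ImputationModel, landscape: Landscape) -> InitialCommunitiesLayer:
    """Assign every forested cell its nearest donor within its type stratum.

    Distance is Euclidean in the model's standardized, selected covariate
    space; ties go to the donor with the smallest plot_id.  Forested cells of
    a type with no donors are left uncovered and reported on the layer.
    """
    cov_matrix, names = landscape.covariates.as_matrix()
    nr, nc = landscape.grid.shape
    donor_id = np.full(nr * nc, -1, dtype=np.int64)
    flat_type = landscape.forest_type.ravel()

    donors_by_id: dict[int, PlotRecord] = {}
    uncovered: list[str] = []
    for f in FOREST_TYPES:
        cells = np.nonzero(flat_type == COVER_CODE[f])[0]
        if len(cells) == 0:
            continue
        tm = model.per_type.get(f)
        if tm is None:
            uncovered.append(f)
            continue
        cols = [names.index(n) for n in tm.covariate_names]
        X = (cov_matrix[np.ix_(cells, cols)] - tm.center) / tm.scale
        # chunked distances keep memory bounded with thousands of donors;
        # argmin returns the first minimum and donors are sorted by plot_id,
        # so ties resolve to the smallest plot_id
        nearest = np.empty(len(cells), dtype=np.int64)
        chunk = max(1, 2_000_000 // max(len(tm.donors), 1))
        for lo in range(0, len(cells), chunk):
            d2 = cdist(X[lo:lo + chunk], tm.donor_features, "sqeuclidean")
            nearest[lo:lo + chunk] = np.argmin(np.round(d2, 12), axis=1)
        for p in tm.donors:
            donors_by_id[p.plot_id] = p
        donor_id[cells] = np.array([tm.donors[k].plot_id for k in nearest])

    # materialize map codes: one integer per distinct cohort list
    code_of_key: dict[tuple, int] = {}
    code_cohorts: dict[int, list[Cohort]] = {}
    donor_code: dict[int, int] = {}
    next_code = 1
    for pid in sorted(donors_by_id):
        key = _cohort_key(donors_by_id[pid].cohorts)
        if key not in code_of_key:
            code_of_key[key] = next_code
            code_cohorts[next_code] = [Cohort(c.species_id, c.age, c.agc)
                                       for c in donors_by_id[pid].cohorts]
            next_code += 1
        donor_code[pid] = code_of_key[key]

    map_code = np.zeros(nr * nc, dtype=np.int32)
    for i in np.nonzero(donor_id >= 0)[0]:
        map_code[i] = donor_code[int(donor_id[i])]

    return InitialCommunitiesLayer(
        grid_shape=(nr, nc),
        donor_id=donor_id.reshape(nr, nc),
        map_code=map_code.reshape(nr, nc),
        code_cohorts=code_cohorts,
        uncovered_types=uncovered,
    )


def build_layer(plots: list[PlotRecord], landscape: Landscape,
                select_covariates: bool = False) -> InitialCommunitiesLayer:
    """Convenience: fit and impute in one step."""
    return impute_layer(fit_imputation(plots, landscape, select_covariates),
                        landscape)


# ---------------------------------------------------------------------------
# Plot-selection schemes


def select_one_plot_per_stand(stands: StandTable, plots: list[PlotRecord],
                              seed: int) -> list[PlotRecord]:
    """Uniformly pick one plot to represent each stand (stand plots share a
    centroid coordinate, so only one can enter an imputation)."""
    rng = np.random.default_rng(seed)
    by_id = {p.plot_id: p for p in plots}
    out = []
    for sid in stands.stand_ids:
        ids = stands.plot_ids[sid]
        if not ids:
            raise ImputationError(f"stand {sid} has no plots")
        out.append(by_id[ids[int(rng.integers(len(ids)))]])
    return out


def subsample_proportional(plots: list[PlotRecord], target_total: int,
                           forest_type_areas: dict[str, float],
                           seed: int) -> list[PlotRecord]:
    """Subsample plots with per-type quotas proportional to landscape area.

    Quotas are largest-remainder rounded so they sum to ``target_total``;
    every type present among the plots gets at least one (relaxed with a
    warning if ``target_total`` is smaller than the number of present types),
    and no quota exceeds that type's available plots (excess redistributed by
    largest remainder).
    """
    if target_total > len(plots):
        raise ImputationError("target_total exceeds available plots")
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[PlotRecord]] = {}
    for p in plots:
        by_type.setdefault(classify_plot(p), []).append(p)
    present = sorted(by_type, key=FOREST_TYPES.index)
    total_area = sum(max(forest_type_areas.get(f, 0.0), 0.0) for f in present)
    if total_area <= 0:
        shares = {f: 1.0 / len(present) for f in present}
    else:
        shares = {f: max(forest_type_areas.get(f, 0.0), 0.0) / total_area
                  for f in present}

    import warnings

    floor = 1
    if target_total < len(present):
        warnings.warn("target_total below number of present forest types; "
                      "minimum-one-plot floor relaxed", stacklevel=2)
        floor = 0

    # proportional apportionment: types whose availability binds are capped
    # and the remainder re-allocated proportionally among the rest, then
    # largest-remainder rounding under the (floor, availability) constraints
    avail = {f: len(by_type[f]) for f in present}
    quota: dict[str, int] = {}
    remaining = list(present)
    target_rem = target_total
    while True:
        share_sum = sum(shares[f] for f in remaining)
        raw = {f: target_rem * shares[f] / share_sum if share_sum > 0
               else target_rem / len(remaining) for f in remaining}
        capped = [f for f in remaining if raw[f] >= avail[f]]
        if not capped:
            break
        for f in capped:
            quota[f] = avail[f]
            target_rem -= avail[f]
            remaining.remove(f)
        if not remaining:
            if target_rem > 0:
                raise ImputationError("cannot reach target_total: no plots left")
            break
    if remaining:
        base = {f: min(avail[f], max(floor, int(raw[f]))) for f in remaining}
        while sum(base.values()) < target_rem:
            cand = [f for f in remaining if base[f] < avail[f]]
            if not cand:
                raise ImputationError("cannot reach target_total: no plots left")
            f = max(cand, key=lambda f: (raw[f] - base[f], -FOREST_TYPES.index(f)))
            base[f] += 1
        while sum(base.values()) > target_rem:
            cand = [f for f in remaining if base[f] > floor] or \
                   [f for f in remaining if base[f] > 0]
            f = min(cand, key=lambda f: (raw[f] - base[f], FOREST_TYPES.index(f)))
            base[f] -= 1
        quota.update(base)

    out: list[PlotRecord] = []
    for f in present:
        pool = sorted(by_type[f], key=lambda p: p.plot_id)
        take = quota[f]
        if take >= len(pool):
            out.extend(pool)
        elif take > 0:
            idx = rng.choice(len(pool), size=take, replace=False)
            out.extend(pool[i] for i in sorted(idx))
    return sorted(out, key=lambda p: p.plot_id)
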