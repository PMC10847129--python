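"""Plot classification, sampling intensity, donor imputation, subsampling."""

import numpy as np
import pytest

import fireshed as fs
from fireshed.imputation import (
    ClassificationError,
    ImputationError,
    classify_plot,
    compute_sampling_intensity,
    fit_imputation,
    subsample_proportional,
)
from fireshed.landscape import (
    ASPEN,
    COVER_CODE,
    DOUGLAS_FIR,
    FOREST_TYPES,
    PINYON,
    PONDEROSA,
    Cohort,
    PlotRecord,
)


def plot_of(plot_id, *cohorts, x=50.0, y=50.0):
    return PlotRecord(plot_id=plot_id, x=x, y=y, source="fia_like",
                      cohorts=[Cohort(*c) for c in cohorts],
                      forest_type="ponderosa")


class TestClassifyPlot:
    def test_pure_ponderosa(self):
        assert classify_plot(plot_of(1, (PONDEROSA, 50, 30.0))) == "ponderosa"

    def test_plurality_groups_douglas_fir_into_mixed_conifer(self):
        p = plot_of(1, (DOUGLAS_FIR, 80, 60.0), (PONDEROSA, 60, 40.0))
        assert classify_plot(p) == "mixed_conifer"

    def test_exact_tie_takes_earlier_category(self):
        p = plot_of(1, (PINYON, 90, 50.0), (PONDEROSA, 50, 50.0))
        assert classify_plot(p) == "pinyon_juniper"

    def test_empty_plot_rejected(self):
        with pytest.raises(ClassificationError):
            classify_plot(PlotRecord(1, 0, 0, "fia_like", [], "ponderosa"))


class TestSamplingIntensity:
    def test_equal_shares_within_type(self, small_landscape, inventory):
        fia, _, cse = inventory
        table = compute_sampling_intensity(fia + cse, small_landscape)
        areas = small_landscape.type_areas_ha()
        by_type = {}
        for pid, (ftype, area) in table.per_plot.items():
            by_type.setdefault(ftype, []).append(area)
        for ftype, shares in by_type.items():
            assert len(set(shares)) == 1  # equal within type
            assert sum(shares) == pytest.approx(areas[ftype])

    def test_single_plot_represents_whole_type_area(self, small_landscape):
        p = fs.sample_fia_like_plots(small_landscape, 1, seed=0)
        (only,) = p
        table = compute_sampling_intensity(p, small_landscape)
        ftype = classify_plot(only)
        assert table.represented_area(only.plot_id) == pytest.approx(
            small_landscape.type_areas_ha()[ftype])

    def test_unplotted_type_reported_uncovered(self, small_landscape):
        p = [pl for pl in fs.sample_fia_like_plots(small_landscape, 30, seed=0)
             if classify_plot(pl) == "ponderosa"]
        table = compute_sampling_intensity(p, small_landscape)
        assert "mixed_conifer" in table.uncovered_types


class TestImputation:
    def test_donor_closure(self, small_landscape, reference_layer):
        donor_lists = {tuple((c.species_id, c.age, round(c.agc, 9)) for c in chs)
                       for chs in reference_layer.code_cohorts.values()}
        nr, nc = reference_layer.grid_shape
        for r in range(nr):
            for c in range(nc):
                chs = reference_layer.cohorts_at(r, c)
                if chs:
                    key = tuple((x.species_id, x.age, round(x.agc, 9)) for x in chs)
                    assert key in donor_lists

    def test_stratum_respect(self, small_landscape, reference_layer, inventory):
        fia, stands, cse = inventory
        sel = fs.select_one_plot_per_stand(stands, cse, seed=3)
        by_id = {p.plot_id: p for p in sel + fia}
        L = small_landscape
        covered = reference_layer.donor_id >= 0
        for r, c in zip(*np.nonzero(covered)):
            donor = by_id[int(reference_layer.donor_id[r, c])]
            assert classify_plot(donor) == L.cover_name(r, c)

    def test_self_imputation_identity(self):
        L = fs.generate_landscape(fs.LandscapeConfig(n_rows=20, n_cols=20), 11)
        forested = L.forested_mask()
        n = int(forested.sum())
        plots = fs.sample_fia_like_plots(L, n, seed=2, noise_sigma=0.0)
        layer = fs.build_layer(plots, L)
        nc = L.grid.n_cols
        for r, c in zip(*np.nonzero(forested)):
            assert layer.cohorts_at(r, c) == L.truth[r * nc + c]
        assert np.allclose(layer.agc_grid(), L.truth_agc_grid())

    def test_single_donor_gives_one_map_code(self, small_landscape):
        plots = fs.sample_fia_like_plots(small_landscape, 60, seed=1)
        by_type = {}
        for p in plots:
            by_type.setdefault(classify_plot(p), []).append(p)
        singles = [min(ps, key=lambda p: p.plot_id) for ps in by_type.values()]
        layer = fs.build_layer(singles, small_landscape)
        for ftype, ps in by_type.items():
            cells = small_landscape.forest_type == COVER_CODE[ftype]
            codes = np.unique(layer.map_code[cells])
            assert len(codes) == 1

    def test_uncovered_type_reported(self, small_landscape):
        plots = [p for p in fs.sample_fia_like_plots(small_landscape, 40, seed=1)
                 if classify_plot(p) == "ponderosa"]
        layer = fs.build_layer(plots, small_landscape)
        assert "mixed_conifer" in layer.uncovered_types
        mc_cells = small_landscape.forest_type == COVER_CODE["mixed_conifer"]
        assert np.all(layer.donor_id[mc_cells] == -1)

    def test_order_independence(self, small_landscape):
        plots = fs.sample_fia_like_plots(small_landscape, 30, seed=4)
        a = fs.build_layer(plots, small_landscape)
        b = fs.build_layer(list(reversed(plots)), small_landscape)
        assert np.array_equal(a.donor_id, b.donor_id)

    def test_identical_plots_both_retained_with_zero_loo_error(self, small_landscape):
        from fireshed.imputation import _loo_error

        feats = np.array([[0.0, 1.0], [2.0, 3.0]])
        agc = np.array([10.0, 10.0])
        assert _loo_error(feats, agc, [0, 1]) == 0.0

    def test_covariate_elimination_finds_elevation(self):
        """AGC depends on elevation by construction; elimination should keep
        it in >= 19 of 20 seeded replicates."""
        hits = 0
        for s in range(20):
            L = fs.generate_landscape(
                fs.LandscapeConfig(n_rows=30, n_cols=30, spectral_noise=5.0,
                                   agc_elevation_effect=0.5), s)
            plots = fs.sample_fia_like_plots(L, 30, seed=s + 100, noise_sigma=0.0)
            model = fit_imputation(plots, L, select_covariates=True)
            kept = set()
            for tm in model.per_type.values():
                kept |= set(tm.covariate_names)
            hits += "elevation" in kept
        assert hits >= 19

    def test_shrinking_donor_range(self, small_landscape):
        """Nested donor subsets: with many cells per donor, the imputed AGC
        range never grows as donors are removed."""
        L = small_landscape
        plots = fs.sample_fia_like_plots(L, 30, seed=13)
        full = fs.build_layer(plots, L)
        mask = full.donor_id >= 0
        rng_full = np.ptp(full.agc_grid()[mask])
        keep = sorted(plots, key=lambda p: p.plot_id)[::2]
        sub = fs.build_layer(keep, L)
        sub_mask = sub.donor_id >= 0
        assert np.ptp(sub.agc_grid()[sub_mask]) <= rng_full + 1e-9


class TestSelectOnePlotPerStand:
    def test_one_per_stand(self, inventory):
        _, stands, cse = inventory
        sel = fs.select_one_plot_per_stand(stands, cse, seed=0)
        assert len(sel) == len(stands.stand_ids)
        assert len({p.stand_id for p in sel}) == len(stands.stand_ids)

    def test_singleton_stand_always_selected(self, small_landscape):
        stands, plots = fs.sample_cse_like_stands(
            small_landscape, 4, plots_per_stand_range=(3, 3), seed=1)
        stands.plot_ids[1] = stands.plot_ids[1][:1]
        for s in range(5):
            sel = fs.select_one_plot_per_stand(stands, plots, seed=s)
            chosen = next(p for p in sel if p.stand_id == 1)
            assert chosen.plot_id == stands.plot_ids[1][0]

    def test_different_seeds_differ(self, inventory):
        _, stands, cse = inventory
        diffs = 0
        for s in range(100):
            a = fs.select_one_plot_per_stand(stands, cse, seed=2 * s)
            b = fs.select_one_plot_per_stand(stands, cse, seed=2 * s + 1)
            diffs += [p.plot_id for p in a] != [p.plot_id for p in b]
        assert diffs > 0


class TestSubsampleProportional:
    def test_exact_proportions(self):
        A = [plot_of(i, (PONDEROSA, 50, 10.0)) for i in range(1, 9)]
        B = [plot_of(i, (PINYON, 50, 10.0)) for i in range(9, 11)]
        sub = subsample_proportional(A + B, 5,
                                     {"ponderosa": 800.0, "pinyon_juniper": 200.0},
                                     seed=0)
        n_a = sum(1 for p in sub if classify_plot(p) == "ponderosa")
        n_b = sum(1 for p in sub if classify_plot(p) == "pinyon_juniper")
        assert (n_a, n_b) == (4, 1)

    def test_identity_subset(self, inventory):
        _, _, cse = inventory
        areas = {f: 100.0 for f in FOREST_TYPES}
        sub = subsample_proportional(cse, len(cse), areas, seed=0)
        assert sorted(p.plot_id for p in sub) == sorted(p.plot_id for p in cse)

    def test_halving_series(self):
        assert fs.halving_levels(1072) == [536, 268, 134, 67]

    def test_quota_sums_to_target(self, small_landscape, inventory):
        _, _, cse = inventory
        areas = small_landscape.type_areas_ha()
        for target in (len(cse) // 2, len(cse) // 4, 7):
            sub = subsample_proportional(cse, target, areas, seed=5)
            assert len(sub) == target

    def test_each_present_type_keeps_at_least_one(self, small_landscape, inventory):
        _, _, cse = inventory
        present = {classify_plot(p) for p in cse}
        sub = subsample_proportional(cse, len(present) + 2,
                                     small_landscape.type_areas_ha(), seed=1)
        assert {classify_plot(p) for p in sub} == present

    def test_floor_relaxed_with_warning(self):
        A = [plot_of(i, (PONDEROSA, 50, 10.0)) for i in range(1, 4)]
        B = [plot_of(i, (PINYON, 50, 10.0)) for i in range(4, 7)]
        with pytest.warns(UserWarning):
            sub = subsample_proportional(A + B, 1,
                                         {"ponderosa": 900.0,
                                          "pinyon_juniper": 100.0}, seed=0)
        assert len(sub) == 1

    def test_target_above_available_rejected(self):
        A = [plot_of(i, (PONDEROSA, 50, 10.0)) for i in range(1, 4)]
        with pytest.raises(ImputationError):
            subsample_proportional(A, 4, {"ponderosa": 100.0}, seed=0)
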