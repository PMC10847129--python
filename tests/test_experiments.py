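"""Uncertainty experiments, significance statistic, NECB, campaign wiring."""

import numpy as np
import pandas as pd
import pytest

import fireshed as fs
from fireshed.experiments import (
    ManifestError,
    StatisticsError,
    derive_seed,
    necb,
    percent_significant,
    sampling_intensity_experiment,
    within_stand_experiment,
)
from fireshed.simulator import FluxLedger


def ledger_from(gains, wildfire=None, thinning=None, rx=None):
    years = len(gains)
    led = FluxLedger.empty(years)
    led.table["photosynthesis_gain"] = gains
    if wildfire is not None:
        led.table["wildfire_loss"] = wildfire
    if thinning is not None:
        led.table["thinning_loss"] = thinning
    if rx is not None:
        led.table["rx_burn_loss"] = rx
    return led


class TestDeriveSeed:
    def test_deterministic_and_bounded(self):
        a = derive_seed(1, "sim", "climate_1", 3)
        assert a == derive_seed(1, "sim", "climate_1", 3)
        assert 0 <= a < 2**31

    def test_distinct_identities_distinct_seeds(self):
        seeds = {derive_seed(1, "sim", c, r)
                 for c in ("a", "b") for r in range(50)}
        assert len(seeds) == 100


class TestWithinStandExperiment:
    def test_manifest_counts(self, small_landscape, inventory, climates):
        fia, stands, cse = inventory
        res = within_stand_experiment(stands, cse, fia, small_landscape,
                                      climates, seed=5)
        n_max = max(len(stands.plot_ids[s]) for s in stands.stand_ids)
        assert len(res.layers) == n_max
        assert res.manifest.n_runs == n_max * len(climates)

    def test_two_climate_product(self, small_landscape, inventory, climates):
        fia, stands, cse = inventory
        res = within_stand_experiment(stands, cse, fia, small_landscape,
                                      climates[:2], seed=5)
        n_max = max(len(stands.plot_ids[s]) for s in stands.stand_ids)
        assert res.manifest.n_runs == n_max * 2

    def test_degenerate_identical_stand_plots(self, small_landscape, climates):
        """If every stand's plots are identical, every layer coincides and
        the difference grid is zero."""
        stands, cse = fs.sample_cse_like_stands(small_landscape, 8, seed=3,
                                                noise_sigma=0.0)
        by_id = {p.plot_id: p for p in cse}
        for sid in stands.stand_ids:
            first = by_id[stands.plot_ids[sid][0]]
            for pid in stands.plot_ids[sid]:
                by_id[pid].cohorts = [fs.Cohort(c.species_id, c.age, c.agc)
                                      for c in first.cohorts]
        fia = fs.sample_fia_like_plots(small_landscape, 10, seed=4)
        res = within_stand_experiment(stands, list(by_id.values()), fia,
                                      small_landscape, climates[:2], seed=5)
        assert np.allclose(res.comparison.difference, 0.0)
        assert res.comparison.exceedance_area_ha == 0.0

    def test_empty_stands_rejected(self, small_landscape, inventory, climates):
        fia, _, cse = inventory
        empty = fs.StandTable(stand_ids=[], centroids={}, plot_ids={})
        with pytest.raises(ManifestError):
            within_stand_experiment(empty, cse, fia, small_landscape,
                                    climates, seed=1)


class TestSamplingIntensityExperiment:
    def test_reference_vs_itself_is_zero(self, small_landscape, inventory):
        fia, _, cse = inventory
        res = sampling_intensity_experiment(fia, cse, small_landscape,
                                            levels=[len(cse)], seed=1)
        assert np.allclose(res.levels[0].comparison.difference, 0.0)

    def test_level_exceeding_pool_rejected(self, small_landscape, inventory):
        fia, _, cse = inventory
        with pytest.raises(ManifestError):
            sampling_intensity_experiment(fia, cse, small_landscape,
                                          levels=[len(cse) + 1], seed=1)

    def test_levels_are_nested_halvings_with_fia_floor(self, small_landscape,
                                                       inventory):
        fia, _, cse = inventory
        res = sampling_intensity_experiment(fia, cse, small_landscape, seed=2)
        labels = [lvl.n_cse_plots for lvl in res.levels]
        assert labels[-1] == 0  # exact-coordinate plots only
        assert all(a > b for a, b in zip(labels[:-1], labels[1:-1]))

    def test_rare_type_variability_bounded_by_shrinking_donor_pool(self):
        """Donor closure at every level: the rare type's imputed AGC values
        are a subset of its donor pool, so the number of distinct values is
        bounded by the (nested, shrinking) donor count and the imputed span
        by the pool span."""
        from fireshed.imputation import classify_plot

        for s in range(5):
            L = fs.generate_landscape(
                fs.LandscapeConfig(n_rows=50, n_cols=50, aspen_fraction=0.05), s)
            fia = fs.sample_fia_like_plots(L, 25, seed=s + 50)
            _, cse = fs.sample_cse_like_stands(L, 40, seed=s + 90)
            res = sampling_intensity_experiment(fia, cse, L, seed=s)
            donor_counts = []
            for lvl in res.levels:
                n_donors = sum(1 for p in lvl.plots
                               if classify_plot(p) == "aspen")
                donor_counts.append(n_donors)
                vals = lvl.comparison.by_forest_type["aspen"]
                vals = vals[vals > 0]
                assert len(np.unique(np.round(vals, 9))) <= max(n_donors, 1)
                if len(vals):
                    assert np.ptp(vals) <= lvl.donor_agc_range("aspen") + 1e-9
            assert all(a >= b for a, b in zip(donor_counts, donor_counts[1:]))


class TestPercentSignificant:
    def test_identical_data_not_significant(self):
        a = np.ones((3, 10, 5, 5))
        df = percent_significant(a, a.copy())
        assert (df.percent_significant == 0).all()

    def test_extreme_effect_full_power(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (25, 10, 10, 10))
        b = rng.normal(10, 1, (25, 10, 10, 10))
        df = percent_significant(a, b)
        assert df.percent_significant.iloc[0] >= 99.0

    def test_null_calibration(self):
        """Type-I rate under a true null stays inside the central 99%
        binomial band around the nominal 1%."""
        from scipy import stats

        counts = 0
        n_cells, n_seeds = 400, 20
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            a = rng.normal(50, 5, (25, 10, 20, 20))
            b = rng.normal(50, 5, (25, 10, 20, 20))
            df = percent_significant(a, b, interval_years=10, alpha=0.01)
            counts += df.percent_significant.iloc[0] * n_cells / 100
        lo, hi = stats.binom.ppf([0.005, 0.995], n_cells * n_seeds, 0.01)
        assert lo <= counts <= hi

    def test_sampled_years_every_decade(self):
        a = np.random.default_rng(1).normal(size=(3, 50, 4, 4))
        df = percent_significant(a, a + 0.0, interval_years=10,
                                 extra_years=(1,))
        assert df.year.tolist() == [1, 10, 20, 30, 40, 50]

    def test_too_few_replicates_rejected(self):
        a = np.ones((1, 10, 4, 4))
        with pytest.raises(StatisticsError):
            percent_significant(a, a)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(StatisticsError):
            percent_significant(np.ones((3, 10, 4, 4)), np.ones((3, 10, 5, 5)))


class TestNecb:
    def test_crossover_arithmetic(self):
        m = ledger_from([10.0, 10.0], wildfire=[15.0, 3.0])
        n = ledger_from([0.0, 0.0])
        s = necb(m, n)
        assert s.cumulative.tolist() == [-5.0, 2.0]
        assert s.crossover_year == 2

    def test_identical_ledgers_no_crossover(self):
        m = ledger_from([5.0, 6.0], wildfire=[1.0, 2.0])
        s = necb(m, ledger_from([5.0, 6.0], wildfire=[1.0, 2.0]))
        assert (s.relative_cumulative == 0).all()
        assert s.crossover_year is None

    def test_equal_gains_no_losses_relative_zero(self):
        m = ledger_from([4.0, 4.0, 4.0])
        s = necb(m, ledger_from([4.0, 4.0, 4.0]))
        assert (s.relative_cumulative == 0).all()

    def test_mortality_excluded_from_necb(self):
        m = ledger_from([10.0])
        m.table["mortality_loss"] = 7.0
        s = necb(m, ledger_from([0.0]))
        assert s.necb.iloc[0] == 10.0

    def test_horizon_mismatch_rejected(self):
        with pytest.raises(StatisticsError):
            necb(ledger_from([1.0]), ledger_from([1.0, 2.0]))


@pytest.fixture(scope="module")
def tiny_campaign():
    cfg = fs.validate_config(data={
        "landscape": {"n_rows": 30, "n_cols": 30},
        "plots": {"n_fia": 15, "n_stands": 10},
        "experiment": {"replicates": 2, "n_climates": 2, "years": 10},
    })
    return fs.run_campaign(cfg, seed=5), cfg


class TestCampaign:
    def test_manifest_arithmetic(self, tiny_campaign):
        res, cfg = tiny_campaign
        expect = cfg.experiment.replicates * cfg.experiment.n_climates * 2
        assert res.manifest.n_runs == expect
        assert res.manifest.simulation_years(cfg.experiment.years) == \
            expect * cfg.experiment.years

    def test_paired_seeds_across_scenarios(self, tiny_campaign):
        res, _ = tiny_campaign
        no = {(r.climate_id, r.replicate): r.seed
              for r in res.manifest.runs if r.scenario == "no_mgmt"}
        mg = {(r.climate_id, r.replicate): r.seed
              for r in res.manifest.runs if r.scenario == "mgmt"}
        assert no == mg

    def test_reduced_rerun_is_bit_identical(self):
        cfg = fs.validate_config(data={
            "landscape": {"n_rows": 25, "n_cols": 25},
            "plots": {"n_fia": 10, "n_stands": 8},
            "experiment": {"replicates": 1, "n_climates": 1, "years": 5},
        })
        a = fs.run_campaign(cfg, seed=9)
        b = fs.run_campaign(cfg, seed=9)
        assert np.array_equal(a.no_mgmt_runs[0].severity,
                              b.no_mgmt_runs[0].severity)
        assert np.array_equal(a.treatment_map.zone, b.treatment_map.zone)
        assert a.necb_series.relative_cumulative.equals(
            b.necb_series.relative_cumulative)

    def test_outputs_present(self, tiny_campaign):
        res, _ = tiny_campaign
        assert res.prob_no_mgmt is not None and res.prob_mgmt is not None
        assert res.treatment_map is not None
        assert res.agc_diff_year_end.shape == res.landscape.grid.shape
        assert len(res.necb_series.relative_cumulative) == 10
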