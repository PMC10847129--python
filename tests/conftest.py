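import numpy as np
import pytest

import fireshed as fs


@pytest.fixture(scope="session")
def small_landscape():
    """40x40 landscape shared by read-only tests."""
    return fs.generate_landscape(fs.LandscapeConfig(n_rows=40, n_cols=40), seed=42)


@pytest.fixture(scope="session")
def inventory(small_landscape):
    fia = fs.sample_fia_like_plots(small_landscape, 25, seed=1)
    stands, cse = fs.sample_cse_like_stands(small_landscape, 20, seed=2)
    return fia, stands, cse


@pytest.fixture(scope="session")
def reference_layer(small_landscape, inventory):
    fia, stands, cse = inventory
    sel = fs.select_one_plot_per_stand(stands, cse, seed=3)
    return fs.build_layer(sel + fia, small_landscape)


@pytest.fixture(scope="session")
def climates():
    return fs.default_climates(years=20)


def make_plot(plot_id, cohorts, x=50.0, y=50.0, source="fia_like", stand_id=None):
    """Hand-built plot; forest_type left to the classifier where relevant."""
    chs = [fs.Cohort(sp, age, agc) for sp, age, agc in cohorts]
    ftype = "ponderosa"
    return fs.PlotRecord(plot_id=plot_id, x=x, y=y, source=source,
                         cohorts=chs, forest_type=ftype, stand_id=stand_id)
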