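"""Small shared builders for hand-constructed fixtures."""

import numpy as np

from fireshed.imputation import InitialCommunitiesLayer


def single_cell_layer(cohorts):
    """A 1x1 initial-communities layer holding the given cohort list."""
    code_cohorts = {1: list(cohorts)} if cohorts else {}
    map_code = np.array([[1 if cohorts else 0]], dtype=np.int32)
    donor = np.array([[1 if cohorts else -1]], dtype=np.int64)
    return InitialCommunitiesLayer(grid_shape=(1, 1), donor_id=donor,
                                   map_code=map_code, code_cohorts=code_cohorts)
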