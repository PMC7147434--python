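import warnings

import pytest

from ednahalo import puget_sound_design, simulate_study

CONTROL_TAXA = ("control_kangaroo", "control_ostrich")


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic survey shared across tests (read-only)."""
    params = puget_sound_design(n_asvs_per_phylum=3, read_depth_mean=3000, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truth = simulate_study(params)
    return table, truth
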