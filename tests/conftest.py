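import numpy as np
import pandas as pd
import pytest

from rnamosaic.lineage import default_tree
from rnamosaic.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_individuals=6, n_tissues=14, n_genes=24,
                     n_background_sites=600)


@pytest.fixture(scope="session")
def noise_free_cohort(small_config):
    return simulate_cohort(small_config.noise_free())


@pytest.fixture(scope="session")
def noisy_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def labeled_calls():
    from rnamosaic.simdata import simulate_labeled_calls

    return simulate_labeled_calls(SimConfig(seed=3), n_true=600, n_false=600)


def make_observation(alt_fwd=0, alt_rev=0, ref_fwd=10, ref_rev=10,
                     ref="C", alt="T", pos=1000, bq=37, **kw):
    from rnamosaic.error_model import SiteObservation

    n_alt = alt_fwd + alt_rev
    return SiteObservation(
        chrom="chr1", pos=pos, ref=ref, alt=alt,
        ref_fwd=ref_fwd, ref_rev=ref_rev, alt_fwd=alt_fwd, alt_rev=alt_rev,
        alt_bq=[bq] * n_alt, **kw,
    )


@pytest.fixture
def obs_factory():
    return make_observation
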