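import numpy as np
import pandas as pd
import pytest

from mirbayes import (
    CohortSpec,
    CtTable,
    PanelSpec,
    default_enriched_set,
    simulate_cohort,
    simulate_panels,
)


@pytest.fixture(scope="session")
def study_cohort():
    """Default-condition cohort: 43 HC / 42 FTD / 33 AD."""
    return simulate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def small_panels():
    """A compact capture/scramble panel pair with 5 known spikes."""
    spec = PanelSpec(n_mirnas=120, present_fraction=0.8, seed=5)
    spec.enriched_set = {f"hsa-miR-s{i:04d}": 3.0 for i in (3, 17, 42, 77, 101)}
    capture, scramble = simulate_panels(spec)
    return spec, capture, scramble


def make_ct_table(rows, **kwargs):
    """Helper: CtTable from (sample, mirna, plate, ct, detected) tuples."""
    df = pd.DataFrame(
        rows, columns=["sample_id", "mirna_id", "plate_id", "ct", "detected"]
    )
    return CtTable(df, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(202)
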