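import numpy as np
import pytest

import cytoscreen as cs


@pytest.fixture(scope="session")
def small_spec() -> cs.CohortSpec:
    """A small but full-design cohort: 6 donors x 2 platforms x triplicate."""
    return cs.CohortSpec(n_donors=6, n_replicates=3, n_events_per_sample=3000,
                         seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return cs.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def screened(small_spec, small_cohort):
    samples, metadata, _truth = small_cohort
    cfg = cs.default_pregate_config(small_spec)
    return cs.run_screen(samples, metadata, cfg, small_spec.panel)


def toy_events(values, markers=("A", "B"), sample_id="s1", transform="arcsinh"):
    """EventMatrix with marker channels only, values already on the
    analysis scale."""
    channels = [cs.Channel(m, "marker", marker=m) for m in markers]
    return cs.EventMatrix(sample_id=sample_id, channels=channels,
                          values=np.asarray(values, dtype=float),
                          transform=transform,
                          cofactors={m: 150.0 for m in markers})
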