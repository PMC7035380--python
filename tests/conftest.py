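import numpy as np
import pytest

from ilof import evaluation, sigproc, synthgen
from ilof.features import feature_table


def build_cohort_table(preset: str, entities_per_class: int = 3,
                       duration: float = 8.0, seed: int = 7):
    """Simulate -> preprocess -> 54-feature table for a desk-scale cohort."""
    counts = {label: entities_per_class for label in synthgen.CLASS_ORDER}
    maker = (synthgen.separated_class_specs if preset == "separated"
             else synthgen.identical_class_specs)
    specs = maker(counts)
    acqs = synthgen.generate_cohort(specs, duration=duration, seed=seed)
    epochs = []
    for acq in acqs:
        epochs.extend(sigproc.preprocess(acq))
    return feature_table(epochs, specs[0].scatter.fs)


@pytest.fixture(scope="session")
def separated_table():
    """Feature table of the well-separated desk-scale cohort (3 entities/class,
    8-s acquisitions)."""
    return build_cohort_table("separated", seed=7)


@pytest.fixture(scope="session")
def identical_table():
    """Feature table of the chance-level control cohort (all classes emit
    identically distributed signals)."""
    return build_cohort_table("identical", seed=7)
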