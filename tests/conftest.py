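import pytest

import msilike as m
from msilike.synthetic import recovery_config


@pytest.fixture(scope="session")
def freq_table():
    return m.load_default_frequency_table()


@pytest.fixture(scope="session")
def class_map():
    return m.load_default_class_map()


@pytest.fixture(scope="session")
def recovery_cohort():
    """Clean two-stratum cohort with strong injected TIL+mutation signal."""
    return m.simulate_cohort(recovery_config(seed=0))


@pytest.fixture(scope="session")
def table1_cohort():
    return m.load_table1_cohort()


@pytest.fixture(scope="session")
def toy_specs():
    """Three nested feature combinations, most to least complete."""
    return [
        m.FeatureSpec(
            name="clin+mut+til",
            blocks=(
                "clinical", "mutation_posterior", "gene_classes_s1",
                "til:CD8+__stromal", "til:CD163+__stromal",
            ),
        ),
        m.FeatureSpec(
            name="clin+mut",
            blocks=("clinical", "mutation_posterior", "gene_classes_s1"),
        ),
        m.FeatureSpec(name="clin", blocks=("clinical",)),
    ]


@pytest.fixture(scope="session")
def toy_registry(recovery_cohort, freq_table, class_map, toy_specs):
    config = m.TrainingConfig.from_base_seed(0, n_seeds=5)
    return m.train_lattice(
        recovery_cohort, toy_specs, config,
        table=freq_table, class_map=class_map,
    )
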