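import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nanosynapse import (
    FieldAnalysis,
    default_cko_config,
    default_control_config,
    generate_field,
)
from nanosynapse.pipeline import analyze_field
from nanosynapse.synthetic_data import SyntheticConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

CONTROL_SEEDS = tuple(range(10))
CKO_SEEDS = tuple(range(100, 110))


def small_config(**overrides) -> SyntheticConfig:
    """A fast, few-synapse field for unit tests that only need structure."""
    base = dict(
        n_synapses=6,
        field_size=(8_000.0, 8_000.0, 2_500.0),
        n_nonsynaptic_nano=6,
        background_density=5.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def _analyze_condition(configs):
    analyses, truths = [], []
    for cfg in configs:
        table, truth = generate_field(cfg)
        analyses.append(
            analyze_field(
                table,
                nano_channel=cfg.nano_channel,
                reference_channel=cfg.reference_channel,
            )
        )
        truths.append(truth)
    return analyses, truths


@pytest.fixture(scope="session")
def control_study() -> tuple[list[FieldAnalysis], list]:
    """Ten control fields (~50 synapses each, fixed seeds), fully analysed."""
    return _analyze_condition([default_control_config(seed=s) for s in CONTROL_SEEDS])


@pytest.fixture(scope="session")
def cko_study() -> tuple[list[FieldAnalysis], list]:
    """Ten conditional-deletion fields, fully analysed."""
    return _analyze_condition([default_cko_config(seed=s) for s in CKO_SEEDS])


@pytest.fixture(scope="session")
def one_control_field():
    """A single generated control field with its ground truth (no analysis)."""
    return generate_field(default_control_config(seed=0))


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
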