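import pandas as pd
import pytest

from senoscreen import SimConfig, gen_expression_groups
from senoscreen.connectivity import call_degs, signature_from_degs
from senoscreen.datatypes import GeneSignature, RankedProfile


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def expression_fixture(default_cfg):
    """Planted-DE matrix plus truth labels (6v6, 100 DE genes at 1 log2, SD 0.3)."""
    return gen_expression_groups(default_cfg)


@pytest.fixture(scope="session")
def aging_signature(expression_fixture) -> GeneSignature:
    matrix, _ = expression_fixture
    degs = call_degs(matrix, "young", "old")
    return signature_from_degs(degs, name="aging")


@pytest.fixture
def tiny_profile() -> RankedProfile:
    """Four-gene profile ranked a > b > c > d."""
    return RankedProfile.from_scores(
        "tiny", {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}
    )


def make_cohort(durations, events=None, group="g"):
    durations = list(durations)
    events = list(events) if events is not None else [1] * len(durations)
    return pd.DataFrame(
        {
            "subject_id": [f"{group}_{i}" for i in range(len(durations))],
            "duration_days": durations,
            "event": events,
            "group": group,
        }
    )
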