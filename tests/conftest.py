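import numpy as np
import pytest

from repliscore import (
    EffectEstimate,
    EffectScale,
    Interpretation,
    PairRecord,
    Reporting,
    SimConfig,
    generate_dataset,
)


def make_pair(
    orig_est: float,
    orig_se: float,
    rep_est: float,
    rep_se: float,
    interpretation: Interpretation = Interpretation.POSITIVE,
    outcome_id: str = "o1",
    **kwargs,
) -> PairRecord:
    """Minimal numeric pair on the SMD scale for criterion tests."""
    return PairRecord(
        paper_id=kwargs.pop("paper_id", "p1"),
        experiment_id=kwargs.pop("experiment_id", "e1"),
        effect_id=kwargs.pop("effect_id", "f1"),
        outcome_id=outcome_id,
        original=EffectEstimate(
            scale=EffectScale.COHENS_D, estimate=orig_est, se=orig_se
        ),
        replication=EffectEstimate(
            scale=EffectScale.COHENS_D, estimate=rep_est, se=rep_se
        ),
        original_interpretation=interpretation,
        reporting=Reporting.NUMERIC,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_ensemble():
    """A reproducible mid-sized synthetic ensemble shared across tests."""
    records, truth = generate_dataset(SimConfig(seed=20240917, n_papers=40))
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
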