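import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from twostepmr import HarmonizedSet, SummaryStatRecord, SyntheticConfig, simulate_tripartite

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_harmonized(bx, by, sy, sx=None, ids=None, **names) -> HarmonizedSet:
    """Build a HarmonizedSet from short argument lists."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    if sx is None:
        sx = np.full_like(bx, 0.01)
    if ids is None:
        ids = [f"rs{i + 1}" for i in range(len(bx))]
    return HarmonizedSet(
        variant_id=np.array(ids, dtype=object),
        beta_exposure=bx,
        se_exposure=np.asarray(sx, float),
        beta_outcome=by,
        se_outcome=sy,
        **names,
    )


def make_record(variant_id="rs1", effect_allele="A", other_allele="G", beta=0.1,
                se=0.01, pval=1e-10, **kw) -> SummaryStatRecord:
    return SummaryStatRecord(
        variant_id=variant_id, effect_allele=effect_allele, other_allele=other_allele,
        beta=beta, se=se, pval=pval, **kw,
    )


@pytest.fixture
def consensus_h() -> HarmonizedSet:
    """Five instruments whose Wald ratios all equal exactly 0.5."""
    bx = np.array([0.10, 0.15, 0.20, 0.25, 0.30])
    return make_harmonized(bx, 0.5 * bx, np.full(5, 0.01))


@pytest.fixture(scope="session")
def default_scenario():
    """One simulated study triple under the default generating model."""
    return simulate_tripartite(SyntheticConfig(seed=7))
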