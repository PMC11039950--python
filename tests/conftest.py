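import numpy as np
import pytest

from gutmr import (
    EstimatorConfig,
    HarmonizedInstrumentSet,
    SummaryStatistics,
    SyntheticConfig,
    VariantAssociation,
    build_instrument_set,
    simulate_pair,
)


@pytest.fixture
def ivw_worked_set() -> HarmonizedInstrumentSet:
    """Two ratios (0.5, se 0.1) and (0.3, se 0.2): gamma = 1, sigma_y = se."""
    return HarmonizedInstrumentSet.from_arrays(
        gamma=[1.0, 1.0], sigma_x=[0.1, 0.1], Gamma=[0.5, 0.3], sigma_y=[0.1, 0.2]
    )


@pytest.fixture
def egger_worked_set() -> HarmonizedInstrumentSet:
    """gamma = (0.1, 0.2, 0.3), Gamma = (0.03, 0.05, 0.07), equal sigma_y."""
    return HarmonizedInstrumentSet.from_arrays(
        gamma=[0.1, 0.2, 0.3], sigma_x=[0.01] * 3, Gamma=[0.03, 0.05, 0.07], sigma_y=[1.0] * 3
    )


@pytest.fixture
def median_worked_set() -> HarmonizedInstrumentSet:
    """Sorted ratios (0.2, 0.5, 0.9) with normalized weights (0.2, 0.3, 0.5)."""
    w = np.array([2.0, 3.0, 5.0])
    return HarmonizedInstrumentSet.from_arrays(
        gamma=[1.0] * 3, sigma_x=[0.01] * 3, Gamma=[0.2, 0.5, 0.9], sigma_y=1.0 / np.sqrt(w)
    )


@pytest.fixture
def simulated_pair():
    """A clean protective-effect pair with a known generating truth."""
    cfg = SyntheticConfig(J=15, beta0=-0.4, seed=424242)
    return simulate_pair(cfg)


@pytest.fixture
def simulated_hset(simulated_pair) -> HarmonizedInstrumentSet:
    exposure, outcome, _ = simulated_pair
    return build_instrument_set(exposure, outcome)


@pytest.fixture
def estimator_config() -> EstimatorConfig:
    return EstimatorConfig(seed=97)


def make_variant(snp_id="rs1", ea="A", oa="G", beta=0.05, se=0.01, p=1e-6, **kw):
    return VariantAssociation(
        snp_id=snp_id, effect_allele=ea, other_allele=oa, beta=beta, se=se, pvalue=p, **kw
    )


def make_stats(records, trait_id="taxon", trait_type="continuous"):
    return SummaryStatistics(trait_id=trait_id, trait_type=trait_type, records=records)


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def stats_factory():
    return make_stats
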