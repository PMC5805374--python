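import numpy as np
import pytest

from ribojam.io import CodonRateTable, SENSE_CODONS, SimConfig, Transcript


def make_transcript(rates, gene_id="g", termination_rate=None, codon="GCT"):
    """Homogeneous-codon transcript with explicit per-site rates."""
    rates = np.asarray(rates, dtype=float)
    return Transcript(
        gene_id=gene_id,
        codons=tuple([codon] * len(rates)),
        site_rates=rates,
        termination_rate=termination_rate if termination_rate is not None else rates.max(),
    )


@pytest.fixture(scope="session")
def uniform_rate_table():
    return CodonRateTable({c: 0.2 for c in SENSE_CODONS})


@pytest.fixture(scope="session")
def synthetic_rate_table():
    from ribojam.fixtures import FixtureSpec, make_rate_table

    return make_rate_table(FixtureSpec(seed=11))


@pytest.fixture
def fast_config():
    return SimConfig(warmup_terminations=50, monitored_terminations=2000, seed=7)
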