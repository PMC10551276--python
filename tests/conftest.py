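import pytest

from mitoprofile.mitogenome import DEFAULT_MAP
from mitoprofile.simulate import (
    SimulationConfig,
    known_variants_from_ledger,
    simulate_cohort,
    synthetic_reference,
)


@pytest.fixture(scope="session")
def gene_map():
    return DEFAULT_MAP


@pytest.fixture(scope="session")
def reference():
    """Deterministic synthetic 16,569-bp reference (not the real rCRS)."""
    return synthetic_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient simulated cohort with its truth ledger and known table."""
    config = SimulationConfig(n_patients=12, seed=42)
    patients, ledger = simulate_cohort(config)
    known = known_variants_from_ledger(ledger)
    return patients, ledger, known
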