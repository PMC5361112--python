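import pytest

from paleomito import (
    MappedRead,
    SimulationParams,
    generate_reference,
    process_batch,
    simulate_batch,
)


def make_read(start, bases, barcode="S1", read_id=None, quals=None):
    """Shorthand for a MappedRead with uniform Q30 qualities."""
    n = len(bases)
    if quals is None:
        quals = (30,) * n
    elif isinstance(quals, int):
        quals = (quals,) * n
    return MappedRead(
        read_id=read_id or f"{barcode}.{start}.{bases[:4]}",
        barcode=barcode,
        start=start,
        end=start + n,
        bases=bases,
        qualities=tuple(quals),
    )


@pytest.fixture(scope="session")
def reference():
    return generate_reference(2000, n_features_per_category=1, seed=7)


@pytest.fixture(scope="session")
def study_params():
    """The standard simulated study conditions: 30x, 10% terminal damage,
    0.2% sequencing error, 2 extra PCR copies per molecule, 2% bleed."""
    return SimulationParams(
        coverage=30.0,
        damage_rate=0.1,
        error_rate=0.002,
        duplication_rate=2.0,
        bleed_rate=0.02,
    )


@pytest.fixture(scope="session")
def study_batch(reference, study_params):
    """Five samples at 25 substitutions each from the 2 kb reference."""
    return simulate_batch(reference, 5, 25, study_params, seed=1)


@pytest.fixture(scope="session")
def study_result(study_batch, reference):
    return process_batch(study_batch.pooled_reads, reference.length)
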