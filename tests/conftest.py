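import pytest

from epiwin import AntigenRecord, SimulationConfig, generate_antigens


@pytest.fixture
def labeled_antigen():
    """A tiny hand-labeled antigen: residues 3-5 interact."""
    return AntigenRecord(
        id="ag1",
        sequence="ACDEFGHIKL",
        labels=[0, 0, 1, 1, 1, 0, 0, 0, 0, 0],
    )


@pytest.fixture(scope="session")
def small_synthetic_set():
    """A small but learnable synthetic antigen set (shared across tests)."""
    cfg = SimulationConfig(n_antigens=40, length_range=(120, 120), seed=11)
    return generate_antigens(cfg)
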