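import pytest

from mifish import CENTROMERE_CONTROL, GENE_TARGET, Probe, ProbePanel, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_panel():
    """Compact 5-probe panel (3 genes + 2 centromeres) for hand-sized tests."""
    return ProbePanel(
        (
            Probe("GENE_A", GENE_TARGET, "1p"),
            Probe("GENE_B", GENE_TARGET, "2q"),
            Probe("GENE_C", GENE_TARGET, "3q"),
            Probe("CEN_1", CENTROMERE_CONTROL, "1cen"),
            Probe("CEN_2", CENTROMERE_CONTROL, "2cen"),
        )
    )
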