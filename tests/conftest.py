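import pytest

from sexscan import ChromTable, Thresholds


@pytest.fixture
def chroms() -> ChromTable:
    return ChromTable.from_pairs([("LG1", 250_000), ("LG2", 100_000)])


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture
def sim_chroms() -> ChromTable:
    """The default simulated genome: five 2-Mb chromosomes."""
    return ChromTable.from_pairs([(f"sim{i + 1}", 2_000_000) for i in range(5)])
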