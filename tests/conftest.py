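import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from germpanel.panel import GenePanel, TargetRegion

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_panel() -> GenePanel:
    """Two genes on two chromosomes; MLH9 is minus-strand (exon order flips)."""
    regions = [
        TargetRegion("chr1", 100, 200, "BRCA9", 1, "+"),
        TargetRegion("chr1", 300, 400, "BRCA9", 2, "+"),
        TargetRegion("chr1", 500, 600, "BRCA9", 3, "+"),
        TargetRegion("chr2", 1000, 1100, "MLH9", 2, "-"),
        TargetRegion("chr2", 1300, 1400, "MLH9", 1, "-"),
    ]
    return GenePanel(regions=regions, flank_bp=50)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
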