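import numpy as np
import pytest

from dggekit import DetectionConfig, GradientSpec, SimulationConfig, simulate_gel


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic ATAD gel with its ground truth (rendered once)."""
    cfg = SimulationConfig()
    gel, truth = simulate_gel(cfg)
    return cfg, gel, truth


@pytest.fixture(scope="session")
def clean_sim():
    """Noiseless, baseline-free, warped gel: the de-warping test bed."""
    cfg = SimulationConfig(noise_sd=0.0, baseline_amp=0.0, warp_amp=0.03)
    gel, truth = simulate_gel(cfg)
    return cfg, gel, truth


@pytest.fixture
def gradient():
    return GradientSpec(35.0, 75.0)


@pytest.fixture
def clean_detection():
    """Detection settings for noiseless profiles."""
    return DetectionConfig(min_prominence=0.5)


def planted_presence(truth, sample_ids):
    """True lane × species presence matrix from ground-truth fingerprints,
    species (columns) ordered by melting position."""
    fps = [fp for fp in truth if fp.lane_id in sample_ids]
    species = sorted({b.denaturant for fp in fps for b in fp.bands})
    col = {d: j for j, d in enumerate(species)}
    mat = np.zeros((len(fps), len(species)), dtype=int)
    for i, fp in enumerate(fps):
        for b in fp.bands:
            mat[i, col[b.denaturant]] = 1
    return mat, species
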