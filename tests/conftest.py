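import numpy as np
import pytest

from adgscan.adg_caller import PipelineConfig
from adgscan.motif_model import BackgroundModel
from adgscan.pipeline import analyze_genome
from adgscan.synthetic_fixtures import SimSpec, simulate_genome


@pytest.fixture(scope="session")
def uniform_bg():
    return BackgroundModel.uniform()


@pytest.fixture(scope="session")
def random_pwms(uniform_bg):
    """A bank of small random PWMs (Dirichlet columns), deterministic."""
    from adgscan.motif_model import PWMMotif

    rng = np.random.default_rng(42)
    pwms = []
    for i in range(20):
        w = int(rng.integers(2, 7))
        probs = rng.dirichlet(np.ones(4) * 0.7, size=w)
        pwms.append(PWMMotif(f"rand{i}", probs * 0, probs, uniform_bg, 0.25))
    return pwms


@pytest.fixture(scope="session")
def sim_genome():
    """One implanted synthetic genome with its ground truth."""
    return simulate_genome(SimSpec(seed=1))


@pytest.fixture(scope="session")
def analyzed(sim_genome):
    """Full per-genome analysis of the seed-1 genome (discover+scan+call)."""
    genome, truth = sim_genome
    return analyze_genome(genome, PipelineConfig()), truth
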