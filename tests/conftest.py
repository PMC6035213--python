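import numpy as np
import pytest

from alusite import GuideSpec, WindowSpec
from alusite.simulate import SynthConfig


def small_config(seed: int, **overrides) -> SynthConfig:
    """Desk-scale simulation config for unit tests: 2 x 400 kb contigs
    hosting a 60-gene pool (capacity 72 windows of 11 kb + gap)."""
    params = dict(
        seed=seed,
        n_contigs=2,
        contig_length=400_000,
        gc_content=0.41,
        pool_size=60,
        enriched_set_size=8,
        peaks_per_sample=60,
        n_control_samples=3,
        n_treated_samples=3,
        control_overlap_fraction=0.05,
        treated_overlap_fraction=0.25,
        guide=GuideSpec(name="g1", protospacer="GATTCGCAAGCTGT", pam="NGG"),
    )
    params.update(overrides)
    return SynthConfig(**params)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """One shared small synthetic dataset (with peaks) for read-only tests."""
    from alusite.simulate import simulate_dataset

    return simulate_dataset(small_config(11))


@pytest.fixture(scope="session")
def small_hits(small_dataset):
    from alusite.scan import find_guide_sites

    return find_guide_sites(small_dataset.genome, small_dataset.config.guide)
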