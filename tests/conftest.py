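import numpy as np
import pytest

from cislink.simulate import SimulationConfig, generate_annotation


def small_config(**overrides) -> SimulationConfig:
    """A reduced study: 2 x 3 Mb genome, 60 enhancers, 120 genes.

    Keeps every planted structure of the default design at a size where
    full pipeline runs take seconds.
    """
    fields = dict(
        genome=(("chr1", 3_000_000), ("chr2", 3_000_000)),
        n_genes=120,
        n_enhancers=60,
        seed=0,
    )
    fields.update(overrides)
    return SimulationConfig(**fields)


@pytest.fixture(scope="session")
def sim_small():
    """Annotation + truth for the reduced study (seed 0)."""
    cfg = small_config()
    annotation, truth = generate_annotation(cfg)
    return cfg, annotation, truth


@pytest.fixture(scope="session")
def sim_default():
    """Annotation + truth at the default study size (seed 1)."""
    cfg = SimulationConfig(seed=1)
    annotation, truth = generate_annotation(cfg)
    return cfg, annotation, truth


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     max_pos: int = 100_000, max_len: int = 500):
    from cislink.intervals import GenomicInterval

    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
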