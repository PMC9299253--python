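import numpy as np
import pytest

from sgvscan import sim


def make_counts(rows, samples):
    """Build a CountTable from (chrom, pos, ref, [six-tuple per sample])."""
    from sgvscan.io import CountTable

    chrom = np.asarray([r[0] for r in rows], dtype=object)
    pos = np.asarray([r[1] for r in rows], dtype=np.int64)
    ref = np.asarray([r[2] for r in rows], dtype=object)
    counts = np.asarray([r[3] for r in rows], dtype=np.int64)
    return CountTable(samples=list(samples), chrom=chrom, pos=pos, ref=ref,
                      counts=counts)


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests: both habitats,
    6 marine pools, a few individuals, planted adaptive loci."""
    cfg = sim.study_design(
        scenario="neutral_flat",
        n_neutral_sites=3_000,
        n_planted_adaptive=40,
        pool_depth=100,
        n_individuals_per_habitat=4,
        rng_seed=11,
    )
    truth = sim.draw_true_frequencies(cfg)
    counts = sim.sample_counts(truth, cfg)
    return cfg, truth, counts
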