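"""Generate a synthetic pooled-sequencing study with known ground truth.

The study design mirrors a two-habitat freshwater contrast (one acidic and
one basic pool of 100 fish each) plus six marine pools ordered by distance
from the freshwater system.  Fifty "planted" adaptive sites are near-fixed
for opposite alleles in the two freshwater pools; everything else drifts
around a shared ancestral frequency under a Balding-Nichols model whose
spread is calibrated to realistic background FST levels.
"""

from pathlib import Path

import numpy as np

from sgvscan import sim

OUT = Path(__file__).parent / "output" / "fixture_flat"


def main() -> None:
    cfg = sim.study_design(
        scenario="neutral_flat",      # marine frequency constant at 0.30
        n_neutral_sites=20_000,
        n_planted_adaptive=50,
        pool_depth=85,                # pooled libraries
        n_individuals_per_habitat=4,  # a few 16x individuals per habitat
        rng_seed=42,
    )
    truth = sim.draw_true_frequencies(cfg)
    counts = sim.sample_counts(truth, cfg)
    path = sim.write_fixture(truth, counts, cfg, OUT)

    planted = truth.planted_mask()
    ja = truth.samples.index("acidic")
    jb = truth.samples.index("basic")
    print(f"fixture written under {path.parent}")
    print(f"samples: {', '.join(truth.samples)}")
    print(f"sites: {truth.n_sites} total, {int(planted.sum())} planted adaptive")
    print("planted acidic-basic truth AFD: "
          f"min {np.min(truth.freq[planted, ja] - truth.freq[planted, jb]):.3f}, "
          f"max {np.max(truth.freq[planted, ja] - truth.freq[planted, jb]):.3f}")
    print(f"mean sequenced depth (acidic pool): "
          f"{counts.depth()[:, counts.sample_index('acidic')].mean():.1f}x")


if __name__ == "__main__":
    main()
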