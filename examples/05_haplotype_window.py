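"""Genotype a short window around an adaptive SNP and export it for
phasing.

Within the window every individual is genotyped per site (missing below
10x, heterozygous when the read minor-allele fraction exceeds 0.1),
individuals with more than 25% missing calls are dropped, and sites are
screened for missingness (<= 40%) and minor-allele frequency (>= 5%).  The
surviving matrix is written in a fastPHASE-style .inp layout plus a TSV
twin.
"""

from pathlib import Path

import numpy as np

from sgvscan.hapwindows import export_phasing_input, window_genotype
from sgvscan.sim import simulate_haplotype_window

OUT = Path(__file__).parent / "output"


def main() -> None:
    # a self-contained window: 12 individuals at 16x over a divergent locus
    counts, marine, acidic = simulate_haplotype_window(rng_seed=5)
    center = int(np.median(counts.pos))
    width = int(counts.pos.max() + 10)

    matrix = window_genotype(counts, marine + acidic, counts.chrom[0],
                             center, width_bp=width)
    print(f"window {matrix.chrom}:{center} +/- {width // 2} bp")
    print(f"{matrix.n_individuals} individuals x {matrix.n_sites} sites "
          "after filtering")
    for line in matrix.filter_log:
        print(f"  filter: {line}")
    n_het = sum(g[0] != g[1]
                for row in matrix.genotypes for g in row if g != "??")
    print(f"heterozygous calls: {n_het}")

    out = OUT / "window.inp"
    export_phasing_input(matrix, out)
    print(f"phasing input written to {out.name} (+ {out.with_suffix('.tsv').name})")


if __name__ == "__main__":
    main()
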