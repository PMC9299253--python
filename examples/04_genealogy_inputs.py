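"""Prepare genealogy inputs from individually sequenced fish.

Individuals are haploidized (read-majority allele per SNP), SNPs strongly
differentiated in both the marine-freshwater and the acidic-basic contrast
are removed, and only markers in the peripheral 5 Mb of each chromosome are
kept — enriching for neutrally evolving loci.  The result is written as a
concatenated-SNP FASTA (for external tree inference) plus a quick
neighbour-joining tree on p-distances.

Run 01_simulate_study.py first (it includes 16x individuals).
"""

from pathlib import Path

from sgvscan.ascertain import AscertainParams, ascertain_indseq
from sgvscan.diffstats import afd_vector
from sgvscan.genealogy import (
    distance_tree,
    haploid_genotypes,
    marine_freshwater_contrast,
    neutral_filter,
)
from sgvscan.io import read_chroms, read_counts, read_manifest, write_fasta

FIXTURE = Path(__file__).parent / "output" / "fixture_flat"
OUT = Path(__file__).parent / "output"


def main() -> None:
    manifest = read_manifest(FIXTURE / "manifest.tsv")
    counts = read_counts(FIXTURE / "counts.sync.tsv", manifest)
    chroms = read_chroms(FIXTURE / "chromosomes.tsv")

    marine = manifest.select(kind="individual", habitat="marine")
    fresh = [i for i in manifest.select(kind="individual") if i not in marine]
    sites = ascertain_indseq(
        counts, AscertainParams(maf_reference_samples=marine))
    print(f"{sites.n_sites} SNPs pass the individual-sequencing filters")

    afd_mf = marine_freshwater_contrast(counts, sites, marine, fresh, rng_seed=0)
    ia, ib = sites.sample_index("acidic"), sites.sample_index("basic")
    afd_ab = afd_vector(sites.freq[:, ia, :], sites.freq[:, ib, :])
    neutral = neutral_filter(sites, afd_mf, afd_ab, chroms)
    print(f"{neutral.n_sites} SNPs survive the neutrality filter "
          "(not differentiated in both contrasts, peripheral 5 Mb)")

    individuals = manifest.select(kind="individual")
    haploids = haploid_genotypes(counts, neutral, individuals, rng_seed=0)
    fasta = OUT / "neutral_haploids.fasta"
    write_fasta(haploids.labels, haploids.sequences, fasta)
    newick = distance_tree(haploids)
    (OUT / "neutral_haploids.nwk").write_text(newick + "\n")
    print(f"{len(individuals)} haploid sequences of "
          f"{len(haploids.sequences[0])} SNPs -> {fasta.name}")
    print(f"NJ tree: {newick[:90]}...")


if __name__ == "__main__":
    main()
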