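"""Inputs for genealogical analysis: haploid multilocus genotypes,
selection-reduced ("neutral") SNP sets, synthetic pooled genotypes, and a
small neighbour-joining utility for structure-recovery checks.

Individual genotypes are haploidized by taking the read-majority allele at
each SNP (a seeded random pick among ties), sidestepping diploid calling at
low depth.  The neutral SNP set removes markers differentiated in *both*
the marine-freshwater and the acidic-basic contrast (AFD > 0.4 in both) and
keeps only markers in the peripheral 5 Mb of each chromosome, where high
recombination weakens linked-selection footprints.  Tree inference proper
(maximum likelihood, bootstraps) is left to external tools operating on the
exported FASTA; the distance tree here is a test utility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ascertain import SnpSites
from .io import NUCLEOTIDES, ChromTable, CountTable


@dataclass
class NeutralFilterParams:
    afd_exclude_threshold: float = 0.4
    peripheral_bp: int = 5_000_000
    maf_min_contrast: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.afd_exclude_threshold <= 1.0:
            raise ValueError("afd_exclude_threshold must be in [0, 1]")
        if self.peripheral_bp < 0:
            raise ValueError("peripheral_bp must be >= 0")
        if not 0.0 <= self.maf_min_contrast <= 0.5:
            raise ValueError("maf_min_contrast must be in [0, 0.5]")


@dataclass
class HaploidGenotypes:
    """One concatenated-SNP nucleotide string per sequence unit (individual
    or pooled sample location)."""

    labels: list[str]
    sequences: list[str]
    snp_chrom: np.ndarray
    snp_pos: np.ndarray
    rng_seed: int

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in length")
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise ValueError("haploid strings have unequal lengths")


def _counts_at_sites(counts: CountTable, snps: SnpSites) -> np.ndarray:
    """Rows of the count table matching the SNP sites, in SNP order."""
    key = counts.site_key()
    try:
        rows = [key[(c, int(p))] for c, p in zip(snps.chrom, snps.pos)]
    except KeyError as exc:
        raise KeyError(f"SNP site {exc.args[0]} missing from count table") from None
    return np.asarray(rows, dtype=int)


def haploid_genotypes(
    counts: CountTable,
    snps: SnpSites,
    individuals: list[str],
    rng_seed: int = 0,
) -> HaploidGenotypes:
    """Haploid multilocus genotypes: per individual per SNP the
    read-majority nucleotide, ties broken by a seeded uniform draw."""
    rng = np.random.default_rng(rng_seed)
    rows = _counts_at_sites(counts, snps)
    col = [counts.sample_index(lab) for lab in individuals]
    nuc = counts.counts[np.ix_(rows, col)][:, :, :4]  # (n_snps, n_ind, 4)
    sequences = []
    for j, lab in enumerate(individuals):
        chars = []
        for i in range(len(rows)):
            c = nuc[i, j]
            total = c.sum()
            if total == 0:
                raise ValueError(
                    f"individual {lab} has no nucleotide reads at "
                    f"{snps.chrom[i]}:{snps.pos[i]}"
                )
            best = c.max()
            tied = np.flatnonzero(c == best)
            k = int(tied[0]) if len(tied) == 1 else int(rng.choice(tied))
            chars.append(NUCLEOTIDES[k])
        sequences.append("".join(chars))
    return HaploidGenotypes(
        labels=list(individuals),
        sequences=sequences,
        snp_chrom=snps.chrom,
        snp_pos=snps.pos,
        rng_seed=rng_seed,
    )


def marine_freshwater_contrast(
    counts: CountTable,
    snps: SnpSites,
    marine_individuals: list[str],
    freshwater_individuals: list[str],
    params: NeutralFilterParams | None = None,
    rng_seed: int = 0,
) -> np.ndarray:
    """Per-SNP AFD between a marine and a freshwater group of individuals.

    Two nucleotides are drawn with replacement from each individual's read
    pileup at each SNP (seeded), pooled within groups, and the group allele
    frequencies are compared.  SNPs whose pooled MAF over both groups falls
    below ``maf_min_contrast`` are dropped from the contrast (NaN).
    """
    params = params or NeutralFilterParams()
    if set(marine_individuals) & set(freshwater_individuals):
        raise ValueError("marine and freshwater groups overlap")
    if not marine_individuals or not freshwater_individuals:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(rng_seed)
    rows = _counts_at_sites(counts, snps)

    def group_draws(members: list[str]) -> np.ndarray:
        col = [counts.sample_index(lab) for lab in members]
        nuc = counts.counts[np.ix_(rows, col)][:, :, :4].astype(float)
        depth = nuc.sum(axis=2)
        if np.any(depth == 0):
            i, j = np.argwhere(depth == 0)[0]
            raise ValueError(
                f"individual {members[j]} has no reads at "
                f"{snps.chrom[i]}:{snps.pos[i]}"
            )
        probs = nuc / depth[:, :, None]
        # two draws with replacement per individual per SNP
        draws = rng.multinomial(2, probs.reshape(-1, 4)).reshape(nuc.shape)
        return draws.sum(axis=1)  # pooled counts per SNP (n_snps, 4)

    pa = group_draws(marine_individuals)
    pb = group_draws(freshwater_individuals)
    fa = pa / pa.sum(axis=1, keepdims=True)
    fb = pb / pb.sum(axis=1, keepdims=True)

    pooled = pa + pb
    maf = 1.0 - pooled.max(axis=1) / pooled.sum(axis=1)
    afd = 0.5 * np.abs(fa - fb).sum(axis=1)
    afd[maf < params.maf_min_contrast] = np.nan
    return afd


def neutral_filter(
    snps: SnpSites,
    afd_mf: np.ndarray,
    afd_ab: np.ndarray,
    chroms: ChromTable,
    params: NeutralFilterParams | None = None,
) -> SnpSites:
    """Selection-reduced SNP set.

    Keeps SNPs that are NOT strongly differentiated in both contrasts
    (``afd > threshold`` in the marine-freshwater AND the acidic-basic
    comparison; an unmeasured contrast, NaN, never counts as exceeding),
    and that lie within the peripheral ``peripheral_bp`` of their
    chromosome (pos <= peripheral or pos > length - peripheral, 1-based).
    """
    params = params or NeutralFilterParams()
    if len(afd_mf) != snps.n_sites or len(afd_ab) != snps.n_sites:
        raise ValueError("AFD vectors are not aligned to the SNP table")
    t = params.afd_exclude_threshold
    with np.errstate(invalid="ignore"):
        selected = (afd_mf > t) & (afd_ab > t)  # NaN compares False
    lengths = np.asarray([chroms.length(c) for c in snps.chrom])
    peripheral = (snps.pos <= params.peripheral_bp) | (
        snps.pos > lengths - params.peripheral_bp
    )
    keep = ~selected & peripheral
    return snps.take(np.flatnonzero(keep))


def synthetic_pool_genotypes(
    snps: SnpSites, pool_labels: list[str], rng_seed: int = 0
) -> HaploidGenotypes:
    """Synthetic haploid genotypes for pooled samples: one seeded
    categorical draw per pool per SNP with probabilities equal to the
    pool's allele frequencies, concatenated per location."""
    rng = np.random.default_rng(rng_seed)
    sequences = []
    for lab in pool_labels:
        j = snps.sample_index(lab)
        probs = snps.freq[:, j, :]
        if np.isnan(probs).any():
            i = int(np.flatnonzero(np.isnan(probs).any(axis=1))[0])
            raise ValueError(
                f"pool {lab} has no reads at {snps.chrom[i]}:{snps.pos[i]}"
            )
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError(f"pool {lab}: allele frequencies do not sum to 1")
        draws = rng.multinomial(1, probs).argmax(axis=1)
        sequences.append("".join(NUCLEOTIDES[k] for k in draws))
    return HaploidGenotypes(
        labels=list(pool_labels),
        sequences=sequences,
        snp_chrom=snps.chrom,
        snp_pos=snps.pos,
        rng_seed=rng_seed,
    )


def p_distance_matrix(haploids: HaploidGenotypes) -> np.ndarray:
    """Pairwise fraction of mismatching SNPs between haploid strings."""
    seqs = [np.frombuffer(s.encode(), dtype="S1") for s in haploids.sequences]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(np.mean(seqs[i] != seqs[j]))
    return d


def distance_tree(haploids: HaploidGenotypes) -> str:
    """Neighbour-joining tree on pairwise p-distances, as a newick string.

    Deterministic given the input order.  A convenience utility for
    structure-recovery checks; likelihood-based inference is external.
    """
    if len(haploids.labels) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    if len(set(haploids.labels)) != len(haploids.labels):
        raise ValueError("duplicate sequence labels")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(p_distance_matrix(haploids), ids=haploids.labels)
    tree = nj(dm)
    return str(tree)
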