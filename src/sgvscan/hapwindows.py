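"""Diploid genotyping and filtering within short windows around adaptive
SNPs, and export of phasing-ready genotype matrices.

Within a window (5 kb by default) every individual is genotyped at every
position with sufficient read depth: heterozygous when the within-individual
read minor-allele frequency exceeds ``het_maf`` (strictly), homozygous for
the majority read allele otherwise, missing below the depth floor.  Filters
are then applied in a fixed order: individuals with too much missingness are
dropped first, and only then are sites screened for missingness and
minor-allele frequency over the retained individuals' called alleles.
Phasing itself and haplotype-network construction are external; this module
writes their input matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import NUCLEOTIDES, CountTable

MISSING = "?"


@dataclass
class Genotype:
    """A diploid call: two nucleotide characters, or missing."""

    a1: str
    a2: str

    @property
    def is_het(self) -> bool:
        return self.a1 != self.a2


@dataclass
class WindowGenotypeMatrix:
    """Filtered diploid genotypes of one window.

    ``genotypes`` has one row per retained individual and one column per
    retained position; entries are two-character strings (alleles in
    alphabetical order) or ``"??"`` for missing.
    """

    chrom: str
    center_pos: int
    width_bp: int
    individuals: list[str]
    positions: np.ndarray
    genotypes: np.ndarray  # (n_ind, n_pos) of 2-char strings
    filter_log: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genotypes,
            index=pd.Index(self.individuals, name="individual"),
            columns=[str(p) for p in self.positions],
        )


def _call_genotype(nuc_counts: np.ndarray, depth_total: int, depth_min: int,
                   het_maf: float) -> str:
    """Call one individual at one position from its 4-nucleotide counts."""
    if depth_total < depth_min:
        return MISSING * 2
    nuc_total = nuc_counts.sum()
    if nuc_total == 0:
        return MISSING * 2
    order = np.argsort(-nuc_counts, kind="stable")
    major, second = order[0], order[1]
    maf = 1.0 - nuc_counts[major] / nuc_total
    if maf > het_maf and nuc_counts[second] > 0:
        pair = sorted((NUCLEOTIDES[major], NUCLEOTIDES[second]))
        return pair[0] + pair[1]
    return NUCLEOTIDES[major] * 2


def window_genotype(
    counts: CountTable,
    individuals: list[str],
    chrom: str,
    center_pos: int,
    width_bp: int = 5_000,
    depth_min: int = 10,
    het_maf: float = 0.1,
    max_ind_missing: float = 0.25,
    max_snp_missing: float = 0.40,
    maf_min: float = 0.05,
    sites_filter_first: bool = False,
) -> WindowGenotypeMatrix:
    """Genotype and filter a window centred on an adaptive SNP.

    Candidate positions are all count-table sites within
    ``[center - width/2, center + width/2 - 1]``.  Per individual per
    position: missing below ``depth_min`` total reads; heterozygous when
    read MAF is strictly above ``het_maf``; else homozygous major.  Then
    individuals with a missing fraction above ``max_ind_missing`` are
    dropped, and among the remaining data positions are retained when their
    missing fraction is at most ``max_snp_missing`` and their called-allele
    MAF is at least ``maf_min`` (two alleles per homozygote, one of each
    per heterozygote, missing excluded).  ``sites_filter_first`` swaps the
    two filter stages for sensitivity analysis.
    """
    half = width_bp // 2
    lo, hi = center_pos - half, center_pos + width_bp - half - 1
    in_win = (counts.chrom == chrom) & (counts.pos >= lo) & (counts.pos <= hi)
    pos_idx = np.flatnonzero(in_win)
    log: list[str] = []
    if len(pos_idx) == 0:
        raise ValueError(f"window {chrom}:{lo}-{hi} contains no positions")

    col = [counts.sample_index(lab) for lab in individuals]
    sub = counts.counts[np.ix_(pos_idx, col)]
    depth_total = sub.sum(axis=2)
    nuc = sub[:, :, :4]

    n_pos, n_ind = len(pos_idx), len(individuals)
    geno = np.empty((n_ind, n_pos), dtype=object)
    for i in range(n_pos):
        for j in range(n_ind):
            geno[j, i] = _call_genotype(nuc[i, j], int(depth_total[i, j]),
                                        depth_min, het_maf)

    positions = counts.pos[pos_idx]

    def drop_individuals(g, ind_labels):
        miss = np.mean(np.equal(g, MISSING * 2), axis=1)
        keep = miss <= max_ind_missing
        for lab, m, k in zip(ind_labels, miss, keep):
            if not k:
                log.append(f"dropped individual {lab}: {m:.0%} missing")
        return g[keep], [lab for lab, k in zip(ind_labels, keep) if k]

    def drop_sites(g, pos):
        keep = np.ones(g.shape[1], dtype=bool)
        for i in range(g.shape[1]):
            calls = [c for c in g[:, i] if c != MISSING * 2]
            miss_frac = 1.0 - len(calls) / g.shape[0] if g.shape[0] else 1.0
            if miss_frac > max_snp_missing:
                keep[i] = False
                log.append(f"dropped site {chrom}:{pos[i]}: {miss_frac:.0%} missing")
                continue
            alleles = "".join(calls)
            if not alleles:
                keep[i] = False
                log.append(f"dropped site {chrom}:{pos[i]}: no calls")
                continue
            counts_ = pd.Series(list(alleles)).value_counts()
            maf = 1.0 - counts_.iloc[0] / counts_.sum()
            if maf < maf_min:
                keep[i] = False
                log.append(f"dropped site {chrom}:{pos[i]}: MAF {maf:.3f} < {maf_min}")
        return g[:, keep], pos[keep]

    kept_ind = list(individuals)
    if sites_filter_first:
        geno, positions = drop_sites(geno, positions)
        geno, kept_ind = drop_individuals(geno, kept_ind)
    else:
        geno, kept_ind = drop_individuals(geno, kept_ind)
        geno, positions = drop_sites(geno, positions)

    if not kept_ind:
        log.append("all individuals dropped")
    return WindowGenotypeMatrix(
        chrom=chrom,
        center_pos=center_pos,
        width_bp=width_bp,
        individuals=kept_ind,
        positions=positions,
        genotypes=geno if len(kept_ind) else np.empty((0, 0), dtype=object),
        filter_log=log,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_phasing_input(matrix: WindowGenotypeMatrix, path: str | Path) -> None:
    """Write a fastPHASE-style ``.inp`` file plus a TSV twin.

    ``.inp`` layout: number of individuals, number of sites, a ``P`` line
    of 1-based positions, then per individual an ``# id`` line followed by
    two haplotype-ambiguous allele lines (line 1 carries the alphabetically
    first allele of each genotype, line 2 the other; ``?`` for missing).
    The TSV twin (same stem, ``.tsv``) holds the genotype strings and
    round-trips via :func:`read_genotype_tsv`.
    """
    if matrix.n_individuals == 0 or matrix.n_sites == 0:
        raise ValueError("cannot export an empty genotype matrix")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{matrix.n_individuals}\n{matrix.n_sites}\n")
        fh.write("P " + " ".join(str(p) for p in matrix.positions) + "\n")
        for j, lab in enumerate(matrix.individuals):
            line1 = "".join(g[0] for g in matrix.genotypes[j])
            line2 = "".join(g[1] for g in matrix.genotypes[j])
            fh.write(f"# {lab}\n{line1}\n{line2}\n")
    tsv = path.with_suffix(".tsv")
    df = matrix.to_frame()
    df.insert(0, "chrom", matrix.chrom)
    df.reset_index().to_csv(tsv, sep="\t", index=False)


def read_genotype_tsv(path: str | Path, chrom: str | None = None,
                      center_pos: int = 0, width_bp: int = 5_000) -> WindowGenotypeMatrix:
    """Read back the TSV twin written by :func:`export_phasing_input`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    individuals = list(df["individual"])
    chrom = chrom if chrom is not None else str(df["chrom"].iloc[0])
    pos_cols = [c for c in df.columns if c not in ("individual", "chrom")]
    positions = np.asarray([int(c) for c in pos_cols], dtype=np.int64)
    geno = df[pos_cols].to_numpy(dtype=object)
    return WindowGenotypeMatrix(
        chrom=chrom,
        center_pos=center_pos,
        width_bp=width_bp,
        individuals=individuals,
        positions=positions,
        genotypes=geno,
    )
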