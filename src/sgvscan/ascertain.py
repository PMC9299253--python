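"""SNP ascertainment from individual-level and pool-level count tables.

Two ascertainment modes are provided, mirroring the two sequencing designs:

``indseq``
    individual whole-genome sequencing; sites qualify on minor-allele
    frequency computed from read counts summed across a reference set of
    individuals, a cumulative-depth ceiling over the same set (purging
    repeats), a per-sample depth floor of 1x over *all* individuals (no
    missing data), and a physical spacing filter (purging micro-indel
    clusters);
``poolseq``
    pooled sequencing of two contrast pools; sites qualify on combined
    depth range, combined minor-allele frequency, and a per-pool depth
    floor, then are genotyped (allele frequency = count / nucleotide depth)
    in every sample of the table.

Depth filters count all six read classes (including N and deletions);
allele frequencies are always computed over the four nucleotides only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NUC_INDEX, NUCLEOTIDES, CountTable


@dataclass
class AscertainParams:
    """Thresholds of one ascertainment run.

    Defaults are the indseq thresholds (MAF >= 0.04 across the marine
    reference individuals, cumulative depth <= 1000, >= 1x everywhere,
    >= 100 bp spacing); poolseq runs use ``maf_min=0.25``,
    ``depth_range_combined=(100, 500)`` and ``depth_min_per_pool=50``.
    """

    mode: str = "indseq"  # indseq | poolseq
    maf_min: float = 0.04
    depth_min_per_sample: int = 1
    depth_max_cumulative: int = 1000
    depth_range_combined: tuple[int, int] = (100, 500)
    depth_min_per_pool: int = 50
    spacing_min_bp: int = 100
    maf_reference_samples: list[str] = field(default_factory=list)
    #: if True, the spacing filter keeps the first member of each close
    #: pair instead of removing both (the default purges whole clusters)
    spacing_keep_one: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("indseq", "poolseq"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if self.spacing_min_bp < 0:
            raise ValueError("spacing_min_bp must be >= 0")
        lo, hi = self.depth_range_combined
        if lo < 0 or hi < lo:
            raise ValueError("invalid combined depth range")
        if self.depth_min_per_sample < 0 or self.depth_min_per_pool < 0:
            raise ValueError("depth thresholds must be >= 0")


POOLSEQ_DEFAULTS = dict(
    mode="poolseq",
    maf_min=0.25,
    depth_range_combined=(100, 500),
    depth_min_per_pool=50,
    spacing_min_bp=0,
)


def poolseq_params(**overrides) -> AscertainParams:
    """Convenience constructor with the pooled-contrast defaults."""
    kw = dict(POOLSEQ_DEFAULTS)
    kw.update(overrides)
    return AscertainParams(**kw)


@dataclass
class SnpSites:
    """Ascertained SNP sites with per-sample allele frequencies.

    ``freq`` holds, per site and sample, the frequency of each of the four
    nucleotides (A, T, C, G order) over that sample's nucleotide depth; rows
    with zero depth are NaN.  ``alleles`` lists, per site, the observed
    nucleotides ranked by total count across samples (2-4 characters).
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    alleles: list[str]
    freq: np.ndarray  # (n_sites, n_samples, 4)
    depth: np.ndarray  # (n_sites, n_samples) nucleotide depth

    def __post_init__(self) -> None:
        n = len(self.pos)
        if self.freq.shape != (n, len(self.samples), 4):
            raise ValueError("freq shape mismatch")
        if self.depth.shape != (n, len(self.samples)):
            raise ValueError("depth shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, label: str) -> int:
        try:
            return self.samples.index(label)
        except ValueError:
            raise KeyError(f"sample {label!r} not in SNP table") from None

    def take(self, idx) -> "SnpSites":
        idx = np.asarray(idx)
        return SnpSites(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            alleles=[self.alleles[i] for i in idx],
            freq=self.freq[idx],
            depth=self.depth[idx],
        )

    def site_key(self) -> dict[tuple[str, int], int]:
        return {(c, int(p)): i for i, (c, p) in enumerate(zip(self.chrom, self.pos))}

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: per-site alleles plus, per sample, the frequency
        of the top-ranked allele and the nucleotide depth."""
        df = pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "alleles": self.alleles}
        )
        rows = np.arange(self.n_sites)
        top = np.asarray(
            [NUC_INDEX[a[0]] if a else 0 for a in self.alleles], dtype=int
        )
        for j, lab in enumerate(self.samples):
            df[f"freq1_{lab}"] = self.freq[rows, j, top]
            df[f"depth_{lab}"] = self.depth[:, j]
        return df


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _ranked_alleles(total_nuc_counts: np.ndarray) -> list[str]:
    """Observed nucleotides per site, ranked by descending total count
    (ties by A,T,C,G order)."""
    out = []
    order_all = np.argsort(-total_nuc_counts, axis=1, kind="stable")
    for i in range(total_nuc_counts.shape[0]):
        obs = [NUCLEOTIDES[k] for k in order_all[i] if total_nuc_counts[i, k] > 0]
        out.append("".join(obs))
    return out


def _build_sites(counts: CountTable, keep: np.ndarray) -> SnpSites:
    sub = counts.take(np.flatnonzero(keep))
    nuc = sub.counts[:, :, :4].astype(float)
    depth = nuc.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = nuc / depth[:, :, None]
    total = sub.counts[:, :, :4].sum(axis=1)
    return SnpSites(
        samples=list(sub.samples),
        chrom=sub.chrom,
        pos=sub.pos,
        alleles=_ranked_alleles(total),
        freq=freq,
        depth=depth.astype(np.int64),
    )


def _maf_from_counts(nuc_counts: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per site from summed nucleotide counts:
    1 - (major-allele count / total).  Zero-depth sites get MAF 0."""
    total = nuc_counts.sum(axis=1)
    major = nuc_counts.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, 1.0 - major / np.where(total > 0, total, 1), 0.0)
    return maf


# ---------------------------------------------------------------------------
# spacing filter
# ---------------------------------------------------------------------------


def spacing_filter(sites: SnpSites, spacing_min_bp: int, keep_one: bool = False) -> SnpSites:
    """Purge SNPs closer than ``spacing_min_bp`` to a neighbouring SNP.

    By default *both* members of a close pair are removed (close clusters
    are treated as alignment artifacts wholesale); with ``keep_one`` the
    leftmost member of each run of close sites is retained instead.
    """
    if sites.n_sites == 0 or spacing_min_bp <= 0:
        return sites
    keep = np.ones(sites.n_sites, dtype=bool)
    same_next = sites.chrom[:-1] == sites.chrom[1:]
    gap = np.where(same_next, sites.pos[1:] - sites.pos[:-1], np.iinfo(np.int64).max)
    close = gap < spacing_min_bp
    if keep_one:
        # greedy left-to-right thinning within each run of close sites
        last_kept_pos = None
        last_chrom = None
        for i in range(sites.n_sites):
            if sites.chrom[i] != last_chrom:
                last_chrom, last_kept_pos = sites.chrom[i], sites.pos[i]
                continue
            if sites.pos[i] - last_kept_pos < spacing_min_bp:
                keep[i] = False
            else:
                last_kept_pos = sites.pos[i]
    else:
        keep[:-1] &= ~close
        keep[1:] &= ~close
    return sites.take(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# ascertainment
# ---------------------------------------------------------------------------


def ascertain_indseq(counts: CountTable, params: AscertainParams) -> SnpSites:
    """Individual-sequencing SNP ascertainment.

    Retains sites where (a) the MAF over read counts summed across the
    reference individuals is >= ``maf_min``; (b) cumulative depth across
    the reference individuals is <= ``depth_max_cumulative``; (c) every
    sample in the table has depth >= ``depth_min_per_sample``; then
    (d) applies the spacing filter to the survivors.
    """
    if params.mode != "indseq":
        raise ValueError("params.mode must be 'indseq'")
    ref = params.maf_reference_samples
    if not ref:
        raise ValueError("maf_reference_samples is empty")
    missing = [s for s in ref if s not in counts.samples]
    if missing:
        raise ValueError(f"reference samples not in count table: {missing}")
    ref_idx = [counts.sample_index(s) for s in ref]

    nuc_ref = counts.counts[:, ref_idx, :4].sum(axis=1)
    maf = _maf_from_counts(nuc_ref)
    depth_all = counts.depth()
    cum_ref = depth_all[:, ref_idx].sum(axis=1)

    keep = (
        (maf >= params.maf_min)
        & (cum_ref <= params.depth_max_cumulative)
        & (depth_all >= params.depth_min_per_sample).all(axis=1)
    )
    sites = _build_sites(counts, keep)
    return spacing_filter(sites, params.spacing_min_bp, params.spacing_keep_one)


def ascertain_poolseq(
    counts: CountTable, pool_a: str, pool_b: str, params: AscertainParams
) -> SnpSites:
    """Pooled-contrast SNP ascertainment.

    Retains sites whose combined read depth over the two contrast pools is
    within ``depth_range_combined`` (closed), whose combined-count MAF is
    >= ``maf_min``, and whose per-pool depth is >= ``depth_min_per_pool``;
    surviving sites are genotyped in *all* samples of the table.
    """
    if params.mode != "poolseq":
        raise ValueError("params.mode must be 'poolseq'")
    if pool_a == pool_b:
        raise ValueError("contrast pools must differ")
    ia, ib = counts.sample_index(pool_a), counts.sample_index(pool_b)

    depth_all = counts.depth()
    combined_depth = depth_all[:, ia] + depth_all[:, ib]
    nuc_comb = counts.counts[:, ia, :4] + counts.counts[:, ib, :4]
    maf = _maf_from_counts(nuc_comb)
    lo, hi = params.depth_range_combined

    keep = (
        (combined_depth >= lo)
        & (combined_depth <= hi)
        & (maf >= params.maf_min)
        & (depth_all[:, ia] >= params.depth_min_per_pool)
        & (depth_all[:, ib] >= params.depth_min_per_pool)
    )
    sites = _build_sites(counts, keep)
    if params.spacing_min_bp > 0:
        sites = spacing_filter(sites, params.spacing_min_bp, params.spacing_keep_one)
    return sites
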