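"""Adaptive and baseline SNP panels, acidic-allele frequency profiles, and
the distance-gradient contrast.

The adaptive panel collects autosomal SNPs with extreme acidic-basic AFD
(default >= 0.85), thinned so that any two panel members on a chromosome lie
at least 100 kb apart.  The baseline panel collects spaced SNPs whose AFD
sits at the genome-wide median (within a 0.1% relative band by default).
At each panel SNP the "acidic allele" is the nucleotide predominant in the
acidic pool (adaptive panel) or relatively more common in acidic than basic
fish (baseline panel); its frequency across the marine pools, ordered by
distance from the derived habitat, is the object of the gene flow-selection
balance vs. neutrality contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ascertain import SnpSites
from .diffstats import DiffProfile
from .io import NUCLEOTIDES, ChromTable, SampleManifest

logger = logging.getLogger(__name__)


@dataclass
class PanelParams:
    afd_min_adaptive: float = 0.85
    spacing_min_bp: int = 100_000
    baseline_n: int = 500
    baseline_tolerance: float = 0.001  # relative band around the genome median
    #: alternative reading of the baseline band: +/- this many percentile
    #: points of the AFD distribution instead of a relative value band
    baseline_band_mode: str = "relative_value"  # or "percentile"
    autosomal_only: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.afd_min_adaptive <= 1.0:
            raise ValueError("afd_min_adaptive must be in (0, 1]")
        if self.baseline_n < 1:
            raise ValueError("baseline_n must be >= 1")
        if self.baseline_band_mode not in ("relative_value", "percentile"):
            raise ValueError(f"unknown baseline_band_mode {self.baseline_band_mode!r}")


@dataclass
class SnpPanel:
    """An ordered panel of selected SNPs (a subset of ascertained sites)."""

    label: str  # 'adaptive' | 'baseline'
    sites: SnpSites
    afd: np.ndarray
    acidic_allele: np.ndarray | None = None
    tie_broken: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.sites.n_sites

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chrom": self.sites.chrom, "pos": self.sites.pos, "afd": self.afd}
        )
        if self.acidic_allele is not None:
            df["acidic_allele"] = self.acidic_allele
        return df


def _greedy_spacing(
    chrom: np.ndarray, pos: np.ndarray, order: np.ndarray, spacing_min_bp: int
) -> list[int]:
    """Accept candidates in the given order, each only if >= spacing from
    every already-accepted site on its chromosome; returns accepted indices."""
    accepted_pos: dict[str, list[int]] = {}
    accepted: list[int] = []
    for i in order:
        c, p = chrom[i], int(pos[i])
        others = accepted_pos.get(c)
        if others and min(abs(p - q) for q in others) < spacing_min_bp:
            continue
        accepted.append(int(i))
        accepted_pos.setdefault(c, []).append(p)
    return accepted


def select_adaptive(
    profile: DiffProfile, sites: SnpSites, chroms: ChromTable, params: PanelParams
) -> SnpPanel:
    """High-differentiation panel: autosomal SNPs with AFD >= the adaptive
    threshold, greedily thinned in descending AFD order (ties by coordinate)
    under the spacing constraint; output sorted by coordinate."""
    _check_aligned(profile, sites)
    autosomes = chroms.autosomes()
    if params.autosomal_only and not autosomes:
        raise ValueError("no chromosome is marked autosomal")
    mask = profile.afd >= params.afd_min_adaptive
    if params.autosomal_only:
        mask &= np.isin(sites.chrom, list(autosomes))
    cand = np.flatnonzero(mask & ~np.isnan(profile.afd))
    if len(cand) == 0:
        logger.warning("adaptive panel: no candidate SNPs above AFD threshold")
        return SnpPanel("adaptive", sites.take(cand), profile.afd[cand])
    # descending AFD, ties by genome coordinate
    order = cand[np.lexsort((sites.pos[cand], sites.chrom[cand].astype(str), -profile.afd[cand]))]
    accepted = _greedy_spacing(sites.chrom, sites.pos, order, params.spacing_min_bp)
    accepted = sorted(accepted, key=lambda i: (str(sites.chrom[i]), int(sites.pos[i])))
    idx = np.asarray(accepted, dtype=int)
    return SnpPanel("adaptive", sites.take(idx), profile.afd[idx])


def select_baseline(
    profile: DiffProfile, sites: SnpSites, chroms: ChromTable, params: PanelParams
) -> SnpPanel:
    """Median-differentiation panel: autosomal SNPs whose AFD lies within
    the tolerance band around the genome-wide median, spacing-thinned in
    seeded random order and, if oversubscribed, subsampled to
    ``baseline_n``; output sorted by coordinate."""
    _check_aligned(profile, sites)
    med = profile.genome_median_afd
    if not np.isfinite(med):
        raise ValueError("genome-wide median AFD unavailable")
    if params.baseline_band_mode == "relative_value":
        lo = med - params.baseline_tolerance * med
        hi = med + params.baseline_tolerance * med
        in_band = (profile.afd >= lo) & (profile.afd <= hi)
    else:
        # percentile reading: the band is +/- baseline_tolerance*100
        # percentile points around the median's rank
        pct = stats.rankdata(profile.afd, nan_policy="omit") / np.sum(~np.isnan(profile.afd))
        in_band = np.abs(pct - 0.5) <= params.baseline_tolerance
    mask = in_band & ~np.isnan(profile.afd)
    if params.autosomal_only:
        mask &= np.isin(sites.chrom, list(chroms.autosomes()))
    cand = np.flatnonzero(mask)
    if len(cand) == 0:
        raise ValueError("no baseline candidates within the median band")
    rng = np.random.default_rng(params.rng_seed)
    order = cand[rng.permutation(len(cand))]
    accepted = _greedy_spacing(sites.chrom, sites.pos, order, params.spacing_min_bp)
    if len(accepted) > params.baseline_n:
        pick = rng.choice(len(accepted), size=params.baseline_n, replace=False)
        accepted = [accepted[i] for i in pick]
    accepted = sorted(accepted, key=lambda i: (str(sites.chrom[i]), int(sites.pos[i])))
    idx = np.asarray(accepted, dtype=int)
    return SnpPanel("baseline", sites.take(idx), profile.afd[idx])


def _check_aligned(profile: DiffProfile, sites: SnpSites) -> None:
    if len(profile.pos) != sites.n_sites or not (
        np.array_equal(profile.pos, sites.pos) and np.array_equal(profile.chrom, sites.chrom)
    ):
        raise ValueError("differentiation profile is not aligned to the SNP table")


def define_acidic_allele(
    panel: SnpPanel, acidic_label: str, basic_label: str, rng_seed: int = 0
) -> SnpPanel:
    """Set the acidic allele at every panel SNP.

    Adaptive panel: the nucleotide with maximal frequency in the acidic
    pool.  Baseline panel: the nucleotide maximizing freq_acidic -
    freq_basic.  Exact ties are broken by a seeded uniform draw and flagged.
    """
    sites = panel.sites
    ia, ib = sites.sample_index(acidic_label), sites.sample_index(basic_label)
    fa, fb = sites.freq[:, ia, :], sites.freq[:, ib, :]
    score = fa if panel.label == "adaptive" else fa - fb
    rng = np.random.default_rng(rng_seed)
    allele = np.empty(sites.n_sites, dtype=object)
    tie = np.zeros(sites.n_sites, dtype=bool)
    for i in range(sites.n_sites):
        s = score[i]
        if np.all(np.isnan(s)):
            raise ValueError(
                f"cannot define acidic allele at {sites.chrom[i]}:{sites.pos[i]}: "
                "no reads in the contrast pools"
            )
        if np.nanmax(fa[i]) == 1.0 and np.nanmax(fb[i]) == 1.0 and (
            int(np.nanargmax(fa[i])) == int(np.nanargmax(fb[i]))
        ):
            raise ValueError(
                f"site {sites.chrom[i]}:{sites.pos[i]} is monomorphic in both pools"
            )
        best = np.nanmax(s)
        tied = np.flatnonzero(s == best)
        if len(tied) > 1:
            choice = int(rng.choice(tied))
            tie[i] = True
            logger.info(
                "acidic-allele tie at %s:%d broken to %s",
                sites.chrom[i], sites.pos[i], NUCLEOTIDES[choice],
            )
        else:
            choice = int(tied[0])
        allele[i] = NUCLEOTIDES[choice]
    return SnpPanel(panel.label, sites, panel.afd, acidic_allele=allele, tie_broken=tie)


@dataclass
class FrequencyProfile:
    """Acidic-allele frequency matrix of one panel across sample pools."""

    panel_label: str
    chrom: np.ndarray
    pos: np.ndarray
    acidic_allele: np.ndarray
    freq: pd.DataFrame  # sites x sample columns
    marine_labels: list[str]  # ordered by increasing distance rank
    distance_ranks: np.ndarray
    pool_medians: pd.Series  # per marine pool
    overall_marine_median: float
    minor_subset: np.ndarray  # boolean mask over sites

    def minor_profile(self) -> "FrequencyProfile":
        """Restrict to the SNPs whose acidic allele is the minor allele in
        every marine pool."""
        m = self.minor_subset
        sub = self.freq.loc[m]
        marine = sub[self.marine_labels]
        return FrequencyProfile(
            panel_label=self.panel_label + "_minor",
            chrom=self.chrom[m],
            pos=self.pos[m],
            acidic_allele=self.acidic_allele[m],
            freq=sub.reset_index(drop=True),
            marine_labels=list(self.marine_labels),
            distance_ranks=self.distance_ranks,
            pool_medians=marine.median(),
            overall_marine_median=float(np.nanmedian(marine.to_numpy())) if len(sub) else float("nan"),
            minor_subset=np.ones(len(sub), dtype=bool),
        )


def profile_frequencies(
    panel: SnpPanel,
    manifest: SampleManifest,
    combine: dict[str, list[str]] | None = None,
) -> FrequencyProfile:
    """Frequency of the acidic allele at each panel SNP in every sample.

    ``combine`` optionally builds extra pools by summing the nucleotide
    counts of individually sequenced samples (the combined frequency is the
    depth-weighted mean of member frequencies, i.e. exactly the frequency
    of the summed counts); combined pools inherit habitat and distance rank
    from their first member's manifest row unless that member is itself a
    marine pool.
    """
    if panel.acidic_allele is None:
        raise ValueError("acidic allele not defined; run define_acidic_allele first")
    sites = panel.sites
    allele_idx = np.asarray(
        [NUCLEOTIDES.index(a) for a in panel.acidic_allele], dtype=np.int64
    )
    rows = np.arange(sites.n_sites)

    data: dict[str, np.ndarray] = {}
    for lab in sites.samples:
        j = sites.sample_index(lab)
        col = sites.freq[rows, j, allele_idx]
        if np.isnan(col).any():
            k = int(np.flatnonzero(np.isnan(col))[0])
            raise ValueError(
                f"panel site {sites.chrom[k]}:{sites.pos[k]} has no reads in sample {lab}"
            )
        data[lab] = col

    rank_map: dict[str, int] = {}
    mtab = manifest.table
    for _, r in mtab[(mtab["kind"] == "pool") & (mtab["habitat"] == "marine")].iterrows():
        if not pd.isna(r["distance_rank"]):
            rank_map[r["label"]] = int(r["distance_rank"])

    if combine:
        for new_label, members in combine.items():
            miss = [m for m in members if m not in sites.samples]
            if miss:
                raise KeyError(f"combine members missing from SNP table: {miss}")
            idx = [sites.sample_index(m) for m in members]
            d = sites.depth[:, idx].astype(float)
            f = sites.freq[rows[:, None], idx, allele_idx[:, None]]
            num = (f * d).sum(axis=1)
            den = d.sum(axis=1)
            if np.any(den == 0):
                k = int(np.flatnonzero(den == 0)[0])
                raise ValueError(
                    f"combined pool {new_label} has no reads at "
                    f"{sites.chrom[k]}:{sites.pos[k]}"
                )
            data[new_label] = num / den
            ranks = {int(manifest.row(m)["distance_rank"]) for m in members
                     if not pd.isna(manifest.row(m)["distance_rank"])}
            if len(ranks) == 1:
                rank_map[new_label] = ranks.pop()

    freq = pd.DataFrame(data)
    marine_labels = sorted(rank_map, key=lambda k: rank_map[k])
    marine_labels = [m for m in marine_labels if m in freq.columns]
    if not marine_labels:
        raise ValueError("no marine pools with distance ranks available")
    marine = freq[marine_labels]
    minor = (marine.to_numpy() < 0.5).all(axis=1)
    return FrequencyProfile(
        panel_label=panel.label,
        chrom=sites.chrom,
        pos=sites.pos,
        acidic_allele=panel.acidic_allele,
        freq=freq,
        marine_labels=marine_labels,
        distance_ranks=np.asarray([rank_map[m] for m in marine_labels]),
        pool_medians=marine.median(),
        overall_marine_median=float(np.nanmedian(marine.to_numpy())),
        minor_subset=minor,
    )


@dataclass
class GradientResult:
    statistic: float  # Spearman rho of per-pool median vs distance rank
    p_value: float  # one-sided, for a negative correlation
    n_permutations: int
    pool_medians: pd.Series


def gradient_contrast(
    fp: FrequencyProfile, n_permutations: int = 999, rng_seed: int = 0
) -> GradientResult:
    """Test for a decline of acidic-allele frequency with distance.

    Statistic: Spearman rank correlation between distance rank and the
    per-pool median acidic-allele frequency.  The null is built by randomly
    permuting the pool medians over the ranks; the one-sided p-value is the
    permutation probability of a correlation at least as negative as
    observed (add-one correction).
    """
    if len(fp.marine_labels) < 3:
        raise ValueError("need at least 3 marine pools with distinct distance ranks")
    ranks = fp.distance_ranks.astype(float)
    if len(np.unique(ranks)) < 3:
        raise ValueError("need at least 3 distinct distance ranks")
    medians = fp.pool_medians[fp.marine_labels].to_numpy(dtype=float)

    def rho(vals: np.ndarray) -> float:
        # constant medians leave the correlation undefined; score them 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            r = stats.spearmanr(ranks, vals).statistic
        return 0.0 if np.isnan(r) else float(r)

    obs = rho(medians)
    rng = np.random.default_rng(rng_seed)
    hits = 0
    for _ in range(n_permutations):
        if rho(rng.permutation(medians)) <= obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return GradientResult(
        statistic=obs,
        p_value=p,
        n_permutations=n_permutations,
        pool_medians=fp.pool_medians[fp.marine_labels],
    )
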