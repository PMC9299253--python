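"""Differentiation statistics: AFD, Nei FST, sliding-window scans and
pairwise sample matrices.

The absolute allele frequency difference (AFD) between two samples at a SNP
is half the L1 distance between their allele-frequency vectors; for a
biallelic site this reduces to the absolute difference of either allele's
frequencies.  Nei's FST is the two-sample G_ST, (H_T - H_S) / H_T, computed
from unweighted mean allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ascertain import SnpSites

_SUM_TOL = 1e-9


def _validate_pair(freqs_a, freqs_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"allele vectors differ in length: {a.shape} vs {b.shape}")
    for name, v in (("first", a), ("second", b)):
        if np.any(v < -_SUM_TOL) or abs(v.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"{name} frequency vector is not normalized: {v}")
    return a, b


def afd(freqs_a, freqs_b) -> float:
    """Absolute allele frequency difference: 0.5 * sum |p_a - p_b|."""
    a, b = _validate_pair(freqs_a, freqs_b)
    return 0.5 * float(np.abs(a - b).sum())


def nei_fst(freqs_a, freqs_b) -> float:
    """Two-sample Nei FST (G_ST): (H_T - H_S) / H_T with unweighted mean
    frequencies; 0 when both samples are monomorphic for the same allele."""
    a, b = _validate_pair(freqs_a, freqs_b)
    hs = 1.0 - 0.5 * (float(np.square(a).sum()) + float(np.square(b).sum()))
    pbar = 0.5 * (a + b)
    ht = 1.0 - float(np.square(pbar).sum())
    if ht <= 0.0:
        return 0.0
    return (ht - hs) / ht


# vectorized forms over SnpSites frequency arrays ---------------------------


def afd_vector(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Per-site AFD for two (n_sites, n_alleles) frequency arrays."""
    return 0.5 * np.abs(fa - fb).sum(axis=1)


def nei_fst_vector(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    hs = 1.0 - 0.5 * (np.square(fa).sum(axis=1) + np.square(fb).sum(axis=1))
    pbar = 0.5 * (fa + fb)
    ht = 1.0 - np.square(pbar).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    out[np.isnan(hs) | np.isnan(ht)] = np.nan
    return out


@dataclass
class DiffProfile:
    """Per-SNP and windowed differentiation for one sample contrast."""

    contrast: tuple[str, str]
    chrom: np.ndarray
    pos: np.ndarray
    afd: np.ndarray
    fst: np.ndarray | None
    windows: pd.DataFrame  # chrom, start, end, mean_afd, n_snps
    genome_median_afd: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos, "afd": self.afd})
        if self.fst is not None:
            df["fst"] = self.fst
        return df


def window_scan(
    chrom: np.ndarray,
    pos: np.ndarray,
    values: np.ndarray,
    window_bp: int = 10_000,
    step_bp: int = 5_000,
    min_snps: int = 6,
) -> pd.DataFrame:
    """Sliding-window means of a per-SNP statistic.

    Windows start at 1, 1+step, ... on each chromosome and span
    ``[start, start + window_bp - 1]``; windows containing fewer than
    ``min_snps`` SNPs are discarded.
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    rows = []
    for c in pd.unique(pd.Series(chrom)):
        m = chrom == c
        p = pos[m]
        v = values[m]
        if len(p) == 0:
            continue
        max_pos = int(p.max())
        start = 1
        while start <= max_pos:
            end = start + window_bp - 1
            inside = (p >= start) & (p <= end)
            n = int(inside.sum())
            if n >= min_snps:
                rows.append((c, start, end, float(np.nanmean(v[inside])), n))
            start += step_bp
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_afd", "n_snps"])
    return df.astype({"start": np.int64, "end": np.int64,
                      "mean_afd": float, "n_snps": np.int64})


def contrast_profile(
    sites: SnpSites,
    sample_a: str,
    sample_b: str,
    window_bp: int = 10_000,
    step_bp: int = 5_000,
    min_snps: int = 6,
    with_fst: bool = True,
) -> DiffProfile:
    """Per-SNP AFD (and FST) plus window scan for one contrast."""
    ia, ib = sites.sample_index(sample_a), sites.sample_index(sample_b)
    fa, fb = sites.freq[:, ia, :], sites.freq[:, ib, :]
    per_snp_afd = afd_vector(fa, fb)
    per_snp_fst = nei_fst_vector(fa, fb) if with_fst else None
    windows = window_scan(sites.chrom, sites.pos, per_snp_afd, window_bp, step_bp, min_snps)
    return DiffProfile(
        contrast=(sample_a, sample_b),
        chrom=sites.chrom,
        pos=sites.pos,
        afd=per_snp_afd,
        fst=per_snp_fst,
        windows=windows,
        genome_median_afd=float(np.nanmedian(per_snp_afd)) if len(per_snp_afd) else float("nan"),
    )


def pairwise_matrix(sites: SnpSites, labels: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric matrices of genome-wide median per-SNP AFD and Nei FST
    over all pairs of the given samples; diagonals are 0."""
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    idx = [sites.sample_index(lab) for lab in labels]
    n = len(labels)
    med_afd = np.zeros((n, n))
    med_fst = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fa, fb = sites.freq[:, idx[i], :], sites.freq[:, idx[j], :]
            a = float(np.nanmedian(afd_vector(fa, fb)))
            f = float(np.nanmedian(nei_fst_vector(fa, fb)))
            med_afd[i, j] = med_afd[j, i] = a
            med_fst[i, j] = med_fst[j, i] = f
    return (
        pd.DataFrame(med_afd, index=labels, columns=labels),
        pd.DataFrame(med_fst, index=labels, columns=labels),
    )


def pairwise_mean_fst(sites: SnpSites, labels: list[str]) -> float:
    """Mean per-SNP two-sample Nei FST over all pairs of the given samples
    (the quantity the synthetic generator's background FST calibrates)."""
    idx = [sites.sample_index(lab) for lab in labels]
    vals = []
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            vals.append(np.nanmean(nei_fst_vector(sites.freq[:, idx[i], :], sites.freq[:, idx[j], :])))
    return float(np.mean(vals))
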