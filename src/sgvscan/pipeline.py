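"""End-to-end convenience chains over the stage modules."""

from __future__ import annotations

from dataclasses import dataclass

from .ascertain import SnpSites, ascertain_poolseq, poolseq_params
from .diffstats import DiffProfile, contrast_profile
from .io import ChromTable, CountTable, SampleManifest
from .panels import (
    FrequencyProfile,
    GradientResult,
    PanelParams,
    SnpPanel,
    define_acidic_allele,
    gradient_contrast,
    profile_frequencies,
    select_adaptive,
)


@dataclass
class ScanResult:
    sites: SnpSites
    profile: DiffProfile
    adaptive_panel: SnpPanel
    frequency_profile: FrequencyProfile


def acidic_basic_scan(
    counts: CountTable,
    manifest: SampleManifest,
    chroms: ChromTable,
    acidic_label: str = "acidic",
    basic_label: str = "basic",
    ascertain_overrides: dict | None = None,
    panel_params: PanelParams | None = None,
) -> ScanResult:
    """poolSeq ascertainment -> acidic-basic AFD scan -> adaptive panel ->
    acidic-allele frequency profile across the marine pools."""
    params = poolseq_params(**(ascertain_overrides or {}))
    sites = ascertain_poolseq(counts, acidic_label, basic_label, params)
    profile = contrast_profile(sites, acidic_label, basic_label)
    pp = panel_params or PanelParams()
    panel = select_adaptive(profile, sites, chroms, pp)
    panel = define_acidic_allele(panel, acidic_label, basic_label, rng_seed=pp.rng_seed)
    fp = profile_frequencies(panel, manifest)
    return ScanResult(sites=sites, profile=profile, adaptive_panel=panel,
                      frequency_profile=fp)


def run_gradient_analysis(
    counts: CountTable,
    manifest: SampleManifest,
    chroms: ChromTable,
    n_permutations: int = 999,
    rng_seed: int = 0,
    **scan_kwargs,
) -> tuple[ScanResult, GradientResult]:
    """Full chain ending in the distance-gradient permutation test."""
    scan = acidic_basic_scan(counts, manifest, chroms, **scan_kwargs)
    grad = gradient_contrast(scan.frequency_profile, n_permutations, rng_seed)
    return scan, grad
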