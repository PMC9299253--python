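import numpy as np
import pandas as pd
import pytest

from _oracles import all_admissible_subsets, oracle_greedy_panel
from sgvscan.ascertain import SnpSites, ascertain_poolseq, poolseq_params
from sgvscan.diffstats import contrast_profile
from sgvscan.io import ChromTable, SampleManifest
from sgvscan.panels import (
    PanelParams,
    define_acidic_allele,
    gradient_contrast,
    profile_frequencies,
    select_adaptive,
    select_baseline,
)


def chroms_table(names=("chrI", "chrII"), length=10_000_000, sex=()):
    return ChromTable(pd.DataFrame({
        "chrom": list(names),
        "length_bp": [length] * len(names),
        "autosomal": [c not in sex for c in names],
    }))


def biallelic_sites(coords, freqs_by_sample, depth=100):
    """freqs_by_sample: {label: [freq of allele A per site]} (rest is T)."""
    labels = list(freqs_by_sample)
    n = len(coords)
    freq = np.zeros((n, len(labels), 4))
    for j, lab in enumerate(labels):
        f = np.asarray(freqs_by_sample[lab], dtype=float)
        freq[:, j, 0], freq[:, j, 1] = f, 1 - f
    return SnpSites(
        samples=labels,
        chrom=np.asarray([c for c, _ in coords], dtype=object),
        pos=np.asarray([p for _, p in coords], dtype=np.int64),
        alleles=["AT"] * n,
        freq=freq,
        depth=np.full((n, len(labels)), depth, dtype=np.int64),
    )


def panel_coords(panel):
    return set(zip(panel.sites.chrom, (int(p) for p in panel.sites.pos)))


class TestSelectAdaptive:
    def test_threshold_spacing_and_sex_exclusion(self):
        coords = [("chrI", 1_000), ("chrI", 40_000), ("chrI", 500_000),
                  ("chrX", 10_000)]
        fa = [0.95, 1.00, 0.97, 1.00]
        fb = [0.05, 0.05, 0.02, 0.00]
        sites = biallelic_sites(coords, {"acidic": fa, "basic": fb})
        prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
        panel = select_adaptive(
            prof, sites, chroms_table(("chrI", "chrX"), sex=("chrX",)),
            PanelParams())
        # chrI:1000 and chrI:40000 are closer than 100 kb: the higher-AFD
        # site (40000, AFD 0.95) wins; the sex-linked SNP is excluded
        assert panel_coords(panel) == {("chrI", 40_000), ("chrI", 500_000)}
        # output sorted by coordinate
        assert list(panel.sites.pos) == [40_000, 500_000]

    def test_every_member_meets_threshold_and_spacing(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 400, replace=False))
        coords = [("chrI", int(p)) for p in pos]
        fa = rng.uniform(0.5, 1.0, 400)
        fb = rng.uniform(0.0, 0.5, 400)
        sites = biallelic_sites(coords, {"acidic": fa, "basic": fb})
        prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
        panel = select_adaptive(prof, sites, chroms_table(("chrI",)), PanelParams())
        assert panel.n_sites > 0
        assert np.all(panel.afd >= 0.85)
        assert np.all(np.diff(panel.sites.pos) >= 100_000)

    def test_matches_greedy_oracle(self):
        for seed in range(200):
            rng = np.random.default_rng(40_000 + seed)
            n = int(rng.integers(1, 25))
            chrom = np.sort(rng.choice(["chrI", "chrII"], size=n))
            pos_col = []
            for c in ("chrI", "chrII"):
                k = int(np.sum(chrom == c))
                pos_col += sorted(rng.choice(np.arange(1, 4_000), size=k,
                                             replace=False).tolist())
            coords = list(zip(chrom.tolist(), pos_col))
            fa = rng.uniform(0.9, 1.0, n)  # all pass the 0.85 threshold
            sites = biallelic_sites(coords, {"acidic": fa, "basic": np.zeros(n)})
            prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
            spacing = int(rng.integers(1, 1_500))
            panel = select_adaptive(
                prof, sites, chroms_table(),
                PanelParams(afd_min_adaptive=0.85, spacing_min_bp=spacing))
            cands = [(float(a), c, p) for a, (c, p) in zip(prof.afd, coords)]
            assert panel_coords(panel) == oracle_greedy_panel(cands, spacing), seed

    def test_greedy_result_is_maximal_admissible(self):
        # on tiny instances, the greedy panel must be admissible and not
        # extendable by any leftover candidate
        for seed in range(40):
            rng = np.random.default_rng(50_000 + seed)
            n = int(rng.integers(1, 7))
            pos = sorted(rng.choice(np.arange(1, 60), size=n, replace=False).tolist())
            coords = [("chrI", int(p)) for p in pos]
            fa = rng.uniform(0.9, 1.0, n)
            sites = biallelic_sites(coords, {"acidic": fa, "basic": np.zeros(n)})
            prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
            spacing = int(rng.integers(1, 30))
            panel = select_adaptive(
                prof, sites, chroms_table(("chrI",)),
                PanelParams(spacing_min_bp=spacing))
            got = panel_coords(panel)
            cands = [(float(a), c, p) for a, (c, p) in zip(prof.afd, coords)]
            admissible = all_admissible_subsets(cands, spacing)
            assert got in admissible, seed
            for extra in set((c, p) for _, c, p in cands) - got:
                assert got | {extra} not in admissible, (seed, extra)

    def test_empty_when_nothing_qualifies(self):
        sites = biallelic_sites([("chrI", 10)], {"acidic": [0.6], "basic": [0.4]})
        prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
        panel = select_adaptive(prof, sites, chroms_table(("chrI",)), PanelParams())
        assert panel.n_sites == 0


class TestSelectBaseline:
    def make(self, n=2_000, seed=3):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 20_000_000), n, replace=False))
        coords = [("chrI", int(p)) for p in pos]
        fa = rng.uniform(0, 1, n)
        fb = np.clip(fa + rng.normal(0, 0.2, n), 0, 1)
        sites = biallelic_sites(coords, {"acidic": fa, "basic": fb})
        prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
        return sites, prof

    def test_band_membership_spacing_and_size(self):
        sites, prof = self.make()
        params = PanelParams(baseline_n=20, baseline_tolerance=0.05,
                             spacing_min_bp=50_000, rng_seed=7)
        panel = select_baseline(prof, sites, chroms_table(("chrI",)), params)
        med = prof.genome_median_afd
        assert panel.n_sites == 20
        assert np.all(np.abs(panel.afd - med) <= 0.05 * med + 1e-12)
        assert np.all(np.diff(panel.sites.pos) >= 50_000)

    def test_same_seed_reproducible(self):
        sites, prof = self.make()
        params = PanelParams(baseline_n=20, baseline_tolerance=0.05,
                             spacing_min_bp=50_000, rng_seed=7)
        p1 = select_baseline(prof, sites, chroms_table(("chrI",)), params)
        p2 = select_baseline(prof, sites, chroms_table(("chrI",)), params)
        assert panel_coords(p1) == panel_coords(p2)

    def test_empty_band_rejected(self):
        sites = biallelic_sites(
            [("chrI", 10), ("chrI", 200_000)],
            {"acidic": [0.9, 0.1], "basic": [0.1, 0.9]})
        prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
        params = PanelParams(baseline_tolerance=1e-9)
        # move every per-SNP AFD off the cached genome median so the band
        # (relative width 1e-9) contains no candidate
        prof.afd[:] = [0.81, 0.79]
        with pytest.raises(ValueError, match="baseline"):
            select_baseline(prof, sites, chroms_table(("chrI",)), params)


class TestDefineAcidicAllele:
    def test_adaptive_takes_acidic_major_allele(self):
        sites = biallelic_sites(
            [("chrI", 10), ("chrI", 200_000)],
            {"acidic": [0.95, 0.05], "basic": [0.05, 0.95]})
        prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
        panel = select_adaptive(prof, sites, chroms_table(("chrI",)), PanelParams())
        panel = define_acidic_allele(panel, "acidic", "basic")
        # site 1: A predominant in acidic; site 2: T predominant
        assert list(panel.acidic_allele) == ["A", "T"]
        assert not panel.tie_broken.any()

    def test_baseline_takes_largest_frequency_excess(self):
        sites = biallelic_sites(
            [("chrI", 10)], {"acidic": [0.55], "basic": [0.55]}, depth=100)
        prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
        # force a baseline-style panel at this site
        from sgvscan.panels import SnpPanel
        panel = SnpPanel("baseline", sites, prof.afd)
        # equal excess for A and T (both 0) -> seeded tie-break, flagged
        out1 = define_acidic_allele(panel, "acidic", "basic", rng_seed=5)
        out2 = define_acidic_allele(panel, "acidic", "basic", rng_seed=5)
        assert out1.tie_broken[0]
        assert out1.acidic_allele[0] == out2.acidic_allele[0]

    def test_monomorphic_in_both_pools_rejected(self):
        sites = biallelic_sites(
            [("chrI", 10)], {"acidic": [1.0], "basic": [1.0]})
        from sgvscan.panels import SnpPanel
        panel = SnpPanel("adaptive", sites, np.asarray([0.0]))
        with pytest.raises(ValueError, match="monomorphic"):
            define_acidic_allele(panel, "acidic", "basic")


def marine_manifest(pools):
    rows = [{"label": "acidic", "kind": "pool", "habitat": "acidic",
             "location": "x", "distance_rank": pd.NA},
            {"label": "basic", "kind": "pool", "habitat": "basic",
             "location": "x", "distance_rank": pd.NA}]
    for lab, rank in pools:
        rows.append({"label": lab, "kind": "pool", "habitat": "marine",
                     "location": lab, "distance_rank": rank})
    return SampleManifest(pd.DataFrame(rows))


def profile_for(marine_freqs, acidic=0.95, basic=0.05, n=9):
    """Panel of n SNPs; marine_freqs maps label -> constant acidic-A freq."""
    coords = [("chrI", 1 + 200_000 * i) for i in range(n)]
    by = {"acidic": [acidic] * n, "basic": [basic] * n}
    ranks = []
    for r, (lab, f) in enumerate(marine_freqs.items()):
        by[lab] = [f] * n
        ranks.append((lab, r))
    sites = biallelic_sites(coords, by)
    prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
    panel = select_adaptive(prof, sites, chroms_table(("chrI",)), PanelParams())
    panel = define_acidic_allele(panel, "acidic", "basic")
    return profile_frequencies(panel, marine_manifest(ranks))


class TestProfileFrequencies:
    def test_extracts_acidic_allele_frequency_by_rank(self):
        fp = profile_for({"m0": 0.4, "m1": 0.2, "m2": 0.1})
        assert fp.marine_labels == ["m0", "m1", "m2"]
        assert fp.pool_medians.tolist() == pytest.approx([0.4, 0.2, 0.1])
        assert fp.overall_marine_median == pytest.approx(0.2)
        # every marine frequency < 0.5 -> all sites are in the minor subset
        assert fp.minor_subset.all()
        minor = fp.minor_profile()
        assert minor.overall_marine_median == pytest.approx(0.2)

    def test_minor_subset_requires_minor_in_every_pool(self):
        fp = profile_for({"m0": 0.6, "m1": 0.2, "m2": 0.1})
        assert not fp.minor_subset.any()

    def test_combined_pool_is_depth_weighted(self):
        coords = [("chrI", 1)]
        by = {"acidic": [0.95], "basic": [0.05], "i1": [1.0], "i2": [0.0],
              "m0": [0.3], "m1": [0.3], "m2": [0.3]}
        sites = biallelic_sites(coords, by)
        sites.depth[:, sites.sample_index("i1")] = 30
        sites.depth[:, sites.sample_index("i2")] = 10
        prof = contrast_profile(sites, "acidic", "basic", min_snps=1)
        panel = select_adaptive(prof, sites, chroms_table(("chrI",)), PanelParams())
        panel = define_acidic_allele(panel, "acidic", "basic")
        rows = marine_manifest([("m0", 0), ("m1", 1), ("m2", 2)]).table
        rows = rows.to_dict("records") + [
            {"label": "i1", "kind": "individual", "habitat": "marine",
             "location": "y", "distance_rank": pd.NA, "n_individuals": 1},
            {"label": "i2", "kind": "individual", "habitat": "marine",
             "location": "y", "distance_rank": pd.NA, "n_individuals": 1},
        ]
        manifest = SampleManifest(pd.DataFrame(rows))
        fp = profile_frequencies(panel, manifest,
                                 combine={"joint": ["i1", "i2"]})
        # (1.0*30 + 0.0*10) / 40
        assert fp.freq["joint"].iloc[0] == pytest.approx(0.75)


class TestGradientContrast:
    def test_monotone_decline_detected(self):
        fp = profile_for({f"m{i}": 0.4 * 0.5**i for i in range(6)})
        res = gradient_contrast(fp, n_permutations=999, rng_seed=1)
        assert res.statistic == pytest.approx(-1.0)
        # 6 pools: the monotone ordering is 1 of 720 permutations
        assert res.p_value < 0.01

    def test_flat_profile_not_significant(self):
        fp = profile_for({f"m{i}": 0.3 for i in range(6)})
        res = gradient_contrast(fp, n_permutations=999, rng_seed=1)
        assert res.statistic == 0.0
        assert res.p_value > 0.05

    def test_increasing_profile_not_significant(self):
        fp = profile_for({f"m{i}": 0.1 + 0.05 * i for i in range(6)})
        res = gradient_contrast(fp, n_permutations=999, rng_seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value > 0.5

    def test_too_few_pools_rejected(self):
        fp = profile_for({"m0": 0.4, "m1": 0.2})
        with pytest.raises(ValueError, match="3"):
            gradient_contrast(fp)

    def test_permutation_p_reproducible(self):
        fp = profile_for({"m0": 0.4, "m1": 0.35, "m2": 0.2, "m3": 0.25})
        r1 = gradient_contrast(fp, n_permutations=499, rng_seed=9)
        r2 = gradient_contrast(fp, n_permutations=499, rng_seed=9)
        assert r1.p_value == r2.p_value


class TestOnSimulatedStudy:
    def test_adaptive_panel_recovers_planted_sites(self, small_study):
        cfg, truth, counts = small_study
        sites = ascertain_poolseq(counts, "acidic", "basic", poolseq_params())
        prof = contrast_profile(sites, "acidic", "basic")
        panel = select_adaptive(prof, sites, cfg.chrom_table(), PanelParams())
        planted = set(zip(truth.chrom[truth.planted_mask()],
                          (int(p) for p in truth.pos[truth.planted_mask()])))
        got = panel_coords(panel)
        assert len(got & planted) / len(got) > 0.9

    def test_baseline_panel_sits_at_genome_median(self, small_study):
        cfg, truth, counts = small_study
        sites = ascertain_poolseq(counts, "acidic", "basic", poolseq_params())
        prof = contrast_profile(sites, "acidic", "basic")
        params = PanelParams(baseline_n=100, baseline_tolerance=0.05,
                             spacing_min_bp=10_000)
        panel = select_baseline(prof, sites, cfg.chrom_table(), params)
        med = prof.genome_median_afd
        assert abs(float(np.median(panel.afd)) - med) <= 0.05 * med
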