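"""Synthetic study generator: truth tables, read counts, and on-disk fixtures.

Emulates the sequencing design behind the acidic-adaptation scan: an acidic
and a basic freshwater pool of pooled individuals, several marine pools
ordered by swimming distance from the derived habitat, and a handful of
individually sequenced fish.  Two generative scenarios are supported for the
planted adaptive loci:

``neutral_flat``
    the acidic allele segregates at the same frequency in every marine
    sample, whatever its distance rank (selective neutrality);
``gene_flow_decline``
    its frequency decays geometrically with distance rank
    (gene flow-selection balance).

Neutral background sites follow a Balding-Nichols model: an ancestral
frequency drawn uniformly, and per-sample frequencies drawn from a Beta
distribution around it with a habitat-specific drift parameter calibrated so
that the expected per-SNP two-sample Nei FST within a habitat group matches
the configured background value (see docs/methods.md for the calibration).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    NUCLEOTIDES,
    NUC_INDEX,
    ChromTable,
    CountTable,
    FormatError,
    SampleManifest,
    read_chroms,
    read_counts,
    read_manifest,
    write_chroms,
    write_counts,
    write_manifest,
)

SCENARIOS = ("neutral_flat", "gene_flow_decline")


@dataclass(frozen=True)
class PoolSpec:
    label: str
    habitat: str  # acidic | basic | marine
    n_individuals: int
    target_depth: float


@dataclass(frozen=True)
class IndividualSpec:
    label: str
    habitat: str
    target_depth: float


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults mirror the sequencing design the generator emulates: seven
    pools at 85x median depth (one acidic and one basic pool of 100
    individuals, six marine pools ordered by swimming distance from the
    derived habitat) and individually sequenced fish at 16x.
    """

    n_chromosomes: int = 21
    chrom_length_bp: int = 21_000_000
    n_neutral_sites: int = 10_000
    n_planted_adaptive: int = 50
    pool_specs: list[PoolSpec] = field(default_factory=list)
    individual_specs: list[IndividualSpec] = field(default_factory=list)
    scenario: str = "neutral_flat"
    marine_distance_ranks: dict[str, int] = field(default_factory=dict)
    acidic_allele_marine_freq: float = 0.30
    decline_rate: float = 0.5
    background_fst_freshwater: float = 0.068
    background_fst_marine: float = 0.019
    seq_error_rate: float = 0.002
    min_site_spacing_bp: int = 150
    sex_chromosome: str | None = "chrXIX"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in (
            "acidic_allele_marine_freq",
            "decline_rate",
            "background_fst_freshwater",
            "background_fst_marine",
            "seq_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_planted_adaptive < 0:
            raise ValueError("n_planted_adaptive must be >= 0")
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ValueError("need at least one chromosome of positive length")
        for spec in self.pool_specs:
            if spec.target_depth < 1:
                raise ValueError(f"pool {spec.label}: target_depth must be >= 1")
        for spec in self.individual_specs:
            if spec.target_depth < 1:
                raise ValueError(f"individual {spec.label}: target_depth must be >= 1")
        marine_pools = [s.label for s in self.pool_specs if s.habitat == "marine"]
        missing = [p for p in marine_pools if p not in self.marine_distance_ranks]
        if missing:
            raise ValueError(f"marine pools without distance rank: {missing}")
        labels = [s.label for s in self.pool_specs] + [s.label for s in self.individual_specs]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate sample labels in config")
        if not labels:
            raise ValueError("config defines no samples")

    @property
    def sample_labels(self) -> list[str]:
        return [s.label for s in self.pool_specs] + [s.label for s in self.individual_specs]

    def chrom_names(self) -> list[str]:
        roman = [
            "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
            "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX",
            "XX", "XXI",
        ]
        names = []
        for i in range(self.n_chromosomes):
            names.append("chr" + (roman[i] if i < len(roman) else str(i + 1)))
        return names

    def chrom_table(self) -> ChromTable:
        names = self.chrom_names()
        return ChromTable(
            pd.DataFrame(
                {
                    "chrom": names,
                    "length_bp": self.chrom_length_bp,
                    "autosomal": [n != self.sex_chromosome for n in names],
                }
            )
        )

    def manifest(self) -> SampleManifest:
        rows = []
        for s in self.pool_specs:
            rows.append(
                dict(
                    label=s.label,
                    kind="pool",
                    habitat=s.habitat,
                    location=s.label,
                    distance_rank=self.marine_distance_ranks.get(s.label),
                    n_individuals=s.n_individuals,
                )
            )
        for s in self.individual_specs:
            rows.append(
                dict(
                    label=s.label,
                    kind="individual",
                    habitat=s.habitat,
                    location=s.label,
                    distance_rank=None,
                    n_individuals=1,
                )
            )
        return SampleManifest(pd.DataFrame(rows))


def study_design(
    scenario: str = "neutral_flat",
    n_neutral_sites: int = 10_000,
    n_planted_adaptive: int = 50,
    pool_depth: float = 85.0,
    individual_depth: float = 16.0,
    n_individuals_per_habitat: int = 0,
    rng_seed: int = 0,
    **overrides,
) -> SimConfig:
    """The default study layout: 2 freshwater + 6 marine pools (+ optional
    individually sequenced fish per habitat)."""
    marine = ["NU", "IR", "NL", "DE", "IS", "CA"]  # increasing distance rank
    pools = [
        PoolSpec("acidic", "acidic", 100, pool_depth),
        PoolSpec("basic", "basic", 100, pool_depth),
    ] + [PoolSpec(m, "marine", 25, pool_depth) for m in marine]
    individuals = []
    for hab in ("acidic", "basic", "marine"):
        for i in range(n_individuals_per_habitat):
            individuals.append(IndividualSpec(f"{hab}_ind{i + 1}", hab, individual_depth))
    return SimConfig(
        n_neutral_sites=n_neutral_sites,
        n_planted_adaptive=n_planted_adaptive,
        pool_specs=pools,
        individual_specs=individuals,
        scenario=scenario,
        marine_distance_ranks={m: i for i, m in enumerate(marine)},
        rng_seed=rng_seed,
        **overrides,
    )


@dataclass
class TruthTable:
    """Ground truth of a synthetic study: per-site class and true allele
    frequencies.

    ``alt_allele`` is the tracked (non-reference) allele; at planted sites it
    is the acidic allele.  ``freq`` holds its true frequency per sample.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    site_class: np.ndarray  # 'planted_adaptive' | 'neutral'
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    freq: np.ndarray  # (n_sites, n_samples)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.pos), len(self.samples)):
            raise ValueError("freq shape does not match sites x samples")
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ValueError("true frequencies outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def planted_mask(self) -> np.ndarray:
        return np.asarray(self.site_class) == "planted_adaptive"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "class": self.site_class,
                "ref_allele": self.ref_allele,
                "acidic_allele": self.alt_allele,
            }
        )
        for j, lab in enumerate(self.samples):
            df[f"freq_{lab}"] = self.freq[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthTable":
        samples = [c[len("freq_"):] for c in df.columns if c.startswith("freq_")]
        freq = (
            df[[f"freq_{s}" for s in samples]].to_numpy(dtype=float)
            if samples
            else np.zeros((len(df), 0))
        )
        return cls(
            samples=samples,
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            site_class=df["class"].to_numpy(dtype=object),
            ref_allele=df["ref_allele"].to_numpy(dtype=object),
            alt_allele=df["acidic_allele"].to_numpy(dtype=object),
            freq=freq,
        )


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------


def _mean_pair_fst_for_f(F: float, anc: np.ndarray, rng_seed: int) -> float:
    """Monte-Carlo mean of the per-SNP two-sample Nei FST for Beta drift F
    around the given ancestral frequencies (common random numbers via a
    fixed seed, so the map F -> FST is smooth and monotone)."""
    rng = np.random.default_rng(rng_seed)
    scale = (1.0 - F) / F
    a = anc * scale
    b = (1.0 - anc) * scale
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    num = 0.5 * (p1 - p2) ** 2
    pbar = 0.5 * (p1 + p2)
    ht = 2.0 * pbar * (1.0 - pbar)
    ratio = np.where(ht > 0, num / np.where(ht > 0, ht, 1.0), 0.0)
    return float(ratio.mean())


@lru_cache(maxsize=None)
def beta_f_parameter(fst_target: float, n_calib: int = 150_000,
                     calib_seed: int = 20_260) -> float:
    """Beta drift parameter F whose expected per-SNP two-sample Nei FST
    equals ``fst_target``.

    The closed-form ratio-of-expectations map F/(2-F) overstates the mean
    per-SNP FST because the numerator and H_T are positively correlated
    across the ancestral-frequency mixture; the exact value is found by
    bisection against a fixed-seed Monte-Carlo evaluation over the same
    Uniform(0.05, 0.95) ancestral distribution the generator uses.
    """
    if fst_target <= 0.0:
        return 0.0
    anc = np.random.default_rng(calib_seed).uniform(0.05, 0.95, size=n_calib)
    lo = fst_target  # measured FST is always below F (F/(2-F) < ... < F)
    hi = min(0.999, 6.0 * fst_target)
    while _mean_pair_fst_for_f(hi, anc, calib_seed + 1) < fst_target and hi < 0.999:
        hi = min(0.999, 2.0 * hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _mean_pair_fst_for_f(mid, anc, calib_seed + 1) < fst_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _spaced_positions(rng: np.random.Generator, n: int, length: int, spacing: int) -> np.ndarray:
    """n sorted positions in [1, length] with pairwise distance >= spacing."""
    slack = length - 1 - (n - 1) * spacing
    if n > 0 and slack < 0:
        raise ValueError(
            f"cannot place {n} sites with spacing {spacing} on {length} bp"
        )
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if slack + 1 >= n:
        raw = np.sort(rng.choice(slack + 1, size=n, replace=False))
    elif spacing >= 1:
        # repeated raw offsets still yield distinct positions exactly
        # `spacing` apart
        raw = np.sort(rng.integers(0, slack + 1, size=n))
    else:
        raise ValueError("cannot place distinct positions with spacing 0")
    return (raw + 1 + spacing * np.arange(n)).astype(np.int64)


def _sample_beta(rng: np.random.Generator, anc: np.ndarray, F: float, size_cols: int) -> np.ndarray:
    """Per-sample frequencies around ancestral ``anc`` with drift F."""
    if F <= 0:
        return np.repeat(anc[:, None], size_cols, axis=1)
    scale = (1.0 - F) / F
    a = np.clip(anc * scale, 1e-9, None)
    b = np.clip((1.0 - anc) * scale, 1e-9, None)
    return rng.beta(a[:, None], b[:, None], size=(len(anc), size_cols))


def draw_true_frequencies(cfg: SimConfig) -> TruthTable:
    """Draw the ground-truth allele frequencies of every site.

    Neutral sites get a Uniform(0.05, 0.95) ancestral frequency and
    Balding-Nichols per-sample frequencies with a habitat-group drift
    parameter.  Planted adaptive sites are near-fixed for alternative
    alleles between the acidic and basic pools (acidic >= 0.925, basic
    <= 0.075, hence expected sample AFD >= 0.85) and take the configured
    marine frequency, flat or geometrically declining with distance rank.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    chrom_names = cfg.chrom_names()
    autosomes = [c for c in chrom_names if c != cfg.sex_chromosome]
    if cfg.n_planted_adaptive > 0 and not autosomes:
        raise ValueError("no autosomes available to place planted sites")

    n_total = cfg.n_neutral_sites + cfg.n_planted_adaptive
    # distribute sites over chromosomes, then mark planted sites among
    # autosomal positions
    per_chrom = rng.multinomial(n_total, np.full(len(chrom_names), 1.0 / len(chrom_names)))
    chroms: list[str] = []
    poss: list[int] = []
    for name, k in zip(chrom_names, per_chrom):
        p = _spaced_positions(rng, int(k), cfg.chrom_length_bp, cfg.min_site_spacing_bp)
        chroms.extend([name] * len(p))
        poss.extend(p.tolist())
    chrom_arr = np.asarray(chroms, dtype=object)
    pos_arr = np.asarray(poss, dtype=np.int64)

    autosomal_idx = np.flatnonzero(np.isin(chrom_arr, autosomes))
    if cfg.n_planted_adaptive > len(autosomal_idx):
        raise ValueError("more planted sites requested than autosomal sites available")
    planted_idx = rng.choice(autosomal_idx, size=cfg.n_planted_adaptive, replace=False)
    site_class = np.full(n_total, "neutral", dtype=object)
    site_class[planted_idx] = "planted_adaptive"

    # ref/alt nucleotides per site
    ref_i = rng.integers(0, 4, size=n_total)
    alt_shift = rng.integers(1, 4, size=n_total)
    alt_i = (ref_i + alt_shift) % 4
    nucs = np.asarray(NUCLEOTIDES, dtype=object)
    ref_allele = nucs[ref_i]
    alt_allele = nucs[alt_i]

    labels = cfg.sample_labels
    habitats = {s.label: s.habitat for s in cfg.pool_specs}
    habitats.update({s.label: s.habitat for s in cfg.individual_specs})
    freq = np.zeros((n_total, len(labels)))

    # neutral background: Balding-Nichols per habitat group
    anc = rng.uniform(0.05, 0.95, size=n_total)
    F_fw = beta_f_parameter(cfg.background_fst_freshwater)
    F_ma = beta_f_parameter(cfg.background_fst_marine)
    for j, lab in enumerate(labels):
        F = F_ma if habitats[lab] == "marine" else F_fw
        freq[:, j] = _sample_beta(rng, anc, F, 1)[:, 0]

    # planted adaptive sites overwrite the neutral draw
    pm = site_class == "planted_adaptive"
    n_pl = int(pm.sum())
    fa = rng.uniform(0.925, 1.0, size=n_pl)
    fb = rng.uniform(0.0, 0.075, size=n_pl)
    marine_base = np.full(n_pl, cfg.acidic_allele_marine_freq)
    for j, lab in enumerate(labels):
        hab = habitats[lab]
        if hab == "acidic":
            freq[pm, j] = fa
        elif hab == "basic":
            freq[pm, j] = fb
        else:
            rank = cfg.marine_distance_ranks.get(lab, 0)
            if cfg.scenario == "gene_flow_decline":
                f = marine_base * cfg.decline_rate**rank
            else:
                f = marine_base
            if np.any(f > 1.0):
                raise ValueError("scenario produces planted marine frequency > 1")
            freq[pm, j] = f

    return TruthTable(
        samples=labels,
        chrom=chrom_arr,
        pos=pos_arr,
        site_class=site_class,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        freq=freq,
    )


# ---------------------------------------------------------------------------
# read-count sampling
# ---------------------------------------------------------------------------


def _error_probs(f_alt: np.ndarray, ref_i: np.ndarray, alt_i: np.ndarray,
                 err: float) -> np.ndarray:
    """Per-site 6-category read probabilities (sync order) for a biallelic
    site with alt-allele frequency ``f_alt``; each true allele emits itself
    with probability 1-err and each other nucleotide with err/3.  N and
    deletion classes are never emitted."""
    n = len(f_alt)
    probs = np.full((n, 6), 0.0)
    rows = np.arange(n)
    # contribution of ref reads
    ref_part = np.full((n, 4), err / 3.0)
    ref_part[rows, ref_i] = 1.0 - err
    alt_part = np.full((n, 4), err / 3.0)
    alt_part[rows, alt_i] = 1.0 - err
    probs[:, :4] = (1.0 - f_alt)[:, None] * ref_part + f_alt[:, None] * alt_part
    return probs


def sample_counts(truth: TruthTable, cfg: SimConfig) -> CountTable:
    """Sample read counts for every site and sample.

    Pools: depth ~ Poisson(target_depth), reads multinomial over nucleotides
    with the true frequency perturbed by the sequencing-error rate.
    Individuals: a Hardy-Weinberg genotype is drawn from the sample's true
    frequency, then reads are multinomial over the genotype's allele mix.
    Byte-reproducible from ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))
    labels = cfg.sample_labels
    if truth.samples != labels:
        raise ValueError("truth table samples do not match config")
    n = truth.n_sites
    ref_i = np.asarray([NUC_INDEX[a] for a in truth.ref_allele], dtype=np.int64)
    alt_i = np.asarray([NUC_INDEX[a] for a in truth.alt_allele], dtype=np.int64)
    counts = np.zeros((n, len(labels), 6), dtype=np.int64)

    depth_by_label = {s.label: s.target_depth for s in cfg.pool_specs}
    depth_by_label.update({s.label: s.target_depth for s in cfg.individual_specs})
    kinds = {s.label: "pool" for s in cfg.pool_specs}
    kinds.update({s.label: "individual" for s in cfg.individual_specs})

    for j, lab in enumerate(labels):
        depth = rng.poisson(depth_by_label[lab], size=n)
        f = truth.freq[:, j]
        if kinds[lab] == "individual":
            # HW genotype: number of alt copies ~ Binomial(2, f)
            g = rng.binomial(2, f)
            f = g / 2.0
        probs = _error_probs(f, ref_i, alt_i, cfg.seq_error_rate)
        counts[:, j, :] = rng.multinomial(depth, probs)
    return CountTable(
        samples=labels,
        chrom=truth.chrom,
        pos=truth.pos,
        ref=truth.ref_allele,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "counts": "counts.sync.tsv",
    "manifest": "manifest.tsv",
    "chroms": "chromosomes.tsv",
    "truth": "truth.tsv",
}


def write_truth(truth: TruthTable, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "ref_allele", "acidic_allele", "class"):
        df[col] = df[col].astype(object)
    return TruthTable.from_frame(df)


def write_fixture(truth: TruthTable, counts: CountTable, cfg: SimConfig,
                  out_dir: str | Path) -> Path:
    """Write a complete fixture (counts, manifest, chromosome table, truth)
    and return the path to the fixture manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        write_counts(counts, out / FIXTURE_FILES["counts"])
        write_manifest(cfg.manifest(), out / FIXTURE_FILES["manifest"])
        write_chroms(cfg.chrom_table(), out / FIXTURE_FILES["chroms"])
        write_truth(truth, out / FIXTURE_FILES["truth"])
        meta = {"files": FIXTURE_FILES, "scenario": cfg.scenario,
                "rng_seed": cfg.rng_seed}
        manifest_path = out / "fixture.json"
        manifest_path.write_text(json.dumps(meta, indent=2) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture to {out}: {exc}") from exc
    return manifest_path


def read_fixture(out_dir: str | Path) -> tuple[TruthTable, CountTable, SampleManifest, ChromTable]:
    out = Path(out_dir)
    manifest = read_manifest(out / FIXTURE_FILES["manifest"])
    counts = read_counts(out / FIXTURE_FILES["counts"], manifest)
    chroms = read_chroms(out / FIXTURE_FILES["chroms"])
    truth = read_truth(out / FIXTURE_FILES["truth"])
    return truth, counts, manifest, chroms


# ---------------------------------------------------------------------------
# correlated-site window generator (for haplotype-window tests)
# ---------------------------------------------------------------------------


def simulate_haplotype_window(
    n_sites: int = 30,
    n_per_group: int = 6,
    depth: float = 16.0,
    divergence: float = 0.9,
    chrom: str = "chrI",
    start: int = 1_000,
    spacing: int = 100,
    seq_error_rate: float = 0.002,
    rng_seed: int = 0,
) -> tuple[CountTable, list[str], list[str]]:
    """A single 5-kb-style window with two divergent haplotype backgrounds.

    Unlike the genome-wide generator, sites here are *correlated*: two
    ancestral haplotypes differ at a fraction ``divergence`` of sites, and
    each individual carries two haplotype copies drawn from its group's
    background (acidic-origin individuals from background 1, marine-origin
    from background 0, with a 5% swap rate emulating shared variation).
    Returns the count table and the two groups' individual labels.
    """
    rng = np.random.default_rng(rng_seed)
    pos = start + spacing * np.arange(n_sites)
    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
    divergent = rng.random(n_sites) < divergence
    # haplotype backgrounds: hap0 = ref everywhere; hap1 = alt at divergent sites
    hap = np.stack([np.zeros(n_sites, dtype=int), divergent.astype(int)])

    group_a = [f"marine_ind{i+1}" for i in range(n_per_group)]
    group_b = [f"acidic_ind{i+1}" for i in range(n_per_group)]
    labels = group_a + group_b
    counts = np.zeros((n_sites, len(labels), 6), dtype=np.int64)
    nucs = np.asarray(NUCLEOTIDES, dtype=object)
    for j, lab in enumerate(labels):
        background = 0 if lab in group_a else 1
        copies = []
        for _ in range(2):
            b = background if rng.random() > 0.05 else 1 - background
            copies.append(hap[b])
        f_alt = (copies[0] + copies[1]) / 2.0
        d = rng.poisson(depth, size=n_sites)
        probs = _error_probs(f_alt, ref_i, alt_i, seq_error_rate)
        counts[:, j, :] = rng.multinomial(d, probs)
    table = CountTable(
        samples=labels,
        chrom=np.asarray([chrom] * n_sites, dtype=object),
        pos=pos.astype(np.int64),
        ref=nucs[ref_i],
        counts=counts,
    )
    return table, group_a, group_b
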