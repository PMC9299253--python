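"""On-disk formats: sync-dialect count tables, manifests, chromosome tables,
FASTA export and GFF3 gene lookup.

The count-table dialect follows the PoPoolation2 "sync" convention: one line
per genomic position, tab-separated, with one ``A:T:C:G:N:del`` column of
colon-separated integer read counts per sample.  Unlike classic sync files,
files written here carry a header line (``#chrom  pos  ref  <label> ...``)
naming the samples; the reader accepts files with or without it, but always
validates the column count against the sample manifest.

Coordinates are 1-based and inclusive throughout, matching pileup and GFF
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: fixed count-column order of the sync dialect
SYNC_ORDER = ("A", "T", "C", "G", "N", "del")
#: the four nucleotides (first four sync columns); allele frequencies are
#: always expressed over these, never over N or deletion counts
NUCLEOTIDES = ("A", "T", "C", "G")
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

HABITATS = ("acidic", "basic", "marine")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Per-site, per-sample nucleotide read counts.

    Attributes
    ----------
    samples : list of str
        Ordered sample labels; one count column per label.
    chrom, pos : ndarray
        Site coordinates, 1-based, sorted by (chrom group, position).
    ref : ndarray
        Reference nucleotide per site.
    counts : ndarray of shape (n_sites, n_samples, 6)
        Read counts in sync order A, T, C, G, N, deletion.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.pos)
        if self.counts.shape != (n, len(self.samples), 6):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{n} sites x {len(self.samples)} samples x 6"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative read counts")
        _check_sorted(self.chrom, self.pos)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, label: str) -> int:
        try:
            return self.samples.index(label)
        except ValueError:
            raise KeyError(f"sample {label!r} not in count table") from None

    def depth(self) -> np.ndarray:
        """Total read depth (all six count classes) per site and sample."""
        return self.counts.sum(axis=2)

    def nuc_depth(self) -> np.ndarray:
        """Nucleotide read depth (A+T+C+G only) per site and sample."""
        return self.counts[:, :, :4].sum(axis=2)

    def take(self, idx) -> "CountTable":
        idx = np.asarray(idx)
        return CountTable(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            counts=self.counts[idx],
        )

    def site_key(self) -> dict[tuple[str, int], int]:
        """Map (chrom, pos) -> row index."""
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.chrom, self.pos))
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleManifest:
    """Study design table: one row per sequenced sample."""

    table: pd.DataFrame  # label, kind, habitat, location, distance_rank, n_individuals

    REQUIRED = ("label", "kind", "habitat", "location")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"manifest missing column {col!r}")
        for col in ("distance_rank", "n_individuals"):
            if col not in df.columns:
                df[col] = pd.NA
        df["distance_rank"] = df["distance_rank"].astype("Int64")
        df["n_individuals"] = df["n_individuals"].astype("Int64")
        if df["label"].duplicated().any():
            dup = df["label"][df["label"].duplicated()].iloc[0]
            raise FormatError(f"duplicate sample label {dup!r}")
        bad_kind = set(df["kind"]) - {"pool", "individual"}
        if bad_kind:
            raise FormatError(f"unknown sample kind(s): {sorted(bad_kind)}")
        bad_hab = set(df["habitat"]) - set(HABITATS)
        if bad_hab:
            raise FormatError(f"unknown habitat(s): {sorted(bad_hab)}")
        self.table = df.reset_index(drop=True)

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    def row(self, label: str) -> pd.Series:
        hit = self.table[self.table["label"] == label]
        if hit.empty:
            raise KeyError(f"sample {label!r} not in manifest")
        return hit.iloc[0]

    def select(self, kind: str | None = None, habitat: str | None = None) -> list[str]:
        df = self.table
        if kind is not None:
            df = df[df["kind"] == kind]
        if habitat is not None:
            df = df[df["habitat"] == habitat]
        return list(df["label"])

    def marine_pools_by_distance(self) -> list[str]:
        """Marine pools sorted by increasing distance rank (requires ranks)."""
        df = self.table[(self.table["kind"] == "pool") & (self.table["habitat"] == "marine")]
        if df["distance_rank"].isna().any():
            missing = list(df.loc[df["distance_rank"].isna(), "label"])
            raise FormatError(f"marine pools without distance_rank: {missing}")
        return list(df.sort_values("distance_rank")["label"])


@dataclass
class ChromTable:
    """Chromosome names, lengths and autosomal status."""

    table: pd.DataFrame  # chrom, length_bp, autosomal

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("chrom", "length_bp", "autosomal"):
            if col not in df.columns:
                raise FormatError(f"chromosome table missing column {col!r}")
        if df["chrom"].duplicated().any():
            raise FormatError("duplicate chromosome names")
        df["length_bp"] = df["length_bp"].astype(np.int64)
        if (df["length_bp"] < 1).any():
            raise FormatError("chromosome length < 1")
        df["autosomal"] = df["autosomal"].astype(bool)
        self.table = df.reset_index(drop=True)

    def length(self, chrom: str) -> int:
        hit = self.table[self.table["chrom"] == chrom]
        if hit.empty:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return int(hit["length_bp"].iloc[0])

    def autosomes(self) -> set[str]:
        return set(self.table.loc[self.table["autosomal"], "chrom"])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _check_sorted(chrom: np.ndarray, pos: np.ndarray) -> None:
    """Positions must be strictly increasing within each chromosome block."""
    prev_chrom, prev_pos = None, None
    seen: set[str] = set()
    for i, (c, p) in enumerate(zip(chrom, pos)):
        if c != prev_chrom:
            if c in seen:
                raise FormatError(f"chromosome {c!r} appears in multiple blocks (row {i})")
            seen.add(c)
            prev_chrom, prev_pos = c, p
            continue
        if p <= prev_pos:
            raise FormatError(
                f"positions not strictly increasing on {c} at row {i} "
                f"(pos {p} after {prev_pos})"
            )
        prev_pos = p


# ---------------------------------------------------------------------------
# count table I/O
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, manifest: SampleManifest) -> CountTable:
    """Read a sync-dialect count table, validating against the manifest.

    Malformed lines (bad nucleotide, non-integer counts, wrong column
    count, unsorted positions) raise :class:`FormatError` naming the
    offending 1-based line number; no line is ever silently dropped.
    """
    path = Path(path)
    labels = manifest.labels
    ncols = 3 + len(labels)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    count_rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                if len(header) >= 3 and header[3:] and header[3:] != labels:
                    raise FormatError(
                        f"{path}:{lineno}: header samples {header[3:]} "
                        f"do not match manifest {labels}"
                    )
                continue
            fields = line.split("\t")
            if len(fields) != ncols:
                raise FormatError(
                    f"{path}:{lineno}: expected {ncols} columns, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[:3]
            if ref not in NUCLEOTIDES:
                raise FormatError(f"{path}:{lineno}: bad reference nucleotide {ref!r}")
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            row: list[int] = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise FormatError(
                        f"{path}:{lineno}: count field {col!r} must have 6 values"
                    )
                try:
                    vals = [int(v) for v in parts]
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count in {col!r}"
                    ) from None
                if any(v < 0 for v in vals):
                    raise FormatError(f"{path}:{lineno}: negative count in {col!r}")
                row.extend(vals)
            chroms.append(chrom)
            poss.append(pos)
            refs.append(ref)
            count_rows.append(row)
    counts = (
        np.asarray(count_rows, dtype=np.int64).reshape(len(count_rows), len(labels), 6)
        if count_rows
        else np.zeros((0, len(labels), 6), dtype=np.int64)
    )
    try:
        return CountTable(
            samples=labels,
            chrom=np.asarray(chroms, dtype=object),
            pos=np.asarray(poss, dtype=np.int64),
            ref=np.asarray(refs, dtype=object),
            counts=counts,
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_counts(table: CountTable, path: str | Path) -> None:
    """Write a count table in the sync dialect (with a header line)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\t" + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            cols = [
                ":".join(str(v) for v in table.counts[i, j])
                for j in range(len(table.samples))
            ]
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t{table.ref[i]}\t" + "\t".join(cols) + "\n"
            )


# ---------------------------------------------------------------------------
# manifest / chromosome table I/O
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "location": str})
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def read_chroms(path: str | Path) -> ChromTable:
    df = pd.read_csv(path, sep="\t")
    return ChromTable(df)


def write_chroms(chroms: ChromTable, path: str | Path) -> None:
    out = chroms.table.copy()
    out["autosomal"] = out["autosomal"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(labels: Sequence[str], sequences: Sequence[str], path: str | Path) -> None:
    """Write concatenated-SNP strings as 80-column wrapped multi-FASTA.

    All sequences must have equal length (they are aligned columns of SNP
    alleles) and be drawn from {A, C, G, T}.
    """
    if len(labels) != len(sequences):
        raise ValueError("label and sequence lists differ in length")
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    for lab, seq in zip(labels, sequences):
        bad = set(seq) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(f"sequence {lab!r} contains non-nucleotide characters {bad}")
    records = [
        SeqRecord(Seq(seq), id=str(lab), description="")
        for lab, seq in zip(labels, sequences)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    records = list(SeqIO.parse(str(path), "fasta"))
    return [r.id for r in records], [str(r.seq) for r in records]


# ---------------------------------------------------------------------------
# GFF3 gene lookup
# ---------------------------------------------------------------------------


def load_gff(gff_path: str | Path):
    """Load a GFF3 file into an in-memory gffutils database."""
    import gffutils

    return gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    name: str | None = None


def genes_in_window(gff, chrom: str, center_pos: int, width_bp: int) -> list[GeneRecord]:
    """Genes overlapping a window of ``width_bp`` centred at ``center_pos``.

    The window spans ``[center - width/2, center + width/2 - 1]`` for even
    widths (total span exactly ``width_bp``), 1-based closed; a gene is
    returned when its [start, end] interval overlaps the window, boundary
    touches included.  ``gff`` may be a path or a preloaded database from
    :func:`load_gff`.  An unknown chromosome yields an empty list.
    """
    if width_bp <= 0:
        raise ValueError("width_bp must be positive")
    if isinstance(gff, (str, Path)):
        gff = load_gff(gff)
    half = width_bp // 2
    lo = max(1, center_pos - half)
    hi = center_pos + width_bp - half - 1
    out: list[GeneRecord] = []
    for feat in gff.region(seqid=chrom, start=lo, end=hi, featuretype="gene",
                           completely_within=False):
        name = feat.attributes.get("Name", [None])[0]
        out.append(GeneRecord(gene_id=feat.id, chrom=feat.seqid,
                              start=feat.start, end=feat.end, name=name))
    out.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return out
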