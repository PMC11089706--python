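"""Readers, writers and tabular containers shared by all pipeline stages.

Internal coordinate convention is 0-based half-open everywhere (BED-style).
GTF input (1-based inclusive) is converted on read. Region identifiers are
serialized as ``"contig:start-end"`` with half-open start/end.
"""

from __future__ import annotations

import io as _io
import os
import re
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "GenomeIndex",
    "ReadSet",
    "GeneAnnotation",
    "SampleSheet",
    "read_genome_index",
    "read_bed_reads",
    "read_annotation",
    "derive_introns",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_matrix",
    "write_matrix",
    "region_key",
    "parse_region_key",
    "grch37_primary_index",
]


class ParseError(ValueError):
    """Malformed input outside the supported dialect; carries position info."""


def _as_text_lines(source) -> list[str]:
    """Accept a path, raw text containing newlines, or a file-like object."""
    if hasattr(source, "read"):
        return source.read().splitlines()
    text = os.fspath(source) if isinstance(source, os.PathLike) else source
    if isinstance(text, str) and ("\n" in text or "\t" in text) and not os.path.exists(text):
        return text.splitlines()
    with open(text, "rt") as fh:
        return fh.read().splitlines()


# ---------------------------------------------------------------------------
# Genome index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeIndex:
    """Ordered contig table (name, length in bp), as in a FASTA ``.fai``."""

    contigs: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ParseError(f"duplicate contig name(s): {', '.join(dup)}")
        for name, length in self.contigs:
            if not name:
                raise ParseError("empty contig name")
            if length < 1:
                raise ParseError(f"contig {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.contigs)

    def subset(self, names: Sequence[str]) -> "GenomeIndex":
        """Restrict to the given contigs, keeping this index's order."""
        keep = set(names)
        missing = keep - set(self.names)
        if missing:
            raise KeyError(f"contigs not in index: {sorted(missing)}")
        return GenomeIndex(tuple(c for c in self.contigs if c[0] in keep))

    def __len__(self) -> int:
        return len(self.contigs)


def read_genome_index(source) -> GenomeIndex:
    """Parse a FASTA-index-style TSV (name, length, [extra columns ignored])."""
    contigs = []
    for i, line in enumerate(_as_text_lines(source), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"line {i}: expected at least 2 columns, got {len(parts)}")
        name = parts[0]
        try:
            length = int(parts[1])
        except ValueError:
            raise ParseError(f"line {i}: non-integer contig length {parts[1]!r}") from None
        contigs.append((name, length))
    return GenomeIndex(tuple(contigs))


def grch37_primary_index(nuclear_only: bool = False) -> GenomeIndex:
    """Bundled GRCh37 primary-chromosome index (1-22, X, Y, MT).

    With ``nuclear_only`` the mitochondrial contig is dropped, matching a
    small-RNA workflow in which mitochondrial reads are screened out before
    alignment.
    """
    path = os.path.join(os.path.dirname(__file__), "data", "grch37_primary.fai")
    idx = read_genome_index(path)
    if nuclear_only:
        idx = GenomeIndex(tuple(c for c in idx.contigs if c[0] != "MT"))
    return idx


# ---------------------------------------------------------------------------
# Mapped-read intervals
# ---------------------------------------------------------------------------

_STRANDS = {"+", "-", "."}


@dataclass
class ReadSet:
    """Uniquely-mapped read intervals for one sample (0-based half-open)."""

    sample_id: str
    intervals: pd.DataFrame  # columns: contig, start, end, strand

    def __post_init__(self):
        required = ["contig", "start", "end", "strand"]
        missing = [c for c in required if c not in self.intervals.columns]
        if missing:
            raise ValueError(f"ReadSet intervals missing column(s): {missing}")
        bad = self.intervals["end"] <= self.intervals["start"]
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            row = self.intervals.iloc[i]
            raise ValueError(
                f"empty or inverted interval at row {i}: "
                f"{row['contig']}:{row['start']}-{row['end']}"
            )

    def __len__(self) -> int:
        return len(self.intervals)


def read_bed_reads(source, sample_id: str = "sample") -> ReadSet:
    """Parse BED3/BED6 into a ReadSet; strand '.' (or BED3) means unknown."""
    recs = []
    for i, line in enumerate(_as_text_lines(source), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"line {i}: BED needs >= 3 columns, got {len(parts)}")
        contig = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ParseError(f"line {i}: non-integer coordinates") from None
        if end <= start:
            raise ParseError(f"line {i}: empty interval {contig}:{start}-{end}")
        strand = parts[5] if len(parts) >= 6 else "."
        if strand not in _STRANDS:
            raise ParseError(f"line {i}: invalid strand {strand!r}")
        recs.append((contig, start, end, strand))
    df = pd.DataFrame(recs, columns=["contig", "start", "end", "strand"])
    return ReadSet(sample_id=sample_id, intervals=df)


def write_bed_reads(readset: ReadSet, path) -> None:
    df = readset.intervals
    with open(path, "wt") as fh:
        for contig, start, end, strand in df.itertuples(index=False):
            fh.write(f"{contig}\t{start}\t{end}\t{readset.sample_id}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

BIOTYPES = {
    "snoRNA", "lincRNA", "tRNA", "snRNA", "miRNA", "rRNA", "misc_RNA",
    "protein_coding", "pseudogene",
}

_ANN_COLUMNS = ["gene_id", "gene_name", "biotype", "contig", "start", "end",
                "strand", "feature"]


@dataclass
class GeneAnnotation:
    """Gene/exon/intron records with 0-based half-open coordinates."""

    records: pd.DataFrame  # columns as _ANN_COLUMNS

    def __post_init__(self):
        missing = [c for c in _ANN_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"GeneAnnotation missing column(s): {missing}")
        bad = self.records["end"] <= self.records["start"]
        if bad.any():
            raise ValueError("annotation contains records with start >= end")

    def genes(self) -> pd.DataFrame:
        return self.records[self.records["feature"] == "gene"]

    def by_biotype(self, biotype: str) -> pd.DataFrame:
        g = self.genes()
        return g[g["biotype"] == biotype]

    def __len__(self) -> int:
        return len(self.records)


def read_annotation(source) -> GeneAnnotation:
    """Read a GTF (gene/exon features) into a GeneAnnotation.

    Coordinates are converted to 0-based half-open. Records must carry a
    ``gene_id`` attribute; ``gene_name`` falls back to gene_id and
    ``gene_biotype`` to ``"protein_coding"`` when absent from a record.
    """
    import pyranges as pr

    lines = _as_text_lines(source)
    for i, line in enumerate(lines, start=1):
        if line.strip() and not line.startswith("#"):
            attrs = line.split("\t")[-1]
            if "gene_id" not in attrs:
                raise ParseError(f"line {i}: GTF attribute field lacks gene_id")
    with tempfile.NamedTemporaryFile("wt", suffix=".gtf", delete=False) as fh:
        fh.write("\n".join(lines) + "\n")
        tmp = fh.name
    try:
        df = pr.read_gtf(tmp).df
    finally:
        os.unlink(tmp)
    df = df[df["Feature"].isin(["gene", "exon"])].copy()
    if "gene_name" not in df.columns:
        df["gene_name"] = df["gene_id"]
    else:
        df["gene_name"] = df["gene_name"].fillna(df["gene_id"])
    if "gene_biotype" not in df.columns:
        df["gene_biotype"] = "protein_coding"
    else:
        df["gene_biotype"] = df["gene_biotype"].fillna("protein_coding")
    out = pd.DataFrame({
        "gene_id": df["gene_id"],
        "gene_name": df["gene_name"],
        "biotype": df["gene_biotype"],
        "contig": df["Chromosome"].astype(str),
        "start": df["Start"].astype(int),
        "end": df["End"].astype(int),
        "strand": df["Strand"].astype(str),
        "feature": df["Feature"].astype(str),
    }).reset_index(drop=True)
    return GeneAnnotation(records=out)


def derive_introns(annotation: GeneAnnotation) -> pd.DataFrame:
    """Introns as each gene's span minus the union of its exons."""
    recs = []
    ann = annotation.records
    for gid, grp in ann.groupby("gene_id", sort=False):
        gene = grp[grp["feature"] == "gene"]
        exons = grp[grp["feature"] == "exon"].sort_values("start")
        if gene.empty or exons.empty:
            continue
        g = gene.iloc[0]
        cursor = int(g["start"])
        for _, ex in exons.iterrows():
            if ex["start"] > cursor:
                recs.append((gid, g["gene_name"], g["biotype"], g["contig"],
                             cursor, int(ex["start"]), g["strand"], "intron"))
            cursor = max(cursor, int(ex["end"]))
        if cursor < int(g["end"]):
            recs.append((gid, g["gene_name"], g["biotype"], g["contig"],
                         cursor, int(g["end"]), g["strand"], "intron"))
    return pd.DataFrame(recs, columns=_ANN_COLUMNS)


def write_annotation_gtf(annotation: GeneAnnotation, path) -> None:
    """Serialize gene/exon records back to GTF (1-based inclusive)."""
    with open(path, "wt") as fh:
        for r in annotation.records.itertuples(index=False):
            if r.feature not in ("gene", "exon"):
                continue
            attrs = (f'gene_id "{r.gene_id}"; gene_name "{r.gene_name}"; '
                     f'gene_biotype "{r.biotype}";')
            fh.write(f"{r.contig}\turoev\t{r.feature}\t{r.start + 1}\t{r.end}\t."
                     f"\t{r.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["sample_id", "group", "gender", "age", "dna_rna_ratio",
                 "obesity", "hypertension"]
_GROUPS = {"case", "control"}
_GENDERS = {"male", "female"}
_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


@dataclass
class SampleSheet:
    """Per-sample clinical covariates and QC measurements."""

    rows: pd.DataFrame

    def __post_init__(self):
        df = self.rows
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing column(s): {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id(s): {dups}")
        bad_group = set(df["group"]) - _GROUPS
        if bad_group:
            raise ValueError(f"invalid group value(s): {sorted(bad_group)}")
        bad_gender = set(df["gender"]) - _GENDERS
        if bad_gender:
            raise ValueError(f"invalid gender value(s): {sorted(bad_gender)}")
        if ((df["age"] < 18) | (df["age"] > 120)).any():
            raise ValueError("age outside plausible bounds [18, 120]")
        if (df["dna_rna_ratio"] < 0).any():
            raise ValueError("dna_rna_ratio must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return self.rows["sample_id"].tolist()

    def n_by_group(self) -> dict[str, int]:
        return self.rows["group"].value_counts().to_dict()

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        keep = set(sample_ids)
        return SampleSheet(self.rows[self.rows["sample_id"].isin(keep)]
                           .reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.rows)


def read_sample_sheet(source) -> SampleSheet:
    lines = _as_text_lines(source)
    buf = _io.StringIO("\n".join(lines))
    df = pd.read_csv(buf, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"sample sheet missing required column(s): {missing}")
    out = df.copy()
    try:
        out["age"] = df["age"].astype(float)
    except ValueError as e:
        raise ParseError(f"non-numeric age value: {e}") from None
    try:
        out["dna_rna_ratio"] = df["dna_rna_ratio"].astype(float)
    except ValueError as e:
        raise ParseError(f"non-numeric dna_rna_ratio: {e}") from None
    for col in ("obesity", "hypertension"):
        vals = df[col].str.strip().str.lower()
        bad = set(vals) - set(_BOOL_MAP)
        if bad:
            raise ParseError(f"column {col}: non-boolean value(s) {sorted(bad)}")
        out[col] = vals.map(_BOOL_MAP)
    return SampleSheet(rows=out)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    df = sheet.rows.copy()
    for col in ("obesity", "hypertension"):
        df[col] = df[col].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Region-keyed matrices
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^(.+):(\d+)-(\d+)$")


def region_key(contig: str, start: int, end: int) -> str:
    return f"{contig}:{start}-{end}"


def parse_region_key(key: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(key)
    if not m:
        raise ParseError(f"malformed region key {key!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a region x sample table; index must hold region keys."""
    df.to_csv(path, sep="\t", index=True, index_label="region")


def read_matrix(source, dtype=None) -> pd.DataFrame:
    lines = _as_text_lines(source)
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t", index_col="region")
    for key in df.index:
        parse_region_key(key)
    if dtype is not None:
        df = df.astype(dtype)
    return df
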