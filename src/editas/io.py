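"""Readers and writers for the standard formats the pipeline touches.

All coordinates exposed by this module are **1-based inclusive** (the GTF/VCF
convention).  BED input/output is 0-based half-open on disk; the conversion
happens here and nowhere else.

Count tables are wide TSVs: one row per candidate site with columns
``chrom pos ref alt strand`` followed by a ``cov_<sample>`` / ``alt_<sample>``
pair per sample.  Junction tables are analogous with ``inc_<sample>`` /
``skip_<sample>`` pairs per alternative-splicing event.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, SchemaError, ValidationError

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """Closed interval on a chromosome, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class GeneModel:
    """One transcript of one gene: ordered exons plus optional CDS intervals.

    Exons are stored sorted in genomic order regardless of strand; for a
    minus-strand transcript the *first* exon in transcription order is the
    genomically last one.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        self.cds = sorted(self.cds, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping exons in {self.transcript_id}: {a} / {b}"
                )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start - a.end > 1
        ]


@dataclass
class SampleDesign:
    """sample_id -> group label mapping (e.g. UIA / RIA / control)."""

    groups: dict[str, str]

    def samples(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self.groups)
        return [s for s, g in self.groups.items() if g == group]

    def group_of(self, sample: str) -> str:
        return self.groups[sample]

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a ``{chrom: uppercase sequence}`` mapping."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}: not a FASTA file (no '>' header)")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse GTF exon/CDS features into per-transcript :class:`GeneModel`.

    Uses ``gffutils`` for feature parsing; transcripts are returned sorted by
    (chrom, start, transcript_id).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: dict[str, GeneModel] = {}
    for kind in ("exon", "CDS"):
        for feat in db.features_of_type(kind):
            try:
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ParseError(
                    f"{path}: {kind} feature at {feat.seqid}:{feat.start} "
                    f"missing {exc} attribute"
                ) from None
            model = models.get(tx_id)
            if model is None:
                model = GeneModel(gene_id, tx_id, feat.seqid, feat.strand, [], [])
                models[tx_id] = model
            iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
            (model.exons if kind == "exon" else model.cds).append(iv)
    out = []
    for model in models.values():
        # re-run sorting/validation now that all features are attached
        out.append(
            GeneModel(model.gene_id, model.transcript_id, model.chrom,
                      model.strand, model.exons, model.cds)
        )
    out.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return out


def write_gtf(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id)):
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for kind, ivs in (("exon", m.exons), ("CDS", m.cds)):
                for iv in ivs:
                    fh.write(
                        f"{m.chrom}\teditas\t{kind}\t{iv.start}\t{iv.end}\t.\t"
                        f"{m.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# VCF (site lists only; genotypes are ignored)

def read_vcf_sites(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Read a VCF into ``{(chrom, pos, ref, alt)}``, expanding multi-allelics."""
    import pysam

    sites: set[tuple[str, int, str, str]] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                sites.add((rec.chrom, rec.pos, rec.ref, alt))
    return sites


def write_vcf_sites(
    sites: Iterable[tuple[str, int, str, str]], path: str | Path
) -> None:
    rows = sorted(set(sites))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=editas\n")
        for chrom in sorted({r[0] for r in rows}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def read_site_mask(path: str | Path) -> set[tuple[str, int]]:
    """Read a dbSNP/WES-style position mask from VCF or 2-column TSV.

    Matching downstream is on (chrom, pos) only — no allele check.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##fileformat") or head.startswith("#CHROM"):
        return {(c, p) for c, p, _r, _a in read_vcf_sites(path)}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1], names=["chrom", "pos"], dtype={0: str})
    return set(zip(df["chrom"], df["pos"].astype(int)))


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 and convert to 1-based inclusive intervals.

    The BED ``name`` column, when present, is attached via the parallel list
    returned by :func:`read_bed_named`.
    """
    return [iv for iv, _name in read_bed_named(path)]


def read_bed_named(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise ParseError(
                    f"{path}:{ln}: BED end ({end0}) <= start ({start0})"
                )
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            out.append((GenomicInterval(chrom, start0 + 1, end0, strand), name))
    return out


def write_bed(
    intervals: Iterable[tuple[GenomicInterval, str]] | Iterable[GenomicInterval],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for item in intervals:
            iv, name = item if isinstance(item, tuple) else (item, ".")
            cols = [iv.chrom, str(iv.start - 1), str(iv.end), name, "0", iv.strand]
            if iv.strand == "." and name == ".":
                cols = cols[:3]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Count / junction tables

SITE_KEY_COLS = ["chrom", "pos", "ref", "alt", "strand"]


def site_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def _paired_samples(columns: Iterable[str], a: str, b: str, path) -> list[str]:
    cov = {c[len(a):] for c in columns if c.startswith(a)}
    alt = {c[len(b):] for c in columns if c.startswith(b)}
    if cov != alt:
        missing = cov.symmetric_difference(alt)
        raise SchemaError(
            f"{path}: unpaired {a}*/{b}* columns for samples {sorted(missing)}"
        )
    if not cov:
        raise SchemaError(f"{path}: no {a}*/{b}* sample columns found")
    return sorted(cov)


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a per-site mismatch count table.

    Returns a DataFrame indexed by ``site_id`` with the key columns plus one
    ``cov_<s>``/``alt_<s>`` integer pair per sample.  Raises
    :class:`ValidationError` if any edited count exceeds its coverage.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str,
                                            "strand": str})
    missing = [c for c in SITE_KEY_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    samples = _paired_samples(df.columns, "cov_", "alt_", path)
    for s in samples:
        cov, alt = df[f"cov_{s}"].astype(int), df[f"alt_{s}"].astype(int)
        df[f"cov_{s}"], df[f"alt_{s}"] = cov, alt
        bad = alt > cov
        if bad.any():
            row = df[bad].iloc[0]
            raise ValidationError(
                f"{path}: edited > coverage at "
                f"{row['chrom']}:{row['pos']} sample {s}"
            )
    df.index = pd.Index(
        [site_id(c, p, r, a)
         for c, p, r, a in zip(df.chrom, df.pos, df.ref, df.alt)],
        name="site_id",
    )
    return df


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def count_table_samples(df: pd.DataFrame) -> list[str]:
    return sorted(c[4:] for c in df.columns if c.startswith("cov_"))


EVENT_KEY_COLS = ["event_id", "type", "gene_id", "chrom", "strand",
                  "coords", "len_inc", "len_skip"]


def read_junction_table(path: str | Path) -> pd.DataFrame:
    """Read an AS-event junction count table (``inc_*``/``skip_*`` pairs)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str,
                                            "event_id": str, "coords": str})
    missing = [c for c in EVENT_KEY_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    samples = _paired_samples(df.columns, "inc_", "skip_", path)
    for s in samples:
        df[f"inc_{s}"] = df[f"inc_{s}"].astype(int)
        df[f"skip_{s}"] = df[f"skip_{s}"].astype(int)
    return df.set_index("event_id", drop=False)


def write_junction_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def junction_table_samples(df: pd.DataFrame) -> list[str]:
    return sorted(c[4:] for c in df.columns if c.startswith("inc_"))


# ---------------------------------------------------------------------------
# Design table

def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise SchemaError(f"{path}: design table needs sample_id and group columns")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    return SampleDesign(dict(zip(df["sample_id"], df["group"])))


def write_design(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.groups), "group": list(design.groups.values())}
    ).to_csv(path, sep="\t", index=False)
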