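"""High-confidence RNA editing site calling and annotation.

Candidate sites arrive as per-sample mismatch/coverage count tables.  A site
is retained when it survives the four-step cascade: (1) not a genomic variant
in the matched WES calls, (2) not a known SNP (dbSNP-style mask), (3) at
least 3 edited reads, (4) at least 10 reads of coverage — steps (3)/(4) being
satisfied jointly in at least one sample.  Each rejected site is attributed
to the *first* failing step.

Count tables store ``ref``/``alt`` as genomic plus-strand bases; ``strand``
is the strand of the host transcript.  Edit types (A-to-G etc.) are named on
the transcript strand, so a genomic T>C on '-' is an A-to-G edit.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ValidationError
from .io import GeneModel, GenomicInterval, count_table_samples
from .seqtools import complement, fetch

BASES = "ACGT"

REGION_PRECEDENCE = ["splice-site", "3'UTR", "5'UTR", "exonic", "intronic",
                     "intergenic"]
CONSEQUENCE_SEVERITY = ["stopgain", "stoploss", "nonsynonymous", "synonymous",
                        "noncoding"]

FILTER_NAMES = {1: "wes_variant", 2: "dbsnp", 3: "min_edited", 4: "min_coverage"}

#: number of intronic bases adjacent to an exon boundary classed as splice-site
SPLICE_SITE_MARGIN = 2


def classify_edit_type(ref: str, alt: str, strand: str) -> str:
    """Name one of the 12 mismatch classes, resolved to the transcript strand."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in BASES or alt not in BASES:
        raise ValidationError(f"invalid bases {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError(f"ref == alt ({ref})")
    if strand == "-":
        ref, alt = complement(ref), complement(alt)
    return f"{ref}-to-{alt}"


def apply_filters(
    candidates: pd.DataFrame,
    wes_sites: set[tuple[str, int]] | set,
    dbsnp_sites: set[tuple[str, int]] | set,
    min_edited: int = 3,
    min_coverage: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the four-step cascade on a candidate count table.

    ``wes_sites``/``dbsnp_sites`` may contain ``(chrom, pos)`` pairs or
    ``(chrom, pos, ref, alt)`` tuples; matching is on position only.

    Returns ``(passing, rejections)`` where ``rejections`` has one row per
    rejected site with the 1-based index and name of the first failing filter.
    """
    wes_pos = {(t[0], t[1]) for t in wes_sites}
    dbsnp_pos = {(t[0], t[1]) for t in dbsnp_sites}
    samples = count_table_samples(candidates)
    cov = candidates[[f"cov_{s}" for s in samples]].to_numpy()
    alt = candidates[[f"alt_{s}" for s in samples]].to_numpy()

    reasons: dict[str, int] = {}
    for i, (sid, row) in enumerate(candidates.iterrows()):
        key = (row["chrom"], int(row["pos"]))
        if key in wes_pos:
            reasons[sid] = 1
        elif key in dbsnp_pos:
            reasons[sid] = 2
        elif not (alt[i] >= min_edited).any():
            reasons[sid] = 3
        elif not ((alt[i] >= min_edited) & (cov[i] >= min_coverage)).any():
            reasons[sid] = 4

    passing = candidates.loc[[s for s in candidates.index if s not in reasons]]
    rejections = pd.DataFrame(
        {
            "site_id": list(reasons),
            "filter_index": list(reasons.values()),
            "filter": [FILTER_NAMES[i] for i in reasons.values()],
        }
    ).set_index("site_id")
    return passing, rejections


def rejection_tally(rejections: pd.DataFrame) -> dict[str, int]:
    return dict(Counter(rejections["filter"]))


# ---------------------------------------------------------------------------
# Annotation (GTF arithmetic in place of an external annotator)

def _region_in_transcript(pos: int, model: GeneModel) -> str | None:
    if not (model.start <= pos <= model.end):
        return None
    for intron in model.introns():
        if intron.contains(pos):
            near_start = pos - intron.start < SPLICE_SITE_MARGIN
            near_end = intron.end - pos < SPLICE_SITE_MARGIN
            return "splice-site" if (near_start or near_end) else "intronic"
    in_exon = any(e.contains(pos) for e in model.exons)
    if not in_exon:  # between transcripts' exons but outside this one
        return None
    if model.cds:
        cds_start, cds_end = model.cds[0].start, model.cds[-1].end
        if pos < cds_start:
            return "5'UTR" if model.strand == "+" else "3'UTR"
        if pos > cds_end:
            return "3'UTR" if model.strand == "+" else "5'UTR"
    return "exonic"


def annotate_region(
    chrom: str, pos: int, gene_models: list[GeneModel]
) -> tuple[str, str | None]:
    """Classify a position against all transcripts; precedence
    splice-site > 3'UTR > 5'UTR > exonic > intronic > intergenic.

    Returns ``(region_class, gene_id)`` where ``gene_id`` is the host gene of
    the winning transcript (lexicographically smallest on ties), or ``None``
    for intergenic positions.
    """
    best = "intergenic"
    best_gene: str | None = None
    for model in gene_models:
        if model.chrom != chrom:
            continue
        region = _region_in_transcript(pos, model)
        if region is None:
            continue
        if REGION_PRECEDENCE.index(region) < REGION_PRECEDENCE.index(best) or (
            region == best and (best_gene is None or model.gene_id < best_gene)
        ):
            best, best_gene = region, model.gene_id
    return best, best_gene


def annotate_repeat(
    chrom: str, pos: int, repeats: list[tuple[GenomicInterval, str]]
) -> str:
    """Alu / repetitive non-Alu / non-repetitive, from a named repeat BED."""
    klass = "non-repetitive"
    for iv, name in repeats:
        if iv.chrom == chrom and iv.contains(pos):
            if name.startswith("Alu"):
                return "Alu"
            klass = "repetitive non-Alu"
    return klass


def coding_consequence(
    chrom: str,
    pos: int,
    alt: str,
    gene_models: list[GeneModel],
    genome: dict[str, str],
) -> str:
    """Codon-level consequence of substituting ``alt`` (genomic plus-strand
    base) at ``pos``; the most severe consequence across transcripts wins.
    """
    best = "noncoding"
    for model in gene_models:
        if model.chrom != chrom or not model.cds:
            continue
        if not any(c.contains(pos) for c in model.cds):
            continue
        cds_seq = "".join(fetch(genome, chrom, c.start, c.end) for c in model.cds)
        if len(cds_seq) % 3 != 0:
            warnings.warn(
                f"CDS length of {model.transcript_id} not divisible by 3; "
                f"skipping consequence call"
            )
            continue
        offset = 0
        for c in model.cds:
            if c.contains(pos):
                offset += pos - c.start
                break
            offset += len(c)
        mutated = cds_seq[:offset] + alt.upper() + cds_seq[offset + 1 :]
        if model.strand == "-":
            cds_tx, mut_tx = (
                str(Seq(cds_seq).reverse_complement()),
                str(Seq(mutated).reverse_complement()),
            )
        else:
            cds_tx, mut_tx = cds_seq, mutated
        aa_ref = str(Seq(cds_tx).translate())
        aa_alt = str(Seq(mut_tx).translate())
        for i, (a, b) in enumerate(zip(aa_ref, aa_alt)):
            if a == b:
                continue
            if b == "*":
                call = "stopgain"
            elif a == "*":
                call = "stoploss"
            else:
                call = "nonsynonymous"
            break
        else:
            call = "synonymous"
        if CONSEQUENCE_SEVERITY.index(call) < CONSEQUENCE_SEVERITY.index(best):
            best = call
    return best


def annotate_sites(
    sites: pd.DataFrame,
    gene_models: list[GeneModel],
    repeats: list[tuple[GenomicInterval, str]] | None = None,
    genome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Attach edit_type / region_class / gene_id / repeat_class / consequence
    columns to a (filtered) site table."""
    out = sites.copy()
    out["edit_type"] = [
        classify_edit_type(r, a, s)
        for r, a, s in zip(out["ref"], out["alt"], out["strand"])
    ]
    regions, genes = [], []
    for chrom, pos in zip(out["chrom"], out["pos"]):
        region, gene = annotate_region(chrom, int(pos), gene_models)
        regions.append(region)
        genes.append(gene if gene is not None else "")
    out["region_class"] = regions
    out["gene_id"] = genes
    if repeats is not None:
        out["repeat_class"] = [
            annotate_repeat(c, int(p), repeats)
            for c, p in zip(out["chrom"], out["pos"])
        ]
    if genome is not None:
        out["consequence"] = [
            coding_consequence(c, int(p), a, gene_models, genome)
            if rc == "exonic"
            else "noncoding"
            for c, p, a, rc in zip(out["chrom"], out["pos"], out["alt"],
                                   out["region_class"])
        ]
    return out


def select_edit_type(sites: pd.DataFrame, edit_type: str = "A-to-G") -> pd.DataFrame:
    """Restrict to one strand-resolved mismatch class (default the A-to-I
    signature A-to-G); all 12 classes remain available in the input table."""
    if "edit_type" not in sites.columns:
        sites = annotate_sites(sites, [])[list(sites.columns) + ["edit_type"]]
    return sites[sites["edit_type"] == edit_type]


def edit_type_tally(sites: pd.DataFrame) -> dict[str, int]:
    types = [
        classify_edit_type(r, a, s)
        for r, a, s in zip(sites["ref"], sites["alt"], sites["strand"])
    ]
    return dict(Counter(types))


# ---------------------------------------------------------------------------
# Editing levels

def editing_levels(
    sites: pd.DataFrame, min_coverage: int = 10
) -> pd.DataFrame:
    """Per-site per-sample editing level (edited/coverage); samples below
    ``min_coverage`` at a site are set to NaN (missing, not zero)."""
    samples = count_table_samples(sites)
    cov = sites[[f"cov_{s}" for s in samples]].to_numpy(float)
    alt = sites[[f"alt_{s}" for s in samples]].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lvl = np.where(cov > 0, alt / np.maximum(cov, 1), np.nan)
    lvl[cov < min_coverage] = np.nan
    return pd.DataFrame(lvl, index=sites.index, columns=samples)


def editing_index(sites: pd.DataFrame, sample: str) -> float:
    """Coverage-weighted global editing level for one sample:
    sum(edited)/sum(coverage) over all sites."""
    cov = int(sites[f"cov_{sample}"].sum())
    if cov == 0:
        raise ValidationError(f"sample {sample}: zero total coverage")
    return float(sites[f"alt_{sample}"].sum()) / cov


def editing_index_by_sample(sites: pd.DataFrame) -> pd.Series:
    return pd.Series(
        {s: editing_index(sites, s) for s in count_table_samples(sites)},
        name="editing_index",
    )
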