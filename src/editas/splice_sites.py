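"""Splice-site windows and editing-induced strength change.

The donor (5'ss) window is a 9-mer: the last 3 exonic and first 6 intronic
nucleotides; the acceptor (3'ss) window is a 23-mer: the last 20 intronic and
first 3 exonic nucleotides.  Windows are stored 5'->3' on the transcript
strand.  Positions are labelled by their 1-based distance from the
exon-intron boundary, e.g. ``5'ss-2e`` (2 nt into the exon at a donor) or
``3'ss-2i`` (2 nt into the intron at an acceptor).

Strength is a maximum-entropy log2-odds score.  When a directory with the
published MaxEntScan model tables is supplied, the standard 9-mer lookup
(donor) and sub-sequence decomposition product (acceptor) are used; otherwise
a first-order position-weight-matrix model trained on a genome's annotated
true splice sites serves as the scoring model so the pipeline runs without
external data.  The editing delta is ``score(edited) - score(unedited)``
(negative = weakening), with the A->G edit applied on the transcript strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, UserInputError, ValidationError
from .io import GeneModel, GenomicInterval
from .seqtools import fetch, revcomp

DONOR_LEN, DONOR_EXONIC = 9, 3
ACCEPTOR_LEN, ACCEPTOR_EXONIC = 23, 3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SpliceSiteWindow:
    kind: str  # 'donor' or 'acceptor'
    interval: GenomicInterval
    sequence: str  # transcript 5'->3'
    gene_id: str = ""
    transcript_id: str = ""

    def __post_init__(self) -> None:
        want = DONOR_LEN if self.kind == "donor" else ACCEPTOR_LEN
        if len(self.sequence) != want:
            raise ValidationError(
                f"{self.kind} window must be {want} nt, got {len(self.sequence)}"
            )


@dataclass
class StrengthDelta:
    site_id: str
    kind: str
    label: str
    unedited_score: float
    edited_score: float

    @property
    def delta(self) -> float:
        return self.edited_score - self.unedited_score


def extract_window(
    exon_boundary: int,
    kind: str,
    strand: str,
    chrom: str,
    genome: dict[str, str],
    gene_id: str = "",
    transcript_id: str = "",
) -> SpliceSiteWindow:
    """Extract the splice-site window around an exon boundary.

    ``exon_boundary`` is the genomic coordinate of the exon's terminal base at
    the junction (exon end for a '+' donor, exon start for a '-' donor, etc.).
    Minus-strand windows are reverse-complemented so the sequence reads
    5'->3' on the transcript.
    """
    if kind not in ("donor", "acceptor"):
        raise ValidationError(f"kind must be donor/acceptor, got {kind!r}")
    exonic = DONOR_EXONIC if kind == "donor" else ACCEPTOR_EXONIC
    intronic = (DONOR_LEN - DONOR_EXONIC) if kind == "donor" else (
        ACCEPTOR_LEN - ACCEPTOR_EXONIC
    )
    # On '+', a donor's intron lies right of the boundary and an acceptor's
    # intron lies left of it; on '-' the picture mirrors.
    intron_right = (kind == "donor") == (strand == "+")
    if intron_right:
        start = exon_boundary - exonic + 1
        end = exon_boundary + intronic
    else:
        start = exon_boundary - intronic
        end = exon_boundary + exonic - 1
    try:
        seq = fetch(genome, chrom, start, end)
    except IndexError as exc:
        raise UserInputError(f"splice window off chromosome end: {exc}") from None
    if strand == "-":
        seq = revcomp(seq)
    return SpliceSiteWindow(
        kind, GenomicInterval(chrom, start, end, strand), seq,
        gene_id, transcript_id,
    )


def _window_offset(pos: int, window: SpliceSiteWindow) -> int | None:
    """0-based transcript-strand offset of a genomic position, or None."""
    iv = window.interval
    if not iv.contains(pos):
        return None
    return (pos - iv.start) if iv.strand != "-" else (iv.end - pos)


def locate_res_in_window(pos: int, window: SpliceSiteWindow) -> str | None:
    """Positional label of a genomic position inside a window, else None."""
    off = _window_offset(pos, window)
    if off is None:
        return None
    return offset_to_label(window.kind, off)


def offset_to_label(kind: str, offset: int) -> str:
    if kind == "donor":
        if not 0 <= offset < DONOR_LEN:
            raise ValidationError(f"donor offset {offset} out of range")
        if offset < DONOR_EXONIC:
            return f"5'ss-{DONOR_EXONIC - offset}e"
        return f"5'ss-{offset - DONOR_EXONIC + 1}i"
    if kind == "acceptor":
        if not 0 <= offset < ACCEPTOR_LEN:
            raise ValidationError(f"acceptor offset {offset} out of range")
        intronic = ACCEPTOR_LEN - ACCEPTOR_EXONIC
        if offset < intronic:
            return f"3'ss-{intronic - offset}i"
        return f"3'ss-{offset - intronic + 1}e"
    raise ValidationError(f"unknown window kind {kind!r}")


_LABEL_RE = re.compile(r"^(5|3)'ss-(\d+)([ie])$")


def label_to_offset(label: str) -> tuple[str, int]:
    """Inverse of :func:`offset_to_label`; returns (kind, offset)."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValidationError(f"bad positional label {label!r}")
    ss, k, side = m.group(1), int(m.group(2)), m.group(3)
    if k < 1:
        raise ValidationError(f"label {label!r}: distance must be >= 1")
    kind = "donor" if ss == "5" else "acceptor"
    if kind == "donor":
        off = DONOR_EXONIC - k if side == "e" else DONOR_EXONIC + k - 1
        limit = DONOR_LEN
    else:
        intronic = ACCEPTOR_LEN - ACCEPTOR_EXONIC
        off = intronic - k if side == "i" else intronic + k - 1
        limit = ACCEPTOR_LEN
    if not 0 <= off < limit:
        raise ValidationError(f"label {label!r} outside the window")
    return kind, off


# ---------------------------------------------------------------------------
# Scoring models

class PWMSpliceModel:
    """First-order position-weight-matrix splice model (log2-odds vs uniform
    background), trainable from a genome's annotated true splice sites."""

    def __init__(self, kind: str, matrix: np.ndarray, pseudocount: float = 0.5):
        want = DONOR_LEN if kind == "donor" else ACCEPTOR_LEN
        if matrix.shape != (want, 4):
            raise ValidationError(f"matrix must be {want}x4")
        self.kind = kind
        self.matrix = matrix / matrix.sum(axis=1, keepdims=True)

    @classmethod
    def train(cls, kind: str, sequences: list[str], pseudocount: float = 0.5
              ) -> "PWMSpliceModel":
        want = DONOR_LEN if kind == "donor" else ACCEPTOR_LEN
        counts = np.full((want, 4), pseudocount)
        for seq in sequences:
            if len(seq) != want:
                raise ValidationError(f"training sequence of length {len(seq)}")
            for i, b in enumerate(seq):
                counts[i, _BASE_INDEX[b]] += 1
        return cls(kind, counts)

    @classmethod
    def from_gene_models(cls, kind: str, gene_models: list[GeneModel],
                         genome: dict[str, str]) -> "PWMSpliceModel":
        seqs = [w.sequence for w in windows_from_models(gene_models, genome)
                if w.kind == kind]
        if not seqs:
            raise ValidationError(f"no {kind} sites in the annotation")
        return cls.train(kind, seqs)

    def score(self, sequence: str) -> float:
        sequence = _check_seq(sequence, self.kind)
        idx = [_BASE_INDEX[b] for b in sequence]
        return float(np.sum(np.log2(self.matrix[np.arange(len(idx)), idx] / 0.25)))


def _check_seq(sequence: str, kind: str) -> str:
    want = DONOR_LEN if kind == "donor" else ACCEPTOR_LEN
    sequence = sequence.upper()
    if len(sequence) != want:
        raise ValidationError(
            f"{kind} model needs a {want}-mer, got {len(sequence)} nt"
        )
    if any(b not in _BASE_INDEX for b in sequence):
        raise ValidationError(f"non-ACGT base in {sequence!r}")
    return sequence


def _hash_kmer(kmer: str) -> int:
    h = 0
    for b in kmer:
        h = h * 4 + _BASE_INDEX[b]
    return h


def _load_table(path: Path, length: int) -> np.ndarray:
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                vals.append(float(line.split()[-1]))
    if len(vals) != 4 ** length:
        raise ParseError(
            f"{path}: expected {4 ** length} values, found {len(vals)}"
        )
    return np.array(vals)


class MaxEntDonorModel:
    """Donor (5'ss) maximum-entropy model using the published table layout:
    a 16384-entry probability table over the 7 non-consensus positions plus
    consensus factors for the GT dinucleotide at window positions 4-5."""

    CONS1 = {"A": 0.004, "C": 0.0032, "G": 0.9896, "T": 0.0072}
    CONS2 = {"A": 0.0034, "C": 0.0039, "G": 0.0042, "T": 0.9884}
    BGD = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
    kind = "donor"

    def __init__(self, table: np.ndarray):
        if len(table) != 4 ** 7:
            raise ValidationError("donor table must have 4^7 entries")
        self.table = table

    @classmethod
    def from_dir(cls, directory: str | Path) -> "MaxEntDonorModel":
        return cls(_load_table(Path(directory) / "me2x5", 7))

    def score(self, sequence: str) -> float:
        s = _check_seq(sequence, "donor")
        consensus = (
            self.CONS1[s[3]] * self.CONS2[s[4]] / (self.BGD[s[3]] * self.BGD[s[4]])
        )
        rest = s[:3] + s[5:]
        return float(np.log2(consensus * self.table[_hash_kmer(rest)]))


class MaxEntAcceptorModel:
    """Acceptor (3'ss) maximum-entropy model: consensus AG factor at window
    positions 19-20 and the published 9-table decomposition product over
    sub-sequences of the remaining 21-mer."""

    CONS1 = {"A": 0.9903, "C": 0.0032, "G": 0.0034, "T": 0.0030}
    CONS2 = {"A": 0.0027, "C": 0.0037, "G": 0.9905, "T": 0.0030}
    BGD = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
    kind = "acceptor"

    # (table index, start in the 21-mer rest, k-mer length); the final score
    # multiplies the first five and divides by the last four
    _PIECES = [
        (0, 0, 7), (1, 7, 7), (2, 14, 7), (3, 4, 7), (4, 11, 7),
        (5, 4, 3), (6, 7, 4), (7, 11, 3), (8, 14, 4),
    ]

    def __init__(self, tables: list[np.ndarray]):
        if len(tables) != 9:
            raise ValidationError("acceptor model needs 9 tables")
        self.tables = tables

    @classmethod
    def from_dir(cls, directory: str | Path) -> "MaxEntAcceptorModel":
        directory = Path(directory)
        lengths = [7, 7, 7, 7, 7, 3, 4, 3, 4]
        return cls(
            [_load_table(directory / f"me2x3acc{i + 1}", lengths[i])
             for i in range(9)]
        )

    def score(self, sequence: str) -> float:
        s = _check_seq(sequence, "acceptor")
        consensus = (
            self.CONS1[s[18]] * self.CONS2[s[19]]
            / (self.BGD[s[18]] * self.BGD[s[19]])
        )
        rest = s[:18] + s[20:]
        num, den = 1.0, 1.0
        for i, (tbl, start, k) in enumerate(self._PIECES):
            v = self.tables[tbl][_hash_kmer(rest[start : start + k])]
            if i < 5:
                num *= v
            else:
                den *= v
        return float(np.log2(consensus * num / den))


def load_maxent_models(directory: str | Path
                       ) -> dict[str, MaxEntDonorModel | MaxEntAcceptorModel]:
    return {
        "donor": MaxEntDonorModel.from_dir(directory),
        "acceptor": MaxEntAcceptorModel.from_dir(directory),
    }


def pwm_models_from_annotation(gene_models: list[GeneModel],
                               genome: dict[str, str]) -> dict[str, PWMSpliceModel]:
    return {
        kind: PWMSpliceModel.from_gene_models(kind, gene_models, genome)
        for kind in ("donor", "acceptor")
    }


def score_splice_site(sequence: str, model) -> float:
    """Score a 9-mer (donor model) or 23-mer (acceptor model)."""
    return model.score(sequence)


# ---------------------------------------------------------------------------
# Window enumeration and editing deltas

def windows_from_models(
    gene_models: list[GeneModel], genome: dict[str, str]
) -> list[SpliceSiteWindow]:
    """All donor/acceptor windows of annotated introns, deduplicated by
    genomic interval."""
    seen = set()
    out = []
    for m in gene_models:
        for a, b in zip(m.exons, m.exons[1:]):
            if m.strand == "-":
                donor_boundary, acceptor_boundary = b.start, a.end
            else:
                donor_boundary, acceptor_boundary = a.end, b.start
            for kind, boundary in (("donor", donor_boundary),
                                   ("acceptor", acceptor_boundary)):
                w = extract_window(boundary, kind, m.strand, m.chrom, genome,
                                   m.gene_id, m.transcript_id)
                key = (kind, m.chrom, w.interval.start, w.interval.end, m.strand)
                if key not in seen:
                    seen.add(key)
                    out.append(w)
    return out


def delta_strength(
    site_id: str, pos: int, window: SpliceSiteWindow, model
) -> StrengthDelta:
    """Editing-induced strength change at a site inside a window.

    The A->G edit is applied on the transcript strand; if the window base at
    the site is not A the site is flagged inconsistent and no delta is
    computed (``ValidationError``).
    """
    off = _window_offset(pos, window)
    if off is None:
        raise ValidationError(f"site at {pos} outside window {window.interval}")
    if window.sequence[off] != "A":
        raise ValidationError(
            f"window base at {pos} is {window.sequence[off]!r}, not A; "
            f"edit inconsistent with an A-to-I site"
        )
    edited = window.sequence[:off] + "G" + window.sequence[off + 1 :]
    return StrengthDelta(
        site_id,
        window.kind,
        offset_to_label(window.kind, off),
        model.score(window.sequence),
        model.score(edited),
    )


def scan_sites(
    sites: pd.DataFrame,
    gene_models: list[GeneModel],
    genome: dict[str, str],
    models: dict | None = None,
) -> pd.DataFrame:
    """Locate A-to-I sites inside splice windows and score their deltas.

    ``models`` maps 'donor'/'acceptor' to scoring models; defaults to PWM
    models trained on the annotation itself.
    """
    if models is None:
        models = pwm_models_from_annotation(gene_models, genome)
    windows = windows_from_models(gene_models, genome)
    by_chrom: dict[str, list[SpliceSiteWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.interval.chrom, []).append(w)
    rows = []
    for sid, row in sites.iterrows():
        pos = int(row["pos"])
        for w in by_chrom.get(row["chrom"], []):
            if not w.interval.contains(pos):
                continue
            if w.interval.strand != row["strand"]:
                continue
            try:
                d = delta_strength(sid, pos, w, models[w.kind])
            except ValidationError:
                rows.append((sid, w.kind, locate_res_in_window(pos, w),
                             np.nan, np.nan, np.nan, "inconsistent_base"))
                continue
            rows.append((sid, d.kind, d.label, d.unedited_score,
                         d.edited_score, d.delta, "ok"))
    return pd.DataFrame(
        rows,
        columns=["site_id", "kind", "label", "unedited_score", "edited_score",
                 "delta", "status"],
    )


def splice_proximal_fractions(deltas: pd.DataFrame) -> dict[str, float]:
    """Fraction of splice-proximal sites at acceptors (3'ss) vs donors."""
    n = len(deltas)
    if n == 0:
        return {"acceptor": float("nan"), "donor": float("nan")}
    acc = float((deltas["kind"] == "acceptor").mean())
    return {"acceptor": acc, "donor": 1.0 - acc}
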