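"""Editing-induced change in RBP motif binding.

For each A-to-I site, the +/-50 nt flank (transcript strand) is extracted
from the genome, the central A->G edit applied, and each RBP's position
weight matrix scanned over both versions.  The binding delta is the change in
the best log2-odds hit; a site-RBP combination is "altered" when the relative
change — delta over |unedited best| with a floor of 1.0 on the denominator —
strictly exceeds 20 %.

PWM text format: an ``>RBP_NAME`` header line followed by one line per motif
position with four whitespace-separated probabilities (A C G T order).  A
pseudocount of 1e-3 is applied on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .seqtools import revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
PSEUDOCOUNT = 1e-3
DEFAULT_RADIUS = 50
ALTERED_THRESHOLD = 0.20


@dataclass
class PWMotif:
    rbp: str
    matrix: np.ndarray  # length x 4 probabilities
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError("PWM must be L x 4")
        if not 4 <= len(self.matrix) <= 12:
            raise ValidationError(
                f"PWM length {len(self.matrix)} outside 4..12"
            )
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-6):
            raise ValidationError(f"{self.rbp}: PWM rows must sum to 1")
        if np.any(self.matrix <= 0):
            raise ValidationError(f"{self.rbp}: zero probability after pseudocount")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def logodds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


def _apply_pseudocount(matrix: np.ndarray, pseudocount: float = PSEUDOCOUNT
                       ) -> np.ndarray:
    m = np.asarray(matrix, float) + pseudocount
    return m / m.sum(axis=1, keepdims=True)


def motif_from_consensus(rbp: str, consensus: str) -> PWMotif:
    """Near-one-hot PWM for a consensus k-mer (pseudocount applied)."""
    m = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus.upper()):
        m[i, _BASE_INDEX[b]] = 1.0
    return PWMotif(rbp, _apply_pseudocount(m))


def read_pwms(path: str | Path) -> list[PWMotif]:
    motifs: list[PWMotif] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        if name is not None:
            if not rows:
                raise ParseError(f"{path}: motif {name!r} has no matrix rows")
            motifs.append(PWMotif(name, _apply_pseudocount(np.array(rows))))

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].strip(), []
            else:
                vals = line.split()
                if len(vals) != 4:
                    raise ParseError(f"{path}:{ln}: expected 4 probabilities")
                rows.append([float(v) for v in vals])
    flush()
    return motifs


def write_pwms(motifs: list[PWMotif], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.rbp}\n")
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Flank extraction and editing

@dataclass
class Flank:
    site_id: str
    sequence: str  # transcript strand
    center: int  # index of the edited base within sequence
    truncated: bool = False


def extract_flank(
    site_id: str,
    chrom: str,
    pos: int,
    strand: str,
    genome: dict[str, str],
    radius: int = DEFAULT_RADIUS,
) -> Flank:
    """+/-radius nt around a site, transcript-strand oriented.

    Near a chromosome end the flank is truncated (and flagged) rather than
    refused.
    """
    seq = genome[chrom]
    lo = max(1, pos - radius)
    hi = min(len(seq), pos + radius)
    sub = seq[lo - 1 : hi].upper()
    center = pos - lo
    if strand == "-":
        sub = revcomp(sub)
        center = len(sub) - 1 - center
    return Flank(site_id, sub, center, truncated=(hi - lo) < 2 * radius)


def apply_edit(flank: Flank, base_from: str = "A", base_to: str = "G") -> Flank:
    """Introduce the A->G edit at the flank center (transcript strand)."""
    cur = flank.sequence[flank.center]
    if cur != base_from:
        raise ValidationError(
            f"{flank.site_id}: center base is {cur!r}, expected {base_from!r}"
        )
    seq = (
        flank.sequence[: flank.center] + base_to
        + flank.sequence[flank.center + 1 :]
    )
    return Flank(flank.site_id, seq, flank.center, flank.truncated)


# ---------------------------------------------------------------------------
# Scanning

def scan_best_hit(sequence: str, motif: PWMotif) -> tuple[float, int]:
    """Best log2-odds score over all offsets, ties to the smallest offset."""
    L = len(motif)
    if len(sequence) < L:
        raise ValidationError(
            f"sequence ({len(sequence)} nt) shorter than motif ({L} nt)"
        )
    lo = motif.logodds
    idx = np.array([_BASE_INDEX.get(b, -1) for b in sequence.upper()])
    n = len(sequence) - L + 1
    scores = np.empty(n)
    for off in range(n):
        window = idx[off : off + L]
        if np.any(window < 0):
            scores[off] = -np.inf
            continue
        scores[off] = lo[np.arange(L), window].sum()
    best = int(np.argmax(scores))  # argmax returns the first maximum
    return float(scores[best]), best


@dataclass
class BindingDelta:
    site_id: str
    rbp: str
    unedited_score: float
    edited_score: float
    unedited_offset: int
    edited_offset: int

    @property
    def delta(self) -> float:
        return self.edited_score - self.unedited_score

    @property
    def relative_change(self) -> float:
        return self.delta / max(abs(self.unedited_score), 1.0)

    @property
    def altered(self) -> bool:
        return abs(self.relative_change) > ALTERED_THRESHOLD


def binding_delta(flank: Flank, motif: PWMotif) -> BindingDelta:
    """Best-hit score change between unedited and edited flank for one RBP."""
    edited = apply_edit(flank)
    s0, o0 = scan_best_hit(flank.sequence, motif)
    s1, o1 = scan_best_hit(edited.sequence, motif)
    return BindingDelta(flank.site_id, motif.rbp, s0, s1, o0, o1)


def is_altered(bd: BindingDelta, threshold: float = ALTERED_THRESHOLD,
               mode: str = "relative") -> bool:
    """Alteration call.  ``relative`` (default) compares |delta| over
    max(|unedited|, 1) to the threshold; ``absolute`` compares |delta|
    directly.  Strictly-greater in both modes."""
    if mode == "absolute":
        return abs(bd.delta) > threshold
    if mode != "relative":
        raise ValidationError(f"unknown alteration mode {mode!r}")
    return abs(bd.relative_change) > threshold


def scan_cohort(
    sites: pd.DataFrame,
    genome: dict[str, str],
    motifs: list[PWMotif],
    radius: int = DEFAULT_RADIUS,
    threshold: float = ALTERED_THRESHOLD,
) -> pd.DataFrame:
    """Binding deltas for every (A-to-I site, motif) combination."""
    rows = []
    for sid, row in sites.iterrows():
        flank = extract_flank(sid, row["chrom"], int(row["pos"]),
                              row["strand"], genome, radius)
        if flank.sequence[flank.center] != "A":
            continue  # not an A on the transcript strand; nothing to edit
        for motif in motifs:
            bd = binding_delta(flank, motif)
            rows.append(
                (sid, motif.rbp, bd.unedited_score, bd.edited_score,
                 bd.unedited_offset, bd.edited_offset, bd.delta,
                 bd.relative_change, abs(bd.relative_change) > threshold,
                 flank.truncated)
            )
    return pd.DataFrame(
        rows,
        columns=["site_id", "rbp", "unedited_score", "edited_score",
                 "unedited_offset", "edited_offset", "delta",
                 "relative_change", "altered", "flank_truncated"],
    )


def summarize_altered_rbps(deltas: pd.DataFrame) -> pd.DataFrame:
    """Per-RBP counts of altered sites, split into gain/loss of binding."""
    if deltas.empty:
        return pd.DataFrame(columns=["rbp", "gain", "loss", "total"]).set_index(
            "rbp"
        )
    alt = deltas[deltas["altered"]]
    rows = []
    for rbp, grp in alt.groupby("rbp"):
        gain = int((grp["delta"] > 0).sum())
        loss = int((grp["delta"] < 0).sum())
        rows.append((rbp, gain, loss, gain + loss))
    return (
        pd.DataFrame(rows, columns=["rbp", "gain", "loss", "total"])
        .sort_values("rbp")
        .set_index("rbp")
    )
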