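"""Small strand-aware sequence helpers shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(base: str) -> str:
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def fetch(genome: dict[str, str], chrom: str, start: int, end: int) -> str:
    """1-based inclusive substring of a chromosome; raises if out of range."""
    seq = genome[chrom]
    if start < 1 or end > len(seq):
        raise IndexError(
            f"{chrom}:{start}-{end} outside chromosome (length {len(seq)})"
        )
    return seq[start - 1 : end]
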