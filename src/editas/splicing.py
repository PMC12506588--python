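"""Alternative-splicing event enumeration, PSI quantification and testing.

Five event classes are derived from annotation by pairwise transcript
comparison within a gene: skipped exon (SE), retained intron (RI),
alternative 5'/3' splice site (A5SS/A3SS) and mutually exclusive exons (MXE).
Per-sample inclusion/skipping junction counts yield the length-normalized
percent-spliced-in,

    PSI = (I/L_I) / (I/L_I + S/L_S),

with junction-count effective lengths L_I/L_S of 2/1 (SE, RI), 2/2 (MXE) and
1/1 (A5SS, A3SS).  Differential splicing is a binomial likelihood-ratio test
with a group term (chi-square, 1 df); events are called at |dPSI| > 0.1 and
BH FDR < 0.05.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import GeneModel, GenomicInterval, junction_table_samples

EVENT_TYPES = ["SE", "A5SS", "A3SS", "MXE", "RI"]

#: (inclusion, skipping) effective junction counts per event class
EFFECTIVE_LENGTHS: dict[str, tuple[int, int]] = {
    "SE": (2, 1),
    "RI": (2, 1),
    "MXE": (2, 2),
    "A5SS": (1, 1),
    "A3SS": (1, 1),
}


@dataclass
class ASEvent:
    event_id: str
    type: str
    gene_id: str
    chrom: str
    strand: str
    coords: tuple[int, ...]  # sorted defining boundary coordinates
    len_inc: int = 1
    len_skip: int = 1
    inc: dict[str, int] = field(default_factory=dict)
    skip: dict[str, int] = field(default_factory=dict)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, min(self.coords), max(self.coords),
                               self.strand)

    def defining_boundaries(self) -> tuple[int, ...]:
        return self.coords


def _make_event(etype: str, gene: GeneModel, coords: tuple[int, ...]) -> ASEvent:
    coords = tuple(sorted(coords))
    eid = f"{etype}_{gene.chrom}_" + "_".join(map(str, coords))
    li, ls = EFFECTIVE_LENGTHS[etype]
    return ASEvent(eid, etype, gene.gene_id, gene.chrom, gene.strand, coords,
                   li, ls)


def enumerate_as_events(gene_models: list[GeneModel]) -> list[ASEvent]:
    """Derive the five AS event classes from multi-transcript genes.

    Event ids are deterministic (type + sorted defining coordinates), and
    duplicate discoveries across transcript pairs are merged.
    """
    by_gene: dict[str, list[GeneModel]] = defaultdict(list)
    for m in gene_models:
        by_gene[m.gene_id].append(m)

    events: dict[str, ASEvent] = {}

    def emit(etype: str, gene: GeneModel, coords: tuple[int, ...]) -> None:
        ev = _make_event(etype, gene, coords)
        events.setdefault(ev.event_id, ev)

    for gene_id, txs in by_gene.items():
        if len(txs) < 2:
            continue
        junctions = {
            t.transcript_id: {(a.end, b.start)
                              for a, b in zip(t.exons, t.exons[1:])}
            for t in txs
        }
        exon_sets = {
            t.transcript_id: {(e.start, e.end) for e in t.exons} for t in txs
        }
        all_junctions = set().union(*junctions.values())

        for t1 in txs:
            for i in range(1, len(t1.exons) - 1):
                prev, mid, nxt = t1.exons[i - 1 : i + 2]
                skip_jn = (prev.end, nxt.start)
                for t2 in txs:
                    if t2.transcript_id == t1.transcript_id:
                        continue
                    # SE: another transcript joins the flanks directly
                    if skip_jn in junctions[t2.transcript_id] and (
                        (mid.start, mid.end) not in exon_sets[t2.transcript_id]
                    ):
                        emit("SE", t1,
                             (prev.end, mid.start, mid.end, nxt.start))
                    # MXE: same flanking junction endpoints, different middle
                    for j in range(1, len(t2.exons) - 1):
                        p2, m2, n2 = t2.exons[j - 1 : j + 2]
                        if (
                            p2.end == prev.end
                            and n2.start == nxt.start
                            and (m2.start, m2.end) != (mid.start, mid.end)
                            and (m2.end < mid.start or mid.end < m2.start)
                            and (mid.start, mid.end) not in exon_sets[t2.transcript_id]
                            and (m2.start, m2.end) not in exon_sets[t1.transcript_id]
                        ):
                            first, second = sorted(
                                [(mid.start, mid.end), (m2.start, m2.end)]
                            )
                            emit("MXE", t1,
                                 (prev.end, *first, *second, nxt.start))
            # RI: a junction of t1 whose intron is fully inside an exon of t2
            for d, a in junctions[t1.transcript_id]:
                for t2 in txs:
                    if t2.transcript_id == t1.transcript_id:
                        continue
                    if any(s <= d and a <= e
                           for s, e in exon_sets[t2.transcript_id]):
                        emit("RI", t1, (d, a))

        # A5SS / A3SS from junction pairs sharing one boundary.  The two
        # differing boundaries must belong to overlapping exons (long/short
        # variants of the same exon); disjoint exons sharing a junction
        # endpoint arise from SE/MXE structures, not alternative splice sites.
        gene_exons = sorted(set().union(*exon_sets.values()))
        ends_at: dict[int, list[tuple[int, int]]] = defaultdict(list)
        starts_at: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for ex in gene_exons:
            ends_at[ex[1]].append(ex)
            starts_at[ex[0]].append(ex)

        def variants_overlap(exs1, exs2) -> bool:
            return any(
                e1[0] <= e2[1] and e2[0] <= e1[1] for e1 in exs1 for e2 in exs2
            )

        by_right: dict[int, set[int]] = defaultdict(set)
        by_left: dict[int, set[int]] = defaultdict(set)
        for d, a in all_junctions:
            by_right[a].add(d)
            by_left[d].add(a)
        strand = txs[0].strand
        for a, donors in by_right.items():
            etype = "A5SS" if strand == "+" else "A3SS"
            for d1 in sorted(donors):
                for d2 in sorted(donors):
                    if d1 < d2 and variants_overlap(ends_at[d1], ends_at[d2]):
                        emit(etype, txs[0], (d1, d2, a))
        for d, accs in by_left.items():
            etype = "A3SS" if strand == "+" else "A5SS"
            for a1 in sorted(accs):
                for a2 in sorted(accs):
                    if a1 < a2 and variants_overlap(starts_at[a1],
                                                    starts_at[a2]):
                        emit(etype, txs[0], (d, a1, a2))

    return sorted(events.values(), key=lambda e: (e.chrom, e.coords, e.event_id))


# ---------------------------------------------------------------------------
# PSI

def compute_psi(inc: int, skip: int, len_inc: int, len_skip: int) -> float:
    """Length-normalized percent-spliced-in; NaN when no informative reads."""
    if len_inc < 1 or len_skip < 1:
        raise ValidationError("effective lengths must be >= 1")
    if inc < 0 or skip < 0:
        raise ValidationError("negative junction counts")
    if inc + skip == 0:
        return float("nan")
    i = inc / len_inc
    s = skip / len_skip
    return i / (i + s)


def psi_matrix(junctions: pd.DataFrame) -> pd.DataFrame:
    """Event x sample PSI matrix from a junction count table."""
    samples = junction_table_samples(junctions)
    inc = junctions[[f"inc_{s}" for s in samples]].to_numpy(float)
    skip = junctions[[f"skip_{s}" for s in samples]].to_numpy(float)
    li = junctions["len_inc"].to_numpy(float)[:, None]
    ls = junctions["len_skip"].to_numpy(float)[:, None]
    i = inc / li
    s = skip / ls
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(inc + skip > 0, i / (i + s), np.nan)
    return pd.DataFrame(psi, index=junctions.index, columns=samples)


# ---------------------------------------------------------------------------
# Differential splicing

def _binom_ll(i: float, t: float) -> float:
    if t == 0:
        return 0.0
    p = i / t
    ll = 0.0
    if i > 0:
        ll += i * np.log(p)
    if t - i > 0:
        ll += (t - i) * np.log(1 - p)
    return ll


def differential_splicing(
    junctions: pd.DataFrame,
    design,
    group_a: str = "UIA",
    group_b: str = "RIA",
    min_samples: int = 2,
) -> pd.DataFrame:
    """Binomial LRT with a group term on inclusion counts, per event.

    dPSI is the mean length-normalized PSI difference (group_b - group_a).
    Events with fewer than ``min_samples`` defined-PSI samples in either group
    are skipped, not imputed.  Adds BH FDR over tested events.
    """
    table_samples = set(junction_table_samples(junctions))
    sa = [s for s in design.samples(group_a) if s in table_samples]
    sb = [s for s in design.samples(group_b) if s in table_samples]
    psi = psi_matrix(junctions)
    rows = []
    for eid, row in junctions.iterrows():
        ia = np.array([row[f"inc_{s}"] for s in sa], float)
        ka = np.array([row[f"skip_{s}"] for s in sa], float)
        ib = np.array([row[f"inc_{s}"] for s in sb], float)
        kb = np.array([row[f"skip_{s}"] for s in sb], float)
        def_a = (ia + ka) > 0
        def_b = (ib + kb) > 0
        if def_a.sum() < min_samples or def_b.sum() < min_samples:
            rows.append((eid, row["type"], np.nan, np.nan, np.nan, np.nan,
                         "insufficient_samples"))
            continue
        Ia, Ta = ia.sum(), (ia + ka).sum()
        Ib, Tb = ib.sum(), (ib + kb).sum()
        llr = 2.0 * (
            _binom_ll(Ia, Ta) + _binom_ll(Ib, Tb) - _binom_ll(Ia + Ib, Ta + Tb)
        )
        llr = max(0.0, llr)
        p = float(stats.chi2.sf(llr, df=1))
        psi_a = float(np.nanmean(psi.loc[eid, sa])) if def_a.any() else np.nan
        psi_b = float(np.nanmean(psi.loc[eid, sb])) if def_b.any() else np.nan
        rows.append((eid, row["type"], psi_a, psi_b, psi_b - psi_a, p, "ok"))
    out = pd.DataFrame(
        rows,
        columns=["event_id", "type", f"psi_{group_a}", f"psi_{group_b}",
                 "dpsi", "pvalue", "status"],
    ).set_index("event_id")
    tested = out["status"] == "ok"
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = bh_fdr(out.loc[tested, "pvalue"].to_numpy())
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values outside [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_dase(
    results: pd.DataFrame, min_dpsi: float = 0.1, max_fdr: float = 0.05
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Differential AS events: |dPSI| strictly > min_dpsi and FDR < max_fdr.

    Returns the significant subset plus a per-event-type tally (all five
    classes present, zero-filled).
    """
    tally = {t: 0 for t in EVENT_TYPES}
    if results.empty:
        return results, tally
    keep = (
        (results["status"] == "ok")
        & (results["dpsi"].abs() > min_dpsi)
        & (results["fdr"] < max_fdr)
    )
    out = results[keep]
    tally.update(Counter(out["type"]))
    return out, tally


def events_to_frame(events: list[ASEvent], samples: list[str] | None = None
                    ) -> pd.DataFrame:
    """Serialize ASEvent objects to the junction-table layout (counts of
    missing samples default to 0)."""
    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id, "type": ev.type, "gene_id": ev.gene_id,
            "chrom": ev.chrom, "strand": ev.strand,
            "coords": ",".join(map(str, ev.coords)),
            "len_inc": ev.len_inc, "len_skip": ev.len_skip,
        }
        for s in samples or sorted(set(ev.inc) | set(ev.skip)):
            row[f"inc_{s}"] = ev.inc.get(s, 0)
            row[f"skip_{s}"] = ev.skip.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("event_id", drop=False)


def frame_to_events(df: pd.DataFrame) -> list[ASEvent]:
    samples = junction_table_samples(df)
    events = []
    for _, row in df.iterrows():
        ev = ASEvent(
            row["event_id"], row["type"], row["gene_id"], row["chrom"],
            row["strand"], tuple(int(x) for x in str(row["coords"]).split(",")),
            int(row["len_inc"]), int(row["len_skip"]),
        )
        for s in samples:
            ev.inc[s] = int(row[f"inc_{s}"])
            ev.skip[s] = int(row[f"skip_{s}"])
        events.append(ev)
    return events
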