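"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the structure of a two-group aneurysm cohort (8
ruptured, 5 unruptured, optionally 16 controls): a small genome of
multi-transcript genes with canonical GT..AG introns, beta-binomially
distributed editing counts with group-specific means, five alternative
splicing classes with group-shifted PSI, editing-coupled PSI for planted
site-event pairs, RBP motifs created/destroyed by the A->G substitution, and
eCLIP-style peaks covering planted RBP-event regions.

Editing counts: ``coverage ~ Poisson(mean_coverage)`` truncated at 1,
``edited ~ BetaBinomial(coverage, mu_g, phi)`` with ``a = mu/phi``,
``b = (1-mu)/phi``.  Splicing: inclusion junction reads
``I ~ Binomial(depth, p)`` with ``p = psi*L_I / (psi*L_I + (1-psi)*L_S)`` so
the length-normalized PSI estimator is centred on the planted psi; for
coupled pairs ``logit(psi_s) = logit(psi_g) + slope * (e_s - mu_g)`` where
``e_s`` is that sample's realized editing level.

All randomness flows from integer-seeded per-component streams, so a fixed
seed gives byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ValidationError
from . import io as eio
from .io import GeneModel, GenomicInterval, SampleDesign
from .rbp import PWMotif, motif_from_consensus, write_pwms
from .seqtools import revcomp
from .splicing import ASEvent, enumerate_as_events


# ---------------------------------------------------------------------------
# Configuration and truth

@dataclass
class SimulationConfig:
    seed: int = 1
    # genome
    n_genes: int = 30
    exons_per_gene: int = 4
    exon_len: int = 120
    intron_len: int = 150
    intergenic: int = 300
    # cohort (mirrors the 8 ruptured + 5 unruptured study design)
    n_ria: int = 8
    n_uia: int = 5
    n_control: int = 0
    # editing sites
    n_sites: int = 60           # ordinary null sites
    n_dres: int = 30            # planted differential sites
    n_coupled: int = 8          # editing-coupled site/event pairs
    n_triplets: int = 12        # fully planted RES-RBP-AS triplets
    n_splice_window: int = 6    # sites inside donor/acceptor windows
    n_other_type: int = 5       # non-A-to-G mismatch sites
    n_gain: int = 4             # motif-creation (gain) disruption plans
    wes_fraction: float = 0.1
    dbsnp_fraction: float = 0.05
    # count models
    mean_coverage: float = 50.0
    phi_default: float = 0.02
    phi_coupled: float = 0.1
    phi_triplet: float = 0.3
    dres_mu: tuple[float, float] = (0.2, 0.4)
    coupled_mu: float = 0.4
    # splicing
    depth: int = 200
    n_dase: int = 10
    dase_psi: tuple[float, float] = (0.35, 0.65)
    coupling_slope: float = 4.0
    triplet_slope: float = 8.0
    # motifs
    motif_len: int = 6


@dataclass
class TruthSet:
    """Planted ground truth: per-site group means and overdispersion,
    per-event group PSI, coupled pairs, motif disruptions, peak plan."""

    sites: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    coupled_pairs: list[dict] = field(default_factory=list)
    motif_plan: list[dict] = field(default_factory=list)
    peak_plan: list[dict] = field(default_factory=list)
    wes_masked: list[str] = field(default_factory=list)
    dbsnp_masked: list[str] = field(default_factory=list)
    decoy_triplets: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        site_ids = {s["site_id"] for s in self.sites}
        event_ids = {e["event_id"] for e in self.events}
        for s in self.sites:
            for mu in s["mu"].values():
                if not 0 <= mu <= 1:
                    raise ValidationError(f"mu outside [0,1] at {s['site_id']}")
            if s["phi"] <= 0:
                raise ValidationError(f"phi <= 0 at {s['site_id']}")
        for e in self.events:
            for psi in e["psi"].values():
                if not 0 <= psi <= 1:
                    raise ValidationError(f"psi outside [0,1] at {e['event_id']}")
        for pair in self.coupled_pairs:
            if pair["site_id"] not in site_ids:
                raise ValidationError(f"coupling references missing site "
                                      f"{pair['site_id']}")
            if pair["event_id"] not in event_ids:
                raise ValidationError(f"coupling references missing event "
                                      f"{pair['event_id']}")

    def site(self, site_id: str) -> dict:
        for s in self.sites:
            if s["site_id"] == site_id:
                return s
        raise KeyError(site_id)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def make_design(config: SimulationConfig) -> SampleDesign:
    groups: dict[str, str] = {}
    for i in range(config.n_ria):
        groups[f"RIA_{i + 1}"] = "RIA"
    for i in range(config.n_uia):
        groups[f"UIA_{i + 1}"] = "UIA"
    for i in range(config.n_control):
        groups[f"CTL_{i + 1}"] = "control"
    return SampleDesign(groups)


# ---------------------------------------------------------------------------
# Genome

def simulate_genome(
    n_genes: int = 30,
    exons_per_gene: int = 4,
    exon_len: int = 120,
    intron_len: int = 150,
    seed: int = 1,
    intergenic: int = 300,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome with multi-transcript genes and canonical GT..AG introns.

    Every gene carries a full-length primary transcript (with CDS leaving
    30 nt UTRs) and one variant transcript cycling through the five AS
    classes, so annotation-derived event enumeration finds one planted event
    family per gene.  Strands alternate + / -.
    """
    if min(n_genes, exons_per_gene, exon_len, intron_len) < 1:
        raise ValidationError("all sizes must be >= 1")
    if exons_per_gene < 4:
        raise ValidationError("need >= 4 exons per gene for all event classes")
    rng = _rng(seed, 0)
    gene_span = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    total = n_genes * (gene_span + intergenic) + intergenic
    seq = rng.choice(list("ACGT"), size=total)
    chrom = "chr1"
    models: list[GeneModel] = []
    variant_cycle = ["SE", "RI", "A5SS", "A3SS", "MXE"]

    def set_base(pos: int, base: str) -> None:  # pos is 1-based
        seq[pos - 1] = base

    def set_intron_ends(s: int, e: int, strand: str) -> None:
        if strand == "+":
            set_base(s, "G"); set_base(s + 1, "T")
            set_base(e - 1, "A"); set_base(e, "G")
        else:
            set_base(s, "C"); set_base(s + 1, "T")
            set_base(e - 1, "A"); set_base(e, "C")

    for g in range(n_genes):
        start = intergenic + g * (gene_span + intergenic) + 1
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"G{g + 1:03d}"
        exons = []
        for i in range(exons_per_gene):
            es = start + i * (exon_len + intron_len)
            exons.append(GenomicInterval(chrom, es, es + exon_len - 1, strand))
        for a, b in zip(exons, exons[1:]):
            set_intron_ends(a.end + 1, b.start - 1, strand)

        # primary transcript: all exons, CDS trimmed by 30 nt at each end
        cds = [GenomicInterval(chrom, e.start, e.end, strand) for e in exons]
        cds[0] = GenomicInterval(chrom, cds[0].start + 30, cds[0].end, strand)
        cds[-1] = GenomicInterval(chrom, cds[-1].start, cds[-1].end - 30, strand)
        models.append(GeneModel(gene_id, f"{gene_id}.t1", chrom, strand,
                                exons, cds))

        vtype = variant_cycle[g % len(variant_cycle)]
        shift = 30
        if vtype == "SE":
            vex = [exons[0]] + exons[2:]
        elif vtype == "RI":
            merged = GenomicInterval(chrom, exons[0].start, exons[1].end, strand)
            vex = [merged] + exons[2:]
        elif vtype == "A5SS":
            ext = GenomicInterval(chrom, exons[0].start, exons[0].end + shift,
                                  strand)
            vex = [ext] + exons[1:]
            set_intron_ends(ext.end + 1, exons[1].start - 1, strand)
        elif vtype == "A3SS":
            ext = GenomicInterval(chrom, exons[1].start - shift, exons[1].end,
                                  strand)
            vex = [exons[0], ext] + exons[2:]
            set_intron_ends(exons[0].end + 1, ext.start - 1, strand)
        else:  # MXE: primary uses e1,e2,e4; variant uses e1,e3,e4
            models[-1] = GeneModel(gene_id, f"{gene_id}.t1", chrom, strand,
                                   [exons[0], exons[1], exons[3]], [])
            vex = [exons[0], exons[2], exons[3]]
            set_intron_ends(exons[1].end + 1, exons[3].start - 1, strand)
            set_intron_ends(exons[0].end + 1, exons[2].start - 1, strand)
            set_intron_ends(exons[2].end + 1, exons[3].start - 1, strand)
        models.append(GeneModel(gene_id, f"{gene_id}.t2", chrom, strand,
                                vex, []))

    return {chrom: "".join(seq)}, models


# ---------------------------------------------------------------------------
# Truth planning (places sites, fixes genome bases, assigns models)

def _tx_strand_pos_base(strand: str, base: str) -> str:
    from .seqtools import complement

    return base if strand != "-" else complement(base)


class _GenomeEditor:
    def __init__(self, genome: dict[str, str]):
        self.seqs = {c: list(s) for c, s in genome.items()}

    def set_tx_base(self, chrom: str, pos: int, strand: str, base: str) -> None:
        self.seqs[chrom][pos - 1] = _tx_strand_pos_base(strand, base)

    def get(self, chrom: str, pos: int) -> str:
        return self.seqs[chrom][pos - 1]

    def finalize(self) -> dict[str, str]:
        return {c: "".join(s) for c, s in self.seqs.items()}


def plan_truth(
    genome: dict[str, str],
    models: list[GeneModel],
    config: SimulationConfig,
) -> tuple[dict[str, str], TruthSet, list[ASEvent]]:
    """Place every planted site, pin the required genome bases, and build the
    :class:`TruthSet`.  Returns the (edited) genome, truth, and events."""
    rng = _rng(config.seed, 1)
    editor = _GenomeEditor(genome)
    events = enumerate_as_events(models)
    by_gene_events: dict[str, list[ASEvent]] = {}
    for ev in events:
        by_gene_events.setdefault(ev.gene_id, []).append(ev)

    genes = sorted({m.gene_id for m in models})
    primaries = {m.gene_id: m for m in models if m.transcript_id.endswith(".t1")}
    chrom = models[0].chrom
    truth = TruthSet()
    used: set[int] = set()

    def claim(pos: int, margin: int = 6) -> bool:
        if any(abs(pos - u) < margin for u in used):
            return False
        used.add(pos)
        return True

    def add_site(pos: int, strand: str, mu: dict[str, float], phi: float,
                 category: str, ref_tx: str = "A", alt_tx: str = "G",
                 force_base: bool = True) -> str:
        if force_base:
            editor.set_tx_base(chrom, pos, strand, ref_tx)
        ref = _tx_strand_pos_base(strand, ref_tx)
        alt = _tx_strand_pos_base(strand, alt_tx)
        sid = eio.site_id(chrom, pos, ref, alt)
        truth.sites.append(
            {"site_id": sid, "chrom": chrom, "pos": pos, "strand": strand,
             "ref": ref, "alt": alt, "mu": mu, "phi": phi,
             "category": category}
        )
        return sid

    def groups_mu(mu_uia: float, mu_ria: float) -> dict[str, float]:
        mu = {"UIA": mu_uia, "RIA": mu_ria}
        if config.n_control:
            mu["control"] = mu_uia
        return mu

    # --- coupled and triplet sites: one gene each, site in exon 3 interior
    n_special = config.n_triplets + config.n_coupled
    if n_special > len(genes):
        raise ValidationError("not enough genes for planted pairs")
    coupled_pairs_plain: list[dict] = []  # (site, event) without an RBP layer
    for i in range(n_special):
        gene = genes[i]
        model = primaries[gene]
        exon = model.exons[min(2, len(model.exons) - 1)]
        pos = exon.start + 60 + (i % 3)
        if not claim(pos):
            raise ValidationError("site placement collision")
        is_triplet = i < config.n_triplets
        phi = config.phi_triplet if is_triplet else config.phi_coupled
        slope = config.triplet_slope if is_triplet else config.coupling_slope
        sid = add_site(pos, model.strand,
                       groups_mu(config.coupled_mu, config.coupled_mu), phi,
                       "triplet" if is_triplet else "coupled")
        event = by_gene_events[gene][0]
        pair = {"site_id": sid, "event_id": event.event_id, "slope": slope}
        truth.coupled_pairs.append(pair)
        if is_triplet:
            rbp = f"RBP{i + 1:02d}"
            truth.motif_plan.append({"site_id": sid, "rbp": rbp, "sign": "loss"})
            truth.peak_plan.append({"rbp": rbp, "event_id": event.event_id})
        else:
            coupled_pairs_plain.append(pair)

    # motif-creation (gain) plans on plain coupled sites: the edited flank
    # gains a perfect match.  No peaks, so these never seed triplets.
    for k, pair in enumerate(coupled_pairs_plain[: config.n_gain]):
        truth.motif_plan.append(
            {"site_id": pair["site_id"], "rbp": f"RBPg{k + 1}", "sign": "gain"}
        )
    # decoy triplet combinations, each deterministically lacking one layer
    decoy_pool = coupled_pairs_plain[config.n_gain :]
    if len(decoy_pool) >= 1:  # altered motif + significant pair, no peak
        pair = decoy_pool[0]
        truth.motif_plan.append(
            {"site_id": pair["site_id"], "rbp": "RBPnoPeak", "sign": "loss"}
        )
        truth.decoy_triplets.append(
            {"site_id": pair["site_id"], "rbp": "RBPnoPeak",
             "event_id": pair["event_id"], "missing": "peak"}
        )
    if len(decoy_pool) >= 2:  # peak + significant pair, motif never altered
        pair = decoy_pool[1]
        truth.peak_plan.append(
            {"rbp": "RBPnoMotif", "event_id": pair["event_id"]}
        )
        truth.decoy_triplets.append(
            {"site_id": pair["site_id"], "rbp": "RBPnoMotif",
             "event_id": pair["event_id"], "missing": "motif"}
        )

    # --- splice-window sites at intron-2 boundaries of later genes
    window_genes = genes[n_special : n_special + config.n_splice_window]
    for j, gene in enumerate(window_genes):
        model = primaries[gene]
        if len(model.exons) < 3:
            continue
        e2, e3 = model.exons[1], model.exons[2]
        if model.strand == "+":
            # alternate acceptor 3'ss-2i (the A of AG) and donor 5'ss-2e
            pos = (e3.start - 2) if j % 2 == 0 else (e2.end - 1)
        else:
            pos = (e2.end + 2) if j % 2 == 0 else (e3.start + 1)
        if not claim(pos, margin=1):
            continue
        add_site(pos, model.strand, groups_mu(0.3, 0.3), config.phi_default,
                 "splice_window")

    # --- ordinary / differential / other-type sites across remaining genes
    pool_genes = genes[n_special:] or genes
    pool_positions: list[tuple[int, str]] = []
    for gene in pool_genes:
        model = primaries[gene]
        for exon in model.exons:
            for off in range(10, len(exon) - 10, 9):
                pool_positions.append((exon.start + off, model.strand))
        for intron in model.introns():
            for off in range(10, len(intron) - 10, 23):
                pool_positions.append((intron.start + off, model.strand))
    # a few intergenic positions between genes
    span = primaries[genes[0]].exons[0].start
    for k in range(1, 9):
        pool_positions.append((max(1, span - 30 * k), "+"))
    order = rng.permutation(len(pool_positions))

    mu_choices = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    cursor = 0

    def next_pos() -> tuple[int, str]:
        nonlocal cursor
        while cursor < len(order):
            pos, strand = pool_positions[order[cursor]]
            cursor += 1
            if claim(pos):
                return pos, strand
        raise ValidationError("ran out of candidate positions")

    for _ in range(config.n_sites):
        pos, strand = next_pos()
        mu = float(rng.choice(mu_choices))
        add_site(pos, strand, groups_mu(mu, mu), config.phi_default, "null")
    for k in range(config.n_dres):
        pos, strand = next_pos()
        lo, hi = config.dres_mu
        mu_uia, mu_ria = (lo, hi) if k % 2 == 0 else (hi, lo)
        add_site(pos, strand, groups_mu(mu_uia, mu_ria), config.phi_default,
                 "dres")
    for k in range(config.n_other_type):
        pos, strand = next_pos()
        add_site(pos, strand, groups_mu(0.3, 0.3), config.phi_default,
                 "other_type", ref_tx="C", alt_tx="T")

    # --- event truth: PSI per group
    special_events = {p["event_id"] for p in truth.coupled_pairs}
    psi_choices = np.array([0.3, 0.4, 0.5, 0.6, 0.7])
    dase_budget = config.n_dase
    for ev in events:
        if ev.event_id in special_events:
            psi = {"UIA": 0.5, "RIA": 0.5}
        elif dase_budget > 0 and ev.gene_id in pool_genes[config.n_splice_window:]:
            psi = {"UIA": config.dase_psi[0], "RIA": config.dase_psi[1]}
            dase_budget -= 1
        else:
            p = float(rng.choice(psi_choices))
            psi = {"UIA": p, "RIA": p}
        if config.n_control:
            psi["control"] = psi["UIA"]
        truth.events.append(
            {"event_id": ev.event_id, "type": ev.type, "gene_id": ev.gene_id,
             "psi": psi}
        )

    # make every planned motif's maximal hit unique within its +/-50 flank:
    # duplicate exact occurrences of the consensus (or its edited form) would
    # leave the best score unchanged by the edit
    for plan in truth.motif_plan:
        _ensure_unique_motif_site(editor, truth.site(plan["site_id"]),
                                  config.motif_len)

    new_genome = editor.finalize()
    truth.validate()
    return new_genome, truth, events


_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "C"}


def _tx_flank_from_editor(editor: _GenomeEditor, site: dict,
                          radius: int = 50) -> str:
    chrom, pos, strand = site["chrom"], site["pos"], site["strand"]
    seq = editor.seqs[chrom]
    if pos - radius < 1 or pos + radius > len(seq):
        raise ValidationError("planted motif site too close to chromosome end")
    sub = "".join(seq[pos - radius - 1 : pos + radius])
    return revcomp(sub) if strand == "-" else sub


def _ensure_unique_motif_site(editor: _GenomeEditor, site: dict,
                              motif_len: int, radius: int = 50) -> None:
    """Rewrite chance duplicate matches so the planned consensus (and its
    edited form) occurs exactly once in the site's flank, at the centre."""
    half = motif_len // 2
    planned = radius - half
    for _ in range(40):
        flank = _tx_flank_from_editor(editor, site, radius)
        cons_a = flank[planned : planned + motif_len]
        if cons_a[half] != "A":
            raise ValidationError(
                f"{site['site_id']}: flank centre is {cons_a[half]!r}, not A"
            )
        cons_g = cons_a[:half] + "G" + cons_a[half + 1 :]
        offending: tuple[int, str] | None = None
        for pat in (cons_a, cons_g):
            start = 0
            while offending is None:
                off = flank.find(pat, start)
                if off == -1:
                    break
                if not (pat == cons_a and off == planned):
                    offending = (off, pat)
                start = off + 1
            if offending:
                break
        if offending is None:
            return
        off, _pat = offending
        for j in range(off, off + motif_len):
            if planned <= j < planned + motif_len or j == radius:
                continue  # never touch the planned window or the site itself
            base = flank[j]
            pos_g = (site["pos"] - radius + j if site["strand"] != "-"
                     else site["pos"] + radius - j)
            editor.set_tx_base(site["chrom"], pos_g, site["strand"],
                               _NEXT_BASE[base])
            break
        else:
            raise ValidationError("cannot break duplicate motif occurrence")
    else:
        raise ValidationError(
            f"{site['site_id']}: duplicate motif matches persist"
        )


# ---------------------------------------------------------------------------
# Counts

def _truncated_poisson(rng: np.random.Generator, lam: float, size: int
                       ) -> np.ndarray:
    x = rng.poisson(lam, size=size)
    while (x == 0).any():
        zero = x == 0
        x[zero] = rng.poisson(lam, size=int(zero.sum()))
        # Poisson(lam) with lam >= 1 makes repeated zeros vanishingly rare;
        # the loop still terminates for tiny lam because each pass redraws.
        if lam < 1e-9:
            x[zero] = 1
    return x


def sample_betabinom(rng: np.random.Generator, n: np.ndarray, mu: float,
                     phi: float) -> np.ndarray:
    """Draw beta-binomial counts in the (mu, phi) parameterization; the
    degenerate mu in {0, 1} and phi -> 0 limits are handled exactly."""
    if mu <= 0:
        return np.zeros_like(n)
    if mu >= 1:
        return n.copy()
    if phi < 1e-8:
        p = np.full(len(n), mu)
    else:
        p = rng.beta(mu / phi, (1 - mu) / phi, size=len(n))
    return rng.binomial(n, p)


def simulate_editing_counts(
    truth: TruthSet,
    design: SampleDesign,
    mean_coverage: float = 50.0,
    seed: int = 1,
) -> pd.DataFrame:
    """Per-site per-sample (coverage, edited) count table from the truth."""
    rng = _rng(seed, 2)
    samples = design.samples()
    rows = []
    for site in truth.sites:
        rec = {"chrom": site["chrom"], "pos": site["pos"], "ref": site["ref"],
               "alt": site["alt"], "strand": site["strand"]}
        for s in samples:
            g = design.group_of(s)
            cov = int(_truncated_poisson(rng, mean_coverage, 1)[0])
            edited = int(sample_betabinom(
                rng, np.array([cov]), site["mu"][g], site["phi"])[0])
            rec[f"cov_{s}"] = cov
            rec[f"alt_{s}"] = edited
        rows.append(rec)
    df = pd.DataFrame(rows)
    df.index = pd.Index(
        [eio.site_id(c, p, r, a)
         for c, p, r, a in zip(df.chrom, df.pos, df.ref, df.alt)],
        name="site_id",
    )
    return df


def realized_editing_levels(counts: pd.DataFrame) -> pd.DataFrame:
    samples = eio.count_table_samples(counts)
    cov = counts[[f"cov_{s}" for s in samples]].to_numpy(float)
    alt = counts[[f"alt_{s}" for s in samples]].to_numpy(float)
    return pd.DataFrame(alt / np.maximum(cov, 1), index=counts.index,
                        columns=samples)


def simulate_splicing_counts(
    truth: TruthSet,
    design: SampleDesign,
    events: list[ASEvent],
    depth: int = 200,
    editing_levels: pd.DataFrame | None = None,
    seed: int = 1,
) -> pd.DataFrame:
    """Junction count table; coupled events tilt per-sample PSI by the
    realized editing level of their partner site."""
    rng = _rng(seed, 3)
    samples = design.samples()
    truth_by_event = {e["event_id"]: e for e in truth.events}
    coupling = {p["event_id"]: p for p in truth.coupled_pairs}
    ev_by_id = {e.event_id: e for e in events}

    for pair in truth.coupled_pairs:
        if editing_levels is not None and (
            pair["site_id"] not in editing_levels.index
        ):
            raise ValidationError(
                f"coupling references site {pair['site_id']} absent from the "
                f"editing-level table"
            )
        if pair["event_id"] not in ev_by_id:
            raise ValidationError(
                f"coupling references unknown event {pair['event_id']}"
            )

    rows = []
    for et in truth.events:
        ev = ev_by_id[et["event_id"]]
        rec = {"event_id": ev.event_id, "type": ev.type, "gene_id": ev.gene_id,
               "chrom": ev.chrom, "strand": ev.strand,
               "coords": ",".join(map(str, ev.coords)),
               "len_inc": ev.len_inc, "len_skip": ev.len_skip}
        pair = coupling.get(ev.event_id)
        for s in samples:
            g = design.group_of(s)
            psi = float(et["psi"][g])
            if pair is not None and editing_levels is not None:
                site = truth.site(pair["site_id"])
                e_s = float(editing_levels.loc[pair["site_id"], s])
                mu_g = float(site["mu"][g])
                psi = float(
                    expit(logit(np.clip(psi, 1e-6, 1 - 1e-6))
                          + pair["slope"] * (e_s - mu_g))
                )
            if psi >= 1.0:
                inc = depth
            elif psi <= 0.0:
                inc = 0
            else:
                p = psi * ev.len_inc / (psi * ev.len_inc
                                        + (1 - psi) * ev.len_skip)
                inc = int(rng.binomial(depth, p))
            rec[f"inc_{s}"] = inc
            rec[f"skip_{s}"] = depth - inc
        rows.append(rec)
    return pd.DataFrame(rows).set_index("event_id", drop=False)


# ---------------------------------------------------------------------------
# Motifs, peaks, masks

PYRIMIDINE_DECOYS = ["TTCTTC", "CCTTCC"]


def simulate_motifs_and_peaks(
    truth: TruthSet,
    genome: dict[str, str],
    events: list[ASEvent],
    motif_len: int = 6,
    seed: int = 1,
) -> tuple[list[PWMotif], list[tuple[GenomicInterval, str]]]:
    """PWMs realizing the motif-disruption plan, plus eCLIP-style peaks.

    'loss' plans embed the unedited flank k-mer (centre A) as the motif
    consensus so the A->G edit breaks a perfect match; 'gain' plans use the
    edited k-mer (centre G).  Decoy RBPs carry all-pyrimidine consensi whose
    scores are provably unchanged by an A->G edit.
    """
    if not 4 <= motif_len <= 8:
        raise ValidationError("motif length must be in 4..8")
    if not truth.motif_plan and not truth.peak_plan:
        return [], []
    motifs: list[PWMotif] = []
    half = motif_len // 2
    for plan in truth.motif_plan:
        site = truth.site(plan["site_id"])
        kmer = _tx_kmer(genome, site["chrom"], site["pos"], site["strand"],
                        half, motif_len)
        if kmer[half] != "A":
            raise ValidationError(
                f"{plan['site_id']}: flank centre is {kmer[half]!r}, not A"
            )
        if plan["sign"] == "gain":
            kmer = kmer[:half] + "G" + kmer[half + 1 :]
        motifs.append(motif_from_consensus(plan["rbp"], kmer))
    # peak-plan RBPs without a motif plan (decoys) and two global decoys get
    # all-pyrimidine consensi: an A->G edit provably never changes their score
    planned_rbps = {p["rbp"] for p in truth.motif_plan}
    peak_only = sorted({p["rbp"] for p in truth.peak_plan} - planned_rbps)
    for i, rbp_name in enumerate(peak_only):
        cons = (PYRIMIDINE_DECOYS[i % len(PYRIMIDINE_DECOYS)] * 2)[:motif_len]
        motifs.append(motif_from_consensus(rbp_name, cons))
    for i, cons in enumerate(PYRIMIDINE_DECOYS):
        motifs.append(motif_from_consensus(f"RBPdecoy{i + 1}",
                                           (cons * 2)[:motif_len]))

    ev_by_id = {e.event_id: e for e in events}
    peaks: list[tuple[GenomicInterval, str]] = []
    for plan in truth.peak_plan:
        ev = ev_by_id[plan["event_id"]]
        lo, hi = min(ev.coords), max(ev.coords)
        mid = (lo + hi) // 2
        peaks.append(
            (GenomicInterval(ev.chrom, max(1, mid - 25), mid + 25, "."),
             plan["rbp"])
        )
    # decoy peaks for decoy RBPs, far from every gene (chromosome tail)
    chrom = next(iter(genome))
    tail = len(genome[chrom])
    for i in range(len(PYRIMIDINE_DECOYS)):
        start = max(1, tail - 120 - 60 * i)
        peaks.append((GenomicInterval(chrom, start, start + 50, "."),
                      f"RBPdecoy{i + 1}"))
    return motifs, sorted(peaks, key=lambda p: (p[0].start, p[1]))


def simulate_wes_mask(
    counts: pd.DataFrame,
    fraction: float,
    seed: int = 1,
    eligible: list[str] | None = None,
) -> list[str]:
    """Mark a deterministic-size random subset of candidate sites as genomic
    variants (``round(fraction * n)`` of the eligible sites)."""
    if not 0 <= fraction <= 1:
        raise ValidationError("fraction must be in [0, 1]")
    rng = _rng(seed, 4)
    ids = list(eligible) if eligible is not None else list(counts.index)
    n_mask = int(round(fraction * len(ids)))
    if n_mask == 0:
        return []
    chosen = rng.choice(len(ids), size=n_mask, replace=False)
    return sorted(ids[i] for i in chosen)


# ---------------------------------------------------------------------------
# Whole-cohort convenience

def generate_cohort(
    outdir: str | Path, config: SimulationConfig | None = None
) -> dict[str, Path]:
    """Write a complete synthetic cohort (FASTA, GTF, TSVs, VCF, BEDs, PWMs,
    truth JSON) and return the file paths."""
    config = config or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, models = simulate_genome(
        config.n_genes, config.exons_per_gene, config.exon_len,
        config.intron_len, config.seed, config.intergenic,
    )
    genome, truth, events = plan_truth(genome, models, config)
    design = make_design(config)
    counts = simulate_editing_counts(truth, design, config.mean_coverage,
                                     config.seed)

    # masks over ordinary sites only, keeping planted couplings intact
    eligible = [s["site_id"] for s in truth.sites
                if s["category"] in ("null", "dres")]
    truth.wes_masked = simulate_wes_mask(counts, config.wes_fraction,
                                         config.seed, eligible)
    remaining = [s for s in eligible if s not in set(truth.wes_masked)]
    truth.dbsnp_masked = simulate_wes_mask(counts, config.dbsnp_fraction,
                                           config.seed + 1, remaining)

    levels = realized_editing_levels(counts)
    junctions = simulate_splicing_counts(truth, design, events, config.depth,
                                         levels, config.seed)
    motifs, peaks = simulate_motifs_and_peaks(truth, genome, events,
                                              config.motif_len, config.seed)

    # repeat annotation covering a subset of sites
    repeats: list[tuple[GenomicInterval, str]] = []
    for i, site in enumerate(truth.sites):
        if i % 3 == 0:
            repeats.append(
                (GenomicInterval(site["chrom"], max(1, site["pos"] - 20),
                                 site["pos"] + 20, "."), "AluSx")
            )
        elif i % 3 == 1:
            repeats.append(
                (GenomicInterval(site["chrom"], max(1, site["pos"] - 20),
                                 site["pos"] + 20, "."), "L1MA3")
            )
    repeats = sorted(repeats, key=lambda p: (p[0].start, p[1]))

    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "junctions": outdir / "junctions.tsv",
        "wes": outdir / "wes.vcf",
        "dbsnp": outdir / "dbsnp.tsv",
        "repeats": outdir / "repeats.bed",
        "motifs": outdir / "motifs.pwm",
        "eclip": outdir / "eclip.bed",
        "truth": outdir / "truth.json",
    }
    eio.write_fasta(genome, paths["genome"])
    eio.write_gtf(models, paths["gtf"])
    eio.write_count_table(counts, paths["counts"])
    eio.write_design(design, paths["design"])
    eio.write_junction_table(junctions, paths["junctions"])

    by_id = {s["site_id"]: s for s in truth.sites}
    eio.write_vcf_sites(
        [(by_id[s]["chrom"], by_id[s]["pos"], by_id[s]["ref"], by_id[s]["alt"])
         for s in truth.wes_masked],
        paths["wes"],
    )
    with open(paths["dbsnp"], "w") as fh:
        for s in truth.dbsnp_masked:
            fh.write(f"{by_id[s]['chrom']}\t{by_id[s]['pos']}\n")
    eio.write_bed(repeats, paths["repeats"])
    eio.write_bed(peaks, paths["eclip"])
    write_pwms(motifs, paths["motifs"])
    truth.to_json(paths["truth"])
    return paths


def _tx_kmer(genome: dict[str, str], chrom: str, pos: int, strand: str,
             half: int, k: int) -> str:
    """k-mer around a position on the transcript strand, centre index
    ``half``."""
    if strand == "-":
        lo, hi = pos - (k - 1 - half), pos + half
    else:
        lo, hi = pos - half, pos + k - 1 - half
    sub = genome[chrom][lo - 1 : hi].upper()
    return revcomp(sub) if strand == "-" else sub
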