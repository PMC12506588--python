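"""End-to-end orchestration: detect -> diff-edit -> splice -> associate ->
score-ss -> rbp -> network, with a machine- and human-readable summary.

Every stage writes its table before the next starts, so a failed run keeps
its partial outputs and later stages can be re-run against an existing run
directory.  The report contains no timestamps; a re-run on the same inputs
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import associate, detect, diffedit, network, rbp, splice_sites, splicing
from . import io as eio
from .errors import UserInputError

log = logging.getLogger("editas")

STAGES = ["detect", "diff-edit", "splice", "associate", "score-ss", "rbp",
          "network"]


@dataclass
class PipelineConfig:
    # inputs
    counts: str = "counts.tsv"
    design: str = "design.tsv"
    gtf: str = "genes.gtf"
    genome: str = "genome.fa"
    repeats: str | None = None
    wes: str | None = None
    dbsnp: str | None = None
    junctions: str = "junctions.tsv"
    motifs: str | None = None
    eclip: str | None = None
    maxent_dir: str | None = None
    # thresholds (defaults follow the published criteria)
    min_edited: int = 3
    min_coverage: int = 10
    min_delta: float = 0.05
    alpha: float = 0.05
    min_dpsi: float = 0.1
    max_fdr: float = 0.05
    min_abs_r: float = 0.5
    rbp_threshold: float = 0.20
    flank: int = 300
    radius: int = 50
    # groups and misc
    group_a: str = "UIA"
    group_b: str = "RIA"
    edit_type: str = "A-to-G"
    corr_method: str = "spearman"
    seed: int = 1

    def validate(self) -> None:
        for name, lo, hi in [("min_delta", 0, 1), ("alpha", 0, 1),
                             ("min_dpsi", 0, 1), ("max_fdr", 0, 1),
                             ("min_abs_r", 0, 1), ("rbp_threshold", 0, 10)]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise UserInputError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_edited < 0 or self.min_coverage < 0:
            raise UserInputError("count thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise UserInputError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> Path:
    """Execute all stages in dependency order into ``run_dir``."""
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    design = eio.read_design(config.design)
    gene_models = eio.read_gtf(config.gtf)
    genome = eio.read_fasta(config.genome)

    # ---- detect
    log.info("stage detect")
    counts = eio.read_count_table(config.counts)
    wes = eio.read_site_mask(config.wes) if config.wes else set()
    dbsnp = eio.read_site_mask(config.dbsnp) if config.dbsnp else set()
    passing, rejections = detect.apply_filters(
        counts, wes, dbsnp, config.min_edited, config.min_coverage
    )
    repeats = eio.read_bed_named(config.repeats) if config.repeats else None
    sites = detect.annotate_sites(passing, gene_models, repeats, genome)
    sites.to_csv(run_dir / "sites.tsv", sep="\t", index_label="site_id")
    rejections.to_csv(run_dir / "rejections.tsv", sep="\t")
    ag_sites = detect.select_edit_type(sites, config.edit_type)

    # ---- diff-edit
    log.info("stage diff-edit")
    dres_all = diffedit.test_differential_editing(
        ag_sites, design, config.group_a, config.group_b, config.min_coverage
    )
    dres_all.to_csv(run_dir / "diffedit.tsv", sep="\t")
    dres = diffedit.call_dres(dres_all, config.min_delta, config.alpha)
    dres.to_csv(run_dir / "dres.tsv", sep="\t")

    # ---- splice
    log.info("stage splice")
    junctions = eio.read_junction_table(config.junctions)
    psi = splicing.psi_matrix(junctions)
    psi.to_csv(run_dir / "psi.tsv", sep="\t", index_label="event_id")
    ds = splicing.differential_splicing(junctions, design, config.group_a,
                                        config.group_b)
    ds.to_csv(run_dir / "diffsplice.tsv", sep="\t")
    dase, dase_tally = splicing.call_dase(ds, config.min_dpsi, config.max_fdr)
    dase.to_csv(run_dir / "dase.tsv", sep="\t")
    events = splicing.frame_to_events(junctions)
    eio.write_bed([(ev.span, ev.event_id) for ev in events],
                  run_dir / "events.bed")

    # ---- associate
    log.info("stage associate")
    levels = detect.editing_levels(ag_sites, config.min_coverage)
    by_gene: dict[str, list] = {}
    for ev in events:
        by_gene.setdefault(ev.gene_id, []).append(ev)
    pairs = []
    for sid, row in ag_sites.iterrows():
        gene = row.get("gene_id", "")
        if not gene or gene not in by_gene:
            continue
        pair = associate.assign_nearest_event(sid, int(row["pos"]),
                                              by_gene[gene], gene)
        if pair is not None:
            pairs.append(pair)
    pair_stats = associate.correlate_pairs(pairs, levels, psi,
                                           method=config.corr_method)
    pair_stats.to_csv(run_dir / "pairs.tsv", sep="\t", index=False)
    sig_pairs = associate.filter_pairs(pair_stats, config.min_abs_r,
                                       config.alpha)
    sig_pairs.to_csv(run_dir / "sig_pairs.tsv", sep="\t", index=False)

    # ---- score-ss
    log.info("stage score-ss")
    if config.maxent_dir:
        models = splice_sites.load_maxent_models(config.maxent_dir)
    else:
        models = splice_sites.pwm_models_from_annotation(gene_models, genome)
    ss_deltas = splice_sites.scan_sites(ag_sites, gene_models, genome, models)
    ss_deltas.to_csv(run_dir / "splice_deltas.tsv", sep="\t", index=False)

    # ---- rbp
    log.info("stage rbp")
    if config.motifs:
        motifs = rbp.read_pwms(config.motifs)
        deltas = rbp.scan_cohort(ag_sites, genome, motifs, config.radius,
                                 config.rbp_threshold)
    else:
        deltas = pd.DataFrame(
            columns=["site_id", "rbp", "unedited_score", "edited_score",
                     "unedited_offset", "edited_offset", "delta",
                     "relative_change", "altered", "flank_truncated"]
        )
    deltas.to_csv(run_dir / "binding_deltas.tsv", sep="\t", index=False)
    tally = rbp.summarize_altered_rbps(deltas)
    tally.to_csv(run_dir / "rbp_tally.tsv", sep="\t")

    # ---- network
    log.info("stage network")
    peaks_by_rbp: dict[str, list] = {}
    if config.eclip:
        for iv, name in eio.read_bed_named(config.eclip):
            peaks_by_rbp.setdefault(name, []).append(iv)
    links = network.rbp_event_links(peaks_by_rbp, events, config.flank)
    triplets = network.build_triplets(deltas, links, sig_pairs)
    pd.DataFrame(
        [(t.site_id, t.rbp, t.event_id) for t in triplets],
        columns=["site_id", "rbp", "event_id"],
    ).to_csv(run_dir / "triplets.tsv", sep="\t", index=False)
    g = network.build_network(triplets)
    network.export_network(g, run_dir / "network_edges.tsv", "edge-list")
    network.export_network(g, run_dir / "network.graphml", "graphml")
    network.hub_degrees(g).to_csv(run_dir / "hubs.tsv", sep="\t", index=False)

    summarize_run(run_dir)
    return run_dir


def _count_rows(path: Path) -> int | None:
    if not path.exists():
        return None
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - 1)


def summarize_run(run_dir: str | Path) -> dict:
    """Recount stage outputs into report.json / report.txt.

    Counts are recomputed from the stage TSVs alone, so the report can be
    regenerated from a finished run directory; missing stages are listed as
    absent rather than crashing.
    """
    run_dir = Path(run_dir)
    report: dict = {"stages": {}}
    simple = {
        "sites_pass": "sites.tsv",
        "sites_rejected": "rejections.tsv",
        "sites_tested": "diffedit.tsv",
        "dres": "dres.tsv",
        "as_events": "diffsplice.tsv",
        "dase": "dase.tsv",
        "res_as_pairs": "pairs.tsv",
        "sig_pairs": "sig_pairs.tsv",
        "splice_window_res": "splice_deltas.tsv",
        "binding_deltas": "binding_deltas.tsv",
        "altered_rbps": "rbp_tally.tsv",
        "triplets": "triplets.tsv",
        "network_edges": "network_edges.tsv",
    }
    for key, fname in simple.items():
        n = _count_rows(run_dir / fname)
        report["stages"][key] = n if n is not None else "absent"

    dase_path = run_dir / "dase.tsv"
    if dase_path.exists():
        dase = pd.read_csv(dase_path, sep="\t")
        tally = {t: 0 for t in splicing.EVENT_TYPES}
        if "type" in dase.columns:
            for t, c in dase["type"].value_counts().items():
                tally[t] = int(c)
        report["dase_by_type"] = tally
    rej_path = run_dir / "rejections.tsv"
    if rej_path.exists():
        rej = pd.read_csv(rej_path, sep="\t")
        report["rejections_by_filter"] = (
            {k: int(v) for k, v in
             sorted(rej["filter"].value_counts().items())}
            if "filter" in rej.columns and len(rej) else {}
        )
    hubs_path = run_dir / "hubs.tsv"
    if hubs_path.exists():
        hubs = pd.read_csv(hubs_path, sep="\t")
        report["top_hubs"] = [
            {"node": r["node"], "kind": r["kind"], "degree": int(r["degree"])}
            for _, r in hubs.head(10).iterrows()
        ]

    with open(run_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    lines = ["editas run summary", "=" * 18]
    for key in simple:
        lines.append(f"{key:20s} {report['stages'][key]}")
    if "rejections_by_filter" in report:
        lines.append("rejections: " + json.dumps(
            report["rejections_by_filter"], sort_keys=True))
    if "dase_by_type" in report:
        lines.append("dase by type: " + json.dumps(
            report["dase_by_type"], sort_keys=True))
    for hub in report.get("top_hubs", []):
        lines.append(f"hub {hub['node']} ({hub['kind']}) degree {hub['degree']}")
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
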