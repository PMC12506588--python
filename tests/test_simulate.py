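import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from editas import io as eio
from editas import rbp
from editas.errors import ValidationError
from editas.seqtools import fetch, revcomp
from editas.simulate import (
    SimulationConfig,
    TruthSet,
    generate_cohort,
    make_design,
    sample_betabinom,
    simulate_editing_counts,
    simulate_genome,
    simulate_motifs_and_peaks,
    simulate_splicing_counts,
    simulate_wes_mask,
)


class TestGenome:
    def test_gene_count_and_two_transcripts_each(self):
        _, models = simulate_genome(n_genes=20, seed=3)
        genes = {m.gene_id for m in models}
        assert len(genes) == 20
        assert len(models) == 40

    def test_canonical_gt_ag_introns_everywhere(self):
        genome, models = simulate_genome(n_genes=10, seed=4)
        for m in models:
            for intron in m.introns():
                seq = fetch(genome, m.chrom, intron.start, intron.end)
                if m.strand == "-":
                    seq = revcomp(seq)
                assert seq[:2] == "GT", (m.transcript_id, intron)
                assert seq[-2:] == "AG", (m.transcript_id, intron)

    def test_same_seed_is_deterministic(self):
        g1, m1 = simulate_genome(seed=9)
        g2, m2 = simulate_genome(seed=9)
        assert g1 == g2
        assert m1 == m2
        g3, _ = simulate_genome(seed=10)
        assert g3 != g1

    def test_size_validation(self):
        with pytest.raises(ValidationError):
            simulate_genome(n_genes=0)


def _mini_truth(mu, phi=0.02):
    return TruthSet(sites=[{
        "site_id": "chr1:5:A>G", "chrom": "chr1", "pos": 5, "strand": "+",
        "ref": "A", "alt": "G", "mu": {"UIA": mu, "RIA": mu}, "phi": phi,
        "category": "null",
    }])


class TestEditingCounts:
    def test_degenerate_levels(self):
        design = make_design(SimulationConfig())
        zeros = simulate_editing_counts(_mini_truth(0.0), design, 30, seed=2)
        assert (zeros.filter(like="alt_").to_numpy() == 0).all()
        ones = simulate_editing_counts(_mini_truth(1.0), design, 30, seed=2)
        assert (ones.filter(like="alt_").to_numpy()
                == ones.filter(like="cov_").to_numpy()).all()

    def test_coverage_truncated_at_one(self):
        design = make_design(SimulationConfig())
        counts = simulate_editing_counts(_mini_truth(0.5), design, 1.0,
                                         seed=3)
        assert (counts.filter(like="cov_").to_numpy() >= 1).all()

    def test_binomial_limit_recovers_mean(self):
        """phi -> 0 at mu=0.5: per-site mean level approaches 0.5 within
        3 standard errors over 1000 sites (binomial closed form)."""
        rng = np.random.default_rng(5)
        n = rng.poisson(100, 1000) + 1
        k = sample_betabinom(rng, n, 0.5, 1e-12)
        levels = k / n
        se = float(np.sqrt(np.mean(0.25 / n) / 1000))
        assert abs(levels.mean() - 0.5) < 3 * se

    def test_overdispersion_widens_levels(self):
        rng = np.random.default_rng(6)
        n = np.full(4000, 200)
        tight = sample_betabinom(rng, n, 0.4, 1e-6) / n
        wide = sample_betabinom(rng, n, 0.4, 0.3) / n
        assert wide.std() > 3 * tight.std()


class TestSplicingCounts:
    def test_degenerate_psi_and_coupling_validation(self, cohort_dir):
        truth = TruthSet.from_json(cohort_dir / "truth.json")
        design = eio.read_design(cohort_dir / "design.tsv")
        from editas.splicing import frame_to_events

        events = frame_to_events(
            eio.read_junction_table(cohort_dir / "junctions.tsv"))
        # psi = 1 -> no skipping reads anywhere
        for e in truth.events:
            e["psi"] = {g: 1.0 for g in e["psi"]}
        truth.coupled_pairs = []
        jt = simulate_splicing_counts(truth, design, events, depth=50, seed=8)
        assert (jt.filter(like="skip_").to_numpy() == 0).all()
        # a coupling that names a missing site is rejected
        truth.coupled_pairs = [{"site_id": "chr1:1:A>G",
                                "event_id": events[0].event_id, "slope": 2}]
        levels = pd.DataFrame(
            np.zeros((1, len(design.samples()))),
            index=["other"], columns=design.samples())
        with pytest.raises(ValidationError, match="absent"):
            simulate_splicing_counts(truth, design, events, 50, levels, 8)


class TestMotifsAndPeaks:
    def test_no_plan_gives_empty_outputs(self, cohort_dir):
        truth = TruthSet.from_json(cohort_dir / "truth.json")
        truth.motif_plan = []
        truth.peak_plan = []
        genome = eio.read_fasta(cohort_dir / "genome.fa")
        from editas.splicing import frame_to_events

        events = frame_to_events(
            eio.read_junction_table(cohort_dir / "junctions.tsv"))
        motifs, peaks = simulate_motifs_and_peaks(truth, genome, events)
        assert motifs == [] and peaks == []

    def test_loss_plan_breaks_consensus_match(self, cohort_dir, truth):
        """For every planted loss, the unedited flank carries a perfect
        consensus match through the site and the edited flank does not."""
        genome = eio.read_fasta(cohort_dir / "genome.fa")
        motifs = {m.rbp: m for m in rbp.read_pwms(cohort_dir / "motifs.pwm")}
        sites = {s["site_id"]: s for s in truth["sites"]}
        for plan in truth["motif_plan"]:
            site = sites[plan["site_id"]]
            flank = rbp.extract_flank(site["site_id"], site["chrom"],
                                      site["pos"], site["strand"], genome)
            motif = motifs[plan["rbp"]]
            cons = motif.consensus
            if plan["sign"] == "loss":
                assert cons in flank.sequence
                edited = rbp.apply_edit(flank)
                assert cons not in edited.sequence
            else:  # gain: consensus appears only after editing
                assert cons not in flank.sequence
                assert cons in rbp.apply_edit(flank).sequence


class TestWesMask:
    def _counts(self, n):
        df = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(1, n + 1), "ref": "A",
            "alt": "G", "strand": "+", "cov_s1": 30, "alt_s1": 5,
        })
        df.index = pd.Index([f"chr1:{p}:A>G" for p in df.pos])
        return df

    def test_fraction_extremes_and_exact_count(self):
        counts = self._counts(500)
        assert simulate_wes_mask(counts, 0.0, seed=1) == []
        assert len(simulate_wes_mask(counts, 1.0, seed=1)) == 500
        assert len(simulate_wes_mask(counts, 0.1, seed=1)) == 50

    def test_fraction_out_of_range(self):
        with pytest.raises(ValidationError):
            simulate_wes_mask(self._counts(10), 1.5)


class TestCohortFiles:
    def test_byte_identical_regeneration(self, cohort_dir, tmp_path):
        cfg = SimulationConfig(seed=1)
        generate_cohort(tmp_path / "again", cfg)
        for f in ["genome.fa", "genes.gtf", "counts.tsv", "design.tsv",
                  "junctions.tsv", "wes.vcf", "dbsnp.tsv", "repeats.bed",
                  "motifs.pwm", "eclip.bed", "truth.json"]:
            assert filecmp.cmp(cohort_dir / f, tmp_path / "again" / f,
                               shallow=False), f

    def test_truth_references_only_existing_ids(self, cohort_dir, truth):
        counts = eio.read_count_table(cohort_dir / "counts.tsv")
        junctions = eio.read_junction_table(cohort_dir / "junctions.tsv")
        site_ids = set(counts.index)
        event_ids = set(junctions.index)
        assert {s["site_id"] for s in truth["sites"]} == site_ids
        assert {e["event_id"] for e in truth["events"]} == event_ids
        for p in truth["coupled_pairs"]:
            assert p["site_id"] in site_ids and p["event_id"] in event_ids
        for m in truth["motif_plan"]:
            assert m["site_id"] in site_ids
        assert set(truth["wes_masked"]) <= site_ids
        assert set(truth["dbsnp_masked"]).isdisjoint(truth["wes_masked"])

    def test_cohort_mirrors_study_design(self, cohort_dir):
        design = eio.read_design(cohort_dir / "design.tsv")
        assert len(design.samples("RIA")) == 8
        assert len(design.samples("UIA")) == 5
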