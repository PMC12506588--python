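import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from editas import splicing
from editas.errors import ValidationError
from editas.io import GeneModel, GenomicInterval, SampleDesign


def _tx(gene, tx, exons, strand="+"):
    return GeneModel(gene, tx, "chr1", strand,
                     [GenomicInterval("chr1", s, e, strand) for s, e in exons])


class TestEnumerate:
    def test_skipped_exon(self):
        t1 = _tx("g", "t1", [(1, 100), (201, 300), (401, 500)])
        t2 = _tx("g", "t2", [(1, 100), (401, 500)])
        events = splicing.enumerate_as_events([t1, t2])
        assert [e.type for e in events] == ["SE"]
        assert events[0].coords == (100, 201, 300, 401)
        assert (events[0].len_inc, events[0].len_skip) == (2, 1)

    def test_retained_intron(self):
        t1 = _tx("g", "t1", [(1, 100), (201, 300)])
        t2 = _tx("g", "t2", [(1, 300)])
        events = splicing.enumerate_as_events([t1, t2])
        assert [e.type for e in events] == ["RI"]
        assert events[0].coords == (100, 201)

    def test_alternative_splice_sites_strand_aware(self):
        # donor of intron shifts by 30 -> A5SS on '+', A3SS on '-'
        for strand, expected in (("+", "A5SS"), ("-", "A3SS")):
            t1 = _tx("g", "t1", [(1, 100), (201, 300)], strand)
            t2 = _tx("g", "t2", [(1, 130), (201, 300)], strand)
            events = splicing.enumerate_as_events([t1, t2])
            assert [e.type for e in events] == [expected]

    def test_mutually_exclusive_exons_without_spurious_altss(self):
        t1 = _tx("g", "t1", [(1, 100), (201, 300), (601, 700)])
        t2 = _tx("g", "t2", [(1, 100), (401, 500), (601, 700)])
        events = splicing.enumerate_as_events([t1, t2])
        assert [e.type for e in events] == ["MXE"]
        assert events[0].coords == (100, 201, 300, 401, 500, 601)

    def test_single_transcript_gene_has_no_events(self):
        t1 = _tx("g", "t1", [(1, 100), (201, 300)])
        assert splicing.enumerate_as_events([t1]) == []

    def test_event_ids_deterministic(self):
        t1 = _tx("g", "t1", [(1, 100), (201, 300), (401, 500)])
        t2 = _tx("g", "t2", [(1, 100), (401, 500)])
        a = splicing.enumerate_as_events([t1, t2])
        b = splicing.enumerate_as_events([t2, t1])
        assert [e.event_id for e in a] == [e.event_id for e in b]


class TestPsi:
    @pytest.mark.parametrize("inc,skip,li,ls,expected", [
        (0, 7, 2, 1, 0.0),
        (10, 0, 2, 1, 1.0),
        (30, 10, 2, 1, 0.6),   # (30/2)/(30/2 + 10/1)
        (30, 10, 1, 1, 0.75),
        (12, 4, 2, 2, 0.75),
    ])
    def test_formula(self, inc, skip, li, ls, expected):
        assert splicing.compute_psi(inc, skip, li, ls) == pytest.approx(
            expected)

    def test_undefined_without_reads(self):
        assert math.isnan(splicing.compute_psi(0, 0, 2, 1))

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            splicing.compute_psi(1, 1, 0, 1)
        with pytest.raises(ValidationError):
            splicing.compute_psi(-1, 1, 2, 1)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(1, 20))
    def test_scaling_invariance(self, inc, skip, factor):
        if inc + skip == 0:
            return
        a = splicing.compute_psi(inc, skip, 2, 1)
        b = splicing.compute_psi(inc * factor, skip * factor, 2, 1)
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(b)


class TestBhFdr:
    def test_known_values(self):
        assert splicing.bh_fdr([0.04]) == pytest.approx([0.04])
        np.testing.assert_allclose(
            splicing.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        np.testing.assert_allclose(splicing.bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_monotone_in_p(self):
        p = np.array([0.001, 0.01, 0.2, 0.9, 0.04, 0.5])
        fdr = splicing.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            splicing.bh_fdr([0.5, 1.5])


def _junction_frame(inc_by_sample, depth=100, li=2, ls=1):
    row = {"event_id": "E1", "type": "SE", "gene_id": "g", "chrom": "chr1",
           "strand": "+", "coords": "1,2,3,4", "len_inc": li, "len_skip": ls}
    for s, inc in inc_by_sample.items():
        row[f"inc_{s}"] = inc
        row[f"skip_{s}"] = depth - inc
    return pd.DataFrame([row]).set_index("event_id", drop=False)


class TestDifferentialSplicing:
    def test_identical_profiles_are_null(self):
        jt = _junction_frame({"U1": 40, "U2": 40, "R1": 40, "R2": 40})
        design = SampleDesign({"U1": "UIA", "U2": "UIA",
                               "R1": "RIA", "R2": "RIA"})
        res = splicing.differential_splicing(jt, design)
        assert res.loc["E1", "dpsi"] == pytest.approx(0.0)
        assert res.loc["E1", "pvalue"] > 0.99

    def test_insufficient_samples_skipped(self):
        jt = _junction_frame({"U1": 40, "R1": 40, "R2": 40})
        jt["inc_U1"], jt["skip_U1"] = 0, 0
        design = SampleDesign({"U1": "UIA", "R1": "RIA", "R2": "RIA"})
        res = splicing.differential_splicing(jt, design)
        assert res.loc["E1", "status"] == "insufficient_samples"

    def test_dpsi_sign_follows_group_b_minus_group_a(self):
        jt = _junction_frame({"U1": 20, "U2": 20, "R1": 80, "R2": 80})
        design = SampleDesign({"U1": "UIA", "U2": "UIA",
                               "R1": "RIA", "R2": "RIA"})
        res = splicing.differential_splicing(jt, design)
        assert res.loc["E1", "dpsi"] > 0
        assert res.loc["E1", "pvalue"] < 1e-6


class TestCallDase:
    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["event_id", "type", "dpsi", "fdr"])
        df["status"] = "ok"
        return df.set_index("event_id")

    def test_boundaries_and_tallies(self):
        res = self._results([
            ("e1", "SE", 0.10, 0.01),    # dropped: strict > on |dPSI|
            ("e2", "SE", 0.11, 0.049),   # kept
            ("e3", "RI", -0.5, 0.01),    # kept
            ("e4", "MXE", 0.5, 0.05),    # dropped: FDR not < 0.05
        ])
        out, tally = splicing.call_dase(res)
        assert list(out.index) == ["e2", "e3"]
        assert tally == {"SE": 1, "A5SS": 0, "A3SS": 0, "MXE": 0, "RI": 1}

    def test_empty(self):
        out, tally = splicing.call_dase(self._results([]))
        assert len(out) == 0
        assert sum(tally.values()) == 0

    def test_equals_brute_force_on_cohort(self, cohort):
        res = splicing.differential_splicing(cohort["junctions"],
                                             cohort["design"])
        out, _ = splicing.call_dase(res)
        expected = {
            eid for eid, row in res.iterrows()
            if row["status"] == "ok" and abs(row["dpsi"]) > 0.1
            and row["fdr"] < 0.05
        }
        assert set(out.index) == expected


def test_cohort_psi_recovery(cohort, truth):
    """PSI estimated from simulated junction counts recovers the planted
    group PSI of uncoupled events to within 0.03 on average."""
    psi = splicing.psi_matrix(cohort["junctions"])
    design = cohort["design"]
    coupled = {p["event_id"] for p in truth["coupled_pairs"]}
    errs = []
    for ev in truth["events"]:
        if ev["event_id"] in coupled:
            continue
        for g in ("UIA", "RIA"):
            est = psi.loc[ev["event_id"], design.samples(g)].mean()
            errs.append(abs(est - ev["psi"][g]))
    assert np.mean(errs) < 0.03


def test_events_frame_round_trip(cohort):
    events = splicing.frame_to_events(cohort["junctions"])
    frame = splicing.events_to_frame(
        events, samples=sorted(cohort["design"].groups))
    back = splicing.frame_to_events(frame)
    assert [(e.event_id, e.coords, e.inc, e.skip) for e in back] == [
        (e.event_id, e.coords, e.inc, e.skip) for e in events]
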