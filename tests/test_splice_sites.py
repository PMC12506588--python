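import math

import numpy as np
import pytest

from editas import detect, splice_sites as ss
from editas.errors import UserInputError, ValidationError
from editas.seqtools import revcomp


@pytest.fixture()
def flat_genome():
    rng = np.random.default_rng(1)
    return {"chrW": "".join(rng.choice(list("ACGT"), 600))}


class TestExtractWindow:
    def test_plus_donor_geometry(self, flat_genome):
        w = ss.extract_window(200, "donor", "+", "chrW", flat_genome)
        assert (w.interval.start, w.interval.end) == (198, 206)
        assert len(w.sequence) == 9
        assert w.sequence == flat_genome["chrW"][197:206]

    def test_plus_acceptor_geometry(self, flat_genome):
        w = ss.extract_window(300, "acceptor", "+", "chrW", flat_genome)
        assert (w.interval.start, w.interval.end) == (280, 302)
        assert len(w.sequence) == 23

    def test_minus_strand_equals_mirrored_plus(self, flat_genome):
        """Extraction on '-' equals extraction on the reverse-complemented
        genome at the mirrored coordinate."""
        seq = flat_genome["chrW"]
        mirrored = {"chrW": revcomp(seq)}
        L = len(seq)
        for kind in ("donor", "acceptor"):
            w_minus = ss.extract_window(200, kind, "-", "chrW", flat_genome)
            w_plus = ss.extract_window(L - 200 + 1, kind, "+", "chrW",
                                       mirrored)
            assert w_minus.sequence == w_plus.sequence

    def test_off_chromosome_rejected(self, flat_genome):
        with pytest.raises(UserInputError):
            ss.extract_window(2, "acceptor", "+", "chrW", flat_genome)


class TestPositionalLabels:
    def test_paper_positions(self, flat_genome):
        donor = ss.extract_window(200, "donor", "+", "chrW", flat_genome)
        assert ss.locate_res_in_window(202, donor) == "5'ss-2i"
        assert ss.locate_res_in_window(199, donor) == "5'ss-2e"
        acceptor = ss.extract_window(300, "acceptor", "+", "chrW", flat_genome)
        assert ss.locate_res_in_window(298, acceptor) == "3'ss-2i"
        assert ss.locate_res_in_window(270, acceptor) is None  # 30 nt away

    def test_label_offset_bijection(self):
        seen = set()
        for kind, L in (("donor", 9), ("acceptor", 23)):
            for off in range(L):
                label = ss.offset_to_label(kind, off)
                assert ss.label_to_offset(label) == (kind, off)
                seen.add(label)
        assert len(seen) == 32

    def test_bad_labels_rejected(self):
        for label in ("5'ss-0e", "5'ss-7i", "3'ss-21i", "x'ss-1i"):
            with pytest.raises(ValidationError):
                ss.label_to_offset(label)


class TestPwmModel:
    def test_score_is_pure_and_consensus_maximal(self, cohort):
        models = ss.pwm_models_from_annotation(cohort["models"],
                                               cohort["genome"])
        donor = models["donor"]
        seq = "CAGGTAAGT"
        assert donor.score(seq) == donor.score(seq)
        # the positionwise-consensus 9-mer scores at least as high as any
        # training window
        cons = "".join("ACGT"[i] for i in donor.matrix.argmax(axis=1))
        windows = [w.sequence for w in
                   ss.windows_from_models(cohort["models"], cohort["genome"])
                   if w.kind == "donor"]
        assert all(donor.score(cons) >= donor.score(w) for w in windows)

    def test_wrong_length_or_alphabet_rejected(self, cohort):
        models = ss.pwm_models_from_annotation(cohort["models"],
                                               cohort["genome"])
        with pytest.raises(ValidationError):
            models["donor"].score("ACGT")
        with pytest.raises(ValidationError):
            models["donor"].score("CAGGTNAGT")


def _write_tables(d):
    def write(name, length):
        vals = [1 + (i % 7) / 10 for i in range(4 ** length)]
        (d / name).write_text("\n".join(f"{v:.6f}" for v in vals) + "\n")
    write("me2x5", 7)
    for i, L in enumerate([7, 7, 7, 7, 7, 3, 4, 3, 4]):
        write(f"me2x3acc{i + 1}", L)


class TestMaxEntTables:
    """The table-driven scorers are checked against hand-computed values on
    synthetic tables (the published tables are external data)."""

    BI = {"A": 0, "C": 1, "G": 2, "T": 3}

    def _hash(self, kmer):
        v = 0
        for b in kmer:
            v = v * 4 + self.BI[b]
        return v

    def _val(self, kmer):
        return 1 + (self._hash(kmer) % 7) / 10

    def test_donor_decomposition(self, tmp_path):
        _write_tables(tmp_path)
        model = ss.MaxEntDonorModel.from_dir(tmp_path)
        seq = "CAGGTAAGT"
        cons = (model.CONS1[seq[3]] * model.CONS2[seq[4]]
                / (model.BGD[seq[3]] * model.BGD[seq[4]]))
        expected = math.log2(cons * self._val(seq[:3] + seq[5:]))
        assert model.score(seq) == pytest.approx(expected)

    def test_acceptor_decomposition(self, tmp_path):
        _write_tables(tmp_path)
        model = ss.MaxEntAcceptorModel.from_dir(tmp_path)
        seq = "TTCTTTTTCTTTTTTTTTAGGTC"
        cons = (model.CONS1[seq[18]] * model.CONS2[seq[19]]
                / (model.BGD[seq[18]] * model.BGD[seq[19]]))
        rest = seq[:18] + seq[20:]
        num = (self._val(rest[0:7]) * self._val(rest[7:14])
               * self._val(rest[14:21]) * self._val(rest[4:11])
               * self._val(rest[11:18]))
        den = (self._val(rest[4:7]) * self._val(rest[7:11])
               * self._val(rest[11:14]) * self._val(rest[14:18]))
        assert model.score(seq) == pytest.approx(math.log2(cons * num / den))

    def test_truncated_table_rejected(self, tmp_path):
        (tmp_path / "me2x5").write_text("1.0\n2.0\n")
        with pytest.raises(Exception):
            ss.MaxEntDonorModel.from_dir(tmp_path)


class TestDeltaStrength:
    def test_planted_consensus_breaking_edit_weakens(self, cohort, truth):
        """Acceptor-window edits at the AG's adenosine destroy the canonical
        3'ss; the delta must be negative and match brute-force rescoring."""
        models = ss.pwm_models_from_annotation(cohort["models"],
                                               cohort["genome"])
        sites = detect.annotate_sites(cohort["counts"], cohort["models"])
        deltas = ss.scan_sites(sites, cohort["models"], cohort["genome"],
                               models)
        window_sites = {s["site_id"] for s in truth["sites"]
                        if s["category"] == "splice_window"}
        hit = deltas[deltas["site_id"].isin(window_sites)
                     & (deltas["status"] == "ok")]
        assert len(hit) >= len(window_sites) - 1
        acceptors = hit[hit["label"] == "3'ss-2i"]
        assert len(acceptors) > 0
        assert (acceptors["delta"] < 0).all()
        # brute force: rescore the window with the base substituted
        windows = {
            (w.kind, w.interval.start, w.interval.end): w
            for w in ss.windows_from_models(cohort["models"], cohort["genome"])
        }
        for _, row in hit.iterrows():
            site = sites.loc[row["site_id"]]
            for w in windows.values():
                if w.kind == row["kind"] and w.interval.contains(
                        int(site["pos"])) and w.interval.strand == site["strand"]:
                    off = (int(site["pos"]) - w.interval.start
                           if w.interval.strand != "-"
                           else w.interval.end - int(site["pos"]))
                    edited = (w.sequence[:off] + "G" + w.sequence[off + 1:])
                    expect = (models[w.kind].score(edited)
                              - models[w.kind].score(w.sequence))
                    assert row["delta"] == pytest.approx(expect)
                    break

    def test_non_adenosine_site_flagged(self, flat_genome):
        w = ss.extract_window(200, "donor", "+", "chrW", flat_genome)
        off = next(i for i, b in enumerate(w.sequence) if b != "A")
        pos = w.interval.start + off

        class One:
            def score(self, s):
                return 0.0

        with pytest.raises(ValidationError, match="not A"):
            ss.delta_strength("s", pos, w, One())

    def test_outside_window_rejected(self, flat_genome):
        w = ss.extract_window(200, "donor", "+", "chrW", flat_genome)

        with pytest.raises(ValidationError, match="outside"):
            ss.delta_strength("s", 500, w, None)

    def test_delta_zero_when_sequence_unchanged(self):
        d = ss.StrengthDelta("s", "donor", "5'ss-1e", 3.2, 3.2)
        assert d.delta == 0.0


def test_splice_proximal_fractions(cohort):
    models = ss.pwm_models_from_annotation(cohort["models"], cohort["genome"])
    sites = detect.annotate_sites(cohort["counts"], cohort["models"])
    deltas = ss.scan_sites(sites, cohort["models"], cohort["genome"], models)
    frac = ss.splice_proximal_fractions(deltas)
    brute_acc = (deltas["kind"] == "acceptor").sum() / len(deltas)
    assert frac["acceptor"] == pytest.approx(brute_acc)
    assert frac["acceptor"] + frac["donor"] == pytest.approx(1.0)
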