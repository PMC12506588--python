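import numpy as np
import pandas as pd
import pytest

from editas import detect
from editas import io as eio
from editas.errors import ValidationError
from editas.io import GenomicInterval
from editas.seqtools import revcomp


@pytest.mark.parametrize(
    "ref,alt,strand,expected",
    [
        ("A", "G", "+", "A-to-G"),
        ("T", "C", "-", "A-to-G"),  # genomic T>C on '-' is an A-to-I edit
        ("C", "T", "+", "C-to-T"),
        ("G", "A", "-", "C-to-T"),
    ],
)
def test_edit_type_strand_resolution(ref, alt, strand, expected):
    assert detect.classify_edit_type(ref, alt, strand) == expected


def test_edit_type_rejects_identity():
    with pytest.raises(ValidationError):
        detect.classify_edit_type("A", "A", "+")


def _table(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "strand",
                                     "cov_s1", "alt_s1", "cov_s2", "alt_s2"])
    df.index = pd.Index(
        [eio.site_id(c, p, r, a)
         for c, p, r, a in zip(df.chrom, df.pos, df.ref, df.alt)],
        name="site_id")
    return df


class TestFilterCascade:
    def test_boundaries_and_attribution(self):
        table = _table([
            ("chr1", 1, "A", "G", "+", 10, 3, 5, 0),   # boundary pass
            ("chr1", 2, "A", "G", "+", 9, 3, 9, 3),    # coverage rule
            ("chr1", 3, "A", "G", "+", 100, 50, 90, 40),  # WES variant
            ("chr1", 4, "A", "G", "+", 100, 2, 50, 2),  # too few edited reads
            ("chr1", 5, "A", "G", "+", 100, 50, 90, 40),  # known SNP
        ])
        wes = {("chr1", 3)}
        dbsnp = {("chr1", 5), ("chr1", 3)}  # overlap goes to the WES filter
        passing, rej = detect.apply_filters(table, wes, dbsnp)
        assert list(passing.index) == ["chr1:1:A>G"]
        assert rej.loc["chr1:3:A>G", "filter"] == "wes_variant"
        assert rej.loc["chr1:5:A>G", "filter"] == "dbsnp"
        assert rej.loc["chr1:2:A>G", "filter"] == "min_coverage"
        assert rej.loc["chr1:4:A>G", "filter"] == "min_edited"
        assert detect.rejection_tally(rej) == {
            "wes_variant": 1, "dbsnp": 1, "min_coverage": 1, "min_edited": 1}

    def test_relaxing_thresholds_is_monotone(self, cohort):
        counts = cohort["counts"]
        strict, _ = detect.apply_filters(counts, cohort["wes"],
                                         cohort["dbsnp"], 3, 10)
        for me, mc in [(2, 10), (3, 5), (1, 1)]:
            relaxed, _ = detect.apply_filters(counts, cohort["wes"],
                                              cohort["dbsnp"], me, mc)
            assert set(strict.index) <= set(relaxed.index)

    def test_equals_brute_force_on_cohort(self, cohort):
        counts = cohort["counts"]
        wes = {t[:2] for t in cohort["wes"]}
        dbsnp = {t[:2] for t in cohort["dbsnp"]}
        samples = eio.count_table_samples(counts)
        expected = {
            sid for sid, row in counts.iterrows()
            if (row["chrom"], row["pos"]) not in wes
            and (row["chrom"], row["pos"]) not in dbsnp
            and any(row[f"alt_{s}"] >= 3 and row[f"cov_{s}"] >= 10
                    for s in samples)
        }
        passing, _ = detect.apply_filters(counts, cohort["wes"],
                                          cohort["dbsnp"])
        assert set(passing.index) == expected


class TestAnnotation:
    def test_region_precedence(self, toy_gene):
        model, _ = toy_gene
        cases = {
            130: "exonic", 105: "5'UTR", 275: "3'UTR",
            161: "splice-site", 162: "splice-site", 219: "splice-site",
            190: "intronic", 50: "intergenic", 350: "intergenic",
        }
        for pos, expected in cases.items():
            region, gene = detect.annotate_region("chrT", pos, [model])
            assert region == expected, pos
            assert (gene == "G1") == (expected != "intergenic")

    def test_repeat_classes(self):
        repeats = [(GenomicInterval("chr1", 100, 200), "AluSx"),
                   (GenomicInterval("chr1", 300, 400), "L1MA3")]
        assert detect.annotate_repeat("chr1", 150, repeats) == "Alu"
        assert detect.annotate_repeat("chr1", 350, repeats) == (
            "repetitive non-Alu")
        assert detect.annotate_repeat("chr1", 250, repeats) == "non-repetitive"

    def test_alu_wins_over_other_repeat_overlap(self):
        repeats = [(GenomicInterval("chr1", 100, 200), "L1MA3"),
                   (GenomicInterval("chr1", 150, 250), "AluY")]
        assert detect.annotate_repeat("chr1", 180, repeats) == "Alu"


class TestCodingConsequence:
    def _gene(self, seq, strand="+"):
        n = len(seq)
        exon = [GenomicInterval("chrC", 1, n, strand)]
        model = eio.GeneModel("G", "G.t", "chrC", strand, exon, exon)
        return model, {"chrC": seq}

    def test_standard_code_examples(self):
        model, genome = self._gene("AAACCA")  # Lys, Pro
        # A>G at codon position 1: AAA (Lys) -> GAA (Glu)
        assert detect.coding_consequence("chrC", 1, "G", [model],
                                         genome) == "nonsynonymous"
        # A>G at codon position 3: CCA (Pro) -> CCG (Pro)
        assert detect.coding_consequence("chrC", 6, "G", [model],
                                         genome) == "synonymous"

    def test_stopgain(self):
        model, genome = self._gene("TGCAAA")  # Cys; TGC -> TGA would be stop
        assert detect.coding_consequence("chrC", 3, "A", [model],
                                         genome) == "stopgain"

    def test_minus_strand_matches_full_translation_oracle(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(5)
        for _ in range(20):
            cds_tx = "ATG" + "".join(rng.choice(list("ACGT"), 9))
            genome_seq = revcomp(cds_tx)  # gene on the minus strand
            model, genome = self._gene(genome_seq, strand="-")
            pos = int(rng.integers(1, len(genome_seq) + 1))
            # a genomic T>C edit is A>G on the transcript strand
            alt = "C"
            mutated = genome_seq[: pos - 1] + alt + genome_seq[pos:]
            aa_ref = str(Seq(revcomp(genome_seq)).translate())
            aa_alt = str(Seq(revcomp(mutated)).translate())
            got = detect.coding_consequence("chrC", pos, alt, [model], genome)
            expected = "synonymous"
            for a, b in zip(aa_ref, aa_alt):
                if a != b:
                    expected = ("stopgain" if b == "*"
                                else "stoploss" if a == "*"
                                else "nonsynonymous")
                    break
            assert got == expected


class TestEditingIndex:
    def test_pooling_arithmetic(self):
        table = _table([("chr1", 1, "A", "G", "+", 10, 3, 10, 3),
                        ("chr1", 2, "A", "G", "+", 10, 0, 10, 3)])
        assert detect.editing_index(table, "s1") == pytest.approx(0.15)
        assert detect.editing_index(table, "s2") == pytest.approx(0.3)

    def test_all_zero_edited(self):
        table = _table([("chr1", 1, "A", "G", "+", 10, 0, 10, 0)])
        assert detect.editing_index(table, "s1") == 0.0

    def test_zero_coverage_flagged(self):
        table = _table([("chr1", 1, "A", "G", "+", 0, 0, 10, 0)])
        with pytest.raises(ValidationError):
            detect.editing_index(table, "s1")


def test_levels_below_coverage_are_missing():
    table = _table([("chr1", 1, "A", "G", "+", 9, 3, 20, 5)])
    lv = detect.editing_levels(table, min_coverage=10)
    assert np.isnan(lv.iloc[0]["s1"])
    assert lv.iloc[0]["s2"] == pytest.approx(0.25)


def test_cohort_annotation_matches_truth(cohort, truth):
    sites = detect.annotate_sites(cohort["counts"], cohort["models"],
                                  cohort["repeats"], cohort["genome"])
    by_id = {s["site_id"]: s for s in truth["sites"]}
    for sid, row in sites.iterrows():
        cat = by_id[sid]["category"]
        if cat == "other_type":
            assert row["edit_type"] == "C-to-T"
        else:
            assert row["edit_type"] == "A-to-G"
        if cat in ("triplet", "coupled"):
            assert row["region_class"] == "exonic"
        if cat == "splice_window":
            # acceptor 2i positions are intronic splice-site; donor 2e
            # positions sit 2 nt inside the exon
            assert row["region_class"] in ("splice-site", "exonic")
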