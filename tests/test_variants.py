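import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from venomtx import seqio, variants
from venomtx.seqio import TranscriptRecord


def make_transcript(cds_body="GCTGGAAAA", cls="PLA2"):
    """Transcript with CDS = ATG + body + TAA starting at position 3."""
    seq = "AAA" + "ATG" + cds_body + "TAA" + "TT"
    return TranscriptRecord("t1", f"{cls}-1", cls, seq, 3,
                            3 + 3 + len(cds_body) + 3)


def pileup_with_column(transcript, pos0, counts):
    """Pileup for one transcript with given A/C/G/T counts at pos0 and
    clean deep reference coverage elsewhere."""
    pile = variants.Pileup({transcript.id: len(transcript.sequence)})
    arr = pile.counts[transcript.id]
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for i, base in enumerate(transcript.sequence):
        arr[i, base_idx[base]] = 100
    arr[pos0] = 0
    for base, n in counts.items():
        arr[pos0, base_idx[base]] = n
    return pile


class TestCallSnps:
    def test_biallelic_55_45_called(self):
        t = make_transcript()
        pos = t.cds_start + 4
        pile = pileup_with_column(t, pos, {"A": 55, "G": 45})
        (call,) = variants.call_snps(pile, [t])
        assert call.position == pos + 1  # 1-based report
        assert (call.ref_base, call.alt_base) == ("A", "G")
        assert call.snp_pct == pytest.approx(45.0)
        assert call.coverage == 100

    @pytest.mark.parametrize("counts, called", [
        ({"A": 61, "G": 39}, False),   # 39 < 40
        ({"A": 60, "G": 40}, True),    # inclusive lower bound
        ({"A": 40, "G": 60}, True),    # inclusive upper bound
        ({"A": 10, "G": 9}, False),    # coverage 19 < 20
        ({"A": 11, "G": 9}, True),     # coverage 20 inclusive
        ({"A": 12000, "G": 9000}, False),  # coverage 21000 > 20000
    ])
    def test_window_and_coverage_bounds(self, counts, called):
        t = make_transcript()
        pos = t.cds_start + 4
        pile = pileup_with_column(t, pos, counts)
        calls = variants.call_snps(pile, [t])
        assert (len(calls) == 1) == called

    def test_sites_outside_cds_not_called(self):
        t = make_transcript()
        pile = pileup_with_column(t, 0, {"A": 50, "G": 50})  # 5' UTR
        assert variants.call_snps(pile, [t]) == []

    def test_triallelic_column_skipped(self):
        t = make_transcript()
        pos = t.cds_start + 4
        pile = pileup_with_column(t, pos, {"A": 50, "G": 40, "C": 10})
        assert variants.call_snps(pile, [t]) == []

    def test_monotone_in_window_and_coverage(self, rng):
        # relaxing the SNP% window or the coverage bounds never loses calls
        t = make_transcript(cds_body="GCTGGAAAA" * 20)
        pile = variants.Pileup({t.id: len(t.sequence)})
        arr = pile.counts[t.id]
        cov = rng.integers(5, 300, size=len(t.sequence))
        minor = (cov * rng.uniform(0.2, 0.5, size=len(t.sequence))).astype(
            int)
        arr[:, 0] = cov - minor
        arr[:, 2] = minor
        strict = variants.call_snps(pile, [t], min_pct=45, max_pct=55,
                                    min_cov=50, max_cov=200)
        loose = variants.call_snps(pile, [t], min_pct=40, max_pct=60,
                                   min_cov=20, max_cov=20000)
        strict_keys = {(c.transcript_id, c.position) for c in strict}
        loose_keys = {(c.transcript_id, c.position) for c in loose}
        assert strict_keys <= loose_keys


class TestClassifySnp:
    def test_third_position_synonymous(self):
        t = make_transcript(cds_body="GCTGGAAAA")
        # codon GCT at CDS offset 3..6; third position T->C stays Ala
        pos = t.cds_start + 5
        call = variants.classify_snp(t, pos, "T", "C")
        assert call.effect == "synonymous"
        assert call.aa_ref == call.aa_alt == "A"

    def test_first_position_gly_to_arg(self):
        t = make_transcript(cds_body="GCTGGAAAA")
        # codon GGA at CDS offset 6; G->A gives AGA (Arg)
        pos = t.cds_start + 6
        call = variants.classify_snp(t, pos, "G", "A")
        assert call.effect == "nonsynonymous"
        assert (call.aa_ref, call.aa_alt) == ("G", "R")

    def test_nonsense_flagged(self):
        t = make_transcript(cds_body="TGCGGAAAA")
        # codon TGC at CDS offset 3: C->A at third position gives TGA stop
        pos = t.cds_start + 5
        call = variants.classify_snp(t, pos, "C", "A")
        assert call.effect == "nonsense"
        assert call.aa_alt == "*"

    def test_outside_cds_rejected(self):
        t = make_transcript()
        with pytest.raises(ValueError):
            variants.classify_snp(t, 0, "A", "G")

    def test_agrees_with_exhaustive_codon_oracle(self):
        # every codon x position x alternate base, against biopython
        # translation as the independent oracle
        for codon in ("".join(c) for c in
                      itertools.product("ACGT", repeat=3)):
            if codon in seqio.STOP_CODONS:
                continue
            t = TranscriptRecord("t1", "PLA2-1", "PLA2",
                                 "ATG" + codon + "AAATAA", 0, 12)
            for within in range(3):
                for alt in "ACGT":
                    ref = codon[within]
                    if alt == ref:
                        continue
                    call = variants.classify_snp(t, 3 + within, ref, alt)
                    alt_codon = (codon[:within] + alt
                                 + codon[within + 1:])
                    aa_ref = str(Seq(codon).translate())
                    aa_alt = str(Seq(alt_codon).translate())
                    if aa_alt == "*":
                        assert call.effect == "nonsense"
                    elif aa_ref == aa_alt:
                        assert call.effect == "synonymous"
                    else:
                        assert call.effect == "nonsynonymous"
                    assert call.aa_ref == aa_ref


class TestTable3Effects:
    def test_toxin_nonsynonymous_share(self):
        t3 = seqio.load_fixture("table3")
        tox = t3[t3.type == "Toxin"]
        assert len(tox) == 11
        assert tox.transcript.nunique() == 9
        nonsyn = (tox.aa_ref != tox.aa_alt).mean()
        assert 100 * nonsyn == pytest.approx(45.5, abs=0.05)

    def test_nontoxin_counts(self):
        t3 = seqio.load_fixture("table3")
        nt = t3[t3.type == "Nontoxin"]
        assert len(nt) == 87
        assert nt.transcript.nunique() == 69
        assert 100 * (nt.aa_ref != nt.aa_alt).mean() == pytest.approx(
            26.4, abs=0.05)

    def test_kunitz_replacement_is_g_to_r(self):
        t3 = seqio.load_fixture("table3")
        row = t3[t3.transcript == "Kunitz inhibitor 1a"].iloc[0]
        assert (row.aa_ref, row.aa_alt) == ("G", "R")
        assert row.position == 280


class TestSnpDensity:
    def _records(self):
        body = "GCTGGAAAA" * 111  # 999 nt body, 1005-nt CDS total
        tox = TranscriptRecord("tox1", "PLA2-1", "PLA2",
                               "ATG" + body + "TAA", 0, 1005)
        nt = TranscriptRecord("nt1", "NONTOXIN-1", "NONTOXIN",
                              "ATG" + body + "TAA", 0, 1005)
        return [tox, nt]

    def test_two_snps_per_kb(self):
        body = "GCTGGAAAA" * 110 + "GCT"  # 993 nt; CDS totals 999 nt
        t = TranscriptRecord("tox1", "PLA2-1", "PLA2",
                             "ATG" + body + "TAA", 0, 999)
        calls = [variants.classify_snp(t, 5, body[2], "C"),
                 variants.classify_snp(t, 8, body[5], "C")]
        assert variants.snp_density(calls, [t], "toxin") \
            == pytest.approx(2.0, abs=0.01)

    def test_no_snps_is_absent_not_zero(self):
        recs = self._records()
        assert variants.snp_density([], recs, "toxin") is None

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            variants.snp_density([], [], "viral")


class TestHeterozygosityTest:
    @staticmethod
    def pearson_2x2(a, b, c, d):
        # hand-evaluated Pearson statistic on [[a, b-a], [c, d-c]]
        table = np.array([[a, b - a], [c, d - c]], dtype=float)
        total = table.sum()
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows @ cols / total
        return float(((table - expected) ** 2 / expected).sum())

    def test_study_counts_give_pearson_value(self):
        res = variants.heterozygosity_test(9, 75, 69, 1950)
        oracle = self.pearson_2x2(9, 75, 69, 1950)
        assert res.statistic == pytest.approx(oracle, rel=1e-12)
        assert res.statistic == pytest.approx(13.96, abs=0.005)
        assert res.df == 1

    def test_equal_frequencies_give_zero(self):
        res = variants.heterozygosity_test(10, 100, 100, 1000)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            variants.heterozygosity_test(0, 0, 5, 10)


class TestChisqSf:
    def test_closed_forms(self):
        from scipy.special import erfc
        for x in (0.1, 1.0, 4.2, 17.3):
            assert variants.chisq_sf(x, 2) == pytest.approx(
                np.exp(-x / 2), rel=1e-12)
            assert variants.chisq_sf(x, 1) == pytest.approx(
                erfc(np.sqrt(x / 2)), rel=1e-12)

    def test_boundary(self):
        assert variants.chisq_sf(0.0, 1) == 1.0

    def test_study_tail_values(self):
        assert variants.chisq_sf(6.383, 1) == pytest.approx(0.0115,
                                                            abs=5e-5)
        assert variants.chisq_sf(5.84, 2) == pytest.approx(0.0539,
                                                           abs=5e-5)
        assert variants.chisq_sf(20.02, 2) == pytest.approx(4.49e-5,
                                                            rel=5e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            variants.chisq_sf(-1.0, 1)
        with pytest.raises(ValueError):
            variants.chisq_sf(1.0, 3)
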