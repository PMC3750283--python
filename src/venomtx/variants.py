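"""Heterozygous SNP calling and the toxin-vs-nontoxin comparison.

A diploid venom gland sequenced deeply enough shows heterozygous sites as
biallelic pileup columns with the minor allele near 50%. A site is called
a putative heterozygous SNP iff it lies in the CDS of an annotated
transcript, coverage is within [20, 20000], and the second-most-common
base accounts for 40-60% of reads. Calls are classified as synonymous or
nonsynonymous by translating the affected codon with the reference versus
alternate base, and the per-class frequency of heterozygous transcripts
is compared with a Pearson chi-square test (df=1, no continuity
correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .abundance import MappingHit
from .readmerge import reverse_complement
from .seqio import TranscriptRecord, translate_codon

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class Pileup:
    """Per-position A/C/G/T counts for each transcript."""

    def __init__(self, lengths: dict[str, int]):
        self.counts: dict[str, np.ndarray] = {
            tid: np.zeros((length, 4), dtype=np.int64)
            for tid, length in lengths.items()}

    def coverage(self, transcript_id: str) -> np.ndarray:
        return self.counts[transcript_id].sum(axis=1)

    def add_read(self, transcript_id: str, start: int, seq: str) -> None:
        arr = self.counts[transcript_id]
        if start < 0 or start + len(seq) > arr.shape[0]:
            raise IndexError(
                f"read beyond bounds of {transcript_id} "
                f"(start {start}, length {len(seq)})")
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        pos = np.arange(start, start + len(seq))
        for base, col in _BASE_INDEX.items():
            mask = codes == ord(base)
            if mask.any():
                np.add.at(arr[:, col], pos[mask], 1)


def build_pileup(hits: list[MappingHit],
                 reads: dict[str, str],
                 transcripts: list[TranscriptRecord]) -> Pileup:
    """Tally every aligned read base at its transcript coordinate."""
    pileup = Pileup({t.id: len(t.sequence) for t in transcripts})
    for h in hits:
        seq = reads[h.read_id]
        if h.reverse:
            seq = reverse_complement(seq)
        pileup.add_read(h.transcript_id, h.start, seq)
    return pileup


@dataclass(frozen=True)
class SnpCall:
    transcript_id: str
    position: int  # 1-based, as printed in reports
    ref_base: str
    alt_base: str
    snp_pct: float  # minor-allele read fraction x 100
    coverage: int
    effect: str  # synonymous | nonsynonymous | nonsense
    aa_ref: str
    aa_alt: str


def call_snps(pileup: Pileup,
              transcripts: list[TranscriptRecord],
              min_pct: float = 40.0, max_pct: float = 60.0,
              min_cov: int = 20, max_cov: int = 20000,
              noise_floor: float = 0.05) -> list[SnpCall]:
    """Call heterozygous SNPs under the frequency/coverage filters.

    Bounds are inclusive. Columns where more than two bases exceed
    ``noise_floor`` of the coverage are ambiguous (tri-allelic or noisy)
    and are skipped. The majority base is the reference, the runner-up the
    alternate.
    """
    calls: list[SnpCall] = []
    for t in transcripts:
        if t.id not in pileup.counts:
            continue
        arr = pileup.counts[t.id]
        cov = arr.sum(axis=1)
        in_window = (cov >= min_cov) & (cov <= max_cov)
        in_window[:t.cds_start] = False
        in_window[t.cds_end:] = False
        sorted_counts = np.sort(arr, axis=1)
        second = sorted_counts[:, -2]
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(cov > 0, 100.0 * second / np.maximum(cov, 1), 0.0)
        candidate = in_window & (pct >= min_pct) & (pct <= max_pct)
        for pos in np.nonzero(candidate)[0]:
            column = arr[pos]
            n_above = int(np.count_nonzero(column > noise_floor * cov[pos]))
            if n_above > 2:
                continue  # not a clean biallelic column
            order = np.argsort(column, kind="stable")
            ref = _BASES[order[-1]]
            alt = _BASES[order[-2]]
            call = classify_snp(t, int(pos), ref, alt,
                                snp_pct=float(pct[pos]),
                                coverage=int(cov[pos]))
            calls.append(call)
    return calls


def classify_snp(transcript: TranscriptRecord, position0: int,
                 ref_base: str, alt_base: str,
                 snp_pct: float = float("nan"),
                 coverage: int = 0) -> SnpCall:
    """Classify the coding effect of a biallelic site (0-based position).

    The codon containing the site is translated with the reference versus
    the alternate base; identical amino acids mean synonymous. An
    alternate allele creating a stop codon is flagged ``nonsense`` and is
    excluded from synonymous/nonsynonymous tallies downstream.
    """
    if not (transcript.cds_start <= position0 < transcript.cds_end):
        raise ValueError(
            f"position {position0} outside CDS of {transcript.id}")
    offset = position0 - transcript.cds_start
    codon_i = offset // 3
    within = offset % 3
    codon = transcript.cds[3 * codon_i:3 * codon_i + 3]
    ref_codon = codon[:within] + ref_base + codon[within + 1:]
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    if aa_alt == "*" or aa_ref == "*":
        effect = "nonsense"
    elif aa_ref == aa_alt:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return SnpCall(transcript_id=transcript.id, position=position0 + 1,
                   ref_base=ref_base, alt_base=alt_base, snp_pct=snp_pct,
                   coverage=coverage, effect=effect,
                   aa_ref=aa_ref, aa_alt=aa_alt)


def snp_density(calls: list[SnpCall],
                transcripts: list[TranscriptRecord],
                group: str) -> float | None:
    """SNPs per kb of CDS of the SNP-containing transcripts of ``group``.

    ``group`` is "toxin" or "nontoxin". Returns None when the group has no
    SNP-containing transcripts (the quantity is undefined, not zero).
    """
    if group not in {"toxin", "nontoxin"}:
        raise ValueError(f"group must be 'toxin' or 'nontoxin', got {group!r}")
    by_id = {t.id: t for t in transcripts}
    want_toxin = group == "toxin"
    group_calls = [c for c in calls
                   if by_id[c.transcript_id].is_toxin == want_toxin]
    if not group_calls:
        return None
    carriers = {c.transcript_id for c in group_calls}
    cds_total = sum(by_id[tid].cds_end - by_id[tid].cds_start
                    for tid in carriers)
    return 1000.0 * len(group_calls) / cds_total


@dataclass(frozen=True)
class HetTestResult:
    het_toxin: int
    tot_toxin: int
    het_nontoxin: int
    tot_nontoxin: int
    statistic: float
    df: int
    p_value: float


def heterozygosity_test(het_toxin: int, tot_toxin: int,
                        het_nontoxin: int, tot_nontoxin: int,
                        ) -> HetTestResult:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2 table
    of heterozygous vs homozygous transcript counts per class."""
    if tot_toxin <= 0 or tot_nontoxin <= 0:
        raise ValueError("class totals must be positive")
    if het_toxin > tot_toxin or het_nontoxin > tot_nontoxin:
        raise ValueError("heterozygous count exceeds class total")
    table = np.array([[het_toxin, tot_toxin - het_toxin],
                      [het_nontoxin, tot_nontoxin - het_nontoxin]])
    if (table.sum(axis=0) == 0).any():
        # zero column margin: both classes have identical (degenerate)
        # frequencies; the statistic is zero by continuity
        statistic, p_value = 0.0, 1.0
    else:
        res = stats.chi2_contingency(table, correction=False)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    return HetTestResult(het_toxin=het_toxin, tot_toxin=tot_toxin,
                         het_nontoxin=het_nontoxin,
                         tot_nontoxin=tot_nontoxin,
                         statistic=statistic, df=1, p_value=p_value)


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability for df in {1, 2}.

    For df=2 this equals exp(-x/2); for df=1, erfc(sqrt(x/2)).
    """
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    return float(stats.chi2.sf(x, df))
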