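"""Merge 3'-overlapping read pairs into longer composite reads.

Paired-end reads from short cDNA fragments overlap at their 3' ends; a
pair drawn from a 134-nt fragment as two 100-nt reads shares 66 nt. The
merger reverse-complements the second read, scans candidate overlaps, and
emits a single composite read with consensus qualities: at agreeing
positions quality is q1+q2 (capped at 93, the highest encodable phred+33
score), at disagreeing positions the higher-quality base wins with
quality |q1-q2|.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import seqio

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PHRED_CAP = 93


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MergedRead:
    id: str
    sequence: str
    qualities: list[int]
    merged_flag: bool

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")


def merge_pair(read1: tuple[str, str, list[int]],
               read2: tuple[str, str, list[int]],
               min_overlap: int = 10,
               max_mismatch_rate: float = 0.1) -> MergedRead | None:
    """Merge one read pair, or return None if no acceptable overlap exists.

    ``read2`` is given in sequencing orientation and reverse-complemented
    internally. Candidate overlaps of length >= min_overlap are scored by
    matches - mismatches; overlaps whose mismatch rate exceeds
    ``max_mismatch_rate`` are discarded. Ties break toward the longer
    overlap. Overlaps longer than either read (read-through into adapter
    territory) are not considered: the merged fragment is at least as long
    as each read.
    """
    rid, seq1, q1 = read1
    _, raw2, raw_q2 = read2
    seq2 = reverse_complement(raw2)
    q2 = raw_q2[::-1]
    len1, len2 = len(seq1), len(seq2)
    if min(len1, len2) < min_overlap:
        return None

    # Match counts for every candidate overlap in one pass: cross-correlate
    # one-hot base indicators (N matches nothing, so N columns count as
    # mismatches).
    a = np.frombuffer(seq1.encode(), dtype=np.uint8)
    b = np.frombuffer(seq2.encode(), dtype=np.uint8)
    corr = np.zeros(len1 + len2 - 1)
    for code in (65, 67, 71, 84):  # A C G T
        corr += np.correlate((a == code).astype(float),
                             (b == code).astype(float), mode="full")
    olaps = np.arange(min_overlap, min(len1, len2) + 1)
    matches = corr[(len1 - olaps) + len2 - 1]
    mism = olaps - matches
    ok = mism <= max_mismatch_rate * olaps
    if not ok.any():
        return None
    score = 2 * matches - olaps
    # ties break toward the longer overlap: olaps ascend, argmax keeps the
    # first maximum, so search the reversed arrays
    key = score[ok]
    cand = olaps[ok]
    idx = len(key) - 1 - int(np.argmax(key[::-1]))
    olap = int(cand[idx])
    off = len(seq1) - olap
    merged_seq = list(seq1[:off])
    merged_q = list(q1[:off])
    for i in range(olap):
        b1, b2 = seq1[off + i], seq2[i]
        p1, p2 = q1[off + i], q2[i]
        if b1 == b2:
            merged_seq.append(b1)
            merged_q.append(min(p1 + p2, PHRED_CAP))
        elif p1 >= p2:
            merged_seq.append(b1)
            merged_q.append(p1 - p2)
        else:
            merged_seq.append(b2)
            merged_q.append(p2 - p1)
    merged_seq.extend(seq2[olap:])
    merged_q.extend(q2[olap:])
    return MergedRead(rid, "".join(merged_seq), merged_q, True)


@dataclass
class MergeSummary:
    n_pairs: int
    n_merged: int
    mean_merged_length: float
    mean_merged_phred: float

    @property
    def merge_rate(self) -> float:
        return self.n_merged / self.n_pairs if self.n_pairs else 0.0


def merge_stream(fastq1: str | Path, fastq2: str | Path,
                 out_merged: str | Path,
                 out_unmerged1: str | Path | None = None,
                 out_unmerged2: str | Path | None = None,
                 min_overlap: int = 10,
                 max_mismatch_rate: float = 0.1) -> MergeSummary:
    """Merge two paired, ordered FASTQ files; write merged + leftover pairs."""
    n_pairs = n_merged = 0
    tot_len = 0
    tot_qual = 0
    merged_out: list[tuple[str, str, list[int]]] = []
    un1: list[tuple[str, str, list[int]]] = []
    un2: list[tuple[str, str, list[int]]] = []
    stream2 = seqio.read_fastq(fastq2)
    for r1 in seqio.read_fastq(fastq1):
        try:
            r2 = next(stream2)
        except StopIteration:
            raise ValueError(f"unpaired record {r1[0]!r}: mate file exhausted")
        if _pair_key(r1[0]) != _pair_key(r2[0]):
            raise ValueError(f"unpaired records {r1[0]!r} / {r2[0]!r}")
        n_pairs += 1
        merged = merge_pair(r1, r2, min_overlap, max_mismatch_rate)
        if merged is None:
            un1.append(r1)
            un2.append(r2)
        else:
            n_merged += 1
            tot_len += len(merged.sequence)
            tot_qual += sum(merged.qualities)
            merged_out.append((merged.id, merged.sequence, merged.qualities))
    try:
        extra = next(stream2)
    except StopIteration:
        pass
    else:
        raise ValueError(f"unpaired record {extra[0]!r}: first file exhausted")

    seqio.write_fastq(merged_out, out_merged)
    if out_unmerged1 is not None:
        seqio.write_fastq(un1, out_unmerged1)
    if out_unmerged2 is not None:
        seqio.write_fastq(un2, out_unmerged2)
    return MergeSummary(
        n_pairs=n_pairs, n_merged=n_merged,
        mean_merged_length=tot_len / n_merged if n_merged else 0.0,
        mean_merged_phred=tot_qual / tot_len if tot_len else 0.0)


def _pair_key(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[:-2]
    return read_id
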