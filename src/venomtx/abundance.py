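"""Map merged reads to transcripts and build expression tables.

Reads are assigned to their best-identity transcript, gaplessly, with a
minimum match percentage (identity = matching bases / read length, no
terminal clipping). Cluster-level read counts become the two headline
percentages of the expression table: the share of all toxin-mapped reads
(``pct_toxin_reads``) and the share of all input reads
(``pct_total_reads``).

The mapper is seed-and-extend: exact k-mer seeds locate candidate
diagonals on a concatenated transcript index, each candidate is scored by
ungapped comparison over the full read, and ties are broken uniformly at
random under the caller's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ToxinCluster
from .readmerge import reverse_complement
from .seqio import TranscriptRecord, toxin_class_of


@dataclass(frozen=True)
class MappingHit:
    read_id: str
    transcript_id: str
    start: int  # 0-based on the transcript
    identity: float
    reverse: bool = False


class TranscriptIndex:
    """Exact k-mer index over a set of transcripts."""

    def __init__(self, transcripts: list[TranscriptRecord], k: int = 21):
        if not transcripts:
            raise ValueError("empty reference")
        self.k = k
        self.ids = [t.id for t in transcripts]
        spacer = "#" * k
        concat = spacer.join(t.sequence for t in transcripts)
        self.cat = np.frombuffer(concat.encode(), dtype=np.uint8)
        self.starts = np.zeros(len(transcripts), dtype=np.int64)
        self.ends = np.zeros(len(transcripts), dtype=np.int64)
        pos = 0
        for i, t in enumerate(transcripts):
            self.starts[i] = pos
            self.ends[i] = pos + len(t.sequence)
            pos += len(t.sequence) + k
        index: dict[bytes, list[int]] = {}
        data = concat.encode()
        for i, t in enumerate(transcripts):
            off = int(self.starts[i])
            for j in range(len(t.sequence) - k + 1):
                index.setdefault(data[off + j:off + j + k], []).append(off + j)
        self.index = {kmer: np.asarray(v, dtype=np.int64)
                      for kmer, v in index.items()}

    def transcript_at(self, gpos: int, length: int) -> int | None:
        """Transcript containing [gpos, gpos+length), or None."""
        i = int(np.searchsorted(self.starts, gpos, side="right")) - 1
        if i < 0:
            return None
        if gpos >= self.starts[i] and gpos + length <= self.ends[i]:
            return i
        return None


def map_reads(reads: list[tuple[str, str]],
              transcripts: list[TranscriptRecord],
              min_identity: float = 0.95,
              k: int = 21,
              seed: int = 0,
              index: TranscriptIndex | None = None,
              both_strands: bool = True,
              ) -> tuple[list[MappingHit], int]:
    """Assign each read to its best-identity transcript.

    Returns (hits, n_unmapped). A read maps iff its best gapless identity
    over all seeded candidates is >= min_identity; among tied best
    candidates one is chosen uniformly at random (seeded).
    """
    idx = index if index is not None else TranscriptIndex(transcripts, k)
    rng = np.random.default_rng(seed)
    hits: list[MappingHit] = []
    n_unmapped = 0
    for read_id, seq in reads:
        cands = _best_candidates(seq, idx, min_identity)
        if both_strands:
            cands += [(s, g, True) for s, g, _ in
                      _best_candidates(reverse_complement(seq), idx,
                                       min_identity)]
        if not cands:
            n_unmapped += 1
            continue
        top = max(s for s, _, _ in cands)
        ties = sorted(c for c in cands if c[0] == top)
        score, gpos, is_rc = ties[int(rng.integers(len(ties)))] \
            if len(ties) > 1 else ties[0]
        t_i = idx.transcript_at(gpos, len(seq))
        hits.append(MappingHit(
            read_id=read_id, transcript_id=idx.ids[t_i],
            start=int(gpos - idx.starts[t_i]),
            identity=score / len(seq), reverse=is_rc))
    return hits, n_unmapped


def _best_candidates(seq: str, idx: TranscriptIndex, min_identity: float,
                     ) -> list[tuple[int, int, bool]]:
    """Candidate (matches, global_start, False) triples meeting min_identity."""
    k = idx.k
    length = len(seq)
    if length < k:
        return []
    data = seq.encode()
    offsets = sorted({0, length // 3, (2 * length) // 3, length - k})
    cand: set[int] = set()
    for off in offsets:
        positions = idx.index.get(data[off:off + k])
        if positions is not None:
            cand.update(int(p) - off for p in positions)
    if not cand:
        return []
    arr = np.frombuffer(data, dtype=np.uint8)
    need = int(np.ceil(min_identity * length))
    out = []
    for g in cand:
        if g < 0 or g + length > len(idx.cat):
            continue
        if idx.transcript_at(g, length) is None:
            continue
        matches = int(np.count_nonzero(idx.cat[g:g + length] == arr))
        if matches >= need:
            out.append((matches, g, False))
    out.sort(key=lambda c: (-c[0], c[1]))
    return out


@dataclass
class AbundanceTable:
    """Cluster-level expression table plus bookkeeping totals.

    ``clusters`` columns: cluster_name, toxin_class, cluster_size, reads
    (NaN for fixture pass-through), pct_toxin_reads, pct_total_reads.
    """

    clusters: pd.DataFrame
    n_input_reads: int
    n_mapped: int
    n_toxin_mapped: int
    n_nontoxin_mapped: int
    transcript_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_unmapped(self) -> int:
        return self.n_input_reads - self.n_mapped

    @classmethod
    def from_fixture(cls, table1: pd.DataFrame) -> "AbundanceTable":
        """Adapt the bundled expression table (percentages, no raw counts)."""
        df = table1.copy()
        df["toxin_class"] = df.cluster_name.map(toxin_class_of)
        df["reads"] = np.nan
        df = df[["cluster_name", "toxin_class", "cluster_size", "reads",
                 "pct_toxin_reads", "pct_total_reads"]]
        return cls(clusters=df, n_input_reads=0, n_mapped=0,
                   n_toxin_mapped=0, n_nontoxin_mapped=0)


def estimate_abundance(hits: list[MappingHit],
                       clusters: list[ToxinCluster],
                       n_input_reads: int,
                       ) -> AbundanceTable:
    """Aggregate per-read hits to per-cluster counts and percentages.

    Transcripts not in any cluster are treated as nontoxins: they
    contribute to the mapped total (the denominator of pct_total_reads is
    all input reads) but not to the toxin percentages.
    """
    if n_input_reads < len(hits):
        raise ValueError("n_input_reads smaller than number of mapped reads")
    member_to_cluster: dict[str, ToxinCluster] = {}
    for c in clusters:
        for m in c.member_ids:
            member_to_cluster[m] = c
    t_counts: dict[str, int] = {}
    for h in hits:
        t_counts[h.transcript_id] = t_counts.get(h.transcript_id, 0) + 1
    cluster_reads = {c.name: sum(t_counts.get(m, 0) for m in c.member_ids)
                     for c in clusters}
    n_toxin = sum(cluster_reads.values())
    n_nontoxin = len(hits) - n_toxin
    rows = []
    for c in clusters:
        reads = cluster_reads[c.name]
        rows.append({
            "cluster_name": c.name, "toxin_class": c.toxin_class,
            "cluster_size": len(c.member_ids), "reads": reads,
            "pct_toxin_reads": 100.0 * reads / n_toxin if n_toxin else 0.0,
            "pct_total_reads": 100.0 * reads / n_input_reads,
        })
    df = pd.DataFrame(rows, columns=["cluster_name", "toxin_class",
                                     "cluster_size", "reads",
                                     "pct_toxin_reads", "pct_total_reads"])
    df = df.sort_values("pct_toxin_reads", ascending=False,
                        kind="mergesort").reset_index(drop=True)
    return AbundanceTable(clusters=df, n_input_reads=n_input_reads,
                          n_mapped=len(hits), n_toxin_mapped=n_toxin,
                          n_nontoxin_mapped=n_nontoxin,
                          transcript_counts=t_counts)


def class_summary(table: AbundanceTable) -> pd.DataFrame:
    """Per-toxin-class rollup: clusters, transcripts, read percentages."""
    df = table.clusters
    out = df.groupby("toxin_class").agg(
        n_clusters=("cluster_name", "count"),
        n_transcripts=("cluster_size", "sum"),
        pct_toxin_reads=("pct_toxin_reads", "sum"),
        pct_total_reads=("pct_total_reads", "sum"),
    ).reset_index()
    return out.sort_values("pct_toxin_reads", ascending=False,
                           kind="mergesort").reset_index(drop=True)


def within_class_shares(table: AbundanceTable, toxin_class: str,
                        ) -> pd.DataFrame:
    """Each cluster's share of its class's reads (sums to 100)."""
    df = table.clusters[table.clusters.toxin_class == toxin_class]
    if df.empty:
        raise KeyError(f"no clusters of class {toxin_class!r}")
    total = df.pct_toxin_reads.sum()
    out = df[["cluster_name", "pct_toxin_reads"]].copy()
    out["pct_class_reads"] = 100.0 * out.pct_toxin_reads / total
    return out.sort_values("pct_class_reads", ascending=False,
                           kind="mergesort").reset_index(drop=True)
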