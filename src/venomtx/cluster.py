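"""Group toxin transcripts into clusters at <1% nucleotide divergence.

A cluster is the unit of abundance and SNP reporting: it absorbs alleles,
very recent duplicates, and residual assembly or sequencing errors so that
each sequencing read maps to a unique representative. Clusters are
single-linkage connected components of the graph whose edges join pairs
below the divergence threshold, and never span toxin classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd
from Bio import Align

from .seqio import TranscriptRecord


@dataclass
class ToxinCluster:
    name: str
    member_ids: list[str]  # suffixed a, b, c... by descending abundance
    representative_id: str
    toxin_class: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster must have at least one member")
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


def _make_aligner() -> Align.PairwiseAligner:
    # Needleman-Wunsch with penalized end gaps: unrelated sequences then
    # align over their full length (high divergence) instead of snapping
    # to a short coincidental overlap. Terminal gap columns from UTR
    # overhangs are excluded from the divergence denominator afterwards.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_divergence(seq_a: str, seq_b: str) -> float:
    """Nucleotide divergence on a global alignment, in [0, 1].

    mismatches / aligned columns, with terminal gap columns excluded from
    the denominator and internal gap columns counted as mismatches.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_a == seq_b:
        return 0.0
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    a, b = alignment[0], alignment[1]
    # trim terminal gap runs on either sequence
    start = 0
    end = len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    n_cols = end - start
    if n_cols == 0:
        return 1.0
    mism = sum(1 for i in range(start, end) if a[i] != b[i])
    return mism / n_cols


def cluster_transcripts(records: list[TranscriptRecord],
                        threshold: float = 0.01,
                        abundances: dict[str, float] | None = None,
                        ) -> list[ToxinCluster]:
    """Single-linkage clustering of toxin transcripts below ``threshold``.

    Edges are drawn where divergence < threshold (strict, mirroring the
    "<1%" rule) and only within a toxin class. The representative is the
    longest member (ties to lexicographically smallest id). Member letter
    suffixes are assigned by descending ``abundances`` value when given,
    otherwise by id order. Cluster numbering within a class follows the
    representatives' id order.
    """
    if any(not r.is_toxin for r in records):
        raise ValueError("cluster_transcripts expects toxin records only")
    graph = nx.Graph()
    graph.add_nodes_from(r.id for r in records)
    by_id = {r.id: r for r in records}
    for ra, rb in combinations(records, 2):
        if ra.toxin_class != rb.toxin_class:
            continue
        if pairwise_divergence(ra.sequence, rb.sequence) < threshold:
            graph.add_edge(ra.id, rb.id)

    clusters: list[ToxinCluster] = []
    class_counters: dict[str, int] = {}
    components = sorted(nx.connected_components(graph),
                        key=lambda comp: min(comp))
    for comp in components:
        members = sorted(comp)
        # longest member; ties -> lexicographically smallest id
        longest = max(len(by_id[m].sequence) for m in members)
        rep = min(m for m in members if len(by_id[m].sequence) == longest)
        cls = by_id[members[0]].toxin_class
        class_counters[cls] = class_counters.get(cls, 0) + 1
        if abundances is not None:
            members = sorted(members,
                             key=lambda mid: (-abundances.get(mid, 0.0), mid))
        clusters.append(ToxinCluster(
            name=f"{cls}-{class_counters[cls]}",
            member_ids=members, representative_id=rep, toxin_class=cls))
    return clusters


def cluster_summary(clusters: list[ToxinCluster],
                    records: list[TranscriptRecord]) -> pd.DataFrame:
    """Per-cluster table: name, size, representative length."""
    lengths = {r.id: len(r.sequence) for r in records}
    rows = [{"cluster_name": c.name, "cluster_size": len(c.member_ids),
             "length": lengths[c.representative_id]} for c in clusters]
    return pd.DataFrame(rows, columns=["cluster_name", "cluster_size",
                                       "length"])
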