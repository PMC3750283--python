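"""Sequence and table I/O plus the shared transcript data model.

The pipeline starts from annotated full-length venom-gland transcripts:
a FASTA file and a companion annotation table assigning each transcript a
toxin class, a human-readable cluster-style name and a CDS window.
Coordinates are 0-based half-open internally; user-facing reports print
1-based positions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
import pandas as pd
from Bio.Data import CodonTable

TOXIN_CLASSES = frozenset({
    "3FTx", "CTL", "CREGF", "HYAL", "KUN", "LAAO", "LCN", "NGF",
    "NP", "NUC", "PDE", "PLA2", "PLB", "SVMP", "VEGF", "NONTOXIN",
})

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

_VALID_BASES = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class FastqParseError(ValueError):
    """Malformed FASTQ input."""


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code ('*' for stop)."""
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD_TABLE.forward_table.get(codon, "X")


@dataclass(frozen=True)
class TranscriptRecord:
    """An annotated full-length transcript.

    ``name`` encodes the toxin class and cluster (e.g. ``PLA2-2a``);
    nontoxins use the class label ``NONTOXIN``. The CDS window is 0-based
    half-open on the transcript, a multiple of three long, and free of
    internal stop codons.
    """

    id: str
    name: str
    toxin_class: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.toxin_class not in TOXIN_CLASSES:
            raise ValueError(f"unknown toxin class {self.toxin_class!r}")
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.id}: CDS window [{self.cds_start},{self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}")
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError(f"{self.id}: CDS length not a multiple of 3")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"{self.id}: invalid bases {sorted(bad)}")
        cds = self.cds
        for i in range(0, len(cds) - 3, 3):  # internal codons only
            if cds[i:i + 3] in STOP_CODONS:
                raise ValueError(f"{self.id}: internal stop codon at CDS offset {i}")

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start:self.cds_end]

    def iter_codons(self) -> Iterator[str]:
        cds = self.cds
        for i in range(0, len(cds), 3):
            yield cds[i:i + 3]

    @property
    def is_toxin(self) -> bool:
        return self.toxin_class != "NONTOXIN"


ANNOTATION_COLUMNS = ["id", "name", "toxin_class", "cds_start", "cds_end"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as a list of (id, sequence), order preserved.

    Sequences are uppercased and U is mapped to T. Ambiguity codes other
    than N are rejected: downstream codon arithmetic assumes {A,C,G,T,N}.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    parts: list[str] = []
    header_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    _append_fasta(records, header, parts, header_line)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                parts = []
                header_line = lineno
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any header")
                parts.append(line)
    if header is not None:
        _append_fasta(records, header, parts, header_line)
    return records


def _append_fasta(records, header, parts, header_line) -> None:
    seq = "".join(parts).upper().replace("U", "T")
    if not seq:
        raise FastaParseError(f"line {header_line}: empty record {header!r}")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise FastaParseError(
            f"record {header!r}: unsupported characters {sorted(bad)}")
    records.append((header, seq))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Stream (id, sequence, phred scores) from a phred+33 FASTQ file."""
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            head = head.rstrip("\n")
            if not head.startswith("@"):
                raise FastqParseError(f"expected '@' header, got {head!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise FastqParseError(f"record {head!r}: missing '+' line")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {head!r}: sequence/quality length mismatch "
                    f"({len(seq)} vs {len(qual)})")
            yield head[1:].split()[0], seq.upper().replace("U", "T"), \
                [ord(c) - 33 for c in qual]


def write_fastq(records: Iterable[tuple[str, str, list[int]]],
                path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, quals in records:
            fh.write(f"@{rid}\n{seq}\n+\n")
            fh.write("".join(chr(min(q, 93) + 33) for q in quals) + "\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single Newick tree.

    Missing branch lengths are set to 0 and ``tree.branch_lengths_set`` is
    False so callers can distinguish "zero" from "absent".
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse error in {path}: {exc}") from exc
    had_lengths = all(e.length is not None for e in tree.edges()
                      if e.head_node is not tree.seed_node)
    for edge in tree.edges():
        if edge.length is None:
            edge.length = 0.0
    tree.branch_lengths_set = had_lengths
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True))


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the TSV annotation table (id, name, toxin_class, cds_start, cds_end)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "name": str,
                                            "toxin_class": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    if df.id.duplicated().any():
        dup = df.id[df.id.duplicated()].iloc[0]
        raise ValueError(f"duplicate transcript id {dup!r} in annotations")
    return df[ANNOTATION_COLUMNS]


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def join_annotations(fasta_records: list[tuple[str, str]],
                     annotations: pd.DataFrame) -> list[TranscriptRecord]:
    """Join FASTA sequences with the annotation table into TranscriptRecords.

    Every annotated id must be present in the FASTA; FASTA-only records are
    ignored (they are unannotated contigs).
    """
    seqs = dict(fasta_records)
    records = []
    for row in annotations.itertuples():
        if row.id not in seqs:
            raise KeyError(f"annotated id {row.id!r} absent from FASTA")
        records.append(TranscriptRecord(
            id=row.id, name=row.name, toxin_class=row.toxin_class,
            sequence=seqs[row.id], cds_start=int(row.cds_start),
            cds_end=int(row.cds_end)))
    return records


_FIXTURES = {"table1": "table1.tsv", "table3": "table3.tsv",
             "table4": "table4.tsv"}


def load_fixture(table_name: str) -> pd.DataFrame:
    """Load one of the bundled worked-example tables.

    ``table1``: per-cluster expression levels (rank, cluster_name,
    cluster_size, length, pct_toxin_reads, pct_total_reads).
    ``table3``: putative heterozygous SNPs with coverage, 1-based position,
    minor-allele percentage and amino-acid effect.
    ``table4``: codon site-model summary per toxin class (M1/M2 parameter
    estimates, −lnL values, M0 ω, LRT λ and p).
    """
    if table_name not in _FIXTURES:
        raise KeyError(f"unknown fixture {table_name!r}; "
                       f"expected one of {sorted(_FIXTURES)}")
    ref = importlib.resources.files("venomtx") / "tables" / _FIXTURES[table_name]
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def toxin_class_of(cluster_name: str) -> str:
    """Toxin class encoded in a cluster or transcript name (``PLA2-2a`` → ``PLA2``)."""
    return cluster_name.rsplit("-", 1)[0]
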