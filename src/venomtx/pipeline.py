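"""Run the pipeline stages under one configuration and write report tables.

Stages: merge -> cluster -> quant -> snps -> selection. Each stage writes a
TSV, and a summary JSON collects read counts, toxin/nontoxin percentages,
SNP counts and test results. The configuration embeds the analysis
constants: clustering threshold 0.01, minimum match percentage 0.95, SNP%
window 40-60 with coverage bounds 20-20,000, omega cap 999, chi-square
tests at df 1 (heterozygosity) and df 2 (LRT).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, cluster, codonsel, readmerge, seqio, variants

logger = logging.getLogger("venomtx")


@dataclass
class PipelineConfig:
    fasta: str = ""
    annotations: str = ""
    fastq1: str = ""
    fastq2: str = ""
    outdir: str = "venomtx_out"
    seed: int = 0
    # merge
    min_overlap: int = 10
    max_mismatch_rate: float = 0.1
    # cluster
    cluster_threshold: float = 0.01
    # quant
    min_identity: float = 0.95
    kmer_size: int = 21
    # snps
    min_pct: float = 40.0
    max_pct: float = 60.0
    min_cov: int = 20
    max_cov: int = 20000
    # selection
    selection_models: tuple[str, ...] = ("M0", "M1", "M2")
    selection_min_taxa: int = 5
    freqs: str = "f3x4"
    ncat: int = 10
    omega_cap: float = 999.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0 < self.cluster_threshold < 1):
            raise ValueError("cluster_threshold must be in (0, 1)")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0 <= self.min_pct <= self.max_pct <= 100):
            raise ValueError("SNP%% window invalid")
        if not (0 < self.min_cov <= self.max_cov):
            raise ValueError("coverage bounds invalid")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "selection_models" in data:
            data["selection_models"] = tuple(data["selection_models"])
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run merge -> cluster -> quant -> snps -> selection; return outdir."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed}
    try:
        _run_stages(config, out, summary)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _run_stages(config: PipelineConfig, out: Path, summary: dict) -> None:
    records = seqio.join_annotations(
        seqio.read_fasta(config.fasta),
        seqio.read_annotations(config.annotations))
    logger.info("loaded %d annotated transcripts", len(records))

    # --- merge
    merge_summary = readmerge.merge_stream(
        config.fastq1, config.fastq2, out / "merged.fastq",
        out / "unmerged_1.fastq", out / "unmerged_2.fastq",
        min_overlap=config.min_overlap,
        max_mismatch_rate=config.max_mismatch_rate)
    logger.info("merged %d/%d pairs (mean length %.1f, mean phred %.1f)",
                merge_summary.n_merged, merge_summary.n_pairs,
                merge_summary.mean_merged_length,
                merge_summary.mean_merged_phred)
    summary["merge"] = dataclasses.asdict(merge_summary)

    # --- cluster
    toxins = [r for r in records if r.is_toxin]
    clusters = cluster.cluster_transcripts(
        toxins, threshold=config.cluster_threshold)
    cluster_rows = [{"cluster_name": c.name, "member_id": m,
                     "representative": c.representative_id}
                    for c in clusters for m in c.member_ids]
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t",
                                      index=False)
    summary["clusters"] = {"n_clusters": len(clusters),
                           "n_toxin_transcripts": len(toxins)}

    # --- quant
    merged_reads = [(rid, seq) for rid, seq, _ in
                    seqio.read_fastq(out / "merged.fastq")]
    hits, n_unmapped = abundance.map_reads(
        merged_reads, records, min_identity=config.min_identity,
        k=config.kmer_size, seed=config.seed)
    table = abundance.estimate_abundance(hits, clusters,
                                         n_input_reads=len(merged_reads))
    expr = make_expression_report(table)
    expr.to_csv(out / "expression.tsv", sep="\t", index=False)
    summary["quant"] = {
        "n_reads": table.n_input_reads, "n_mapped": table.n_mapped,
        "n_unmapped": n_unmapped,
        "pct_toxin_of_total": 100.0 * table.n_toxin_mapped
        / table.n_input_reads if table.n_input_reads else 0.0,
        "pct_nontoxin_of_total": 100.0 * table.n_nontoxin_mapped
        / table.n_input_reads if table.n_input_reads else 0.0,
    }

    # --- snps
    pileup = variants.build_pileup(hits, dict(merged_reads), records)
    calls = variants.call_snps(
        pileup, records, min_pct=config.min_pct, max_pct=config.max_pct,
        min_cov=config.min_cov, max_cov=config.max_cov)
    het_table, het_summary = make_het_report(calls, records, clusters)
    het_table.to_csv(out / "snps.tsv", sep="\t", index=False)
    summary["snps"] = het_summary

    # --- selection
    report = _selection_stage(records, clusters, config)
    if report is None:
        report = pd.DataFrame(columns=[
            "toxin_class", "n", "m1_p0", "m1_p1", "m1_w0", "m1_w1",
            "m1_neglnl", "m2_p0", "m2_p1", "m2_p2", "m2_w0", "m2_w1",
            "m2_w2", "m2_neglnl", "m0_omega", "lambda", "p_value"])
    report.to_csv(out / "selection.tsv", sep="\t", index=False)
    if len(report):
        summary["selection"] = {
            r["toxin_class"]: {"m0_omega": float(r["m0_omega"]),
                               "lambda": float(r["lambda"]),
                               "p_value": float(r["p_value"])}
            for _, r in report.iterrows()}


def _selection_stage(records, clusters, config) -> pd.DataFrame | None:
    """Fit site models per toxin class on cluster representatives.

    Classes need >= selection_min_taxa equal-length CDSs (the synthetic
    generator emits unaligned real-length transcripts, so only classes
    whose representatives align trivially are analysable; empirical use
    passes pre-aligned input through the `selection` CLI instead).
    """
    by_class: dict[str, list] = {}
    by_id = {r.id: r for r in records}
    for c in clusters:
        by_class.setdefault(c.toxin_class, []).append(
            by_id[c.representative_id])
    results = {}
    for cls, members in sorted(by_class.items()):
        cds = [(m.id, m.cds) for m in members]
        lengths = {len(s) for _, s in cds}
        if len(cds) < config.selection_min_taxa or len(lengths) != 1:
            continue
        try:
            aln = codonsel.preprocess_alignment(cds)
        except ValueError:
            continue
        tree = codonsel.nj_guide_tree(aln)
        fits = {}
        cfg = codonsel.FitConfig(seed=config.seed, freqs=config.freqs,
                                 ncat=config.ncat,
                                 omega_cap=config.omega_cap)
        fits["M0"] = codonsel.fit_model(aln, tree, "M0", cfg)
        fits["M1"], fits["M2"], fits["lrt"] = codonsel.fit_nested_pair(
            aln, tree, ("M1", "M2"), cfg)
        fits["n"] = len(cds)
        results[cls] = fits
    if not results:
        return None
    return codonsel.selection_report(results)


def make_expression_report(table: abundance.AbundanceTable) -> pd.DataFrame:
    """Rank clusters by descending share of toxin reads (rank 1 = top)."""
    df = table.clusters.sort_values(
        "pct_toxin_reads", ascending=False, kind="mergesort").reset_index(
        drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def make_het_report(calls: list[variants.SnpCall],
                    records: list[seqio.TranscriptRecord],
                    clusters: list[cluster.ToxinCluster] | None = None,
                    ) -> tuple[pd.DataFrame, dict]:
    """Per-call table plus the per-class heterozygosity summary."""
    by_id = {r.id: r for r in records}
    rows = [{
        "transcript": c.transcript_id,
        "type": "Toxin" if by_id[c.transcript_id].is_toxin else "Nontoxin",
        "coverage": c.coverage, "position": c.position,
        "snp_pct": round(c.snp_pct, 1), "aa_ref": c.aa_ref,
        "aa_alt": c.aa_alt, "effect": c.effect,
    } for c in calls]
    table = pd.DataFrame(rows, columns=["transcript", "type", "coverage",
                                        "position", "snp_pct", "aa_ref",
                                        "aa_alt", "effect"])
    tox_calls = [c for c in calls if by_id[c.transcript_id].is_toxin]
    nt_calls = [c for c in calls if not by_id[c.transcript_id].is_toxin]
    summary = {
        "n_snps_toxin": len(tox_calls),
        "n_snps_nontoxin": len(nt_calls),
        "n_het_toxin_transcripts":
            len({c.transcript_id for c in tox_calls}),
        "n_het_nontoxin_transcripts":
            len({c.transcript_id for c in nt_calls}),
        "snp_density_toxin": variants.snp_density(calls, records, "toxin"),
        "snp_density_nontoxin":
            variants.snp_density(calls, records, "nontoxin"),
    }
    n_nontoxin = sum(1 for r in records if not r.is_toxin)
    if clusters is not None:
        # heterozygous clusters out of all toxin clusters, as reported
        rep_cluster = {m: c.name for c in clusters for m in c.member_ids}
        het_clusters = {rep_cluster[c.transcript_id] for c in tox_calls
                        if c.transcript_id in rep_cluster}
        tot_toxin = len(clusters)
        het_toxin = len(het_clusters)
    else:
        tot_toxin = sum(1 for r in records if r.is_toxin)
        het_toxin = summary["n_het_toxin_transcripts"]
    het_nontoxin = summary["n_het_nontoxin_transcripts"]
    if tot_toxin and n_nontoxin:
        test = variants.heterozygosity_test(het_toxin, tot_toxin,
                                            het_nontoxin, n_nontoxin)
        summary["het_test"] = {
            "het_toxin": het_toxin, "tot_toxin": tot_toxin,
            "het_nontoxin": het_nontoxin, "tot_nontoxin": n_nontoxin,
            "statistic": test.statistic, "df": test.df,
            "p_value": test.p_value}
    return table, summary


def reproduce_tables(outdir: str | Path) -> dict:
    """Recompute the study's printed summary statistics from the bundled
    fixtures only (no reads, no downloads); write TSVs and return the
    statistics as a dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stats: dict[str, float] = {}

    t1 = seqio.load_fixture("table1")
    table = abundance.AbundanceTable.from_fixture(t1)
    cls = abundance.class_summary(table)
    cls.to_csv(out / "class_summary.tsv", sep="\t", index=False)
    by_class = cls.set_index("toxin_class")
    stats["pla2_pct_toxin_reads"] = float(by_class.pct_toxin_reads["PLA2"])
    stats["threeftx_pct_toxin_reads"] = float(
        by_class.pct_toxin_reads["3FTx"])
    stats["pla2_plus_3ftx_pct_toxin_reads"] = (
        stats["pla2_pct_toxin_reads"] + stats["threeftx_pct_toxin_reads"])
    top5 = ["PLA2", "3FTx", "LCN", "SVMP", "KUN"]
    stats["top5_pct_toxin_reads"] = float(
        by_class.pct_toxin_reads[top5].sum())
    stats["top5_pct_clusters"] = float(
        100.0 * by_class.n_clusters[top5].sum() / by_class.n_clusters.sum())
    stats["top5_pct_transcripts"] = float(
        100.0 * by_class.n_transcripts[top5].sum()
        / by_class.n_transcripts.sum())
    shares = abundance.within_class_shares(table, "3FTx")
    stats["threeftx2_pct_class_reads"] = float(
        shares.set_index("cluster_name").pct_class_reads["3FTx-2"])
    stats["toxin_pct_total_reads"] = float(t1.pct_total_reads.sum())

    t3 = seqio.load_fixture("table3")
    tox = t3[t3.type == "Toxin"]
    stats["toxin_pct_nonsynonymous"] = float(
        100.0 * (tox.effect == "nonsynonymous").mean())
    stats["nontoxin_pct_nonsynonymous"] = float(
        100.0 * (t3[t3.type == "Nontoxin"].effect
                 == "nonsynonymous").mean())
    stats["p_het_printed_chi2"] = variants.chisq_sf(6.383, 1)
    stats["chi2_het_pearson"] = variants.heterozygosity_test(
        9, 75, 69, 1950).statistic

    t4 = seqio.load_fixture("table4").set_index("toxin_class")
    for cls_name, key in [("3FTx", "threeftx"), ("KUN", "kun"),
                          ("LCN", "lcn")]:
        lam, p = codonsel.lrt_from_neg_lnl(
            float(t4.m1_neglnl[cls_name]), float(t4.m2_neglnl[cls_name]))
        stats[f"lambda_{key}"] = lam
        stats[f"p_{key}"] = p
    with open(out / "reproduced_statistics.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return stats
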