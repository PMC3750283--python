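"""Synthetic validation studies: parameter recovery, LRT power, caller recall.

These routines generate data with the simulate module, run the analysis
machinery on it, and score the result against the generator's truth.
They back the validation analyses and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import abundance, codonsel, readmerge, simulate, variants


@dataclass
class OmegaRecoveryResult:
    estimates: list[float]
    truth: float
    n_within: int  # estimates inside the tolerance band

    @property
    def fraction_within(self) -> float:
        return self.n_within / len(self.estimates)


def m0_omega_recovery(n_replicates: int = 20, n_taxa: int = 8,
                      n_codons: int = 500, omega: float = 0.5,
                      kappa: float = 2.0, band: tuple[float, float] = (0.4, 0.6),
                      seed: int = 0) -> OmegaRecoveryResult:
    """Simulate under M0 and refit; score estimates against the truth band."""
    pi = codonsel.equal_frequencies()
    estimates = []
    for rep in range(n_replicates):
        tree = simulate.random_tree(n_taxa, seed=seed + 1000 + rep,
                                    mean_branch_length=0.3)
        spec = codonsel.CodonModelSpec("M0", kappa=kappa, pi=pi,
                                       params={"omega": omega})
        aln, _ = simulate.simulate_codon_alignment(tree, spec, n_codons,
                                                   seed=seed + 2000 + rep)
        guide = codonsel.nj_guide_tree(aln)
        fit = codonsel.fit_model(
            aln, guide, "M0",
            codonsel.FitConfig(n_starts=1, seed=seed, freqs="equal"))
        estimates.append(fit.spec.params["omega"])
    lo, hi = band
    n_within = sum(1 for w in estimates if lo <= w <= hi)
    return OmegaRecoveryResult(estimates=estimates, truth=omega,
                               n_within=n_within)


@dataclass
class LrtPowerResult:
    p_values: list[float]
    n_reject: int
    alpha: float

    @property
    def rejection_rate(self) -> float:
        return self.n_reject / len(self.p_values)


def m1_vs_m2_lrt_study(n_replicates: int = 20, n_taxa: int = 8,
                       n_codons: int = 300, under_alternative: bool = True,
                       p2: float = 0.2, omega2: float = 4.0,
                       alpha: float = 0.05, seed: int = 0) -> LrtPowerResult:
    """LRT rejection rate under the selection truth (power) or the
    nearly-neutral truth (type-I error, boundary-conservative)."""
    pi = codonsel.equal_frequencies()
    if under_alternative:
        truth = codonsel.CodonModelSpec(
            "M2", kappa=2.0, pi=pi,
            params={"p0": 1.0 - p2 - 0.3, "p1": 0.3, "omega0": 0.1,
                    "omega2": omega2})
    else:
        truth = codonsel.CodonModelSpec(
            "M1", kappa=2.0, pi=pi, params={"p0": 0.7, "omega0": 0.2})
    p_values = []
    for rep in range(n_replicates):
        tree = simulate.random_tree(n_taxa, seed=seed + 3000 + rep,
                                    mean_branch_length=0.3)
        aln, _ = simulate.simulate_codon_alignment(tree, truth, n_codons,
                                                   seed=seed + 4000 + rep)
        guide = codonsel.nj_guide_tree(aln)
        _, _, res = codonsel.fit_nested_pair(
            aln, guide, ("M1", "M2"),
            codonsel.FitConfig(n_starts=1, seed=seed, freqs="equal"))
        p_values.append(res.p_value)
    n_reject = sum(1 for p in p_values if p < alpha)
    return LrtPowerResult(p_values=p_values, n_reject=n_reject, alpha=alpha)


@dataclass
class CallerRecoveryResult:
    n_planted: int
    n_recovered: int
    n_false: int
    homozygous_cds_bases: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 1.0


def het_caller_recovery(seed: int = 11) -> CallerRecoveryResult:
    """Run the het_calling scenario end to end and score the SNP caller."""
    cfg = simulate.benchmark_scenario("het_calling")
    cfg.seed = seed
    records, _, truth = simulate.simulate_transcriptome(cfg)
    reads1, reads2, _ = simulate.simulate_reads(records, truth.weights,
                                                cfg, truth.alleles)
    merged = []
    for r1, r2 in zip(reads1, reads2):
        m = readmerge.merge_pair(r1, r2)
        if m is not None:
            merged.append((m.id, m.sequence))
    hits, _ = abundance.map_reads(merged, records, seed=seed)
    pileup = variants.build_pileup(hits, dict(merged), records)
    calls = variants.call_snps(pileup, records)
    planted = {(row.transcript_id, int(row.position) + 1)
               for row in truth.alleles.itertuples()}
    called = {(c.transcript_id, c.position) for c in calls}
    het_transcripts = {t for t, _ in planted}
    hom_bases = sum(r.cds_end - r.cds_start for r in records
                    if r.id not in het_transcripts)
    return CallerRecoveryResult(
        n_planted=len(planted),
        n_recovered=len(planted & called),
        n_false=len(called - planted),
        homozygous_cds_bases=hom_bases)


@dataclass
class AbundanceRecoveryResult:
    n_reads: int
    fraction_true_cluster: float


def abundance_recovery(n_reads: int = 50000, error_rate: float = 0.01,
                       seed: int = 0) -> AbundanceRecoveryResult:
    """Draw reads from known transcripts and score cluster assignment."""
    cfg = simulate.SimConfig(seed=seed, n_nontoxin=0, n_toxin_families=10,
                             family_sizes=[3, 2, 2, 1, 1, 1, 1, 1, 1, 1],
                             expression_model="lognormal",
                             lognormal_sigma=0.5, toxin_read_fraction=1.0,
                             toxin_het_fraction=0.0,
                             n_read_pairs=n_reads, error_rate=error_rate)
    records, _, truth = simulate.simulate_transcriptome(cfg)
    reads1, reads2, read_truth = simulate.simulate_reads(
        records, truth.weights, cfg)
    from . import cluster as cluster_mod
    clusters = cluster_mod.cluster_transcripts(records)
    member_to_cluster = {m: c.name for c in clusters for m in c.member_ids}
    merged = []
    for r1, r2 in zip(reads1, reads2):
        m = readmerge.merge_pair(r1, r2)
        if m is not None:
            merged.append((m.id, m.sequence))
    hits, _ = abundance.map_reads(merged, records, seed=seed)
    true_cluster = {row.read_id: member_to_cluster[row.transcript_id]
                    for row in read_truth.itertuples()}
    hit_of = {h.read_id: member_to_cluster[h.transcript_id] for h in hits}
    n_correct = sum(1 for rid, cl in hit_of.items()
                    if true_cluster.get(rid.split("/")[0], cl) == cl)
    return AbundanceRecoveryResult(
        n_reads=len(merged),
        fraction_true_cluster=n_correct / len(merged) if merged else 1.0)
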