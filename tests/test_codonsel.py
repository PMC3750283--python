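import itertools

import dendropy
import numpy as np
import pytest
from Bio.Data import CodonTable
from scipy.linalg import expm
from scipy.stats import chisquare

from venomtx import codonsel as cs
from venomtx import simulate

# --------------------------------------------------------------------------
# independent oracle: rebuild the codon process from first principles

_TABLE = CodonTable.unambiguous_dna_by_id[1]
ORACLE_CODONS = [c for c in ("".join(p) for p in
                             itertools.product("TCAG", repeat=3))
                 if c not in _TABLE.stop_codons]


def oracle_q(kappa, omega, pi):
    n = len(ORACLE_CODONS)
    q = np.zeros((n, n))
    for i, ci in enumerate(ORACLE_CODONS):
        for j, cj in enumerate(ORACLE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            rate = pi[j]
            if diffs[0] in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}:
                rate *= kappa
            if _TABLE.forward_table[ci] != _TABLE.forward_table[cj]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def oracle_star_loglik(tip_codons, lengths, kappa, pi, props, omegas):
    """Brute-force likelihood of a star tree: sum over the internal state.

    ``tip_codons``: (n_tips, n_sites) codon indices. The mixture shares
    one scale so the average rate over classes is one.
    """
    mus = [-(pi @ np.diag(oracle_q(kappa, w, pi))) for w in omegas]
    rate = float(np.dot(props, mus))
    total = 0.0
    n_sites = tip_codons.shape[1]
    for s in range(n_sites):
        site_l = 0.0
        for p_k, w in zip(props, omegas):
            q = oracle_q(kappa, w, pi) / rate
            mats = [expm(q * t) for t in lengths]
            lk = 0.0
            for x in range(len(ORACLE_CODONS)):
                term = pi[x]
                for tip, p_mat in zip(tip_codons[:, s], mats):
                    term *= p_mat[x, tip]
                lk += term
            site_l += p_k * lk
        total += np.log(site_l)
    return total


# --------------------------------------------------------------------------

class TestRateMatrix:
    def test_codon_inventory_matches_standard_code(self):
        assert cs.SENSE_CODONS == ORACLE_CODONS
        assert cs.N_CODONS == 61

    def test_rows_sum_to_zero(self, rng):
        pi = rng.dirichlet(np.ones(61))
        q = cs.build_rate_matrix(3.1, 0.4, pi)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self, rng):
        pi = rng.dirichlet(np.ones(61))
        q = cs.build_rate_matrix(2.4, 1.7, pi)
        flux = pi[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-14

    def test_neutral_equal_frequencies_uniform_rates(self):
        pi = cs.equal_frequencies()
        q = cs.build_rate_matrix(1.0, 1.0, pi, scale=False)
        off = q[~np.eye(61, dtype=bool) & cs.SINGLE_MASK]
        assert np.allclose(off, off[0])
        assert np.all(q[~np.eye(61, dtype=bool) & ~cs.SINGLE_MASK] == 0)

    def test_unit_expected_rate(self, rng):
        pi = rng.dirichlet(np.ones(61))
        q = cs.build_rate_matrix(5.0, 0.2, pi)
        assert -(pi @ np.diag(q)) == pytest.approx(1.0)

    def test_transition_matrix_matches_expm(self, rng):
        pi = rng.dirichlet(np.ones(61) * 5)
        q = cs.build_rate_matrix(2.0, 0.5, pi)
        p = cs._transition_matrix(cs._eigen(q, pi), 0.1)
        assert np.abs(p - expm(q * 0.1)).max() < 1e-10
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-10

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            cs.build_rate_matrix(2.0, 0.5, np.ones(61))


class TestPruning:
    def test_single_taxon_is_log_pi(self):
        pi = cs.equal_frequencies()
        tree = dendropy.Tree.get(data="(A:0.0);", schema="newick")
        aln = cs.CodonAlignment(taxa=["A"], sequences=["ATGCTGAAA"])
        spec = cs.CodonModelSpec("M0", kappa=2.0, pi=pi,
                                 params={"omega": 0.5})
        _, total = cs.site_log_likelihoods(aln, tree, spec)
        expected = sum(np.log(pi[cs.CODON_INDEX[c]])
                       for c in ("ATG", "CTG", "AAA"))
        assert total == pytest.approx(expected, rel=1e-10)

    def test_two_taxa_matches_direct_summation(self, rng):
        pi = rng.dirichlet(np.ones(61) * 10)
        tree = dendropy.Tree.get(data="(A:0.17,B:0.33);", schema="newick")
        aln = cs.CodonAlignment(taxa=["A", "B"], sequences=["ATG", "CTG"])
        spec = cs.CodonModelSpec("M0", kappa=1.7, pi=pi,
                                 params={"omega": 0.6})
        _, total = cs.site_log_likelihoods(aln, tree, spec)
        q = oracle_q(1.7, 0.6, pi)
        q /= -(pi @ np.diag(q))
        p = expm(q * 0.5)
        i, j = cs.CODON_INDEX["ATG"], cs.CODON_INDEX["CTG"]
        assert total == pytest.approx(np.log(pi[i] * p[i, j]), rel=1e-8)

    @pytest.mark.parametrize("model, params", [
        ("M0", {"omega": 0.5}),
        ("M1", {"p0": 0.6, "omega0": 0.1}),
        ("M2", {"p0": 0.5, "p1": 0.3, "omega0": 0.1, "omega2": 3.0}),
    ])
    def test_three_taxa_vs_brute_force(self, model, params, rng):
        pi = rng.dirichlet(np.ones(61) * 8)
        lengths = [0.11, 0.23, 0.35]
        tree = dendropy.Tree.get(
            data=f"(A:{lengths[0]},B:{lengths[1]},C:{lengths[2]});",
            schema="newick")
        spec = cs.CodonModelSpec(model, kappa=2.3, pi=pi, params=params)
        sim_aln, _ = simulate.simulate_codon_alignment(tree, spec, 5,
                                                       seed=42)
        _, total = cs.site_log_likelihoods(sim_aln, tree, spec)
        tips = sim_aln.codon_matrix()
        props, omegas = spec.site_classes()
        oracle = oracle_star_loglik(tips, lengths, 2.3, pi, props, omegas)
        assert total == pytest.approx(oracle, rel=1e-8)

    def test_rerooting_invariance(self):
        # pulley principle: the unrooted likelihood ignores root placement
        pi = cs.equal_frequencies()
        spec = cs.CodonModelSpec("M0", kappa=2.0, pi=pi,
                                 params={"omega": 0.4})
        for seed in range(3):
            tree = simulate.random_tree(6, seed=seed)
            aln, _ = simulate.simulate_codon_alignment(tree, spec, 40,
                                                       seed=seed + 100)
            _, base = cs.site_log_likelihoods(aln, tree, spec)
            work = tree.clone(depth=1)
            internal = [n for n in work.preorder_node_iter()
                        if not n.is_leaf() and n is not work.seed_node]
            node = internal[seed % len(internal)]
            work.reroot_at_node(node, update_bipartitions=False)
            _, rerooted = cs.site_log_likelihoods(aln, work, spec)
            assert rerooted == pytest.approx(base, rel=1e-9)

    def test_branch_rate_rescaling_invariance(self, rng):
        # likelihood depends on Q*t only: doubling rates and halving
        # lengths changes nothing
        pi = rng.dirichlet(np.ones(61) * 5)
        tree = simulate.random_tree(5, seed=1)
        spec = cs.CodonModelSpec("M0", kappa=2.0, pi=pi,
                                 params={"omega": 0.7})
        aln, _ = simulate.simulate_codon_alignment(tree, spec, 30, seed=2)
        engine = cs.PruningEngine(aln, tree)
        lengths = engine.tree.lengths
        a = engine.class_site_logliks(lengths, 2.0, 0.7, pi, rate_scale=1.0)
        b = engine.class_site_logliks(lengths * 2.0, 2.0, 0.7, pi,
                                      rate_scale=2.0)
        assert np.allclose(a, b, rtol=1e-9)


class TestPreprocess:
    def test_gap_column_dropped(self):
        raw = [("A", "ATGGCC"), ("B", "ATG---")]
        aln = cs.preprocess_alignment(raw, min_codons=1)
        assert aln.sequences == ["ATG", "ATG"]
        assert aln.kept_columns == [0]

    def test_stop_column_dropped(self):
        raw = [("A", "ATGTAAGCC"), ("B", "ATGCAAGCC")]
        aln = cs.preprocess_alignment(raw, min_codons=1)
        assert aln.sequences == ["ATGGCC", "ATGGCC"]
        assert aln.kept_columns == [0, 2]

    def test_signal_peptides_removed(self):
        tree = simulate.random_tree(6, seed=9)
        pi = cs.equal_frequencies()
        spec = cs.CodonModelSpec("M0", kappa=2.0, pi=pi,
                                 params={"omega": 0.5})
        aln, _ = simulate.simulate_codon_alignment(tree, spec, 60, seed=3)
        spans = {t: (0, 20) for t in aln.taxa}
        out = cs.preprocess_alignment(list(zip(aln.taxa, aln.sequences)),
                                      spans)
        assert out.n_codons == 40

    def test_too_short_rejected(self):
        raw = [("A", "ATGGCC"), ("B", "ATGGCC")]
        with pytest.raises(ValueError, match="codon columns"):
            cs.preprocess_alignment(raw, min_codons=10)


class TestDiscreteBeta:
    def test_category_means_average_to_beta_mean(self):
        for p, q in [(0.5, 1.5), (2.0, 2.0), (0.1, 0.4)]:
            means = cs.discrete_beta(p, q, 10)
            assert means.shape == (10,)
            assert np.all((means > 0) & (means < 1))
            assert np.all(np.diff(means) > 0)
            assert means.mean() == pytest.approx(p / (p + q), rel=1e-6)


class TestFitModel:
    def test_identical_sequences_degenerate_limit(self):
        pi = cs.equal_frequencies()
        seq = "ATGGCCAAACTGGCCAAACTGGCCAAACTGGCCAAACTG"[:36]
        aln = cs.CodonAlignment(taxa=["A", "B", "C"], sequences=[seq] * 3)
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1,C:0.1);",
                                 schema="newick")
        fit = cs.fit_model(aln, tree, "M0",
                           cs.FitConfig(n_starts=1, freqs="equal",
                                        branch_mode="full"))
        expected = sum(np.log(pi[cs.CODON_INDEX[seq[i:i + 3]]])
                       for i in range(0, len(seq), 3))
        assert fit.lnl == pytest.approx(expected, abs=0.01)
        assert np.all(fit.branch_lengths < 1e-4)

    def test_nesting_m1_within_m2(self):
        tree = simulate.random_tree(6, seed=21, mean_branch_length=0.25)
        pi = cs.equal_frequencies()
        truth = cs.CodonModelSpec("M1", kappa=2.0, pi=pi,
                                  params={"p0": 0.7, "omega0": 0.2})
        aln, _ = simulate.simulate_codon_alignment(tree, truth, 150,
                                                   seed=22)
        guide = cs.nj_guide_tree(aln)
        cfg = cs.FitConfig(n_starts=1, freqs="equal")
        m1, m2, res = cs.fit_nested_pair(aln, guide, ("M1", "M2"), cfg)
        assert m2.neg_lnl <= m1.neg_lnl + 1e-6
        assert res.statistic >= 0.0
        assert 0.0 <= res.p_value <= 1.0

    def test_nesting_m7_within_m8(self):
        tree = simulate.random_tree(5, seed=31, mean_branch_length=0.25)
        pi = cs.equal_frequencies()
        truth = cs.CodonModelSpec("M7", kappa=2.0, pi=pi,
                                  params={"p_beta": 0.8, "q_beta": 1.6})
        aln, _ = simulate.simulate_codon_alignment(tree, truth, 120,
                                                   seed=32)
        guide = cs.nj_guide_tree(aln)
        m7, m8, res = cs.fit_nested_pair(
            aln, guide, ("M7", "M8"),
            cs.FitConfig(n_starts=1, freqs="equal", ncat=5))
        assert m8.neg_lnl <= m7.neg_lnl + 1e-6
        assert res.statistic >= 0.0


class TestLrt:
    def _fake_fit(self, model, lnl):
        spec = cs.CodonModelSpec(model, kappa=2.0,
                                 pi=cs.equal_frequencies(),
                                 params={"p0": 0.5, "omega0": 0.1,
                                         "p1": 0.3, "omega2": 2.0,
                                         "omega": 1.0})
        return cs.CodonModelFit(spec=spec, lnl=lnl,
                                branch_lengths=np.ones(3),
                                converged=True, n_starts=1)

    def test_study_3ftx_lambda(self):
        lam, p = cs.lrt_from_neg_lnl(1600.40, 1576.50)
        assert lam == pytest.approx(47.8, abs=1e-9)

    def test_study_kun_lambda_and_p(self):
        lam, p = cs.lrt_from_neg_lnl(965.08, 962.16)
        assert lam == pytest.approx(5.84, abs=1e-9)
        assert p == pytest.approx(0.0539, abs=5e-5)

    def test_equal_likelihoods(self):
        res = cs.lrt(self._fake_fit("M1", -100.0),
                     self._fake_fit("M2", -100.0))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            cs.lrt(self._fake_fit("M0", -10.0), self._fake_fit("M2", -9.0))


class TestNjGuideTree:
    def test_three_taxa_unique_topology(self):
        aln = cs.CodonAlignment(
            taxa=["A", "B", "C"],
            sequences=["ATGGCCAAACTGATG", "ATGGCCAAACTGATG",
                       "ATGGGGAAACTGATG"])
        tree = cs.nj_guide_tree(aln)
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} \
            == {"A", "B", "C"}

    def test_planted_split_recovered(self, rng):
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=999))

        def mutate(seq, positions):
            out = list(seq)
            for p in positions:
                out[p] = {"A": "C", "C": "G", "G": "T",
                          "T": "A"}[out[p]]
            return "".join(out)

        a = base
        b = mutate(base, range(0, 12))
        c = mutate(base, range(100, 190))
        d = mutate(c, range(300, 312))
        aln = cs.CodonAlignment(taxa=["A", "B", "C", "D"],
                                sequences=[a, b, c, d])
        tree = cs.nj_guide_tree(aln)
        tree.encode_bipartitions()
        splits = {frozenset(taxon.label
                            for taxon in bip.leafset_taxa(
                                tree.taxon_namespace))
                  for bip in tree.bipartition_encoding}
        assert frozenset({"A", "B"}) in splits \
            or frozenset({"C", "D"}) in splits

    def test_identical_sequences_zero_lengths(self):
        seq = "ATGGCCAAACTG"
        aln = cs.CodonAlignment(taxa=["A", "B", "C", "D"],
                                sequences=[seq] * 4)
        tree = cs.nj_guide_tree(aln)
        assert all((e.length or 0.0) == 0.0 for e in tree.edges())

    def test_fewer_than_three_rejected(self):
        aln = cs.CodonAlignment(taxa=["A", "B"],
                                sequences=["ATG", "ATG"])
        with pytest.raises(ValueError):
            cs.nj_guide_tree(aln)


class TestSimulatedEvolution:
    def test_omega_zero_means_no_amino_acid_changes(self):
        tree = simulate.random_tree(6, seed=13, mean_branch_length=0.4)
        pi = cs.equal_frequencies()
        spec = cs.CodonModelSpec("M0", kappa=2.0, pi=pi,
                                 params={"omega": 0.0})
        aln, _ = simulate.simulate_codon_alignment(tree, spec, 100, seed=14)
        proteins = {
            "".join(cs.CODON_AA[cs.CODON_INDEX[s[i:i + 3]]]
                    for i in range(0, len(s), 3))
            for s in aln.sequences}
        assert len(proteins) == 1  # structural zero: only synonymous moves

    def test_long_branch_reaches_stationarity(self):
        pi = cs.equal_frequencies()
        tree = dendropy.Tree.get(data="(A:40.0,B:40.0);", schema="newick")
        spec = cs.CodonModelSpec("M0", kappa=2.0, pi=pi,
                                 params={"omega": 1.0})
        aln, _ = simulate.simulate_codon_alignment(tree, spec, 3000,
                                                   seed=15)
        counts = np.zeros(61)
        for s in aln.sequences:
            for i in range(0, len(s), 3):
                counts[cs.CODON_INDEX[s[i:i + 3]]] += 1
        stat, p = chisquare(counts, counts.sum() * pi)
        assert p > 0.01

    def test_site_class_truth_shapes(self):
        tree = simulate.random_tree(4, seed=3)
        spec = cs.CodonModelSpec("M2", kappa=2.0,
                                 pi=cs.equal_frequencies(),
                                 params={"p0": 0.5, "p1": 0.3,
                                         "omega0": 0.1, "omega2": 4.0})
        aln, classes = simulate.simulate_codon_alignment(tree, spec, 200,
                                                         seed=4)
        assert classes.shape == (200,)
        assert set(np.unique(classes)) <= {0, 1, 2}
        assert aln.n_codons == 200


class TestSelectionReport:
    def test_report_shape(self):
        tree = simulate.random_tree(5, seed=41, mean_branch_length=0.2)
        pi = cs.equal_frequencies()
        truth = cs.CodonModelSpec("M0", kappa=2.0, pi=pi,
                                  params={"omega": 0.5})
        aln, _ = simulate.simulate_codon_alignment(tree, truth, 100,
                                                   seed=42)
        guide = cs.nj_guide_tree(aln)
        cfg = cs.FitConfig(n_starts=1, freqs="equal")
        fits = {m: cs.fit_model(aln, guide, m, cfg)
                for m in ("M0", "M1")}
        warm = dict(fits["M1"].spec.params, kappa=fits["M1"].spec.kappa)
        fits["M2"] = cs.fit_model(aln, guide, "M2",
                                  cs.FitConfig(n_starts=1, freqs="equal",
                                               init=warm))
        fits["lrt"] = cs.lrt(fits["M1"], fits["M2"])
        fits["n"] = 5
        report = cs.selection_report({"PLA2": fits})
        assert list(report.toxin_class) == ["PLA2"]
        row = report.iloc[0]
        assert row.m2_p0 + row.m2_p1 + row.m2_p2 == pytest.approx(1.0)
        assert row["lambda"] >= 0.0
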