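"""Codon site models (M0, M1a, M2a, M7, M8) and likelihood-ratio tests.

The substitution process follows the Goldman-Yang codon model: only
single-nucleotide changes have positive rate, transitions are scaled by
kappa, nonsynonymous changes by omega, and target-codon frequencies pi
multiply every rate. Site-to-site variation in omega is modelled as a
finite mixture: a single ratio (M0), nearly neutral two-class (M1a:
omega0<1 estimated, omega1=1), positive selection (M2a: adds omega2>=1),
a discretized beta on (0,1) (M7), and beta plus a selected class (M8).
Nested pairs (M1a/M2a, M7/M8) are compared with likelihood-ratio tests
against chi-square with two degrees of freedom.

Likelihoods are computed by Felsenstein pruning on an unrooted tree with
branch lengths in expected substitutions per codon; rate matrices are
jointly rescaled so the mixture-average rate is one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as _replace

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .seqio import STOP_CODONS, translate_codon
from .variants import chisq_sf

# ---------------------------------------------------------------------------
# codon bookkeeping (universal code, 61 sense codons)

SENSE_CODONS: list[str] = [
    "".join(c) for c in itertools.product("TCAG", repeat=3)
    if "".join(c) not in STOP_CODONS]
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = np.array([translate_codon(c) for c in SENSE_CODONS])

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _build_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    synonymous = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = diffs[0] in _TRANSITIONS
            synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return single, transition, synonymous


SINGLE_MASK, TS_MASK, SYN_MASK = _build_masks()


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                      scale: bool = True) -> np.ndarray:
    """61x61 codon rate generator; optionally scaled to one expected
    substitution per codon per unit time at stationarity."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"pi must have length {N_CODONS}")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("codon frequencies must sum to 1")
    factor = np.where(SINGLE_MASK,
                      np.where(TS_MASK, kappa, 1.0)
                      * np.where(SYN_MASK, 1.0, omega), 0.0)
    q = factor * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        mu = -float(pi @ np.diag(q))
        if mu > 0:
            q = q / mu
    return q


def _eigen(q: np.ndarray, pi: np.ndarray):
    """Symmetric eigendecomposition of a reversible generator.

    Returns (w, left, right) with P(t) = right @ diag(exp(w t)) @ left.
    """
    sqrt_pi = np.sqrt(pi)
    b = sqrt_pi[:, None] * q / sqrt_pi[None, :]
    b = (b + b.T) / 2.0  # exact symmetry up to rounding for reversible q
    w, v = np.linalg.eigh(b)
    right = v / sqrt_pi[:, None]
    left = v.T * sqrt_pi[None, :]
    return w, left, right


def _transition_matrix(eig, t: float) -> np.ndarray:
    w, left, right = eig
    p = (right * np.exp(w * t)) @ left
    np.clip(p, 0.0, None, out=p)
    return p


# ---------------------------------------------------------------------------
# alignments

@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences plus the preprocessing mask."""

    taxa: list[str]
    sequences: list[str]
    kept_columns: list[int] = field(default_factory=list)  # original codon cols

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must be aligned to equal length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length must be a multiple of 3")
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa/sequence count mismatch")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def codon_matrix(self) -> np.ndarray:
        """(n_taxa, n_codons) sense-codon indices; -1 where untranslatable."""
        mat = np.full((len(self.taxa), self.n_codons), -1, dtype=np.int64)
        for r, seq in enumerate(self.sequences):
            for c in range(self.n_codons):
                mat[r, c] = CODON_INDEX.get(seq[3 * c:3 * c + 3], -1)
        return mat


def preprocess_alignment(raw: list[tuple[str, str]],
                         signal_peptide_spans: dict[str, tuple[int, int]]
                         | None = None,
                         min_codons: int = 10) -> CodonAlignment:
    """Drop gapped, signal-peptide, and stop-containing codon columns.

    ``raw`` is an aligned set of in-frame sequences; spans are per-taxon
    (start, end) half-open intervals in that taxon's own ungapped codon
    coordinates. A column is removed if any sequence has a gap in it, if
    it overlaps any taxon's signal peptide, or if any sequence shows a
    stop codon in it.
    """
    taxa = [t for t, _ in raw]
    seqs = [s.upper() for _, s in raw]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("input sequences are not aligned")
    if len(seqs[0]) % 3:
        raise ValueError("alignment length must be a multiple of 3")
    n_cols = len(seqs[0]) // 3
    spans = signal_peptide_spans or {}

    keep = []
    codon_counter = {t: 0 for t in taxa}
    for col in range(n_cols):
        cells = [s[3 * col:3 * col + 3] for s in seqs]
        gapped = any("-" in cell for cell in cells)
        in_signal = False
        for taxon, cell in zip(taxa, cells):
            if "-" in cell:
                continue
            idx = codon_counter[taxon]
            codon_counter[taxon] += 1
            span = spans.get(taxon)
            if span is not None and span[0] <= idx < span[1]:
                in_signal = True
        if gapped or in_signal:
            continue
        if any(cell in STOP_CODONS for cell in cells):
            continue
        keep.append(col)

    out_seqs = ["".join(s[3 * c:3 * c + 3] for c in keep) for s in seqs]
    aln = CodonAlignment(taxa=taxa, sequences=out_seqs, kept_columns=keep)
    if aln.n_codons < min_codons:
        raise ValueError(
            f"only {aln.n_codons} codon columns remain after preprocessing; "
            f"need at least {min_codons}")
    return aln


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies."""
    counts = np.zeros((3, 4))
    base_index = {b: i for i, b in enumerate("TCAG")}
    for seq in alignment.sequences:
        for i, base in enumerate(seq):
            j = base_index.get(base)
            if j is not None:
                counts[i % 3, j] += 1
    freqs = (counts + 1e-6) / (counts + 1e-6).sum(axis=1, keepdims=True)
    pi = np.array([freqs[0, base_index[c[0]]]
                   * freqs[1, base_index[c[1]]]
                   * freqs[2, base_index[c[2]]] for c in SENSE_CODONS])
    return pi / pi.sum()


def equal_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


# ---------------------------------------------------------------------------
# site-class mixtures

def discrete_beta(p: float, q: float, ncat: int) -> np.ndarray:
    """Means of ``ncat`` equal-probability categories of Beta(p, q)."""
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, ncat + 1), p, q)
    upper = stats.beta.cdf(edges, p + 1, q)
    means = (upper[1:] - upper[:-1]) * ncat * (p / (p + q))
    return np.clip(means, 1e-8, 1.0)


@dataclass
class CodonModelSpec:
    """One site model: omega mixture + kappa + codon frequencies."""

    model: str  # M0 | M1 | M2 | M7 | M8
    kappa: float
    pi: np.ndarray
    params: dict[str, float]
    ncat: int = 10
    omega_cap: float = 999.0

    def site_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (proportions, omegas) of the mixture."""
        p = self.params
        if self.model == "M0":
            return np.array([1.0]), np.array([p["omega"]])
        if self.model == "M1":
            return (np.array([p["p0"], 1.0 - p["p0"]]),
                    np.array([p["omega0"], 1.0]))
        if self.model == "M2":
            p2 = 1.0 - p["p0"] - p["p1"]
            return (np.array([p["p0"], p["p1"], p2]),
                    np.array([p["omega0"], 1.0, p["omega2"]]))
        if self.model == "M7":
            means = discrete_beta(p["p_beta"], p["q_beta"], self.ncat)
            return np.full(self.ncat, 1.0 / self.ncat), means
        if self.model == "M8":
            means = discrete_beta(p["p_beta"], p["q_beta"], self.ncat)
            props = np.append(np.full(self.ncat, p["p0"] / self.ncat),
                              1.0 - p["p0"])
            return props, np.append(means, p["omega_s"])
        raise ValueError(f"unknown model {self.model!r}")


# ---------------------------------------------------------------------------
# trees and pruning

class LikTree:
    """Array form of a (de)rooted tree for pruning.

    Nodes are indexed in postorder with the seed node last; every node
    except the seed carries the branch to its parent. Tip order matches
    the alignment's taxa.
    """

    def __init__(self, tree: dendropy.Tree, taxa: list[str]):
        work = tree.clone(depth=1)
        if len(work.seed_node.child_nodes()) == 2 and len(taxa) > 2:
            work.deroot()
        nodes = list(work.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(n): i for i, n in enumerate(nodes)}
        label_to_row = {t: r for r, t in enumerate(taxa)}
        self.tip_row = np.full(self.n_nodes, -1, dtype=np.int64)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        lengths = []
        self.edge_of_node = np.full(self.n_nodes, -1, dtype=np.int64)
        for i, node in enumerate(nodes):
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if label not in label_to_row:
                    raise ValueError(f"tree leaf {label!r} not in alignment")
                self.tip_row[i] = label_to_row[label]
            for child in node.child_nodes():
                self.children[i].append(index[id(child)])
            if node is not work.seed_node:
                self.parent[i] = index[id(node.parent_node)]
                self.edge_of_node[i] = len(lengths)
                lengths.append(node.edge.length or 0.0)
        if sorted(self.tip_row[self.tip_row >= 0]) != sorted(
                range(len(taxa))):
            raise ValueError("tree leaves do not match alignment taxa")
        self.lengths = np.asarray(lengths, dtype=float)
        self.root = self.n_nodes - 1

    @property
    def n_edges(self) -> int:
        return len(self.lengths)


class PruningEngine:
    """Pattern-compressed likelihood evaluator for one alignment + tree."""

    def __init__(self, alignment: CodonAlignment, tree: dendropy.Tree):
        self.tree = LikTree(tree, alignment.taxa)
        mat = alignment.codon_matrix()
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True)
        self.patterns = patterns  # (n_taxa, n_patterns)
        self.weights = counts.astype(float)
        self.pattern_of_site = inverse
        self.n_patterns = patterns.shape[1]
        self.n_sites = mat.shape[1]

    def class_site_logliks(self, lengths: np.ndarray, kappa: float,
                           omega: float, pi: np.ndarray,
                           rate_scale: float = 1.0) -> np.ndarray:
        """Per-pattern log-likelihood under a single omega class.

        ``rate_scale`` divides the generator: mixtures share a joint
        scaling so that branch lengths stay in expected substitutions per
        codon under the mixture.
        """
        q = build_rate_matrix(kappa, omega, pi, scale=False) / rate_scale
        eig = _eigen(q, pi)
        tr = self.tree
        partials: list[np.ndarray | None] = [None] * tr.n_nodes
        logscale = np.zeros(self.n_patterns)
        for i in range(tr.n_nodes):
            if not tr.children[i]:
                continue
            part = np.ones((N_CODONS, self.n_patterns))
            for child in tr.children[i]:
                p_mat = _transition_matrix(eig, lengths[tr.edge_of_node[child]])
                if tr.tip_row[child] >= 0:
                    codes = self.patterns[tr.tip_row[child]]
                    msg = p_mat[:, np.clip(codes, 0, N_CODONS - 1)]
                    msg = np.where(codes[None, :] >= 0, msg, 1.0)
                else:
                    msg = p_mat @ partials[child]
                    partials[child] = None
                part *= msg
            peak = part.max(axis=0)
            peak = np.where(peak > 0, peak, 1.0)
            part /= peak
            logscale += np.log(peak)
            partials[i] = part
        root = partials[tr.root]
        site_l = pi @ root
        return np.log(np.clip(site_l, 1e-300, None)) + logscale

    def log_likelihood(self, lengths: np.ndarray, spec: CodonModelSpec,
                       per_site: bool = False):
        props, omegas = spec.site_classes()
        mus = np.array([
            -float(spec.pi @ np.diag(build_rate_matrix(spec.kappa, w, spec.pi,
                                                       scale=False)))
            for w in omegas])
        rate = float(props @ mus)
        rate = rate if rate > 0 else 1.0
        logs = np.stack([
            self.class_site_logliks(lengths, spec.kappa, w, spec.pi,
                                    rate_scale=rate)
            for w in omegas])
        log_props = np.log(np.maximum(props, 1e-300))  # empty class ok
        site_log = special.logsumexp(logs + log_props[:, None], axis=0)
        total = float(self.weights @ site_log)
        if per_site:
            return site_log[self.pattern_of_site], total
        return total


def site_log_likelihoods(alignment: CodonAlignment, tree: dendropy.Tree,
                         spec: CodonModelSpec,
                         ) -> tuple[np.ndarray, float]:
    """Per-codon-site log-likelihoods and their total."""
    engine = PruningEngine(alignment, tree)
    return engine.log_likelihood(engine.tree.lengths, spec, per_site=True)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitConfig:
    n_starts: int = 2
    seed: int = 0
    branch_mode: str = "scale"  # "scale" | "full"
    ncat: int = 10
    freqs: str = "f3x4"  # "f3x4" | "equal"
    omega_cap: float = 999.0
    maxiter: int = 300
    init: dict[str, float] | None = None  # warm start (model params + kappa)


@dataclass
class CodonModelFit:
    spec: CodonModelSpec
    lnl: float
    branch_lengths: np.ndarray
    converged: bool
    n_starts: int
    model: str = ""

    def __post_init__(self) -> None:
        self.model = self.spec.model

    @property
    def neg_lnl(self) -> float:
        return -self.lnl


_KAPPA_BOUNDS = (np.log(0.05), np.log(99.0))


def _param_layout(model: str, cap: float):
    """(names, bounds, defaults) of the free parameters in optimizer space.

    kappa, omega-like and beta parameters are log-transformed; proportions
    are raw in (0,1).
    """
    logc = np.log
    if model == "M0":
        return (["log_kappa", "log_omega"],
                [_KAPPA_BOUNDS, (logc(1e-4), logc(cap))],
                [logc(2.0), logc(0.3)])
    if model == "M1":
        return (["log_kappa", "p0", "log_omega0"],
                [_KAPPA_BOUNDS, (1e-6, 1 - 1e-6), (logc(1e-4), 0.0)],
                [logc(2.0), 0.7, logc(0.2)])
    if model == "M2":
        return (["log_kappa", "p0", "p1f", "log_omega0", "log_omega2"],
                [_KAPPA_BOUNDS, (1e-6, 1 - 1e-6), (1e-6, 1 - 1e-6),
                 (logc(1e-4), 0.0), (0.0, logc(cap))],
                [logc(2.0), 0.6, 0.75, logc(0.2), logc(3.0)])
    if model == "M7":
        return (["log_kappa", "log_p", "log_q"],
                [_KAPPA_BOUNDS, (logc(0.005), logc(99.0)),
                 (logc(0.005), logc(99.0))],
                [logc(2.0), 0.0, 0.0])
    if model == "M8":
        return (["log_kappa", "p0", "log_p", "log_q", "log_omega_s"],
                [_KAPPA_BOUNDS, (1e-6, 1 - 1e-6),
                 (logc(0.005), logc(99.0)), (logc(0.005), logc(99.0)),
                 (0.0, logc(cap))],
                [logc(2.0), 0.9, 0.0, 0.0, logc(3.0)])
    raise ValueError(f"unknown model {model!r}")


def _unpack(model: str, names: list[str], x: np.ndarray,
            ) -> tuple[float, dict[str, float]]:
    vals = dict(zip(names, x))
    kappa = float(np.exp(vals.pop("log_kappa")))
    params: dict[str, float] = {}
    if model == "M0":
        params["omega"] = float(np.exp(vals["log_omega"]))
    elif model == "M1":
        params["p0"] = float(vals["p0"])
        params["omega0"] = float(np.exp(vals["log_omega0"]))
    elif model == "M2":
        p0 = float(vals["p0"])
        params["p0"] = p0
        params["p1"] = (1.0 - p0) * float(vals["p1f"])
        params["omega0"] = float(np.exp(vals["log_omega0"]))
        params["omega2"] = float(np.exp(vals["log_omega2"]))
    elif model == "M7":
        params["p_beta"] = float(np.exp(vals["log_p"]))
        params["q_beta"] = float(np.exp(vals["log_q"]))
    elif model == "M8":
        params["p0"] = float(vals["p0"])
        params["p_beta"] = float(np.exp(vals["log_p"]))
        params["q_beta"] = float(np.exp(vals["log_q"]))
        params["omega_s"] = float(np.exp(vals["log_omega_s"]))
    return kappa, params


def _pack_init(model: str, names: list[str], defaults: list[float],
               init: dict[str, float]) -> list[float]:
    """Overlay a warm start (natural-scale params) onto optimizer defaults."""
    x = list(defaults)
    nat_to_opt = {
        "kappa": ("log_kappa", np.log), "omega": ("log_omega", np.log),
        "p0": ("p0", float), "omega0": ("log_omega0", np.log),
        "omega2": ("log_omega2", lambda v: np.log(max(v, 1.0))),
        "p_beta": ("log_p", np.log), "q_beta": ("log_q", np.log),
        "omega_s": ("log_omega_s", lambda v: np.log(max(v, 1.0))),
    }
    for key, value in init.items():
        if key == "p1":  # derived: needs p0
            continue
        if key in nat_to_opt:
            opt_name, fwd = nat_to_opt[key]
            if opt_name in names:
                lo, hi = dict(zip(names, _param_layout(model, 999.0)[1]))[
                    opt_name]
                x[names.index(opt_name)] = float(
                    np.clip(fwd(value), lo, hi))
    if model == "M2" and "p0" in init:
        if "p1" in init:
            rest = 1.0 - init["p0"]
            if rest > 1e-9:
                x[names.index("p1f")] = float(
                    np.clip(init["p1"] / rest, 1e-6, 1 - 1e-6))
        else:
            # warm start from a fitted null: begin with a small but
            # identifiable selected class
            x[names.index("p1f")] = 0.95
    return x


def fit_model(alignment: CodonAlignment, tree: dendropy.Tree, model: str,
              config: FitConfig | None = None) -> CodonModelFit:
    """Maximum-likelihood fit of one site model on a fixed topology.

    Branch lengths, kappa and the model's mixture parameters are
    optimized by bounded quasi-Newton (L-BFGS-B) from ``n_starts`` seeded
    starting points; the best likelihood is kept. In the default
    ``branch_mode="scale"`` the guide tree's branch-length proportions are
    held fixed and a single scale factor is free; ``"full"`` frees every
    branch length (log-transformed).
    """
    cfg = config or FitConfig()
    engine = PruningEngine(alignment, tree)
    pi = (equal_frequencies() if cfg.freqs == "equal"
          else f3x4_frequencies(alignment))
    base_len = engine.tree.lengths.copy()
    if not np.any(base_len > 0):
        base_len = np.full_like(base_len, 0.1)
    base_len = np.maximum(base_len, 1e-6)

    names, bounds, defaults = _param_layout(model, cfg.omega_cap)
    if cfg.init:
        defaults = _pack_init(model, names, defaults, cfg.init)
    if cfg.branch_mode == "scale":
        names = ["log_bscale"] + names
        bounds = [(np.log(1e-3), np.log(300.0))] + bounds
        defaults = [0.0] + list(defaults)
    elif cfg.branch_mode == "full":
        nb = len(base_len)
        names = [f"log_t{i}" for i in range(nb)] + names
        bounds = [(np.log(1e-6), np.log(50.0))] * nb + list(bounds)
        defaults = list(np.log(base_len)) + list(defaults)
    else:
        raise ValueError(f"unknown branch_mode {cfg.branch_mode!r}")

    def lengths_from(x: np.ndarray) -> np.ndarray:
        if cfg.branch_mode == "scale":
            return base_len * np.exp(x[0])
        return np.exp(x[:len(base_len)])

    n_model = len(names) - (1 if cfg.branch_mode == "scale"
                            else len(base_len))

    def objective(x: np.ndarray) -> float:
        kappa, params = _unpack(model, names[-n_model:], x[-n_model:])
        spec = CodonModelSpec(model=model, kappa=kappa, pi=pi,
                              params=params, ncat=cfg.ncat,
                              omega_cap=cfg.omega_cap)
        try:
            return -engine.log_likelihood(lengths_from(x), spec)
        except (linalg.LinAlgError, FloatingPointError):
            return 1e12

    rng = np.random.default_rng(cfg.seed)
    best = None
    converged = False
    for start in range(max(cfg.n_starts, 1)):
        x0 = np.asarray(defaults, dtype=float)
        if start > 0:
            jitter = rng.normal(0.0, 0.35, size=len(x0))
            x0 = np.clip(x0 + jitter,
                         [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": cfg.maxiter,
                                         "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    kappa, params = _unpack(model, names[-n_model:], best.x[-n_model:])
    spec = CodonModelSpec(model=model, kappa=kappa, pi=pi, params=params,
                          ncat=cfg.ncat, omega_cap=cfg.omega_cap)
    return CodonModelFit(spec=spec, lnl=-float(best.fun),
                         branch_lengths=lengths_from(best.x),
                         converged=converged,
                         n_starts=max(cfg.n_starts, 1))


def fit_nested_pair(alignment: CodonAlignment, tree: dendropy.Tree,
                    pair: tuple[str, str] = ("M1", "M2"),
                    config: FitConfig | None = None,
                    ) -> tuple[CodonModelFit, CodonModelFit, "LrtResult"]:
    """Fit a nested null/alternative pair and run the LRT.

    The alternative is warm-started from the fitted null. Because the
    null is a boundary case of the alternative (empty selected class),
    the alternative can never be genuinely worse; if the optimizer still
    returns a lower likelihood, the embedded null point is used instead.
    """
    if pair not in _NESTED_PAIRS:
        raise ValueError(f"unsupported nested pair {pair!r}")
    cfg = config or FitConfig()
    null = fit_model(alignment, tree, pair[0], cfg)
    warm = dict(null.spec.params, kappa=null.spec.kappa)
    alt = fit_model(alignment, tree, pair[1], _replace(cfg, init=warm))
    if alt.lnl < null.lnl:
        params = dict(null.spec.params)
        if pair == ("M1", "M2"):
            params = {"p0": params["p0"], "p1": 1.0 - params["p0"],
                      "omega0": params["omega0"], "omega2": 1.0}
        else:
            params = {"p0": 1.0, "p_beta": params["p_beta"],
                      "q_beta": params["q_beta"], "omega_s": 1.0}
        spec = CodonModelSpec(model=pair[1], kappa=null.spec.kappa,
                              pi=null.spec.pi, params=params,
                              ncat=cfg.ncat, omega_cap=cfg.omega_cap)
        alt = CodonModelFit(spec=spec, lnl=null.lnl,
                            branch_lengths=null.branch_lengths,
                            converged=alt.converged, n_starts=alt.n_starts)
    return null, alt, lrt(null, alt)


_NESTED_PAIRS = {("M1", "M2"), ("M7", "M8")}


@dataclass
class LrtResult:
    null_fit: CodonModelFit
    alt_fit: CodonModelFit
    statistic: float
    df: int
    p_value: float
    convergence_failure: bool = False


def lrt(null_fit: CodonModelFit, alt_fit: CodonModelFit) -> LrtResult:
    """Likelihood-ratio test of a nested site-model pair (df = 2)."""
    if (null_fit.model, alt_fit.model) not in _NESTED_PAIRS:
        raise ValueError(
            f"{null_fit.model} vs {alt_fit.model} is not a supported "
            f"nested pair (M1/M2 or M7/M8)")
    lam = 2.0 * (alt_fit.lnl - null_fit.lnl)
    failure = lam < -1e-6
    lam = max(lam, 0.0)
    return LrtResult(null_fit=null_fit, alt_fit=alt_fit, statistic=lam,
                     df=2, p_value=chisq_sf(lam, 2),
                     convergence_failure=failure)


def lrt_from_neg_lnl(neg_lnl_null: float, neg_lnl_alt: float,
                     ) -> tuple[float, float]:
    """(lambda, p) from two reported -lnL values (worked-example helper)."""
    lam = 2.0 * (neg_lnl_null - neg_lnl_alt)
    return lam, chisq_sf(max(lam, 0.0), 2)


# ---------------------------------------------------------------------------
# guide tree

def _pairwise_nucleotide_distance(a: str, b: str) -> float:
    """Jukes-Cantor distance; uncorrected p-distance when saturated."""
    pairs = [(x, y) for x, y in zip(a, b)
             if x in "ACGT" and y in "ACGT"]
    if not pairs:
        return 0.0
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return p  # saturated: fall back to the uncorrected distance
    return -0.75 * np.log(arg)


def nj_guide_tree(alignment: CodonAlignment) -> dendropy.Tree:
    """Neighbor-joining guide tree from JC-corrected nucleotide distances.

    Negative NJ branch lengths are clamped to zero. For three taxa this is
    the unique unrooted topology.
    """
    n = len(alignment.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa for a guide tree")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _pairwise_nucleotide_distance(alignment.sequences[i],
                                              alignment.sequences[j])
            dist[i, j] = dist[j, i] = d
    dm = DistanceMatrix(dist, ids=alignment.taxa)
    sk_tree = _skbio_nj(dm, neg_as_zero=True)
    tree = dendropy.Tree.get(data=str(sk_tree), schema="newick",
                             preserve_underscores=True)
    for edge in tree.edges():
        if edge.length is None or edge.length < 0:
            edge.length = 0.0
    tree.branch_lengths_set = True
    return tree


# ---------------------------------------------------------------------------
# reporting

def selection_report(class_results: dict[str, dict]) -> pd.DataFrame:
    """Summary table with one row per toxin class.

    ``class_results[name]`` maps model names to CodonModelFit ("M0", "M1",
    "M2") plus "lrt" (LrtResult for M1 vs M2).
    """
    rows = []
    for name, res in class_results.items():
        m0, m1, m2 = res["M0"], res["M1"], res["M2"]
        test = res["lrt"]
        p1, w1 = m1.spec.site_classes()
        p2, w2 = m2.spec.site_classes()
        rows.append({
            "toxin_class": name,
            "n": res.get("n"),
            "m1_p0": p1[0], "m1_p1": p1[1],
            "m1_w0": w1[0], "m1_w1": w1[1],
            "m1_neglnl": m1.neg_lnl,
            "m2_p0": p2[0], "m2_p1": p2[1], "m2_p2": p2[2],
            "m2_w0": w2[0], "m2_w1": w2[1], "m2_w2": w2[2],
            "m2_neglnl": m2.neg_lnl,
            "m0_omega": m0.spec.params["omega"],
            "lambda": test.statistic,
            "p_value": test.p_value,
        })
    return pd.DataFrame(rows)
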