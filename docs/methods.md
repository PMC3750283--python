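# Methods

This note documents the models and procedures implemented in `venomtx`,
the parameter choices behind them, and what the synthetic validation does
and does not establish.

## Data model

A transcript is a nucleotide sequence over {A,C,G,T,N} with a toxin-class
label and a CDS window (0-based, half-open, a multiple of three, free of
internal stop codons under the standard genetic code). Ambiguity codes
other than N are rejected at parse time because all downstream codon
arithmetic assumes a four-letter alphabet. Positions are 0-based
internally; every user-facing table prints 1-based positions. FASTQ
qualities are phred+33 throughout (HiSeq-era data); no offset
autodetection is attempted.

## Read merging

Read pairs from fragments shorter than twice the read length overlap at
their 3' ends. The merger reverse-complements the second read and scores
every candidate overlap of length ≥ `min_overlap` (default 10) by
matches − mismatches, discarding candidates whose mismatch rate exceeds
`max_mismatch_rate` (default 0.1); ties break toward the longer overlap.
Overlap scoring is computed for all offsets at once by cross-correlating
one-hot base indicators, so N positions match nothing. Consensus
qualities follow a standard min-sum rule: agreeing positions get
q1+q2 capped at 93 (the largest encodable phred+33 score), disagreeing
positions keep the higher-quality base at quality |q1−q2|. The defaults
are deliberately permissive: on synthetic pairs drawn from ~134-nt
fragments every true overlap is found, and merged length is always within
[max(len1, len2), len1+len2−min_overlap].

## Clustering

Toxin transcripts are clustered at <1% nucleotide divergence (strict
inequality). Divergence is computed on a Needleman–Wunsch global
alignment (match +1, mismatch −1, gap open −4, extend −1) as
mismatches / aligned columns, where terminal gap columns (UTR-length
differences) are excluded from the denominator and internal gap columns
count as mismatches. End gaps are penalized during alignment so that
unrelated sequences align over their full length rather than snapping to
a short coincidental overlap; the terminal-gap exclusion is applied
afterwards. Clusters are single-linkage connected components — the choice
that matches the clusters' purpose of absorbing alleles and errors so
every read maps inside its cluster — and edges never cross toxin classes,
since cluster names are class-scoped. The representative is the longest
member (ties to the lexicographically smallest id) and member letter
suffixes (a, b, c, …) are assigned by descending member abundance when
abundances are available.

## Abundance

Mapping is seed-and-extend: exact k-mer seeds (k = 21, four seed
positions spread across the read) locate candidate diagonals on a
concatenated transcript index; each candidate is scored by ungapped
full-read comparison. Identity is matches / read length — read-relative,
with no terminal clipping — and a read is assigned to its best transcript
if identity ≥ 0.95, both strands considered. Ties are broken uniformly at
random under the caller's seed, implementing best-hit (not fractional)
multiread resolution: clustering at 1% guarantees that reads rarely tie
across clusters, only within them. Cluster percentages are reported on
two denominators: all toxin-mapped reads (`pct_toxin_reads`) and all
input reads of the quantification run (`pct_total_reads`).

## Heterozygous SNP calling

Every mapped read base is tallied into a per-transcript pileup. A site is
called a putative heterozygous SNP iff it lies inside the CDS, total
coverage is within [20, 20000] (bounds inclusive), and the
second-most-common base accounts for 40–60% of reads (inclusive; the
reported SNP% is the minor-allele fraction, which keeps all printed
values ≤ 60). Columns where more than two bases exceed a 5% noise floor
are considered ambiguous and skipped. The coding effect is determined by
translating the affected codon with the majority (reference) versus
runner-up (alternate) base; an alternate creating a stop codon is flagged
`nonsense` and excluded from synonymous/nonsynonymous tallies. SNP
density is 1000 × (SNPs in class) / (total CDS length of SNP-containing
transcripts of that class), reported as absent (not zero) when no
transcript in the class carries a SNP. The toxin-vs-nontoxin comparison
of heterozygous-locus frequency is a Pearson χ² on the 2×2 table with one
degree of freedom and no continuity correction; for the study's counts
(9/75 vs 69/1950) this gives χ² ≈ 13.96. `chisq_sf` wraps the χ² survival
function for df ∈ {1, 2} (equal to erfc(√(x/2)) and exp(−x/2)
respectively).

## Codon site models

The substitution process is the Goldman–Yang codon model on the 61 sense
codons: zero rate for multi-nucleotide changes, target-codon frequency
π_j for synonymous transversions, κπ_j for synonymous transitions, ωπ_j
and ωκπ_j for their nonsynonymous counterparts. The generator is
reversible for any π, so likelihoods are computed through a symmetric
eigendecomposition (B = D^{1/2} Q D^{−1/2}), giving exact transition
matrices for arbitrary branch lengths. Rate matrices of a site-class
mixture share one scaling constant — the mixture-average rate — so branch
lengths are in expected substitutions per codon under the model.

Site-to-site ω variation: M0 (one ω), M1a (p0 with ω0 ∈ (0,1] estimated,
the rest neutral — the variant with estimated ω0, matching fits that
report ω0 > 0), M2a (adds p2 with ω2 ∈ [1, 999]), M7 (beta(p, q)
discretized into K = 10 equal-probability categories represented by their
means), M8 (beta plus a selected class). The ω cap of 999 reproduces the
boundary estimates that arise when a class has no synonymous
substitutions. Codon frequencies default to F3x4 (position-specific
nucleotide frequencies with a 10⁻⁶ pseudocount); equal frequencies are
available and used in simulations.

Likelihoods use Felsenstein pruning over pattern-compressed alignment
columns with per-node rescaling (no underflow on valid input); mixtures
are combined per site by logsumexp. The likelihood is invariant to root
placement (pulley principle), which the tests exercise by rerooting.

Fitting maximizes lnL by bounded L-BFGS-B over log-transformed κ,
ω-like and beta parameters and raw mixture proportions, from `n_starts`
seeded starting points (default 2; the first is a deterministic warm
start, the rest jittered). Branch lengths are handled in one of two
modes: the default `scale` mode holds the guide tree's branch-length
proportions fixed and frees a single scale factor — accurate enough for ω
inference and an order of magnitude faster — while `full` mode frees
every branch length (log-transformed). Nested pairs are fitted with
`fit_nested_pair`, which warm-starts the alternative from the fitted null
(with a small but identifiable selected class so the extra parameters
keep gradient signal) and, should the optimizer still return a lower
likelihood than the null, substitutes the embedded null point — the null
is a boundary case of the alternative, so the alternative's maximum can
never be genuinely lower. LRTs use λ = 2(lnL_alt − lnL_null) against χ²
with two degrees of freedom for both M1a-vs-M2a and M7-vs-M8;
boundary-corrected mixture nulls are deliberately out of scope, making
the tests conservative. λ below −10⁻⁶ is flagged as a convergence
failure; tiny negatives are clamped to zero.

Guide trees are neighbor joining (scikit-bio) on Jukes–Cantor-corrected
nucleotide distances, falling back to the uncorrected p-distance when the
JC logarithm is undefined (saturation); negative NJ branch lengths are
clamped to zero. Preprocessing for selection input drops codon columns
with any gap, columns overlapping any taxon's signal peptide (spans given
in each taxon's own ungapped codon coordinates — only the mature,
secreted protein is under the selection of interest), and columns
containing stop codons; fewer than 10 remaining codons is an error.

## Synthetic data

The generator emulates the study system. Toxin gene families are built by
duplicating a random in-frame template (ATG …sense codons… stop, flanked
by UTRs) with within-family divergence below 1%; independent templates
keep families tens of percent apart, so clustering at 1% recovers the
family partition exactly. A configurable fraction of transcripts
(defaults: 12% of toxins, 3.5% of nontoxins) carries a second allele
differing at 1–3 CDS sites; reads sample the two alleles 50/50 (diploid,
no allelic imbalance; imbalance is a config knob for caller stress
tests). Expression weights for toxin clusters are drawn from the bundled
empirical expression table by default (log-normal as fallback), giving
the real data's dynamic range; members within a family decay
geometrically. Reads are 2×100 nt from ~Normal(134, 10) fragments —
hence 3'-overlapping pairs — with i.i.d. substitution errors at a
configured rate and phred-consistent constant qualities. Codon alignments
are evolved on a tree by exact transition matrices with i.i.d. site
classes, and every simulation writes complete truth tables (family
membership, allele positions, expression weights, per-read origins, site
classes). All randomness flows from a single integer seed; outputs are
byte-identical across runs.

What the generator does not model: indels, RNA degradation, positional
coverage bias, sequencing-quality decay along reads, allele-specific
expression, and paralogs at intermediate (1–5%) divergence. Passing
validation therefore demonstrates the correctness of the algorithms under
the stated statistical assumptions, not robustness to every artifact of
real libraries.

## Problem sizes for validation

The validation studies are sized for a single CPU. M0 recovery: 20
replicates of 8 taxa × 500 codons at ω = 0.5 (estimates scored against
[0.4, 0.6]). LRT power and type-I: 20 replicates each of 8 taxa × 300
codons (effect p2 = 0.2, ω2 = 4 for power; the nearly-neutral truth for
type-I, where the boundary null makes χ²(2) conservative). The SNP-caller
study runs a downscaled transcriptome (40 transcripts) with near-uniform
expression so that ~80,000 merged reads give >200× coverage at planted
heterozygous loci, heterozygous fractions raised (50% toxins, 25%
nontoxins — preserving the toxin > nontoxin ordering) so recall is
estimated over ~20 loci, and >10 kb of homozygous CDS for the
false-call count. The full-scale scenario (`paper_like`: 1,950 nontoxins,
the 75 empirical toxin families, 100,000 read pairs — 1/100 of the
study's quantification depth) is used for end-to-end cluster recovery and
expression-share checks.

## Known limitations

- The `scale` branch-length mode inherits the guide tree's length
  proportions; on very unbalanced trees `full` mode is the safer choice.
- F3x4 frequencies are estimated once from the alignment, not jointly
  optimized.
- Empirical-Bayes identification of selected sites (NEB/BEB), branch and
  branch-site models, and tree topology search are out of scope; the tree
  is fixed (user-supplied or NJ).
- The mapper is gapless; reads spanning indels (not generated here) would
  go unmapped rather than soft-clipped.
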