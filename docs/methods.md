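# Methods

This note records the models implemented in famevol, the conventions and
numerical choices behind them, and what the synthetic-data generators do
and do not emulate. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Codon substitution model

All likelihood computations use a GY94-family model on the 61 sense codons
of the standard code. The instantaneous rate i→j is nonzero only for
single-nucleotide changes and equals π_j times κ for transitions and times
ω for nonsynonymous changes. Each class matrix is scaled so that
−Σ π_i q_ii = 1, i.e. branch lengths are expected substitutions per codon
*within that ω class*. (codeml instead scales the proportion-weighted
mixture; with the per-class convention the simulator and the engine invert
each other exactly, which is what the round-trip tests rely on.)

Because the chain is reversible with respect to π, transition matrices are
computed from a symmetric eigendecomposition of D^{1/2} Q D^{−1/2} rather
than a generic matrix exponential; decompositions are memoized per
(κ, ω, π).

Codon frequencies: `equal` (uniform over 61) or `F3x4` (products of
position-specific nucleotide frequencies renormalized over sense codons,
with a 0.1 pseudocount per cell). F3x4 is the fitting default; the
simulator defaults to uniform.

## Site models and branch-site model A

- **M0**: one ω (1 free ω-distribution parameter).
- **M3**: three discrete classes, (p0, p1, p2; ω0, ω1, ω2) — 5 free.
- **M7**: ω ~ Beta(p, q) — 2 free.
- **M8**: p0·Beta(p, q) + p1·{ω_s ≥ 1} — 4 free.
- **Model A**: classes 0/1/2a/2b with proportions
  (p0, p1, p2·p0/(p0+p1), p2·p1/(p0+p1)); background ω ∈ {ω0, 1},
  foreground ω2 ≥ 1 on branches tagged `#1` (or passed explicitly). The
  null fixes ω2 = 1; the LRT has df = 1.

The beta component is discretized into K = 10 equal-probability
categories; each category's ω is its conditional mean, computed from the
regularized incomplete beta function (the means average exactly to
p/(p+q), which is asserted in tests).

Optimization is bounded L-BFGS-B on transformed parameters (log κ, log
branch-scale, softmax proportions, log/logit ω terms) with seedable random
multi-starts (default 5 for site models). The branch-length *scale* for
M3/M7/M8 is fixed at the M0 estimate by default (`reestimate_branch_lengths`
frees it); M3 and M8 additionally seed one start from the cached M0 and M7
solutions, which is what makes the nested-dominance property (lnL M3 ≥ M0,
M8 ≥ M7 within 1e-4) hold in practice. In the Monte-Carlo branch-site runs
κ and the scale are both taken from the M0 fit and held fixed — the same
speed/identifiability convention extended one step; with them free the
optima agree to within ~0.2 lnL units on the test problems but each fit
costs several times more.

LRT p-values use the plain χ²_df upper tail; for the branch-site test the
50:50 mixture of a point mass at zero and χ²₁ is available via
`mixture=True`. The plain χ²₁ convention is conservative, which is why the
measured type-I error in the acceptance run sits well below the nominal
0.05. A negative 2Δℓ (optimizer noise on a boundary null) is flagged and
reported with p = 1.

Positively selected sites are called by naive empirical Bayes: posterior
P(class k | site) ∝ p_k L_k(site) at the MLE, summed over ω > 1 classes,
with strict thresholds 0.95/0.99. `gridBEB` averages the NEB posteriors
over an 8-point grid (±25% on κ, the positive-class ω and its proportion),
weighted by each grid point's data likelihood. It is labelled as an
approximation everywhere; full Bayes-empirical-Bayes integration is not
implemented.

## Simulator

`simulate_codon_alignment` draws, in order: one multinomial site-class
vector, root codons from π (unless a root sequence is supplied, which must
be stop-free), then child states branch by branch in pre-order with
classes processed in ascending index. Site classes are drawn once and kept
along the whole tree — the site-model assumption — and foreground branches
switch classes to their foreground ω. One integer seed determines every
draw; identical inputs give bit-identical alignments.

Not emulated: indels, recombination, rate variation beyond the ω-class
structure, codon-usage drift along branches, or read-level RNA-Seq noise
(expression counts are generated directly at the matrix level). Passing
tests therefore demonstrate correctness of the inference machinery under
its own model assumptions, not robustness to alignment error or model
misspecification in real data.

The genome-layout generator plants tandem clusters on random chromosomes
with 0-or-1-gene gaps drawn per adjacent pair and keeps every other family
gene at least three ranks away, so the adjacency rule recovers exactly the
planted clusters; anchor Ks values are drawn i.i.d. from a stated
distribution (default normal(0.15, 0.05) truncated to (0, 1) by
rejection) and recorded exactly as drawn. The expression generator plants
class-consistent rows (constitutive rows are flat enough that no tissue
holds ≥ 50% of the row sum; peak rows have ≥ 2 expressed and ≥ 1 silent
tissue). The promoter generator plants exact non-overlapping forward-strand
motif copies and redraws the background until the both-strand scan count
equals the planted count.

## Distances, NJ, subfamily assignment

Protein distances use pairwise deletion of gap columns; p = mismatches /
compared sites, Poisson d = −ln(1 − p). NJ is the Saitou–Nei Q-criterion
agglomeration; leaves are sorted lexicographically first and Q-ties break
at the lowest (row, column) pair, so the output is reproducible and
invariant to input order. Negative branch-length estimates are clamped to
zero with a warning. On additive matrices the reconstruction is exact
(topology and branch lengths), which the tests assert to 1e-9.

Subfamily assignment gives each query the label of the smallest
bipartition side containing it whose reference leaves are monotypic;
failing that, the label of the topologically nearest reference (ties
broken by name) with an `ambiguous` flag.

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree, and counts recovered nontrivial bipartitions (0–100 scale),
seeded; default 1000 replicates.

## Ka/Ks, 4DTv, dating

NG86 counting: per codon, the synonymous site count at each position is
the synonymous fraction of the single-nucleotide changes that do not
create a stop codon (stop-creating changes are excluded from both
numerator and denominator). Differences in multi-hit codons are averaged
over all orderings of the differing positions with equal weight,
discarding orderings that pass through a stop; codon pairs whose every
pathway is blocked are dropped entirely. Proportions pN, pS are corrected
with Jukes–Cantor d = −(3/4)ln(1 − 4p/3), undefined (an error) at
p ≥ 3/4. ω = Ka/Ks is NaN when Ks = 0.

4DTv: a column qualifies iff both codons are fourfold-degenerate at the
third position and identical at the first two; the value is the raw
transversion proportion among qualifying third positions (uncorrected —
the published values in the 0.12–0.33 range are raw proportions; an
HKY-style correction was considered and left out of scope).

Dating: anchors are filtered to the *open* window 0 < Ks < 1, events with
fewer than 3 surviving anchors are rejected with a reason, the sample
(n−1) standard deviation is reported, and T = mean Ks / (2λ) with
λ = 6.1 × 10⁻⁹/site/year, printed as million years rounded half-up to the
nearest integer. This rounding reproduces 47 of the 48 published table
rows exactly; the one exception (mean Ks printed as 0.177 → 14.51 → 15
vs. a printed age of 14) is consistent with the source having used an
unrounded mean below 0.1769, and no rounding rule reproduces both that row
and the 0.157 → 13 row from the printed precision.

## Functional divergence

**Type-I.** The observable per site is the Fitch minimum-change count in
each cluster's induced subtree (gaps act as missing data). Counts are
modelled as Poisson with exposure d_A (d_B) times a site rate; rates are
Gamma(α, mean 1). With probability θ the two clusters draw independent
rates; otherwise one shared rate. Both marginals are closed-form
(negative-binomial-type) expressions, so the likelihood is exact; θ, α,
d_A, d_B are estimated by L-BFGS-B with restarts (default 10, seedable).
The LRT against θ = 0 uses χ²₁; Q_k is the posterior probability of the
independent-rates class; the s.e. of θ comes from the finite-difference
curvature of the profile in logit space (delta method). Clusters with
fewer than four sequences are refused ("cannot be analyzed"): the mixture
has essentially no information at that size.

**Type-II.** A deliberately simple moment construction, not the full
Gu-2006 ML: among sites internally conserved in both clusters, let f be
the radical fraction of the between-cluster fixed differences (radical =
consensus residues in different groups of the packaged partition:
aliphatic GAVLIPM, aromatic FWY, polar STCNQ, acidic DE, basic KRH). The
baseline radical rate p_r is estimated from within-cluster polymorphism
(variant vs. consensus pairs), regularized by one pseudo-observation at
the uniform residue-pair rate so tiny samples cannot pin it to 0 or 1.
Then θ_II = (f − p_r)/(1 − p_r), with a binomial delta-method s.e.;
negative estimates are reported unclamped. Q_k is the two-class posterior
that a radical fixed difference is model-divergent rather than baseline;
non-radical sites get Q_k = 0.

CAAS calls use a strict cutoff (Q_k > 0.95 by default; 0.80 available),
reported as 1-based alignment columns; `intersect_caas` intersects two
call sets (e.g. type-I ∩ type-II).

## Expression and promoters

RPKM = count / (length/10³) / (library/10⁶). Clustering uses 1 − Pearson r
with scipy's average linkage; constant-profile genes (including the
never-expressed) are excluded with a warning because their correlation is
undefined. Specificity classes are assigned with precedence silent →
single-tissue-exclusive → constitutive (all tissues > 0) →
single-tissue-peak (max tissue ≥ 50% of the row sum — the "marked peak"
threshold is this package's quantification; nothing in the source material
fixes one) → other, making the five classes mutually exclusive and
exhaustive.

Motif scans compile IUPAC consensi to regular expressions and count
overlapping matches of the motif and of its reverse complement against the
forward sequence, deduplicating matches that start at the same locus (a
palindromic motif counts once per locus). The packaged cis-element table
(G-box CACGTG, Box 4 ATTAAT, TCA-element, MBS, ARE, HSE, GARE-motif,
circadian CAANNNNATC) carries *approximate* consensi and is meant as a
default, not a reference database; callers can supply their own
definitions. Per-family mean copy numbers are reported to three decimals.

## Protein descriptors

pI: bisection on (0, 14) of the Henderson–Hasselbalch net charge to
|charge| < 1e-4, using a Bjellqvist-style pKa set (side chains C 9.00,
D 4.05, E 4.45, H 5.98, K 10.0, R 12.0, Y 10.0; residue-specific
N-terminal pKas; C-terminal carboxyl fixed at 3.55). The C-terminal pKa is
deliberately context-independent: residue-specific terminal values make
the pI non-monotone under appending acidic residues, and monotonicity is a
contract of this implementation. Mw: sum of average residue masses
computed from residue elemental compositions with IUPAC standard atomic
weights, plus one water (18.015 Da); the empty chain returns one water.

Signal peptides are pass-through annotations; no predictor is bundled.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks run at sizes chosen to make their statistical
tolerances meaningful on a single CPU: M0 recovery at 4 taxa × 300 codons
× 20 replicates; branch-site type-I error at 4 taxa × 100 codons × 200
replicates (100 in the acceptance script); branch-site power at 8 taxa ×
500 codons with a four-leaf foreground clade (branch-site LRTs carry
little information when the foreground is a single short branch, so the
power condition uses a clade, as subfamily tests do in practice); θ_I
recovery at 500 sites × 50 replicates; planted-structure round trips over
100 seeds each.

## Known limitations

- NEB posteriors ignore parameter uncertainty; gridBEB is a labelled
  approximation, not BEB.
- The type-II estimator is a moment construction; its s.e. is a binomial
  approximation and its Q_k is coarse (0 for all non-radical sites).
- The likelihood engine fixes the input topology; only a global scale is
  re-estimated. No ML tree search is provided.
- NG86 is a counting method; for highly diverged pairs (p ≥ 3/4) it
  refuses rather than extrapolating, and for Ks near saturation the ML
  pairwise route (fitting M0 on a two-leaf tree) is the better tool.
- 4DTv is reported uncorrected.
- The simulator's independence assumptions (no indels, fixed site
  classes) mean real-alignment artefacts are out of scope for the tests.
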