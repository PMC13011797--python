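# Methods

`clockevol` re-implements, as one tested pipeline, the comparative
molecular-evolution toolkit used to study how a gene network (the worked
case being the *Drosophila* circadian clock: *per*, *tim*, *Clk*, *cyc*,
*cwo*, *cry*, *jet*, *dbt*, *sgg*, *vri*, *Pdp1*) evolves across a species
radiation: windowed divergence and Ka/Ks tracks, codon site-model selection
tests, inter-protein coevolution scanning, pleiotropy–rate regression, and
tanglegram incongruence metrics, plus a synthetic codon-evolution generator
that provides ground truth for every stage.

## Alignment quality control

Input alignments are in-frame codon FASTA.  Two filters run in sequence:

1. **Gap pruning** — drop any sequence whose gap fraction exceeds
   `max_gap_frac` (default 0.05) *or* whose absolute gap count exceeds
   `max_gap_count` (default 100 bases).  `N` is an ambiguous base, not a
   gap.
2. **Consensus filter** — score each sequence by the fraction of its
   unambiguous positions matching the column-majority residue (ties broken
   alphabetically; gaps and `N` never win a column) and drop sequences
   below `min_consensus` (default 0.40).

The order (gap pruning first) follows the narrative order of the original
protocol; the consensus score is the simplest interpretable reading of a
"percent consensus" cutoff.  Both filters are single-pass; on realistic
data a second application is a no-op because the retained majority is
essentially unchanged.

## Sliding windows

**Dxy** (default window 180 nt, step 6 nt) is the mean over unordered
sequence pairs of mismatches / compared sites, comparing only positions
where both sequences carry A/C/G/T (pairwise deletion).  A window is masked
when the mean per-pair comparable length falls below 50% of the window
(configurable).  The source protocol states 180 nt in its methods but 150 nt
in a figure caption; 180 is the default and both are one flag away.

**Ka/Ks** (default window 150 nt, step 6 nt, codon-aligned) uses
Nei–Gojobori (1986) counting: per-codon synonymous site fractions from the
genetic code (changes to stop codons count as nonsynonymous so that
N + S = 3 exactly), differences partitioned by averaging over all minimal
substitution pathways with stop-codon intermediates excluded, and
Jukes–Cantor correction.  Per window each statistic is the mean of per-pair
values; omega is the mean of per-pair ratios (not the ratio of means) and
is masked when fewer than 25% of pairs have a valid Ks.  Note that pathway
averaging can attribute a small nonsynonymous count to purely synonymous
histories (e.g. the Leu pair TTA/CTC), so windowed Ka on omega = 0 data is
near, not exactly, zero.

**Ka\*** is the maximum windowed Ka among windows whose gap fraction is
below 1000/6630 ≈ 0.151 (the source protocol's absolute cutoff, generalised
to a fraction).  Gene-wide Ka is full-length NG86 averaged over pairs.

## Codon site models

The rate matrix is GY94-style on the 61 sense codons of the standard code:
zero rate for multi-nucleotide changes, kappa on transitions, omega on
nonsynonymous changes, target-codon frequency on every change.  Codon
frequencies default to F3x4 estimated from the alignment (uniform, F1x4 and
explicit vectors available).  Q is scaled so the *mixture-average* rate is
one, so branch lengths are expected substitutions per codon site under the
fitted model.

Likelihoods use Felsenstein pruning over site patterns with per-pattern
rescaling; tips with gap/ambiguous/stop codons are marginalised over all 61
states.  Site models: M0 (one ratio), M1a (nearly neutral), M2a (positive
selection), M7 (beta, K = 10 equal-probability categories represented by
category means), M8 (beta plus a class at omega_s >= 1).  The simulator
uses the identical discretisation.

Fits run bounded L-BFGS-B in log-parameter space (kappa in [0.01, 100],
omega in [1e-4, 50], beta shapes in [0.005, 99], p0 in (0, 1), omega_s in
[1, 50]) with deterministic seed-derived restarts.  The standard workflow
estimates a single global branch-length scale under M0 and fixes it for the
richer models; M8 warm-starts from the M7 optimum (with a boundary refit
guard), which keeps the nesting l(M8) >= l(M7) numerically true.  A
four-start diagnostic showed the warm start recovers the M8 optimum to
better than 0.01 likelihood-ratio units on desk-scale data.

LRTs: M0 vs M1a (df 1), M1a vs M2a (df 2), M7 vs M8 (df 2); negative raw
2Δℓ (optimiser noise in nested fits) is reported raw and clamped to zero
for the chi-square p-value.  Positively selected sites come from naive
empirical Bayes (NEB) posteriors of the omega > 1 class; Bayes empirical
Bayes is not implemented, which is the main deviation from CodeML's
preferred site test.  Site coordinates are reported both as alignment
columns and projected onto a named reference sequence.

The per-site episodic scan is a fixed-effects approximation of the
branch-mixture methods: each codon column gets its own synonymous rate
alpha and nonsynonymous rate beta (null: beta = alpha), tested one-sided
for beta > alpha against the ½χ²₀ + ½χ²₁ mixture.  The full random-effects
branch mixture is out of scope.

## Synthetic data generator

Trees are Yule topologies rescaled so the mean root-to-tip path equals the
requested height (expected substitutions per codon site; default 0.5, which
produces pairwise nucleotide divergences in the 0.1–0.3 range typical of a
several-tens-of-millions-of-years radiation).  Codon alignments evolve
site-by-site by exact Gillespie simulation along each branch under the same
GY94 mixtures the estimators fit, with true per-site class labels returned
for recovery tests.  Gaps are injected i.i.d. per (sequence, codon) as
whole codons.  The generator shares the model definition with the
estimators but no code path: simulation is event-based, inference is
matrix-exponential-based.

Coupled column pairs: both sites evolve under GY94 with `omega_pair`
(default 3 — compensatory sites are modelled as repeatedly exchanging
nonsynonymous variants); every amino-acid-changing event at one site
triggers, with probability rho, a compensating single-nucleotide
nonsynonymous jump at the partner on the same branch, symmetrically.
rho = 0 is exact independence.  A `rate_multiplier` is exposed; the default
is 1 because faster coupled sites saturate a single codon's pairwise
signal and *reduce* detectability.

Pleiotropy tables: GO Biological Process counts are negative binomial
(mean 25, shape 2); Ka = exp(-3 + slope·count + Normal(0, sd)).  slope = 0
is the null world.

What the generator does not emulate: indel evolution (gaps are independent
of the substitution process), among-site rate variation beyond the omega
classes, codon usage bias beyond the stationary frequencies, alignment
error, and orthology mistakes.  Passing tests therefore demonstrate
correctness of the estimators under the generating model, not robustness
to real-data artefacts.

## Coevolution scan

For each protein column, every sequence pair (i, j) receives the BLOSUM62
transition score B(a_i, a_j), and the per-column linear trend of B on the
pair's divergence time t_ij (patristic distance; Poisson-corrected protein
distance when no tree is supplied) is removed, leaving a mean-centred
residual vector theta.  This detrending *is* the divergence-time
correction: the textbook alternative, dividing B by t_ij, makes every
column vector proportional to 1/t — the closest species pairs dominate by
orders of magnitude, all column pairs correlate near r = 1, and on
tree-structured null data we measured over 60% of pairs being called
significant.  Detrending reduces the null flagged fraction to ~3%.

Columns with fewer than 2 distinct residues or fewer than 3 gap-free pairs
are untestable.  Pair significance comes from an explicit permutation null
(taxon assignment of one column reshuffled; add-one p-estimator; default
10,000 permutations), two-sided on |r| by default with a one-sided
positive-correlation option (`alternative="greater"`), which is the
directional hypothesis of compensatory coevolution.  Benjamini–Hochberg FDR
runs across all tested pairs; a pair is *flagged* when q < 0.05, raw
p <= alpha, and |r| lies in the top (1 − bootstrap_level) tail of tested
pairs.  The last rule mirrors the original method's bootstrap-level
thresholding of the correlation and compensates for the residual
phylogenetic confounding of taxon permutation (columns cluster with the
tree, so raw p on null tree-structured data is mildly inflated — about
0.16 at p <= 0.05 in our null measurements — rather than uniform).

Detector calibration, frozen after a one-time power study: on 32-taxon
trees of height 1.2 with 25-codon proteins, injected rho = 1 pairs are
recovered at q < 0.05 in >= 80% of replicates while the null flagged
fraction stays <= 0.05.  Deeper trees (height 2) lose power to saturation.

## Pleiotropy regression

Pleiotropy scores: distinct GO Biological Process term count ("highest
level of the GO hierarchy" is read as the namespace filter, not a
depth filter), and degree in the deduplicated undirected interaction graph
(A–B equals B–A, multi-source duplicates collapse, self-loops count once).
The response (gene-wide Ka or Ka*) is Box-Cox transformed with lambda
chosen by profile log-likelihood on the grid [-2, 2] step 0.05 (zeros
offset by half the smallest positive value), then ordinary least squares on
one predictor; reported as F(1, n−2), p, adjusted R².  The "top 10%
most pleiotropic" report includes all ties at the 90th percentile.

## Tree comparison

Neighbor joining (negative branches floored at zero with mass moved to the
sibling) is the fallback when no externally inferred tree is supplied.
Ultrametric conversion is deterministic mean-path-length clock projection
(every node at the mean root-to-tip depth of its subtree, children clipped
below parents): the ultrametric tree is used only for dendrogram
comparison, so a penalised-likelihood dating model would add machinery
without changing any downstream number.  Entanglement is the normalised
sum of |rank difference|^p over matched leaves (p = 1 default), after a
deterministic two-sided greedy untangling (post-order node flips,
first-improvement, up to 25 sweeps); 0 for identical leaf orders, 1 for a
fully reversed caterpillar pair.  Robinson–Foulds counts bipartitions
present in exactly one unrooted topology.

## Numerical choices and degenerate inputs

- Per-pattern likelihood rescaling guards against underflow up to at least
  65 taxa; non-finite site likelihoods raise with the offending pattern.
- Transition matrices are built by symmetrised eigendecomposition of the
  reversible Q; tiny negative entries are clipped to zero.
- Patristic distances are floored at 1e-6 to avoid division blow-ups.
- NG86 omega is masked (nan) when Ks = 0 or a JC argument leaves the
  domain; masked values propagate as nan with a recorded mask reason.
- Invariant columns in the episodic scan short-circuit to statistic 0,
  p = 1.
- Ties in the NJ joining criterion and in consensus majorities resolve to
  the lowest index / alphabetically first candidate, so all outputs are
  reproducible byte-for-byte from (inputs, seed).

## Problem sizes used in the test suite

Desk-scale sizes keep the full suite within a coffee break while leaving
the statistics meaningful: the M7-vs-M8 size calibration uses 100 null
replicates of 12 taxa x 300 codons at tree height 0.5 (at height 0.3 the
boundary null is so conservative that the empirical size is indistinguishable
from zero); M0 recovery uses 12 taxa x 800 codons; the coevolution power
study uses 50 replicates at the frozen conditions above; the pleiotropy
null calibration uses 200 replicates of 150 genes.  `scripts/acceptance.py`
re-runs the same computations at somewhat smaller replicate counts and
prints every headline number it computes.

## Known limitations

- NEB only (no BEB): posterior site calls ignore parameter uncertainty and
  can be anticonservative near boundary fits.
- The episodic scan is fixed-effects: it detects sites with elevated
  average beta, not selection confined to a few lineages.
- The coevolution permutation null retains clade-level confounding; raw p
  should be interpreted jointly with the flag rule, and the statistic is a
  re-derivation of the CAPS idea, not a byte-compatible clone.
- Branch lengths are fixed (up to one global scale) during site-model
  fitting; per-branch re-optimisation is available behind a flag but not
  exercised by the default pipeline.
- The full-scale reproduction of the published per-gene statistics
  requires the deposited 65-species alignments and is not runnable from
  the synthetic generator.
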