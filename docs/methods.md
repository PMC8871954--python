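# Methods

`traitlab` reconstructs ancestral states of bacterial cell-wall traits on a
fixed rooted phylogeny, compares rate-prior schemes by Bayes factors, tests
for correlated evolution between two binary traits, reconstructs the
ancestral gene order of the *dcw* (division and cell-wall synthesis)
cluster, and classifies phylum-level presence/absence profiles of 16
outer-membrane genes. This note records the models, the defaults and why,
the numerical choices, and what the synthetic-data experiments do and do not
establish.

## Discrete-trait model

A trait with k states (k = 2 for the membrane count, k = 3 for the
peptidoglycan layer) evolves along the tree as a continuous-time Markov
chain with generator Q, all off-diagonal rates q_ij free and possibly
asymmetric (no reversibility assumed). Branch lengths are expected
substitutions per site; before rate inference the tree is rescaled so the
mean branch length is 0.1, which puts rates on a common, interpretable
scale across trees. Exactly-zero internal branches are replaced by 1e-8 so
marginal reconstruction at their child nodes stays well defined; every such
replacement is logged.

Tip observations may be ambiguity sets (the peptidoglycan state "12" =
{thin, thick} for a taxon whose thickness is undocumented); they enter the
pruning likelihood as 0/1 indicator partials and are never renormalized at
the tip. The root prior is uniform over states by default; a stationary
option is provided. The published analyses this package re-implements
delegate the root treatment to their inference program's default and do not
state it, so both options are exposed.

Transition probabilities are `expm(Q t)` (scipy's scaling-and-squaring Padé)
in the public API. The MCMC inner loop uses a closed form for k = 2 and an
eigendecomposition applied to all branches at once for k = 3, 4, falling
back to `expm` when the eigenvector matrix is ill-conditioned or the
reconstruction error exceeds 1e-8 per row. Likelihoods come from
Felsenstein pruning with per-node rescaling (numba-compiled kernel);
marginal ancestral probabilities combine the standard upward partials with
an outside (downward) pass and are normalized per node.

## Rate priors and MCMC

Six prior schemes over the rates:

| scheme  | prior on each q_ij                                     |
|---------|--------------------------------------------------------|
| E       | Exponential, mean 10                                   |
| H1      | Exponential, mean ~ Uniform(0, 10)                     |
| H2      | Exponential, mean ~ Uniform(0, 100)                    |
| R1      | H1 + reverse-jump over rate-model structures           |
| R2      | H2 + reverse-jump                                      |
| HBIASED | binary only: gain mean ~ U(0, 1), loss mean ~ U(1, 10) |

"Exponential of 10" is read as mean 10, and "hyperprior 0 to 10" as an
exponential whose mean is uniform on (0, 10) — the convention of the
program whose analyses these schemes mirror. HBIASED is the sensitivity
scheme purposely biased toward losing the derived state; it defaults to 100
chains.

Rates update by multiplicative log-normal proposals whose step size is
tuned to a 20–40% acceptance rate during burnin and frozen afterwards (so
the post-burnin kernel satisfies detailed balance). Hyperprior means update
by a uniform window with reflection at the interval bounds.

Reverse jump operates on a partition of the rate pairs into shared-rate
classes plus a "zero" set of pinned rates, with a uniform prior over
structures. Four moves: split a class (the leaving subset gets a fresh rate
drawn from the prior), merge two classes (a uniformly chosen member's rate
survives), pin a whole class to zero, and revive a uniformly chosen
non-empty subset of the zero set with a fresh prior-drawn rate. Because new
dimensions are born from the prior, Jacobians are unity and the born rate's
prior density cancels; the remaining Hastings factors count move
availability, class/pair selection and the 2^s − 2 ordered split outcomes.
Correctness is verified by a flat-likelihood run: the four structures of a
binary trait appear with equal frequency and the non-zero rate marginal
matches the hyperprior mixture (KS < 0.02).

Default chain settings follow the full-scale protocol (1,100,000
iterations, burnin 100,000, one sample per 1,000, 10 chains). Those
settings yield 1,000 retained samples per chain; the source protocol's
summary text mentions 10,000 per chain, which its own cycle counts do not
produce — the package follows the stated cycles/thinning/burnin and the
sample count is whatever they give. Convergence is summarized by the
largest standardized discrepancy between a single chain's mean and the
pooled mean over rate parameters; values above 0.5 emit a warning, never a
silent pass.

## Marginal likelihoods and Bayes factors

The stepping-stone estimator runs one chain annealed from the posterior
(β = 1) to the prior (β = 0) along the ladder β_j = (j/K)^(1/0.4) —
Beta(0.4, 1)-spaced powers, the standard choice that concentrates stones
near the prior, where the integrand varies fastest. Stone j contributes
log mean exp((β_{j+1} − β_j)·logL) over its retained draws; 20% of each
stone's iterations are discarded as settling time after each β change.
Full-scale default: 100 stones × 10,000 iterations. All-(−inf) weights
raise an error suggesting a denser ladder rather than returning −inf.

Bayes factors are reported on the doubled-log scale, BF = 2·Δlog mL, with
evidence labels: > 2 positive, 5–10 strong, > 20 very strong; the unnamed
interval (10, 20] is labelled "strong-to-very-strong".

## Correlated evolution

Two binary traits are combined into a 4-state chain over (00, 01, 10, 11)
with simultaneous double changes structurally forbidden. The independent
model ties each trait's gain and loss across the other trait's state (4
free rates); the dependent model frees all 8 conditional rates. The test
statistic is the stepping-stone BF between them. The three-state
peptidoglycan trait is first recoded to binary under case A (absent vs
present), B (thick vs rest) or C (thin vs rest); the ambiguity set {1,2}
recodes as thin. Both models use the H1-style hyperprior by default — the
source analyses do not state which prior their correlation runs used, so
the package picks the adaptive-scale family and exposes the choice.

## dcw gene order

Input gene-order tables carry, per gene, its genome, molecule, ordinal
index among all genes on the molecule, strand and family (17 families,
mraZ…murB). Encoding inserts artificial telomeres where consecutive dcw
genes are separated by more than 5 intervening non-dcw genes (a 10 kb
distance mode is available); "too far" is not pinned down by the source
description, and 5 intervening genes is a conservative cluster definition
consistent with the sub-cluster examples it gives. Tandem same-family
copies collapse to one gene. Remaining paralogs resolve by, in order:
most dcw-gene context on the artificial chromosome; residence on the main
DNA molecule (largest `molecule_size` if given, else the lexicographically
smallest molecule id); orientation matching the main molecule's dcw genes;
lowest coordinate as a deterministic last resort. Every choice is logged
with the rule that made it.

Cluster status per family: the largest dcw-carrying chromosome with ≥ 3
genes is the main cluster (ties reported as `main-cluster(tied)`), other
chromosomes with ≥ 2 genes are sub-clusters, singletons are outside, and
missing families are absent.

Ancestral gene orders are reconstructed by per-adjacency parsimony: every
adjacency observed in an extant genome is a binary character; unit-cost
Sankoff up and down passes give, per node, the set of states attainable in
a minimum-change labeling; ambiguous nodes resolve toward presence, the
loss-leaning choice appropriate for a locus whose history is dominated by
gene loss and delocalization rather than gain. Accepted adjacencies are
made mutually consistent (one adjacency per gene extremity; circular
components broken) by dropping the side with lower leaf support, ties
alphabetical, all conflicts logged. Remaining adjacencies assemble into
linear signed gene orders; a family present in the data but absent from a
node's adjacencies is emitted as "outside" — ancestors are never called
absent, mirroring the behaviour of the homology-based reconstruction this
substitutes for. An export of the extant karyotypes in the block format
that program reads is provided so the original can be run for comparison.

## Outer-membrane patterns

Phylum-level calls from the genome × gene boolean matrix: present when the
carrier fraction reaches 0.5; "?" when the fraction is positive but at most
0.1 (isolated occurrences that may be contamination or recent transfer);
"variable" for intermediate fractions (presence in a sub-group only);
absent at zero. Four three-valued templates (present/absent/variable)
describe the recurring patterns; assignment minimizes Hamming distance over
the template's non-variable entries, with "?" counted as absent and ties
reported rather than broken. In the true-diderms-LPS template the
non-diagnostic Lpt/Tol-Pal members (lptA, lptC, lptF, lptG, tolA, tolQ,
tolR, ybgF, lolB) are "variable" because their presence there is
phylum-specific, ranging from strongly reduced to complete; the diagnostic
entries are bamA plus lptD/lptE and pal/tolB, the outer-membrane-facing
components never found in atypical diderms. Templates ship as editable
config, since the authoritative per-cell calls live in a figure rather
than a table.

## Synthetic data

Generators are pure functions of (config, seed). Trees are Yule
(pure-birth): tree shape is not the object of study and a one-parameter
model suffices; branch lengths rescale to mean 0.1 like the real tree.
Traits evolve by exact jump-chain simulation, so parent→child transition
frequencies match `expm(Q t)` by construction. Default binary truth rates
(gain 2.4, loss 0.1) sit at the magnitude inferred for the membrane trait,
so calibration probes the regime the real analysis operates in. The
dependent-pair generator couples each trait's rates to the other's state by
a factor of 40 around a base rate of 1; gene orders evolve by per-branch
gene escape (to a fresh molecule) and loss, with no gain; presence/absence
matrices draw each genome from its phylum's pattern vector with independent
flip noise.

What the synthetic data do not emulate: non-clocklike branch-length error,
phylogenetic uncertainty (the tree is taken as known), correlated
missingness in trait surveys, assembly artifacts in gene order
(fragmentation is only approximated by the escape event), and contamination
structure in presence/absence matrices (noise is i.i.d. flips). Passing
calibrations therefore validate the machinery under the stated model, not
robustness to real-data pathologies.

## Validation experiment design

- Likelihood: pruning equals exhaustive enumeration over internal states
  (trees ≤ 6 tips, k ≤ 3, 100 random generators, tolerance 1e-10), and the
  2-state transition matrix equals its closed form to 1e-10.
- Prior recovery: with fully ambiguous tips each scheme reproduces its
  marginal prior on q01 (KS < 0.02 on 10,000 retained samples). For the
  reverse-jump schemes the check uses the non-zero samples — the marginal
  prior there carries an atom at zero — and the structure frequencies are
  checked for uniformity separately.
- Quadrature: on a two-tip fixture (branches 0.5, prior mean 1) posterior
  rate means agree with dense 2-D grid quadrature within 0.02 and the
  stepping-stone log marginal likelihood within 0.1.
- Rate recovery: 20 replicates of 85-tip trees at truth (2.4, 0.1), chains
  of 110,000 iterations under H1, central 95% intervals cover the truth in
  ≥ 90% of (rate, replicate) checks. The root state is drawn from the root
  prior because credible-interval calibration is only guaranteed when the
  generative model matches the inference model; with a root pinned to one
  state and a fixed-mean prior (scheme E) whose own 2.5% quantile (0.25)
  exceeds the loss-rate truth (0.1), coverage drops to ~88% for the loss
  rate whenever the data contain few losses — a prior-tail effect worth
  knowing about when reading the real analyses, not an MCMC defect (the
  posterior itself is quadrature-verified).
- Correlation: strongly dependent pairs on 200-tip trees yield BF > 2 in
  ≥ 80% of 20 replicates; independent pairs keep the median BF below 2.
  Desk-scale stepping stone: 16 stones × 500 iterations.
- Parsimony: per-adjacency state sets equal brute-force minimum-change
  enumeration on 6-leaf problems; ancestral adjacency recovery ≥ 90% at
  escape probability 0.05 per branch. The recovery bound concerns the
  escape process; adding gene loss (which removes a gene and both its
  adjacencies from every descendant) lowers recoverable information for
  any method — the loss-included figure is reported alongside as a
  diagnostic, not a bound.
- Patterns: ≥ 95% of phyla recover their generating pattern at 5% flip
  noise.

## Known limitations

- The reverse-jump structure prior is uniform over partitions including the
  zero assignments; programs in this space differ in that prior, so
  posterior model-structure frequencies are comparable only qualitatively.
- The stepping-stone ladder and per-stone settling fractions are the
  literature defaults, not a match to any particular program build.
- Adjacency parsimony reconstructs each adjacency independently; unlike
  block-building methods it can propose ancestor adjacency sets that need
  conflict resolution, which is done greedily by leaf support.
- No rate heterogeneity across branches, no covarion behaviour, no
  continuous traits.
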