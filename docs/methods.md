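# Methods

`skytree` is a compact Bayesian phylodynamic inference engine: it samples
the posterior P(T, θ | D) ∝ P(D | T, θ) P(T | θ) P(θ) over rooted time
trees T (possibly containing sampled ancestors) and model parameters θ,
given a nucleotide alignment D with per-taxon sampling dates. This note
records the models, the numerical choices, and what the validation suite
does and does not establish.

## Time trees and sampled ancestors

Node heights are measured backwards in time from the latest sampled tip
(height 0); an edge's duration is the parent height minus the child
height. A *sampled ancestor* — a sample that is a direct ancestor of
another sample — is represented internally as a degree-2 node carrying a
taxon. On disk, sampled ancestors are exchanged as zero-length terminal
branches (the common interchange convention); a pendant branch shorter
than 1e-10 × root height is decoded as a sampled-ancestor attachment.
Every parse, and every accepted MCMC proposal (spot-checked on a fixed
cadence), re-validates the tree invariants: one root, parent above child,
degree-2 nodes only with a taxon, leaf heights equal to their sampling
times.

Tip dates given as forward-time values (e.g. decimal years) are converted
to heights by subtracting from the maximum; all-gap or all-ambiguous
alignment columns count as invariant-capable for all four nucleotides,
consistent with treating gaps as missing data.

## Substitution models and model averaging

Reversible nucleotide models are indexed by six-digit restricted-growth
codes over the alphabetically ordered rate pairs A-C, A-G, A-T, C-G, C-T,
G-T; `121121` is HKY, `111111` is JC69/F81, and the full space of 203
codes is the set partitions of six rates (Bell(6)). The generator is
Q_ij = r_ij π_j, normalized to unit mean rate; transition probabilities
come from the symmetrized eigendecomposition (exact for reversible Q).
Discrete-gamma rate heterogeneity uses mean-of-bin category rates, so the
mixture mean is exactly 1 by construction (the incomplete-gamma identity,
not quadrature); the proportion of invariable sites enters the likelihood
mixture as a separate point mass at rate zero.

The model-averaging chain moves through this space by reversible jump:
a *split* divides a rate group in two, drawing u ~ U(0,1) and setting the
pair (2u·r, 2(1−u)·r) so the group mean is preserved and a merge-back
reconstructs the original exactly (Jacobian 4r); a *merge* averages two
group rates (Jacobian 1/(4r_new)). Proposal counts are corrected by the
number of admissible refinements/coarsenings on each side, so that a
data-free chain with a uniform prior over codes visits all 203 codes
uniformly — this χ² uniformity check is the operative validation of the
Jacobian bookkeeping. Indicator flips (unequal frequencies, gamma,
invariable sites) draw newly activated parameters from their priors
(Dirichlet(4,4,4,4), Exp(1), U(0,1)), so their acceptance reduces to the
likelihood ratio.

## Phylogenetic likelihood

Felsenstein pruning over compressed site patterns, with ambiguity codes
as indicator tip partials and sampled ancestors contributing their
observed states as degree-2 constraints. The invariable-sites term uses a
fast path: only patterns where some nucleotide is compatible with every
tip can contribute, and their contribution is a base-frequency sum —
no pruning pass at rate zero. A deliberately plain per-site
implementation (`log_likelihood_naive`, which realizes the invariant
class as an explicit rate-0 mixture component) is kept as the correctness
oracle; the two agree to 1e-10 on random instances, and both agree with
exhaustive internal-state enumeration on all rooted shapes with ≤ 5
taxa. Per-pattern rescaling activates when partials drop below 1e-300;
the invariant-sites term is combined with the rescaled variable part in
log space.

Clocks: strict, or uncorrelated-lognormal relaxed in the discretized
form (an integer rate category per branch over equal-probability
lognormal quantile bins, renormalized to mean 1 so `mean_rate` alone
carries the time scale).

## Tree priors

**Coalescent.** Serial (heterochronous) constant-size coalescent with
pairwise merger rate 1/Ne in tree time units.

**Birth-death with serial sampling and sampled ancestors.** One lineage
starts at the origin height t0; lineages birth at rate λ, die at rate μ,
are ψ-sampled (removed with probability r upon sampling), and surviving
lineages are ρ-sampled at height 0. The sampled-tree density is computed
in a labelled-tree convention derived from first principles:

- each edge from height a down to b contributes q(a)/q(b), where
  d log q/dt = −(λ+μ+ψ) + 2λ p0(t) and p0 is the no-sample probability
  (closed forms via the usual c1/c2 constants);
- each bifurcation contributes 2λ; each ψ-leaf ψ(r + (1−r) p0(y)); each
  sampled ancestor ψ(1−r); each ρ-tip ρ; and a global 1/n! labelling
  constant (n = number of samples).

The 2^{#bifurcations} orientation factor is *not* a cosmetic constant: it
varies with the sampled-ancestor count and is required for the SA-count
distribution to match direct simulation. r = 0 is the fossilized
birth-death special case; r = 1 assigns −∞ to any tree containing a
sampled ancestor. Densities condition on the origin and, by default, on
observing at least one sample; an `at_least_two` option divides by
P(≥ 2 samples) (1 − p0(t0) minus a quadrature of the one-sample density)
so that inference can condition exactly as a simulator that rejects
single-sample replicates — the calibration study needs this match.

**Birth-death skyline.** Piecewise-constant (λ_i, μ_i, ψ_i) on
user-fixed height intervals with shared r and ρ; per-interval (A_i, B_i)
coefficients are glued continuously at the change heights and edges
crossing boundaries multiply per-interval q-ratios. The epidemiological
parameterization (Re = λ/δ, δ = μ + ψr, p = ψ/δ) is provided as an exact
algebraic bijection. A single interval collapses to the serial
birth-death form (checked to 1e-10), and the piecewise p and q functions
are checked against direct ODE integration.

Validation is a three-way consistency triangle, the same logic the
platform field uses for operator validation: direct Gillespie simulation,
MCMC prior sampling (flat likelihood), and — for two-tip trees — analytic
quadrature must agree. For serial-sampling priors, the direct simulator
is conditioned on a fixed total sample count by rejection while the MCMC
side treats tip times as free variables (the density is a density over
tip times too); root height and tree length are compared by KS,
sampled-ancestor counts by χ². The two-tip quadrature reproduces the
exact Yule outcome probability e^{−λt0}(1 − e^{−λt0}) and the simulated
outcome frequency for a μ > 0, ρ < 1 setting; for birth-death priors the
integral over the two-tip class equals the class's outcome probability,
not 1 (only the coalescent, which conditions on its tips, integrates to
exactly 1).

## MCMC

Metropolis-Hastings with α = min(1, exp(Δ log posterior + log adj)),
where the adjustment is the combined Hastings ratio and Jacobian. Scale
draws are log-uniform (adjustment d·log s for d scaled coordinates);
uniform node-height, tip-date and symmetric subtree-exchange moves have
adjustment 0; Wilson-Balding carries the candidate-count and
height-density ratio; the sampled-ancestor toggle converts a pendant leaf
into a degree-2 ancestor and back, with the uniform re-insertion height
density as the dimension-matching term. Scale operators auto-tune toward
0.234 acceptance during an initial tuning phase only (Robbins-Monro on
the log window), keeping the post-tuning kernel fixed. A single seeded
`numpy` Generator drives everything; equal seeds give bit-identical
traces. Default operator mix for posterior runs: tree moves 60%,
scalar moves 20%, reversible-jump moves 15%, sampled-ancestor toggles 5%.

Traces are tab-separated with a leading `Sample` column; tree logs are
NEXUS with a Translate block. Summaries: Geyer initial-positive-sequence
ESS (constant series defined as 0), smallest-interval HPDs, cumulative
credible model sets (lexicographic tie-break), clade supports, and the
maximum-clade-credibility tree (the sampled tree maximizing the product
of clade frequencies, ties to first occurrence) with mean and 95% HPD
node heights.

## Marginal likelihood

Nested sampling follows the classic recursion with E[log X_i] = −i/n_live
shrinkage; the worst live point is replaced by subchain MCMC from a
random survivor under the likelihood constraint (threshold inclusive, so
constant likelihoods terminate exactly). The subchain proposal scale
adapts multiplicatively to the contracting constrained region; without
this the sampler stalls once the likelihood shell is narrower than the
prior-scale proposal. Termination when max live L × X_i <
1e-6 × accumulated Z. Reported uncertainty is sqrt(H/n_live) with H the
information; the weighted dead points form the posterior sample.

Path sampling integrates E_β[log L] over a Beta(0.3, 1)-spaced β ladder
(dense near β = 0) by trapezoid; stepping stone multiplies per-rung
importance ratios on the same ladder, warm-starting each rung from the
previous. Both report Monte-Carlo standard errors from
autocorrelation-adjusted per-rung sample sizes (the trapezoid
discretization bias is checked separately to shrink as the ladder
refines). On the conjugate normal benchmark all three estimators agree
with the closed-form marginal within their reported uncertainties.

## Simulators and validation studies

The Gillespie birth-death simulator runs forward from the origin with
piecewise-constant rates, caps the population at 10^6 (hitting the cap
aborts the replicate rather than truncating), prunes unsampled lineages,
and emits ψ-sampled non-removed ancestors of later samples as degree-2
nodes. Conditioning on a minimum sample count is by rejection with the
retry count bounded. The coalescent simulator handles serial tips; the
two-species pair simulator draws the gene divergence as speciation time
plus an Exponential with mean 2Ne generations (diploid convention:
pairwise coalescence rate 1/(2Ne) per generation — the convention under
which the "2Ne excess" statement is exact; the single-population
coalescent elsewhere uses tree-time units with rate 1/Ne). Sequence
simulation draws root states from π, per-site gamma/invariant rate
classes, and evolves states with the model's transition matrices.

The well-calibrated study draws (λ, origin) from uniform priors
(λ ∈ [0.8, 1.5], origin ∈ [1.5, 2.5]; μ = 0.2, ψ = 0.4, r = 0, ρ = 0
fixed), simulates a tree conditioned on ≥ 2 samples and a 300-site JC
strict-clock alignment (rate 1.0), runs tree-and-parameter MCMC (20,000
steps, conditioning matched to the simulator), and records whether each
truth lies in its 95% HPD. Coverage over 100 replicates is compared to
the exact binomial 99% interval around 0.95. These problem sizes (tens of
tips, hundreds of sites, short well-mixing chains) were chosen so the
whole study is a desk-scale computation; they validate the joint
correctness of simulator, density, likelihood and operators, not the
performance of the sampler on large empirical datasets. A deliberately
mis-specified inference prior drives coverage to zero, confirming the
study can fail.

Posterior-predictive adequacy checks simulate trees from posterior
parameter draws and report the doubled-tail p-value with a +1 continuity
correction: p = min(1, 2·min((1+#{sim ≤ obs})/(n+1), (1+#{sim ≥ obs})/(n+1))),
so one simulation gives p = 1 and an observation outside the simulated
range gives 2/(n+1).

## What the synthetic data does not show

All validation data are generated by the package's own simulators under
the models being fitted. Passing tests therefore establish internal
consistency (density ↔ simulator ↔ sampler) and calibration under
correct specification; they say nothing about model adequacy for real
sequence data, alignment error, recombination, rate variation beyond the
implemented clocks, or mixing on trees with hundreds of taxa.

## Known limitations

Single-locus likelihoods only; no structured/multi-type models; skyline
change heights are fixed, not estimated; the relaxed clock is the
discretized-category form; nested sampling over tree space relies on the
operator kernel for constrained moves and inherits its mixing; the
Wilson-Balding above-root move without an origin uses a shifted
exponential whose mean is a fixed tuning constant.
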