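# skytree

Bayesian phylodynamic inference on rooted time trees, in plain scientific
Python. `skytree` samples the posterior

    P(T, θ | D) ∝ P(D | T, θ) · P(T | θ) · P(θ)

over time trees *T* — with node ages in calendar time and, where the
sampling process allows it, *sampled ancestors* (samples that are direct
ancestors of other samples, represented as degree-2 nodes) — and model
parameters *θ*, given a dated nucleotide alignment *D*. It is aimed at
people who study epidemics and macroevolution with birth-death-sampling
and coalescent tree priors and who want a small, fully testable engine
whose every density has a matching direct simulator.

What is in the box:

- **Tree priors**: constant-size serial coalescent; birth-death with
  serial sampling (λ, μ, ψ, removal probability r, present-day sampling
  ρ), including the fossilized-birth-death case r = 0 and sampled
  ancestors for r < 1; the **birth-death skyline** with
  piecewise-constant rates and the epidemiological parameterization
  R_e = λ/δ, δ = μ + ψr, p = ψ/δ.
- **Site models**: all 203 reversible nucleotide substitution models
  indexed by six-digit rate-grouping codes (`121121` = HKY,
  `111111` = JC69/F81), discrete-gamma rate heterogeneity, a proportion
  of invariable sites with a fast likelihood path, and
  **reversible-jump model averaging** across the code space with
  credible-set summaries.
- **MCMC** over trees and parameters: scale / node-height / tip-date /
  exchange / Wilson-Balding moves, a sampled-ancestor toggle,
  reversible-jump split-merge moves, bit-reproducible seeded runs,
  tab-separated trace logs (first column `Sample`, readable by the usual
  trace-inspection tools) and NEXUS tree logs, ESS / HPD / clade-support /
  MCC-tree summaries.
- **Marginal likelihoods**: nested sampling (with an uncertainty
  estimate sqrt(H/n_live)), path sampling and stepping stone.
- **Simulators** for every implemented model (Gillespie birth-death
  with sampled ancestors, serial coalescent, sequence evolution, the
  two-species coalescent pair), powering prior-sampling equivalence
  tests, well-calibrated coverage studies and posterior-predictive
  adequacy checks.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Simulate data under a known coalescent tree, then recover the tree
height and population size by MCMC:

```python
import math
import numpy as np
from skytree.alignment import compress_patterns
from skytree.likelihood import ClockModel, TreeLikelihood
from skytree.mcmc import (McmcState, OperatorSchedule, run_mcmc, compute_ess,
    hpd_interval, TreeScaleOperator, UniformNodeHeightOperator,
    ExchangeOperator, WilsonBaldingOperator, ScaleOperator)
from skytree.simulate import simulate_coalescent_tree, simulate_sequences
from skytree.substitution import SiteModel
from skytree.treeprior import CoalescentParams, coalescent_log_density

rng = np.random.default_rng(42)
true_tree = simulate_coalescent_tree(8, Ne=1.0, rng=rng)
site, clock = SiteModel(), ClockModel(mean_rate=0.5)   # JC, strict clock
aln = simulate_sequences(true_tree, site, clock, 500, rng)
lik = TreeLikelihood(compress_patterns(aln))

def target(state):                 # posterior: likelihood x coalescent x Exp(1) prior on Ne
    ne = state.params["Ne"]
    if ne <= 0:
        return -math.inf
    return (coalescent_log_density(state.tree, CoalescentParams(ne)) - ne
            + lik.log_likelihood(state.tree, site, clock))

ops = [TreeScaleOperator(2.0), UniformNodeHeightOperator(6.0),
       ExchangeOperator(2.0), WilsonBaldingOperator(2.0), ScaleOperator("Ne", 3.0)]
res = run_mcmc(McmcState(tree=true_tree, params={"Ne": 1.0}), target,
               OperatorSchedule(ops, tune_for=5000), chain_length=50000,
               log_every=25, seed=42)
tr = res.trace.burned(0.1)
for col in ("root_height", "Ne"):
    lo, hi = hpd_interval(tr[col], 0.95)
    print(f"{col}: posterior mean {tr[col].mean():.3f}  "
          f"95% HPD [{lo:.3f}, {hi:.3f}]  ESS {compute_ess(tr[col]):.0f}")
```

Output:

```
root_height: posterior mean 0.517  95% HPD [0.460, 0.588]  ESS 57
Ne: posterior mean 0.796  95% HPD [0.316, 1.387]  ESS 1205
```

The simulated truth (root height 0.498, Ne = 1.0) sits inside both HPD
intervals: the 500-site alignment pins the root height tightly, while
eight tips leave Ne loosely identified, as expected.

The same machinery is available from the shell: `skytree run` (posterior
MCMC from a YAML config), `skytree ns` / `skytree ps` (marginal
likelihoods), `skytree simulate`, `skytree validate` (well-calibrated
coverage study) and `skytree summarize` (trace ESS, MCC tree).

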