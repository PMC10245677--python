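# cmegf

Generating-function solvers for stochastic models of transcription observed
through single-cell RNA sequencing.

## The problem

Single-cell RNA-seq snapshots convolve several stochastic layers: bursty or
fluctuating transcription, RNA splicing and decay, asynchronous sampling of
cells from a transient process, and technical noise from droplet
encapsulation, ambient debris, cDNA library construction and read ambiguity.
`cmegf` evaluates exact count distributions for this whole stack so that
mechanistic models can be fitted to (nascent, mature) UMI count matrices and
compared by likelihood, and so that the limits of such inference can be
mapped by simulation.

## The method

Models are Markov systems with `N` gene states, `n` discrete molecular
species and `m` continuous variables (e.g. an SDE transcription rate). The
chemical master equation for the joint generating function
`G(g, h, t)` (PGF in the discrete arguments `g`, MGF in the continuous
arguments `h`, `u = g - 1`) is a first-order PDE solved by characteristics:

    dU/ds = C U + diag(U) D U              (downstream: conversion, decay,
                                            catalysis, square-root noise)
    dG/ds = -H^T G - G o A(U(s), t - s)    (upstream: state switching and
                                            burst/drift production)

`C`, `D`, `H` and `A` are assembled mechanically from a reaction list.
With `D = 0` the characteristics are matrix exponentials in closed form; a
single gene state reduces the upstream ODE to one quadrature
`log G = log G0(U(t)) + ∫ A(U(s)) ds`. PMFs are recovered by evaluating `G`
at FFT roots of unity and inverting. Technical noise enters as composition:
Bernoulli/binomial/Poisson encapsulation `Gbc(G)`, Poisson pseudobulk
background `exp(c Σ μ_i u_i)`, library construction `u_i -> p_i u_i`
(sequestering) or `u_i -> exp(λ_i u_i) - 1` (non-sequestering), and a
row-stochastic ambiguity map `u -> P_a u`. Transient snapshot sampling
marginalizes `G(t)` over a reactor internal-age distribution (uniform,
exponential, or Pareto-derived).

Built-in families: constitutive, monomolecular cascades, telegraph,
gamma Ornstein-Uhlenbeck (Γ-OU), Cox-Ingersoll-Ross (CIR), bursty (with
time-dependent burst size), autocatalytic, and two-gene coupling (mixtures,
state-coupled, co-bursting). Inference tools: exact likelihoods, bounded
L-BFGS-B fitting of the transient bursty model under competing reactor
architectures, Akaike-weight model selection, `(x, y)` qualitative-parameter
landscapes, and a posterior for the nascent/mature capture-rate ratio.

## Worked example

Telegraph versus Γ-OU versus CIR at matched averages, discriminated from 200
simulated cells by Akaike weights:

```python
import numpy as np
from cmegf import models as M, inference as I, simulate as S

truth = M.SDEDriverParams("gou", kappa=0.1, a=0.4, theta=1.0, beta=0.8, gamma=0.9)
coords = M.process_to_qualitative(truth, species_mode="two")
print(f"x = {coords.x:.4f}, y = {coords.y:.4f}")   # x = 0.0556, y = 0.7143

pmf = M.stationary_pmf(truth, shape=(50, 51))       # joint (nascent, mature) law
data = S.sample_from_pmf(pmf, 200, seed=1)

logLs = []
for fam in ("gou", "cir", "telegraph"):
    params = M.qualitative_to_process(coords, fam)
    node = M.stationary_pmf(params, shape=(50, 51))
    logLs.append(I.log_likelihood(data, node))
w = I.akaike_weights(logLs, 0).weights
print(np.round(w, 3))                               # [0.353 0.647 0.   ]
```

`x = 0.0556` says the transcription-rate process is ~18x slower than RNA
turnover (a "mixture-like" regime); `y = 0.71` is a high noise intensity.
The weights show the two SDE drivers are nearly indistinguishable from 200
cells in this regime (0.35 vs 0.65 - both gamma-distributed rate models fit),
while the telegraph model is confidently rejected; which SDE driver wins
fluctuates from seed to seed.

A transient experiment end to end from the command line (simulate a
plug-flow-reactor snapshot, fit all three reactor architectures, select):

```
cmegf transient --config examples/transient.yaml --seed 1 --out out/
# Akaike weights: dirac_pfr=0.655, exponential_cstr=0.211, pareto_lfr=0.135
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch through the package's own parameter maps and GF
inversion: the autocorrelation rate implied by the burst-like qualitative
coordinate, the two-species embeddings of two illustrative one-species
coordinates, and the negative-binomial shape of the bursty stationary
nascent marginal (verified pointwise against the inverted GF), writing one
JSON object keyed by target id.
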