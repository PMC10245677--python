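# Methods

## Model class and solution strategy

`cmegf` solves chemical master equations for systems with `N` categorical
gene states, `n` nonnegative discrete species (molecule counts) and `m`
nonnegative continuous variables (transcription rates, high-copy species).
Allowed reactions are zero- and first-order only: state switching,
constitutive and bursty production (geometric bursts, possibly co-released
across species), conversion, degradation, catalysis (`X -> 2X` or
`X_i -> X_i + X_j`), continuous drift, mean reversion, square-root (CIR)
noise, compound-Poisson jumps, and cross couplings between the discrete and
continuous blocks. Bimolecular and feedback reactions make the generating
function PDE higher than first order and are rejected at assembly with an
explicit error.

The joint generating function is a PGF in the discrete arguments and an MGF
in the continuous ones. Its PDE is reduced by the method of characteristics
to a downstream ODE `dU/ds = C U + diag(U) D U` (started at the spectral
point `u`) and an upstream ODE for the `N`-vector of per-state GF values,
driven by `H(t)` and the burst/drift operator `A(u, t)`. Only the burst
parameters (`alpha`, burst-size law) may be time-dependent; time-dependent
`H` is supported structurally but untested. The `C`/`D` block layout places
conversion/degradation/mean-reversion in `C` and the catalytic plus
`sigma^2/2` square-root-noise terms in `D`; for the CIR driver this makes
the `D` entry `kappa * theta`, a convention pinned by the test that the
stationary driver variance equals `a theta^2 / kappa`.

Numerical choices:

* **Characteristics.** When `D = 0` the linear system is solved through the
  eigendecomposition of `C`; a defective `C` (e.g. `beta = gamma` in a
  splicing cascade) falls back to per-node matrix exponentials with a logged
  notice. Otherwise the Riccati-type system is integrated with adaptive
  RK45 at `rtol 1e-8`, `atol 1e-10`.
* **Upstream quadrature.** For `N = 1` the log-GF integral is evaluated by
  Gauss-Legendre panels (default 16 points per panel) on a geometrically
  graded partition of `[0, t]` whose boundaries are log-spaced from
  `t * 1e-7`: the integrand is a smooth combination of decaying
  exponentials, so panelled Gauss-Legendre converges spectrally even when
  rates span two decades. A plain 1024-node trapezoid was measured at
  ~4e-4 absolute error on the stationary negative-binomial benchmark and was
  replaced for that reason. For `N > 1` the upstream matrix ODE is
  integrated with adaptive RK45.
* **Stationary evaluation** integrates to `t = 40 / min |nonzero rate|`.
  The tail of the log-GF integral decays like `exp(-r t)`; 40 time constants
  put the truncation error near 4e-18, needed for the 1e-8-level pointwise
  agreement the stationary benchmarks require (10 time constants leave a
  visible 5e-5 error).
* **Inversion.** The GF is evaluated at `g_k = exp(+2 pi i k / S)` per axis
  and inverted by `P = FFT(G) / S`. Truncation manifests as aliasing (tail
  mass wraps around), so grids are sized at `ceil(mu + 4 sigma) + 4` from
  model moments (slow-driver variance bounds for the SDE/telegraph
  families), or observed max + 4 for data-driven fits. Negative values
  above `-1e-10` are clipped; larger negatives and normalization defects
  beyond 1e-4 raise warnings recommending a larger grid.

## Technical noise

Noise stages compose in spectral coordinates, innermost closest to the
observed counts: ambiguity (`u -> P_a u`, row-stochastic), library
construction (`u_i -> p_i u_i` sequestering, `u_i -> exp(lambda_i u_i) - 1`
non-sequestering), then encapsulation and additive Poisson background
`exp(c sum_i mu_i u_i)` multiplying the cell GF. Doublets default to the
0-or-1-cell Bernoulli scheme (binomial and Poisson schemes are provided);
background means default to the model's stationary means (pseudobulk), with
an override for measured means. Per-droplet capture-rate variability is a
known, unmodeled residual source of overdispersion.

## Transient snapshots ("reactor" sampling)

A cell entering the observation medium starts a transcriptional program;
sequencing samples cells currently inside. The internal-age density is
`f(t) = P(residence > t) / T` for three one-parameter architectures: plug
flow (Dirac residence, uniform age), stirred tank (exponential), laminar
flow (Pareto with minimum `T/2`; uniform then `T / (4 t^2)`). The transient
transcription model is bursty production with a three-stage piecewise-
constant burst mean `b(t)` (changes at `tau1 < tau2`), splicing `beta`,
degradation `gamma`, started from a bivariate Poisson at the stage-1
stationary means so the mean is flat over the first stage. Its log-GF is
the monomolecular characteristic pair plus
`alpha * int_0^t [1 / (1 - b(t-s) UN(u, s)) - 1] ds`; the `-1` inside the
integrand (the full shifted burst PGF) is required for `G(0) = 1`.

Likelihoods over a batch of cells reuse quadrature nodes: all cell times
(plus `t0 = 0`, plus inserted midpoints when fewer than 100 cells are
supplied) form one shared grid on which the integrand is evaluated once per
burst stage. Each cell's integral is then assembled from at most three
stage segments using per-stage cumulative trapezoids with exact endpoint
corrections at `t_i - tau_k` (the characteristics are closed-form, so the
integrand can be evaluated exactly at the stage boundaries). A plain
shared-node trapezoid of the full integrand matrix makes an O(h) error at
the burst-size discontinuities, measured at 3e-3 in per-cell log-likelihood
terms - above the 1e-3 agreement demanded of the recycled-vs-independent
quadrature check - which motivated the segmented form. The classical
matrices (lower-triangular `b(t_i - t_j)`, diagonal `UN(u, t_j)`, and their
elementwise transform) remain available via `build_quadrature_cache`.

Reactor fitting maximizes this likelihood over `log10` of the six
parameters (three burst means, `alpha`, `beta`, `gamma`) with L-BFGS-B,
bounds `(-1.5, 1.5)` per log-parameter, finite-difference step `1e-4`, at
most 20 iterations, initialized at the generating parameters (the question
asked is model discrimination at the MLE, not optimizer robustness). Cell
times and stage-change times are first mapped into the candidate reactor's
clock by the quantile transform `F_k^{-1}(F_true(t))`. Model selection uses
Akaike weights with 6 parameters per model; AIC ties break by model order
(irrelevant to the weights themselves).

## Simulation and the synthetic world

All stochastic components draw from one root seed through fixed
`SeedSequence` spawn paths, so datasets are bit-reproducible. The SSA for
the transient bursty model is exact despite time-dependent `b(t)`: only the
burst-size law varies, never an event rate, so inter-event times stay
exponential and the geometric size (support `{0, 1, ...}`, mean `b`,
matching the GF factor `1/(1 - b u)`) is drawn at the event time.

The random-parameter reactor experiment draws `log10` burst means from
Normal(0.8, 1) and the other log-rates from Normal(0, 1), clips to
`[-1.4, 1.4]`, and accepts a draw when, at the largest burst mean, both
species satisfy `mu + 4 sigma < 25` under the stationary bursty moments
(`var_N = mu_N (1 + b)`, `var_M = mu_M (1 + b beta / (beta + gamma))`) -
keeping PMF grids near 25 x 25.

Synthetic droplet datasets draw cell counts per gene from the stationary
bursty joint PMF (the shared burst driver produces the intra-gene
nascent-mature correlation real cells show) and empty-droplet counts from
independent Poissons with pseudobulk means `c * mu_i * p_i`. An optional
contamination channel adds compound-Poisson counts (geometric packets,
default mean 20 at rate 0.05/droplet) to chosen genes in empty droplets,
emulating co-released aggregates such as whole mitochondria. These fixtures
emulate the distributional signatures the droplet-QC module screens for;
they do not emulate read-depth variation across droplets, barcode
collisions, doublets, or gene-length effects, so a green QC test
establishes the statistics behave as designed on the stated world, not that
real data satisfy the pseudobulk model.

## Inference conventions

Probabilities are floored at 1e-12 before logs (finite grids truncate
tails). Landscape analyses use a uniform `(x, y)` grid on `[0.01, 0.99]`
(14 x 15 by default) at fixed averages, with
`x = kappa / (kappa + beta + gamma)` (or `kappa / (kappa + beta)` for
one-species data) and `y = theta / (a + theta)`; the telegraph family joins
through the identification `kappa = kon + koff`, `a = kon kappa / koff`,
`theta = koff kinit / kappa`, whose inverse takes the positive root of
`(kon/koff)^2 = muK (1/y - 1) / kappa`. Bernoulli dropout with probability
`p` is equivalent to `theta -> p theta` (SDE drivers), `kinit -> p kinit`
(telegraph) or `b -> p b` (bursty), which is how dropout experiments are
realized without re-simulation. The capture-ratio posterior evaluates the
bursty likelihood on 200 evenly spaced points of
`log10(pM/pN) in [-2, 2]` under a flat prior, holding `alpha`, `b pN` and
both species means fixed and setting the larger of `(pN, pM)` to one.

## Known limitations

* Feedback and bimolecular kinetics are out of scope by construction.
* The co-regulation builder covers the symmetric two-gene four-state motif
  and its co-bursting/mixture limits only.
* Transient fitting assumes known cell times up to the reactor clock; no EM
  over latent times is provided.
* CIR evaluation integrates a Riccati system per spectral point and is an
  order of magnitude slower than the closed-form families; landscape scans
  over the CIR family at full grid resolution are correspondingly costly.
* The stationary horizon heuristic assumes the slowest nonzero rate governs
  relaxation; pathological rate separations beyond ~3 decades would need a
  manual horizon.
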