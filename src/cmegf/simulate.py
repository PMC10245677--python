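"""Stochastic simulation: SSA, PMF samplers and synthetic droplet datasets.

All randomness flows from a single integer seed; per-component generators are
spawned deterministically via ``numpy.random.SeedSequence``.

The SSA for the transient bursty model is exact despite the time-dependent
burst size: only the burst-size law (not any event rate) varies in time, so
inter-event times remain exponential with constant total propensity between
events and the geometric size is simply drawn at the event time.

Geometric burst convention: support {0, 1, 2, ...} with mean ``b``
(success probability 1/(1+b)), matching the GF factor 1/(1 - b u).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import BurstyParams, bursty_moments, stationary_pmf
from .noise import PerSpeciesNoise
from .reactors import ReactorSpec, TransientModelParams

__all__ = [
    "SimulationConfig",
    "CountDataset",
    "DropletDataset",
    "child_rng",
    "ssa_transient",
    "sample_from_pmf",
    "sample_reactor_times",
    "rejection_sample_params",
    "simulate_droplet_dataset",
    "apply_count_noise",
]


def child_rng(seed: int, *path: int) -> np.random.Generator:
    """Deterministic child generator: one root seed, fixed spawn path."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(path)))


@dataclass
class SimulationConfig:
    """Plumbing for a reproducible simulation run."""

    seed: int
    n_cells: int
    reactor: ReactorSpec | None = None
    params: object | None = None
    noise: PerSpeciesNoise | None = None


@dataclass
class CountDataset:
    """Per-cell nascent/mature counts, optionally with per-cell process times."""

    nascent: np.ndarray
    mature: np.ndarray
    times: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.nascent)

    def counts(self) -> np.ndarray:
        return np.stack([self.nascent, self.mature], axis=1)


@dataclass
class DropletDataset:
    """Droplets x genes x {nascent, mature} counts with empty/cell labels."""

    nascent: np.ndarray  # (droplets, genes)
    mature: np.ndarray
    is_cell: np.ndarray  # bool per droplet
    gene_names: list[str] = field(default_factory=list)
    barcodes: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# SSA
# ---------------------------------------------------------------------------

def _geometric0(rng: np.random.Generator, b: float, size=None):
    """Geometric on {0, 1, ...} with mean b."""
    return rng.geometric(1.0 / (1.0 + b), size=size) - 1


def ssa_transient(
    params: TransientModelParams,
    observe_at: Sequence[float],
    seed: int | np.random.Generator,
) -> CountDataset:
    """Exact SSA of the transient bursty model, one trajectory per time point.

    Reactions: geometric burst arrivals at rate alpha with mean size b(t),
    splicing at beta * xN, degradation at gamma * xM.  Each requested
    observation time gets an independent trajectory started from the
    bivariate Poisson initial condition.
    """
    observe_at = np.asarray(observe_at, dtype=float)
    if np.any(np.diff(observe_at) < 0):
        raise ValueError("observation times must be sorted")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha, beta, gamma = params.alpha, params.beta, params.gamma
    prof = params.profile
    xN_out = np.empty(len(observe_at), dtype=np.int64)
    xM_out = np.empty(len(observe_at), dtype=np.int64)
    for c, t_obs in enumerate(observe_at):
        xN = rng.poisson(params.lamN0)
        xM = rng.poisson(params.lamM0)
        t = 0.0
        while True:
            total = alpha + beta * xN + gamma * xM
            t_next = t + rng.exponential(1.0 / total)
            if t_next >= t_obs:
                break
            t = t_next
            r = rng.uniform() * total
            if r < alpha:
                xN += _geometric0(rng, float(prof(t)))
            elif r < alpha + beta * xN:
                xN -= 1
                xM += 1
            else:
                xM -= 1
        xN_out[c], xM_out[c] = xN, xM
    return CountDataset(nascent=xN_out, mature=xM_out, times=observe_at.copy())


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def sample_from_pmf(pmf, n: int, seed: int | np.random.Generator,
                    tol: float = 1e-2) -> CountDataset:
    """I.i.d. categorical draws over the flattened truncated state space."""
    values = np.asarray(pmf.values if hasattr(pmf, "values") else pmf, dtype=float)
    total = values.sum()
    if abs(total - 1.0) > tol:
        raise ValueError(f"PMF mass {total:.4f} deviates from 1 beyond tolerance {tol}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = values.reshape(-1) / total
    draws = rng.choice(flat.size, size=n, p=flat)
    idx = np.unravel_index(draws, values.shape)
    if values.ndim == 1:
        return CountDataset(nascent=idx[0], mature=np.zeros(n, dtype=np.int64))
    return CountDataset(nascent=idx[0], mature=idx[1])


def sample_reactor_times(spec: ReactorSpec, n: int,
                         seed: int | np.random.Generator) -> np.ndarray:
    """Inverse-transform draws of internal ages, sorted ascending."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = spec.ppf(rng.uniform(0.0, 1.0 - 1e-12, size=n))
    return np.sort(times)


def rejection_sample_params(
    seed: int | np.random.Generator,
    tau: tuple[float, float] = (1.0, 3.0),
    bound: float = 25.0,
    log_clip: float = 1.4,
    max_tries: int = 10000,
) -> TransientModelParams:
    """Rejection-sample transient parameters restricted to a small state space.

    log10 of the burst means is drawn from Normal(0.8, 1) and the remaining
    log-rates from Normal(0, 1), clipped to [-log_clip, log_clip].  A draw is
    accepted iff, at the largest burst mean, mu + 4 sigma < ``bound`` for both
    species under the stationary bursty-model moments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_tries):
        log_b = rng.normal(0.8, 1.0, size=3)
        log_r = rng.normal(0.0, 1.0, size=3)
        theta = np.clip(np.concatenate([log_b, log_r]), -log_clip, log_clip)
        b_max = 10.0 ** theta[:3].max()
        alpha, beta, gamma = 10.0 ** theta[3:]
        (muN, muM), (sdN, sdM) = bursty_moments(alpha, b_max, beta, gamma)
        if muN + 4.0 * sdN < bound and muM + 4.0 * sdM < bound:
            b1, b2, b3 = 10.0 ** theta[:3]
            from .reactors import StepBurstProfile

            return TransientModelParams(
                StepBurstProfile(b1, b2, b3, tau[0], tau[1]), alpha, beta, gamma
            )
    raise RuntimeError(f"rejection sampling failed after {max_tries} proposals")


# ---------------------------------------------------------------------------
# Droplet datasets
# ---------------------------------------------------------------------------

def simulate_droplet_dataset(
    gene_params: Sequence[BurstyParams],
    n_cells: int,
    n_empty: int,
    c: float,
    seed: int,
    capture: tuple[float, float] = (1.0, 1.0),
    contaminated_genes: Sequence[int] = (),
    aggregate_rate: float = 0.05,
    aggregate_size: float = 20.0,
) -> DropletDataset:
    """Synthetic droplet dataset: overdispersed cells + Poisson empty droplets.

    Cell-containing droplets draw per-gene (nascent, mature) pairs from the
    stationary bursty joint PMF (the shared burst driver induces the
    intra-gene nascent-mature correlation seen in real cells), thinned by the
    capture probabilities.  Empty droplets are independent Poisson with mean
    ``c * mu_i * p_i`` (pseudobulk).  Genes listed in ``contaminated_genes``
    additionally receive compound-Poisson "aggregate" counts in empty
    droplets, emulating co-released debris such as whole mitochondria.
    """
    rng = child_rng(seed, 0)
    G = len(gene_params)
    pN, pM = capture
    nasc = np.zeros((n_cells + n_empty, G), dtype=np.int64)
    mat = np.zeros_like(nasc)
    is_cell = np.zeros(n_cells + n_empty, dtype=bool)
    is_cell[:n_cells] = True
    muN_all, muM_all = np.empty(G), np.empty(G)
    for j, par in enumerate(gene_params):
        (muN, muM), _ = bursty_moments(par.alpha, par.b, par.beta, par.gamma)
        muN_all[j], muM_all[j] = muN * pN, muM * pM
        pmf = stationary_pmf(par, pN=pN, pM=pM)
        cells = sample_from_pmf(pmf, n_cells, rng)
        nasc[:n_cells, j] = cells.nascent
        mat[:n_cells, j] = cells.mature
    nasc[n_cells:] = rng.poisson(c * muN_all[None, :], size=(n_empty, G))
    mat[n_cells:] = rng.poisson(c * muM_all[None, :], size=(n_empty, G))
    for j in contaminated_genes:
        events = rng.poisson(aggregate_rate, size=n_empty)
        extra = np.array([
            _geometric0(rng, aggregate_size, size=k).sum() if k else 0 for k in events
        ])
        mat[n_cells:, j] += extra
    genes = [f"gene{j}" for j in range(G)]
    barcodes = [f"bc{i:06d}" for i in range(n_cells + n_empty)]
    meta = {
        "seed": seed, "c": c, "capture": capture,
        "contaminated_genes": list(contaminated_genes),
        "mu_nascent": muN_all.tolist(), "mu_mature": muM_all.tolist(),
    }
    return DropletDataset(nascent=nasc, mature=mat, is_cell=is_cell,
                          gene_names=genes, barcodes=barcodes, metadata=meta)


def apply_count_noise(dataset: CountDataset, noise: PerSpeciesNoise,
                      seed: int | np.random.Generator) -> CountDataset:
    """Realize library-construction noise at the sample level.

    Sequestering -> per-molecule Bernoulli thinning (binomial); non-
    sequestering -> per-molecule Poisson replication (Poisson with rate
    lambda * count).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = [dataset.nascent, dataset.mature]
    out = []
    for i, arr in enumerate(arrays):
        if i >= len(noise.modes):
            out.append(arr.copy())
            continue
        mode, val = noise.modes[i], noise.params[i]
        if mode == "sequestering":
            out.append(rng.binomial(arr, val))
        else:
            out.append(rng.poisson(val * arr))
    return CountDataset(nascent=out[0], mature=out[1],
                        times=None if dataset.times is None else dataset.times.copy())
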