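"""Likelihood evaluation, model fitting and Akaike-weight model selection.

Model discrimination uses Akaike weights
``w_k = exp(-Delta_k / 2) / sum_j exp(-Delta_j / 2)`` with
``Delta_k = AIC_k - AIC_min`` and ``AIC_k = -2 logL_k + 2 varsigma_k``;
a weight near 1/3 (three candidates) carries no information, a weight above
1/2 gives even odds for the selected model.

Transient reactor fitting maximizes the batch transient-bursty likelihood
over log10 of the six parameters with L-BFGS-B, bounds (-1.5, 1.5) per
log-parameter and an iteration cap of 20; cell times are first mapped into
each candidate reactor's clock by the quantile transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .models import (
    QualitativeCoords,
    qualitative_to_process,
    stationary_pmf,
)
from .reactors import (
    ReactorSpec,
    TransientModelParams,
    batch_transient_log_gf,
    transform_times,
)
from .gf_core import spectral_grid
from .simulate import CountDataset, sample_from_pmf

__all__ = [
    "PROB_FLOOR",
    "FitResult",
    "AkaikeResult",
    "LandscapeGrid",
    "RatioPosterior",
    "log_likelihood",
    "transient_log_likelihood",
    "fit_transient_mle",
    "akaike_weights",
    "landscape_axes",
    "likelihood_landscape",
    "model_weight_landscape",
    "ratio_posterior",
]

PROB_FLOOR = 1e-12  # finite grids truncate tails; floor probabilities before log


# ---------------------------------------------------------------------------
# Likelihood primitives
# ---------------------------------------------------------------------------

def log_likelihood(dataset: CountDataset, pmf) -> float:
    """Sum of log-probabilities of the observed counts under one PMF grid.

    ``pmf`` may be a PMFGrid or array; 1-D grids score the nascent counts
    only.  Counts outside the grid raise (enlarge the grid upstream).
    """
    values = np.asarray(pmf.values if hasattr(pmf, "values") else pmf, dtype=float)
    if values.ndim == 1:
        if dataset.nascent.max(initial=0) >= values.shape[0]:
            raise ValueError("observed count outside the PMF grid")
        probs = values[dataset.nascent]
    else:
        if (dataset.nascent.max(initial=0) >= values.shape[0]
                or dataset.mature.max(initial=0) >= values.shape[1]):
            raise ValueError("observed count outside the PMF grid")
        probs = values[dataset.nascent, dataset.mature]
    return float(np.log(np.maximum(probs, PROB_FLOOR)).sum())


def transient_log_likelihood(
    dataset: CountDataset,
    params: TransientModelParams,
    shape: tuple[int, int],
    times: np.ndarray | None = None,
    min_nodes: int = 100,
) -> float:
    """Log-likelihood of time-labelled counts under the transient bursty model.

    One shared-quadrature batch GF evaluation covers all cells; each cell is
    scored against the PMF at its own (possibly transformed) time.
    """
    t = np.asarray(dataset.times if times is None else times, dtype=float)
    order = np.argsort(t, kind="stable")
    grid = spectral_grid(shape)
    phi = batch_transient_log_gf(grid.points, t[order], params, min_nodes=min_nodes)
    size = grid.size
    xN = dataset.nascent[order]
    xM = dataset.mature[order]
    if xN.max(initial=0) >= shape[0] or xM.max(initial=0) >= shape[1]:
        raise ValueError("observed count outside the PMF grid")
    total = 0.0
    for row, n_c, m_c in zip(phi, xN, xM):
        G = np.exp(row).reshape(shape)
        pmf = (np.fft.fftn(G) / size).real
        total += math.log(max(pmf[n_c, m_c], PROB_FLOOR))
    return total


# ---------------------------------------------------------------------------
# Transient MLE
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: TransientModelParams
    log10_theta: np.ndarray
    logL: float
    n_params: int
    converged: bool
    n_iter: int
    reactor: ReactorSpec | None = None


def fit_transient_mle(
    dataset: CountDataset,
    reactor: ReactorSpec,
    true_reactor: ReactorSpec,
    theta0: Sequence[float],
    tau: tuple[float, float],
    bounds: tuple[float, float] = (-1.5, 1.5),
    maxiter: int = 20,
    shape: tuple[int, int] | None = None,
    min_nodes: int = 100,
) -> FitResult:
    """Bounded quasi-Newton MLE of the transient model under one reactor clock.

    Cell times recorded under ``true_reactor`` are quantile-transformed into
    ``reactor``'s clock (as are the stage-change times ``tau``), then the
    negative log-likelihood is minimized over log10 Theta with L-BFGS-B,
    finite-difference gradients (step 1e-4) and at most ``maxiter`` steps,
    initialized at ``theta0``.
    """
    if dataset.times is None:
        raise ValueError("dataset must carry per-cell times")
    times_k = transform_times(dataset.times, true_reactor, reactor)
    tau_k = tuple(transform_times(np.asarray(tau, dtype=float), true_reactor, reactor))
    if shape is None:
        shape = (int(dataset.nascent.max()) + 5, int(dataset.mature.max()) + 5)
    theta0 = np.asarray(theta0, dtype=float)
    x0 = np.clip(np.log10(theta0), bounds[0] + 1e-9, bounds[1] - 1e-9)

    def objective(x: np.ndarray) -> float:
        params = TransientModelParams.from_theta(10.0**x, *tau_k)
        return -transient_log_likelihood(dataset, params, shape,
                                         times=times_k, min_nodes=min_nodes)

    f0 = objective(x0)
    if not np.isfinite(f0):
        raise RuntimeError(f"objective not finite at the initial point: {f0}")
    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[bounds] * 6,
        options={"maxiter": maxiter, "eps": 1e-4},
    )
    x_best, f_best = (res.x, res.fun) if res.fun <= f0 else (x0, f0)
    return FitResult(
        params=TransientModelParams.from_theta(10.0**x_best, *tau_k),
        log10_theta=np.asarray(x_best),
        logL=-float(f_best),
        n_params=6,
        converged=bool(res.success),
        n_iter=int(res.nit),
        reactor=reactor,
    )


# ---------------------------------------------------------------------------
# Akaike weights
# ---------------------------------------------------------------------------

@dataclass
class AkaikeResult:
    logL: np.ndarray
    n_params: np.ndarray
    aic: np.ndarray
    delta: np.ndarray
    weights: np.ndarray

    @property
    def best(self) -> int:
        return int(np.argmin(self.aic))


def akaike_weights(logL: Sequence[float], n_params: Sequence[int] | int) -> AkaikeResult:
    """Akaike weights from per-model maximized log-likelihoods."""
    logL = np.asarray([f.logL if isinstance(f, FitResult) else f for f in logL], dtype=float)
    if logL.size < 2:
        raise ValueError("need at least two models")
    if np.isscalar(n_params):
        n_params = np.full(logL.size, int(n_params))
    n_params = np.asarray(n_params, dtype=int)
    aic = -2.0 * logL + 2.0 * n_params
    delta = aic - aic.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    return AkaikeResult(logL=logL, n_params=n_params, aic=aic, delta=delta, weights=w)


# ---------------------------------------------------------------------------
# (x, y) landscapes
# ---------------------------------------------------------------------------

@dataclass
class LandscapeGrid:
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray  # (len(x), len(y))
    replicates: int = 1

    def top_decile_mask(self) -> np.ndarray:
        """Nodes in the 90th percentile of the statistic (least distinguishable)."""
        thr = np.quantile(self.values, 0.9)
        return self.values >= thr


def landscape_axes(nx: int = 14, ny: int = 15,
                   lo: float = 0.01, hi: float = 0.99) -> tuple[np.ndarray, np.ndarray]:
    """Uniform (x, y) grid bounded by [0.01, 0.99]; 14 x 15 = 210 nodes."""
    return np.linspace(lo, hi, nx), np.linspace(lo, hi, ny)


def _node_pmf(family: str, x: float, y: float, muK: float, beta: float,
              gamma: float, shape: tuple[int, int], nodes: int = 256):
    coords = QualitativeCoords(x=x, y=y, muK=muK, beta=beta, gamma=gamma,
                               species_mode="two")
    params = qualitative_to_process(coords, family)
    return stationary_pmf(params, shape=shape, nodes=nodes)


def likelihood_landscape(
    dataset: CountDataset,
    family: Literal["gou", "cir", "telegraph"],
    muK: float,
    beta: float,
    gamma: float,
    mode: Literal["nascent", "bivariate"] = "bivariate",
    x_grid: np.ndarray | None = None,
    y_grid: np.ndarray | None = None,
    shape: tuple[int, int] = (50, 51),
    nodes: int = 256,
) -> LandscapeGrid:
    """Data log-likelihood over the (x, y) grid at fixed averages.

    ``mode='nascent'`` scores the nascent marginal only; ``'bivariate'``
    scores the joint counts and breaks the marginal degeneracy between
    mixture-like and burst-like regimes.
    """
    if x_grid is None or y_grid is None:
        xg, yg = landscape_axes()
        x_grid = xg if x_grid is None else x_grid
        y_grid = yg if y_grid is None else y_grid
    out = np.zeros((len(x_grid), len(y_grid)))
    for i, x in enumerate(x_grid):
        for j, y in enumerate(y_grid):
            pmf = _node_pmf(family, x, y, muK, beta, gamma, shape, nodes)
            if len(dataset) == 0:
                out[i, j] = 0.0
                continue
            if mode == "nascent":
                out[i, j] = log_likelihood(dataset, pmf.values.sum(axis=1))
            else:
                out[i, j] = log_likelihood(dataset, pmf)
    return LandscapeGrid(x=np.asarray(x_grid), y=np.asarray(y_grid), values=out)


def model_weight_landscape(
    truth_family: Literal["gou", "cir", "telegraph"],
    muK: float,
    beta: float,
    gamma: float,
    n_cells: int,
    reps: int,
    seed: int,
    mode: Literal["nascent", "bivariate"] = "bivariate",
    x_grid: np.ndarray | None = None,
    y_grid: np.ndarray | None = None,
    families: Sequence[str] = ("gou", "cir", "telegraph"),
    shape: tuple[int, int] = (50, 51),
    nodes: int = 256,
) -> LandscapeGrid:
    """Mean Akaike weight of the true model over the (x, y) grid.

    At each node all candidate likelihoods are evaluated at the *same*
    known parameters (no fitting), datasets are simulated from the truth, and
    the truth's Akaike weight is averaged over replicates.
    """
    if x_grid is None or y_grid is None:
        xg, yg = landscape_axes()
        x_grid = xg if x_grid is None else x_grid
        y_grid = yg if y_grid is None else y_grid
    rng = np.random.default_rng(seed)
    out = np.zeros((len(x_grid), len(y_grid)))
    truth_idx = list(families).index(truth_family)
    for i, x in enumerate(x_grid):
        for j, y in enumerate(y_grid):
            pmfs = [_node_pmf(fam, x, y, muK, beta, gamma, shape, nodes)
                    for fam in families]
            if mode == "nascent":
                grids = [p.values.sum(axis=1) for p in pmfs]
            else:
                grids = [p.values for p in pmfs]
            w_acc = 0.0
            for _ in range(reps):
                data = sample_from_pmf(pmfs[truth_idx], n_cells, rng)
                logLs = [log_likelihood(data, g) for g in grids]
                w_acc += akaike_weights(logLs, 0).weights[truth_idx]
            out[i, j] = w_acc / reps
    return LandscapeGrid(x=np.asarray(x_grid), y=np.asarray(y_grid),
                         values=out, replicates=reps)


# ---------------------------------------------------------------------------
# Capture-ratio posterior
# ---------------------------------------------------------------------------

@dataclass
class RatioPosterior:
    log10_ratio: np.ndarray
    posterior: np.ndarray

    def mean(self) -> float:
        return float((self.log10_ratio * self.posterior).sum())

    def sd(self) -> float:
        mu = self.mean()
        return float(np.sqrt(((self.log10_ratio - mu) ** 2 * self.posterior).sum()))


def ratio_posterior(
    dataset: CountDataset,
    alpha: float,
    b_pN: float,
    muN: float,
    muM: float,
    grid_points: int = 200,
    log10_range: tuple[float, float] = (-2.0, 2.0),
    buffer: int = 3,
    nodes: int = 256,
) -> RatioPosterior:
    """Flat-prior posterior over log10(pM / pN) for the bursty model.

    ``alpha``, the nascent-scale product ``b * pN``, and both species means
    are held fixed (beta = alpha b pN / muN); for each candidate ratio the
    larger of (pN, pM) is set to one, the other parameters follow, and the
    joint-likelihood vector over the grid is normalized to sum to one.
    """
    from .models import BurstyParams

    log_r = np.linspace(log10_range[0], log10_range[1], grid_points)
    beta = alpha * b_pN / muN
    shape = (int(dataset.nascent.max()) + buffer + 1,
             int(dataset.mature.max()) + buffer + 1)
    logL = np.empty(grid_points)
    for k, lr in enumerate(log_r):
        ratio = 10.0**lr
        if ratio >= 1.0:
            pM, pN = 1.0, 1.0 / ratio
        else:
            pN, pM = 1.0, ratio
        b = b_pN / pN
        gamma = alpha * b * pM / muM
        params = BurstyParams(alpha=alpha, b=b, beta=beta, gamma=gamma)
        pmf = stationary_pmf(params, shape=shape, pN=pN, pM=pM, nodes=nodes)
        logL[k] = log_likelihood(dataset, pmf)
    post = np.exp(logL - logL.max())
    post /= post.sum()
    return RatioPosterior(log10_ratio=log_r, posterior=post)
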