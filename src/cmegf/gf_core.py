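"""Generating-function machinery for master equations of transcription.

A model is split into an *upstream* part (gene-state switching ``H`` and the
burst/drift operator ``A``) and a *downstream* part (linear conversion /
degradation / catalysis, collected in unified matrices ``C`` and ``D``).  The
joint generating function (PGF over discrete molecule counts, MGF over
continuous variables) obeys a first-order PDE that the method of
characteristics reduces to ODEs:

* downstream characteristics:  dU/ds = C U + diag(U) D U,  U(0) = u,
* upstream state weights:      dG/ds = -H^T G - G o A(U(s), t - s),

integrated from s = t down to s = 0 with initial condition ``G0(U(t))``.
Probabilities are recovered from the GF evaluated at FFT roots of unity by an
inverse fast Fourier transform.

Spectral convention: for discrete species the spectral variable is
``u = g - 1`` with ``g`` on the complex unit circle; for continuous species it
is the MGF argument ``h`` directly (set to 0 to marginalize).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.linalg import expm

logger = logging.getLogger(__name__)

__all__ = [
    "UnsupportedReactionError",
    "StateSwitch",
    "Production",
    "GeometricBurstProduction",
    "Conversion",
    "Degradation",
    "Catalysis",
    "MeanReversion",
    "Drift",
    "SqrtNoise",
    "ExponentialJump",
    "CatalyticProduction",
    "ContinuousFromDiscrete",
    "Bimolecular",
    "GeneStateKinetics",
    "DownstreamOperators",
    "BurstDriftOperator",
    "ModelSpec",
    "SpectralGrid",
    "CharacteristicPath",
    "PMFGrid",
    "assemble_operators",
    "spectral_grid",
    "hybrid_s_grid",
    "solve_characteristics",
    "integrate_upstream",
    "gf_evaluator",
    "invert_gf",
    "gf_to_pmf",
    "marginalize_gene_state",
    "default_grid_shape",
]


class UnsupportedReactionError(ValueError):
    """Raised for reactions outside the solvable (first-order, feedback-free) class."""


# ---------------------------------------------------------------------------
# Reaction vocabulary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSwitch:
    """Gene-state transition ``S_i -> S_j`` at a constant rate."""

    source: int
    target: int
    rate: float


@dataclass(frozen=True)
class Production:
    """Poisson point production ``0 -> X`` of one discrete species.

    ``state`` restricts the reaction to a single gene state (``None`` = all).
    ``rate`` may be a callable of process time.
    """

    species: str
    rate: float | Callable[[np.ndarray], np.ndarray]
    state: int | None = None


@dataclass(frozen=True)
class GeometricBurstProduction:
    """Bursty production ``0 -> B x X`` with geometric burst size on {0,1,2,...}.

    ``species`` may be a tuple for co-bursting (a single geometric copy count
    shared by several species).  ``mean_size`` may be a callable of process
    time; per the model class only burst parameters may be time dependent.
    """

    species: str | tuple[str, ...]
    frequency: float | Callable[[np.ndarray], np.ndarray]
    mean_size: float | Callable[[np.ndarray], np.ndarray]
    state: int | None = None


@dataclass(frozen=True)
class Conversion:
    """Monomolecular conversion ``X_i -> X_j`` at rate ``rate * x_i``."""

    source: str
    target: str
    rate: float


@dataclass(frozen=True)
class Degradation:
    """First-order decay ``X -> 0`` (discrete) or mean reversion-free loss."""

    species: str
    rate: float


@dataclass(frozen=True)
class Catalysis:
    """Catalytic production ``X_i -> X_i + X_j`` at rate ``rate * x_i``.

    ``source == target`` encodes autocatalysis ``X -> 2X``.
    """

    source: str
    target: str
    rate: float


@dataclass(frozen=True)
class MeanReversion:
    """Continuous mean reversion ``dy = -rate * y dt``."""

    species: str
    rate: float


@dataclass(frozen=True)
class Drift:
    """Deterministic drift ``dy = rate dt`` of a continuous species."""

    species: str
    rate: float | Callable[[np.ndarray], np.ndarray]
    state: int | None = None


@dataclass(frozen=True)
class SqrtNoise:
    """Square-root (CIR-type) diffusion ``sigma * sqrt(y) dW`` on a continuous species."""

    species: str
    sigma: float


@dataclass(frozen=True)
class ExponentialJump:
    """Compound-Poisson jumps of a continuous species with Exp(mean_size) marks."""

    species: str
    frequency: float | Callable[[np.ndarray], np.ndarray]
    mean_size: float
    state: int | None = None


@dataclass(frozen=True)
class CatalyticProduction:
    """Discrete production driven by a continuous variable: ``0 -> X_j`` at rate ``rate * y_i``."""

    driver: str
    product: str
    rate: float


@dataclass(frozen=True)
class ContinuousFromDiscrete:
    """Continuous production driven by a discrete count: ``dy_i += rate * x_j dt``."""

    source: str
    target: str
    rate: float


@dataclass(frozen=True)
class Bimolecular:
    """Second-order reaction placeholder; always rejected by the solver."""

    reactants: tuple[str, ...]
    rate: float


# ---------------------------------------------------------------------------
# Assembled operator containers
# ---------------------------------------------------------------------------

@dataclass
class GeneStateKinetics:
    """Gene-state switching rates.

    ``H[i, j]`` is the rate of switching from state ``i`` to state ``j``;
    rows sum to zero.  ``H`` may be a callable of process time.
    """

    N: int
    H: np.ndarray | Callable[[float], np.ndarray]

    def __post_init__(self) -> None:
        if not callable(self.H):
            H = np.asarray(self.H, dtype=float)
            if H.shape != (self.N, self.N):
                raise ValueError(f"H must be {self.N}x{self.N}")
            off = H - np.diag(np.diag(H))
            if np.any(off < -1e-12):
                raise ValueError("off-diagonal switching rates must be nonnegative")
            if np.any(np.abs(H.sum(axis=1)) > 1e-9 * max(1.0, np.abs(H).max())):
                raise ValueError("rows of H must sum to zero")
            self.H = H

    def at(self, t: float) -> np.ndarray:
        return self.H(t) if callable(self.H) else self.H

    def stationary(self) -> np.ndarray:
        """Stationary gene-state occupancies (left null vector of H^T)."""
        H = self.at(0.0)
        if self.N == 1:
            return np.ones(1)
        w, v = np.linalg.eig(H.T)
        k = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class DownstreamOperators:
    """Unified downstream matrices for the characteristic ODE.

    ``C`` collects conversion, degradation, catalysis, mean-reversion and
    cross couplings; ``D`` collects catalysis and the sigma^2/2 square-root
    noise diagonal.  ``block_sources`` records which reaction supplied each
    entry, mostly for debugging and validation.
    """

    n: int
    m: int
    C: np.ndarray
    D: np.ndarray
    block_sources: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.n + self.m

    @property
    def is_linear(self) -> bool:
        """True when D = 0, i.e. no catalysis and no square-root noise."""
        return not np.any(self.D)


@dataclass
class BurstDriftOperator:
    """Per-state burst/drift operator ``A_s(u, t)``.

    ``terms`` is a list of ``(state, contribution)`` pairs where ``state`` is
    an int or ``None`` (all states) and ``contribution(U, T)`` maps spectral
    values ``U`` of shape ``(S, dim, P)`` and process times ``T`` of shape
    ``(S,)`` to an ``(S, P)`` array.  ``A_s(0) = 0`` for every term by
    construction (PGF/MGF normalization).
    """

    N: int
    dim: int
    terms: list = field(default_factory=list)
    time_dependent: bool = False

    def __call__(self, U: np.ndarray, T) -> np.ndarray:
        U = np.asarray(U)
        single = U.ndim == 2
        if single:
            U = U[None]
        S, dim, P = U.shape
        T = np.asarray(T, dtype=float)
        if T.ndim == 0:
            T = np.full(S, float(T))
        out = np.zeros((S, self.N, P), dtype=complex)
        for state, contrib in self.terms:
            val = contrib(U, T)
            if state is None:
                out += val[:, None, :]
            else:
                out[:, state, :] += val
        return out[0] if single else out


def _timefun(x):
    """Wrap a constant or callable-of-time as a vectorized callable."""
    if callable(x):
        return lambda T: np.asarray(x(T), dtype=float)
    return lambda T: np.full_like(np.asarray(T, dtype=float), float(x))


@dataclass
class ModelSpec:
    """Complete operator description of one stochastic system."""

    kinetics: GeneStateKinetics
    downstream: DownstreamOperators
    bursts: BurstDriftOperator
    initial_logGF: Callable[[np.ndarray], np.ndarray] | None = None
    state_weights: np.ndarray | None = None
    species: tuple[tuple[str, ...], tuple[str, ...]] = ((), ())
    rates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.bursts.dim != self.downstream.dim:
            raise ValueError("spectral dimensionality of bursts and downstream must agree")
        if self.state_weights is None:
            self.state_weights = self.kinetics.stationary()

    @property
    def n_discrete(self) -> int:
        return self.downstream.n

    def phi0(self, u: np.ndarray) -> np.ndarray:
        """Log-GF of the initial condition at spectral points ``u`` (dim, P)."""
        if self.initial_logGF is None:
            return np.zeros(u.shape[-1], dtype=complex)
        return np.asarray(self.initial_logGF(u), dtype=complex)

    def stationary_horizon(self, factor: float = 40.0) -> float:
        """Integration horizon ``factor / min |nonzero rate|`` for steady state."""
        rates = [abs(r) for r in self.rates if abs(r) > 0]
        Cd = np.abs(np.diag(self.downstream.C))
        rates += [r for r in Cd if r > 0]
        if not rates:
            return factor
        return factor / min(rates)


# ---------------------------------------------------------------------------
# Operator assembly
# ---------------------------------------------------------------------------

def assemble_operators(
    reactions: Sequence,
    *,
    discrete: Sequence[str] = (),
    continuous: Sequence[str] = (),
    n_states: int = 1,
    initial_logGF: Callable[[np.ndarray], np.ndarray] | None = None,
    state_weights: np.ndarray | None = None,
) -> ModelSpec:
    """Assemble the ``H``, ``C``, ``D`` and ``A`` operators from a reaction list.

    Only zero- and first-order reactions are allowed (state switching,
    constitutive/bursty production, conversion, degradation, catalysis,
    drift, mean reversion, square-root noise, jump driving).  Second-order or
    feedback reactions raise :class:`UnsupportedReactionError`.
    """
    discrete = list(discrete)
    continuous = list(continuous)
    n, m = len(discrete), len(continuous)
    dim = n + m
    idx = {name: i for i, name in enumerate(discrete)}
    idx.update({name: n + i for i, name in enumerate(continuous)})

    C = np.zeros((dim, dim))
    D = np.zeros((dim, dim))
    sources: dict = {}
    H = np.zeros((n_states, n_states))
    terms: list = []
    rates: list[float] = []
    time_dependent = False

    def _disc(name: str) -> int:
        if name not in idx or idx[name] >= n:
            raise UnsupportedReactionError(f"{name!r} is not a discrete species")
        return idx[name]

    def _cont(name: str) -> int:
        if name not in idx or idx[name] < n:
            raise UnsupportedReactionError(f"{name!r} is not a continuous species")
        return idx[name]

    for rx in reactions:
        if isinstance(rx, StateSwitch):
            if not (0 <= rx.source < n_states and 0 <= rx.target < n_states):
                raise ValueError("gene state index out of range")
            H[rx.source, rx.target] += rx.rate
            rates.append(rx.rate)
        elif isinstance(rx, Conversion):
            i, j = _disc(rx.source), _disc(rx.target)
            C[i, i] -= rx.rate
            C[i, j] += rx.rate
            sources[(i, j)] = "Cdd"
            rates.append(rx.rate)
        elif isinstance(rx, Degradation):
            i = _disc(rx.species)
            C[i, i] -= rx.rate
            sources[(i, i)] = "Cdd"
            rates.append(rx.rate)
        elif isinstance(rx, Catalysis):
            i, j = _disc(rx.source), _disc(rx.target)
            C[i, j] += rx.rate
            D[i, j] += rx.rate
            sources[(i, j)] = "Qd"
            rates.append(rx.rate)
        elif isinstance(rx, MeanReversion):
            i = _cont(rx.species)
            C[i, i] -= rx.rate
            sources[(i, i)] = "Ccc"
            rates.append(rx.rate)
        elif isinstance(rx, SqrtNoise):
            i = _cont(rx.species)
            D[i, i] += 0.5 * rx.sigma**2
            sources[(i, i)] = "Qc"
        elif isinstance(rx, CatalyticProduction):
            i, j = _cont(rx.driver), _disc(rx.product)
            C[i, j] += rx.rate
            sources[(i, j)] = "Ccd"
            rates.append(rx.rate)
        elif isinstance(rx, ContinuousFromDiscrete):
            j, i = _disc(rx.source), _cont(rx.target)
            C[j, i] += rx.rate
            D[j, i] += rx.rate
            sources[(j, i)] = "Cdc"
            rates.append(rx.rate)
        elif isinstance(rx, Production):
            k = idx[rx.species]
            rate_f = _timefun(rx.rate)
            time_dependent |= callable(rx.rate)
            terms.append((rx.state, _linear_term(k, rate_f)))
            if not callable(rx.rate):
                rates.append(float(rx.rate))
        elif isinstance(rx, Drift):
            k = _cont(rx.species)
            rate_f = _timefun(rx.rate)
            time_dependent |= callable(rx.rate)
            terms.append((rx.state, _linear_term(k, rate_f)))
            if not callable(rx.rate):
                rates.append(float(rx.rate))
        elif isinstance(rx, GeometricBurstProduction):
            names = rx.species if isinstance(rx.species, tuple) else (rx.species,)
            ks = tuple(_disc(s) for s in names)
            freq_f = _timefun(rx.frequency)
            size_f = _timefun(rx.mean_size)
            time_dependent |= callable(rx.frequency) or callable(rx.mean_size)
            terms.append((rx.state, _geometric_term(ks, freq_f, size_f)))
            if not callable(rx.frequency):
                rates.append(float(rx.frequency))
        elif isinstance(rx, ExponentialJump):
            k = _cont(rx.species)
            freq_f = _timefun(rx.frequency)
            size_f = _timefun(rx.mean_size)
            time_dependent |= callable(rx.frequency)
            terms.append((rx.state, _geometric_term((k,), freq_f, size_f)))
            if not callable(rx.frequency):
                rates.append(float(rx.frequency))
        else:
            raise UnsupportedReactionError(
                f"reaction {rx!r} is outside the supported class; higher-order "
                "and feedback reactions cannot be treated by the method of "
                "characteristics"
            )

    np.fill_diagonal(H, np.diag(H) - H.sum(axis=1))
    kinetics = GeneStateKinetics(N=n_states, H=H)
    downstream = DownstreamOperators(n=n, m=m, C=C, D=D, block_sources=sources)
    bursts = BurstDriftOperator(N=n_states, dim=dim, terms=terms, time_dependent=time_dependent)
    return ModelSpec(
        kinetics=kinetics,
        downstream=downstream,
        bursts=bursts,
        initial_logGF=initial_logGF,
        state_weights=state_weights,
        species=(tuple(discrete), tuple(continuous)),
        rates=tuple(rates),
    )


def _linear_term(k: int, rate_f):
    def contrib(U, T):
        return rate_f(T)[:, None] * U[:, k, :]

    return contrib


def _geometric_term(ks: tuple[int, ...], freq_f, size_f):
    """Burst term ``alpha * (1 / (1 - b * sum_k U_k) - 1)``.

    The reciprocal is evaluated through the principal branch of
    ``log(1 - b U)``; ``|b U| < 1`` is not guaranteed on the evaluation
    circle, so the integrand is computed in log space.
    """

    def contrib(U, T):
        arg = U[:, ks[0], :].copy()
        for k in ks[1:]:
            arg += U[:, k, :]
        b = size_f(T)[:, None]
        denom = 1.0 - b * arg
        if np.any(np.abs(denom) < 1e-12):
            warnings.warn("geometric burst PGF evaluated at a branch-cut singularity")
        return freq_f(T)[:, None] * np.expm1(-np.log(denom))

    return contrib


# ---------------------------------------------------------------------------
# Spectral grid
# ---------------------------------------------------------------------------

@dataclass
class SpectralGrid:
    """FFT evaluation grid: ``u = g - 1`` with ``g`` at roots of unity.

    ``points`` has shape ``(n + m, P)`` with continuous coordinates pinned to
    zero (marginalized).  The flattened ordering is C order over ``shape``.
    """

    shape: tuple[int, ...]
    points: np.ndarray
    n_continuous: int = 0

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))


def spectral_grid(shape: Sequence[int], n_continuous: int = 0) -> SpectralGrid:
    """Build the FFT spectral grid for the given per-species truncation."""
    shape = tuple(int(s) for s in shape)
    axes = [np.exp(2j * np.pi * np.arange(s) / s) - 1.0 for s in shape]
    mesh = np.meshgrid(*axes, indexing="ij") if axes else []
    P = int(np.prod(shape)) if shape else 1
    pts = np.zeros((len(shape) + n_continuous, P), dtype=complex)
    for i, Mx in enumerate(mesh):
        pts[i] = Mx.reshape(-1)
    return SpectralGrid(shape=shape, points=pts, n_continuous=n_continuous)


def default_grid_shape(mean, sd, buffer: int = 4) -> tuple[int, ...]:
    """Per-species grid size ``ceil(mu + 4 sigma) + buffer`` (+1 for the origin)."""
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    sd = np.atleast_1d(np.asarray(sd, dtype=float))
    return tuple(int(math.ceil(mu + 4.0 * s)) + buffer + 1 for mu, s in zip(mean, sd))


def hybrid_s_grid(t: float, nodes: int = 1024) -> np.ndarray:
    """Quadrature grid on [0, t]: geometric refinement near 0 merged with a linear grid.

    Characteristics decay exponentially, so the integrand concentrates near
    s = 0; half the nodes are log-spaced from ``t * 1e-6``.
    """
    if t <= 0:
        return np.array([0.0])
    n_geo = nodes // 2
    geo = np.geomspace(t * 1e-6, t, n_geo)
    lin = np.linspace(0.0, t, nodes - n_geo)
    s = np.unique(np.concatenate([[0.0], geo, lin]))
    return s


def gauss_panel_grid(t: float, n_panels: int = 24, order: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on a geometrically graded partition of [0, t].

    Panel boundaries are log-spaced from ``t * 1e-7``, which resolves the fast
    initial decay of stiff characteristics; per-panel Gauss-Legendre converges
    spectrally for the smooth exponential integrands encountered here.
    """
    if t <= 0:
        return np.array([0.0]), np.array([0.0])
    xg, wg = np.polynomial.legendre.leggauss(order)
    bounds = np.concatenate([[0.0], np.geomspace(t * 1e-7, t, n_panels)])
    lo, hi = bounds[:-1], bounds[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    s = (mid[:, None] + half[:, None] * xg[None, :]).reshape(-1)
    w = (half[:, None] * wg[None, :]).reshape(-1)
    order_idx = np.argsort(s)
    return s[order_idx], w[order_idx]


# ---------------------------------------------------------------------------
# Characteristics
# ---------------------------------------------------------------------------

@dataclass
class CharacteristicPath:
    """Downstream characteristics ``U(s)`` for a batch of spectral start points."""

    s_grid: np.ndarray
    U: np.ndarray  # (S, dim, P)
    u0: np.ndarray  # (dim, P)
    t: float
    weights: np.ndarray | None = None  # quadrature weights matching s_grid
    _evaluator: Callable[[np.ndarray], np.ndarray] | None = None

    def at(self, s) -> np.ndarray:
        """Evaluate ``U`` at arbitrary ``s`` (array -> (S', dim, P))."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self._evaluator is not None:
            return self._evaluator(s)
        spline = CubicSpline(self.s_grid, self.U, axis=0)
        self._evaluator = lambda ss: spline(ss)
        return self._evaluator(s)


def solve_characteristics(
    ops: DownstreamOperators,
    u: np.ndarray,
    t: float,
    nodes: int = 257,
    s_grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CharacteristicPath:
    """Solve ``dU/ds = C U + diag(U) D U`` from every start point in ``u``.

    With ``D = 0`` the linear system is solved in closed form through the
    eigendecomposition of ``C`` (matrix-exponential fallback when ``C`` is
    defective); otherwise the Riccati-type system is integrated numerically
    with an adaptive Runge-Kutta scheme.
    """
    if t < 0:
        raise ValueError("duration must be nonnegative")
    u = np.asarray(u, dtype=complex)
    if u.ndim == 1:
        u = u[:, None]
    dim, P = u.shape
    if dim != ops.dim:
        raise ValueError("spectral dimension mismatch")
    if s_grid is None:
        if nodes < 2:
            raise ValueError("need at least two quadrature nodes")
        s_grid = np.linspace(0.0, t, nodes)
    s_grid = np.asarray(s_grid, dtype=float)

    C, D = ops.C, ops.D
    if t == 0 or s_grid[-1] == 0:
        U = np.broadcast_to(u, (len(s_grid), dim, P)).copy()
        ev = lambda ss: np.broadcast_to(u, (len(np.atleast_1d(ss)), dim, P)).copy()
        return CharacteristicPath(s_grid, U, u, t, weights, ev)
    if ops.is_linear:
        evaluator = _linear_evaluator(C, u)
        U = evaluator(s_grid)
        return CharacteristicPath(s_grid, U, u, t, weights, evaluator)

    def rhs(_s, y):
        U_ = y.reshape(dim, P)
        return (C @ U_ + U_ * (D @ U_)).reshape(-1)

    sol = solve_ivp(
        rhs,
        (0.0, max(t, float(s_grid[-1]))),
        u.reshape(-1),
        t_eval=s_grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"characteristic integration failed ({sol.message}); "
            f"first spectral point {u[:, 0]}"
        )
    U = sol.y.T.reshape(len(s_grid), dim, P)
    return CharacteristicPath(s_grid, U, u, t, weights)


def _linear_evaluator(C: np.ndarray, u: np.ndarray):
    """Closed-form ``U(s) = V exp(L s) V^-1 u``, with expm fallback if defective."""
    dim = C.shape[0]
    lam, V = np.linalg.eig(C)
    use_eig = True
    if dim > 1:
        # defective C (repeated eigenvalues without full eigenbasis) -> expm
        if np.linalg.cond(V) > 1e10:
            use_eig = False
            logger.info("C is numerically defective; falling back to expm evaluation")
    if use_eig:
        coef = np.linalg.solve(V, u)  # (dim, P)

        def evaluator(s: np.ndarray) -> np.ndarray:
            ex = np.exp(np.multiply.outer(s, lam))  # (S, dim)
            return np.einsum("ij,sj,jp->sip", V, ex, coef)

        return evaluator

    def evaluator(s: np.ndarray) -> np.ndarray:
        out = np.empty((len(s), dim, u.shape[1]), dtype=complex)
        for k, sk in enumerate(s):
            out[k] = expm(C * sk) @ u
        return out

    return evaluator


# ---------------------------------------------------------------------------
# Upstream integration
# ---------------------------------------------------------------------------

def integrate_upstream(
    model: ModelSpec,
    path: CharacteristicPath,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the upstream ODE along the characteristics.

    Returns the per-gene-state GF values ``G_s(u, t)``, shape ``(N, P)``.
    For ``N = 1`` this is the single quadrature
    ``phi(t) = phi0(U(t)) + int_0^t A(U(s), t - s) ds``; for ``N > 1`` the
    matrix ODE is integrated with initial condition ``pi0 * exp(phi0(U(t)))``.
    """
    t = path.t
    N = model.kinetics.N
    s = path.s_grid
    if N == 1:
        A = model.bursts(path.U, t - s)[:, 0, :]  # (S, P)
        if path.weights is not None:
            integral = (path.weights[:, None] * A).sum(axis=0)
        else:
            integral = np.trapezoid(A, x=s, axis=0)
        Ut = path.at(np.array([t]))[0]
        phi = model.phi0(Ut) + integral
        return np.exp(phi)[None, :]

    P = path.u0.shape[1]
    Ut = path.at(np.array([t]))[0]
    G0 = np.asarray(model.state_weights, dtype=complex)[:, None] * np.exp(model.phi0(Ut))[None, :]
    if t == 0:
        return G0

    def rhs(r, y):
        G = y.reshape(N, P)
        U = path.at(np.array([t - r]))[0]
        A = model.bursts(U, r)  # (N, P)
        H = model.kinetics.at(r)
        dG = H.T @ G + A * G
        return dG.reshape(-1)

    sol = solve_ivp(rhs, (0.0, t), G0.reshape(-1), method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"upstream integration failed: {sol.message}")
    return sol.y[:, -1].reshape(N, P)


def marginalize_gene_state(G_states: np.ndarray) -> np.ndarray:
    """Sum the per-state GF values (gene-state spectral coordinates pinned to 0)."""
    G_states = np.asarray(G_states)
    if G_states.ndim == 1:
        return G_states
    return G_states.sum(axis=0)


def gf_evaluator(
    model: ModelSpec,
    t: float | str = "stationary",
    nodes: int = 1024,
) -> Callable[[np.ndarray], np.ndarray]:
    """Return a callable ``G(u)`` for the gene-state-marginal GF at time ``t``.

    For single-gene-state models the upstream integral uses panelled
    Gauss-Legendre quadrature (``nodes`` is an upper bound on node count);
    multi-state models integrate the upstream ODE adaptively.
    """
    t_num = model.stationary_horizon() if t == "stationary" else float(t)
    n_panels = max(4, min(24, nodes // 16))
    s, w = gauss_panel_grid(t_num, n_panels=n_panels)

    def G(u: np.ndarray) -> np.ndarray:
        path = solve_characteristics(model.downstream, u, t_num, s_grid=s, weights=w)
        return marginalize_gene_state(integrate_upstream(model, path))

    return G


# ---------------------------------------------------------------------------
# PMF inversion
# ---------------------------------------------------------------------------

@dataclass
class PMFGrid:
    """Nonnegative probability array over a truncated discrete state space."""

    values: np.ndarray
    shape: tuple[int, ...]
    normalization_defect: float

    def renormalized(self) -> np.ndarray:
        tot = self.values.sum()
        return self.values / tot if tot > 0 else self.values


def invert_gf(
    evaluator: Callable[[np.ndarray], np.ndarray],
    shape: Sequence[int],
    n_continuous: int = 0,
    clip_tol: float = 1e-10,
    defect_tol: float = 1e-4,
) -> PMFGrid:
    """Invert a GF evaluator to a PMF by inverse FFT over the spectral grid.

    Small negative values (>= -clip_tol) are clipped to zero; larger negatives
    and normalization defects above ``defect_tol`` trigger warnings suggesting
    a larger grid.
    """
    grid = spectral_grid(shape, n_continuous)
    G = np.asarray(evaluator(grid.points)).reshape(grid.shape)
    # with g_k = exp(+2 pi i k / S), P(x) = (1/S) sum_k G(g_k) exp(-2 pi i k x / S)
    pmf = np.fft.fftn(G) / grid.size
    imag_max = float(np.abs(pmf.imag).max()) if pmf.size else 0.0
    pmf = pmf.real
    neg_min = float(pmf.min()) if pmf.size else 0.0
    if neg_min < -max(clip_tol, 1e-8):
        warnings.warn(
            f"PMF has negative mass {neg_min:.2e}; the spectral grid is likely "
            "too small for the support"
        )
    pmf = np.clip(pmf, 0.0, None)
    defect = abs(1.0 - float(pmf.sum()))
    if defect > defect_tol:
        warnings.warn(
            f"PMF normalization defect {defect:.2e} exceeds {defect_tol:.0e}; "
            "consider a larger grid"
        )
    logger.debug("invert_gf: defect=%.3e, max|imag|=%.3e", defect, imag_max)
    return PMFGrid(values=pmf, shape=tuple(grid.shape), normalization_defect=defect)


def gf_to_pmf(
    model: ModelSpec,
    shape: Sequence[int],
    t: float | str = "stationary",
    nodes: int = 1024,
    **kwargs,
) -> PMFGrid:
    """Evaluate the model GF on the FFT grid and invert it to a PMF."""
    return invert_gf(
        gf_evaluator(model, t, nodes=nodes),
        shape,
        n_continuous=model.downstream.m,
        **kwargs,
    )
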