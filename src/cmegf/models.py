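"""Concrete transcription-model builders and parameter transformations.

Families
--------
constitutive
    Poisson point production at a constant rate; stationary law is Poisson.
bursty
    Geometric bursts of nascent RNA at frequency ``alpha`` with mean size
    ``b``; the one-species stationary law is negative binomial with shape
    ``alpha / beta`` and scale ``b``.
telegraph
    Two-state gene; initiation at ``kinit`` only in the on state.
gamma Ornstein-Uhlenbeck (gou) / Cox-Ingersoll-Ross (cir)
    Continuous stochastic transcription-rate drivers sharing a gamma
    stationary law (shape ``a / kappa``, scale ``theta``).
autocatalytic
    Constitutive (or bursty) production plus ``X -> 2X`` catalysis.

The qualitative ``(x, y)`` coordinates summarize driver kinetics relative to
RNA turnover: ``x = kappa / (kappa + beta + gamma)`` is the timescale
separation and ``y = theta / (a + theta)`` the noise intensity; both live in
(0, 1) and the map to process parameters at fixed averages is bijective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from . import gf_core
from .gf_core import (
    Catalysis,
    CatalyticProduction,
    Conversion,
    Degradation,
    Drift,
    ExponentialJump,
    GeometricBurstProduction,
    MeanReversion,
    ModelSpec,
    PMFGrid,
    Production,
    SqrtNoise,
    StateSwitch,
    assemble_operators,
    default_grid_shape,
    gf_evaluator,
    invert_gf,
)

__all__ = [
    "NoClosedFormError",
    "ConstitutiveParams",
    "TelegraphParams",
    "SDEDriverParams",
    "BurstyParams",
    "AutocatalyticParams",
    "QualitativeCoords",
    "CoregulationParams",
    "build_model",
    "qualitative_to_process",
    "process_to_qualitative",
    "telegraph_driver_identification",
    "apply_dropout_closure",
    "dropout_y_star",
    "stationary_closed_form",
    "bursty_autocatalytic_gf",
    "reduced_cobursting_rates",
    "build_coupled_model",
    "bursty_moments",
    "moment_bounds",
    "stationary_pmf",
    "PoissonMixture",
]


class NoClosedFormError(ValueError):
    """Raised when no analytic stationary law is available for a family."""


def _positive(**kwargs) -> None:
    for name, val in kwargs.items():
        if not (np.isscalar(val) and val > 0) and not callable(val):
            raise ValueError(f"{name} must be strictly positive, got {val!r}")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstitutiveParams:
    """Constant-rate transcription; ``beta=None`` gives the one-species model."""

    K: float
    gamma: float
    beta: float | None = None

    def __post_init__(self):
        _positive(K=self.K, gamma=self.gamma)
        if self.beta is not None:
            _positive(beta=self.beta)


@dataclass(frozen=True)
class TelegraphParams:
    kon: float
    koff: float
    kinit: float
    beta: float
    gamma: float | None = None  # None -> one-species (decay at beta)

    def __post_init__(self):
        _positive(kon=self.kon, koff=self.koff, kinit=self.kinit, beta=self.beta)
        if self.gamma is not None:
            _positive(gamma=self.gamma)


@dataclass(frozen=True)
class SDEDriverParams:
    """Gamma-OU or CIR transcription-rate driver feeding a splicing cascade."""

    family: Literal["gou", "cir"]
    kappa: float
    a: float
    theta: float
    beta: float
    gamma: float | None = None

    def __post_init__(self):
        if self.family not in ("gou", "cir"):
            raise ValueError("family must be 'gou' or 'cir'")
        _positive(kappa=self.kappa, a=self.a, theta=self.theta, beta=self.beta)
        if self.gamma is not None:
            _positive(gamma=self.gamma)

    @property
    def mean_rate(self) -> float:
        """Stationary driver mean a*theta/kappa (gamma shape a/kappa, scale theta)."""
        return self.a * self.theta / self.kappa


@dataclass(frozen=True)
class BurstyParams:
    """Bursty transcription; ``b`` may be a callable of process time."""

    alpha: float
    b: float | Callable[[np.ndarray], np.ndarray]
    beta: float
    gamma: float | None = None

    def __post_init__(self):
        _positive(alpha=self.alpha, b=self.b, beta=self.beta)
        if self.gamma is not None:
            _positive(gamma=self.gamma)


@dataclass(frozen=True)
class AutocatalyticParams:
    """Production, degradation and autocatalysis; stationarity needs gamma > q."""

    alpha: float
    q: float
    gamma: float
    b: float | None = None  # geometric burst mean for the bursty variant

    def __post_init__(self):
        _positive(alpha=self.alpha, q=self.q, gamma=self.gamma)
        if self.gamma <= self.q:
            raise ValueError("stationarity requires gamma > q")
        if self.b is not None:
            _positive(b=self.b)
            if self.b * self.c - self.q <= 0:
                raise ValueError("stationarity of the bursty variant requires b*c - q > 0")

    @property
    def c(self) -> float:
        return self.gamma - self.q

    @property
    def v(self) -> float:
        if self.b is None:
            raise ValueError("v is defined for the bursty variant only")
        return self.alpha * self.b / (self.b * self.c - self.q)


@dataclass(frozen=True)
class QualitativeCoords:
    """Timescale separation x and noise intensity y, with fixed averages."""

    x: float
    y: float
    muK: float
    beta: float
    gamma: float | None = None
    species_mode: Literal["one", "two"] = "two"

    def __post_init__(self):
        if not (0.0 < self.x < 1.0 and 0.0 < self.y < 1.0):
            raise ValueError("x and y must lie strictly inside (0, 1)")
        _positive(muK=self.muK, beta=self.beta)
        if self.species_mode == "two":
            if self.gamma is None:
                raise ValueError("two-species mode requires gamma")
            _positive(gamma=self.gamma)

    @property
    def turnover(self) -> float:
        """beta + gamma (two-species) or beta (one-species)."""
        return self.beta + (self.gamma if self.species_mode == "two" else 0.0)


@dataclass(frozen=True)
class CoregulationParams:
    """Symmetric two-gene co-regulation via a four-state chain.

    ``eps`` scales the stability of the intermediate one-gene-on states:
    ``eps << 1`` makes them unstable (co-bursting limit), ``eps = 1`` recovers
    two independent telegraph genes.
    """

    eps: float
    kon: float
    koff: float
    kinit: float
    gamma1: float
    gamma2: float

    def __post_init__(self):
        _positive(eps=self.eps, kon=self.kon, koff=self.koff, kinit=self.kinit,
                  gamma1=self.gamma1, gamma2=self.gamma2)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build_model(params) -> ModelSpec:
    """Build the :class:`~cmegf.gf_core.ModelSpec` for a parameter family."""
    if isinstance(params, ConstitutiveParams):
        if params.beta is None:
            rx = [Production("N", params.K), Degradation("N", params.gamma)]
            return assemble_operators(rx, discrete=["N"])
        rx = [
            Production("N", params.K),
            Conversion("N", "M", params.beta),
            Degradation("M", params.gamma),
        ]
        return assemble_operators(rx, discrete=["N", "M"])

    if isinstance(params, TelegraphParams):
        rx = [
            StateSwitch(0, 1, params.kon),
            StateSwitch(1, 0, params.koff),
            Production("N", params.kinit, state=1),
        ]
        rx += _cascade(params.beta, params.gamma)
        species = ["N"] if params.gamma is None else ["N", "M"]
        return assemble_operators(rx, discrete=species, n_states=2)

    if isinstance(params, SDEDriverParams):
        rx = [
            MeanReversion("K", params.kappa),
            CatalyticProduction("K", "N", 1.0),
        ]
        if params.family == "gou":
            rx.append(ExponentialJump("K", params.a, params.theta))
        else:
            rx.append(Drift("K", params.a * params.theta))
            rx.append(SqrtNoise("K", math.sqrt(2.0 * params.kappa * params.theta)))
        rx += _cascade(params.beta, params.gamma)
        species = ["N"] if params.gamma is None else ["N", "M"]
        return assemble_operators(rx, discrete=species, continuous=["K"])

    if isinstance(params, BurstyParams):
        rx = [GeometricBurstProduction("N", params.alpha, params.b)]
        rx += _cascade(params.beta, params.gamma)
        species = ["N"] if params.gamma is None else ["N", "M"]
        return assemble_operators(rx, discrete=species)

    if isinstance(params, AutocatalyticParams):
        if params.b is None:
            rx = [Production("X", params.alpha)]
        else:
            rx = [GeometricBurstProduction("X", params.alpha, params.b)]
        rx += [Degradation("X", params.gamma), Catalysis("X", "X", params.q)]
        return assemble_operators(rx, discrete=["X"])

    if isinstance(params, QualitativeCoords):
        raise TypeError("convert QualitativeCoords with qualitative_to_process first")
    raise TypeError(f"unknown parameter family {type(params).__name__}")


def _cascade(beta: float, gamma: float | None) -> list:
    if gamma is None:
        return [Degradation("N", beta)]
    return [Conversion("N", "M", beta), Degradation("M", gamma)]


# ---------------------------------------------------------------------------
# Qualitative (x, y) parametrization
# ---------------------------------------------------------------------------

def telegraph_driver_identification(params: TelegraphParams) -> tuple[float, float, float]:
    """Map telegraph rates to the driver-process triple (kappa, a, theta).

    kappa = kon + koff is the autocorrelation timescale, a = kon*kappa/koff
    the process scaling and theta = koff*kinit/kappa the gain; these match the
    SDE drivers' autocorrelation exp(-kappa t), mean a*theta/kappa and
    variance theta*muK.
    """
    kappa = params.kon + params.koff
    a = params.kon * kappa / params.koff
    theta = params.koff * params.kinit / kappa
    return kappa, a, theta


def process_to_qualitative(
    params: TelegraphParams | SDEDriverParams,
    species_mode: Literal["one", "two"] | None = None,
) -> QualitativeCoords:
    """Compute (x, y, muK) from process parameters."""
    if isinstance(params, TelegraphParams):
        kappa, a, theta = telegraph_driver_identification(params)
        beta, gamma = params.beta, params.gamma
    else:
        kappa, a, theta = params.kappa, params.a, params.theta
        beta, gamma = params.beta, params.gamma
    if species_mode is None:
        species_mode = "one" if gamma is None else "two"
    turnover = beta + (gamma if species_mode == "two" else 0.0)
    x = kappa / (kappa + turnover)
    y = theta / (a + theta)
    muK = a * theta / kappa
    return QualitativeCoords(x=x, y=y, muK=muK, beta=beta,
                             gamma=gamma if species_mode == "two" else gamma,
                             species_mode=species_mode)


def qualitative_to_process(
    coords: QualitativeCoords,
    family: Literal["gou", "cir", "telegraph"],
) -> TelegraphParams | SDEDriverParams:
    """Invert the (x, y, muK) map for a given family.

    kappa = turnover * x / (1 - x); the (a, theta) pair follows from
    y = theta / (a + theta) and muK = a*theta/kappa, giving
    theta = sqrt(muK * kappa * y / (1 - y)).  For the telegraph family the
    identification (kon/koff)^2 = muK (1/y - 1) / kappa is solved with the
    positive root.
    """
    kappa = coords.turnover * coords.x / (1.0 - coords.x)
    if family in ("gou", "cir"):
        theta = math.sqrt(coords.muK * kappa * coords.y / (1.0 - coords.y))
        a = coords.muK * kappa / theta
        return SDEDriverParams(family=family, kappa=kappa, a=a, theta=theta,
                               beta=coords.beta, gamma=coords.gamma)
    if family == "telegraph":
        c2 = coords.muK * (1.0 / coords.y - 1.0) / kappa
        r = math.sqrt(c2)  # kon / koff, positive root
        kon = r * kappa / (1.0 + r)
        koff = kappa / (1.0 + r)
        kinit = coords.muK * kappa / kon
        return TelegraphParams(kon=kon, koff=koff, kinit=kinit,
                               beta=coords.beta, gamma=coords.gamma)
    raise ValueError(f"unknown family {family!r}")


def apply_dropout_closure(params, p: float):
    """Reparametrize a model so its noise-free PMF equals the Bernoulli-thinned one.

    Bernoulli observation with probability ``p`` on every species is
    equivalent to theta -> p*theta (gamma-OU/CIR), kinit -> p*kinit
    (telegraph) or b -> p*b (bursty).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("observation probability p must lie in (0, 1]")
    if isinstance(params, SDEDriverParams):
        return replace(params, theta=p * params.theta)
    if isinstance(params, TelegraphParams):
        return replace(params, kinit=p * params.kinit)
    if isinstance(params, BurstyParams):
        if callable(params.b):
            b0 = params.b
            return replace(params, b=lambda t: p * np.asarray(b0(t)))
        return replace(params, b=p * params.b)
    raise TypeError(f"dropout closure not defined for {type(params).__name__}")


def dropout_y_star(params: SDEDriverParams, p: float) -> float:
    """Noise intensity after dropout p at fixed averages: y* = p theta / (a/p + p theta)."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    return p * params.theta / (params.a / p + p * params.theta)


# ---------------------------------------------------------------------------
# Closed-form stationary laws (test oracles)
# ---------------------------------------------------------------------------

class PoissonMixture:
    """Finite mixture of Poisson laws with weights ``w`` and means ``mu``."""

    def __init__(self, w: Sequence[float], mu: Sequence[float]):
        self.w = np.asarray(w, dtype=float)
        self.mu = np.asarray(mu, dtype=float)
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def pmf(self, x) -> np.ndarray:
        x = np.asarray(x)
        out = np.zeros(np.shape(x), dtype=float)
        for wk, mk in zip(self.w, self.mu):
            out = out + wk * stats.poisson(mk).pmf(x)
        return out


def stationary_closed_form(params):
    """Analytic stationary law for families that admit one.

    Returns a frozen scipy distribution (or :class:`PoissonMixture`) for the
    *nascent/one-species* marginal.  Telegraph and SDE-driver laws are the
    slow-driver (kappa << turnover) mixture limits; exact laws for those
    families have no elementary closed form and raise
    :class:`NoClosedFormError` outside the limit helpers.
    """
    if isinstance(params, ConstitutiveParams):
        rate = params.K / (params.beta if params.beta is not None else params.gamma)
        return stats.poisson(rate)
    if isinstance(params, BurstyParams):
        if callable(params.b):
            raise NoClosedFormError("time-dependent burst size has no stationary law")
        shape = params.alpha / params.beta
        return stats.nbinom(shape, 1.0 / (1.0 + params.b))
    if isinstance(params, AutocatalyticParams):
        if params.b is None:
            scale = params.q / (params.gamma - params.q)
            return stats.nbinom(params.alpha / params.q, 1.0 / (1.0 + scale))
        raise NoClosedFormError(
            "bursty autocatalysis is an NB-NB mixture; use bursty_autocatalytic_gf"
        )
    if isinstance(params, TelegraphParams):
        # slow-switching limit: scaled-Bernoulli Poisson mixture
        kappa = params.kon + params.koff
        w_on = params.kon / kappa
        return PoissonMixture([1.0 - w_on, w_on], [0.0, params.kinit / params.beta])
    if isinstance(params, SDEDriverParams):
        # slow-driver limit: gamma mixture of Poissons = negative binomial
        shape = params.a / params.kappa
        scale = params.theta / params.beta
        return stats.nbinom(shape, 1.0 / (1.0 + scale))
    raise NoClosedFormError(f"no closed form for {type(params).__name__}")


def bursty_autocatalytic_gf(params: AutocatalyticParams) -> Callable[[np.ndarray], np.ndarray]:
    """Stationary GF of bursty production with autocatalysis.

    G(u) = ((1 - (q/c) u) / (1 - b u))**v with c = gamma - q and
    v = alpha b / (b c - q); this coincides with the transient GF of the
    plain bursty process under q/c = b exp(-kappa tau).
    """
    if params.b is None:
        raise ValueError("the bursty variant requires a burst mean b")
    b, q, c, v = params.b, params.q, params.c, params.v

    def G(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=complex)
        if u.ndim == 2:
            u = u[0]
        return np.exp(v * (np.log(1.0 - (q / c) * u) - np.log(1.0 - b * u)))

    return G


# ---------------------------------------------------------------------------
# Two-gene coupling
# ---------------------------------------------------------------------------

def reduced_cobursting_rates(kon: float, koff: float) -> tuple[float, float]:
    """Effective two-state rates in the eps -> 0 limit of the four-state chain.

    With unstable intermediates the chain leaves 'both off' at rate 2*kon and
    commits to 'both on' with probability kon/(kon+koff), giving
    kon* = 2 kon^2/(kon+koff) and symmetrically koff* = 2 koff^2/(kon+koff).
    """
    kappa = kon + koff
    return 2.0 * kon**2 / kappa, 2.0 * koff**2 / kappa


def build_coupled_model(kind: str, params, **kwargs):
    """Two-gene co-regulation models.

    kind='mixture'        -> GF evaluator sum_k pi_k prod_j G_jk(u_j)
    kind='state_coupled'  -> four-state ModelSpec (CoregulationParams)
    kind='cobursting_reduced' -> two-state limit ModelSpec
    kind='cobursting'     -> single-state shared-geometric-burst ModelSpec
    """
    if kind == "mixture":
        weights = np.asarray(kwargs["weights"], dtype=float)
        components = kwargs["components"]  # per-component joint GF evaluators
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

        def G(u: np.ndarray) -> np.ndarray:
            vals = [Gk(u) for Gk in components]
            return sum(w * v for w, v in zip(weights, vals))

        return G

    if kind == "state_coupled":
        p: CoregulationParams = params
        fast = 1.0 / p.eps
        rx = [
            StateSwitch(0, 1, p.kon), StateSwitch(0, 2, p.kon),
            StateSwitch(1, 0, fast * p.koff), StateSwitch(1, 3, fast * p.kon),
            StateSwitch(2, 0, fast * p.koff), StateSwitch(2, 3, fast * p.kon),
            StateSwitch(3, 1, p.koff), StateSwitch(3, 2, p.koff),
            Production("X1", p.kinit, state=1),
            Production("X2", p.kinit, state=2),
            Production("X1", p.kinit, state=3),
            Production("X2", p.kinit, state=3),
            Degradation("X1", p.gamma1),
            Degradation("X2", p.gamma2),
        ]
        return assemble_operators(rx, discrete=["X1", "X2"], n_states=4)

    if kind == "cobursting_reduced":
        p = params
        kon_s, koff_s = reduced_cobursting_rates(p.kon, p.koff)
        rx = [
            StateSwitch(0, 1, kon_s), StateSwitch(1, 0, koff_s),
            Production("X1", p.kinit, state=1),
            Production("X2", p.kinit, state=1),
            Degradation("X1", p.gamma1),
            Degradation("X2", p.gamma2),
        ]
        return assemble_operators(rx, discrete=["X1", "X2"], n_states=2)

    if kind == "cobursting":
        p = params
        kon_s, koff_s = reduced_cobursting_rates(p.kon, p.koff)
        b = p.kinit / koff_s
        rx = [
            GeometricBurstProduction(("X1", "X2"), kon_s, b),
            Degradation("X1", p.gamma1),
            Degradation("X2", p.gamma2),
        ]
        return assemble_operators(rx, discrete=["X1", "X2"])

    raise ValueError(f"unknown coupling kind {kind!r}")


# ---------------------------------------------------------------------------
# Moments and PMF evaluation
# ---------------------------------------------------------------------------

def bursty_moments(alpha: float, b: float, beta: float, gamma: float | None = None):
    """Stationary means and standard deviations of the bursty model.

    Nascent: mu = alpha b / beta, var = mu (1 + b).
    Mature:  mu = alpha b / gamma, var = mu (1 + b beta / (beta + gamma)).
    """
    muN = alpha * b / beta
    sdN = math.sqrt(muN * (1.0 + b))
    if gamma is None:
        return (muN,), (sdN,)
    muM = alpha * b / gamma
    sdM = math.sqrt(muM * (1.0 + b * beta / (beta + gamma)))
    return (muN, muM), (sdN, sdM)


def moment_bounds(params) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-species stationary mean and an upper bound on the sd (grid sizing)."""
    if isinstance(params, ConstitutiveParams):
        if params.beta is None:
            mu = (params.K / params.gamma,)
        else:
            mu = (params.K / params.beta, params.K / params.gamma)
        return mu, tuple(math.sqrt(m) for m in mu)
    if isinstance(params, BurstyParams):
        b = params.b if not callable(params.b) else float(np.max(params.b(np.linspace(0, 1e3, 64))))
        return bursty_moments(params.alpha, b, params.beta, params.gamma)
    if isinstance(params, (TelegraphParams, SDEDriverParams)):
        if isinstance(params, TelegraphParams):
            kappa, a, theta = telegraph_driver_identification(params)
        else:
            kappa, a, theta = params.kappa, params.a, params.theta
        muK = a * theta / kappa
        rates = [params.beta] + ([params.gamma] if params.gamma is not None else [])
        mu, sd = [], []
        for r in rates:
            m = muK / r
            # slow-driver bound var <= mu (1 + theta / r)
            mu.append(m)
            sd.append(math.sqrt(m * (1.0 + theta / r)))
        return tuple(mu), tuple(sd)
    if isinstance(params, AutocatalyticParams):
        if params.b is None:
            shape, scale = params.alpha / params.q, params.q / (params.gamma - params.q)
        else:
            shape, scale = params.v, params.b
        m = shape * scale
        return (m,), (math.sqrt(m * (1.0 + scale)),)
    raise TypeError(f"no moment bounds for {type(params).__name__}")


def stationary_pmf(
    params,
    shape: Sequence[int] | None = None,
    pN: float = 1.0,
    pM: float = 1.0,
    nodes: int = 1024,
    **kwargs,
) -> PMFGrid:
    """Stationary joint PMF of a model family, optionally Bernoulli-thinned.

    ``pN``/``pM`` thin the nascent and mature species by evaluating the GF at
    scaled spectral coordinates (u_N -> pN u_N, u_M -> pM u_M).
    """
    model = build_model(params)
    if shape is None:
        mu, sd = moment_bounds(params)
        mu = tuple(m * p for m, p in zip(mu, (pN, pM)))
        sd = tuple(s * p for s, p in zip(sd, (pN, pM)))
        shape = default_grid_shape(mu, sd)
    G = gf_evaluator(model, "stationary", nodes=nodes)
    n = model.downstream.n
    scale = np.ones(model.downstream.dim)
    scale[0] = pN
    if n > 1:
        scale[1] = pM

    def G_thinned(u: np.ndarray) -> np.ndarray:
        return G(scale[:, None] * u)

    return invert_gf(G_thinned, shape, n_continuous=model.downstream.m, **kwargs)
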