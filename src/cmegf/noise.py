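"""Composable generating-function transforms for droplet sequencing noise.

The observed-count GF is assembled from four optional stages applied to the
biological per-cell GF ``G(u)``:

* encapsulation ``Genc = Gbc(G)`` (Bernoulli / binomial / Poisson cell counts
  per droplet),
* ambient background ``Gbg = exp(c sum_i mu_i u_i)`` (independent Poisson
  debris with pseudobulk means),
* library construction, substituting per-species ``u_i -> p_i u_i``
  (sequestering; each RNA templates at most one UMI-tagged cDNA) or
  ``u_i -> exp(lambda_i u_i) - 1`` (non-sequestering; Poisson numbers of
  cDNA per molecule),
* read-identity ambiguity, a row-stochastic map ``u_source = P_a u_observed``
  from molecular species to identifiable read classes.

Composition order (innermost applied to the observed coordinates first):
``Gtot,ta(u) = [Genc(G) * Gbg](Gt*(Ga*(u)))``.

All stages operate on spectral points of shape ``(dim, P)`` and preserve the
normalization ``G(0) = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "EncapsulationSpec",
    "BackgroundSpec",
    "PerSpeciesNoise",
    "AmbiguityMatrix",
    "LengthNoiseModel",
    "encapsulation_gf",
    "background_gf",
    "library_substitution",
    "library_gf",
    "ambiguity_transform",
    "compose_full",
]

GFEvaluator = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class EncapsulationSpec:
    """Cells-per-droplet law: 'bernoulli' (0/1), 'binomial' (0/1/2) or 'poisson'."""

    scheme: Literal["bernoulli", "binomial", "poisson"]
    p: float | None = None   # capture probability (bernoulli / binomial)
    lam: float | None = None  # per-droplet cell rate (poisson)

    def __post_init__(self):
        if self.scheme in ("bernoulli", "binomial"):
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ValueError("p must lie in [0, 1]")
        elif self.scheme == "poisson":
            if self.lam is None or self.lam < 0:
                raise ValueError("lam must be nonnegative")
        else:
            raise ValueError(f"unknown encapsulation scheme {self.scheme!r}")


@dataclass(frozen=True)
class BackgroundSpec:
    """Pseudobulk ambient debris: Poisson per species with mean ``c * mu_i``."""

    c: float
    mu: tuple[float, ...]

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("pool constant c must be nonnegative")
        if any(m < 0 for m in self.mu):
            raise ValueError("population means must be nonnegative")


@dataclass(frozen=True)
class PerSpeciesNoise:
    """Per-species library-construction noise.

    ``modes[i]`` is 'sequestering' (Bernoulli, parameter ``params[i]`` = p_i)
    or 'non_sequestering' (Poisson cDNA yield, ``params[i]`` = lambda_i).
    In the lambda << 1 limit the two modes agree to first order.
    """

    modes: tuple[str, ...]
    params: tuple[float, ...]

    def __post_init__(self):
        if len(self.modes) != len(self.params):
            raise ValueError("modes and params must have equal length")
        for mode, val in zip(self.modes, self.params):
            if mode == "sequestering":
                if not 0.0 <= val <= 1.0:
                    raise ValueError("sequestering probability must lie in [0, 1]")
            elif mode == "non_sequestering":
                if val < 0:
                    raise ValueError("capture rate must be nonnegative")
            else:
                raise ValueError(f"unknown noise mode {mode!r}")

    @classmethod
    def sequestering(cls, *p: float) -> "PerSpeciesNoise":
        return cls(("sequestering",) * len(p), tuple(p))

    @classmethod
    def non_sequestering(cls, *lam: float) -> "PerSpeciesNoise":
        return cls(("non_sequestering",) * len(lam), tuple(lam))


@dataclass(frozen=True)
class AmbiguityMatrix:
    """Row-stochastic n x n_bar map from source species to read classes."""

    P: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or np.any(P < 0) or np.any(P > 1):
            raise ValueError("ambiguity matrix entries must lie in [0, 1]")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each ambiguity row must sum to 1")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class LengthNoiseModel:
    """Length-scaled nascent capture rates: lambda_{j,N} = C_N L_j, lambda_{j,M} = lambda_M."""

    C_N: float
    lam_M: float
    lengths: tuple[float, ...]

    def __post_init__(self):
        if self.C_N < 0 or self.lam_M < 0:
            raise ValueError("rates must be nonnegative")

    def nascent_rates(self) -> np.ndarray:
        return self.C_N * np.asarray(self.lengths, dtype=float)

    def per_gene_noise(self, j: int) -> PerSpeciesNoise:
        return PerSpeciesNoise.non_sequestering(self.C_N * self.lengths[j], self.lam_M)


# ---------------------------------------------------------------------------
# Stage constructors
# ---------------------------------------------------------------------------

def encapsulation_gf(spec: EncapsulationSpec, G: GFEvaluator) -> GFEvaluator:
    """Compose the cells-per-droplet PGF with the per-cell GF."""
    if spec.scheme == "bernoulli":
        p = spec.p
        return lambda u: p * G(u) + (1.0 - p)
    if spec.scheme == "binomial":
        p = spec.p
        return lambda u: (p * G(u) + (1.0 - p)) ** 2
    lam = spec.lam
    return lambda u: np.exp(lam * (G(u) - 1.0))


def background_gf(spec: BackgroundSpec) -> GFEvaluator:
    """Independent-Poisson ambient debris, mean ``c * mu_i`` per species."""
    mu = np.asarray(spec.mu, dtype=float)

    def G(u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(np.asarray(u, dtype=complex))
        return np.exp(spec.c * (mu[: u.shape[0], None] * u).sum(axis=0))

    return G


def library_substitution(noise: PerSpeciesNoise) -> Callable[[np.ndarray], np.ndarray]:
    """Spectral substitution ``u_i -> Gt*_i(u_i)`` for library construction."""

    def substitute(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=complex)
        out = u.copy()
        for i, (mode, val) in enumerate(zip(noise.modes, noise.params)):
            if i >= u.shape[0]:
                break
            if mode == "sequestering":
                out[i] = val * u[i]
            else:
                out[i] = np.expm1(val * u[i])
        return out

    return substitute


def library_gf(noise: PerSpeciesNoise, G: GFEvaluator) -> GFEvaluator:
    """Compose a model GF with the library-construction substitution."""
    sub = library_substitution(noise)
    return lambda u: G(sub(u))


def ambiguity_transform(P: AmbiguityMatrix, u_observed: np.ndarray) -> np.ndarray:
    """Map observed-class spectral points to source-species points: ``P @ u``.

    In shifted coordinates the categorical parsing law acts linearly, so a
    full collapse (single read class) sets every source coordinate to the one
    observed coordinate.
    """
    u_observed = np.asarray(u_observed, dtype=complex)
    return P.P @ u_observed


def compose_full(
    G: GFEvaluator,
    encapsulation: EncapsulationSpec | None = None,
    background: BackgroundSpec | None = None,
    library: PerSpeciesNoise | None = None,
    ambiguity: AmbiguityMatrix | None = None,
) -> GFEvaluator:
    """Full observed-count GF: ``[Genc(G) * Gbg] o Gt* o Ga*``.

    Every stage is optional and defaults to the identity.  The returned
    evaluator takes observed-class spectral points; with an ambiguity matrix
    of shape (n, n_bar) these have n_bar discrete coordinates.
    """
    inner: GFEvaluator = G
    if encapsulation is not None:
        inner = encapsulation_gf(encapsulation, inner)
    if background is not None:
        bg = background_gf(background)
        cell_stage = inner
        inner = lambda u: cell_stage(u) * bg(u)
    if library is not None:
        inner = library_gf(library, inner)
    if ambiguity is not None:
        staged = inner
        inner = lambda u: staged(ambiguity_transform(ambiguity, u))
    return inner
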