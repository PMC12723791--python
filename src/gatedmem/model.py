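"""Quenched disorder and nonlinearities of the gated associative memory network.

The model is a two-layer recurrent network: a neuronal layer ``x`` with
symmetric Hebbian couplings built from ``P`` stored patterns, and an
auxiliary neuromodulator layer ``z`` with asymmetric Gaussian couplings
``W``.  Each neuron's drift is multiplied by a logistic gate ``sigma(z_i)``
of steepness ``gamma``, so the gate acts as an activity-dependent rescaling
of the neuron's effective integration time-constant.

Scaling conventions (kept fixed throughout the package):

* recurrent drive ``(g / sqrt(P N)) * J @ phi(x)`` with ``J = Xi^T Xi``,
* modulator drive ``(1 / sqrt(N)) * W @ phi(x)``,

which keep both terms O(1) at order-one memory load ``alpha = P/N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "BINARY_GATE",
    "PatternSet",
    "NetworkSpec",
    "NetworkState",
    "sample_patterns",
    "make_orthogonal_pair",
    "build_hebbian_couplings",
    "hebbian_diagonal",
    "activation",
    "activation_prime",
    "gate",
    "recurrent_drive",
    "make_network",
]

#: Sentinel for the binary (step-function) gating limit gamma -> infinity.
BINARY_GATE = np.inf


class ParameterError(ValueError):
    """Invalid model parameter."""


@dataclass
class PatternSet:
    """Stored patterns; rows of ``patterns`` are the memorized configurations."""

    patterns: np.ndarray  # (P, N)
    kind: str = "binary"  # "binary" | "gaussian"

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 2:
            raise ParameterError("patterns must be a P x N matrix")
        if self.kind not in ("binary", "gaussian"):
            raise ParameterError(f"unknown pattern kind {self.kind!r}")
        if self.kind == "binary" and not np.all(np.abs(self.patterns) == 1.0):
            raise ParameterError("binary patterns must have entries in {-1, +1}")

    @property
    def P(self) -> int:
        return self.patterns.shape[0]

    @property
    def N(self) -> int:
        return self.patterns.shape[1]


@dataclass
class NetworkSpec:
    """Static parameters and quenched disorder of one network realization.

    ``W`` may be ``None`` for ungated runs (``gamma == 0``), where the gate is
    identically 1/2 and the modulator layer never feeds back on ``x``.
    """

    patterns: PatternSet
    g: float = 1.5
    gamma: float = 0.0
    tau_z: float = 1.0
    W: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ParameterError("gamma must be nonnegative (or inf)")
        if self.tau_z <= 0:
            raise ParameterError("tau_z must be positive")
        if self.W is not None:
            self.W = np.asarray(self.W, dtype=float)
            if self.W.shape != (self.N, self.N):
                raise ParameterError("W must be N x N")

    @property
    def N(self) -> int:
        return self.patterns.N

    @property
    def P(self) -> int:
        return self.patterns.P

    @property
    def alpha(self) -> float:
        return self.P / self.N


@dataclass
class NetworkState:
    """Instantaneous state of the two layers at time ``t``."""

    x: np.ndarray
    z: np.ndarray | None = None
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape != self.x.shape:
                raise ParameterError("x and z must have equal length")

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.x.copy(), None if self.z is None else self.z.copy(), self.t
        )


def sample_patterns(
    N: int, P: int, kind: str = "binary", rng: np.random.Generator | int | None = None
) -> PatternSet:
    """Draw ``P`` iid random patterns of length ``N``.

    ``binary`` patterns are uniform on {-1, +1}; ``gaussian`` patterns are
    standard normal.  Both have zero mean and unit variance per entry.
    """
    if N < 2 or P < 1:
        raise ParameterError(f"need N >= 2 and P >= 1, got N={N}, P={P}")
    rng = np.random.default_rng(rng)
    if kind == "binary":
        pats = rng.integers(0, 2, size=(P, N)) * 2.0 - 1.0
    elif kind == "gaussian":
        pats = rng.standard_normal((P, N))
    else:
        raise ParameterError(f"unknown pattern kind {kind!r}")
    return PatternSet(pats, kind)


def make_orthogonal_pair(
    N: int, rng: np.random.Generator | int | None = None
) -> PatternSet:
    """Two exactly orthogonal +/-1 patterns.

    ``xi1`` is uniform on {-1,+1}^N; ``xi2`` flips the sign of exactly N/2
    randomly chosen components of ``xi1``, which forces ``xi1 @ xi2 == 0``.
    """
    if N % 2 != 0:
        raise ParameterError("orthogonal pair construction requires even N")
    rng = np.random.default_rng(rng)
    xi1 = rng.integers(0, 2, size=N) * 2.0 - 1.0
    flip = rng.choice(N, size=N // 2, replace=False)
    xi2 = xi1.copy()
    xi2[flip] *= -1.0
    return PatternSet(np.stack([xi1, xi2]), "binary")


def build_hebbian_couplings(patterns: PatternSet) -> np.ndarray:
    """Dense symmetric Hebbian matrix J = sum_mu xi^mu (xi^mu)^T (rank <= P)."""
    Xi = patterns.patterns
    return Xi.T @ Xi


def activation(x: np.ndarray) -> np.ndarray:
    """Neuronal input-output nonlinearity phi(x) = tanh(x)."""
    return np.tanh(x)


def activation_prime(x: np.ndarray) -> np.ndarray:
    """Derivative phi'(x) = 1 - tanh(x)^2."""
    t = np.tanh(x)
    return 1.0 - t * t


def gate(z: np.ndarray, gamma: float) -> np.ndarray:
    """Neuromodulatory gate sigma(z) in [0, 1].

    Logistic ``1 / (1 + exp(-gamma z))`` for finite gamma; identically 1/2
    at gamma = 0; in the binary limit (gamma = inf) an exact step function
    with sigma(0) = 1/2 (pointwise limit of the logistic family).
    """
    z = np.asarray(z, dtype=float)
    if gamma < 0:
        raise ParameterError("gamma must be nonnegative (or inf)")
    if gamma == 0:
        return np.full_like(z, 0.5)
    if np.isinf(gamma):
        out = np.where(z > 0, 1.0, 0.0)
        return np.where(z == 0, 0.5, out)
    return expit(gamma * z)


def hebbian_diagonal(patterns: PatternSet) -> np.ndarray:
    """Diagonal of J, d_i = sum_mu (xi_i^mu)^2 (equal to P for binary patterns)."""
    return np.sum(patterns.patterns**2, axis=0)


def recurrent_drive(spec: NetworkSpec, phi: np.ndarray) -> np.ndarray:
    """Hebbian drive (g / sqrt(P N)) * sum_{j != i} J_ij phi_j, low-rank form.

    The autapse (J_ii) term is excluded: each neuron is driven by the other
    neurons only.  Computed as ``(g/sqrt(PN)) * (Xi^T (Xi phi) - diag(J) phi)``
    which is O(PN) instead of O(N^2) and agrees with the masked dense
    product to rounding.  ``phi`` may carry leading batch dimensions
    (``(..., N)``).
    """
    Xi = spec.patterns.patterns
    phi = np.asarray(phi, dtype=float)
    if phi.shape[-1] != spec.N:
        raise ValueError(f"phi has length {phi.shape[-1]}, expected N={spec.N}")
    proj = phi @ Xi.T  # (..., P)
    return (spec.g / np.sqrt(spec.P * spec.N)) * (
        proj @ Xi - hebbian_diagonal(spec.patterns) * phi
    )


def make_network(
    N: int,
    P: int,
    gamma: float = 0.0,
    g: float = 1.5,
    tau_z: float = 1.0,
    kind: str = "binary",
    seed: int | None = None,
    with_modulator: bool | None = None,
) -> NetworkSpec:
    """Draw a full quenched-disorder realization (patterns and W) from one seed.

    Child streams are spawned from ``seed`` so patterns and W are
    independently reproducible.  ``W`` is drawn iid standard normal
    (asymmetric).  By default W is only materialized when the run is gated.
    """
    ss = np.random.SeedSequence(seed)
    rng_pat, rng_W = (np.random.default_rng(s) for s in ss.spawn(2))
    patterns = sample_patterns(N, P, kind, rng_pat)
    if with_modulator is None:
        with_modulator = gamma != 0
    W = rng_W.standard_normal((N, N)) if with_modulator else None
    return NetworkSpec(patterns=patterns, g=g, gamma=gamma, tau_z=tau_z, W=W, seed=seed)
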