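"""Nucleotide substitution models.

Continuous-time reversible substitution processes over the DNA alphabet
``{A, C, G, T}``: general time-reversible (GTR) rate matrices, finite-time
substitution probabilities, the Halpern-Bruno construction of
position-specific "foreground" matrices from a target equilibrium (a PWM
column), and the cross-functional change-time mixture used when the selection
regime of a residue switches along a branch (gain or loss of binding
function).

Rate matrices are normalised so that one unit of branch length corresponds to
one expected substitution per site at equilibrium; Newick branch lengths are
therefore on the usual substitutions-per-site scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm

ALPHABET = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "NUC_INDEX",
    "RateMatrix",
    "SubstProbMatrix",
    "FunctionalClass",
    "InvalidDistributionError",
    "DegenerateModelError",
    "InvalidBranchError",
    "build_gtr",
    "jukes_cantor",
    "substitution_probabilities",
    "halpern_bruno",
    "stationary_distribution",
    "cross_functional_matrix",
]


class InvalidDistributionError(ValueError):
    """A probability vector is not a valid distribution."""


class DegenerateModelError(ValueError):
    """Model parameters define a degenerate (zero-rate) process."""


class InvalidBranchError(ValueError):
    """A branch length is negative or otherwise unusable."""


@dataclass(frozen=True)
class RateMatrix:
    """An instantaneous substitution rate matrix with its equilibrium.

    Attributes
    ----------
    rates
        4x4 matrix; off-diagonals are instantaneous i->j rates, each row
        sums to zero.
    equilibrium
        Stationary nucleotide distribution (left null vector of ``rates``).
    """

    rates: np.ndarray
    equilibrium: np.ndarray
    _spectral: tuple | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        eq = np.asarray(self.equilibrium, dtype=float)
        if rates.shape != (4, 4):
            raise ValueError("rate matrix must be 4x4")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "equilibrium", eq)
        if not np.allclose(rates.sum(axis=1), 0.0, atol=1e-8):
            raise ValueError("rate matrix rows must sum to 0")
        off = rates[~np.eye(4, dtype=bool)]
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.any(eq <= 0) or abs(eq.sum() - 1.0) > 1e-8:
            raise InvalidDistributionError(
                "equilibrium must be strictly positive and sum to 1"
            )

    @property
    def spectral(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition ``(eigenvalues d, M, M_inv)`` with Q = M diag(d) M^-1.

        Reversible matrices are symmetrised with ``diag(pi)^{1/2}`` before the
        (then symmetric-eigenvalue) decomposition, which keeps the
        decomposition real and well conditioned.  Cached per instance.
        """
        if self._spectral is None:
            object.__setattr__(self, "_spectral", _decompose(self))
        return self._spectral

    def expected_rate(self) -> float:
        """Expected substitutions per unit time at equilibrium."""
        return float(-np.dot(self.equilibrium, np.diag(self.rates)))

    def is_reversible(self, atol: float = 1e-8) -> bool:
        flux = self.equilibrium[:, None] * self.rates
        return bool(np.allclose(flux, flux.T, atol=atol))


@dataclass(frozen=True)
class SubstProbMatrix:
    """Finite-time conditional substitution probabilities P(a2 | a1) at branch t."""

    probs: np.ndarray
    t: float

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("substitution probability rows must sum to 1")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError("substitution probabilities must lie in [0, 1]")

    @property
    def log_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(np.clip(self.probs, 0.0, None))


@dataclass(frozen=True)
class FunctionalClass:
    """A selection regime: a label plus the rate matrix it evolves under.

    ``bg`` denotes neutral background; site classes are the per-column
    Halpern-Bruno regimes of a binding profile (one class per PWM column and
    strand).
    """

    id: str
    rate_matrix: RateMatrix

    def __hash__(self):
        return hash(self.id)

    def __eq__(self, other):
        return isinstance(other, FunctionalClass) and self.id == other.id


def _decompose(q: RateMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if q.is_reversible():
        # symmetrise: S = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        sqrt_pi = np.sqrt(q.equilibrium)
        s = sqrt_pi[:, None] * q.rates / sqrt_pi[None, :]
        s = (s + s.T) / 2.0
        d, u = np.linalg.eigh(s)
        m = u / sqrt_pi[:, None]
        m_inv = u.T * sqrt_pi[None, :]
        return d, m, m_inv
    d, m = np.linalg.eig(q.rates)
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("rate matrix is not safely diagonalizable")
    return d, m, np.linalg.inv(m)


def build_gtr(exchangeabilities, equilibrium) -> RateMatrix:
    """Build a normalised GTR rate matrix.

    Parameters
    ----------
    exchangeabilities
        Six symmetric exchange parameters in the order
        (AC, AG, AT, CG, CT, GT); all must be >= 0 with at least one > 0.
    equilibrium
        Target stationary distribution over (A, C, G, T).

    The result satisfies detailed balance ``pi_i q_ij = pi_j q_ji`` and is
    scaled to one expected substitution per unit branch length.
    """
    ex = np.asarray(exchangeabilities, dtype=float)
    eq = np.asarray(equilibrium, dtype=float)
    if ex.shape != (6,):
        raise ValueError("expected 6 exchangeabilities (AC, AG, AT, CG, CT, GT)")
    if np.any(eq <= 0) or abs(eq.sum() - 1.0) > 1e-8:
        raise InvalidDistributionError(
            "equilibrium must be strictly positive and sum to 1"
        )
    if np.any(ex < 0):
        raise ValueError("exchangeabilities must be non-negative")
    if np.all(ex == 0):
        raise DegenerateModelError("all exchangeabilities are zero")

    s = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for k, (i, j) in enumerate(pairs):
        s[i, j] = s[j, i] = ex[k]
    rates = s * eq[None, :]
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    scale = -np.dot(eq, np.diag(rates))
    if scale <= 0:
        raise DegenerateModelError("zero expected substitution rate")
    return RateMatrix(rates / scale, eq)


def jukes_cantor() -> RateMatrix:
    """The Jukes-Cantor matrix (uniform equilibrium, equal rates, scaled to 1)."""
    return build_gtr(np.ones(6), np.full(4, 0.25))


def substitution_probabilities(q: RateMatrix, t: float) -> SubstProbMatrix:
    """Finite-time substitution matrix ``expm(t * Q)``."""
    if t < 0:
        raise InvalidBranchError(f"negative branch length {t}")
    if t == 0:
        return SubstProbMatrix(np.eye(4), 0.0)
    p = expm(t * q.rates)
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    return SubstProbMatrix(p, t)


def stationary_distribution(q: RateMatrix) -> np.ndarray:
    """Unique left null vector of the rate matrix, normalised to sum 1."""
    w, v = np.linalg.eig(q.rates.T)
    idx = np.where(np.abs(w) < 1e-9)[0]
    if len(idx) == 0:
        raise ValueError("no stationary distribution found")
    if len(idx) > 1:
        raise ValueError("stationary distribution is not unique (reducible matrix)")
    pi = np.real(v[:, idx[0]])
    pi = pi / pi.sum()
    if np.any(pi < -1e-9):
        raise ValueError("stationary vector has negative entries")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def halpern_bruno(background: RateMatrix, target_dist) -> RateMatrix:
    """Halpern-Bruno foreground rate matrix for a PWM column.

    Scales each background rate ``q_ij`` by the fixation factor
    ``ln(x) / (1 - 1/x)`` with ``x = (pi_j q_ji) / (pi_i q_ij)`` for the
    target distribution ``pi``.  The result is reversible with stationary
    distribution exactly ``target_dist`` and stays on the background's time
    scale (selection slows the site; no renormalisation is applied).
    """
    pi = np.asarray(target_dist, dtype=float)
    if pi.shape != (4,):
        raise ValueError("target distribution must have 4 entries")
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise InvalidDistributionError(
            "target distribution must be strictly positive and sum to 1 "
            "(apply pseudocounts upstream)"
        )
    if not background.is_reversible():
        raise ValueError("Halpern-Bruno requires a reversible background matrix")

    q = background.rates
    rates = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j or q[i, j] == 0:
                continue
            x = (pi[j] * q[j, i]) / (pi[i] * q[i, j])
            rates[i, j] = q[i, j] * _fixation_factor(x)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    return RateMatrix(rates, pi)


def _fixation_factor(x: float) -> float:
    # x*ln(x)/(x-1), continuous at x=1 with value 1
    if abs(x - 1.0) < 1e-9:
        return 1.0
    return x * np.log(x) / (x - 1.0)


def cross_functional_matrix(
    ancestor_class: FunctionalClass,
    descendant_class: FunctionalClass,
    t: float,
    quadrature_fallback: bool = True,
) -> SubstProbMatrix:
    """Change-time mixture substitution matrix ``P_{B->b}(t)``.

    A residue evolves under the ancestral class ``B`` until an unobserved
    change time ``s`` (uniform on ``[0, t]``) and under the descendant class
    ``b`` thereafter:

        P_{B->b}(t) = (1/t) * integral_0^t  P_B(s) . P_b(t - s)  ds

    Evaluated in closed form from the spectral decompositions
    ``Q_B = M_1 D_1 M_1^-1`` and ``Q_b = M_2 D_2 M_2^-1``:

        P_{B->b}(t) = M_1 (K o Phi(t)) M_2^-1,   K = M_1^-1 M_2,
        Phi_ij(t) = (e^{d1_i t} - e^{d2_j t}) / (t (d1_i - d2_j)),

    with the analytic limit ``e^{d t}`` for (near-)coincident eigenvalue
    pairs.  Defective rate matrices fall back to adaptive numerical
    quadrature of the integral.
    """
    if t <= 0:
        raise InvalidBranchError("cross-functional mixture requires t > 0")
    if ancestor_class == descendant_class:
        return substitution_probabilities(ancestor_class.rate_matrix, t)
    qa = ancestor_class.rate_matrix
    qb = descendant_class.rate_matrix
    try:
        d1, m1, m1i = qa.spectral
        d2, m2, m2i = qb.spectral
    except np.linalg.LinAlgError:
        if not quadrature_fallback:
            raise
        return _mixture_by_quadrature(qa, qb, t)

    k = m1i @ m2
    diff = d1[:, None] - d2[None, :]
    near = np.abs(diff) < 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (np.exp(d1[:, None] * t) - np.exp(d2[None, :] * t)) / (t * diff)
    phi = np.where(near, np.exp(d2[None, :] * t), phi)
    p = m1 @ (k * phi) @ m2i
    p = np.real(p)
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    return SubstProbMatrix(p, t)


def _mixture_by_quadrature(qa: RateMatrix, qb: RateMatrix, t: float) -> SubstProbMatrix:
    p = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            f = lambda s: (expm(s * qa.rates) @ expm((t - s) * qb.rates))[i, j]
            val, _ = quad(f, 0.0, t, epsrel=1e-8, limit=200)
            p[i, j] = val / t
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    return SubstProbMatrix(p, t)
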