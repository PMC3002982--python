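"""Birth-death kinetics of whole binding sites.

A candidate interval in a regulatory region is either vacant or occupied by a
functional binding site.  Vacant intervals acquire a site at instantaneous
rate ``lambda`` (birth) and functional sites die at rate ``mu``.  For a
branch of length ``t`` this two-state process gives closed-form
probabilities:

* ``p(t)`` - a site present in the ancestor is retained in the descendant,
* ``q(t) = 1 - p(t)`` - the site is lost,
* ``b(t)`` - a vacant ancestral interval carries a site in the descendant,
* ``b_inf = lambda / (lambda + mu)`` - the long-time limit of ``b(t)``,
  equal to the stationary site density per candidate interval,
* ``s(t) = 1 - (1 - b_inf)(1 - b(t))`` - the probability of leaving the
  background model, which sets the total mass of gain + loss + retention
  transitions in the assembled CRM model.

The forms solve the linear system  dp/dt = -mu p + lambda q,
dq/dt = mu p - lambda q,  db/dt = lambda - (lambda + mu) b  with
p(0) = 1, q(0) = 0, b(0) = 0:

    p(t) = (lambda + mu e^{-(lambda+mu) t}) / (lambda + mu)
    q(t) = mu (1 - e^{-(lambda+mu) t}) / (lambda + mu)
    b(t) = lambda (1 - e^{-(lambda+mu) t}) / (lambda + mu)

Note the detailed-balance identity ``(1 - b_inf) b(t) = b_inf q(t)``: at
stationarity the flux of gains equals the flux of losses, which is what makes
the assembled background/site model reversible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .substitution import InvalidBranchError

__all__ = [
    "BirthDeathParams",
    "TurnoverProbs",
    "DegenerateProcessError",
    "turnover_probabilities",
    "background_exit",
    "derive_lambda",
]


class DegenerateProcessError(ValueError):
    """Both birth and death rates are zero."""


@dataclass(frozen=True)
class BirthDeathParams:
    """Birth rate ``birth_rate`` (lambda) and death rate ``death_rate`` (mu),
    both per unit branch length."""

    birth_rate: float
    death_rate: float

    def __post_init__(self):
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("birth and death rates must be non-negative")

    @property
    def asymptotic_gain(self) -> float:
        """``b_inf = lambda / (lambda + mu)``, the stationary site density."""
        total = self.birth_rate + self.death_rate
        if total == 0:
            raise DegenerateProcessError("lambda = mu = 0")
        return self.birth_rate / total


@dataclass(frozen=True)
class TurnoverProbs:
    """Gain/loss/retention probabilities for one branch."""

    t: float
    gain: float        # b(t)
    loss: float        # q(t)
    retention: float   # p(t)
    background_exit: float  # s(t)
    asymptotic_gain: float  # b_inf


def turnover_probabilities(params: BirthDeathParams, t: float) -> TurnoverProbs:
    """Closed-form ``(b, p, q, s)`` for a branch of length ``t``."""
    if t < 0:
        raise InvalidBranchError(f"negative branch length {t}")
    lam, mu = params.birth_rate, params.death_rate
    total = lam + mu
    if total == 0:
        raise DegenerateProcessError("lambda = mu = 0")
    b_inf = lam / total
    decay = math.exp(-total * t)
    b = b_inf * (1.0 - decay)
    q = (mu / total) * (1.0 - decay)
    p = 1.0 - q
    b = min(max(b, 0.0), b_inf)  # guard round-off at t ~ 0
    s = 1.0 - (1.0 - b_inf) * (1.0 - b)
    return TurnoverProbs(
        t=t, gain=b, loss=q, retention=p, background_exit=s, asymptotic_gain=b_inf
    )


def background_exit(params: BirthDeathParams, t: float) -> float:
    """``s(t) = 1 - (1 - b_inf)(1 - b(t))``, the background-exit probability."""
    return turnover_probabilities(params, t).background_exit


def derive_lambda(delta: float, mu: float) -> float:
    """Birth rate from the target site density: ``lambda = delta mu / (1 - delta)``.

    With this constraint the stationary density ``b_inf`` equals ``delta``
    exactly.
    """
    if not 0 <= delta < 1:
        raise ValueError(f"site density delta must lie in [0, 1), got {delta}")
    if mu <= 0:
        raise ValueError("death rate mu must be positive")
    return delta * mu / (1.0 - delta)
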