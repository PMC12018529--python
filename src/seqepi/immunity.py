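"""Partial-immunity models for the second epidemic.

The second epidemic is parametrised by four contact probabilities
pi_ij (i, j in {0, 1}): the probability that an infectious individual
with first-epidemic status i (1 = previously infected) makes infectious
contact with a given neighbour of status j.  Special cases:

* leaky (multiplicative): pi = (p', aS p', aI p', aS aI p') -- prior
  infection scales susceptibility by alpha_S and infectivity by alpha_I
  on every contact;
* leaky (rate-based): the scaling acts on contact rates inside the
  exponential, pi_ij = 1 - exp(-beta' * scale * ell);
* polarized (all-or-nothing): a prior case is fully susceptible with
  probability alpha, otherwise fully immune; on the forward tree this is
  equivalent to pi = (p', alpha p', p', alpha p').

This module also locates the critical immunity parameter alpha_c at
which the second-epidemic reproduction number equals one, both via the
closed-form quadratic (polarized, p' = p) and by bisection on
R0_2(alpha) = 1 for any model builder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .degrees import DegreeDistribution
from .first_epidemic import R0_first, solve_q_tilde
from .forward import LabelMeans, R0_second, label_means, offspring_matrix

__all__ = [
    "ImmunityModel",
    "general",
    "pi_from_rates",
    "leaky_multiplicative",
    "leaky_rates",
    "polarized",
    "alpha_c_polarized_quadratic",
    "alpha_c_numeric",
]

_KINDS = ("general", "leaky_multiplicative", "leaky_rates", "polarized")


def _check_prob(name: str, x: float) -> float:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return float(x)


@dataclass(frozen=True)
class ImmunityModel:
    """Second-epidemic contact-probability table with a variant tag.

    ``kind`` determines how the backward (susceptibility-set) process is
    built: the polarized model needs the alpha-mixture PGFs,
    everything else uses the plain transposed table.
    """

    kind: str
    pi_00: float
    pi_01: float
    pi_10: float
    pi_11: float
    alpha: float | None = None
    alpha_S: float | None = None
    alpha_I: float | None = None
    p_prime: float | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown immunity kind {self.kind!r}")
        for name in ("pi_00", "pi_01", "pi_10", "pi_11"):
            _check_prob(name, getattr(self, name))

    @property
    def pi_matrix(self) -> np.ndarray:
        """2x2 array pi[i, j] indexed by first-epidemic status."""
        return np.array([[self.pi_00, self.pi_01], [self.pi_10, self.pi_11]])


def general(pi_00: float, pi_01: float, pi_10: float, pi_11: float) -> ImmunityModel:
    """Arbitrary contact-probability table."""
    return ImmunityModel("general", pi_00, pi_01, pi_10, pi_11)


def pi_from_rates(
    beta_00: float,
    beta_01: float,
    beta_10: float,
    beta_11: float,
    ell_0: float = 1.0,
    ell_1: float = 1.0,
) -> ImmunityModel:
    """General model from contact rates: pi_ij = 1 - exp(-beta_ij * ell_i)."""
    for name, b in (("beta_00", beta_00), ("beta_01", beta_01),
                    ("beta_10", beta_10), ("beta_11", beta_11)):
        if b < 0:
            raise ValueError(f"{name} must be non-negative")
    if ell_0 <= 0 or ell_1 <= 0:
        raise ValueError("infectious periods must be positive")
    e = lambda b, ell: -float(np.expm1(-b * ell))
    return ImmunityModel(
        "general",
        pi_00=e(beta_00, ell_0),
        pi_01=e(beta_01, ell_0),
        pi_10=e(beta_10, ell_1),
        pi_11=e(beta_11, ell_1),
    )


def leaky_multiplicative(p_prime: float, alpha_S: float, alpha_I: float) -> ImmunityModel:
    """Leaky immunity acting multiplicatively on transmission probabilities."""
    p_prime = _check_prob("p_prime", p_prime)
    alpha_S = _check_prob("alpha_S", alpha_S)
    alpha_I = _check_prob("alpha_I", alpha_I)
    return ImmunityModel(
        "leaky_multiplicative",
        pi_00=p_prime,
        pi_01=alpha_S * p_prime,
        pi_10=alpha_I * p_prime,
        pi_11=alpha_S * alpha_I * p_prime,
        alpha_S=alpha_S,
        alpha_I=alpha_I,
        p_prime=p_prime,
    )


def leaky_rates(
    beta_prime: float,
    alpha_S: float,
    alpha_I: float,
    ell_0: float = 1.0,
    ell_1: float = 1.0,
) -> ImmunityModel:
    """Leaky immunity acting on contact rates (vaccine-action formulation)."""
    if beta_prime < 0:
        raise ValueError("beta_prime must be non-negative")
    alpha_S = _check_prob("alpha_S", alpha_S)
    alpha_I = _check_prob("alpha_I", alpha_I)
    if ell_0 <= 0 or ell_1 <= 0:
        raise ValueError("infectious periods must be positive")
    e = lambda rate, ell: -float(np.expm1(-rate * ell))
    return ImmunityModel(
        "leaky_rates",
        pi_00=e(beta_prime, ell_0),
        pi_01=e(beta_prime * alpha_S, ell_0),
        pi_10=e(beta_prime * alpha_I, ell_1),
        pi_11=e(beta_prime * alpha_S * alpha_I, ell_1),
        alpha_S=alpha_S,
        alpha_I=alpha_I,
    )


def polarized(p_prime: float, alpha: float) -> ImmunityModel:
    """All-or-nothing immunity: a prior case keeps full susceptibility with
    probability alpha, else is fully immune (forward-equivalent table)."""
    p_prime = _check_prob("p_prime", p_prime)
    alpha = _check_prob("alpha", alpha)
    return ImmunityModel(
        "polarized",
        pi_00=p_prime,
        pi_01=alpha * p_prime,
        pi_10=p_prime,
        pi_11=alpha * p_prime,
        alpha=alpha,
        p_prime=p_prime,
    )


def alpha_c_polarized_quadratic(lm: LabelMeans, p: float) -> float:
    """Critical alpha for polarized immunity with p' = p: smallest root in
    [0, 1] of the quadratic

        p^3 (1 - p muBB)(muAA muBB - muAB muBA) a^2
        - p [(1 - p muBB)(muAA + p muBB) + p(1-p) muAB muBA] a
        + 1 - p muBB = 0.

    The roots are computed in a cancellation-safe form; a numerically
    degenerate leading coefficient falls back to the linear root.
    """
    muAA, muAB, muBA, muBB = lm.mu_AA, lm.mu_AB, lm.mu_BA, lm.mu_BB
    a = p**3 * (1.0 - p * muBB) * (muAA * muBB - muAB * muBA)
    b = -p * ((1.0 - p * muBB) * (muAA + p * muBB) + p * (1.0 - p) * muAB * muBA)
    c = 1.0 - p * muBB
    if abs(a) < 1e-12 * max(abs(b), 1.0):
        if b == 0.0:
            raise ValueError("degenerate quadratic: no alpha_c root")
        root = -c / b
        if not -1e-10 <= root <= 1.0 + 1e-10:
            raise ValueError("no alpha_c root in [0, 1]")
        return min(max(root, 0.0), 1.0)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError("no real alpha_c root (preconditions violated?)")
    sq = float(np.sqrt(disc))
    # stable pair: r1 via the larger-magnitude sum, r2 via Vieta
    r1 = (-b + sq) / (2.0 * a) if b < 0 else (-b - sq) / (2.0 * a)
    r2 = c / (a * r1) if r1 != 0 else (-b - sq) / (2.0 * a)
    roots = sorted([r1, r2])
    in_range = [r for r in roots if -1e-10 <= r <= 1.0 + 1e-10]
    if not in_range:
        raise ValueError("no alpha_c root in [0, 1]")
    return min(max(in_range[0], 0.0), 1.0)


def R0_second_of_model(
    dist: DegreeDistribution, p: float, im: ImmunityModel, q_tilde: float | None = None
) -> float:
    """R0_2 for a given first-epidemic p and immunity model."""
    if q_tilde is None:
        q_tilde = solve_q_tilde(dist, p)
    lm = label_means(dist, p, q_tilde)
    return R0_second(offspring_matrix(lm, im, p))


def alpha_c_numeric(
    dist: DegreeDistribution,
    p: float,
    model_builder: Callable[[float], ImmunityModel],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Bisection root of R0_2(alpha) = 1 on [0, 1].

    ``model_builder`` maps alpha to an :class:`ImmunityModel` (leaky or
    polarized).  R0_2(alpha) is continuous and strictly increasing, and a
    supercritical first epidemic guarantees R0_2(0) < 1 < R0_2(1) when the
    unrestricted second epidemic is supercritical.
    """
    if R0_first(dist, p) <= 1.0:
        raise ValueError("alpha_c requires a supercritical first epidemic")
    q_tilde = solve_q_tilde(dist, p)
    lm = label_means(dist, p, q_tilde)

    def r0(alpha: float) -> float:
        return R0_second(offspring_matrix(lm, model_builder(alpha), p))

    lo, hi = 0.0, 1.0
    f_lo, f_hi = r0(lo) - 1.0, r0(hi) - 1.0
    if f_lo >= 0 or f_hi <= 0:
        raise ValueError(
            f"alpha_c bracket failure: R0_2(0)-1={f_lo:.3g}, R0_2(1)-1={f_hi:.3g}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if r0(mid) - 1.0 <= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
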