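"""First-epidemic analysis via bond percolation.

With a constant infectious period (scaled to one time unit) the SIR
epidemic on the network has the same final-size law as bond percolation
with per-edge retention probability ``p = 1 - exp(-beta)``.  The basic
reproduction number is ``R0_1 = p E[D-tilde - 1]``; the probability that
the cluster of a uniformly chosen seed stays small is

    q = f_D(1 - p + p q_tilde),

where ``q_tilde`` is the smallest solution in [0, 1] of the fixed-point
equation ``s = f_{D-tilde-1}(1 - p + p s)``.  Both the major-outbreak
probability and (conditional on a major outbreak) the infected fraction
converge to ``1 - q``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .degrees import DegreeDistribution

__all__ = [
    "PercolationSummary",
    "edge_prob_from_rate",
    "R0_first",
    "solve_q_tilde",
    "first_outbreak",
]


@dataclass(frozen=True)
class PercolationSummary:
    """First-epidemic asymptotics: transmission probability p, R0_1, the
    branching-process extinction probabilities q_tilde (edge-level) and q
    (vertex-level), and whether the epidemic is supercritical."""

    p: float
    R0_1: float
    q_tilde: float
    q: float
    supercritical: bool

    @property
    def major_outbreak_probability(self) -> float:
        return 1.0 - self.q

    @property
    def attack_rate(self) -> float:
        """Fraction infected given a major outbreak (= outbreak probability
        because the infectious period is constant)."""
        return 1.0 - self.q


def edge_prob_from_rate(beta: float) -> float:
    """Per-edge transmission probability 1 - e^{-beta} (unit infectious period)."""
    if beta < 0:
        raise ValueError("contact rate beta must be non-negative")
    return -float(np.expm1(-beta))


def R0_first(dist: DegreeDistribution, p: float) -> float:
    """R0 of the first epidemic: p * E[D-tilde - 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return p * dist.mean_excess_degree()


def _check_pathological(dist: DegreeDistribution, p: float) -> None:
    # all-degree-2 with p=1: every component is a cycle traversed surely;
    # q_tilde is ill-defined (every s in [0,1] solves s = s).
    if p == 1.0 and abs(dist.pmf(2) - 1.0) < 1e-12:
        raise ValueError(
            "degenerate case: all vertices have degree 2 and p = 1 "
            "(fixed-point equation is the identity)"
        )


def solve_q_tilde(
    dist: DegreeDistribution,
    p: float,
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> float:
    """Smallest solution in [0, 1] of s = f_{D-tilde-1}(1 - p + p s).

    Monotone fixed-point iteration from 0 converges to the smallest root
    because the map is a PGF composition (increasing and convex).
    Subcritical inputs return 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    _check_pathological(dist, p)
    if R0_first(dist, p) <= 1.0:
        return 1.0
    s = 0.0
    for _ in range(max_iter):
        s_next = dist.pgf_excess(1.0 - p + p * s)
        if abs(s_next - s) < tol:
            return s_next
        s = s_next
    raise RuntimeError("q_tilde fixed-point iteration did not converge")


def first_outbreak(dist: DegreeDistribution, p: float) -> PercolationSummary:
    """Full first-epidemic summary: R0_1, q_tilde, q = f_D(1-p+p*q_tilde)."""
    r0 = R0_first(dist, p)
    q_tilde = solve_q_tilde(dist, p)
    q = dist.pgf(1.0 - p + p * q_tilde)
    return PercolationSummary(
        p=p, R0_1=r0, q_tilde=q_tilde, q=q, supercritical=r0 > 1.0
    )
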