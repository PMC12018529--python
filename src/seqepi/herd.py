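"""Disease-induced herd immunity under complete infection-acquired immunity.

When the first epidemic confers complete immunity (pi_11 = pi_01 = 0)
the second epidemic spreads only among first-epidemic escapees and its
early phase is a single-type branching process with offspring mean

    R0_2 = pi_00 * E[(D-tilde - 1)(1 - p + p q_tilde)^{D-tilde - 2}]
         = pi_00 * f_D''(1 - p + p q_tilde) / mu_D.

Given an unrestricted reproduction number R0' = pi_00 E[D-tilde - 1] > 1,
the herd-immunity threshold is the first-epidemic transmission
probability p' at which R0_2 = 1; the immune fraction it leaves behind
is 1 - q'.  For Poisson-type degree distributions (f_D' proportional to
a power of f_D, with exponent kappa) the threshold has the closed form
q' = (1/R0')^{1/(2 kappa - 1)}, which for kappa > 1 undershoots the
homogeneous-mixing benchmark 1 - 1/R0'.
"""

from __future__ import annotations

from dataclasses import dataclass

from .degrees import DegreeDistribution
from .first_epidemic import solve_q_tilde

__all__ = [
    "HerdImmunityResult",
    "R0_second_complete_immunity",
    "critical_p_for_herd_immunity",
    "poisson_type_q_prime",
    "poisson_type_kappa",
    "check_overshoot_inequality",
]


@dataclass(frozen=True)
class HerdImmunityResult:
    """Herd-immunity threshold after a first outbreak.

    ``p_crit`` is the first-epidemic transmission probability at which
    the second epidemic is critical; ``immune_fraction`` = 1 - q' is the
    disease-induced herd immunity level; ``hom_benchmark`` = 1 - 1/R0'
    is the classical uniform-immunisation level for comparison.
    """

    R0_prime: float
    p_crit: float
    q_tilde_prime: float
    q_prime: float

    @property
    def immune_fraction(self) -> float:
        return 1.0 - self.q_prime

    @property
    def hom_benchmark(self) -> float:
        return 1.0 - 1.0 / self.R0_prime


def R0_second_complete_immunity(
    dist: DegreeDistribution, p: float, pi_00: float
) -> float:
    """Single-type R0 of a second epidemic among first-epidemic escapees."""
    q_tilde = solve_q_tilde(dist, p)
    x_star = 1.0 - p + p * q_tilde
    return pi_00 * dist.pgf_d2(x_star) / dist.mean


def critical_p_for_herd_immunity(
    dist: DegreeDistribution,
    pi_00: float,
    tol: float = 1e-10,
) -> HerdImmunityResult:
    """Bisection solve of R0_2(p) = 1 over p, with q_tilde(p) re-solved
    inside the objective (the objective is monotone non-increasing in p)."""
    r0_prime = pi_00 * dist.mean_excess_degree()
    if r0_prime <= 1.0:
        raise ValueError(
            "unrestricted second epidemic must be supercritical (R0' > 1)"
        )

    def r0_2(p: float) -> float:
        return R0_second_complete_immunity(dist, p, pi_00)

    # below first-epidemic criticality q_tilde = 1 and R0_2 = R0' > 1
    p_lo = 1.0 / dist.mean_excess_degree()
    p_hi = 1.0
    if r0_2(p_hi) >= 1.0:
        raise ValueError("no herd-immunity root: R0_2(1) >= 1")
    for _ in range(200):
        mid = 0.5 * (p_lo + p_hi)
        if r0_2(mid) >= 1.0:
            p_lo = mid
        else:
            p_hi = mid
        if p_hi - p_lo < tol:
            break
    p_crit = 0.5 * (p_lo + p_hi)
    qt = solve_q_tilde(dist, p_crit, tol=1e-12)
    q_prime = dist.pgf(1.0 - p_crit + p_crit * qt)
    return HerdImmunityResult(
        R0_prime=r0_prime, p_crit=p_crit, q_tilde_prime=qt, q_prime=q_prime
    )


def poisson_type_q_prime(R0_prime: float, kappa: float) -> float:
    """Closed-form q' = (1/R0')^{1/(2 kappa - 1)} for Poisson-type D.

    Poisson-type means f_D'(s) = f_D'(1) (f_D(s))^kappa; then
    q_tilde = q^kappa and the threshold equation collapses.  Requires
    kappa > 1/2 (the exponent diverges at kappa = 1/2).
    """
    if R0_prime <= 1.0:
        raise ValueError("R0' must exceed 1")
    if kappa <= 0.5:
        raise ValueError("kappa must exceed 1/2")
    return (1.0 / R0_prime) ** (1.0 / (2.0 * kappa - 1.0))


def poisson_type_kappa(dist: DegreeDistribution) -> float:
    """kappa for the Poisson-type families: Poisson -> 1; constant d
    (= Binomial(d, 1)) -> (d-1)/d.  Other families are not Poisson-type."""
    if dist.family == "poisson":
        return 1.0
    if dist.family == "constant":
        d = dist.params["d"]
        if d < 1:
            raise ValueError("constant degree must be >= 1")
        return (d - 1) / d
    raise ValueError(f"family {dist.family!r} is not Poisson-type")


def check_overshoot_inequality(
    dist: DegreeDistribution, pi_00: float
) -> tuple[bool, float]:
    """Whether 1 - q' <= 1 - 1/R0' (no overshoot past the uniform
    benchmark), with the signed margin q' - 1/R0'.

    Always true for Mixed-Poisson degree distributions; reversed for
    sub-Poisson families such as constant degree.
    """
    res = critical_p_for_herd_immunity(dist, pi_00)
    margin = res.q_prime - 1.0 / res.R0_prime
    return margin >= -1e-12, margin
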