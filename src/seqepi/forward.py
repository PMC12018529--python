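"""Forward three-type branching process for the second epidemic.

Conditional on a large first epidemic, the local structure around a
uniformly chosen vertex is a Galton-Watson tree whose edges are "red"
(first-epidemic transmission routes) independently with probability p.
Vertices fall into three types: type 1 (infected in the first epidemic,
with an infinite red path of descent), type 2 (infected, no red path of
descent) and type 3 (escaped the first epidemic).  Types 1 vs {2,3} are
also labelled A vs B.

The early second epidemic is a three-type Galton-Watson process whose
offspring mean matrix M is built from the label means mu_AA, mu_AB,
mu_BA, mu_BB and the contact probabilities pi_ij; its Perron root is the
second-epidemic reproduction number R0_2.  The extinction-probability
fixed point xi of the non-root offspring PGFs, combined with the root
PGFs f_1, f_3, yields the major-outbreak probability.

Note on mu_AB: the A->B label mean carries a q_tilde/(1-q_tilde)
prefactor arising from the Bayes inversion in its derivation; it is
validated here by the exact match between the Jacobian of the offspring
PGFs at (1,1,1) and M.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable

import numpy as np

from .degrees import DegreeDistribution
from .first_epidemic import first_outbreak

if TYPE_CHECKING:  # pragma: no cover
    from .immunity import ImmunityModel

__all__ = [
    "LabelMeans",
    "ForwardPGFs",
    "ForwardSolution",
    "label_means",
    "offspring_matrix",
    "R0_second",
    "forward_pgfs",
    "solve_fixed_point",
    "major_outbreak_probability",
    "root_type3_weight",
    "second_epidemic_forward",
]


@dataclass(frozen=True)
class LabelMeans:
    """Mean numbers of label-j children of a non-root label-i vertex."""

    mu_AA: float
    mu_AB: float
    mu_BA: float
    mu_BB: float


def label_means(dist: DegreeDistribution, p: float, q_tilde: float) -> LabelMeans:
    """Label means from the excess-degree PGF derivative at x* = 1-p+p*q_tilde.

    mu_AA = (f_D''(1) - (1-p) f_D''(x*)) / mu_D
    mu_AB = (q_tilde/(1-q_tilde)) (f_D''(1) - f_D''(x*)) / mu_D
    mu_BA = ((1-p)(1-q_tilde)/q_tilde) f_D''(x*) / mu_D
    mu_BB = f_D''(x*) / mu_D

    Requires 0 < q_tilde < 1 except at p = 1 where q_tilde = 0 is allowed:
    label B then has probability zero on the giant tree, mu_AB and mu_BB
    vanish in the limit, and the indeterminate mu_BA is set to 0 (the
    "sterile B" convention -- B rows never influence any observable when
    label B has measure zero).
    """
    if q_tilde >= 1.0:
        raise ValueError("label means require a supercritical first epidemic")
    mu = dist.mean
    x_star = 1.0 - p + p * q_tilde
    f2_1 = dist.pgf_d2(1.0)
    f2_x = dist.pgf_d2(x_star)
    mu_AA = (f2_1 - (1.0 - p) * f2_x) / mu
    if q_tilde == 0.0:
        if p < 1.0:
            raise ValueError("q_tilde = 0 with p < 1 is inconsistent")
        # p = 1: x* = 0; type-B vertices have no children in the giant tree.
        mu_AB = 0.0
        mu_BA = 0.0
        mu_BB = f2_x / mu
    else:
        mu_AB = q_tilde / (1.0 - q_tilde) * (f2_1 - f2_x) / mu
        mu_BA = (1.0 - p) * (1.0 - q_tilde) / q_tilde * f2_x / mu
        mu_BB = f2_x / mu
    return LabelMeans(mu_AA, mu_AB, mu_BA, mu_BB)


def offspring_matrix(lm: LabelMeans, im: "ImmunityModel", p: float) -> np.ndarray:
    """3x3 mean offspring matrix M of the forward process.

    Rows/columns are types 1, 2, 3.  A label-B child of a red parent is
    type 2 iff its parent's edge is red (probability p); blue parents only
    have type-3 label-B children, hence M[2,1] = 0.
    """
    return np.array(
        [
            [im.pi_11 * lm.mu_AA, p * im.pi_11 * lm.mu_AB, (1 - p) * im.pi_10 * lm.mu_AB],
            [im.pi_11 * lm.mu_BA, p * im.pi_11 * lm.mu_BB, (1 - p) * im.pi_10 * lm.mu_BB],
            [im.pi_01 * lm.mu_BA, 0.0, im.pi_00 * lm.mu_BB],
        ]
    )


def R0_second(M: np.ndarray) -> float:
    """Perron root (spectral radius) of the non-negative matrix M."""
    eig = np.linalg.eigvals(M)
    radius = float(np.max(np.abs(eig)))
    # Perron-Frobenius: the spectral radius of a non-negative matrix is
    # itself an eigenvalue, with negligible imaginary part numerically.
    top = eig[np.argmax(np.abs(eig))]
    if radius > 0 and abs(top.imag) > 1e-10 * max(1.0, radius):
        raise ArithmeticError("dominant eigenvalue is not numerically real")
    return radius


class ForwardPGFs:
    """Offspring PGF bundle of the forward process.

    ``fY1``/``fY3`` are the PGFs of the numbers of children of each type
    of a type-1 / type-3 root; ``fYt1``..``fYt3`` the same for non-root
    vertices.  ``f1``/``f3`` and ``ft1``..``ft3`` compose those with the
    per-child infection-thinning maps t_ij, giving the PGFs of the numbers
    of children *infected* in the second epidemic.
    """

    def __init__(
        self,
        dist: DegreeDistribution,
        p: float,
        q_tilde: float,
        q: float,
        im: "ImmunityModel",
    ):
        if q_tilde >= 1.0:
            raise ValueError("forward PGFs require a supercritical first epidemic")
        self.dist, self.p, self.q_tilde, self.q, self.im = dist, p, q_tilde, q, im

    # -- root/non-root tree-offspring PGFs (no second-epidemic thinning) --

    def fY1(self, s1: float, s2: float, s3: float) -> float:
        p, qt, q = self.p, self.q_tilde, self.q
        u = (1 - qt) * s1 + qt * (p * s2 + (1 - p) * s3)
        v = (1 - p) * (1 - qt) * s1 + qt * (p * s2 + (1 - p) * s3)
        return (self.dist.pgf(u) - self.dist.pgf(v)) / (1.0 - q)

    def fY3(self, s1: float, s2: float, s3: float) -> float:
        p, qt, q = self.p, self.q_tilde, self.q
        return self.dist.pgf((1 - p) * (1 - qt) * s1 + qt * s3) / q

    def fYt1(self, s1: float, s2: float, s3: float) -> float:
        p, qt = self.p, self.q_tilde
        u = (1 - qt) * s1 + qt * (p * s2 + (1 - p) * s3)
        v = (1 - p) * (1 - qt) * s1 + qt * (p * s2 + (1 - p) * s3)
        return (self.dist.pgf_excess(u) - self.dist.pgf_excess(v)) / (1.0 - qt)

    def fYt2(self, s1: float, s2: float, s3: float) -> float:
        p, qt = self.p, self.q_tilde
        if qt == 0.0:
            return 1.0  # p = 1 limit: type-2 vertices have no children
        v = (1 - p) * (1 - qt) * s1 + qt * (p * s2 + (1 - p) * s3)
        return self.dist.pgf_excess(v) / qt

    def fYt3(self, s1: float, s2: float, s3: float) -> float:
        p, qt = self.p, self.q_tilde
        if qt == 0.0:
            return 1.0
        return self.dist.pgf_excess((1 - p) * (1 - qt) * s1 + qt * s3) / qt

    # -- thinning maps ----------------------------------------------------

    def _t_red(self, s1, s2, s3):
        """Arguments seen by a red (type-1/2) infectious parent."""
        im = self.im
        return (
            1 - im.pi_11 + im.pi_11 * s1,
            1 - im.pi_11 + im.pi_11 * s2,
            1 - im.pi_10 + im.pi_10 * s3,
        )

    def _t_blue(self, s1, s2, s3):
        """Arguments seen by a blue (type-3) infectious parent; the second
        component is never read (blue parents have no type-2 children)."""
        im = self.im
        return (
            1 - im.pi_01 + im.pi_01 * s1,
            0.0,
            1 - im.pi_00 + im.pi_00 * s3,
        )

    # -- infected-offspring PGFs -----------------------------------------

    def f1(self, s1: float, s2: float, s3: float) -> float:
        return self.fY1(*self._t_red(s1, s2, s3))

    def f3(self, s1: float, s2: float, s3: float) -> float:
        return self.fY3(*self._t_blue(s1, s2, s3))

    def ft1(self, s1: float, s2: float, s3: float) -> float:
        return self.fYt1(*self._t_red(s1, s2, s3))

    def ft2(self, s1: float, s2: float, s3: float) -> float:
        return self.fYt2(*self._t_red(s1, s2, s3))

    def ft3(self, s1: float, s2: float, s3: float) -> float:
        return self.fYt3(*self._t_blue(s1, s2, s3))

    def ft(self, s: np.ndarray) -> np.ndarray:
        """Vector map of the non-root PGFs, for fixed-point iteration."""
        return np.array(
            [self.ft1(*s), self.ft2(*s), self.ft3(*s)]
        )


def forward_pgfs(
    dist: DegreeDistribution,
    p: float,
    q_tilde: float,
    q: float,
    im: "ImmunityModel",
) -> ForwardPGFs:
    return ForwardPGFs(dist, p, q_tilde, q, im)


def solve_fixed_point(
    f: Callable[[np.ndarray], np.ndarray],
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> np.ndarray:
    """Minimal fixed point in [0,1]^3 of a monotone PGF vector map.

    Iterating from the origin gives a monotone increasing sequence whose
    limit is the smallest fixed point (the extinction probability vector);
    it equals (1,1,1) iff the process is (sub)critical.
    """
    s = np.zeros(3)
    for _ in range(max_iter):
        s_next = f(s)
        if np.max(np.abs(s_next - s)) < tol:
            return np.clip(s_next, 0.0, 1.0)
        s = s_next
    raise RuntimeError("branching-process fixed-point iteration did not converge")


def root_type3_weight(q: float, im: "ImmunityModel") -> float:
    """Probability that the second-epidemic seed escaped the first epidemic,
    under susceptibility-weighted seeding.

    Polarized: seed uniform among remaining susceptibles -> q/(q+alpha(1-q)).
    Leaky: rejection sampling with acceptance alpha_S for prior cases ->
    q/(q+alpha_S(1-q)).  Undefined for a general contact table.
    """
    if im.kind == "polarized":
        a = im.alpha
    elif im.kind in ("leaky_multiplicative", "leaky_rates"):
        a = im.alpha_S
    else:
        raise ValueError(
            "susceptibility-weighted seeding is undefined for a general "
            "immunity model"
        )
    return q / (q + a * (1.0 - q))


def major_outbreak_probability(
    bundle: ForwardPGFs,
    xi: np.ndarray,
    q: float,
    seeding: str = "uniform",
) -> float:
    """Large-outbreak probability 1 - w1 f1(xi) - w3 f3(xi).

    ``seeding='uniform'`` weights the root type by (1-q, q); the
    ``'susceptibility_weighted'`` scheme draws the seed preferentially
    among those still susceptible to the second epidemic.
    """
    if seeding == "uniform":
        w3 = q
    elif seeding == "susceptibility_weighted":
        w3 = root_type3_weight(q, bundle.im)
    else:
        raise ValueError(f"unknown seeding scheme {seeding!r}")
    w1 = 1.0 - w3
    return 1.0 - w1 * bundle.f1(*xi) - w3 * bundle.f3(*xi)


@dataclass(frozen=True)
class ForwardSolution:
    """Second-epidemic forward analysis: extinction fixed point xi, root PGF
    values, R0_2 and major-outbreak probabilities under both seedings
    (``p_major_weighted`` is None for a general contact table)."""

    xi: tuple[float, float, float]
    f1_at_xi: float
    f3_at_xi: float
    R0_2: float
    p_major_uniform: float
    p_major_weighted: float | None
    root_type3_weight: float | None


def second_epidemic_forward(
    dist: DegreeDistribution,
    p: float,
    im: "ImmunityModel",
    tol: float = 1e-12,
) -> ForwardSolution:
    """Full forward pipeline: first-epidemic percolation, offspring matrix,
    extinction fixed point and outbreak probabilities."""
    fe = first_outbreak(dist, p)
    if not fe.supercritical:
        raise ValueError("second-epidemic analysis requires a large first epidemic")
    lm = label_means(dist, p, fe.q_tilde)
    M = offspring_matrix(lm, im, p)
    r0_2 = R0_second(M)
    bundle = forward_pgfs(dist, p, fe.q_tilde, fe.q, im)
    if r0_2 > 1.0:
        xi = solve_fixed_point(bundle.ft, tol=tol)
    else:
        xi = np.ones(3)
    f1_xi = bundle.f1(*xi)
    f3_xi = bundle.f3(*xi)
    p_uni = major_outbreak_probability(bundle, xi, fe.q, "uniform")
    try:
        w3 = root_type3_weight(fe.q, im)
        p_w = major_outbreak_probability(bundle, xi, fe.q, "susceptibility_weighted")
    except ValueError:
        w3, p_w = None, None
    return ForwardSolution(
        xi=tuple(float(x) for x in xi),
        f1_at_xi=float(f1_xi),
        f3_at_xi=float(f3_xi),
        R0_2=float(r0_2),
        p_major_uniform=float(p_uni),
        p_major_weighted=None if p_w is None else float(p_w),
        root_type3_weight=w3,
    )
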