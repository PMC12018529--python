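"""Backward (susceptibility-set) process and second-epidemic final size.

A uniformly chosen vertex is infected by a large second epidemic iff its
susceptibility set -- who could have infected me, grown generation by
generation -- is infinite.  On the coloured tree this set is the total
progeny of a three-type Galton-Watson process whose offspring PGFs are
the forward ones with the contact table transposed (pi_ij -> pi_ji),
because transmission is now traced against the direction of infection.

For polarized immunity the backward process needs its own PGFs: a prior
case tosses its susceptibility coin once for all contacts, so the red
types carry an alpha-mixture
``1 - alpha + alpha * f(1-p'+p's_1, ...)`` instead of per-contact
thinning.

The asymptotic final size of a large second epidemic is
``z = 1 - (1-q) xi_check_1 - q xi_check_3``, where xi_check_i is the
extinction probability rooted at a type-i vertex; the same quantities
give the four-way joint classification over both epidemics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .degrees import DegreeDistribution
from .first_epidemic import first_outbreak
from .forward import ForwardPGFs, solve_fixed_point
from .immunity import ImmunityModel

__all__ = [
    "BackwardPGFs",
    "BackwardSolution",
    "backward_pgfs",
    "backward_pgfs_polarized",
    "make_backward_bundle",
    "final_size",
    "second_epidemic_final_size",
]


class BackwardPGFs:
    """Offspring PGF bundle {fh1, fh2, fh3, fc1, fc3} of the backward process.

    ``fh`` ("hat") are non-root PGFs, ``fc`` ("check") root PGFs; both are
    built on the tree-offspring PGFs of the forward bundle.
    """

    def __init__(
        self,
        dist: DegreeDistribution,
        p: float,
        q_tilde: float,
        q: float,
        im: ImmunityModel,
        polarized_mixture: bool = False,
    ):
        self._fwd = ForwardPGFs(dist, p, q_tilde, q, im)
        self.im = im
        self.polarized_mixture = polarized_mixture
        if polarized_mixture:
            if im.kind != "polarized":
                raise ValueError("polarized backward PGFs need a polarized model")
            self._alpha = im.alpha
            self._pp = im.p_prime

    # transposed thinning maps: pi_hat_ij = pi_ji
    def _th_red(self, s1, s2, s3):
        im = self.im
        return (
            1 - im.pi_11 + im.pi_11 * s1,
            1 - im.pi_11 + im.pi_11 * s2,
            1 - im.pi_01 + im.pi_01 * s3,
        )

    def _th_blue(self, s1, s2, s3):
        im = self.im
        return (
            1 - im.pi_10 + im.pi_10 * s1,
            0.0,
            1 - im.pi_00 + im.pi_00 * s3,
        )

    def _mix(self, s1, s2, s3):
        pp = self._pp
        return (1 - pp + pp * s1, 1 - pp + pp * s2, 1 - pp + pp * s3)

    # -- non-root PGFs ----------------------------------------------------

    def fh1(self, s1, s2, s3):
        if self.polarized_mixture:
            a = self._alpha
            return 1 - a + a * self._fwd.fYt1(*self._mix(s1, s2, s3))
        return self._fwd.fYt1(*self._th_red(s1, s2, s3))

    def fh2(self, s1, s2, s3):
        if self.polarized_mixture:
            a = self._alpha
            return 1 - a + a * self._fwd.fYt2(*self._mix(s1, s2, s3))
        return self._fwd.fYt2(*self._th_red(s1, s2, s3))

    def fh3(self, s1, s2, s3):
        if self.polarized_mixture:
            return self._fwd.fYt3(*self._mix(s1, s2, s3))
        return self._fwd.fYt3(*self._th_blue(s1, s2, s3))

    # -- root PGFs --------------------------------------------------------

    def fc1(self, s1, s2, s3):
        if self.polarized_mixture:
            a = self._alpha
            return 1 - a + a * self._fwd.fY1(*self._mix(s1, s2, s3))
        return self._fwd.fY1(*self._th_red(s1, s2, s3))

    def fc3(self, s1, s2, s3):
        if self.polarized_mixture:
            return self._fwd.fY3(*self._mix(s1, s2, s3))
        return self._fwd.fY3(*self._th_blue(s1, s2, s3))

    def fh(self, s: np.ndarray) -> np.ndarray:
        """Vector map of the non-root PGFs, for fixed-point iteration."""
        return np.array([self.fh1(*s), self.fh2(*s), self.fh3(*s)])


def backward_pgfs(
    dist: DegreeDistribution,
    p: float,
    q_tilde: float,
    q: float,
    im: ImmunityModel,
) -> BackwardPGFs:
    """Backward bundle for a general (incl. leaky) contact table."""
    return BackwardPGFs(dist, p, q_tilde, q, im, polarized_mixture=False)


def backward_pgfs_polarized(
    dist: DegreeDistribution,
    p: float,
    q_tilde: float,
    q: float,
    p_prime: float,
    alpha: float,
) -> BackwardPGFs:
    """Backward bundle with the polarized alpha-mixture PGFs (the
    once-for-all susceptibility coin)."""
    from .immunity import polarized as _pol

    return BackwardPGFs(
        dist, p, q_tilde, q, _pol(p_prime, alpha), polarized_mixture=True
    )


def make_backward_bundle(
    dist: DegreeDistribution,
    p: float,
    q_tilde: float,
    q: float,
    im: ImmunityModel,
) -> BackwardPGFs:
    """Dispatch on the model kind: polarized needs the mixture PGFs."""
    if im.kind == "polarized":
        return backward_pgfs_polarized(dist, p, q_tilde, q, im.p_prime, im.alpha)
    return backward_pgfs(dist, p, q_tilde, q, im)


@dataclass(frozen=True)
class BackwardSolution:
    """Final-size analysis of the second epidemic.

    ``z_major`` is the asymptotic infected fraction in a large second
    epidemic; ``attack_rate_prior_cases`` = 1 - xi_check_1 and
    ``attack_rate_escapees`` = 1 - xi_check_3 split it by first-epidemic
    history; ``joint`` classifies a uniform vertex over both epidemics.
    """

    xi_hat: tuple[float, float, float]
    xi_check_1: float
    xi_check_3: float
    z_major: float
    joint: dict[str, float]

    @property
    def attack_rate_prior_cases(self) -> float:
        return 1.0 - self.xi_check_1

    @property
    def attack_rate_escapees(self) -> float:
        return 1.0 - self.xi_check_3


def final_size(bundle: BackwardPGFs, q: float, tol: float = 1e-12) -> BackwardSolution:
    """Solve the backward fixed point and assemble the final-size summary.

    The minimal fixed point of (fh1, fh2, fh3) from the origin is
    (1,1,1) exactly when the second epidemic is subcritical, in which
    case z = 0.
    """
    xi_hat = solve_fixed_point(bundle.fh, tol=tol)
    xc1 = float(bundle.fc1(*xi_hat))
    xc3 = float(bundle.fc3(*xi_hat))
    z = 1.0 - (1.0 - q) * xc1 - q * xc3
    joint = {
        "neither": q * xc3,
        "first_only": (1.0 - q) * xc1,
        "second_only": q * (1.0 - xc3),
        "both": (1.0 - q) * (1.0 - xc1),
    }
    return BackwardSolution(
        xi_hat=tuple(float(x) for x in xi_hat),
        xi_check_1=xc1,
        xi_check_3=xc3,
        z_major=float(z),
        joint=joint,
    )


def second_epidemic_final_size(
    dist: DegreeDistribution,
    p: float,
    im: ImmunityModel,
    tol: float = 1e-12,
) -> BackwardSolution:
    """Full backward pipeline from model parameters to final size."""
    fe = first_outbreak(dist, p)
    if not fe.supercritical:
        raise ValueError("final-size analysis requires a large first epidemic")
    bundle = make_backward_bundle(dist, p, fe.q_tilde, fe.q, im)
    return final_size(bundle, fe.q, tol=tol)
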