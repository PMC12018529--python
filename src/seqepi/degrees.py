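"""Degree distributions for configuration-model networks.

A :class:`DegreeDistribution` bundles a probability mass function
:math:`p_k = P(D=k)` with exact evaluation of the probability generating
function (PGF) :math:`f_D(x) = E[x^D]`, its first two derivatives, the
size-biased degree :math:`\\tilde D` (the degree of a vertex reached by
following a uniformly chosen edge, :math:`\\tilde p_k = k p_k / \\mu_D`),
and the excess-degree PGF

.. math:: f_{\\tilde D - 1}(x) = \\mu_D^{-1} f_D'(x).

Four named families are supported with closed-form PGFs -- constant,
Poisson, geometric on support {1, 2, ...}, and power law with exponential
cutoff (polylogarithm normalisation) -- together with arbitrary finite
custom pmfs.  All families must have a finite second moment; the
heavy-tailed pure power law is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DegreeDistribution",
    "make_degree_distribution",
    "constant",
    "poisson",
    "geometric",
    "powerlaw_cutoff",
    "custom",
    "from_size_biased",
    "polylog",
]

_FAMILIES = ("constant", "poisson", "geometric", "powerlaw_cutoff", "custom")


def polylog(s: float, z: float, tol: float = 1e-16) -> float:
    """Polylogarithm Li_s(z) = sum_{k>=1} z^k / k^s for 0 <= z < 1.

    Direct series summation in blocks; the series is eventually geometric
    with ratio z, so adaptive truncation at relative size ``tol`` is safe.
    """
    if not 0.0 <= z < 1.0:
        raise ValueError(f"polylog series requires 0 <= z < 1, got z={z}")
    if z == 0.0:
        return 0.0
    total = 0.0
    k0 = 1
    block = 256
    while k0 < 50_000_000:
        k = np.arange(k0, k0 + block, dtype=float)
        terms = z**k * k ** (-s)
        total += float(terms.sum())
        # geometric tail bound: remaining sum <= last_term * z/(1-z)
        if terms[-1] * z / (1.0 - z) < tol * max(total, 1e-300):
            return total
        k0 += block
    raise RuntimeError("polylog series did not converge")


@dataclass(frozen=True)
class DegreeDistribution:
    """A degree distribution D with PGF machinery.

    Use the module-level constructors (:func:`constant`, :func:`poisson`,
    :func:`geometric`, :func:`powerlaw_cutoff`, :func:`custom`,
    :func:`from_size_biased`) or :func:`make_degree_distribution` rather
    than instantiating directly.
    """

    family: str
    params: dict = field(default_factory=dict)
    truncation_tol: float = 1e-14
    # custom only: pmf[k] = P(D=k), k = 0, 1, ...
    _pmf: np.ndarray | None = None

    # -- moments ----------------------------------------------------------

    @property
    def mean(self) -> float:
        f = self.family
        if f == "constant":
            return float(self.params["d"])
        if f == "poisson":
            return float(self.params["mu"])
        if f == "geometric":
            return 1.0 / self.params["theta"]
        if f == "powerlaw_cutoff":
            a, th = self.params["alpha_D"], self._theta
            return polylog(a - 1, th) / polylog(a, th)
        k = np.arange(len(self._pmf))
        return float((k * self._pmf).sum())

    @property
    def second_moment(self) -> float:
        f = self.family
        if f == "constant":
            return float(self.params["d"]) ** 2
        if f == "poisson":
            mu = self.params["mu"]
            return mu + mu**2
        if f == "geometric":
            th = self.params["theta"]
            return (2.0 - th) / th**2
        if f == "powerlaw_cutoff":
            a, th = self.params["alpha_D"], self._theta
            return polylog(a - 2, th) / polylog(a, th)
        k = np.arange(len(self._pmf))
        return float((k**2 * self._pmf).sum())

    @property
    def variance(self) -> float:
        return self.second_moment - self.mean**2

    @property
    def _theta(self) -> float:
        """Powerlaw-cutoff geometric damping factor e^{-1/kappa}."""
        return float(np.exp(-1.0 / self.params["kappa"]))

    # -- pmf --------------------------------------------------------------

    def pmf(self, k: int) -> float:
        if k < 0:
            return 0.0
        f = self.family
        if f == "constant":
            return 1.0 if k == self.params["d"] else 0.0
        if f == "poisson":
            mu = self.params["mu"]
            from scipy.stats import poisson as _pois

            return float(_pois.pmf(k, mu))
        if f == "geometric":
            th = self.params["theta"]
            return 0.0 if k < 1 else (1.0 - th) ** (k - 1) * th
        if f == "powerlaw_cutoff":
            if k < 1:
                return 0.0
            a, th = self.params["alpha_D"], self._theta
            return th**k * k ** (-a) / polylog(a, th)
        return float(self._pmf[k]) if k < len(self._pmf) else 0.0

    def size_biased_pmf(self, k: int) -> float:
        """P(D-tilde = k) = k p_k / mu_D, the degree of an edge endpoint."""
        mu = self.mean
        if mu <= 0.0:
            raise ValueError("size-biased distribution undefined for mu_D = 0")
        return 0.0 if k < 1 else k * self.pmf(k) / mu

    # -- PGFs -------------------------------------------------------------

    def _check_x(self, x: float) -> None:
        if not -1e-12 <= x <= 1.0 + 1e-12:
            raise ValueError(f"PGF argument must lie in [0, 1], got {x}")

    def pgf(self, x: float) -> float:
        """f_D(x) = E[x^D]."""
        self._check_x(x)
        x = min(max(x, 0.0), 1.0)
        f = self.family
        if f == "constant":
            return x ** self.params["d"]
        if f == "poisson":
            return float(np.exp(-self.params["mu"] * (1.0 - x)))
        if f == "geometric":
            th = self.params["theta"]
            return th * x / (1.0 - (1.0 - th) * x)
        if f == "powerlaw_cutoff":
            a, th = self.params["alpha_D"], self._theta
            return polylog(a, th * x) / polylog(a, th)
        k = np.arange(len(self._pmf), dtype=float)
        return float((self._pmf * x**k).sum())

    def pgf_d1(self, x: float) -> float:
        """First derivative f_D'(x)."""
        self._check_x(x)
        x = min(max(x, 0.0), 1.0)
        f = self.family
        if f == "constant":
            d = self.params["d"]
            return 0.0 if d == 0 else d * x ** (d - 1)
        if f == "poisson":
            mu = self.params["mu"]
            return mu * float(np.exp(-mu * (1.0 - x)))
        if f == "geometric":
            th = self.params["theta"]
            return th / (1.0 - (1.0 - th) * x) ** 2
        if f == "powerlaw_cutoff":
            a, th = self.params["alpha_D"], self._theta
            if x == 0.0:
                return self.pmf(1)
            return polylog(a - 1, th * x) / (x * polylog(a, th))
        k = np.arange(1, len(self._pmf), dtype=float)
        return float((self._pmf[1:] * k * x ** (k - 1)).sum())

    def pgf_d2(self, x: float) -> float:
        """Second derivative f_D''(x)."""
        self._check_x(x)
        x = min(max(x, 0.0), 1.0)
        f = self.family
        if f == "constant":
            d = self.params["d"]
            return 0.0 if d < 2 else d * (d - 1) * x ** (d - 2)
        if f == "poisson":
            mu = self.params["mu"]
            return mu**2 * float(np.exp(-mu * (1.0 - x)))
        if f == "geometric":
            th = self.params["theta"]
            return 2.0 * th * (1.0 - th) / (1.0 - (1.0 - th) * x) ** 3
        if f == "powerlaw_cutoff":
            a, th = self.params["alpha_D"], self._theta
            if x == 0.0:
                return 2.0 * self.pmf(2)
            beta = polylog(a, th)
            return (polylog(a - 2, th * x) - polylog(a - 1, th * x)) / (x**2 * beta)
        if len(self._pmf) < 3:
            return 0.0
        k = np.arange(2, len(self._pmf), dtype=float)
        return float((self._pmf[2:] * k * (k - 1) * x ** (k - 2)).sum())

    def pgf_excess(self, x: float) -> float:
        """Excess-degree PGF f_{D-tilde minus 1}(x) = f_D'(x) / mu_D."""
        mu = self.mean
        if mu <= 0.0:
            raise ValueError("excess-degree PGF undefined for mu_D = 0")
        return self.pgf_d1(x) / mu

    def pgf_excess_d1(self, x: float) -> float:
        """Derivative of the excess-degree PGF, f_D''(x) / mu_D."""
        mu = self.mean
        if mu <= 0.0:
            raise ValueError("excess-degree PGF undefined for mu_D = 0")
        return self.pgf_d2(x) / mu

    def mean_excess_degree(self) -> float:
        """E[D-tilde - 1] = f_D''(1)/mu_D = mu_D + sigma_D^2/mu_D - 1."""
        return self.pgf_d2(1.0) / self.mean

    # -- sampling ---------------------------------------------------------

    def _pmf_table(self) -> np.ndarray:
        """Truncated pmf table for inverse-CDF sampling."""
        f = self.family
        if f == "custom":
            return self._pmf
        if f == "powerlaw_cutoff":
            a, th = self.params["alpha_D"], self._theta
            beta = polylog(a, th)
            K = max(64, int(np.ceil(np.log(1e-15 * (1.0 - th)) / np.log(th))))
            k = np.arange(1, K + 1, dtype=float)
            p = th**k * k ** (-a) / beta
            return np.concatenate([[0.0], p])
        raise AssertionError("table sampling not used for this family")

    def sample(self, n: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
        """Draw n i.i.d. degrees; reproducible given a Generator or seed."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        f = self.family
        if f == "constant":
            return np.full(n, int(self.params["d"]), dtype=np.int64)
        if f == "poisson":
            return rng.poisson(self.params["mu"], size=n).astype(np.int64)
        if f == "geometric":
            return rng.geometric(self.params["theta"], size=n).astype(np.int64)
        table = self._pmf_table()
        cdf = np.cumsum(table)
        cdf[-1] = max(cdf[-1], 1.0)
        u = rng.random(n)
        return np.searchsorted(cdf, u, side="right").astype(np.int64)


# -- constructors ---------------------------------------------------------


def constant(d: int, truncation_tol: float = 1e-14) -> DegreeDistribution:
    """All vertices have degree d."""
    if d < 0 or int(d) != d:
        raise ValueError("constant degree must be a non-negative integer")
    return DegreeDistribution("constant", {"d": int(d)}, truncation_tol)


def poisson(mu: float, truncation_tol: float = 1e-14) -> DegreeDistribution:
    """D ~ Poisson(mu), mu > 0."""
    if mu <= 0:
        raise ValueError("Poisson mean must be positive")
    return DegreeDistribution("poisson", {"mu": float(mu)}, truncation_tol)


def geometric(theta: float, truncation_tol: float = 1e-14) -> DegreeDistribution:
    """Geometric on {1, 2, ...}: p_k = (1-theta)^{k-1} theta, mean 1/theta."""
    if not 0.0 < theta <= 1.0:
        raise ValueError("geometric parameter must lie in (0, 1]")
    return DegreeDistribution("geometric", {"theta": float(theta)}, truncation_tol)


def powerlaw_cutoff(
    alpha_D: float, kappa: float, truncation_tol: float = 1e-14
) -> DegreeDistribution:
    """Power law with exponential cutoff.

    p_k = c k^{-alpha_D} e^{-k/kappa} for k >= 1, with c the reciprocal of
    Li_{alpha_D}(e^{-1/kappa}) so the pmf sums to one.  The finite cutoff
    guarantees all moments exist.
    """
    if alpha_D <= 0 or kappa <= 0:
        raise ValueError("powerlaw_cutoff requires alpha_D > 0 and kappa > 0")
    return DegreeDistribution(
        "powerlaw_cutoff",
        {"alpha_D": float(alpha_D), "kappa": float(kappa)},
        truncation_tol,
    )


def custom(pmf: Sequence[float], truncation_tol: float = 1e-14) -> DegreeDistribution:
    """Arbitrary finite pmf; pmf[k] = P(D=k) starting at k = 0.

    The pmf must be non-negative and sum to one (a discrepancy below 1e-6
    is renormalised away; larger discrepancies are rejected).
    """
    p = np.asarray(pmf, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pmf must be a non-empty 1-D sequence")
    if (p < 0).any():
        raise ValueError("pmf values must be non-negative")
    s = p.sum()
    if s <= 0 or abs(s - 1.0) > 1e-6:
        raise ValueError(f"pmf must sum to 1 (got {s})")
    return DegreeDistribution("custom", {}, truncation_tol, _pmf=p / s)


def from_size_biased(
    ptilde: Sequence[float] | dict[int, float], truncation_tol: float = 1e-14
) -> DegreeDistribution:
    """Construct D from its size-biased law: p_k proportional to ptilde_k / k.

    ``ptilde`` is either a dict {k: P(D-tilde = k)} with k >= 1, or a
    sequence indexed from k = 1.
    """
    if isinstance(ptilde, dict):
        kmax = max(ptilde)
        pt = np.zeros(kmax + 1)
        for k, v in ptilde.items():
            if k < 1:
                raise ValueError("size-biased support starts at k = 1")
            pt[k] = v
    else:
        pt = np.concatenate([[0.0], np.asarray(ptilde, dtype=float)])
    if (pt < 0).any() or pt.sum() <= 0:
        raise ValueError("invalid size-biased pmf")
    k = np.arange(len(pt), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(k > 0, pt / np.where(k > 0, k, 1.0), 0.0)
    return custom(p / p.sum(), truncation_tol)


def make_degree_distribution(
    family: str, params: dict, truncation_tol: float = 1e-14
) -> DegreeDistribution:
    """Dispatch constructor keyed by family name (config-file entry point)."""
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {_FAMILIES}")
    if family == "constant":
        return constant(params["d"], truncation_tol)
    if family == "poisson":
        return poisson(params.get("mu", params.get("mu_D")), truncation_tol)
    if family == "geometric":
        return geometric(params["theta"], truncation_tol)
    if family == "powerlaw_cutoff":
        return powerlaw_cutoff(params["alpha_D"], params["kappa"], truncation_tol)
    return custom(params["pmf"], truncation_tol)
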