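"""Finite-difference helpers for checking PGF derivatives.

PGFs are only defined on [0, 1]^3, so derivatives at the all-ones point
use a second-order *one-sided* (backward) difference:

    f'(1) ~ (3 f(1) - 4 f(1-h) + f(1-2h)) / (2h),   error O(h^2).
"""

import numpy as np


def jacobian_at_ones(f, h=1e-5):
    """3x3 Jacobian of a vector map f: [0,1]^3 -> R^3 at (1,1,1)."""
    ones = np.ones(3)
    J = np.zeros((3, 3))
    f1 = np.asarray(f(ones), dtype=float)
    for j in range(3):
        a, b = ones.copy(), ones.copy()
        a[j] -= h
        b[j] -= 2 * h
        J[:, j] = (3 * f1 - 4 * np.asarray(f(a)) + np.asarray(f(b))) / (2 * h)
    return J


def jacobian_interior(f, s0, h=1e-6):
    """Central-difference Jacobian at an interior point of [0,1]^3."""
    J = np.zeros((3, 3))
    for j in range(3):
        up, dn = np.array(s0, float), np.array(s0, float)
        up[j] += h
        dn[j] -= h
        J[:, j] = (np.asarray(f(up)) - np.asarray(f(dn))) / (2 * h)
    return J
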