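"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (loops, sorting, textbook formulas) kept
free of any plaquekit internals so they can stand as second routes.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import stdtr


def percentile_oracle(values, q: float) -> float:
    """Sort-and-interpolate percentile (linear between order statistics)."""
    v = sorted(float(x) for x in np.asarray(values).ravel())
    n = len(v)
    if n == 0:
        raise ValueError("empty pool")
    h = (n - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def welch_oracle(a, b) -> tuple[float, float]:
    """Textbook Welch t statistic, Welch–Satterthwaite df, two-sided p.

    Only the Student-t CDF comes from a library special function; the
    statistic and degrees of freedom are coded from the formulas.
    """
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * (1.0 - stdtr(df, abs(t)))
    return t, p


def manders_oracle(a, b, thr_a: float, thr_b: float) -> tuple[float | None, float | None]:
    """Double-loop thresholded Mander's M1/M2 over 3D arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    num1, den1, num2, den2 = [], [], [], []
    for z in range(a.shape[0]):
        for y in range(a.shape[1]):
            for x in range(a.shape[2]):
                av, bv = a[z, y, x], b[z, y, x]
                if av > thr_a:
                    den1.append(av)
                    if bv > thr_b:
                        num1.append(av)
                if bv > thr_b:
                    den2.append(bv)
                    if av > thr_a:
                        num2.append(bv)
    m1 = math.fsum(num1) / math.fsum(den1) if den1 else None
    m2 = math.fsum(num2) / math.fsum(den2) if den2 else None
    return m1, m2


def max_projection_oracle(stack) -> np.ndarray:
    """Per-pixel loop maximum across slices."""
    stack = np.asarray(stack, dtype=float)
    out = np.empty(stack.shape[1:])
    for y in range(stack.shape[1]):
        for x in range(stack.shape[2]):
            out[y, x] = max(stack[z, y, x] for z in range(stack.shape[0]))
    return out


def roundness_oracle(mask) -> float:
    """4A/(pi L^2) with L the maximal pairwise pixel-center distance."""
    pts = np.argwhere(np.asarray(mask, dtype=bool))
    area = len(pts)
    best = 0.0
    for i in range(area):
        d = np.hypot(*(pts - pts[i]).T)
        best = max(best, float(d.max()))
    return 4.0 * area / (math.pi * best**2) if best > 0 else 1.0
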