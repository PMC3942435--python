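"""Two-sample Kolmogorov-Smirnov distance and its effective-sample-size
scaling.

The screen compares two wells through the maximum vertical distance D
between their empirical cumulative distribution functions, evaluated
exactly at every pooled data point (right-continuous ECDFs, so ties and
discrete features are handled without approximation).  Because wells
differ in cell number, D is rescaled by the square root of the effective
sample size N_e, with 1/N_e = 1/N1 + 1/N2, giving

    D* = sqrt(N_e) * D

which puts comparisons between wells of different population sizes on a
common scale.  D* is used purely as a distance; no asymptotic p-value is
attached to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS comparison of two per-cell samples.

    Attributes
    ----------
    d : float
        sup |ECDF_1 - ECDF_2| over all pooled points, in [0, 1].
    n1, n2 : int
        Sample sizes.
    n_effective : float
        n1 * n2 / (n1 + n2).
    d_star : float
        sqrt(n_effective) * d.
    """

    d: float
    n1: int
    n2: int
    n_effective: float
    d_star: float


def ks_statistic(a, b) -> KSResult:
    """Exact two-sample KS distance between samples ``a`` and ``b``.

    Both samples must be non-empty.  The statistic is symmetric in its
    arguments and exact in the presence of ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_statistic requires two non-empty samples")
    a = np.sort(a)
    b = np.sort(b)
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    n1, n2 = int(a.size), int(b.size)
    n_eff = n1 * n2 / (n1 + n2)
    return KSResult(d=d, n1=n1, n2=n2, n_effective=n_eff,
                    d_star=float(np.sqrt(n_eff) * d))


def d_star_matrix(rows: list[np.ndarray], cols: list[np.ndarray]) -> np.ndarray:
    """D* for every (row sample, column sample) pair.

    Samples must be pre-sorted; this is the inner loop of slide scoring.
    """
    out = np.empty((len(rows), len(cols)))
    col_sizes = np.array([c.size for c in cols], dtype=float)
    for i, a in enumerate(rows):
        n1 = a.size
        for j, b in enumerate(cols):
            pooled = np.concatenate([a, b])
            cdf_a = np.searchsorted(a, pooled, side="right") / n1
            cdf_b = np.searchsorted(b, pooled, side="right") / b.size
            d = np.max(np.abs(cdf_a - cdf_b))
            n_eff = n1 * col_sizes[j] / (n1 + col_sizes[j])
            out[i, j] = np.sqrt(n_eff) * d
    return out
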