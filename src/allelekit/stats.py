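"""Small in-repo statistical primitives shared across stages."""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney–Wilcoxon test, normal approximation with
    tie correction.  Returns ``(U_of_x, p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:  # all observations identical
        return u1, 1.0
    # continuity correction, matching the standard normal approximation
    z = (abs(u1 - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * 0.5 * math.erfc(z / math.sqrt(2.0))
    return u1, min(p, 1.0)
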