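"""Small statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["runs_test_pvalue"]


def runs_test_pvalue(x: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs test on the signs of ``x``.

    Tests whether the sequence of signs is random; a small p-value indicates
    structure (e.g. one long one-signed run from a systematic misfit).  Uses
    the normal approximation with the usual mean/variance of the run count.
    Zeros are dropped.  Returns 1.0 when either sign is absent or fewer than
    two observations remain (no evidence of structure obtainable).
    """
    s = np.sign(np.asarray(x, dtype=float))
    s = s[s != 0]
    n_pos = int(np.sum(s > 0))
    n_neg = int(np.sum(s < 0))
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0 or n < 2:
        return 1.0
    runs = 1 + int(np.sum(s[1:] != s[:-1]))
    mean = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mean) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))
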