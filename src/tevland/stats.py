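"""Small shared statistical helpers.

The Benjamini-Hochberg adjustment lives here so every module applies the
identical procedure to its p-value tables.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values.

    Parameters
    ----------
    pvalues : array-like of float in (0, 1]
        Raw p-values; NaN entries are propagated untouched.

    Returns
    -------
    ndarray of q-values, same shape as the input.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
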