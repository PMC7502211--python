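"""Shared statistical helpers.

``bh_adjust`` is the single source of truth for Benjamini–Hochberg FDR
correction across the package (ASE genes, AMR windows, Dunn pairs, GO terms).
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]

    Returns
    -------
    numpy.ndarray
        q-values in the input order; ``q[i] ∈ [p[i], 1]`` and q is
        non-decreasing in sorted p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
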