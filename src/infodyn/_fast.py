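"""Numba-accelerated inner loops for surrogate testing.

The greedy embedding selection and the surrogate tests evaluate many
conditional-mutual-information statistics that differ only by a circular
shift of one symbol column.  The hot operation - histogramming
``base[i] + col[(i + shift) mod n]`` - is fused into a single pass here so
no shifted copies or temporary code arrays are materialized.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["hist_shifted", "cmi_from_tzv_counts"]


@njit(cache=True)
def _hist_shifted_kernel(base, col, shift, out):  # pragma: no cover - jitted
    n = base.size
    out[:] = 0
    for i in range(n):
        j = i - shift
        if j < 0:
            j += n
        out[base[i] + col[j]] += 1


def hist_shifted(base: np.ndarray, col: np.ndarray, shift: int, out: np.ndarray):
    """Counts of ``base + roll(col, shift)`` accumulated into ``out``."""
    _hist_shifted_kernel(base, col, shift, out)
    return out


def cmi_from_tzv_counts(counts: np.ndarray) -> float:
    """I(T : V | Z) in bits from a (T, Z, V) count tensor."""
    n = counts.sum()
    c_z = counts.sum(axis=(0, 2))
    c_tz = counts.sum(axis=2)
    c_vz = counts.sum(axis=0)
    nzi = counts > 0
    terms = counts[nzi] * (
        np.log2(counts[nzi])
        + np.log2(np.broadcast_to(c_z[None, :, None], counts.shape)[nzi])
        - np.log2(np.broadcast_to(c_tz[:, :, None], counts.shape)[nzi])
        - np.log2(np.broadcast_to(c_vz[None, :, :], counts.shape)[nzi])
    )
    return float(terms.sum() / n)
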