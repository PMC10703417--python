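"""Local storage-transfer correlation (LSTC).

The headline test of the framework: if a processing unit codes for the
predictable parts of its input, local information transfer across the unit
should be high exactly when the input's local predictability (lAIS) is
high, giving a positive Pearson correlation between the two local series;
a unit coding for prediction errors transfers most when the input is
mispredicted, giving a negative correlation.

The two local series are aligned by the reconstructed information-transfer
delay u: the transfer value at time t is paired with the input storage at
t - u (pass u = 0 to disable the shift).  Significance is assessed with a
two-sided permutation test using circular-shift surrogates of the storage
series.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateInputError, InputError, UndefinedCorrelationError
from .series import LocalSeries

__all__ = ["LSTCResult", "compute_lstc"]


@dataclasses.dataclass
class LSTCResult:
    r: float
    p_value: float
    n_valid: int
    delay_used: int
    direction_call: str
    r_spearman: float | None = None  # rank correlation, secondary diagnostic

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom)


def compute_lstc(
    lais_series: LocalSeries,
    lte_series: LocalSeries,
    u: int = 0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    mask: np.ndarray | None = None,
) -> LSTCResult:
    """Pearson correlation between input lAIS and across-unit lTE.

    Parameters
    ----------
    lais_series, lte_series : LocalSeries
        Local storage of the input and local transfer across the unit, from
        the same recording (equal lengths).
    u : int
        Reconstructed transfer delay in bins; lTE at t is paired with lAIS
        at t - u.  Samples where either value is invalid are dropped.
    mask : optional boolean array over lTE time indices
        Restrict the correlation, e.g. to input-spike bins (paired after
        the delay shift).
    """
    if len(lais_series) != len(lte_series):
        raise InputError("local series must have the same length")
    if u < 0:
        raise InputError("delay must be >= 0")
    n = len(lte_series)
    if u >= n:
        raise InputError("delay exceeds series length")
    a_vals = lais_series.values[: n - u] if u else lais_series.values
    a_valid = lais_series.valid[: n - u] if u else lais_series.valid
    b_vals = lte_series.values[u:]
    b_valid = lte_series.valid[u:]
    joint = a_valid & b_valid
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != lte_series.valid.shape:
            raise InputError("mask must align with the lTE series")
        joint &= mask[u:]
    if joint.sum() < 10:
        raise DegenerateInputError("fewer than 10 jointly valid samples")
    a = a_vals[joint]
    b = b_vals[joint]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance in a local series")

    r = _pearson(a, b)
    m = a.size
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        shift = int(rng.integers(1, m))
        if abs(_pearson(np.roll(a, shift), b)) >= abs(r):
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)

    if p <= alpha:
        call = "predictable-coding" if r > 0 else "error-coding"
    else:
        call = "inconclusive"

    ar = np.argsort(np.argsort(a)).astype(float)
    br = np.argsort(np.argsort(b)).astype(float)
    r_s = _pearson(ar, br) if np.ptp(ar) > 0 and np.ptp(br) > 0 else float("nan")
    return LSTCResult(r, float(p), int(m), int(u), call, r_s)
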