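"""Containers for binned point-process realizations and local information series.

A :class:`BinnedSeries` is the discrete-time realization of a (spiking)
process: a vector of small non-negative integers, one per time bin.  For
spike data the values are binary (1 = at least one spike in the bin).  A
:class:`LocalSeries` holds per-time-point local information values in bits
together with a validity mask marking samples whose embedding window
reaches before the start of the recording.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import InputError


@dataclasses.dataclass
class BinnedSeries:
    """Regularly sampled realization of a discrete-valued process.

    Parameters
    ----------
    values : array-like of int
        One symbol per bin; binary for spike data.
    bin_width : float
        Bin duration in ms.
    t0 : float
        Time of the left edge of the first bin, in ms.
    """

    values: np.ndarray
    bin_width: float = 1.0
    t0: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 1 or v.size < 1:
            raise InputError("values must be a non-empty 1-D sequence")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(np.equal(np.mod(v, 1), 0)):
                raise InputError("values must be integers")
        v = v.astype(np.int64)
        if v.min() < 0:
            raise InputError("values must be non-negative")
        if self.bin_width <= 0:
            raise InputError("bin_width must be positive")
        self.values = v

    def __len__(self) -> int:
        return self.values.size

    @property
    def alphabet_size(self) -> int:
        """Number of symbols (at least 2, so constant series stay binary)."""
        return max(2, int(self.values.max()) + 1)

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) * self.bin_width

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ms": self.times_ms, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "BinnedSeries":
        df = pd.read_csv(path)
        if not {"time_ms", "value"} <= set(df.columns):
            raise InputError(f"{path}: expected columns time_ms,value")
        t = df["time_ms"].to_numpy(float)
        if len(t) > 1:
            widths = np.diff(t)
            if not np.allclose(widths, widths[0]):
                raise InputError(f"{path}: bins are not regularly spaced")
            bw = float(widths[0])
        else:
            bw = 1.0
        return cls(df["value"].to_numpy(), bin_width=bw, t0=float(t[0]))


@dataclasses.dataclass
class LocalSeries:
    """Per-time-point local information values (bits) with validity mask.

    ``values`` is NaN where ``valid`` is False.  ``mean`` is the arithmetic
    mean over valid samples and equals the corresponding plug-in average
    information exactly; ``mean_corrected`` additionally carries the
    Panzeri-Treves bias-corrected average (the locals themselves are
    reported uncorrected).
    """

    values: np.ndarray
    valid: np.ndarray
    mean: float
    mean_corrected: float | None = None
    bin_width: float = 1.0
    t0: float = 0.0

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        valid: np.ndarray,
        mean_corrected: float | None = None,
        bin_width: float = 1.0,
        t0: float = 0.0,
    ) -> "LocalSeries":
        values = np.asarray(values, float)
        valid = np.asarray(valid, bool)
        if values.shape != valid.shape:
            raise InputError("values and valid must have the same shape")
        mean = float(values[valid].mean()) if valid.any() else float("nan")
        return cls(values, valid, mean, mean_corrected, bin_width, t0)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) * self.bin_width

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_ms": self.times_ms, "value": self.values, "valid": self.valid.astype(int)}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LocalSeries":
        df = pd.read_csv(path)
        if not {"time_ms", "value"} <= set(df.columns):
            raise InputError(f"{path}: expected columns time_ms,value")
        vals = df["value"].to_numpy(float)
        if "valid" in df.columns:
            valid = df["valid"].to_numpy() != 0
        else:
            valid = ~np.isnan(vals)
        t = df["time_ms"].to_numpy(float)
        bw = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls.from_values(vals, valid, bin_width=bw, t0=float(t[0]))


def as_binary(series: BinnedSeries, name: str = "series") -> BinnedSeries:
    """Clip bins with >= 2 events to 1, warning with the clipped count.

    With 1 ms bins and neural refractoriness multi-event bins are rare;
    clipping keeps the alphabet binary for the estimators.
    """
    clipped = int(np.sum(series.values > 1))
    if clipped:
        warnings.warn(
            f"{name}: clipped {clipped} bins with >=2 events to 1", stacklevel=2
        )
        return BinnedSeries(
            np.minimum(series.values, 1), series.bin_width, series.t0
        )
    return series
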