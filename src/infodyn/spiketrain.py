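"""Spike-level bookkeeping: binning, ISIs, cross-correlograms, relayed-spike
annotation, spike tuples and spike-triggered averages of local measures.

Conventions: time bins are half-open [k*w, (k+1)*w) ms, 0-based; a spike
exactly on a bin edge belongs to the later bin.  An input (RGC) spike in
bin t is *relayed* if the output (LGN) train spikes in bin t + u, where u
is the reconstructed information-transfer delay; efficacy is the
percentage of input spikes relayed, contribution the percentage of output
spikes so triggered.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError
from .series import BinnedSeries, LocalSeries

__all__ = [
    "SpikeTrain",
    "CrossCorrelogram",
    "RelayAnnotation",
    "STAResult",
    "bin_spikes",
    "isi",
    "cross_correlogram",
    "annotate_relayed",
    "find_tuples",
    "spike_triggered_average",
    "label_permutation_test",
]


@dataclasses.dataclass
class SpikeTrain:
    """Strictly increasing spike times (ms) within [0, duration_ms)."""

    times_ms: np.ndarray
    duration_ms: float

    def __post_init__(self):
        t = np.asarray(self.times_ms, float).ravel()
        if t.size and np.any(np.diff(t) <= 0):
            raise InputError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] >= self.duration_ms):
            raise InputError("spike times must lie within [0, duration)")
        if self.duration_ms <= 0:
            raise InputError("duration must be positive")
        self.times_ms = t

    @property
    def n_spikes(self) -> int:
        return self.times_ms.size

    @property
    def rate_hz(self) -> float:
        return self.n_spikes / (self.duration_ms / 1000.0)

    @classmethod
    def from_file(cls, path, duration_ms=None, channel=None) -> "SpikeTrain":
        """Read from plain text (one time per line, ms) or a long CSV with
        columns channel,time_ms."""
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - I/O corner
            raise InputError(f"{path}: unreadable ({exc})") from exc
        if {"channel", "time_ms"} <= set(df.columns):
            if channel is None:
                raise InputError(f"{path}: long CSV requires a channel name")
            times = df.loc[df["channel"] == channel, "time_ms"].to_numpy(float)
        else:
            times = np.loadtxt(path, ndmin=1, dtype=float)
        times = np.sort(times)
        if duration_ms is None:
            duration_ms = float(times[-1]) + 1.0 if times.size else 1.0
        return cls(times, duration_ms)

    def to_file(self, path) -> None:
        np.savetxt(path, self.times_ms, fmt="%.4f")


def bin_spikes(train: SpikeTrain, bin_width_ms: float = 1.0) -> BinnedSeries:
    """Binary binning: value 1 iff at least one spike falls in the bin."""
    n_bins = int(np.ceil(train.duration_ms / bin_width_ms))
    n_bins = max(n_bins, 1)
    idx = np.floor(train.times_ms / bin_width_ms).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    clipped = int(np.sum(counts > 1))
    if clipped:
        warnings.warn(
            f"{clipped} bins contained >=2 spikes and were clipped to 1",
            stacklevel=2,
        )
    return BinnedSeries(np.minimum(counts, 1), bin_width_ms, 0.0)


def isi(train: SpikeTrain) -> np.ndarray:
    """Inter-spike intervals (ms); empty for fewer than two spikes."""
    if train.n_spikes < 2:
        return np.empty(0)
    return np.diff(train.times_ms)


@dataclasses.dataclass
class CrossCorrelogram:
    """Counts of output-minus-input spike time differences per 0.1 ms lag bin.

    Baseline statistics come from lag bins 30-50 ms on either side; the
    peak bin and contiguous neighbours with counts more than 3 SD above the
    baseline mean form ``peak_bins``.  A single-bin 3 SD exceedance can
    arise by chance in a long correlogram, so the operational connectivity
    call ``has_peak`` additionally requires at least ``min_peak_bins``
    contiguous significant bins (a genuine monosynaptic peak at 0.1 ms
    resolution spans several bins).
    """

    lags_ms: np.ndarray
    counts: np.ndarray
    baseline_mean: float
    baseline_sd: float
    peak_bins: np.ndarray  # indices into lags_ms, contiguous, may be empty
    sd_factor: float = 3.0

    @property
    def peak_lag_ms(self) -> float | None:
        if self.peak_bins.size == 0:
            return None
        return float(self.lags_ms[self.peak_bins[np.argmax(self.counts[self.peak_bins])]])

    def has_peak(self, min_peak_bins: int = 2) -> bool:
        return self.peak_bins.size >= min_peak_bins


def cross_correlogram(
    rgc: SpikeTrain,
    lgn: SpikeTrain,
    bin_ms: float = 0.1,
    max_lag_ms: float = 50.0,
    baseline_ms: tuple = (30.0, 50.0),
    sd_factor: float = 3.0,
) -> CrossCorrelogram:
    """Cross-correlogram of output (LGN) relative to input (RGC) spikes."""
    if rgc.n_spikes == 0 or lgn.n_spikes == 0:
        raise InputError("both trains must contain spikes")
    half = int(round(max_lag_ms / bin_ms))
    centers = np.arange(-half, half + 1) * bin_ms
    edges = np.concatenate([centers - bin_ms / 2, [centers[-1] + bin_ms / 2]])
    lo = np.searchsorted(lgn.times_ms, rgc.times_ms - max_lag_ms, side="left")
    hi = np.searchsorted(lgn.times_ms, rgc.times_ms + max_lag_ms, side="right")
    diffs = np.concatenate(
        [lgn.times_ms[a:b] - t for t, a, b in zip(rgc.times_ms, lo, hi)]
    ) if rgc.n_spikes else np.empty(0)
    counts, _ = np.histogram(diffs, bins=edges)
    base = (np.abs(centers) >= baseline_ms[0]) & (np.abs(centers) <= baseline_ms[1])
    baseline_mean = float(counts[base].mean())
    baseline_sd = float(counts[base].std(ddof=1))
    threshold = baseline_mean + sd_factor * baseline_sd
    search = np.abs(centers) < baseline_ms[0]
    masked = np.where(search, counts, -1)
    peak_idx = int(np.argmax(masked))
    if counts[peak_idx] > threshold:
        i = peak_idx
        while i > 0 and counts[i - 1] > threshold and search[i - 1]:
            i -= 1
        j = peak_idx
        while j < counts.size - 1 and counts[j + 1] > threshold and search[j + 1]:
            j += 1
        peak_bins = np.arange(i, j + 1)
    else:
        peak_bins = np.empty(0, dtype=int)
    return CrossCorrelogram(
        centers, counts, baseline_mean, baseline_sd, peak_bins, sd_factor
    )


@dataclasses.dataclass
class RelayAnnotation:
    """Per-input-spike relay labels with efficacy and contribution (%).

    ``contribution_defined`` is False for an empty output train, in which
    case contribution is reported as 0.
    """

    spike_bins: np.ndarray
    relayed: np.ndarray
    delay_used: int
    efficacy: float
    contribution: float
    contribution_defined: bool = True


def annotate_relayed(
    rgc_binned: BinnedSeries,
    lgn_binned: BinnedSeries,
    u: int,
    tolerance_bins: int = 0,
) -> RelayAnnotation:
    """Label input spikes as relayed iff the output spikes u bins later.

    ``tolerance_bins`` relaxes the strict-delay rule: a spike counts as
    relayed if the output spikes anywhere in u +- tolerance bins (default
    is strict equality).
    """
    if u < 1:
        raise InputError("delay u must be >= 1")
    if tolerance_bins < 0 or tolerance_bins >= u:
        raise InputError("tolerance must satisfy 0 <= tolerance < u")
    if len(rgc_binned) != len(lgn_binned):
        raise InputError("series length mismatch")
    n = len(rgc_binned)
    spike_bins = np.flatnonzero(rgc_binned.values > 0)
    lgn_spiked = lgn_binned.values > 0
    relayed = np.zeros(spike_bins.size, bool)
    for du in range(-tolerance_bins, tolerance_bins + 1):
        in_range = spike_bins + u + du < n
        relayed[in_range] |= lgn_spiked[spike_bins[in_range] + u + du]
    n_rgc = spike_bins.size
    efficacy = 100.0 * relayed.sum() / n_rgc if n_rgc else 0.0
    lgn_bins = np.flatnonzero(lgn_spiked)
    n_lgn = lgn_bins.size
    if n_lgn:
        rgc_spiked = rgc_binned.values > 0
        trig = np.zeros(n_lgn, bool)
        for du in range(-tolerance_bins, tolerance_bins + 1):
            src = lgn_bins - u - du
            ok = src >= 0
            trig[ok] |= rgc_spiked[src[ok]]
        contribution = 100.0 * trig.sum() / n_lgn
        defined = True
    else:
        contribution, defined = 0.0, False
    return RelayAnnotation(
        spike_bins, relayed, int(u), float(efficacy), float(contribution), defined
    )


def contribution_in_window(
    rgc: SpikeTrain, lgn: SpikeTrain, window_ms: tuple
) -> float:
    """Correlogram-window variant of the contribution (%): fraction of
    output spikes preceded by an input spike within (lo, hi] ms, e.g. the
    extent of the significant correlogram peak."""
    lo, hi = window_ms
    if lgn.n_spikes == 0:
        return 0.0
    left = np.searchsorted(rgc.times_ms, lgn.times_ms - hi, side="left")
    right = np.searchsorted(rgc.times_ms, lgn.times_ms - lo, side="right")
    return float(100.0 * np.mean(right > left))


def find_tuples(
    train: SpikeTrain, silence_ms: float = 20.0, max_isi_ms: float = 20.0
) -> list:
    """Spike pairs with a preceding silence and a short first ISI.

    A tuple is (first, second) spike times where the first spike is
    preceded by at least ``silence_ms`` without spikes (measured from the
    recording start for the first spike) and the second spike follows
    within ``max_isi_ms``.
    """
    t = train.times_ms
    out = []
    for i in range(t.size - 1):
        silence = t[i] - t[i - 1] if i > 0 else t[i]
        if silence >= silence_ms and (t[i + 1] - t[i]) <= max_isi_ms:
            out.append((float(t[i]), float(t[i + 1])))
    return out


@dataclasses.dataclass
class STAResult:
    offsets: np.ndarray  # bins relative to the event
    mean: np.ndarray
    sd: np.ndarray
    n_events: int


def spike_triggered_average(
    local: LocalSeries,
    event_bins,
    window_bins: tuple = (50, 50),
    align_shift: int = 0,
) -> STAResult:
    """Mean +- SD of local values around events.

    ``align_shift`` shifts the window relative to each event (e.g. by the
    reconstructed delay so that transfer values line up with the input
    spike that caused them).  Events whose window is not entirely within
    the valid range are dropped.
    """
    pre, post = int(window_bins[0]), int(window_bins[1])
    events = np.asarray(event_bins, int) + int(align_shift)
    n = len(local)
    ok = (events - pre >= 0) & (events + post < n)
    events = events[ok]
    offsets = np.arange(-pre, post + 1)
    if events.size == 0:
        raise DegenerateInputError("no events with a complete window")
    windows = local.values[events[:, None] + offsets[None, :]]
    valid = local.valid[events[:, None] + offsets[None, :]].all(axis=1)
    windows = windows[valid]
    if windows.shape[0] == 0:
        raise DegenerateInputError("no events with a fully valid window")
    return STAResult(
        offsets,
        windows.mean(axis=0),
        windows.std(axis=0, ddof=0),
        int(windows.shape[0]),
    )


def label_permutation_test(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed=None,
) -> tuple:
    """One-sided permutation test for mean(values[labels]) > mean(values[~labels]).

    Returns (observed difference, p-value).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise DegenerateInputError("both label groups must be non-empty")
    obs = values[labels].mean() - values[~labels].mean()
    rng = np.random.default_rng(seed)
    k = int(labels.sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values.size)
        sel = np.zeros(values.size, bool)
        sel[perm[:k]] = True
        if values[sel].mean() - values[~sel].mean() >= obs:
            count += 1
    return float(obs), (1.0 + count) / (n_perm + 1.0)
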