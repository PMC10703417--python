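"""Plug-in estimation of local and average information quantities.

All quantities are measured in bits (base-2 logarithms).  Probabilities are
relative frequencies of the symbol configurations observed over the valid
sample range (the first ``max(lags)`` samples of a series are masked
invalid rather than wrapped).  Local values are only ever evaluated at
observed configurations, so their defining probabilities are strictly
positive; averages use the 0 * log 0 = 0 convention.

The mean of a local series over valid samples equals the corresponding
plug-in average exactly: the average mutual information is the
probability-weighted average of the local mutual information values.

Plug-in averages are positively biased for finite samples.  The
Panzeri-Treves analytic correction (bias of each plug-in entropy term
~ -(R - 1) / (2 N ln 2), with R the number of occupied cells) is applied
to averaged estimates only; surrogate testing provides the inferential
control.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.special import xlogy

from .errors import (
    DegenerateInputError,
    InputError,
    UndefinedLocalError,
)
from .series import BinnedSeries, LocalSeries

_LN2 = math.log(2.0)

__all__ = [
    "JointTable",
    "SurrogateTestResult",
    "build_joint_table",
    "local_mi",
    "local_cmi",
    "average_mi",
    "average_cmi",
    "bias_corrected_mean",
    "lais",
    "lte",
    "pais",
    "surrogate_test",
    "ais_surrogate_test",
    "te_surrogate_test",
]


# ---------------------------------------------------------------------------
# joint probability tables


@dataclasses.dataclass
class JointTable:
    """Empirical joint probability table over a small set of discrete variables.

    ``probs`` has one axis per variable, in the order of ``variable_names``.
    When built by the plug-in rule every entry equals count / n_samples.
    """

    variable_names: tuple
    alphabet_sizes: tuple
    probs: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.variable_names = tuple(self.variable_names)
        self.alphabet_sizes = tuple(int(a) for a in self.alphabet_sizes)
        self.probs = np.asarray(self.probs, float).reshape(self.alphabet_sizes)
        if np.any(self.probs < 0):
            raise InputError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise InputError("probabilities must sum to 1")

    @property
    def n_vars(self) -> int:
        return len(self.alphabet_sizes)

    @classmethod
    def from_counts(cls, counts: np.ndarray, variable_names) -> "JointTable":
        counts = np.asarray(counts, float)
        n = counts.sum()
        if n <= 0:
            raise DegenerateInputError("no samples in count table")
        return cls(tuple(variable_names), counts.shape, counts / n, int(round(n)))

    def marginal(self, axes) -> np.ndarray:
        """Marginal over the given variable axes (kept axes, in order)."""
        axes = tuple(axes)
        drop = tuple(i for i in range(self.n_vars) if i not in axes)
        return self.probs.sum(axis=drop)

    def to_json(self) -> dict:
        return {
            "variable_names": list(self.variable_names),
            "alphabet_sizes": list(self.alphabet_sizes),
            "probs": self.probs.ravel().tolist(),  # row-major, variable order
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "JointTable":
        return cls(
            tuple(obj["variable_names"]),
            tuple(obj["alphabet_sizes"]),
            np.asarray(obj["probs"], float).reshape(obj["alphabet_sizes"]),
            int(obj["n_samples"]),
        )


def _lags_of(embedding) -> tuple:
    """Accept an EmbeddingSpec or a bare iterable of lags."""
    lags = getattr(embedding, "lags", embedding)
    lags = tuple(int(l) for l in lags)
    if any(l < 1 for l in lags):
        raise InputError("embedding lags must be >= 1")
    if len(set(lags)) != len(lags):
        raise InputError("duplicate embedding lags")
    return tuple(sorted(lags))


def _encode(cols, sizes):
    """Mixed-radix encoding of parallel symbol columns into one code column."""
    if not cols:
        return np.zeros(0, dtype=np.int64), 1
    code = np.zeros_like(cols[0], dtype=np.int64)
    total = 1
    for col, size in zip(cols, sizes):
        code = code * size + col
        total *= size
    return code, total


def build_joint_table(series, lag_spec, target_index=0) -> JointTable:
    """Empirical joint table over (target at lag 0, specified past variables).

    Parameters
    ----------
    series : list of BinnedSeries
        All of equal length and bin width.
    lag_spec : list of (series_index, lag)
        Past variables; lags >= 0 relative to the target sample.
    target_index : int
        Index of the series supplying the lag-0 target variable.
    """
    if not series:
        raise InputError("need at least one series")
    n = len(series[0])
    bw = series[0].bin_width
    for s in series:
        if len(s) != n:
            raise InputError("all series must have the same length")
        if s.bin_width != bw:
            raise InputError("all series must share one bin width")
    lag_spec = [(int(i), int(l)) for i, l in lag_spec]
    if any(l < 0 for _, l in lag_spec):
        raise InputError("lags must be >= 0")
    max_lag = max((l for _, l in lag_spec), default=0)
    if n - max_lag < 1:
        raise DegenerateInputError("no valid samples after max-lag truncation")

    sizes = [series[target_index].alphabet_size] + [
        series[i].alphabet_size for i, _ in lag_spec
    ]
    cols = [series[target_index].values[max_lag:n]] + [
        series[i].values[max_lag - l : n - l] for i, l in lag_spec
    ]
    code, total = _encode(cols, sizes)
    counts = np.bincount(code, minlength=total).reshape(sizes)
    names = [f"s{target_index}@t"] + [f"s{i}@t-{l}" for i, l in lag_spec]
    return JointTable.from_counts(counts, names)


# ---------------------------------------------------------------------------
# local and average (conditional) mutual information on tables


def local_mi(table: JointTable, x_sample: int, y_sample: int) -> float:
    """Local mutual information i(x:y) = log2 p(x,y)/(p(x)p(y)), in bits."""
    if table.n_vars != 2:
        raise InputError("local_mi needs a two-variable table")
    p_xy = table.probs[x_sample, y_sample]
    if p_xy <= 0:
        raise UndefinedLocalError(
            f"configuration ({x_sample},{y_sample}) was never observed"
        )
    p_x = table.probs.sum(axis=1)[x_sample]
    p_y = table.probs.sum(axis=0)[y_sample]
    return math.log2(p_xy / (p_x * p_y))


def local_cmi(table: JointTable, x_sample: int, y_sample: int, z_sample) -> float:
    """Local conditional MI i(x:y|z) = log2 p(x|y,z)/p(x|z), in bits.

    The table's variables are ordered (X, Y, Z1, Z2, ...); ``z_sample`` is a
    tuple matching the conditioning variables.
    """
    if table.n_vars < 3:
        raise InputError("local_cmi needs at least three variables")
    z = tuple(np.atleast_1d(z_sample).astype(int))
    if len(z) != table.n_vars - 2:
        raise InputError("z_sample length does not match conditioning variables")
    idx = (int(x_sample), int(y_sample)) + z
    p_xyz = table.probs[idx]
    if p_xyz <= 0:
        raise UndefinedLocalError(f"configuration {idx} was never observed")
    p_z = table.probs.sum(axis=(0, 1))[z]
    p_xz = table.probs.sum(axis=1)[(int(x_sample),) + z]
    p_yz = table.probs.sum(axis=0)[(int(y_sample),) + z]
    return math.log2(p_xyz * p_z / (p_xz * p_yz))


def average_mi(table: JointTable) -> float:
    """Plug-in average MI between variable 0 and all remaining variables."""
    p = table.probs.reshape(table.alphabet_sizes[0], -1)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(p, p) - xlogy(p, px * py)
    return float(np.nansum(terms) / _LN2)


def average_cmi(table: JointTable) -> float:
    """Plug-in average conditional MI I(V0 : V1 | V2, ..., Vk)."""
    if table.n_vars < 3:
        raise InputError("average_cmi needs at least three variables")
    p = table.probs.reshape(
        table.alphabet_sizes[0], table.alphabet_sizes[1], -1
    )
    p_z = p.sum(axis=(0, 1))
    p_xz = p.sum(axis=1)
    p_yz = p.sum(axis=0)
    # I = sum p log2( p * p_z / (p_xz * p_yz) )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (
            xlogy(p, p)
            + xlogy(p, p_z[None, None, :])
            - xlogy(p, p_xz[:, None, :])
            - xlogy(p, p_yz[None, :, :])
        )
    return float(np.nansum(terms) / _LN2)


def _occupied(counts: np.ndarray, axes) -> int:
    """Number of occupied cells of the marginal over the kept axes."""
    drop = tuple(i for i in range(counts.ndim) if i not in axes)
    marg = counts.sum(axis=drop) if drop else counts
    return int(np.count_nonzero(marg))


def bias_corrected_mean(table: JointTable, quantity: str = "mi") -> float:
    """Panzeri-Treves bias-corrected plug-in average MI or conditional MI.

    For ``quantity='mi'`` the information is I(V0 : V1..Vk); for ``'cmi'``
    it is I(V0 : V1 | V2..Vk).  The correction subtracts the analytic
    finite-sample bias of each constituent plug-in entropy,
    (R - 1) / (2 N ln 2), with R the number of occupied cells.
    """
    if table.n_samples <= 0:
        raise InputError("n_samples must be positive")
    counts = table.probs * table.n_samples
    n = table.n_samples
    k = table.n_vars
    if quantity == "mi":
        plugin = average_mi(table)
        r_x = _occupied(counts, (0,))
        r_y = _occupied(counts, tuple(range(1, k)))
        r_xy = _occupied(counts, tuple(range(k)))
        corr = ((r_x - 1) + (r_y - 1) - (r_xy - 1)) / (2.0 * n * _LN2)
    elif quantity == "cmi":
        plugin = average_cmi(table)
        zaxes = tuple(range(2, k))
        r_xz = _occupied(counts, (0,) + zaxes)
        r_yz = _occupied(counts, (1,) + zaxes)
        r_z = _occupied(counts, zaxes) if zaxes else 1
        r_xyz = _occupied(counts, tuple(range(k)))
        corr = ((r_xz - 1) + (r_yz - 1) - (r_z - 1) - (r_xyz - 1)) / (2.0 * n * _LN2)
    else:
        raise InputError("quantity must be 'mi' or 'cmi'")
    return plugin + corr


# ---------------------------------------------------------------------------
# local active information storage / transfer entropy / predictable information


def _past_code(series: BinnedSeries, lags, max_lag: int, n: int):
    """Mixed-radix code of the embedded past state over the valid window."""
    m = series.alphabet_size
    cols = [series.values[max_lag - l : n - l] for l in lags]
    return _encode(cols, [m] * len(cols))


def lais(x: BinnedSeries, embedding) -> LocalSeries:
    """Local active information storage i(x_t : x^S), per valid sample.

    Negative values indicate samples that were mispredicted by the
    embedded past.  ``mean`` equals the plug-in average AIS; the
    Panzeri-Treves corrected average is in ``mean_corrected``.
    """
    lags = _lags_of(embedding)
    n = len(x)
    if not lags:
        warnings.warn(
            "empty embedding: AIS of a memoryless model is 0", stacklevel=2
        )
        return LocalSeries.from_values(
            np.zeros(n), np.ones(n, bool), 0.0, x.bin_width, x.t0
        )
    max_lag = max(lags)
    if n - max_lag < 1:
        raise DegenerateInputError("series shorter than the embedding window")
    m = x.alphabet_size
    tgt = x.values[max_lag:]
    s_code, n_s = _past_code(x, lags, max_lag, n)
    nv = n - max_lag
    counts = np.bincount(tgt * n_s + s_code, minlength=m * n_s).reshape(m, n_s)
    c_t = counts.sum(axis=1)
    c_s = counts.sum(axis=0)
    local = np.log2(counts[tgt, s_code] * float(nv)) - np.log2(
        c_t[tgt] * c_s[s_code].astype(float)
    )
    values = np.full(n, np.nan)
    values[max_lag:] = local
    valid = np.zeros(n, bool)
    valid[max_lag:] = True
    r_t = np.count_nonzero(c_t)
    r_s = np.count_nonzero(c_s)
    r_ts = np.count_nonzero(counts)
    corrected = float(local.mean()) + ((r_t - 1) + (r_s - 1) - (r_ts - 1)) / (
        2.0 * nv * _LN2
    )
    return LocalSeries.from_values(values, valid, corrected, x.bin_width, x.t0)


def _lte_codes(x, y, source_lags, target_lags):
    """Shared preparation for lTE estimation and its surrogate test."""
    n = len(x)
    if len(y) != n:
        raise InputError("source and target series must have the same length")
    max_lag = max(source_lags + target_lags) if target_lags else max(source_lags)
    if n - max_lag < 1:
        raise DegenerateInputError("series shorter than the embedding window")
    tgt = y.values[max_lag:]
    xs_code, n_xs = _past_code(x, source_lags, max_lag, n)
    ys_code, n_ys = _past_code(y, target_lags, max_lag, n) if target_lags else (
        np.zeros(n - max_lag, dtype=np.int64),
        1,
    )
    return tgt, y.alphabet_size, xs_code, n_xs, ys_code, n_ys, max_lag


def _cmi_local_from_codes(tgt, m, xs_code, n_xs, ys_code, n_ys):
    nv = tgt.size
    counts = np.bincount(
        (tgt * n_xs + xs_code) * n_ys + ys_code, minlength=m * n_xs * n_ys
    ).reshape(m, n_xs, n_ys)
    c_ys = counts.sum(axis=(0, 1))
    c_t_ys = counts.sum(axis=1)
    c_xs_ys = counts.sum(axis=0)
    local = np.log2(
        counts[tgt, xs_code, ys_code] * c_ys[ys_code].astype(float)
    ) - np.log2(c_t_ys[tgt, ys_code] * c_xs_ys[xs_code, ys_code].astype(float))
    r_t_ys = np.count_nonzero(c_t_ys)
    r_xs_ys = np.count_nonzero(c_xs_ys)
    r_ys = np.count_nonzero(c_ys)
    r_all = np.count_nonzero(counts)
    corr = ((r_t_ys - 1) + (r_xs_ys - 1) - (r_ys - 1) - (r_all - 1)) / (
        2.0 * nv * _LN2
    )
    return local, corr


def cmi_from_codes(tgt, m, xs_code, n_xs, ys_code, n_ys) -> float:
    """Plug-in I(target : source-state | cond-state) in bits, from codes."""
    counts = np.bincount(
        (tgt * n_xs + xs_code) * n_ys + ys_code, minlength=m * n_xs * n_ys
    ).reshape(m, n_xs, n_ys).astype(float)
    nv = tgt.size
    c_z = counts.sum(axis=(0, 1))
    c_xz = counts.sum(axis=1)
    c_yz = counts.sum(axis=0)
    nz = counts > 0
    terms = counts[nz] * (
        np.log2(counts[nz])
        + np.log2(np.broadcast_to(c_z[None, None, :], counts.shape)[nz])
        - np.log2(np.broadcast_to(c_xz[:, None, :], counts.shape)[nz])
        - np.log2(np.broadcast_to(c_yz[None, :, :], counts.shape)[nz])
    )
    return float(terms.sum() / nv)


def lte(
    x: BinnedSeries,
    y: BinnedSeries,
    source_embedding,
    target_embedding,
) -> LocalSeries:
    """Local transfer entropy i(y_t : x^S | y^S), per valid sample.

    ``x`` is the source (input) and ``y`` the target (output) process; the
    source embedding lags are strictly past relative to y_t and subsume the
    conduction delay.  Negative values mark moments at which the source past
    misinformed about the target's actual next state.
    """
    if x is y:
        raise InputError("self-transfer is undefined: source is the target object")
    source_lags = _lags_of(source_embedding)
    if not source_lags:
        raise InputError("source embedding must be non-empty")
    target_lags = _lags_of(target_embedding)
    tgt, m, xs_code, n_xs, ys_code, n_ys, max_lag = _lte_codes(
        x, y, source_lags, target_lags
    )
    local, corr = _cmi_local_from_codes(tgt, m, xs_code, n_xs, ys_code, n_ys)
    n = len(y)
    values = np.full(n, np.nan)
    values[max_lag:] = local
    valid = np.zeros(n, bool)
    valid[max_lag:] = True
    return LocalSeries.from_values(
        values, valid, float(local.mean()) + corr, y.bin_width, y.t0
    )


def pais(
    s: BinnedSeries,
    extra_sources,
    embeddings,
) -> LocalSeries:
    """Predictable information i(s_t : s^-, n^-) from own plus extra pasts.

    ``embeddings[0]`` embeds the past of ``s`` itself, ``embeddings[i+1]``
    the past of ``extra_sources[i]``.  With no extra sources this reduces to
    :func:`lais`.
    """
    extra_sources = list(extra_sources)
    embeddings = list(embeddings)
    if len(embeddings) != 1 + len(extra_sources):
        raise InputError("need one embedding per series (self first)")
    if not extra_sources:
        return lais(s, embeddings[0])
    n = len(s)
    all_series = [s] + extra_sources
    for e in extra_sources:
        if len(e) != n:
            raise InputError("all series must have the same length")
    lag_sets = [_lags_of(e) for e in embeddings]
    if not any(lag_sets):
        warnings.warn("all embeddings empty: predictable information is 0", stacklevel=2)
        return LocalSeries.from_values(
            np.zeros(n), np.ones(n, bool), 0.0, s.bin_width, s.t0
        )
    max_lag = max(l for lags in lag_sets for l in lags)
    cols, sizes = [], []
    for ser, lags in zip(all_series, lag_sets):
        m = ser.alphabet_size
        for l in lags:
            cols.append(ser.values[max_lag - l : n - l])
            sizes.append(m)
    past_code, n_past = _encode(cols, sizes)
    tgt = s.values[max_lag:]
    m = s.alphabet_size
    nv = n - max_lag
    counts = np.bincount(tgt * n_past + past_code, minlength=m * n_past).reshape(
        m, n_past
    )
    c_t = counts.sum(axis=1)
    c_p = counts.sum(axis=0)
    local = np.log2(counts[tgt, past_code] * float(nv)) - np.log2(
        c_t[tgt] * c_p[past_code].astype(float)
    )
    values = np.full(n, np.nan)
    values[max_lag:] = local
    valid = np.zeros(n, bool)
    valid[max_lag:] = True
    r_t = np.count_nonzero(c_t)
    r_p = np.count_nonzero(c_p)
    r_tp = np.count_nonzero(counts)
    corrected = float(local.mean()) + ((r_t - 1) + (r_p - 1) - (r_tp - 1)) / (
        2.0 * nv * _LN2
    )
    return LocalSeries.from_values(values, valid, corrected, s.bin_width, s.t0)


# ---------------------------------------------------------------------------
# surrogate testing


@dataclasses.dataclass
class SurrogateTestResult:
    """One-sided surrogate test of an information estimate.

    p_value = (1 + #{null >= observed}) / (n_perm + 1), so p >= 1/(n_perm+1).
    """

    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    alpha: float
    significant: bool

    @classmethod
    def from_null(cls, observed, null_values, alpha) -> "SurrogateTestResult":
        null_values = np.asarray(null_values, float)
        n_perm = null_values.size
        p = (1.0 + np.count_nonzero(null_values >= observed)) / (n_perm + 1.0)
        return cls(float(observed), null_values, float(p), n_perm, alpha, p <= alpha)


def surrogate_test(
    stat_fn,
    series_to_shuffle: BinnedSeries,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed=None,
    min_shift: int = 1,
) -> SurrogateTestResult:
    """Generic circular-shift surrogate test.

    ``stat_fn`` maps a BinnedSeries (the shuffled one) to a scalar statistic.
    Surrogates preserve the autocorrelation of the shuffled series while
    destroying its cross-dependence; shifts are uniform in
    [min_shift, N - min_shift] where ``min_shift`` should be at least the
    maximum embedding lag.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    n = len(series_to_shuffle)
    if n < 2 * min_shift:
        raise DegenerateInputError("series shorter than twice the minimum shift")
    rng = np.random.default_rng(seed)
    observed = stat_fn(series_to_shuffle)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shift = int(rng.integers(min_shift, n - min_shift + 1))
        surr = BinnedSeries(
            np.roll(series_to_shuffle.values, shift),
            series_to_shuffle.bin_width,
            series_to_shuffle.t0,
        )
        null[i] = stat_fn(surr)
    return SurrogateTestResult.from_null(observed, null, alpha)


def _roll_test(tgt, m, var_code, n_var, cond_code, n_cond, n_perm, alpha, rng, min_shift):
    from ._fast import cmi_from_tzv_counts, hist_shifted

    nv = tgt.size
    if nv < 2 * min_shift:
        raise DegenerateInputError("valid window shorter than twice the minimum shift")
    base = ((tgt * n_cond + cond_code) * n_var).astype(np.int64)
    out = np.zeros(m * n_cond * n_var, dtype=np.int64)
    shape = (m, n_cond, n_var)

    def stat(shift):
        hist_shifted(base, var_code, shift, out)
        return cmi_from_tzv_counts(out.reshape(shape))

    observed = stat(0)
    null = np.empty(n_perm)
    shifts = rng.integers(min_shift, nv - min_shift + 1, size=n_perm)
    for i in range(n_perm):
        null[i] = stat(int(shifts[i]))
    return SurrogateTestResult.from_null(observed, null, alpha)


def ais_surrogate_test(
    x: BinnedSeries,
    embedding,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed=None,
) -> SurrogateTestResult:
    """Surrogate test of the mean AIS: the embedded past-state column is
    circularly rolled against the present sample (shift >= max lag)."""
    lags = _lags_of(embedding)
    if not lags:
        raise DegenerateInputError("cannot test an empty embedding")
    n = len(x)
    max_lag = max(lags)
    tgt = x.values[max_lag:]
    s_code, n_s = _past_code(x, lags, max_lag, n)
    rng = np.random.default_rng(seed)
    dummy = np.zeros(tgt.size, dtype=np.int64)
    return _roll_test(
        tgt, x.alphabet_size, s_code, n_s, dummy, 1, n_perm, alpha, rng, max_lag
    )


def te_surrogate_test(
    x: BinnedSeries,
    y: BinnedSeries,
    source_embedding,
    target_embedding,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed=None,
) -> SurrogateTestResult:
    """Surrogate test of the mean TE: the source past-state column is rolled
    against the aligned target present/past (shift >= max lag)."""
    source_lags = _lags_of(source_embedding)
    if not source_lags:
        raise DegenerateInputError("cannot test an empty source embedding")
    target_lags = _lags_of(target_embedding)
    tgt, m, xs_code, n_xs, ys_code, n_ys, max_lag = _lte_codes(
        x, y, source_lags, target_lags
    )
    rng = np.random.default_rng(seed)
    return _roll_test(
        tgt, m, xs_code, n_xs, ys_code, n_ys, n_perm, alpha, rng, max_lag
    )
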