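"""Independent brute-force reference implementations used as test oracles.

Everything here counts symbol configurations with plain Python dictionaries
and evaluates the defining log-ratios directly, independent of the
package's vectorized estimation path.
"""

import itertools
import math


def enumerate_samples(values_list, target_idx, lag_spec):
    """Yield (target_symbol, tuple of past symbols) over the valid window.

    ``lag_spec`` is a list of (series_index, lag).
    """
    n = len(values_list[0])
    max_lag = max((l for _, l in lag_spec), default=0)
    for t in range(max_lag, n):
        past = tuple(values_list[i][t - l] for i, l in lag_spec)
        yield values_list[target_idx][t], past


def brute_predictive_locals(values, lags):
    """Local i(x_t : x^S) per valid sample by dictionary counting.

    Returns (list of locals, mean).  Uses log2(c_joint * N) - log2(c_t * c_s)
    so the arithmetic path matches the definition exactly.
    """
    n = len(values)
    max_lag = max(lags)
    samples = [
        (values[t], tuple(values[t - l] for l in sorted(lags)))
        for t in range(max_lag, n)
    ]
    nv = len(samples)
    c_joint, c_t, c_s = {}, {}, {}
    for t, s in samples:
        c_joint[(t, s)] = c_joint.get((t, s), 0) + 1
        c_t[t] = c_t.get(t, 0) + 1
        c_s[s] = c_s.get(s, 0) + 1
    locals_ = [
        math.log2(c_joint[(t, s)] * nv) - math.log2(c_t[t] * c_s[s])
        for t, s in samples
    ]
    return locals_, sum(locals_) / nv


def brute_te_locals(x_values, y_values, source_lags, target_lags):
    """Local i(y_t : x^S | y^S) per valid sample by dictionary counting."""
    n = len(y_values)
    all_lags = tuple(source_lags) + tuple(target_lags)
    max_lag = max(all_lags)
    samples = []
    for t in range(max_lag, n):
        xs = tuple(x_values[t - l] for l in sorted(source_lags))
        ys = tuple(y_values[t - l] for l in sorted(target_lags))
        samples.append((y_values[t], xs, ys))
    nv = len(samples)
    c_all, c_tz, c_vz, c_z = {}, {}, {}, {}
    for t, xs, ys in samples:
        c_all[(t, xs, ys)] = c_all.get((t, xs, ys), 0) + 1
        c_tz[(t, ys)] = c_tz.get((t, ys), 0) + 1
        c_vz[(xs, ys)] = c_vz.get((xs, ys), 0) + 1
        c_z[ys] = c_z.get(ys, 0) + 1
    locals_ = [
        math.log2(c_all[(t, xs, ys)] * c_z[ys])
        - math.log2(c_tz[(t, ys)] * c_vz[(xs, ys)])
        for t, xs, ys in samples
    ]
    return locals_, sum(locals_) / nv


def brute_average_mi_from_samples(samples):
    """Plug-in I(T : S) in bits from (t, s) sample pairs."""
    nv = len(samples)
    c_joint, c_t, c_s = {}, {}, {}
    for t, s in samples:
        c_joint[(t, s)] = c_joint.get((t, s), 0) + 1
        c_t[t] = c_t.get(t, 0) + 1
        c_s[s] = c_s.get(s, 0) + 1
    return sum(
        c / nv * (math.log2(c * nv) - math.log2(c_t[t] * c_s[s]))
        for (t, s), c in c_joint.items()
    )


def brute_average_cmi_from_samples(samples):
    """Plug-in I(T : V | Z) in bits from (t, v, z) sample triples."""
    nv = len(samples)
    c_all, c_tz, c_vz, c_z = {}, {}, {}, {}
    for t, v, z in samples:
        c_all[(t, v, z)] = c_all.get((t, v, z), 0) + 1
        c_tz[(t, z)] = c_tz.get((t, z), 0) + 1
        c_vz[(v, z)] = c_vz.get((v, z), 0) + 1
        c_z[z] = c_z.get(z, 0) + 1
    return sum(
        c / nv * (
            math.log2(c * c_z[z]) - math.log2(c_tz[(t, z)] * c_vz[(v, z)])
        )
        for (t, v, z), c in c_all.items()
    )


def all_binary_series(length):
    """All binary sequences of the given length, as lists."""
    for bits in itertools.product((0, 1), repeat=length):
        yield list(bits)


def lag_subsets(pool=(1, 2, 3)):
    """All non-empty subsets of the candidate lag pool."""
    out = []
    for r in range(1, len(pool) + 1):
        out.extend(itertools.combinations(pool, r))
    return out
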