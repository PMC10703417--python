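"""Greedy nonuniform embedding optimization and transfer-delay reconstruction.

Past states are selected by greedy forward selection: at each step the
candidate lag with the largest conditional mutual information with the
predicted sample, given the variables already selected, is tested against
surrogate data and accepted only if significant.  Accepted candidates are
removed from the pool; selection stops at the first non-significant
candidate (no look-ahead).  The resulting lag set approximates Markov
sufficiency: the present becomes conditionally independent of the deeper
past given the selected variables.

Family-wise error across the repeated tests within one selection step is
controlled with a maximum-statistic correction: the observed best gain is
compared against the null distribution of the *maximum* gain over the
remaining pool, computed on circularly shifted candidate columns.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from ._fast import cmi_from_tzv_counts, hist_shifted
from .core import _encode, _lags_of, cmi_from_codes
from .errors import DegenerateInputError, InputError, NoTransferError
from .series import BinnedSeries

__all__ = [
    "EmbeddingSpec",
    "GreedyStep",
    "GreedyTrace",
    "DelayEstimate",
    "optimize_self_embedding",
    "optimize_te_embeddings",
    "reconstruct_delay",
]


@dataclasses.dataclass(frozen=True)
class EmbeddingSpec:
    """A selected set of past-variable lags (in bins, strictly increasing)."""

    lags: tuple
    series_role: str = "self"

    def __post_init__(self):
        lags = tuple(int(l) for l in self.lags)
        if any(l < 1 for l in lags):
            raise InputError("lags must be >= 1")
        if len(set(lags)) != len(lags):
            raise InputError("duplicate lags")
        if list(lags) != sorted(lags):
            lags = tuple(sorted(lags))
        object.__setattr__(self, "lags", lags)
        if self.series_role not in ("self", "source", "target"):
            raise InputError("series_role must be self, source or target")

    def __len__(self) -> int:
        return len(self.lags)

    def lags_ms(self, bin_width: float = 1.0):
        return [l * bin_width for l in self.lags]

    def to_json(self, bin_width: float = 1.0) -> dict:
        return {
            "lags": list(self.lags),
            "series_role": self.series_role,
            "bin_width_ms": bin_width,
        }

    @classmethod
    def from_json(cls, obj) -> "EmbeddingSpec":
        if isinstance(obj, str):
            obj = json.loads(obj)
        return cls(tuple(obj["lags"]), obj.get("series_role", "self"))


@dataclasses.dataclass
class GreedyStep:
    role: str
    lag: int
    gain_bits: float
    p_value: float
    accepted: bool


@dataclasses.dataclass
class GreedyTrace:
    candidate_pool: tuple
    steps: list

    def to_json(self) -> dict:
        return {
            "candidate_pool": list(self.candidate_pool),
            "steps": [dataclasses.asdict(s) for s in self.steps],
        }


@dataclasses.dataclass
class DelayEstimate:
    """Reconstructed information-transfer delay (bins) with per-lag CMI."""

    u_hat: int
    per_lag_contribution: dict


def _greedy_select(
    tgt,
    m,
    cand_cols,
    cand_size,
    cond_code,
    n_cond,
    alpha,
    n_perm,
    rng,
    min_shift,
    role,
    max_vars,
):
    """One greedy forward selection over a candidate pool.

    ``cand_cols`` maps lag -> aligned symbol column.  Returns the selected
    lags (in selection order) and the step records.  ``max_vars`` bounds
    the embedding size: every accepted variable doubles the conditioning
    state space, and past ~2^6 cells (binary symbols, recording lengths of
    order 1e5 bins) the plug-in estimates of further gains are dominated by
    finite-sample bias rather than structure, so selection is cut off once
    the table stops being estimable.
    """
    nv = tgt.size
    if nv < 2 * min_shift:
        raise DegenerateInputError("valid window shorter than twice the minimum shift")
    remaining = dict(sorted(cand_cols.items()))
    selected = []
    steps = []
    cond = cond_code.copy()
    ncond = n_cond
    while remaining and len(selected) < max_vars:
        lags = list(remaining)
        # the (target, conditioning) part of the joint code is fixed within
        # one step; each candidate/surrogate evaluation is then a single
        # fused shift-and-histogram pass
        base = ((tgt * ncond + cond) * cand_size).astype(np.int64)
        out = np.zeros(m * ncond * cand_size, dtype=np.int64)
        shape = (m, ncond, cand_size)

        def step_cmi(col, shift=0):
            hist_shifted(base, col, shift, out)
            return cmi_from_tzv_counts(out.reshape(shape))

        gains = np.array([step_cmi(remaining[l]) for l in lags])
        best_i = int(np.argmax(gains))  # exact ties: smallest lag wins
        best_lag = lags[best_i]
        best_gain = float(gains[best_i])
        # null distribution of the maximum gain over the remaining pool;
        # one shared shift per permutation preserves the dependence between
        # candidate gains under the null
        shifts = rng.integers(min_shift, nv - min_shift + 1, size=n_perm)
        null_max = np.empty(n_perm)
        for p in range(n_perm):
            mx = -np.inf
            for l in lags:
                g = step_cmi(remaining[l], int(shifts[p]))
                if g > mx:
                    mx = g
            null_max[p] = mx
        p_val = (1.0 + np.count_nonzero(null_max >= best_gain)) / (n_perm + 1.0)
        accepted = p_val <= alpha and best_gain > 0
        steps.append(GreedyStep(role, best_lag, best_gain, float(p_val), accepted))
        if not accepted:
            break
        selected.append(best_lag)
        col = remaining.pop(best_lag)
        cond = cond * cand_size + col
        ncond *= cand_size
    return selected, steps


def optimize_self_embedding(
    x: BinnedSeries,
    max_lag: int,
    alpha: float = 0.05,
    n_perm: int = 200,
    seed=None,
    role: str = "self",
    max_vars: int = 6,
):
    """Greedy selection of a maximally informative self-embedding.

    Candidate pool: lags 1..max_lag.  An empty result is a valid outcome
    meaning no detectable storage.  Selection stops at the first
    non-significant candidate or after ``max_vars`` accepted variables
    (the estimability bound, see :func:`_greedy_select`).  Deterministic
    given ``seed``.
    """
    if max_lag < 1:
        raise InputError("max_lag must be >= 1")
    n = len(x)
    if n <= 4 * max_lag:
        raise InputError("series too short: need N > 4 * max_lag")
    rng = np.random.default_rng(seed)
    m = x.alphabet_size
    tgt = x.values[max_lag:]
    cand_cols = {l: x.values[max_lag - l : n - l] for l in range(1, max_lag + 1)}
    dummy = np.zeros(tgt.size, dtype=np.int64)
    selected, steps = _greedy_select(
        tgt, m, cand_cols, m, dummy, 1, alpha, n_perm, rng, max_lag, role, max_vars
    )
    trace = GreedyTrace(tuple(range(1, max_lag + 1)), steps)
    return EmbeddingSpec(tuple(sorted(selected)), role), trace


def optimize_te_embeddings(
    x: BinnedSeries,
    y: BinnedSeries,
    max_lag_source: int,
    max_lag_target: int,
    max_delay: int = None,
    alpha: float = 0.05,
    n_perm: int = 200,
    seed=None,
    max_vars: int = 6,
):
    """Optimize target self-embedding first, then the source embedding in its
    context.

    Source candidates are lags 1..max_lag_source measured back from y_t,
    which subsumes information-transfer delays up to ``max_delay`` (the pool
    must therefore be at least as deep as the largest admissible delay).
    Returns (source EmbeddingSpec, target EmbeddingSpec, GreedyTrace); the
    trace contains the target-selection steps followed by the source steps.
    """
    if len(x) != len(y):
        raise InputError("source and target series must have the same length")
    if max_delay is not None and max_lag_source < max_delay:
        raise InputError("max_lag_source must be >= max_delay")
    rng = np.random.default_rng(seed)
    tgt_emb, tgt_trace = optimize_self_embedding(
        y,
        max_lag_target,
        alpha=alpha,
        n_perm=n_perm,
        seed=rng.integers(2**31),
        role="target",
        max_vars=max_vars,
    )
    n = len(y)
    max_lag = max(max_lag_source, max_lag_target)
    if n <= 4 * max_lag:
        raise InputError("series too short: need N > 4 * max(lag)")
    m = y.alphabet_size
    mx = x.alphabet_size
    tgt = y.values[max_lag:]
    if tgt_emb.lags:
        cond, ncond = _encode(
            [y.values[max_lag - l : n - l] for l in tgt_emb.lags],
            [m] * len(tgt_emb.lags),
        )
    else:
        cond, ncond = np.zeros(tgt.size, dtype=np.int64), 1
    cand_cols = {
        l: x.values[max_lag - l : n - l] for l in range(1, max_lag_source + 1)
    }
    selected, steps = _greedy_select(
        tgt, m, cand_cols, mx, cond, ncond, alpha, n_perm, rng, max_lag, "source",
        max_vars,
    )
    trace = GreedyTrace(tuple(range(1, max_lag_source + 1)), tgt_trace.steps + steps)
    src_emb = EmbeddingSpec(tuple(sorted(selected)), "source")
    return src_emb, tgt_emb, trace


def reconstruct_delay(
    x: BinnedSeries,
    y: BinnedSeries,
    source_embedding,
    target_embedding,
) -> DelayEstimate:
    """Information-transfer delay as the source lag with the highest
    conditional information contribution to y_t.

    u_hat = argmax_u I(y_t : x_{t-u} | {y^S, x^S \\ x_{t-u}}); exact ties are
    broken toward the smallest lag.
    """
    source_lags = _lags_of(source_embedding)
    if not source_lags:
        raise NoTransferError("empty source embedding: no transfer to locate")
    target_lags = _lags_of(target_embedding)
    n = len(y)
    max_lag = max(source_lags + target_lags)
    m = y.alphabet_size
    mx = x.alphabet_size
    tgt = y.values[max_lag:]
    contributions = {}
    for u in source_lags:
        others = [l for l in source_lags if l != u]
        cond_cols = [y.values[max_lag - l : n - l] for l in target_lags] + [
            x.values[max_lag - l : n - l] for l in others
        ]
        cond_sizes = [m] * len(target_lags) + [mx] * len(others)
        cond, ncond = (
            _encode(cond_cols, cond_sizes)
            if cond_cols
            else (np.zeros(tgt.size, dtype=np.int64), 1)
        )
        var = x.values[max_lag - u : n - u]
        contributions[u] = cmi_from_codes(tgt, m, var, mx, cond, ncond)
    best = max(contributions.values())
    # numerical ties (within round-off) break toward the smallest lag
    u_hat = min(u for u, c in contributions.items() if c >= best - 1e-12)
    return DelayEstimate(int(u_hat), contributions)
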