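"""Partial information decomposition via the unique-information optimization.

Decomposes the information two sources S1, S2 hold about a target T into
unique, shared (redundant) and synergistic atoms, using the
Bertschinger-Rauh-Olbrich-Jost-Ay definition: the unique information of S1
is the minimum of I_Q(T:S1|S2) over all distributions Q that preserve the
(T,S1) and (T,S2) pairwise marginals of the observed joint P.  The
remaining atoms follow from the consistency equations

    unique_s1 + shared = I(T:S1)
    unique_s2 + shared = I(T:S2)
    unique_s1 + unique_s2 + shared + synergy = I(T:S1,S2).

Applied to a transfer-entropy joint (T = y_t, S1 = source past x^S,
S2 = target past y^S), the unique information of the source past is the
state-independent transfer and the synergy the state-dependent transfer;
TE = unique_s1 + synergy.  Synergy is the signature of an XOR-like
"generalized prediction error" computation: the output is only determined
when input evidence and the target's own state are considered together.

This module is average-only; the optimization is a convex program over the
marginal-preserving polytope, solved with scipy (SLSQP over a basis of the
polytope's affine hull, analytic gradient).  A brute-force grid search over
the same polytope is shipped as an independent validation oracle for small
systems.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import minimize
from scipy.special import xlogy

from .core import JointTable, _encode, _lags_of
from .errors import ConvergenceError, InputError
from .series import BinnedSeries

_LN2 = math.log(2.0)

__all__ = ["PIDResult", "broja_pid", "brute_force_unique", "decompose_te"]


@dataclasses.dataclass
class PIDResult:
    """Unique / shared / synergistic decomposition of one target vs two sources.

    All atoms in bits.  ``optimizer_gap`` records the achieved numerical
    tolerance (constraint violation plus any clipped negativity).  When
    produced by :func:`decompose_te`, ``state_independent`` (= unique_s1),
    ``state_dependent`` (= synergy) and ``te`` are filled in.
    """

    unique_s1: float
    unique_s2: float
    shared: float
    synergy: float
    mi_total: float
    optimizer_gap: float
    state_independent: float | None = None
    state_dependent: float | None = None
    te: float | None = None
    sparsity_warning: bool = False

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def _as_array(joint) -> np.ndarray:
    if isinstance(joint, JointTable):
        if joint.n_vars != 3:
            raise InputError("PID needs a three-variable table (T, S1, S2)")
        p = joint.probs
    else:
        p = np.asarray(joint, float)
        if p.ndim != 3:
            raise InputError("PID joint must be a 3-D array (T, S1, S2)")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise InputError("joint must be a normalized distribution")
    return p / p.sum()


def _mi(p2: np.ndarray) -> float:
    """MI of a 2-D joint, bits."""
    px = p2.sum(axis=1, keepdims=True)
    py = p2.sum(axis=0, keepdims=True)
    return float((xlogy(p2, p2) - xlogy(p2, px * py)).sum() / _LN2)


def _cond_mi_ts1_given_s2(q: np.ndarray) -> float:
    """I_Q(T:S1|S2) of a (T,S1,S2) joint, bits."""
    q = np.maximum(q, 0.0)
    q_b = q.sum(axis=(0, 1))
    q_tb = q.sum(axis=1)
    q_ab = q.sum(axis=0)
    return float(
        (
            xlogy(q, q).sum()
            + xlogy(q_b, q_b).sum()
            - xlogy(q_tb, q_tb).sum()
            - xlogy(q_ab, q_ab).sum()
        )
        / _LN2
    )


def _basis(nt: int, n1: int, n2: int) -> np.ndarray:
    """Basis of the null space of the (T,S1) and (T,S2) marginal maps."""
    d = nt * (n1 - 1) * (n2 - 1)
    G = np.zeros((d, nt, n1, n2))
    k = 0
    for t in range(nt):
        for a in range(1, n1):
            for b in range(1, n2):
                G[k, t, a, b] += 1.0
                G[k, t, a, 0] -= 1.0
                G[k, t, 0, b] -= 1.0
                G[k, t, 0, 0] += 1.0
                k += 1
    return G


def _min_conditional_mi(P: np.ndarray, tol: float, max_starts: int = 5):
    """Minimize I_Q(T:S1|S2) over the marginal-preserving polytope.

    Returns (minimum in bits, achieved constraint violation).
    """
    nt, n1, n2 = P.shape
    G = _basis(nt, n1, n2)
    d = G.shape[0]
    if d == 0:
        return _cond_mi_ts1_given_s2(P), 0.0
    G2 = G.reshape(d, -1)
    eps = 1e-15

    def fun(lam):
        Q = P + np.tensordot(lam, G, axes=1)
        Qc = np.maximum(Q, eps)
        q_b = Qc.sum(axis=(0, 1))
        q_tb = Qc.sum(axis=1)
        q_ab = Qc.sum(axis=0)
        f = (
            xlogy(Qc, Qc).sum()
            + xlogy(q_b, q_b).sum()
            - xlogy(q_tb, q_tb).sum()
            - xlogy(q_ab, q_ab).sum()
        ) / _LN2
        grad_q = (
            np.log(Qc)
            + np.log(q_b)[None, None, :]
            - np.log(q_tb)[:, None, :]
            - np.log(q_ab)[None, :, :]
        ) / _LN2
        return f, G2 @ grad_q.ravel()

    cons = [
        {
            "type": "ineq",
            "fun": lambda lam: (P + np.tensordot(lam, G, axes=1)).ravel(),
            "jac": lambda lam: G2.T,
        }
    ]
    # each basis vector adds +1 to exactly one cell with a >= 1 and b >= 1,
    # so any feasible lambda lies in [-1, 1]^d
    bounds = [(-1.0, 1.0)] * d
    rng = np.random.default_rng(0)

    def evaluate(res):
        Q = P + np.tensordot(res.x, G, axes=1)
        violation = float(max(0.0, -Q.min()))
        value = _cond_mi_ts1_given_s2(np.maximum(Q, 0.0))
        return value, violation

    best = None
    for start in range(max_starts):
        if start == 0:
            lam0 = np.zeros(d)
        else:
            lam0 = rng.normal(scale=0.02, size=d)
            # shrink into the feasible region
            for _ in range(40):
                if (P + np.tensordot(lam0, G, axes=1)).min() >= 0:
                    break
                lam0 *= 0.5
            else:
                lam0 = np.zeros(d)
        res = minimize(
            fun,
            lam0,
            jac=True,
            method="SLSQP",
            bounds=bounds,
            constraints=cons,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        value, violation = evaluate(res)
        if violation <= 1e-9 and (best is None or value < best[0]):
            best = (value, violation, res)
    if best is None:
        # SLSQP left the polytope on every start: retry with the slower
        # interior-point-style solver
        from scipy.optimize import LinearConstraint

        res = minimize(
            fun,
            np.zeros(d),
            jac=True,
            method="trust-constr",
            bounds=bounds,
            constraints=[LinearConstraint(G2.T, lb=-P.ravel())],
            options={"maxiter": 2000, "gtol": 1e-10, "xtol": 1e-12},
        )
        value, violation = evaluate(res)
        if violation > 1e-6:
            raise ConvergenceError(
                f"polytope constraint violated by {violation:.2e}",
                result=(value, violation, res),
            )
        best = (value, violation, res)
    return best[0], best[1]


def broja_pid(joint, tol: float = 1e-8) -> PIDResult:
    """Bivariate PID of a (T, S1, S2) joint distribution.

    Tiny negative atoms from float round-off are clipped to zero and
    recorded in ``optimizer_gap``; a genuinely failed optimization raises
    :class:`ConvergenceError` with the best iterate attached.
    """
    P = _as_array(joint)
    nt, n1, n2 = P.shape
    i_ts1 = _mi(P.sum(axis=2))
    i_ts2 = _mi(P.sum(axis=1))
    mi_total = _mi(P.reshape(nt, n1 * n2))
    unique_s1, violation = _min_conditional_mi(P, tol)
    shared = i_ts1 - unique_s1
    unique_s2 = i_ts2 - shared
    synergy = mi_total - unique_s1 - unique_s2 - shared
    atoms = {"unique_s1": unique_s1, "unique_s2": unique_s2, "shared": shared,
             "synergy": synergy}
    clip = 0.0
    for k, v in atoms.items():
        if v < 0:
            if v < -1e-5:
                raise ConvergenceError(
                    f"PID atom {k} = {v:.3e} is negative beyond tolerance",
                    result=atoms,
                )
            clip = max(clip, -v)
            atoms[k] = 0.0
    gap = max(violation, clip, 1e-12)
    return PIDResult(
        atoms["unique_s1"], atoms["unique_s2"], atoms["shared"], atoms["synergy"],
        mi_total, gap,
    )


def brute_force_unique(joint, n_grid: int = 21, refine: int = 5) -> float:
    """Unique information of S1 by dense grid search over the polytope.

    Independent validation oracle for small systems (dimension of the
    polytope's affine hull at most 4); exact to roughly the final grid
    spacing, use ``refine`` rounds of zooming for ~1e-3 bits accuracy.
    """
    P = _as_array(joint)
    nt, n1, n2 = P.shape
    G = _basis(nt, n1, n2)
    d = G.shape[0]
    if d == 0:
        return _cond_mi_ts1_given_s2(P)
    if d > 4:
        raise InputError("brute-force oracle limited to polytope dimension <= 4")
    center = np.zeros(d)
    half = 1.0
    best_val, best_lam = np.inf, center
    for _ in range(refine):
        axes = [np.linspace(c - half, c + half, n_grid) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        lam_all = np.stack([g.ravel() for g in grids], axis=1)
        for lam in lam_all:
            Q = P + np.tensordot(lam, G, axes=1)
            if Q.min() < -1e-12:
                continue
            v = _cond_mi_ts1_given_s2(np.maximum(Q, 0.0))
            if v < best_val:
                best_val, best_lam = v, lam
        center = best_lam
        half = half * 2.0 / (n_grid - 1)  # one original grid cell, halved each pass
    return float(best_val)


def _condense_lags(cols, lags, cand_size, max_vars, tgt, m):
    """Keep the ``max_vars`` lags with the largest individual MI contribution."""
    from .core import cmi_from_codes

    if len(lags) <= max_vars:
        return lags
    dummy = np.zeros(tgt.size, dtype=np.int64)
    contrib = {
        l: cmi_from_codes(tgt, m, cols[l], cand_size, dummy, 1) for l in lags
    }
    keep = sorted(sorted(contrib, key=lambda l: -contrib[l])[:max_vars])
    return tuple(keep)


def decompose_te(
    x: BinnedSeries,
    y: BinnedSeries,
    source_embedding,
    target_embedding,
    max_vars: int = 3,
    tol: float = 1e-8,
) -> PIDResult:
    """PID of the transfer: T = y_t, S1 = source past state, S2 = target past.

    ``state_independent`` (unique information of the source past) and
    ``state_dependent`` (synergy) are filled in, and TE = unique + synergy
    holds within tolerance.  Embeddings with more than ``max_vars`` lags are
    condensed to the highest-contribution lags to keep the joint table
    estimable.  A sparsity warning is attached when not every past-state
    configuration of the full embedding was observed.
    """
    source_lags = _lags_of(source_embedding)
    target_lags = _lags_of(target_embedding)
    if not source_lags:
        raise InputError("source embedding must be non-empty")
    n = len(y)
    if len(x) != n:
        raise InputError("series length mismatch")
    max_lag = max(source_lags + target_lags)
    tgt = y.values[max_lag:]
    m = y.alphabet_size
    mx = x.alphabet_size

    def col(series, l):
        return series.values[max_lag - l : n - l]

    if len(source_lags) > max_vars:
        cols = {l: col(x, l) for l in source_lags}
        source_lags = _condense_lags(cols, source_lags, mx, max_vars, tgt, m)
    if len(target_lags) > max_vars:
        cols = {l: col(y, l) for l in target_lags}
        target_lags = _condense_lags(cols, target_lags, m, max_vars, tgt, m)

    xs_code, n_xs = _encode([col(x, l) for l in source_lags], [mx] * len(source_lags))
    if target_lags:
        ys_code, n_ys = _encode(
            [col(y, l) for l in target_lags], [m] * len(target_lags)
        )
    else:
        ys_code, n_ys = np.zeros(tgt.size, dtype=np.int64), 1

    # remap to observed symbols so the optimization stays small
    s1_vals, s1 = np.unique(xs_code, return_inverse=True)
    s2_vals, s2 = np.unique(ys_code, return_inverse=True)
    sparsity_warning = (s1_vals.size < n_xs) or (s2_vals.size < n_ys)
    k1, k2 = s1_vals.size, s2_vals.size
    counts = np.bincount(
        (tgt * k1 + s1) * k2 + s2, minlength=m * k1 * k2
    ).reshape(m, k1, k2)
    P = counts / counts.sum()

    result = broja_pid(P, tol=tol)
    te = float(_cond_mi_ts1_given_s2(P))
    result.state_independent = result.unique_s1
    result.state_dependent = result.synergy
    result.te = te
    result.sparsity_warning = bool(sparsity_warning)
    return result
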