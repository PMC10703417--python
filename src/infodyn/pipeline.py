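"""End-to-end analysis of one input/output spike-train pair.

Stages: bin -> optimize embeddings (input storage; target then source for
transfer) -> surrogate significance of storage and transfer -> delay
reconstruction -> local AIS / local TE -> storage-transfer correlation ->
PID of the transfer -> relayed-spike bookkeeping.  Pairs without
significant storage or transfer are excluded from the downstream stages
(the report carries an early-exit status instead).
"""

from __future__ import annotations

import dataclasses
import logging
import time

import numpy as np

from . import __version__
from .core import ais_surrogate_test, lais, lte, te_surrogate_test
from .embedding import optimize_self_embedding, optimize_te_embeddings, reconstruct_delay
from .errors import InputError
from .lstc import compute_lstc
from .pid import decompose_te
from .series import BinnedSeries
from .spiketrain import (
    SpikeTrain,
    annotate_relayed,
    bin_spikes,
    label_permutation_test,
)

logger = logging.getLogger("infodyn")

__all__ = ["RunConfig", "run_full_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Analysis parameters, defaulting to the retinogeniculate settings:
    1 ms bins, 30 ms storage / 40 ms source / 30 ms target maximum lags,
    delays up to 10 ms, alpha 0.05, 200 selection surrogates and 1000
    permutations for the final correlation test."""

    bin_width_ms: float = 1.0
    max_lag_ais_ms: float = 30.0
    max_lag_source_ms: float = 40.0
    max_lag_target_ms: float = 30.0
    max_delay_ms: float = 10.0
    alpha: float = 0.05
    n_perm_selection: int = 200
    n_perm_lstc: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in (
            "bin_width_ms",
            "max_lag_ais_ms",
            "max_lag_source_ms",
            "max_lag_target_ms",
            "max_delay_ms",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must lie in (0, 1)")

    def bins(self, ms: float) -> int:
        return max(1, int(round(ms / self.bin_width_ms)))

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a YAML/JSON key-value file; absent keys keep defaults."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name, t0):
    logger.info("%s done in %.1f s", name, time.perf_counter() - t0)
    return time.perf_counter()


def run_full_pipeline(rgc, lgn, config: RunConfig | None = None) -> dict:
    """Run the complete analysis on one pair; returns a JSON-ready report.

    ``rgc``/``lgn`` may be :class:`SpikeTrain` objects, file paths, or
    pre-binned :class:`BinnedSeries`.  All randomness flows from
    ``config.seed``; identical inputs and config give identical reports.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(2**31, size=8)

    def as_binned(obj, name):
        if isinstance(obj, BinnedSeries):
            return obj
        if isinstance(obj, SpikeTrain):
            return bin_spikes(obj, config.bin_width_ms)
        return bin_spikes(SpikeTrain.from_file(obj), config.bin_width_ms)

    t0 = time.perf_counter()
    x = as_binned(rgc, "rgc")
    y = as_binned(lgn, "lgn")
    if len(x) != len(y):
        n = min(len(x), len(y))
        x = BinnedSeries(x.values[:n], x.bin_width, x.t0)
        y = BinnedSeries(y.values[:n], y.bin_width, y.t0)
    bw = config.bin_width_ms
    report = {
        "package": "infodyn",
        "version": __version__,
        "config": config.to_json(),
        "n_bins": len(x),
        "status": "ok",
    }
    t0 = _stage("binning", t0)

    ais_emb, ais_trace = optimize_self_embedding(
        x,
        config.bins(config.max_lag_ais_ms),
        alpha=config.alpha,
        n_perm=config.n_perm_selection,
        seed=int(seeds[0]),
    )
    src_emb, tgt_emb, te_trace = optimize_te_embeddings(
        x,
        y,
        config.bins(config.max_lag_source_ms),
        config.bins(config.max_lag_target_ms),
        max_delay=config.bins(config.max_delay_ms),
        alpha=config.alpha,
        n_perm=config.n_perm_selection,
        seed=int(seeds[1]),
    )
    report["embeddings"] = {
        "ais_lags_ms": ais_emb.lags_ms(bw),
        "te_source_lags_ms": src_emb.lags_ms(bw),
        "te_target_lags_ms": tgt_emb.lags_ms(bw),
    }
    t0 = _stage("embedding optimization", t0)

    storage_sig = False
    if ais_emb.lags:
        ais_test = ais_surrogate_test(
            x, ais_emb, n_perm=config.n_perm_selection, alpha=config.alpha,
            seed=int(seeds[2]),
        )
        report["storage"] = {"mean_bits": ais_test.observed, "p": ais_test.p_value}
        storage_sig = ais_test.significant
    else:
        report["storage"] = {"mean_bits": 0.0, "p": 1.0}
    transfer_sig = False
    if src_emb.lags:
        te_test = te_surrogate_test(
            x, y, src_emb, tgt_emb, n_perm=config.n_perm_selection,
            alpha=config.alpha, seed=int(seeds[3]),
        )
        report["transfer"] = {"mean_bits": te_test.observed, "p": te_test.p_value}
        transfer_sig = te_test.significant
    else:
        report["transfer"] = {"mean_bits": 0.0, "p": 1.0}
    t0 = _stage("significance testing", t0)

    if not (storage_sig and transfer_sig):
        report["status"] = "no_significant_" + (
            "transfer" if storage_sig else "storage"
        )
        return report

    delay = reconstruct_delay(x, y, src_emb, tgt_emb)
    report["delay_ms"] = delay.u_hat * bw
    report["delay_contributions_bits"] = {
        str(u * bw): c for u, c in sorted(delay.per_lag_contribution.items())
    }

    lais_series = lais(x, ais_emb)
    lte_series = lte(x, y, src_emb, tgt_emb)
    report["lais_mean_bits"] = lais_series.mean
    report["lais_mean_bits_corrected"] = lais_series.mean_corrected
    report["lte_mean_bits"] = lte_series.mean
    report["lte_mean_bits_corrected"] = lte_series.mean_corrected
    t0 = _stage("local estimation", t0)

    lstc = compute_lstc(
        lais_series,
        lte_series,
        u=delay.u_hat,
        n_perm=config.n_perm_lstc,
        alpha=config.alpha,
        seed=int(seeds[4]),
    )
    report["lstc"] = lstc.to_json()
    t0 = _stage("LSTC", t0)

    pid = decompose_te(x, y, src_emb, tgt_emb)
    transferred = pid.unique_s1 + pid.synergy
    report["pid"] = pid.to_json()
    report["pid"]["unique_share"] = (
        pid.unique_s1 / transferred if transferred > 0 else float("nan")
    )
    report["pid"]["synergy_share"] = (
        pid.synergy / transferred if transferred > 0 else float("nan")
    )
    t0 = _stage("PID", t0)

    ann = annotate_relayed(x, y, delay.u_hat)
    spikes = {
        "n_rgc_spikes": int(ann.spike_bins.size),
        "n_relayed": int(ann.relayed.sum()),
        "efficacy_pct": ann.efficacy,
        "contribution_pct": ann.contribution,
    }
    if ann.relayed.any() and (~ann.relayed).any():
        v_lais = lais_series.values[ann.spike_bins]
        ok = lais_series.valid[ann.spike_bins]
        # lTE aligned to the triggering input spike via the delay
        lte_idx = ann.spike_bins + delay.u_hat
        in_range = lte_idx < len(lte_series)
        ok &= in_range
        v_lte = np.where(in_range, lte_series.values[np.minimum(lte_idx, len(lte_series) - 1)], np.nan)
        ok &= np.where(in_range, lte_series.valid[np.minimum(lte_idx, len(lte_series) - 1)], False)
        lab = ann.relayed[ok]
        d_lais, p_lais = label_permutation_test(
            v_lais[ok], lab, n_perm=config.n_perm_lstc, seed=int(seeds[5])
        )
        d_lte, p_lte = label_permutation_test(
            v_lte[ok], lab, n_perm=config.n_perm_lstc, seed=int(seeds[6])
        )
        spikes["lais_relayed_minus_nonrelayed_bits"] = d_lais
        spikes["lais_relayed_gt_nonrelayed_p"] = p_lais
        spikes["lte_relayed_minus_nonrelayed_bits"] = d_lte
        spikes["lte_relayed_gt_nonrelayed_p"] = p_lte
    report["spikes"] = spikes
    _stage("spike bookkeeping", t0)
    return report
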