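"""Synthetic generators with known ground truth.

Three families of fixtures make every analysis stage testable without
recorded data:

* binary Markov chains of arbitrary order (embedding-recovery ground truth);
* a delayed, ISI-facilitated relay synapse emulating the retinogeniculate
  generative structure: a bursty input point process whose spikes are
  relayed downstream at a fixed conduction delay, with relay probability
  boosted when the preceding inter-spike interval is short;
* two toy predictive-coding strategy units driven by a two-state Markov
  input: a unit that preferentially relays *predicted* input spikes
  (positive storage-transfer correlation) and an error-coding unit that
  fires exactly when the delayed input contradicts its internal state
  (XOR with the unit's last output), producing a negative correlation and
  synergy-dominant transfer.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import InputError
from .series import BinnedSeries
from .spiketrain import SpikeTrain

__all__ = [
    "SimConfig",
    "SimulatedPair",
    "simulate_markov_binary",
    "simulate_relay_synapse",
    "simulate_strategy_unit",
]


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Sizes match the order of typical retinogeniculate recording lengths
    (2e5 one-millisecond bins ~ 200 s).  The input inter-spike-interval
    mixture places a mode at short ISIs (bursts) over a slow background;
    facilitation boosts relay probability for spikes with a preceding ISI
    below ``facilitation_cutoff_ms``, echoing the heightened efficacy of
    short-ISI retinal spikes.
    """

    n_bins: int = 200_000
    bin_width_ms: float = 1.0
    seed: int | None = None
    # Markov-input parameters (strategy units)
    stay_prob: float = 0.8
    # bursty renewal input (relay synapse)
    burst_frac: float = 0.7
    burst_mean_ms: float = 4.0
    burst_min_ms: float = 2.0
    background_mean_ms: float = 60.0
    # coupling
    u_true: int = 3
    p_base: float = 0.25
    facilitation_gain: float = 0.55
    facilitation_cutoff_ms: float = 10.0
    lgn_noise_rate_hz: float = 5.0
    # strategy units
    strategy: str | None = None  # relay_predictable | error_coding
    relay_p_hi: float = 0.9
    relay_p_lo: float = 0.1
    response_noise: float = 0.05

    def __post_init__(self):
        for name in ("stay_prob", "burst_frac", "p_base", "relay_p_hi",
                     "relay_p_lo", "response_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be a probability")
        if self.u_true < 1:
            raise InputError("u_true must be >= 1")
        if self.n_bins < 10:
            raise InputError("n_bins too small")
        if self.strategy not in (None, "relay_predictable", "error_coding"):
            raise InputError("strategy must be relay_predictable or error_coding")


@dataclasses.dataclass
class SimulatedPair:
    """Input/output spike trains with generative ground truth attached.

    ``truth`` holds the conduction delay, per-input-spike relay flags, the
    strategy label and the generatively correct embeddings for analysis.
    """

    rgc: SpikeTrain
    lgn: SpikeTrain
    truth: dict


def simulate_markov_binary(
    order: int, p_spike, n: int, seed=None, burn_in: int = 1000
) -> BinnedSeries:
    """Binary Markov chain of the given order.

    ``p_spike`` is an array of shape (2,)*order giving
    P(x_t = 1 | x_{t-1}, ..., x_{t-order}), first axis = most recent lag.
    """
    p = np.asarray(p_spike, float)
    if p.shape != (2,) * order:
        raise InputError(f"p_spike must have shape {(2,) * order}")
    if np.any(p < 0) or np.any(p > 1):
        raise InputError("transition probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    x = np.zeros(total, dtype=np.int64)
    x[:order] = rng.integers(0, 2, size=order)
    u = rng.random(total)
    flat = p.ravel()
    state = 0
    for i in range(order):  # code = x_{t-1}*2^{order-1} + ... + x_{t-order}
        state = state * 2 + x[order - 1 - i]
    mask = 2 ** (order - 1)
    for t in range(order, total):
        x[t] = u[t] < flat[state]
        state = ((state % mask) * 2 + x[t]) if order > 1 else x[t]
    return BinnedSeries(x[burn_in:], 1.0, 0.0)


def _renewal_isis(rng, cfg: SimConfig, total_ms: float) -> np.ndarray:
    """Draw ISIs from the burst/background exponential mixture."""
    est = int(total_ms / (cfg.burst_frac * (cfg.burst_min_ms + cfg.burst_mean_ms)
                          + (1 - cfg.burst_frac) * cfg.background_mean_ms)) + 50
    out = []
    acc = 0.0
    while acc < total_ms:
        burst = rng.random(est) < cfg.burst_frac
        isis = np.where(
            burst,
            cfg.burst_min_ms + rng.exponential(cfg.burst_mean_ms, est),
            rng.exponential(cfg.background_mean_ms, est),
        )
        out.append(isis)
        acc += isis.sum()
    return np.concatenate(out)


def simulate_relay_synapse(cfg: SimConfig) -> SimulatedPair:
    """Bursty input relayed downstream with ISI-dependent facilitation.

    Each input spike is copied to the output at ``u_true`` bins delay with
    probability ``p_base``, raised by ``facilitation_gain`` when the
    preceding ISI is below the facilitation cutoff.  Independent output
    noise spikes are added at ``lgn_noise_rate_hz``.
    """
    rng = np.random.default_rng(cfg.seed)
    duration = cfg.n_bins * cfg.bin_width_ms
    isis = _renewal_isis(rng, cfg, duration)
    times = np.cumsum(isis)
    times = times[times < duration - cfg.u_true * cfg.bin_width_ms - 1]
    prev_isi = np.concatenate([[np.inf], np.diff(times)])
    p_relay = np.where(
        prev_isi < cfg.facilitation_cutoff_ms,
        np.minimum(cfg.p_base + cfg.facilitation_gain, 1.0),
        cfg.p_base,
    )
    relayed = rng.random(times.size) < p_relay
    lgn_times = times[relayed] + cfg.u_true * cfg.bin_width_ms
    if cfg.lgn_noise_rate_hz > 0:
        n_noise = rng.poisson(cfg.lgn_noise_rate_hz * duration / 1000.0)
        noise = rng.uniform(0, duration, n_noise)
        lgn_times = np.concatenate([lgn_times, noise])
    lgn_times = np.unique(lgn_times)
    lgn_times = lgn_times[lgn_times < duration]
    truth = {
        "u_true": cfg.u_true,
        "relayed": relayed,
        "strategy": "relay_synapse",
        "prev_isi_ms": prev_isi,
    }
    return SimulatedPair(
        SpikeTrain(times, duration), SpikeTrain(lgn_times, duration), truth
    )


def simulate_strategy_unit(cfg: SimConfig) -> SimulatedPair:
    """Toy units implementing the two opposing predictive-coding strategies.

    The input is a two-state Markov chain with stay probability
    ``stay_prob`` (> 0.5), so the most probable continuation of the input
    is its previous symbol.

    relay_predictable:
        an input spike is relayed (delay ``u_true``) with probability
        ``relay_p_hi`` when it confirmed the prediction (previous bin also
        spiked) and ``relay_p_lo`` when it was unpredicted.

    error_coding:
        the unit compares the delayed input symbol with its internal state
        (its own previous output) and fires exactly on mismatch - an XOR
        with the unit's prediction - with flip noise ``response_noise``.
        This transfers most information at unpredicted moments and makes
        the transfer synergy-dominant.
    """
    if cfg.strategy not in ("relay_predictable", "error_coding"):
        raise InputError("strategy must be relay_predictable or error_coding")
    rng = np.random.default_rng(cfg.seed)
    n, u = cfg.n_bins, cfg.u_true
    q = cfg.stay_prob
    x = np.zeros(n, dtype=np.int64)
    x[0] = rng.integers(0, 2)
    stay = rng.random(n) < q
    for t in range(1, n):  # stay-chain: keep the previous symbol w.p. q
        x[t] = x[t - 1] if stay[t] else 1 - x[t - 1]
    y = np.zeros(n, dtype=np.int64)
    if cfg.strategy == "relay_predictable":
        predicted = np.zeros(n, bool)
        predicted[1:] = (x[1:] == 1) & (x[:-1] == 1)
        unpredicted = np.zeros(n, bool)
        unpredicted[1:] = (x[1:] == 1) & (x[:-1] == 0)
        p = np.where(predicted, cfg.relay_p_hi, np.where(unpredicted, cfg.relay_p_lo, 0.0))
        fire = rng.random(n) < p
        idx = np.flatnonzero(fire)
        idx = idx[idx + u < n]
        y[idx + u] = 1
        # the output is a function of the source state alone, so the
        # generatively minimal target embedding is empty
        analysis = {"ais_lags": (1,), "source_lags": (u, u + 1), "target_lags": ()}
    else:
        flip = rng.random(n) < cfg.response_noise
        # y_t = x_{t-u} XOR y_{t-1} (XOR noise): cumulative parity of the
        # delayed input, so the unit's last output is its running prediction
        drive = np.zeros(n, dtype=np.int64)
        drive[u:] = x[: n - u]
        y = np.bitwise_xor.accumulate(drive ^ flip.astype(np.int64))
        analysis = {"ais_lags": (1,), "source_lags": (u,), "target_lags": (1, 2)}
    duration = n * cfg.bin_width_ms
    bw = cfg.bin_width_ms
    rgc = SpikeTrain(np.flatnonzero(x) * bw, duration)
    lgn_idx = np.flatnonzero(y)
    lgn = SpikeTrain(lgn_idx * bw, duration) if lgn_idx.size else SpikeTrain(
        np.empty(0), duration
    )
    truth = {
        "u_true": u,
        "strategy": cfg.strategy,
        "analysis": analysis,
        "x": x,
        "y": y,
    }
    return SimulatedPair(rgc, lgn, truth)
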