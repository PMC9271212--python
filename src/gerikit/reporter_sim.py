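"""Monte Carlo comparison of IEG-cell classification accuracy: a direct RNA
indicator (GERI, read 4-7 min after the stimulus while the TS is visible)
versus a short-half-life GFP reporter (read hours later, after maturation,
against a fluorescence threshold).

Each simulated cell fires basal transcription events as a Poisson process;
stimulus responders add one evoked event at the stimulus time. GERI calls a
cell positive when any event's transcription-on window covers the readout;
shGFP accumulates delayed, exponentially decaying protein fluorescence from
every event and thresholds it. Accuracy is measured against the responder
ground truth, so basal events degrade both reporters — the shGFP reporter
integrates them over hours while GERI only sees a ~minutes-wide window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class ReporterSimConfig:
    n_cells: int = 10_000
    sim_duration_h: float = 24.0  # basal history before the stimulus
    stimulus_time_h: float = 24.0
    evoked_activation_prob: float = 0.25
    basal_rate_per_h: Sequence[float] = (0.0, 0.01, 0.05, 0.1, 0.5)
    transcription_on_min: float = 15.0  # TS visible (decays by ~20 min)
    shgfp_maturation_h: float = 1.0
    shgfp_halflife_h: float = 2.0
    shgfp_threshold: float = 0.5  # units of one event's amplitude
    geri_readout_min: float = 5.0  # within the 4-7 min imaging window
    shgfp_readout_h: float = 2.0  # 1-3 h post stimulus
    n_reps: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.evoked_activation_prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if any(r < 0 for r in self.basal_rate_per_h):
            raise ValueError("rates must be non-negative")
        if self.sim_duration_h <= 0 or self.n_cells <= 0:
            raise ValueError("sim duration and cell count must be positive")


def simulate_cells(config: ReporterSimConfig, basal_rate_per_h: float,
                   rng: np.random.Generator):
    """Transcription event times per cell plus responder ground truth.

    Basal events are Poisson(basal_rate) over [0, sim_duration]; responders
    (drawn with ``evoked_activation_prob``) add one event exactly at the
    stimulus time. Times are in hours.
    """
    n = config.n_cells
    responder = rng.random(n) < config.evoked_activation_prob
    counts = rng.poisson(basal_rate_per_h * config.sim_duration_h, size=n)
    events = []
    for i in range(n):
        t = np.sort(rng.uniform(0, config.sim_duration_h, size=counts[i]))
        if responder[i]:
            t = np.append(t, config.stimulus_time_h)
        events.append(t)
    return events, responder


def geri_readout(events: list[np.ndarray], config: ReporterSimConfig) -> np.ndarray:
    """Positive iff some event's visibility window [t, t + on-time] covers
    the readout time (stimulus + 4-7 min)."""
    t_read = config.stimulus_time_h + config.geri_readout_min / 60.0
    on_h = config.transcription_on_min / 60.0
    return np.array([bool(np.any((t <= t_read) & (t_read <= t + on_h)))
                     for t in events])


def shgfp_readout(events: list[np.ndarray], config: ReporterSimConfig) -> np.ndarray:
    """Threshold the summed matured, decaying protein fluorescence.

    fluorescence(t) = sum_events H(t - t_e - maturation) *
    2^(-(t - t_e - maturation) / halflife), read at stimulus + readout.
    """
    t_read = config.stimulus_time_h + config.shgfp_readout_h
    mat, hl = config.shgfp_maturation_h, config.shgfp_halflife_h
    calls = np.empty(len(events), dtype=bool)
    for i, t in enumerate(events):
        age = t_read - t - mat
        f = float(np.sum(np.exp2(-age[age >= 0] / hl)))
        calls[i] = f > config.shgfp_threshold
    return calls


@dataclass
class SimResult:
    basal_rate_per_h: np.ndarray
    geri_accuracy: np.ndarray  # mean over reps
    shgfp_accuracy: np.ndarray
    geri_ci: np.ndarray  # (n_rates, 2) 95% normal CI over reps
    shgfp_ci: np.ndarray
    confusion: dict = field(default_factory=dict)  # rate -> (tp, fp, tn, fn) summed


def accuracy_sweep(config: ReporterSimConfig) -> SimResult:
    """Classification accuracy of both reporters across a basal-rate sweep.

    Accuracy = (TP + TN) / n against the responder ground truth, averaged
    over ``n_reps`` independent repetitions per basal rate.
    """
    config.validate()
    rates = np.asarray(config.basal_rate_per_h, dtype=float)
    if rates.size < 2:
        raise ValueError("need >= 2 basal rates in the sweep")
    rng = np.random.default_rng(config.seed)
    acc = {"geri": np.zeros((rates.size, config.n_reps)),
           "shgfp": np.zeros((rates.size, config.n_reps))}
    confusion = {}
    for ri, rate in enumerate(rates):
        tp = fp = tn = fn = 0
        for rep in range(config.n_reps):
            events, responder = simulate_cells(config, rate, rng)
            for name, call in (("geri", geri_readout(events, config)),
                               ("shgfp", shgfp_readout(events, config))):
                acc[name][ri, rep] = float(np.mean(call == responder))
                if name == "geri":
                    tp += int(np.sum(call & responder))
                    fp += int(np.sum(call & ~responder))
                    tn += int(np.sum(~call & ~responder))
                    fn += int(np.sum(~call & responder))
        confusion[float(rate)] = (tp, fp, tn, fn)

    def ci(a):
        m = a.mean(axis=1)
        se = a.std(axis=1, ddof=1) / np.sqrt(a.shape[1])
        return np.stack([m - 1.96 * se, m + 1.96 * se], axis=1)

    return SimResult(
        basal_rate_per_h=rates,
        geri_accuracy=acc["geri"].mean(axis=1),
        shgfp_accuracy=acc["shgfp"].mean(axis=1),
        geri_ci=ci(acc["geri"]),
        shgfp_ci=ci(acc["shgfp"]),
        confusion=confusion,
    )


def geri_false_positive_prob(basal_rate_per_h: float,
                             config: ReporterSimConfig) -> float:
    """Analytic GERI false-positive probability for a non-responder:
    1 - exp(-rate * effective_window), the chance a basal event lands in
    the on-time window preceding the readout.

    A basal event at time t is visible at the readout iff
    t_read - on_time <= t <= t_read; intersected with the basal epoch
    [0, stimulus], the window length is on_time - readout_delay (readout
    happens after the stimulus, so the trailing part of the window falls
    outside the basal epoch)."""
    on_h = config.transcription_on_min / 60.0
    delay_h = config.geri_readout_min / 60.0
    w = min(max(on_h - delay_h, 0.0), config.sim_duration_h)
    return 1.0 - float(np.exp(-basal_rate_per_h * w))
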