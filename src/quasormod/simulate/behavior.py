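"""Synthetic larval behavior: crawling tracks, type II firing, Ib bouts.

Emulates restrained/open-field larval recordings: a correlated random walk
with epoch-dependent speed under a dark/light schedule, octopaminergic
type II motor-neuron spiking that alternates between low-frequency tonic
firing and bursts (intraburst inter-spike intervals never shorter than
50 ms, i.e. up to 20 Hz), and glutamatergic Ib transmission bouts that the
type II bursts lead by a configurable interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from quasormod.behavior import EpochSchedule


@dataclass
class BehaviorSim:
    """Ground truth for one synthetic behavior session."""

    trajectory: pd.DataFrame  # t_s, x_mm, y_mm, valid
    typeii_spikes: np.ndarray  # spike times, s
    typeii_burst_onsets: np.ndarray
    ib_trace: pd.DataFrame  # t_s, dff
    ib_bouts: pd.DataFrame  # start_s, end_s
    schedule: EpochSchedule
    speeds_mm_s: dict


def simulate_behavior_traces(
    schedule: EpochSchedule | None = None,
    *,
    frame_rate_hz: float = 1.0,
    speeds_mm_s: dict | None = None,
    turn_sd_rad: float = 0.4,
    tonic_rate_hz: float = 0.1,
    burst_rate_hz: float = 15.0,
    burst_duration_s: float = 2.0,
    burst_lead_s: float = 4.0,
    burst_lead_jitter_s: float = 0.5,
    ib_bout_interval_s: float = 40.0,
    ib_bout_duration_s: float = 5.0,
    ib_trace_dt_s: float = 0.05,
    ib_noise_sd: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> BehaviorSim:
    """Generate one session of coupled locomotion/firing ground truth.

    Type II burst onsets precede each Ib bout onset by ``burst_lead_s``
    (plus jitter); intraburst inter-spike intervals are drawn as
    50 ms + Exponential, so the 20 Hz intraburst cap is never violated.
    """
    if schedule is None:
        schedule = EpochSchedule.default()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if speeds_mm_s is None:
        speeds_mm_s = {"acclimation": 0.1, "dark": 0.1, "light": 0.3}

    duration = schedule.end_s
    dt = 1.0 / frame_rate_hz
    t = np.arange(0.0, duration, dt)

    # correlated random walk
    theta = rng.uniform(0, 2 * math.pi)
    xs, ys = np.empty_like(t), np.empty_like(t)
    x = y = 0.0
    for i, ti in enumerate(t):
        xs[i], ys[i] = x, y
        speed = speeds_mm_s[schedule.label_at(ti)]
        theta += turn_sd_rad * math.sqrt(dt) * rng.standard_normal()
        x += speed * dt * math.cos(theta)
        y += speed * dt * math.sin(theta)
    trajectory = pd.DataFrame({"t_s": t, "x_mm": xs, "y_mm": ys, "valid": True})

    # Ib bouts: renewal process with a refractory gap so bouts never abut
    bout_starts = []
    min_gap_s = 3.0
    tb = rng.exponential(ib_bout_interval_s) + 10.0
    while tb + ib_bout_duration_s < duration:
        bout_starts.append(tb)
        tb += ib_bout_duration_s + min_gap_s + rng.exponential(ib_bout_interval_s)
    ib_bouts = pd.DataFrame(
        {"start_s": bout_starts, "end_s": [b + ib_bout_duration_s for b in bout_starts]}
    )

    # Ib trace: boxcar bouts + noise
    tt = np.arange(0.0, duration, ib_trace_dt_s)
    dff = np.zeros_like(tt)
    for b0, b1 in zip(ib_bouts["start_s"], ib_bouts["end_s"]):
        dff[(tt >= b0) & (tt < b1)] += 1.0
    if ib_noise_sd > 0:
        dff += ib_noise_sd * rng.standard_normal(len(tt))
    ib_trace = pd.DataFrame({"t_s": tt, "dff": dff})

    # type II spikes: tonic background + bursts leading Ib bouts
    spikes = []
    ts = rng.exponential(1.0 / tonic_rate_hz) if tonic_rate_hz > 0 else duration + 1
    while ts < duration:
        spikes.append(ts)
        ts += rng.exponential(1.0 / tonic_rate_hz)
    min_isi = 0.05  # 20 Hz intraburst cap
    mean_isi = max(1.0 / burst_rate_hz, min_isi)
    burst_onsets = []
    for b0 in bout_starts:
        onset = b0 - burst_lead_s + burst_lead_jitter_s * rng.standard_normal()
        onset = max(onset, 0.0)
        burst_onsets.append(onset)
        ts = onset
        while ts < onset + burst_duration_s:
            spikes.append(ts)
            ts += min_isi + rng.exponential(max(mean_isi - min_isi, 1e-3))
    spikes = np.sort(np.array([s for s in spikes if 0 <= s < duration]))

    return BehaviorSim(
        trajectory=trajectory,
        typeii_spikes=spikes,
        typeii_burst_onsets=np.asarray(burst_onsets),
        ib_trace=ib_trace,
        ib_bouts=ib_bouts,
        schedule=schedule,
        speeds_mm_s=dict(speeds_mm_s),
    )
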