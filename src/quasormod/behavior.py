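"""Larval locomotion and motor-neuron bout-coupling analysis.

Covers centroid tracking with the 1 mm / 2 s merge rule, per-epoch
displacement and velocity under dark-light schedules (path length, with a
5 min acclimation excluded from summaries), threshold bout detection on
calcium traces, and the coupling of octopaminergic type II firing to
glutamatergic Ib transmission bouts (firing rate in the 8 s before each
bout versus the whole recording, in 50 ms bins).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from quasormod.stats import run_tests


@dataclass
class EpochSchedule:
    """Ordered, contiguous, non-overlapping behavioral blocks."""

    blocks: list  # of (label, start_s, end_s)

    VALID_LABELS = ("acclimation", "dark", "light")

    def __post_init__(self) -> None:
        prev_end = None
        for label, start, end in self.blocks:
            if label not in self.VALID_LABELS:
                raise ValueError(f"unknown epoch label {label!r}")
            if end <= start:
                raise ValueError("epoch end must exceed start")
            if prev_end is not None and not math.isclose(start, prev_end):
                raise ValueError("epochs must be contiguous and non-overlapping")
            prev_end = end

    @classmethod
    def default(cls) -> "EpochSchedule":
        """5 min acclimation, then dark/light/dark/light at 15 min each."""
        blocks = [("acclimation", 0.0, 300.0)]
        t = 300.0
        for label in ("dark", "light", "dark", "light"):
            blocks.append((label, t, t + 900.0))
            t += 900.0
        return cls(blocks)

    @property
    def end_s(self) -> float:
        return self.blocks[-1][2]

    def label_at(self, t: float) -> str:
        for label, start, end in self.blocks:
            if start <= t < end:
                return label
        return self.blocks[-1][0] if t >= self.end_s else self.blocks[0][0]


def track_centroids(
    frames: np.ndarray | None = None,
    detections: pd.DataFrame | None = None,
    *,
    frame_rate_hz: float = 1.0,
    mm_per_px: float = 1.0,
    merge_radius_mm: float = 1.0,
    merge_window_s: float = 2.0,
) -> pd.DataFrame:
    """Per-frame centroid track with the jitter-merge pass.

    Input is either an image stack (intensity-weighted centroid per frame;
    empty frames are flagged invalid) or a per-frame detection table with
    x_mm / y_mm columns.  Centroids that stay within ``merge_radius_mm`` of
    each other over a sliding ``merge_window_s`` window are collapsed to
    their center of mass, assigned to the window's central frame — this
    never increases path length.
    """
    if (frames is None) == (detections is None):
        raise ValueError("pass exactly one of frames or detections")
    dt = 1.0 / frame_rate_hz
    if frames is not None:
        frames = np.asarray(frames, dtype=float)
        t = np.arange(frames.shape[0]) * dt
        xs, ys, valid = [], [], []
        for f in frames:
            s = f.sum()
            if s <= 0:
                xs.append(np.nan), ys.append(np.nan), valid.append(False)
            else:
                yy, xx = np.mgrid[0 : f.shape[0], 0 : f.shape[1]]
                xs.append((f * xx).sum() / s * mm_per_px)
                ys.append((f * yy).sum() / s * mm_per_px)
                valid.append(True)
        traj = pd.DataFrame({"t_s": t, "x_mm": xs, "y_mm": ys, "valid": valid})
    else:
        traj = detections.copy()
        if "t_s" not in traj.columns:
            traj.insert(0, "t_s", np.arange(len(traj)) * dt)
        if "valid" not in traj.columns:
            traj["valid"] = np.isfinite(traj["x_mm"]) & np.isfinite(traj["y_mm"])

    # merge pass, iterated to a fixpoint (merged samples can merge again)
    current = traj[["t_s", "x_mm", "y_mm", "valid"]].to_numpy()
    while True:
        merged = _merge_once(current, merge_radius_mm, merge_window_s)
        if len(merged) == len(current):
            break
        current = merged
    return pd.DataFrame(current, columns=["t_s", "x_mm", "y_mm", "valid"]).astype(
        {"t_s": float, "x_mm": float, "y_mm": float, "valid": bool}
    )


def _merge_once(arr: np.ndarray, radius_mm: float, window_s: float) -> np.ndarray:
    t = arr[:, 0].astype(float)
    pts = arr[:, 1:3].astype(float)
    valid = arr[:, 3].astype(bool)
    out = []
    i = 0
    n = len(arr)
    while i < n:
        if not valid[i]:
            out.append((t[i], pts[i, 0], pts[i, 1], False))
            i += 1
            continue
        j = i
        # grow the cluster while consecutive samples arrive within the 2 s
        # interval and all members stay strictly within the merge radius of
        # each other: a stationary stretch collapses to one sample
        while j + 1 < n and valid[j + 1] and t[j + 1] - t[j] <= window_s:
            cluster = pts[i : j + 2]
            d = np.sqrt(((cluster[:, None] - cluster[None, :]) ** 2).sum(-1))
            if d.max() < radius_mm:
                j += 1
            else:
                break
        if j > i:
            com = pts[i : j + 1].mean(axis=0)
            mid = (i + j) // 2
            out.append((t[mid], com[0], com[1], True))
        else:
            out.append((t[i], pts[i, 0], pts[i, 1], True))
        i = j + 1
    return np.array(out, dtype=float)


def epoch_displacement(
    traj: pd.DataFrame,
    schedule: EpochSchedule,
    *,
    velocity_smooth_s: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Path-length displacement per epoch plus a smoothed velocity trace.

    Displacement is the cumulative distance over consecutive valid steps
    within the epoch; acclimation is excluded from summaries; an epoch with
    no valid samples is reported as missing (NaN), not zero.
    """
    ok = traj[traj["valid"]].reset_index(drop=True)
    rows = []
    for label, start, end in schedule.blocks:
        sel = ok[(ok["t_s"] >= start) & (ok["t_s"] < end)]
        if len(sel) == 0:
            rows.append({"label": label, "start_s": start, "end_s": end,
                         "displacement_mm": np.nan, "missing": True})
            continue
        steps = np.sqrt(np.diff(sel["x_mm"]) ** 2 + np.diff(sel["y_mm"]) ** 2)
        rows.append({"label": label, "start_s": start, "end_s": end,
                     "displacement_mm": float(steps.sum()), "missing": False})
    epochs = pd.DataFrame(rows)

    dt = np.diff(ok["t_s"].to_numpy())
    steps = np.sqrt(np.diff(ok["x_mm"]) ** 2 + np.diff(ok["y_mm"]) ** 2)
    v = np.where(dt > 0, steps / dt, np.nan)
    tv = ok["t_s"].to_numpy()[1:]
    if len(v):
        win = max(1, int(round(velocity_smooth_s / np.median(dt))))
        v_s = pd.Series(v).rolling(win, center=True, min_periods=1).mean().to_numpy()
    else:
        v_s = v
    velocity = pd.DataFrame({"t_s": tv, "v_mm_s": v, "v_smooth_mm_s": v_s})
    velocity = velocity[velocity["t_s"] >= schedule.blocks[0][2]].reset_index(drop=True) \
        if schedule.blocks[0][0] == "acclimation" else velocity
    return epochs, velocity


def detect_bouts(
    t: np.ndarray,
    trace: np.ndarray,
    *,
    mad_multiplier: float = 3.0,
    min_duration_s: float = 0.5,
    merge_gap_s: float = 0.5,
) -> pd.DataFrame:
    """Threshold bout detection: baseline + c x MAD, minimum duration, gap fusion."""
    t = np.asarray(t, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if len(t) != len(trace):
        raise ValueError("t and trace must align")
    baseline = np.median(trace)
    mad = 1.4826 * np.median(np.abs(trace - baseline))
    if mad == 0:
        return pd.DataFrame(columns=["start_s", "end_s"])
    above = trace > baseline + mad_multiplier * mad
    # maximal runs
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    bouts = [(t[s], t[e - 1] + (t[1] - t[0] if len(t) > 1 else 0.0)) for s, e in zip(starts, ends)]
    # fuse gaps
    fused = []
    for b in bouts:
        if fused and b[0] - fused[-1][1] < merge_gap_s:
            fused[-1] = (fused[-1][0], b[1])
        else:
            fused.append(b)
    fused = [(s, e) for s, e in fused if e - s >= min_duration_s]
    return pd.DataFrame(fused, columns=["start_s", "end_s"])


def bout_coupling_stats(
    spikes_per_recording: list,
    bouts_per_recording: list,
    recording_length_s: float,
    *,
    pre_window_s: float = 8.0,
    bin_s: float = 0.05,
) -> dict:
    """Type II firing rate before Ib bouts vs. the whole recording.

    Rates are events per ``bin_s`` (50 ms) bin; "before" pools the
    [start - 8 s, start) windows of all bouts in a recording (truncated and
    flagged when a bout starts earlier than 8 s in); the paired comparison
    across recordings is a Wilcoxon signed-rank test.
    """
    before_rates, overall_rates = [], []
    n_truncated = 0
    for spikes, bouts in zip(spikes_per_recording, bouts_per_recording):
        spikes = np.asarray(spikes, dtype=float)
        overall_rates.append(len(spikes) * bin_s / recording_length_s)
        window_time = 0.0
        window_events = 0
        starts = bouts["start_s"].to_numpy() if isinstance(bouts, pd.DataFrame) else np.asarray(bouts)
        for b0 in starts:
            w0 = max(0.0, b0 - pre_window_s)
            if w0 > b0 - pre_window_s + 1e-12 or b0 < pre_window_s:
                n_truncated += int(b0 < pre_window_s)
            window_time += b0 - w0
            window_events += int(((spikes >= w0) & (spikes < b0)).sum())
        before_rates.append(window_events * bin_s / window_time if window_time > 0 else np.nan)
    before = np.asarray(before_rates)
    overall = np.asarray(overall_rates)
    finite = np.isfinite(before)
    report = {
        "before_rate_per_bin": before.tolist(),
        "overall_rate_per_bin": overall.tolist(),
        "n_recordings": len(overall),
        "n_truncated_windows": n_truncated,
        "pre_window_s": pre_window_s,
        "bin_s": bin_s,
    }
    if finite.sum() >= 2 and not np.allclose(before[finite], overall[finite]):
        report["wilcoxon"] = run_tests([before[finite], overall[finite]], "wilcoxon_signed_rank")
    else:
        report["wilcoxon"] = None
    return report
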