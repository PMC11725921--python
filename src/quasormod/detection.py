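"""Stimulus-locked quantal event detection.

A raw movie is registered, bleach-corrected, and converted to ΔF/F.  A
single temporal response template (average stimulus-aligned profile of
supra-threshold responses, unit peak) is then fitted per pixel per trial;
pixels whose fitted peak amplitude clears both an absolute ΔF/F threshold
(band 0.04–0.05) and a multiple (1.5–2x) of that pixel's quiescent SD are
grouped into events by 8-adjacency plus trace correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.registration import phase_cross_correlation

from quasormod.movie import DffMovie


@dataclass
class DetectionConfig:
    """Quantal event detection parameters.

    ``amp_threshold_dff`` outside [0.04, 0.05] or ``sd_multiplier`` outside
    [1.5, 2] is allowed but warned about: those bands bracket the operating
    range of the quantal imaging assay this emulates.
    """

    amp_threshold_dff: float = 0.045
    sd_multiplier: float = 1.75
    template_window: int = 20
    corr_threshold: float = 0.6
    response_window: int | None = None  # defaults to template_window
    canonical_tau_frames: float = 5.0

    def __post_init__(self) -> None:
        if self.amp_threshold_dff <= 0 or self.sd_multiplier <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.04 <= self.amp_threshold_dff <= 0.05:
            warnings.warn(
                f"amp_threshold_dff={self.amp_threshold_dff} outside the usual "
                "0.04-0.05 dF/F band"
            )
        if not 1.5 <= self.sd_multiplier <= 2.0:
            warnings.warn(
                f"sd_multiplier={self.sd_multiplier} outside the usual 1.5-2 band"
            )
        if self.template_window < 2:
            raise ValueError("template_window must span at least 2 frames")
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in (0, 1]")
        if self.response_window is None:
            self.response_window = self.template_window


@dataclass(frozen=True)
class DetectedEvent:
    """One detected stimulus-locked quantal event."""

    trial: int
    peak_frame: int
    footprint: frozenset
    peak_pixel: tuple
    peak_dff: float
    amplitude: float
    flags: tuple = ()


def events_to_frame(events: list[DetectedEvent]) -> pd.DataFrame:
    rows = [
        {
            "trial": e.trial,
            "peak_frame": e.peak_frame,
            "row": e.peak_pixel[0],
            "col": e.peak_pixel[1],
            "peak_dff": e.peak_dff,
            "amplitude": e.amplitude,
            "footprint_size": len(e.footprint),
            "flags": ";".join(e.flags),
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "trial",
            "peak_frame",
            "row",
            "col",
            "peak_dff",
            "amplitude",
            "footprint_size",
            "flags",
        ],
    )


def _trial_bounds(stimulus_frames: np.ndarray, n_frames: int, baseline_frames: int) -> list:
    """Half-open [start, stop) frame ranges per trial."""
    bounds = []
    for i, s in enumerate(stimulus_frames):
        start = s - baseline_frames
        stop = stimulus_frames[i + 1] - baseline_frames if i + 1 < len(stimulus_frames) else n_frames
        bounds.append((max(0, start), min(stop, n_frames)))
    return bounds


def quiescent_frames(
    stimulus_frames: np.ndarray, n_frames: int, response_window: int
) -> np.ndarray:
    """Boolean index of frames outside every stimulus response window."""
    quiet = np.ones(n_frames, dtype=bool)
    for s in stimulus_frames:
        quiet[s : min(n_frames, s + response_window)] = False
    return quiet


def preprocess_movie(
    raw: np.ndarray,
    stimulus_frames: np.ndarray,
    pixel_size_nm: float,
    frame_interval_ms: float,
    *,
    baseline_frames: int = 5,
    register: bool = False,
    bleach_correct: bool = False,
    response_window: int = 20,
    mask_percentile: float = 50.0,
    subpixel: bool = False,
) -> tuple[DffMovie, np.ndarray]:
    """Raw movie -> registered, bleach-corrected ΔF/F movie.

    Registration: rigid per-frame translation against the mean of the first
    trial's baseline window by windowed cross-correlation (integer-pixel by
    default).  Bleaching: per-pixel monoexponential fitted to stimulus-free
    frames and divided out.  ΔF/F uses a per-trial F0 (mean of the
    pre-stimulus window); the mask keeps pixels whose mean F0 exceeds the
    ``mask_percentile`` percentile.  Returns the movie and the per-frame
    (dy, dx) shifts that were applied.
    """
    raw = np.asarray(raw, dtype=np.float64)
    stimulus_frames = np.asarray(stimulus_frames, dtype=int)
    if raw.ndim != 3 or raw.shape[0] < 2:
        raise ValueError("raw movie must be (time, rows, cols) with >= 2 frames")
    if len(stimulus_frames) == 0:
        raise ValueError("at least one stimulus frame required")
    if stimulus_frames[0] - baseline_frames < 0:
        raise ValueError("no baseline frames before the first stimulus")

    n_frames = raw.shape[0]
    shifts = np.zeros((n_frames, 2))
    if register:
        ref = raw[stimulus_frames[0] - baseline_frames : stimulus_frames[0]].mean(axis=0)
        movie = np.empty_like(raw)
        upsample = 10 if subpixel else 1
        for f in range(n_frames):
            shift, _, _ = phase_cross_correlation(ref, raw[f], upsample_factor=upsample)
            shifts[f] = shift
            if subpixel:
                movie[f] = ndimage.shift(raw[f], shift, order=1, mode="nearest")
            else:
                sh = np.rint(shift).astype(int)
                shifts[f] = sh
                movie[f] = np.roll(raw[f], tuple(sh), axis=(0, 1))
        raw = movie

    quiet = quiescent_frames(stimulus_frames, n_frames, response_window)
    if bleach_correct and quiet.sum() >= 2:
        # per-pixel log-linear fit on stimulus-free frames; divide out the trend
        t = np.arange(n_frames, dtype=float)
        tq = t[quiet]
        y = np.log(np.clip(raw[quiet], 1e-9, None))
        tq_c = tq - tq.mean()
        slope = (tq_c[:, None, None] * (y - y.mean(axis=0))).sum(axis=0) / (tq_c**2).sum()
        raw = raw / np.exp(slope[None] * (t - tq.mean())[:, None, None])

    dff = np.empty_like(raw)
    f0_sum = np.zeros(raw.shape[1:])
    bounds = _trial_bounds(stimulus_frames, n_frames, baseline_frames)
    for (start, stop), s in zip(bounds, stimulus_frames):
        f0 = raw[s - baseline_frames : s].mean(axis=0)
        f0 = np.clip(f0, 1e-9, None)
        dff[start:stop] = raw[start:stop] / f0 - 1.0
        f0_sum += f0
    f0_mean = f0_sum / len(stimulus_frames)
    mask = f0_mean >= np.percentile(f0_mean, mask_percentile)

    movie = DffMovie(
        frames=dff.astype(np.float32),
        pixel_size_nm=pixel_size_nm,
        frame_interval_ms=frame_interval_ms,
        stimulus_frames=stimulus_frames,
        mask=mask,
        meta={"baseline_frames": baseline_frames},
    )
    return movie, shifts


def canonical_kernel(length: int, tau_frames: float) -> np.ndarray:
    """1-frame rise, exponential decay, unit peak."""
    return np.exp(-np.arange(length) / tau_frames)


def build_template(dff: DffMovie, config: DetectionConfig | None = None) -> np.ndarray:
    """Average stimulus-aligned ΔF/F profile of supra-threshold responses.

    Falls back to the canonical kernel (with a warning) when no response
    anywhere in the mask clears the amplitude threshold.
    """
    if config is None:
        config = DetectionConfig()
    L = config.template_window
    mask = dff.mask if dff.mask is not None else np.ones(dff.shape, dtype=bool)
    # provisional active pixels via a matched filter against the canonical
    # kernel (a raw per-frame max would select pure noise excursions)
    kernel = canonical_kernel(L, config.canonical_tau_frames)
    knorm = float((kernel**2).sum())
    traces = []
    for s in dff.stimulus_frames:
        if s + L > dff.n_frames:
            continue
        window = dff.frames[s : s + L].astype(np.float64)  # (L, rows, cols)
        amp = np.tensordot(kernel, window, axes=(0, 0)) / knorm
        active = (amp >= config.amp_threshold_dff) & mask
        if active.any():
            traces.append(window[:, active])
    if not traces:
        warnings.warn("no supra-threshold responses; using canonical kernel")
        return canonical_kernel(L, config.canonical_tau_frames)
    template = np.concatenate(traces, axis=1).mean(axis=1)
    peak = template.max()
    if peak <= 0:
        warnings.warn("degenerate average response; using canonical kernel")
        return canonical_kernel(L, config.canonical_tau_frames)
    return (template / peak).astype(np.float64)


def pixel_quiescent_sd(dff: DffMovie, response_window: int) -> np.ndarray:
    """Robust per-pixel SD (1.4826 x MAD) over stimulus-free frames."""
    quiet = quiescent_frames(dff.stimulus_frames, dff.n_frames, response_window)
    q = dff.frames[quiet].astype(np.float64)
    med = np.median(q, axis=0)
    return 1.4826 * np.median(np.abs(q - med), axis=0)


def detect_events(
    dff: DffMovie,
    template: np.ndarray,
    config: DetectionConfig | None = None,
) -> list[DetectedEvent]:
    """Template-fit per pixel per trial; group passing pixels into events.

    A pixel passes when its least-squares template amplitude is at least
    ``amp_threshold_dff`` and at least ``sd_multiplier`` times its quiescent
    SD.  Passing pixels that are 8-adjacent and whose response-window traces
    correlate at ``corr_threshold`` or better merge into one event; the peak
    pixel is the footprint argmax of peak ΔF/F (ties toward the smaller
    (row, col)).
    """
    if config is None:
        config = DetectionConfig()
    template = np.asarray(template, dtype=np.float64)
    L = len(template)
    tnorm = float((template**2).sum())
    mask = dff.mask if dff.mask is not None else np.ones(dff.shape, dtype=bool)
    sd = pixel_quiescent_sd(dff, config.response_window)

    events: list[DetectedEvent] = []
    for trial, s in enumerate(dff.stimulus_frames):
        if s + L > dff.n_frames:
            warnings.warn(f"trial {trial}: response window past movie end; skipped")
            continue
        window = dff.frames[s : s + L].astype(np.float64)  # (L, R, C)
        amp = np.tensordot(template, window, axes=(0, 0)) / tnorm
        passing = (amp >= config.amp_threshold_dff) & (amp >= config.sd_multiplier * sd) & mask
        if not passing.any():
            continue
        rows, cols = np.nonzero(passing)
        idx_of = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
        traces = window[:, rows, cols]  # (L, n)
        tz = traces - traces.mean(axis=0)
        norms = np.sqrt((tz**2).sum(axis=0))
        # 8-adjacency edges gated by trace correlation
        src, dst = [], []
        for i, (r, c) in enumerate(zip(rows, cols)):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    j = idx_of.get((r + dr, c + dc))
                    if j is None or j <= i:
                        continue
                    denom = norms[i] * norms[j]
                    corr = (tz[:, i] * tz[:, j]).sum() / denom if denom > 0 else 0.0
                    if corr >= config.corr_threshold:
                        src.append(i)
                        dst.append(j)
        n = len(rows)
        graph = coo_matrix((np.ones(len(src)), (src, dst)), shape=(n, n))
        n_comp, labels = connected_components(graph, directed=False)
        peak_dff_px = window.max(axis=0)
        for comp in range(n_comp):
            members = np.nonzero(labels == comp)[0]
            for group, flags in _split_multi_peak(members, rows, cols, amp, config):
                foot = frozenset((int(rows[i]), int(cols[i])) for i in group)
                # argmax peak dF/F, ties toward smaller (row, col)
                best = min(
                    group,
                    key=lambda i: (-peak_dff_px[rows[i], cols[i]], rows[i], cols[i]),
                )
                pr, pc = int(rows[best]), int(cols[best])
                peak_frame = s + int(np.argmax(window[:, pr, pc]))
                events.append(
                    DetectedEvent(
                        trial=trial,
                        peak_frame=peak_frame,
                        footprint=foot,
                        peak_pixel=(pr, pc),
                        peak_dff=float(peak_dff_px[pr, pc]),
                        amplitude=float(amp[pr, pc]),
                        flags=flags,
                    )
                )
    return events


def _split_multi_peak(
    members: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    amp: np.ndarray,
    config: DetectionConfig,
) -> list:
    """Split a connected footprint holding several amplitude peaks.

    Simultaneous releases at neighboring synapses can bridge into one
    connected group; when the group's fitted-amplitude image holds more
    than one supra-threshold local maximum, pixels are reassigned to their
    nearest maximum so each release yields its own event.
    """
    from skimage.feature import peak_local_max

    pts = np.array([(rows[i], cols[i]) for i in members])
    r0, c0 = pts.min(axis=0)
    sub = np.zeros((pts[:, 0].max() - r0 + 1, pts[:, 1].max() - c0 + 1))
    sub[pts[:, 0] - r0, pts[:, 1] - c0] = amp[pts[:, 0], pts[:, 1]]
    peaks = peak_local_max(
        sub, min_distance=1, threshold_abs=config.amp_threshold_dff, exclude_border=False
    )
    if len(peaks) <= 1:
        return [(list(members), ())]
    d = ((pts[:, None, 0] - r0 - peaks[None, :, 0]) ** 2
         + (pts[:, None, 1] - c0 - peaks[None, :, 1]) ** 2)
    nearest = d.argmin(axis=1)
    groups = []
    for k in range(len(peaks)):
        sel = [m for m, n in zip(members, nearest) if n == k]
        if sel:
            groups.append((sel, ("split",)))
    return groups
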