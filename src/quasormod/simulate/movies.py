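"""Render quantal release truth into functional ΔF/F movies.

Each released quantum adds a transient with a 1-frame rise and exponential
decay in time and a 2D Gaussian point-spread footprint in space, with the
drawn peak amplitude realized exactly at the AZ center.  Movie time is
compressed to a fixed window around each stimulus (real inter-stimulus
intervals at 0.2 Hz are seconds long and carry no signal); the stimulus
frame indices are recorded in the sidecar.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from quasormod.movie import DffMovie
from quasormod.simulate.config import SimConfig
from quasormod.simulate.ground_truth import GroundTruthNMJ


def _lognormal_amplitudes(
    rng: np.random.Generator, n: int, mean: float, cv: float
) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return np.exp(mu + math.sqrt(sigma2) * rng.standard_normal(n))


def movie_shape_for(nmj: GroundTruthNMJ, config: SimConfig, margin_px: int = 8) -> tuple[int, int]:
    """Rows/cols needed to hold every AZ with a detection margin."""
    px = config.pixel_size_nm
    rows = int(math.ceil(nmj.az["y_nm"].max() / px)) + margin_px + 1
    cols = int(math.ceil(nmj.az["x_nm"].max() / px)) + margin_px + 1
    return rows, cols


def render_functional_movie(
    nmj: GroundTruthNMJ,
    truth: pd.DataFrame,
    config: SimConfig,
    *,
    epoch: str | None = None,
    shape: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DffMovie, pd.DataFrame]:
    """Render an event-truth table into a ΔF/F movie.

    Returns the movie plus a per-quantum table (az_id, trial, frame, x_nm,
    y_nm, amplitude) recording the drawn amplitudes and rendered positions
    for recovery tests.  ``truth`` rows must belong to a single epoch (pass
    ``epoch`` to select one from a mixed table).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if epoch is not None:
        truth = truth[truth["epoch"] == epoch]
    elif truth["epoch"].nunique() > 1:
        raise ValueError("truth table mixes epochs; pass epoch= to select one")
    n_stim = int(truth["trial"].max()) + 1 if len(truth) else (
        config.n_stimuli_pre if epoch in (None, "pre") else config.n_stimuli_post
    )
    n_stim = max(
        n_stim,
        config.n_stimuli_pre if (epoch in (None, "pre")) else config.n_stimuli_post,
    )
    fpt = config.frames_per_trial
    n_frames = n_stim * fpt
    if shape is None:
        shape = movie_shape_for(nmj, config)
    rows, cols = shape
    px = config.pixel_size_nm

    az = nmj.az.set_index("az_id")
    # reject AZs outside the field of view
    for az_id, r in az.iterrows():
        if not (0 <= r["x_nm"] <= (cols - 1) * px and 0 <= r["y_nm"] <= (rows - 1) * px):
            raise ValueError(
                f"AZ {az_id} at ({r['x_nm']:.0f}, {r['y_nm']:.0f}) nm lies outside "
                f"the {rows}x{cols} px field of view"
            )

    frames = np.zeros((n_frames, rows, cols), dtype=np.float64)
    stim_frames = np.arange(n_stim) * fpt + config.baseline_frames

    dt = config.frame_interval_ms
    tau = config.decay_tau_ms
    sigma_px = config.psf_sigma_nm / px
    win = int(math.ceil(4 * sigma_px))

    kernel = np.exp(-np.arange(fpt - config.baseline_frames) * dt / tau)

    quanta = []
    amps = _lognormal_amplitudes(rng, len(truth), config.quantal_amp_mean, config.quantal_amp_cv)
    for (row_t, amp) in zip(truth.itertuples(index=False), amps):
        a = az.loc[row_t.az_id]
        f0 = int(stim_frames[row_t.trial])
        x_nm = a["x_nm"]
        y_nm = a["y_nm"]
        cx, cy = x_nm / px, y_nm / px
        c0, c1 = max(0, int(cx) - win), min(cols, int(cx) + win + 1)
        r0, r1 = max(0, int(cy) - win), min(rows, int(cy) + win + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        psf = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2))
        f1 = (row_t.trial + 1) * fpt  # transient truncated at trial end
        frames[f0:f1, r0:r1, c0:c1] += amp * kernel[: f1 - f0, None, None] * psf[None]
        quanta.append((row_t.az_id, row_t.trial, f0, x_nm, y_nm, amp))

    if config.noise_sd_dff > 0:
        frames += config.noise_sd_dff * rng.standard_normal(frames.shape)

    quanta_df = pd.DataFrame(
        quanta, columns=["az_id", "trial", "frame", "x_nm", "y_nm", "amplitude"]
    )
    meta = {
        "epoch": epoch,
        "genotype": nmj.genotype,
        "drug": nmj.drug,
        "n_stimuli": n_stim,
        "frames_per_trial": fpt,
        "baseline_frames": config.baseline_frames,
        "decay_tau_ms": tau,
        "psf_sigma_nm": config.psf_sigma_nm,
    }
    movie = DffMovie(
        frames=frames.astype(np.float32),
        pixel_size_nm=px,
        frame_interval_ms=dt,
        stimulus_frames=stim_frames,
        meta=meta,
    )
    return movie, quanta_df


def baseline_image_for(
    nmj: GroundTruthNMJ, config: SimConfig, shape: tuple[int, int], *, sigma_px: float = 2.0
) -> np.ndarray:
    """Resting-fluorescence map: reporter fill around each AZ over a dim field."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    px = config.pixel_size_nm
    field = np.zeros((rows, cols))
    for r in nmj.az.itertuples(index=False):
        field += np.exp(
            -((xx - r.x_nm / px) ** 2 + (yy - r.y_nm / px) ** 2) / (2 * sigma_px**2)
        )
    field = np.clip(field, 0, 1.5)
    return config.baseline_fluorescence * (0.3 + field)


def to_raw_movie(
    movie: DffMovie,
    config: SimConfig,
    baseline_image: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a ΔF/F movie into raw fluorescence counts.

    raw = F0(x, y) * (1 + dff) * bleach(t), with monoexponential bleaching
    when ``bleach_tau_s`` > 0, then rigidly shifted frame by frame when
    ``drift_nm_per_s`` > 0 (integer-pixel x drift).  ``baseline_image``
    supplies the structured resting fluorescence F0 (uniform when omitted).
    Returns the raw movie and the per-frame (dy, dx) shift log so
    preprocessing registration can be checked against truth.
    """
    if baseline_image is None:
        f0 = np.full(movie.shape, config.baseline_fluorescence)
    else:
        f0 = np.asarray(baseline_image, dtype=np.float64)
        if f0.shape != movie.shape:
            raise ValueError("baseline_image shape must match the movie frames")
    t_s = np.arange(movie.n_frames) * movie.frame_interval_ms / 1000.0
    bleach = (
        np.exp(-t_s / config.bleach_tau_s) if config.bleach_tau_s > 0 else np.ones_like(t_s)
    )
    raw = f0[None] * (1.0 + movie.frames.astype(np.float64)) * bleach[:, None, None]
    shifts = np.zeros((movie.n_frames, 2), dtype=int)
    if config.drift_nm_per_s > 0:
        dx = np.rint(config.drift_nm_per_s * t_s / movie.pixel_size_nm).astype(int)
        shifts[:, 1] = dx
        for f in range(movie.n_frames):
            if dx[f]:
                raw[f] = np.roll(raw[f], dx[f], axis=1)
    return raw.astype(np.float32), shifts
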