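"""Sub-diffraction event localization and synapse ROI definition.

Each detected event's spatial ΔF/F profile in its peak frame is fitted with
a 2D elliptical Gaussian plus constant offset; the fitted centers,
aggregated across trials, form a coordinate cloud that is rendered into an
upsampled, kernel-smoothed density map.  Synapse ROIs are the greedy maxima
of that map with a 350 nm exclusion radius — the coordinate-density
positions that quantal reconstruction assigns release events to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from quasormod.detection import DetectedEvent
from quasormod.movie import DffMovie


@dataclass
class QuantalCoordinate:
    """Sub-pixel coordinate of one quantal event, in nm."""

    event_index: int
    x_nm: float
    y_nm: float
    uncertainty_nm: float
    residual: float
    flagged: bool = False


def coordinates_to_array(coords: list[QuantalCoordinate]) -> np.ndarray:
    return np.array([(c.x_nm, c.y_nm) for c in coords]).reshape(-1, 2)


@dataclass
class SynapseROI:
    """A functional synapse ROI: a coordinate-density maximum."""

    roi_id: int
    x_nm: float
    y_nm: float
    member_indices: list = field(default_factory=list)
    peak_density: float = 0.0

    @property
    def n_events(self) -> int:
        return len(self.member_indices)


def _gauss2d(params, xx, yy):
    a, x0, y0, sx, sy, off = params
    return a * np.exp(-((xx - x0) ** 2) / (2 * sx**2) - ((yy - y0) ** 2) / (2 * sy**2)) + off


def localize_events(
    dff: DffMovie,
    events: list[DetectedEvent],
    *,
    window: int = 7,
) -> list[QuantalCoordinate]:
    """Fit a 2D elliptical Gaussian + offset to each event's peak frame.

    The fit uses the ``window`` x ``window`` pixel patch centered on the
    peak pixel (shrunk and flagged at frame borders).  If the optimizer
    fails or the center leaves the patch, the intensity-weighted centroid
    is used instead and the event is flagged.  Events are never dropped.
    """
    half = window // 2
    px = dff.pixel_size_nm
    out: list[QuantalCoordinate] = []
    rows_n, cols_n = dff.shape
    for idx, ev in enumerate(events):
        pr, pc = ev.peak_pixel
        r0, r1 = max(0, pr - half), min(rows_n, pr + half + 1)
        c0, c1 = max(0, pc - half), min(cols_n, pc + half + 1)
        clipped = (r1 - r0 < window) or (c1 - c0 < window)
        patch = dff.frames[ev.peak_frame, r0:r1, c0:c1].astype(np.float64)
        yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)

        # moment initialization on positive signal
        w = np.clip(patch - np.median(patch), 0, None)
        wsum = w.sum()
        if wsum > 0:
            cx0 = float((w * xx).sum() / wsum)
            cy0 = float((w * yy).sum() / wsum)
        else:
            cx0, cy0 = float(pc), float(pr)
        p0 = [max(patch.max() - np.median(patch), 1e-3), cx0, cy0, 1.0, 1.0, float(np.median(patch))]

        flagged = clipped
        cx, cy = cx0, cy0
        residual = math.nan
        sx = sy = 1.0
        try:
            res = optimize.least_squares(
                lambda p: (_gauss2d(p, xx, yy) - patch).ravel(),
                p0,
                bounds=(
                    [0, c0 - 1, r0 - 1, 0.2, 0.2, -1.0],
                    [np.inf, c1, r1, window, window, 1.0],
                ),
                max_nfev=200,
            )
            a_fit, x_fit, y_fit, sx, sy, _ = res.x
            inside = (c0 - 1 <= x_fit <= c1) and (r0 - 1 <= y_fit <= r1)
            if res.success and inside and a_fit > 0:
                cx, cy = float(x_fit), float(y_fit)
                residual = float(np.sqrt(2 * res.cost / patch.size))
            else:
                flagged = True
        except Exception:
            flagged = True

        # rough localization precision: PSF width over peak signal-to-residual
        amp = max(ev.peak_dff, 1e-6)
        noise = residual if residual == residual else float(patch.std())
        uncertainty = px * float(np.hypot(sx, sy)) / math.sqrt(2) * min(1.0, noise / amp + 0.05)
        out.append(
            QuantalCoordinate(
                event_index=idx,
                x_nm=cx * px,
                y_nm=cy * px,
                uncertainty_nm=uncertainty,
                residual=residual,
                flagged=flagged,
            )
        )
    return out


@dataclass
class DensityMap:
    """Smoothed coordinate-density image on an upsampled grid."""

    values: np.ndarray  # (rows, cols), density per grid cell (counts)
    step_nm: float
    origin_nm: tuple  # (x, y) of grid cell (0, 0) center

    @property
    def integral(self) -> float:
        return float(self.values.sum())

    def nm_of(self, row, col) -> tuple:
        return (self.origin_nm[0] + col * self.step_nm, self.origin_nm[1] + row * self.step_nm)

    def kernel_peak(self, bandwidth_nm: float) -> float:
        """Peak density contributed by a single coordinate."""
        sigma = max(bandwidth_nm / self.step_nm, 1e-9)
        size = int(math.ceil(4 * sigma)) * 2 + 1
        delta = np.zeros((size, size))
        delta[size // 2, size // 2] = 1.0
        return float(ndimage.gaussian_filter(delta, sigma).max())


def build_density_map(
    coords: np.ndarray | list,
    pixel_size_nm: float,
    *,
    upsample: int = 4,
    bandwidth_nm: float = 40.0,
) -> DensityMap:
    """2D histogram on a ``upsample``-finer grid, Gaussian-smoothed.

    The map conserves mass: its integral equals the number of coordinates
    (the grid is padded so no kernel mass leaves it).  Empty input yields
    an empty map with zero integral.
    """
    if hasattr(coords, "__len__") and len(coords) and isinstance(coords[0], QuantalCoordinate):
        coords = coordinates_to_array(coords)
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    step = pixel_size_nm / upsample
    sigma = bandwidth_nm / step
    pad = int(math.ceil(4 * sigma)) + 1
    if len(coords) == 0:
        return DensityMap(values=np.zeros((1, 1)), step_nm=step, origin_nm=(0.0, 0.0))
    gx = coords[:, 0] / step
    gy = coords[:, 1] / step
    x0, x1 = int(math.floor(gx.min())) - pad, int(math.ceil(gx.max())) + pad
    y0, y1 = int(math.floor(gy.min())) - pad, int(math.ceil(gy.max())) + pad
    hist = np.zeros((y1 - y0 + 1, x1 - x0 + 1))
    np.add.at(hist, (np.rint(gy).astype(int) - y0, np.rint(gx).astype(int) - x0), 1.0)
    values = ndimage.gaussian_filter(hist, sigma, mode="constant")
    return DensityMap(values=values, step_nm=step, origin_nm=(x0 * step, y0 * step))


def define_synapse_rois(
    coords: list[QuantalCoordinate] | np.ndarray,
    pixel_size_nm: float,
    *,
    radius_nm: float = 350.0,
    upsample: int = 4,
    bandwidth_nm: float = 40.0,
    min_peak_coords: float = 2.0,
    floor_safety: float = 0.75,
) -> list[SynapseROI]:
    """Greedy coordinate-density peak picking with a 350 nm exclusion radius.

    Repeatedly takes the global density maximum, claims the coordinates
    within ``radius_nm`` (removing them from the residual density),
    suppresses further peaks within that radius of any accepted center,
    and stops when the residual peak density falls below the floor (the
    density ``min_peak_coords`` coordinates would produce, with a safety
    factor for sub-grid splitting).  Coordinates are then assigned to the
    nearest claiming center (ties toward the lower roi id).
    """
    if hasattr(coords, "__len__") and len(coords) and isinstance(coords[0], QuantalCoordinate):
        xy = coordinates_to_array(coords)
    else:
        xy = np.asarray(coords, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        return []
    dmap = build_density_map(xy, pixel_size_nm, upsample=upsample, bandwidth_nm=bandwidth_nm)
    floor = floor_safety * min_peak_coords * dmap.kernel_peak(bandwidth_nm)
    rr, cc = np.mgrid[0 : dmap.values.shape[0], 0 : dmap.values.shape[1]]
    suppressed = np.zeros(dmap.values.shape, dtype=bool)
    unclaimed = np.ones(len(xy), dtype=bool)
    centers = []
    work = dmap.values.copy()
    while True:
        masked = np.where(suppressed, -np.inf, work)
        flat = int(np.argmax(masked))
        r, c = np.unravel_index(flat, masked.shape)
        if masked[r, c] < floor:
            break
        cx, cy = dmap.nm_of(r, c)
        centers.append((cx, cy, float(dmap.values[r, c])))
        suppressed |= ((rr - r) ** 2 + (cc - c) ** 2) * dmap.step_nm**2 <= radius_nm**2
        claimed_now = unclaimed & (
            (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2 <= radius_nm**2
        )
        unclaimed &= ~claimed_now
        # claimed coordinates stop contributing to the residual density
        if claimed_now.any():
            if unclaimed.any():
                residual = build_density_map(
                    xy[unclaimed], pixel_size_nm, upsample=upsample, bandwidth_nm=bandwidth_nm
                )
                work = np.zeros_like(work)
                # paste the residual back on the original grid
                r_off = int(round((residual.origin_nm[1] - dmap.origin_nm[1]) / dmap.step_nm))
                c_off = int(round((residual.origin_nm[0] - dmap.origin_nm[0]) / dmap.step_nm))
                rs, cs = residual.values.shape
                r0, c0 = max(0, r_off), max(0, c_off)
                r1 = min(work.shape[0], r_off + rs)
                c1 = min(work.shape[1], c_off + cs)
                work[r0:r1, c0:c1] = residual.values[
                    r0 - r_off : r1 - r_off, c0 - c_off : c1 - c_off
                ]
            else:
                work = np.zeros_like(work)

    rois = [
        SynapseROI(roi_id=i, x_nm=cx, y_nm=cy, peak_density=pk)
        for i, (cx, cy, pk) in enumerate(centers)
    ]
    if rois:
        cxy = np.array([(roi.x_nm, roi.y_nm) for roi in rois])
        d2 = ((xy[:, None, :] - cxy[None, :, :]) ** 2).sum(axis=2)
        within = d2 <= radius_nm**2
        for i in range(len(xy)):
            claiming = np.nonzero(within[i])[0]
            if len(claiming) == 0:
                continue
            # nearest claiming center; ties toward lower roi id (argmin keeps
            # the first minimum, and roi ids are in ascending order)
            best = claiming[int(np.argmin(d2[i, claiming]))]
            rois[best].member_indices.append(i)
    return rois
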