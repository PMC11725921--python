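"""Structure-function registration: match structural AZs to functional ROIs.

Fixation stretches the tissue between live functional imaging and post hoc
structural imaging, so matching proceeds in three steps: (1) a global
uniform x/y scale + translation estimated by nearest-neighbor cost search;
(2) one-to-one site matching, anchored on unambiguous mutual nearest
neighbors and grown into dense regions under a local displacement
consistency gate; (3) an optional 2D locally weighted mean transform (8-14
control points per local affine) for overlay — quantification always stays
on the untranslated functional coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree


@dataclass
class GlobalTransform:
    """Uniform x/y scale plus translation, structural -> functional frame."""

    sx: float = 1.0
    sy: float = 1.0
    tx: float = 0.0
    ty: float = 0.0
    residual: float = float("nan")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return xy * np.array([self.sx, self.sy]) + np.array([self.tx, self.ty])


@dataclass
class MatchSet:
    """One-to-one AZ-ROI pairing with displacements and leftovers."""

    pairs: pd.DataFrame  # az_id, roi_id, dx_nm, dy_nm
    unmatched_az: list  # candidate silent synapses
    unmatched_roi: list
    transform: GlobalTransform

    def __post_init__(self) -> None:
        if self.pairs["az_id"].duplicated().any() or self.pairs["roi_id"].duplicated().any():
            raise ValueError("matching must be one-to-one")

    @property
    def az_of_roi(self) -> dict:
        return dict(zip(self.pairs["roi_id"], self.pairs["az_id"]))


def _nn_cost(az_t: np.ndarray, roi: np.ndarray) -> float:
    tree = cKDTree(roi)
    d, _ = tree.query(az_t)
    return float(np.sum(d))


def correct_global_stretch(
    az_xy: np.ndarray,
    roi_xy: np.ndarray,
    *,
    scale_range: tuple = (0.75, 1.3),
    n_grid: int = 23,
) -> GlobalTransform:
    """Estimate the uniform x/y stretch + shift mapping AZs onto ROIs.

    Grid search over (sx, sy) with centroid-matched translation, scored by
    the sum of nearest-neighbor distances, then simplex refinement over all
    four parameters.  Degenerate inputs (< 3 points per side or collinear)
    return the identity (or a pure translation) with a warning.
    """
    az_xy = np.asarray(az_xy, dtype=float).reshape(-1, 2)
    roi_xy = np.asarray(roi_xy, dtype=float).reshape(-1, 2)
    if len(az_xy) < 3 or len(roi_xy) < 3:
        warnings.warn("fewer than 3 points; returning translation-only transform")
        if len(az_xy) and len(roi_xy):
            t = roi_xy.mean(axis=0) - az_xy.mean(axis=0)
            return GlobalTransform(1.0, 1.0, float(t[0]), float(t[1]))
        return GlobalTransform()
    # collinearity check via singular values
    sv = np.linalg.svd(az_xy - az_xy.mean(axis=0), compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        warnings.warn("collinear points; returning translation-only transform")
        t = roi_xy.mean(axis=0) - az_xy.mean(axis=0)
        return GlobalTransform(1.0, 1.0, float(t[0]), float(t[1]))

    ca = az_xy.mean(axis=0)
    cr = roi_xy.mean(axis=0)
    scales = np.linspace(scale_range[0], scale_range[1], n_grid)
    best = None
    for sx in scales:
        for sy in scales:
            t = cr - np.array([sx, sy]) * ca
            cost = _nn_cost(az_xy * np.array([sx, sy]) + t, roi_xy)
            if best is None or cost < best[0]:
                best = (cost, sx, sy, t[0], t[1])
    _, sx, sy, tx, ty = best

    def cost_fn(p):
        return _nn_cost(az_xy * np.array([p[0], p[1]]) + np.array([p[2], p[3]]), roi_xy)

    res = optimize.minimize(
        cost_fn, [sx, sy, tx, ty], method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-3, "maxiter": 2000},
    )
    sx, sy, tx, ty = res.x
    return GlobalTransform(float(sx), float(sy), float(tx), float(ty), residual=float(res.fun))


def match_sites(
    az_xy: np.ndarray,
    roi_xy: np.ndarray,
    transform: GlobalTransform | None = None,
    *,
    az_ids: np.ndarray | None = None,
    roi_ids: np.ndarray | None = None,
    anchor_radius_nm: float = 300.0,
    anchor_ambiguity_ratio: float = 1.5,
    variance_gate_nm: float = 150.0,
    max_pair_distance_nm: float = 600.0,
    n_local_anchors: int = 3,
) -> MatchSet:
    """One-to-one AZ-ROI matching: unambiguous anchors, then consistency.

    Stage 1 accepts mutual nearest neighbors closer than
    ``anchor_radius_nm`` whose second candidate is at least
    ``anchor_ambiguity_ratio`` farther (low-density, unambiguous pairs).
    Stage 2 grows into dense regions: remaining AZs are processed in order
    of decreasing clarity and a pair is accepted only when its displacement
    deviates from the median displacement of the nearest accepted pairs by
    less than ``variance_gate_nm``.  Leftover AZs are reported unmatched
    (candidate silent synapses); leftover ROIs likewise.
    """
    az_xy = np.asarray(az_xy, dtype=float).reshape(-1, 2)
    roi_xy = np.asarray(roi_xy, dtype=float).reshape(-1, 2)
    if az_ids is None:
        az_ids = np.arange(len(az_xy))
    if roi_ids is None:
        roi_ids = np.arange(len(roi_xy))
    if transform is None:
        transform = GlobalTransform()
    az_t = transform.apply(az_xy)

    empty = pd.DataFrame(columns=["az_id", "roi_id", "dx_nm", "dy_nm"])
    if len(az_t) == 0 or len(roi_xy) == 0:
        return MatchSet(empty, list(az_ids), list(roi_ids), transform)

    roi_tree = cKDTree(roi_xy)
    az_tree = cKDTree(az_t)
    k_roi = min(2, len(roi_xy))
    d_ar, i_ar = roi_tree.query(az_t, k=k_roi)
    d_ar = np.atleast_2d(d_ar.T).T.reshape(len(az_t), k_roi)
    i_ar = np.atleast_2d(i_ar.T).T.reshape(len(az_t), k_roi)
    d_ra, i_ra = az_tree.query(roi_xy, k=1)

    matched_az: dict[int, int] = {}  # az index -> roi index
    matched_roi: set[int] = set()

    def ratio(i):
        if k_roi < 2 or d_ar[i, 0] == 0:
            return np.inf
        return d_ar[i, 1] / d_ar[i, 0]

    # stage 1: mutual NN anchors
    order = sorted(range(len(az_t)), key=lambda i: (d_ar[i, 0], az_ids[i]))
    for i in order:
        j = int(i_ar[i, 0])
        if d_ar[i, 0] <= anchor_radius_nm and int(i_ra[j]) == i and ratio(i) >= anchor_ambiguity_ratio:
            if j not in matched_roi:
                matched_az[i] = j
                matched_roi.add(j)

    # stage 2: grow under the local-consistency gate, most-unambiguous first
    progress = True
    while progress:
        progress = False
        anchors_idx = sorted(matched_az)
        if not anchors_idx:
            break
        anchor_pos = az_t[anchors_idx]
        anchor_disp = np.array(
            [roi_xy[matched_az[i]] - az_t[i] for i in anchors_idx]
        )
        anchor_tree = cKDTree(anchor_pos)
        remaining = [i for i in range(len(az_t)) if i not in matched_az]
        remaining.sort(key=lambda i: (-ratio(i), d_ar[i, 0], az_ids[i]))
        for i in remaining:
            # nearest unmatched roi
            dists, idxs = roi_tree.query(az_t[i], k=min(len(roi_xy), 6))
            dists, idxs = np.atleast_1d(dists), np.atleast_1d(idxs)
            j = next((int(j) for d, j in zip(dists, idxs)
                      if int(j) not in matched_roi and d <= max_pair_distance_nm), None)
            if j is None:
                continue
            k = min(n_local_anchors, len(anchors_idx))
            _, near = anchor_tree.query(az_t[i], k=k)
            near = np.atleast_1d(near)
            med = np.median(anchor_disp[near], axis=0)
            disp = roi_xy[j] - az_t[i]
            if np.linalg.norm(disp - med) < variance_gate_nm:
                matched_az[i] = j
                matched_roi.add(j)
                progress = True

    rows = []
    for i in sorted(matched_az, key=lambda i: az_ids[i]):
        j = matched_az[i]
        disp = roi_xy[j] - az_t[i]
        rows.append((az_ids[i], roi_ids[j], float(disp[0]), float(disp[1])))
    pairs = pd.DataFrame(rows, columns=["az_id", "roi_id", "dx_nm", "dy_nm"]) if rows else empty
    unmatched_az = [az_ids[i] for i in range(len(az_t)) if i not in matched_az]
    unmatched_roi = [roi_ids[j] for j in range(len(roi_xy)) if j not in matched_roi]
    return MatchSet(pairs, unmatched_az, unmatched_roi, transform)


@dataclass
class LocalTransform:
    """2D locally weighted mean transform over matched control points.

    Each control point carries a local affine fitted to its ``group_size``
    nearest control pairs, offset-corrected to pass exactly through its own
    target; a query point maps to the inverse-square-distance weighted mean
    of these local affine predictions (exact at control points).
    """

    control_src: np.ndarray
    control_dst: np.ndarray
    group_size: int
    _affines: list = field(default_factory=list, repr=False)

    @classmethod
    def fit(
        cls,
        src: np.ndarray,
        dst: np.ndarray,
        *,
        group_bounds: tuple = (8, 14),
    ) -> "LocalTransform":
        src = np.asarray(src, dtype=float).reshape(-1, 2)
        dst = np.asarray(dst, dtype=float).reshape(-1, 2)
        if len(src) != len(dst):
            raise ValueError("control point sets must pair up")
        if len(src) < group_bounds[0]:
            warnings.warn(
                f"only {len(src)} control pairs (< {group_bounds[0]}); "
                "falling back to a single global affine"
            )
            group = len(src)
        else:
            group = min(group_bounds[1], len(src))
        tree = cKDTree(src)
        affines = []
        for i in range(len(src)):
            _, idx = tree.query(src[i], k=group)
            idx = np.atleast_1d(idx)
            A = np.column_stack([src[idx], np.ones(len(idx))])
            M, *_ = np.linalg.lstsq(A, dst[idx], rcond=None)
            # offset-correct to pass exactly through this control point
            pred_i = np.array([src[i, 0], src[i, 1], 1.0]) @ M
            offset = dst[i] - pred_i
            affines.append((M, offset))
        return cls(control_src=src, control_dst=dst, group_size=group, _affines=affines)

    def map(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        out = np.empty_like(xy)
        d2 = ((xy[:, None, :] - self.control_src[None, :, :]) ** 2).sum(axis=2)
        for q in range(len(xy)):
            exact = np.nonzero(d2[q] < 1e-12)[0]
            if len(exact):
                out[q] = self.control_dst[exact[0]]
                continue
            w = 1.0 / d2[q]
            w /= w.sum()
            pt = np.array([xy[q, 0], xy[q, 1], 1.0])
            preds = np.array([pt @ M + off for M, off in self._affines])
            out[q] = (w[:, None] * preds).sum(axis=0)
        return out


def fit_local_weighted_transform(
    matchset: MatchSet,
    az_xy_by_id: dict,
    roi_xy_by_id: dict,
) -> LocalTransform:
    """Overlay transform from functional ROI centers to structural AZ centroids.

    Visualization/overlay only: all quantification stays on the untranslated
    functional coordinates.
    """
    src = np.array([roi_xy_by_id[r] for r in matchset.pairs["roi_id"]]).reshape(-1, 2)
    dst = np.array([az_xy_by_id[a] for a in matchset.pairs["az_id"]]).reshape(-1, 2)
    return LocalTransform.fit(src, dst)


def assign_events(
    coords_xy: np.ndarray,
    matchset: MatchSet,
    roi_xy: np.ndarray,
    roi_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign every quantal coordinate to its nearest ROI center.

    Assignment runs in the functional frame on untranslated data with an
    unlimited radius (the distance is recorded for optional downstream
    filtering).  Coordinates nearest an unmatched ROI keep a roi-only
    assignment (az_id = -1).  Ties go to the lower az id.
    """
    coords_xy = np.asarray(coords_xy, dtype=float).reshape(-1, 2)
    roi_xy = np.asarray(roi_xy, dtype=float).reshape(-1, 2)
    if roi_ids is None:
        roi_ids = np.arange(len(roi_xy))
    az_of_roi = matchset.az_of_roi
    if len(roi_xy) == 0:
        return pd.DataFrame(
            {"event_index": np.arange(len(coords_xy)), "roi_id": -1, "az_id": -1,
             "distance_nm": np.nan}
        )
    rows = []
    d2 = ((coords_xy[:, None, :] - roi_xy[None, :, :]) ** 2).sum(axis=2)
    for i in range(len(coords_xy)):
        dmin = d2[i].min()
        tied = np.nonzero(d2[i] <= dmin * (1 + 1e-12))[0]
        # ties -> lower az id (roi-only assignments rank after matched ones)
        best = min(tied, key=lambda j: (az_of_roi.get(roi_ids[j], np.inf), roi_ids[j]))
        rows.append(
            (
                i,
                int(roi_ids[best]),
                int(az_of_roi.get(roi_ids[best], -1)),
                float(np.sqrt(d2[i, best])),
            )
        )
    return pd.DataFrame(rows, columns=["event_index", "roi_id", "az_id", "distance_nm"])
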