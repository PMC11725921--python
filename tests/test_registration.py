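"""Structure-function point-set registration and event assignment."""

import numpy as np
import pandas as pd
import pytest

from quasormod.registration import (
    GlobalTransform,
    LocalTransform,
    MatchSet,
    assign_events,
    correct_global_stretch,
    fit_local_weighted_transform,
    match_sites,
)
from quasormod.simulate.config import SimConfig
from quasormod.simulate.ground_truth import generate_ground_truth
from quasormod.simulate.volumes import Distortion


def _cloud(n, seed, span=8000.0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(300, span, size=(n * 3, 2))
    # thin to >= 350 nm spacing
    kept = []
    for p in pts:
        if all(np.hypot(*(p - q)) >= 350 for q in kept):
            kept.append(p)
        if len(kept) == n:
            break
    return np.array(kept)


class TestGlobalStretch:
    def test_identity_recovered(self):
        pts = _cloud(30, 0)
        t = correct_global_stretch(pts, pts)
        assert t.sx == pytest.approx(1.0, abs=0.01)
        assert t.sy == pytest.approx(1.0, abs=0.01)
        assert t.residual < 1.0

    def test_synthetic_stretch_recovered(self):
        """Generator's truth transform: (1.10, 0.95) + 500 nm shift."""
        pts = _cloud(40, 1)
        stretched = pts * np.array([1.10, 0.95]) + np.array([500.0, 500.0])
        # we search the map structural -> functional = the inverse transform
        t = correct_global_stretch(stretched, pts)
        assert t.sx == pytest.approx(1 / 1.10, rel=0.01)
        assert t.sy == pytest.approx(1 / 0.95, rel=0.01)
        mapped = t.apply(stretched)
        assert np.abs(mapped - pts).max() < 20.0

    def test_underdetermined_falls_back_to_translation(self):
        with pytest.warns(UserWarning):
            t = correct_global_stretch(np.array([[0.0, 0.0]]), np.array([[100.0, 50.0]]))
        assert (t.sx, t.sy) == (1.0, 1.0)
        assert (t.tx, t.ty) == (100.0, 50.0)

    def test_collinear_warns(self):
        pts = np.column_stack([np.arange(5) * 500.0, np.zeros(5)])
        with pytest.warns(UserWarning):
            t = correct_global_stretch(pts, pts + 100.0)
        assert (t.sx, t.sy) == (1.0, 1.0)


class TestMatchSites:
    def test_identical_sets_match_perfectly(self):
        pts = _cloud(25, 2)
        ms = match_sites(pts, pts)
        assert len(ms.pairs) == 25
        assert ms.unmatched_az == [] and ms.unmatched_roi == []
        assert (ms.pairs["az_id"].to_numpy() == ms.pairs["roi_id"].to_numpy()).all()

    def test_silent_azs_reported_unmatched(self):
        """10% silent AZs under the default warp: >= 95% of active AZs
        correctly paired; silent AZs land in the unmatched list."""
        pts = _cloud(40, 3)
        warp = Distortion(scale_x=1.0, scale_y=1.0, local_warp_amp_nm=80.0)
        az_struct = warp.apply(pts)  # structural positions of all AZs
        silent = set(range(0, 40, 10))  # every 10th AZ silent
        active = [i for i in range(40) if i not in silent]
        roi_xy = pts[active]  # functional ROIs exist only for active AZs
        t = correct_global_stretch(az_struct, roi_xy)
        ms = match_sites(az_struct, roi_xy, t, roi_ids=np.array(active))
        correct = (ms.pairs["az_id"] == ms.pairs["roi_id"]).sum()
        assert correct / len(active) >= 0.95
        assert set(ms.unmatched_az) >= silent - {0}  # border sites may pair loosely

    def test_one_to_one_and_order_invariance(self):
        pts = _cloud(30, 4)
        jitter = pts + np.random.default_rng(5).normal(0, 40, pts.shape)
        ms1 = match_sites(pts, jitter)
        perm = np.random.default_rng(6).permutation(len(pts))
        ms2 = match_sites(pts[perm], jitter, az_ids=perm)
        p1 = sorted(map(tuple, ms1.pairs[["az_id", "roi_id"]].to_numpy()))
        p2 = sorted(map(tuple, ms2.pairs[["az_id", "roi_id"]].to_numpy()))
        assert p1 == p2

    def test_disjoint_inputs_fully_unmatched(self):
        a = _cloud(10, 7)
        b = _cloud(10, 8) + 60_000.0
        ms = match_sites(a, b, GlobalTransform())
        assert len(ms.pairs) == 0
        assert len(ms.unmatched_az) == 10 and len(ms.unmatched_roi) == 10

    def test_duplicate_pairing_rejected_by_matchset(self):
        pairs = pd.DataFrame({"az_id": [0, 0], "roi_id": [1, 2], "dx_nm": 0.0, "dy_nm": 0.0})
        with pytest.raises(ValueError):
            MatchSet(pairs, [], [], GlobalTransform())

    def test_dense_interleaved_rows_stay_one_to_one(self):
        """Two interleaved 250 nm rows: the consistency gate keeps the
        matching one-to-one with no AZ matched twice."""
        xs = np.arange(10) * 500.0
        row1 = np.column_stack([xs, np.zeros(10)])
        row2 = np.column_stack([xs + 250.0, np.full(10, 250.0)])
        az = np.vstack([row1, row2])
        rng = np.random.default_rng(9)
        roi = az + rng.normal(0, 30, az.shape)
        ms = match_sites(az, roi)
        assert not ms.pairs["az_id"].duplicated().any()
        assert not ms.pairs["roi_id"].duplicated().any()
        correct = (ms.pairs["az_id"] == ms.pairs["roi_id"]).mean()
        assert correct >= 0.9


class TestLocalTransform:
    def test_affine_closure(self):
        """Control points from a pure affine map reproduce it everywhere."""
        src = _cloud(20, 10)
        A = np.array([[1.05, 0.02], [-0.01, 0.97]])
        b = np.array([120.0, -80.0])
        dst = src @ A.T + b
        lt = LocalTransform.fit(src, dst)
        q = _cloud(15, 11)
        np.testing.assert_allclose(lt.map(q), q @ A.T + b, atol=1e-6)

    def test_exact_at_control_points(self):
        src = _cloud(12, 12)
        dst = src + np.random.default_rng(13).normal(0, 60, src.shape)
        lt = LocalTransform.fit(src, dst)
        np.testing.assert_allclose(lt.map(src), dst, atol=1e-9)

    def test_few_pairs_fall_back_with_warning(self):
        src = _cloud(5, 14)
        dst = src + 10.0
        with pytest.warns(UserWarning):
            lt = LocalTransform.fit(src, dst)
        np.testing.assert_allclose(lt.map(src), dst, atol=1e-6)

    def test_warped_nmj_mapped_within_50nm(self):
        """Truth-transform comparison on a warped synthetic NMJ."""
        cfg = SimConfig()
        gt = generate_ground_truth(cfg, "wt+none", n_az=40, rng=np.random.default_rng(15))
        roi_xy = gt.az[["x_nm", "y_nm"]].to_numpy()
        warp = Distortion(scale_x=1.08, scale_y=0.95, local_warp_amp_nm=100.0)
        az_xy = warp.apply(roi_xy)
        t = correct_global_stretch(az_xy, roi_xy)
        ms = match_sites(az_xy, roi_xy, t)
        assert len(ms.pairs) >= 35
        az_map = {i: az_xy[i] for i in range(len(az_xy))}
        roi_map = {i: roi_xy[i] for i in range(len(roi_xy))}
        lt = fit_local_weighted_transform(ms, az_map, roi_map)
        mapped = lt.map(roi_xy[ms.pairs["roi_id"].to_numpy()])
        target = az_xy[ms.pairs["az_id"].to_numpy()]
        err = np.hypot(*(mapped - target).T)
        assert np.median(err) < 50.0

    def test_registration_recovery_improves_alignment(self):
        """Over many seeds of the default distortion the local transform
        strictly reduces the median pair displacement."""
        cfg = SimConfig()
        improved = 0
        for seed in range(20):
            gt = generate_ground_truth(
                cfg, "wt+none", n_az=30, rng=np.random.default_rng(100 + seed)
            )
            roi_xy = gt.az[["x_nm", "y_nm"]].to_numpy()
            warp = Distortion(scale_x=1.05, scale_y=0.97, local_warp_amp_nm=80.0)
            az_xy = warp.apply(roi_xy)
            t = correct_global_stretch(az_xy, roi_xy)
            ms = match_sites(az_xy, roi_xy, t)
            if len(ms.pairs) < 8:
                continue
            before = np.median(np.hypot(ms.pairs["dx_nm"], ms.pairs["dy_nm"]))
            lt = fit_local_weighted_transform(
                ms, {i: az_xy[i] for i in range(len(az_xy))},
                {i: roi_xy[i] for i in range(len(roi_xy))},
            )
            mapped = lt.map(roi_xy[ms.pairs["roi_id"].to_numpy()])
            after = np.median(
                np.hypot(*(mapped - az_xy[ms.pairs["az_id"].to_numpy()]).T)
            )
            improved += after < before
        assert improved >= 18  # strict improvement in nearly every seed


class TestAssignEvents:
    def _matchset(self, az_xy, roi_xy):
        t = correct_global_stretch(az_xy, roi_xy)
        return match_sites(az_xy, roi_xy, t)

    def test_event_at_center_assigned_there(self):
        pts = _cloud(10, 16)
        ms = self._matchset(pts, pts)
        asg = assign_events(pts[3:4], ms, pts)
        assert asg["roi_id"].iloc[0] == 3
        assert asg["az_id"].iloc[0] == 3
        assert asg["distance_nm"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_tie_goes_to_lower_az_id(self):
        roi = np.array([[0.0, 0.0], [1000.0, 0.0]])
        ms = self._matchset(roi, roi)
        asg = assign_events(np.array([[500.0, 0.0]]), ms, roi)
        assert asg["az_id"].iloc[0] == 0

    def test_every_coordinate_assigned_exactly_once(self):
        pts = _cloud(15, 17)
        ms = self._matchset(pts, pts)
        rng = np.random.default_rng(18)
        coords = pts[rng.integers(0, 15, 200)] + rng.normal(0, 50, (200, 2))
        asg = assign_events(coords, ms, pts)
        assert len(asg) == 200
        assert asg["event_index"].tolist() == list(range(200))

    def test_unmatched_roi_keeps_roi_only_assignment(self):
        az = _cloud(5, 19)
        roi = np.vstack([az, [[30_000.0, 30_000.0]]])
        t = correct_global_stretch(az, roi[:5])
        ms = match_sites(az, roi, t)
        asg = assign_events(np.array([[30_000.0, 30_000.0]]), ms, roi)
        assert asg["roi_id"].iloc[0] == 5
        assert asg["az_id"].iloc[0] == -1

    def test_empty_roi_set(self):
        ms = MatchSet(
            pd.DataFrame(columns=["az_id", "roi_id", "dx_nm", "dy_nm"]),
            [], [], GlobalTransform(),
        )
        asg = assign_events(np.array([[0.0, 0.0]]), ms, np.empty((0, 2)))
        assert (asg["az_id"] == -1).all()

    def test_synthetic_nmj_assignment_accuracy(self, small_config, default_nmj):
        """>= 95% of simulated coordinates land on their true source AZ."""
        az_xy = default_nmj.az[["x_nm", "y_nm"]].to_numpy()
        ms = self._matchset(az_xy, az_xy)
        rng = np.random.default_rng(20)
        truth_az = rng.integers(0, len(az_xy), 400)
        coords = az_xy[truth_az] + rng.normal(0, 60, (400, 2))
        asg = assign_events(coords, ms, az_xy)
        assert (asg["az_id"].to_numpy() == truth_az).mean() >= 0.95
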