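"""End-to-end orchestration: simulate -> detect -> localize -> segment ->
match -> quantify, under one root seed, with a machine-readable report.

Every random draw descends from the root seed through named substreams, so
a completed run is reproducible bit-for-bit from its manifest, and stages
can be re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from quasormod.detection import DetectionConfig, build_template, detect_events
from quasormod.localization import (
    coordinates_to_array,
    define_synapse_rois,
    localize_events,
)
from quasormod.movie import _jsonable
from quasormod.registration import assign_events, correct_global_stretch, match_sites
from quasormod.segmentation import (
    detect_az_maxima,
    normalize_protein,
    records_to_frame,
    segment_and_quantify,
)
from quasormod.simulate.config import SimConfig
from quasormod.simulate.ground_truth import generate_ground_truth, parse_scenario, simulate_release
from quasormod.simulate.movies import render_functional_movie
from quasormod.simulate.volumes import Distortion, render_structural_volume
from quasormod.stats import (
    bin_delta_pr,
    classify_response,
    compute_pr_table,
    compute_qd,
    fit_sigmoid,
    run_tests,
)

MISSING = "missing"

#: required top-level report sections (the bundled report schema)
REPORT_SCHEMA = {
    "scenario": str,
    "seed": int,
    "n_nmjs": int,
    "qd": (dict, str),
    "pr_table_summary": (dict, str),
    "classification": (dict, str),
    "binned_curve": (list, str),
    "sigmoid_fit": (dict, str),
    "tests": (dict, str),
}


def validate_report(report: dict) -> None:
    """Raise if the report does not follow the bundled schema."""
    for key, types in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing section {key!r}")
        if not isinstance(report[key], types):
            raise ValueError(f"report section {key!r} has wrong type")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    config: dict
    scenario: str
    seed: int
    config_hash: str
    package_version: str
    out_dir: str | None
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(_jsonable(self.__dict__), indent=1, sort_keys=True)


def _substream(root: np.random.SeedSequence, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=root.entropy, spawn_key=key))


def _analyze_one_nmj(
    config: SimConfig,
    scenario: str,
    root: np.random.SeedSequence,
    nmj_index: int,
    distortion: Distortion,
    detection: DetectionConfig,
    warn_log: list,
) -> dict | None:
    """Run the full imaging + analysis chain for one simulated NMJ."""
    gt = generate_ground_truth(config, scenario, rng=_substream(root, nmj_index, 0))
    truth = {
        e: simulate_release(gt, config, e, rng=_substream(root, nmj_index, 1 + k))
        for k, e in enumerate(("pre", "post"))
    }
    movies, coords, events = {}, {}, {}
    template = None
    for k, epoch in enumerate(("pre", "post")):
        movie, _ = render_functional_movie(
            gt, truth[epoch], config, epoch=epoch, rng=_substream(root, nmj_index, 3 + k)
        )
        movies[epoch] = movie
        if template is None:
            template = build_template(movie, detection)
        ev = detect_events(movie, template, detection)
        events[epoch] = ev
        coords[epoch] = localize_events(movie, ev)

    pooled = coords["pre"] + coords["post"]
    if not pooled:
        warn_log.append(f"nmj {nmj_index}: no events detected; skipped")
        return None
    rois = define_synapse_rois(pooled, config.pixel_size_nm)
    if not rois:
        warn_log.append(f"nmj {nmj_index}: no synapse ROIs; skipped")
        return None
    roi_xy = np.array([(r.x_nm, r.y_nm) for r in rois])
    roi_ids = np.array([r.roi_id for r in rois])

    # structural imaging + segmentation
    volume, _, true_centers = render_structural_volume(
        gt, config, distortion, rng=_substream(root, nmj_index, 5)
    )
    maxima = detect_az_maxima(volume)
    if len(maxima) == 0:
        warn_log.append(f"nmj {nmj_index}: no structural maxima; skipped")
        return None
    records, _ = segment_and_quantify(volume, maxima)
    # anatomical MN-type labels: nearest ground-truth AZ in the structural frame
    origin = np.array(volume.meta["origin_nm"])
    seg_xyz = np.array([(r.x_nm, r.y_nm, r.z_nm) for r in records]) + origin
    label_tree = cKDTree(true_centers)
    _, nearest = label_tree.query(seg_xyz)
    mn_types = gt.az["mn_type"].to_numpy()[nearest]
    normalize_protein(records, groups=list(mn_types))
    az_df = records_to_frame(records)
    az_df["mn_type"] = mn_types

    # registration in xy (structural frame is offset + stretched)
    az_xy = az_df[["x_nm", "y_nm"]].to_numpy()
    transform = correct_global_stretch(az_xy, roi_xy)
    matchset = match_sites(az_xy, roi_xy, transform, az_ids=az_df["az_id"].to_numpy(), roi_ids=roi_ids)

    assignments = {}
    for epoch in ("pre", "post"):
        xy = coordinates_to_array(coords[epoch])
        assignments[epoch] = assign_events(xy, matchset, roi_xy, roi_ids)

    pr_table = compute_pr_table(
        assignments["pre"],
        assignments["post"],
        config.n_stimuli_pre,
        config.n_stimuli_post,
        az_df,
    )

    # QD over the functional footprint (pixels near any ROI center)
    rows, cols = movies["pre"].shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    px = config.pixel_size_nm
    pix_xy = np.column_stack([(xx.ravel() * px), (yy.ravel() * px)])
    d, _ = cKDTree(roi_xy).query(pix_xy)
    mask = (d <= 3 * px).reshape(rows, cols)
    qd = {}
    for epoch, n_stim in (("pre", config.n_stimuli_pre), ("post", config.n_stimuli_post)):
        for mn in ("Ib", "Is"):
            sel = pr_table[pr_table["mn_type"] == mn]
            n_ev = int(sel[f"{epoch}_events"].sum())
            if mask.sum():
                qd[f"{mn}_{epoch}"] = compute_qd(n_ev, n_stim, mask, px, epoch).qd
    return {
        "gt": gt,
        "pr_table": pr_table,
        "qd": qd,
        "n_events": {e: len(events[e]) for e in events},
        "matchset": matchset,
    }


def run_pipeline(
    config: SimConfig,
    scenario: str,
    *,
    seed: int = 0,
    n_nmjs: int = 6,
    distortion: Distortion | None = None,
    detection: DetectionConfig | None = None,
    fit_protein: str = "normalized_unc13a",
    out_dir: str | Path | None = None,
) -> tuple[RunManifest, dict]:
    """Simulate and analyze ``n_nmjs`` NMJs under one scenario.

    Returns the manifest and a report holding the pooled P_r table summary,
    per-NMJ quantal densities with the paired pre/post tests, the response
    classification, the binned modulation curve, and its sigmoid fit.
    """
    parse_scenario(scenario)  # validate early
    if distortion is None:
        distortion = Distortion(scale_x=1.05, scale_y=0.97, local_warp_amp_nm=60.0)
    if detection is None:
        detection = DetectionConfig(template_window=min(20, config.frames_per_trial - config.baseline_frames))
    root = np.random.SeedSequence(seed)
    warn_log: list[str] = []
    timings: dict[str, float] = {}

    results = []
    t0 = time.perf_counter()
    for i in range(n_nmjs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _analyze_one_nmj(config, scenario, root, i, distortion, detection, warn_log)
        if res is not None:
            results.append(res)
    timings["per_nmj_total"] = time.perf_counter() - t0

    report: dict = {
        "scenario": scenario,
        "seed": seed,
        "n_nmjs": len(results),
        "qd": MISSING,
        "pr_table_summary": MISSING,
        "classification": MISSING,
        "binned_curve": MISSING,
        "sigmoid_fit": MISSING,
        "tests": MISSING,
    }

    if results:
        pooled = []
        for i, res in enumerate(results):
            t = res["pr_table"].copy()
            t["nmj"] = i
            pooled.append(t)
        pooled = pd.concat(pooled, ignore_index=True)
        report["pr_table_summary"] = {
            "n_az": int(len(pooled)),
            "mean_pr_pre": float(pooled["pr_pre"].mean()),
            "mean_pr_post": float(pooled["pr_post"].mean()),
            "mean_delta_pr": float(pooled["delta_pr"].mean()),
        }
        report["classification"] = classify_response(pooled)
        qd_tab = {}
        for key in ("Ib_pre", "Ib_post", "Is_pre", "Is_post"):
            vals = [r["qd"][key] for r in results if key in r["qd"]]
            qd_tab[key] = vals
        report["qd"] = {
            k: {"values": v, "mean": float(np.mean(v)) if v else None} for k, v in qd_tab.items()
        }
        tests = {}
        for mn in ("Ib", "Is"):
            pre, post = qd_tab.get(f"{mn}_pre", []), qd_tab.get(f"{mn}_post", [])
            if len(pre) >= 3 and len(pre) == len(post):
                tests[f"qd_paired_t_{mn}"] = run_tests([pre, post], "paired_t")
        report["tests"] = tests if tests else MISSING
        ib = pooled[pooled["mn_type"] == "Ib"]
        try:
            binned = bin_delta_pr(ib, protein=fit_protein, n_bins=6)
            report["binned_curve"] = binned.to_dict(orient="records")
            if len(binned) >= 4:
                fit = fit_sigmoid(binned["x_mean"], binned["y_mean"])
                report["sigmoid_fit"] = {
                    "amplitude": fit.amplitude,
                    "midpoint": fit.midpoint,
                    "slope": fit.slope,
                    "sse": fit.sse,
                    "n_points": fit.n_points,
                    "converged": fit.converged,
                }
        except (ValueError, KeyError) as exc:
            warn_log.append(f"binning/fit skipped: {exc}")

    cfg_yaml = json.dumps(_jsonable(config.to_dict()), sort_keys=True)
    manifest = RunManifest(
        config=config.to_dict(),
        scenario=scenario,
        seed=seed,
        config_hash=hashlib.sha256(f"{cfg_yaml}|{scenario}|{seed}".encode()).hexdigest(),
        package_version=_package_version(),
        out_dir=str(out_dir) if out_dir else None,
        timings_s=timings,
        warnings=warn_log,
    )
    if out_dir is not None:
        write_report(report, out_dir)
        Path(out_dir, "manifest.json").write_text(manifest.to_json())
    return manifest, report


def _package_version() -> str:
    import quasormod

    return quasormod.__version__


def report_to_json(report: dict) -> str:
    validate_report(report)
    return json.dumps(_jsonable(report), indent=1, sort_keys=True)


def report_to_markdown(report: dict) -> str:
    validate_report(report)
    lines = [f"# Quantal modulation report — {report['scenario']}", ""]
    lines.append(f"seed {report['seed']}, {report['n_nmjs']} NMJs analyzed\n")
    for section in ("qd", "pr_table_summary", "classification", "tests", "sigmoid_fit"):
        lines.append(f"## {section}\n")
        body = report[section]
        if body == MISSING:
            lines.append("_missing_\n")
        else:
            lines.append("```json")
            lines.append(json.dumps(_jsonable(body), indent=1, sort_keys=True))
            lines.append("```\n")
    if report["binned_curve"] == MISSING:
        lines.append("## binned_curve\n\n_missing_\n")
    else:
        lines.append("## binned_curve\n")
        lines.append("| x_mean | x_sem | y_mean | y_sem | n |")
        lines.append("|---|---|---|---|---|")
        for row in report["binned_curve"]:
            lines.append(
                f"| {row['x_mean']:.4f} | {row['x_sem']:.4f} | {row['y_mean']:.4f} "
                f"| {row['y_sem']:.4f} | {row['n']} |"
            )
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, out_dir: str | Path) -> dict:
    """Write report.json + report.md; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    md_path = out_dir / "report.md"
    json_path.write_text(report_to_json(report))
    md_path.write_text(report_to_markdown(report))
    return {"json": str(json_path), "markdown": str(md_path)}
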