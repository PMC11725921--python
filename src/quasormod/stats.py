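"""Release-probability statistics and modulation-curve fitting.

Per-AZ release probability is the fraction of stimuli that evoked a
detected event at that AZ (P_r = events / #stimuli, in [0, 1]); quantal
density (QD) is events per stimulus per µm² of NMJ footprint.  The change
in P_r across a drug application, binned by normalized protein content, is
summarized by a three-parameter sigmoid y = A / (1 + exp(-(x - x0) k))
fitted by multistart nonlinear least squares, with the sum of squared
errors (SSE) of the best start reported as the goodness of fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


# ---------------------------------------------------------------------------
# P_r tables and quantal density

@dataclass
class QdResult:
    """Quantal density for one epoch: events per stimulus per µm²."""

    epoch: str
    total_events: int
    n_stimuli: int
    nmj_area_um2: float
    qd: float


def compute_pr_table(
    assignments_pre: pd.DataFrame,
    assignments_post: pd.DataFrame,
    n_stimuli_pre: int,
    n_stimuli_post: int,
    az_records: pd.DataFrame,
) -> pd.DataFrame:
    """Exact per-AZ event counting per epoch -> P_r table.

    ``assignments_*`` need an ``az_id`` column (rows with az_id == -1,
    i.e. roi-only assignments, are ignored); ``az_records`` needs ``az_id``
    and optionally mn_type / normalized protein columns, and every AZ in it
    appears in the output (silent matched AZs get zero counts).
    """
    if n_stimuli_pre <= 0 or n_stimuli_post <= 0:
        raise ValueError("stimulus counts must be > 0")
    known = set(az_records["az_id"])
    for name, asg in (("pre", assignments_pre), ("post", assignments_post)):
        ids = set(asg["az_id"]) - {-1}
        stray = ids - known
        if stray:
            raise ValueError(f"{name} assignments reference unknown az_id(s): {sorted(stray)}")

    def counts(asg):
        sel = asg[asg["az_id"] != -1]
        return sel.groupby("az_id").size()

    pre_c = counts(assignments_pre)
    post_c = counts(assignments_post)
    out = az_records[["az_id"]].copy()
    for col in ("mn_type", "normalized_brp", "normalized_unc13a"):
        if col in az_records.columns:
            out[col] = az_records[col].to_numpy()
    out["pre_events"] = out["az_id"].map(pre_c).fillna(0).astype(int)
    out["post_events"] = out["az_id"].map(post_c).fillna(0).astype(int)
    out["n_stimuli_pre"] = n_stimuli_pre
    out["n_stimuli_post"] = n_stimuli_post
    out["pr_pre"] = out["pre_events"] / n_stimuli_pre
    out["pr_post"] = out["post_events"] / n_stimuli_post
    out["delta_pr"] = out["pr_post"] - out["pr_pre"]
    return out


PrTable = pd.DataFrame  # alias: the per-AZ table produced by compute_pr_table


def compute_qd(
    n_events: int,
    n_stimuli: int,
    mask: np.ndarray,
    pixel_size_nm: float,
    epoch: str = "",
) -> QdResult:
    """Events per stimulus per µm² of the NMJ detection-mask footprint."""
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("zero-area mask")
    if n_stimuli <= 0:
        raise ValueError("n_stimuli must be > 0")
    area = n_px * (pixel_size_nm / 1000.0) ** 2
    return QdResult(
        epoch=epoch,
        total_events=int(n_events),
        n_stimuli=int(n_stimuli),
        nmj_area_um2=area,
        qd=n_events / n_stimuli / area,
    )


def classify_response(pr_table: pd.DataFrame) -> dict:
    """Fractions of AZs whose P_r increased / decreased / stayed unchanged.

    "Unchanged" means a delta of exactly zero — counts are integers, so
    exact ties are meaningful.  Fractions are percentages rounded to 0.1.
    """
    if len(pr_table) == 0:
        raise ValueError("empty P_r table")
    delta = pr_table["delta_pr"].to_numpy()
    n = len(delta)
    return {
        "increased_pct": round(float(100.0 * (delta > 0).sum() / n), 1),
        "decreased_pct": round(float(100.0 * (delta < 0).sum() / n), 1),
        "unchanged_pct": round(float(100.0 * (delta == 0).sum() / n), 1),
        "n_az": n,
        "n_increased": int((delta > 0).sum()),
        "n_decreased": int((delta < 0).sum()),
        "n_unchanged": int((delta == 0).sum()),
    }


def bin_delta_pr(
    pr_table: pd.DataFrame,
    protein: str = "normalized_brp",
    n_bins: int = 6,
    value: str = "delta_pr",
) -> pd.DataFrame:
    """Equal-count bins of ``value`` over the normalized protein axis.

    Returns per-bin mean ± SEM of both the protein value (horizontal error
    bars) and the response (vertical).  Bins holding fewer than 3 AZs are
    merged into their neighbor; fewer rows than bins collapses to a single
    bin with a warning.
    """
    if protein not in pr_table.columns:
        raise ValueError(f"P_r table lacks column {protein!r}")
    df = pr_table[[protein, value]].dropna().sort_values(protein, kind="mergesort")
    if len(df) == 0:
        raise ValueError("no finite protein values to bin")
    if len(df) < n_bins:
        warnings.warn(f"only {len(df)} AZs for {n_bins} bins; using a single bin")
        n_bins = 1
    chunks = np.array_split(np.arange(len(df)), n_bins)
    chunks = [c for c in chunks if len(c)]
    # merge small bins into the previous (or next) neighbor
    merged: list[np.ndarray] = []
    for c in chunks:
        if merged and (len(c) < 3 or len(merged[-1]) < 3):
            merged[-1] = np.concatenate([merged[-1], c])
        else:
            merged.append(c)
    rows = []
    x = df[protein].to_numpy()
    y = df[value].to_numpy()
    for c in merged:
        rows.append(
            {
                "x_mean": x[c].mean(),
                "x_sem": x[c].std(ddof=1) / math.sqrt(len(c)) if len(c) > 1 else 0.0,
                "y_mean": y[c].mean(),
                "y_sem": y[c].std(ddof=1) / math.sqrt(len(c)) if len(c) > 1 else 0.0,
                "n": len(c),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model fits

def sigmoid(x, amplitude, midpoint, slope):
    return amplitude / (1.0 + np.exp(-(np.asarray(x, dtype=float) - midpoint) * slope))


def saturating_exp(x, amplitude, scale, offset):
    """y = a (1 - exp(-x/lambda)) + c — the alternative saturating model."""
    return amplitude * (1.0 - np.exp(-np.asarray(x, dtype=float) / scale)) + offset


@dataclass
class SigmoidFit:
    """Best-of-multistart nonlinear least-squares fit result."""

    amplitude: float
    midpoint: float
    slope: float
    sse: float
    n_points: int
    n_starts: int
    converged: bool
    model: str = "sigmoid"

    def predict(self, x):
        if self.model == "sigmoid":
            return sigmoid(x, self.amplitude, self.midpoint, self.slope)
        return saturating_exp(x, self.amplitude, self.midpoint, self.slope)

    def summary(self) -> str:
        name = {"sigmoid": "y = A/(1+exp(-(x-x0)k))", "saturating_exp": "y = a(1-exp(-x/s))+c"}
        lines = [
            f"{self.model} fit: {name[self.model]}",
            f"  A  = {self.amplitude:.6g}",
            f"  x0 = {self.midpoint:.6g}" if self.model == "sigmoid" else f"  s  = {self.midpoint:.6g}",
            f"  k  = {self.slope:.6g}" if self.model == "sigmoid" else f"  c  = {self.slope:.6g}",
            f"  SSE = {self.sse:.6g}  (n = {self.n_points}, {self.n_starts} starts,"
            f" converged = {self.converged})",
        ]
        return "\n".join(lines)


def fit_sigmoid(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    n_starts: int = 32,
    model: str = "sigmoid",
    seed: int = 0,
) -> SigmoidFit:
    """Multistart least squares for the modulation curve.

    Starts are drawn from data-driven ranges (A in [0, 2 max|y|], x0 across
    the x range, k in [0.1, 50]) plus deterministic corner starts; the
    lowest-SSE solution wins.  SSE is reported on the fitted points
    (weighted if weights are given).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in fit input")
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    ymax = max(np.abs(y).max(), 1e-12)
    xmin, xmax = float(x.min()), float(x.max())
    span = max(xmax - xmin, 1e-9)
    rng = np.random.default_rng(seed)

    if model == "sigmoid":
        fn = sigmoid
        # parameters constrained to the data-driven ranges the starts are
        # drawn from: an amplitude beyond 2 max|y| or a midpoint outside the
        # observed x range is not identifiable from the data
        lo = [-2 * ymax, xmin, 0.1]
        hi = [2 * ymax, xmax, 50.0]
        starts = [
            [ymax, (xmin + xmax) / 2, 3.0],
            [ymax, xmin + 0.4 * span, 7.0],
            [0.5 * ymax, xmin + 0.6 * span, 1.0],
        ]
        draw = lambda: [rng.uniform(0, 2 * ymax), rng.uniform(xmin, xmax), rng.uniform(0.1, 50)]
    elif model == "saturating_exp":
        fn = saturating_exp
        lo = [-4 * ymax, 1e-6, -2 * ymax]
        hi = [4 * ymax, 100 * span, 2 * ymax]
        starts = [[ymax, span / 2, 0.0], [0.5 * ymax, span / 5, 0.0]]
        draw = lambda: [rng.uniform(0, 2 * ymax), rng.uniform(span / 50, 2 * span), rng.uniform(-ymax, ymax)]
    else:
        raise ValueError(f"unknown model {model!r}")

    while len(starts) < n_starts:
        starts.append(draw())

    best = None
    any_ok = False
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            res = optimize.least_squares(
                lambda p: sw * (fn(x, *p) - y), p0, bounds=(lo, hi), max_nfev=400
            )
        except Exception:
            continue
        sse = float(np.sum((sw * (fn(x, *res.x) - y)) ** 2))
        any_ok = any_ok or res.success
        if best is None or sse < best[0]:
            best = (sse, res.x, res.success)
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.inf, len(x), len(starts), False, model)
    sse, p, ok = best
    return SigmoidFit(
        amplitude=float(p[0]),
        midpoint=float(p[1]),
        slope=float(p[2]),
        sse=sse,
        n_points=len(x),
        n_starts=len(starts),
        converged=bool(any_ok),
        model=model,
    )


def simulate_modulation_recovery(
    model,
    *,
    n_az: int = 600,
    n_stimuli: int = 100,
    n_bins: int = 6,
    n_seeds: int = 20,
    seed: int = 0,
    base_pr: float = 0.05,
    basal_sigma_log: float = 1.0,
) -> pd.DataFrame:
    """Recover sigmoid modulation parameters under binomial counting noise.

    The virtual experiment the per-AZ analysis performs: ``n_az`` AZs with
    normalized protein content x ~ Uniform(0, 1), basal P_r drawn from the
    generator's default marginal distribution (lognormal around the tonic
    base rate with sigma_log ~ 1, i.e. spanning two orders of magnitude,
    clipped to [1e-4, 0.9]), post P_r = pre + the model's sigmoid curve
    (no heterogeneity), pre/post event counts Binomial(n_stimuli, P_r),
    change in P_r binned into ``n_bins`` equal-count bins and fitted with
    the multistart sigmoid.  One row of fitted parameters per seed.
    """
    rows = []
    for s in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence((seed, s)))
        x = rng.uniform(0, 1, n_az)
        pre = np.clip(base_pr * np.exp(basal_sigma_log * rng.standard_normal(n_az)), 1e-4, 0.9)
        post = np.clip(pre + model.curve(x), 0.0, 1.0)
        pr_pre = rng.binomial(n_stimuli, pre) / n_stimuli
        pr_post = rng.binomial(n_stimuli, post) / n_stimuli
        table = pd.DataFrame({"protein": x, "delta_pr": pr_post - pr_pre})
        binned = bin_delta_pr(table, protein="protein", n_bins=n_bins)
        fit = fit_sigmoid(binned["x_mean"], binned["y_mean"])
        rows.append(
            {
                "seed": s,
                "amplitude": fit.amplitude,
                "midpoint": fit.midpoint,
                "slope": fit.slope,
                "sse": fit.sse,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hypothesis tests

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def run_tests(samples: list, design: str) -> dict:
    """Named hypothesis tests with the field's star convention.

    ``design`` is one of paired_t, wilcoxon_signed_rank, ks_2sample,
    anova_1way; ``samples`` is a list of 1D arrays (two for the paired and
    two-sample designs, two or more for the ANOVA).
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if design in ("paired_t", "wilcoxon_signed_rank"):
        if len(samples) != 2 or len(samples[0]) != len(samples[1]):
            raise ValueError(f"{design} needs two samples of equal length")
        if design == "paired_t":
            if np.allclose(samples[0], samples[1]):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.ttest_rel(samples[0], samples[1])
        else:
            if np.allclose(samples[0], samples[1]):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(samples[0], samples[1])
    elif design == "ks_2sample":
        if len(samples) != 2:
            raise ValueError("ks_2sample needs exactly two samples")
        stat, p = sps.ks_2samp(samples[0], samples[1])
    elif design == "anova_1way":
        if len(samples) < 2:
            raise ValueError("anova_1way needs at least two groups")
        stat, p = sps.f_oneway(*samples)
    else:
        raise ValueError(f"unknown design {design!r}")
    return {
        "design": design,
        "statistic": float(stat),
        "p_value": float(p),
        "n": [len(s) for s in samples],
        "stars": significance_stars(float(p)),
    }
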