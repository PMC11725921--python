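"""Ground-truth NMJs: active-zone geometry, protein content, release probability.

The generator encodes the statistical structure the downstream analysis
assumes: strings of boutons carrying active zones (AZs) at >= 300 nm spacing,
per-AZ Brp/Unc13A content lognormally distributed and mutually correlated,
basal release probability increasing with Unc13A content and spanning at
least two orders of magnitude across the NMJ, phasic (Is) terminals roughly
threefold stronger than tonic (Ib) ones, and drug-induced modulation that is
a sigmoidal function of normalized Unc13A content gated by the octopamine
receptor (OAMB) in a motor-neuron-type-specific way.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from quasormod.simulate.config import SimConfig

GENOTYPES = (
    "wt",
    "oamb_rnai",
    "unc13_rnai",
    "unc13a_rnai",
    "unc13b_rnai",
    "unc13a_h1723k",
)
DRUGS = ("none", "OA", "PdBU")

#: Unc13A protein remaining (relative to wild type) per genotype.  The RNAi
#: knockdown removes ~80% of the isoform; the Unc13B knockdown upregulates
#: Unc13A by ~40% (compensation); the H1723K rescue restores wild-type
#: protein levels but carries a DAG-binding-dead C1 domain.
UNC13A_SCALE = {
    "wt": 1.0,
    "oamb_rnai": 1.0,
    "unc13_rnai": 0.2,
    "unc13a_rnai": 0.2,
    "unc13b_rnai": 1.4,
    "unc13a_h1723k": 1.0,
}


def parse_scenario(scenario: str) -> tuple[str, str]:
    """Split a ``genotype+drug`` label and validate both parts."""
    parts = scenario.split("+")
    if len(parts) != 2:
        raise ValueError(
            f"scenario must look like 'genotype+drug' (e.g. 'wt+OA'), got {scenario!r}"
        )
    genotype, drug = parts[0].strip(), parts[1].strip()
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    # drug labels are matched case-insensitively but reported canonically
    canon = {d.lower(): d for d in DRUGS}
    if drug.lower() not in canon:
        raise ValueError(f"unknown drug {drug!r}; expected one of {DRUGS}")
    return genotype, canon[drug.lower()]


@dataclass
class ModulationModel:
    """Sigmoidal drug modulation of release probability.

    The change in release probability at an AZ with normalized Unc13A
    content ``x`` is::

        delta_pr(x) = gate * amp_scale * A / (1 + exp(-(x - x0) * k)) * h + eps

    with ``h`` a per-AZ multiplicative lognormal heterogeneity factor
    (median 1), ``eps`` an additive zero-mean per-AZ scatter term that lets
    a minority of AZs show decreased P_r, ``gate`` the receptor gate
    (OA acts through OAMB, enriched in Ib and nearly absent from Is
    terminals; the DAG mimic PdBU bypasses the receptor), and ``amp_scale``
    the fraction of DAG-modifiable Unc13A protein present.
    """

    amplitude: float = 0.05
    midpoint: float = 0.37
    slope: float = 7.2
    oamb_gate: dict = field(default_factory=lambda: {"Ib": 1.0, "Is": 0.0})
    heterogeneity_sd: float = 0.5
    decrease_sd: float = 0.015
    dag_sensitive: bool = True

    def __post_init__(self) -> None:
        for mn, g in self.oamb_gate.items():
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"oamb_gate[{mn!r}] must lie in [0, 1], got {g}")
        if self.heterogeneity_sd < 0 or self.decrease_sd < 0:
            raise ValueError("heterogeneity_sd and decrease_sd must be >= 0")

    def curve(self, x):
        """Mean modulation A / (1 + exp(-(x - x0) * k)) with no scatter."""
        x = np.asarray(x, dtype=float)
        return self.amplitude / (1.0 + np.exp(-(x - self.midpoint) * self.slope))

    # -- named presets ---------------------------------------------------
    @classmethod
    def oa_unc13a(cls) -> "ModulationModel":
        """Octopamine modulation vs. normalized Unc13A (A=0.05, x0=0.37, k=7.2)."""
        return cls(amplitude=0.05, midpoint=0.37, slope=7.2)

    @classmethod
    def oa_brp(cls) -> "ModulationModel":
        """Octopamine modulation vs. normalized Brp (A=0.04, x0=0.43, k=3.4)."""
        return cls(amplitude=0.04, midpoint=0.43, slope=3.4)

    @classmethod
    def pdbu(cls) -> "ModulationModel":
        """PdBU (DAG mimic) modulation; receptor gate is bypassed by the drug."""
        return cls(amplitude=0.06, midpoint=0.37, slope=7.2)

    def gate_for(self, genotype: str, drug: str, mn_type: str) -> float:
        if drug == "none" or not self.dag_sensitive:
            return 0.0
        if drug == "OA":
            if genotype == "oamb_rnai":
                return 0.0
            return float(self.oamb_gate.get(mn_type, 0.0))
        if drug == "PdBU":
            return 1.0
        raise ValueError(f"unknown drug {drug!r}")


@dataclass
class GroundTruthNMJ:
    """Per-AZ ground truth table plus scenario labels.

    ``az`` columns: az_id, bouton_id, mn_type, x_nm, y_nm, z_nm, brp_weight,
    unc13a_weight, unc13a_norm (normalized to the wild-type-equivalent max),
    basal_pr, modulated_pr.
    """

    az: pd.DataFrame
    genotype: str = "wt"
    drug: str = "none"

    def __post_init__(self) -> None:
        required = {
            "az_id",
            "bouton_id",
            "mn_type",
            "x_nm",
            "y_nm",
            "z_nm",
            "brp_weight",
            "unc13a_weight",
            "unc13a_norm",
            "basal_pr",
            "modulated_pr",
        }
        missing = required - set(self.az.columns)
        if missing:
            raise ValueError(f"ground truth table missing columns: {sorted(missing)}")
        for col in ("basal_pr", "modulated_pr"):
            vals = self.az[col].to_numpy()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        if (self.az["brp_weight"] <= 0).any() or (self.az["unc13a_weight"] <= 0).any():
            raise ValueError("protein weights must be > 0")

    @property
    def n_az(self) -> int:
        return len(self.az)

    def positions_nm(self) -> np.ndarray:
        return self.az[["x_nm", "y_nm", "z_nm"]].to_numpy()

    def min_pairwise_distance(self) -> float:
        from scipy.spatial.distance import pdist

        if self.n_az < 2:
            return math.inf
        return float(pdist(self.positions_nm()).min())

    # -- round-trip I/O --------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        out = self.az.copy()
        out.insert(0, "genotype", self.genotype)
        out.insert(1, "drug", self.drug)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruthNMJ":
        df = pd.read_csv(path)
        genotype = str(df["genotype"].iloc[0])
        drug = str(df["drug"].iloc[0])
        az = df.drop(columns=["genotype", "drug"]).reset_index(drop=True)
        return cls(az=az, genotype=genotype, drug=drug)


def _place_azs(
    config: SimConfig,
    rng: np.random.Generator,
    n_az: int | None,
) -> pd.DataFrame:
    """Place AZs in disks along two bouton strings (Ib and Is rows)."""
    rows = []
    margin = 2000.0
    n_ib, n_is = config.n_boutons_ib, config.n_boutons_is
    if n_az is not None:
        # extend the bouton chains when the request exceeds packing capacity
        # (xy-projected spacing allows ~38 sites in a 1 um-radius disk)
        max_per_bouton = 22
        while n_az > max_per_bouton * (n_ib + n_is):
            n_ib += 1
            if n_az > max_per_bouton * (n_ib + n_is):
                n_is += 1
    specs = [("Ib", n_ib, margin + 1500.0), ("Is", n_is, margin + 6500.0)]
    # bouton centers
    boutons = []
    for mn_type, n_boutons, y0 in specs:
        for i in range(n_boutons):
            boutons.append(
                (mn_type, margin + 1500.0 + i * config.bouton_spacing_nm, y0)
            )
    if n_az is None:
        counts = rng.poisson(config.az_per_bouton, size=len(boutons))
        counts = np.maximum(counts, 1)
    else:
        counts = np.full(len(boutons), n_az // len(boutons))
        counts[: n_az % len(boutons)] += 1
    placed: list[tuple[float, float, float]] = []
    bid = 0
    for (mn_type, bx, by), count in zip(boutons, counts):
        for _ in range(int(count)):
            for _attempt in range(4000):
                r = config.bouton_radius_nm * math.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * math.pi)
                x = bx + r * math.cos(theta)
                y = by + r * math.sin(theta)
                z = rng.uniform(-300.0, 300.0)
                ok = True
                # spacing enforced on the xy projection (AZs spread along the
                # bouton membrane); implies the 3D min-distance invariant
                for px, py, pz in placed:
                    if (x - px) ** 2 + (y - py) ** 2 < config.min_az_spacing_nm**2:
                        ok = False
                        break
                if ok:
                    placed.append((x, y, z))
                    rows.append((bid, mn_type, x, y, z))
                    break
            else:
                raise RuntimeError(
                    "could not place AZs at the requested density; "
                    "reduce az_per_bouton or min_az_spacing_nm"
                )
        bid += 1
    df = pd.DataFrame(rows, columns=["bouton_id", "mn_type", "x_nm", "y_nm", "z_nm"])
    df.insert(0, "az_id", np.arange(len(df)))
    return df


def generate_ground_truth(
    config: SimConfig,
    scenario: str,
    *,
    n_az: int | None = None,
    rho: float = 0.7,
    gamma: float = 1.0,
    base_pr: float = 0.05,
    pr_scatter_sd: float = 0.45,
    is_pr_factor: float = 3.0,
    unc13a_sigma: float = 0.5,
    brp_sigma: float = 0.5,
    min_pr_span: float = 100.0,
    modulation: ModulationModel | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruthNMJ:
    """Generate a ground-truth NMJ for a ``genotype+drug`` scenario.

    Basal release probability follows a power law of Unc13A content
    (``basal_pr = base_pr * w^gamma`` with lognormal scatter), stretched if
    necessary so the empirical p99/p1 span is at least ``min_pr_span``
    (two orders of magnitude by default) and clipped to [1e-4, 0.9].
    Phasic Is AZs are ``is_pr_factor`` times stronger than tonic Ib AZs.
    """
    genotype, drug = parse_scenario(scenario)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if not 0 < base_pr <= 1 or base_pr * is_pr_factor > 1:
        raise ValueError(
            f"base_pr={base_pr} with is_pr_factor={is_pr_factor} implies P_r > 1"
        )
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")

    az = _place_azs(config, rng, n_az)
    n = len(az)

    # correlated lognormal protein content
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    az["brp_weight"] = 150.0 * np.exp(brp_sigma * z1)
    unc13a_raw = 100.0 * np.exp(unc13a_sigma * z2)

    # normalization reference is the wild-type-equivalent max, fixed before
    # any knockdown scaling so genotype effects shift the normalized axis
    ref = float(unc13a_raw.max())
    scale = UNC13A_SCALE[genotype]
    az["unc13a_weight"] = unc13a_raw * scale
    az["unc13a_norm"] = az["unc13a_weight"] / ref

    # basal P_r: power law of Unc13A content with lognormal scatter
    w_rel = az["unc13a_weight"].to_numpy() / 100.0
    pr = base_pr * w_rel**gamma * np.exp(pr_scatter_sd * rng.standard_normal(n))
    pr = pr * np.where(az["mn_type"].to_numpy() == "Is", is_pr_factor, 1.0)
    # enforce the two-orders-of-magnitude span, then clip
    lo, hi = np.percentile(pr, [1, 99])
    if hi / lo < min_pr_span and n >= 10:
        logp = np.log(pr)
        m = np.median(logp)
        # overshoot slightly so the empirical p99/p1 clears the floor after
        # percentile interpolation and clipping
        stretch = math.log(min_pr_span * 1.05) / math.log(hi / lo)
        logp = m + stretch * (logp - m)
        pr = np.exp(logp)
    az["basal_pr"] = np.clip(pr, 1e-4, 0.9)

    # modulation
    if modulation is None:
        modulation = ModulationModel.pdbu() if drug == "PdBU" else ModulationModel.oa_unc13a()
    if genotype == "unc13a_h1723k":
        modulation = dataclasses.replace(modulation, dag_sensitive=False)
    if modulation.amplitude > 1:
        raise ValueError("modulation amplitude implies P_r > 1")
    gates = np.array(
        [modulation.gate_for(genotype, drug, mn) for mn in az["mn_type"]]
    )
    h = np.exp(modulation.heterogeneity_sd * rng.standard_normal(n))
    eps = modulation.decrease_sd * rng.standard_normal(n)
    delta = gates * scale * modulation.curve(az["unc13a_norm"].to_numpy()) * h + eps
    az["modulated_pr"] = np.clip(az["basal_pr"].to_numpy() + delta, 0.0, 1.0)

    return GroundTruthNMJ(az=az, genotype=genotype, drug=drug)


def simulate_release(
    nmj: GroundTruthNMJ,
    config: SimConfig,
    epoch: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bernoulli release per AZ per stimulus.

    Returns the event-truth table with one row per released quantum:
    columns az_id, trial, epoch.  Uses ``basal_pr`` in the ``pre`` epoch and
    ``modulated_pr`` in ``post``.
    """
    if epoch not in ("pre", "post"):
        raise ValueError(f"epoch must be 'pre' or 'post', got {epoch!r}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n_stim = config.n_stimuli_pre if epoch == "pre" else config.n_stimuli_post
    p = nmj.az["basal_pr" if epoch == "pre" else "modulated_pr"].to_numpy()
    draws = rng.uniform(size=(n_stim, len(p))) < p[None, :]
    trial_idx, az_idx = np.nonzero(draws)
    az_ids = nmj.az["az_id"].to_numpy()[az_idx]
    return pd.DataFrame(
        {"az_id": az_ids, "trial": trial_idx, "epoch": epoch}
    ).sort_values(["trial", "az_id"], ignore_index=True)
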