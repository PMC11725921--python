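"""Shared fixtures: small synthetic NMJs, movies, and volumes."""

import numpy as np
import pandas as pd
import pytest

from quasormod.simulate.config import SimConfig
from quasormod.simulate.ground_truth import GroundTruthNMJ, generate_ground_truth, simulate_release
from quasormod.simulate.movies import render_functional_movie


def make_nmj(positions_nm, pr, mn_type="Ib", modulated=None, brp=None, unc13a=None):
    """Hand-built ground-truth NMJ from explicit positions and P_r values."""
    positions_nm = np.asarray(positions_nm, dtype=float).reshape(-1, 3)
    n = len(positions_nm)
    pr = np.broadcast_to(np.asarray(pr, dtype=float), (n,)).copy()
    modulated = pr if modulated is None else np.broadcast_to(np.asarray(modulated, float), (n,)).copy()
    brp = np.ones(n) * 100 if brp is None else np.asarray(brp, float)
    unc13a = np.ones(n) * 100 if unc13a is None else np.asarray(unc13a, float)
    az = pd.DataFrame(
        {
            "az_id": np.arange(n),
            "bouton_id": 0,
            "mn_type": mn_type if isinstance(mn_type, str) else list(mn_type),
            "x_nm": positions_nm[:, 0],
            "y_nm": positions_nm[:, 1],
            "z_nm": positions_nm[:, 2],
            "brp_weight": brp,
            "unc13a_weight": unc13a,
            "unc13a_norm": unc13a / unc13a.max(),
            "basal_pr": pr,
            "modulated_pr": modulated,
        }
    )
    return GroundTruthNMJ(az=az)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_stimuli_pre=30,
        n_stimuli_post=30,
        n_boutons_ib=2,
        n_boutons_is=1,
        az_per_bouton=5,
        frames_per_trial=25,
    )


@pytest.fixture(scope="session")
def default_nmj(small_config):
    rng = np.random.default_rng(11)
    gt = generate_ground_truth(small_config, "wt+OA", rng=rng)
    # lift release rates so the short recording produces enough events
    gt.az["basal_pr"] = np.clip(gt.az["basal_pr"] * 3, 0.08, 0.9)
    gt.az["modulated_pr"] = np.clip(gt.az["basal_pr"] + 0.05, 0, 1)
    return gt


@pytest.fixture(scope="session")
def rendered_movie(small_config, default_nmj):
    """Pre-epoch movie + event truth + quantum table for the default NMJ."""
    rng = np.random.default_rng(12)
    truth = simulate_release(default_nmj, small_config, "pre", rng)
    movie, quanta = render_functional_movie(
        default_nmj, truth, small_config, epoch="pre", rng=rng
    )
    return movie, truth, quanta
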