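"""Render ground-truth NMJs into fixation-distorted structural volumes.

Fixation and mounting stretch the tissue relative to the live functional
frame; the renderer applies a uniform x/y scale plus a smooth low-frequency
local warp to every AZ position before painting 3D Gaussian blobs into the
Brp and Unc13A channels.  The true transform is returned so registration
recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from quasormod.segmentation import StructuralVolume
from quasormod.simulate.config import SimConfig
from quasormod.simulate.ground_truth import GroundTruthNMJ


@dataclass
class Distortion:
    """Global stretch plus smooth local warp, functional -> structural frame."""

    scale_x: float = 1.0
    scale_y: float = 1.0
    local_warp_amp_nm: float = 0.0
    warp_wavelength_nm: float = 8000.0
    phases: tuple = (0.0, 1.3, 2.1, 0.7)

    def validate(self, min_az_spacing_nm: float) -> None:
        if not (0.8 <= self.scale_x <= 1.3 and 0.8 <= self.scale_y <= 1.3):
            raise ValueError("scales must lie in [0.8, 1.3]")
        if self.local_warp_amp_nm >= min_az_spacing_nm / 2:
            raise ValueError(
                f"local warp amplitude {self.local_warp_amp_nm} nm must stay below "
                f"half the AZ spacing ({min_az_spacing_nm / 2} nm) or matching is ill-posed"
            )

    def apply(self, xy_nm: np.ndarray) -> np.ndarray:
        """Map (n, 2) functional-frame xy (nm) into the structural frame."""
        xy = np.asarray(xy_nm, dtype=float)
        out = xy * np.array([self.scale_x, self.scale_y])
        if self.local_warp_amp_nm > 0:
            k = 2 * math.pi / self.warp_wavelength_nm
            p1, p2, p3, p4 = self.phases
            dx = self.local_warp_amp_nm * np.sin(k * xy[:, 0] + p1) * np.cos(k * xy[:, 1] + p2)
            dy = self.local_warp_amp_nm * np.sin(k * xy[:, 1] + p3) * np.cos(k * xy[:, 0] + p4)
            out = out + np.column_stack([dx, dy])
        return out


def render_structural_volume(
    nmj: GroundTruthNMJ,
    config: SimConfig,
    distortion: Distortion | None = None,
    *,
    blob_sigma_xy_nm: float = 80.0,
    blob_sigma_z_nm: float = 120.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[StructuralVolume, Distortion, np.ndarray]:
    """Paint each AZ as a 3D Gaussian blob in the Brp and Unc13A channels.

    Blob integrated intensity equals the AZ's protein weight exactly (the
    rendering is linear in the weights).  Returns the volume, the distortion
    actually applied (the truth transform), and the (n, 3) distorted AZ
    centers in structural-frame nm.
    """
    if distortion is None:
        distortion = Distortion()
    distortion.validate(config.min_az_spacing_nm)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    xy = nmj.az[["x_nm", "y_nm"]].to_numpy()
    z = nmj.az["z_nm"].to_numpy()
    xy_d = distortion.apply(xy)

    margin_xy = 1000.0
    margin_z = 500.0
    x0 = xy_d[:, 0].min() - margin_xy
    y0 = xy_d[:, 1].min() - margin_xy
    z0 = z.min() - margin_z
    nx = int(math.ceil((xy_d[:, 0].max() + margin_xy - x0) / config.struct_xy_nm)) + 1
    ny = int(math.ceil((xy_d[:, 1].max() + margin_xy - y0) / config.struct_xy_nm)) + 1
    nz = int(math.ceil((z.max() + margin_z - z0) / config.struct_z_nm)) + 1

    brp = np.zeros((nz, ny, nx), dtype=np.float64)
    unc = np.zeros_like(brp)
    rep = np.zeros_like(brp)

    sx = blob_sigma_xy_nm / config.struct_xy_nm
    sz = blob_sigma_z_nm / config.struct_z_nm
    wx = int(math.ceil(4 * sx))
    wz = max(1, int(math.ceil(4 * sz)))

    centers = np.column_stack([xy_d[:, 0], xy_d[:, 1], z])
    for i, row in enumerate(nmj.az.itertuples(index=False)):
        cx = (xy_d[i, 0] - x0) / config.struct_xy_nm
        cy = (xy_d[i, 1] - y0) / config.struct_xy_nm
        cz = (z[i] - z0) / config.struct_z_nm
        c0, c1 = max(0, int(cx) - wx), min(nx, int(cx) + wx + 1)
        r0, r1 = max(0, int(cy) - wx), min(ny, int(cy) + wx + 1)
        s0, s1 = max(0, int(cz) - wz), min(nz, int(cz) + wz + 1)
        zz, yy, xx = np.mgrid[s0:s1, r0:r1, c0:c1]
        g = np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sx**2) - (zz - cz) ** 2 / (2 * sz**2)
        )
        g_sum = g.sum()
        brp[s0:s1, r0:r1, c0:c1] += row.brp_weight * g / g_sum
        unc[s0:s1, r0:r1, c0:c1] += row.unc13a_weight * g / g_sum
        rep[s0:s1, r0:r1, c0:c1] += g / g.max()  # reporter fill, unit peak

    if noise_sd > 0:
        for vol in (brp, unc, rep):
            vol += noise_sd * rng.standard_normal(vol.shape)
            np.clip(vol, 0, None, out=vol)

    volume = StructuralVolume(
        channels={"brp": brp, "unc13a": unc, "reporter": rep},
        xy_nm=config.struct_xy_nm,
        z_nm=config.struct_z_nm,
        meta={
            "origin_nm": [float(x0), float(y0), float(z0)],
            "genotype": nmj.genotype,
            "drug": nmj.drug,
        },
    )
    return volume, distortion, centers
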