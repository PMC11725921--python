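"""Simulation configuration.

All geometry is in physical units (nm, ms, s).  The functional frame uses
x = column direction, y = row direction, origin at the center of pixel
(0, 0), 0-based indices, half-open time windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: quantal amplitudes below this ceiling would sit inside the detection
#: threshold band (0.04-0.05 dF/F) and default scenarios must clear it
DETECTION_THRESHOLD_CEILING = 0.05


@dataclass
class SimConfig:
    """Parameters of the synthetic NMJ experiment.

    Defaults describe a desk-scale stand-in for a spinning-disk quantal
    imaging session: 0.2 Hz nerve stimulation, ~100 stimuli per epoch with
    the movie time compressed to a window around each stimulus, and a
    post hoc structural volume at coarse (50 nm xy) voxels with the 159 nm
    axial pitch of the Airyscan stacks it emulates.
    """

    # functional imaging
    pixel_size_nm: float = 162.0
    frame_interval_ms: float = 10.0
    n_stimuli_pre: int = 100
    n_stimuli_post: int = 100
    stim_rate_hz: float = 0.2
    #: movie frames simulated per stimulus (time-compressed trial window)
    frames_per_trial: int = 30
    #: baseline frames before the stimulus within each trial window
    baseline_frames: int = 5
    # quantal transient
    quantal_amp_mean: float = 0.25
    quantal_amp_cv: float = 0.3
    decay_tau_ms: float = 50.0
    psf_sigma_nm: float = 140.0
    # nuisance processes
    noise_sd_dff: float = 0.015
    bleach_tau_s: float = 0.0  # 0 disables bleaching
    drift_nm_per_s: float = 0.0
    baseline_fluorescence: float = 100.0
    # NMJ geometry
    n_boutons_ib: int = 5
    n_boutons_is: int = 3
    az_per_bouton: float = 6.0
    bouton_radius_nm: float = 1000.0
    bouton_spacing_nm: float = 2600.0
    min_az_spacing_nm: float = 300.0
    # structural volume
    struct_xy_nm: float = 50.0  # the instrument this emulates resolves 11 nm/px
    struct_z_nm: float = 159.0
    # randomness
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "pixel_size_nm",
            "frame_interval_ms",
            "stim_rate_hz",
            "quantal_amp_mean",
            "decay_tau_ms",
            "psf_sigma_nm",
            "struct_xy_nm",
            "struct_z_nm",
            "bouton_radius_nm",
            "bouton_spacing_nm",
            "min_az_spacing_nm",
            "baseline_fluorescence",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ["n_stimuli_pre", "n_stimuli_post", "frames_per_trial", "baseline_frames"]:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.baseline_frames >= self.frames_per_trial:
            raise ValueError("baseline_frames must be < frames_per_trial")
        if self.quantal_amp_mean <= DETECTION_THRESHOLD_CEILING:
            raise ValueError(
                "quantal_amp_mean must exceed the detection threshold ceiling "
                f"({DETECTION_THRESHOLD_CEILING} dF/F); got {self.quantal_amp_mean}"
            )
        if not 0 <= self.quantal_amp_cv < 1:
            raise ValueError("quantal_amp_cv must lie in [0, 1)")
        if self.noise_sd_dff < 0 or self.bleach_tau_s < 0 or self.drift_nm_per_s < 0:
            raise ValueError("noise/bleach/drift parameters must be >= 0")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)
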