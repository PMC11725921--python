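"""The ΔF/F movie container and its TIFF + JSON sidecar I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class DffMovie:
    """A ΔF/F movie with its acquisition geometry and stimulus train.

    ``frames`` is (time, rows, cols).  Physical coordinates use
    x = column direction, y = row direction, in nm, with the origin at the
    center of pixel (0, 0).
    """

    frames: np.ndarray
    pixel_size_nm: float
    frame_interval_ms: float
    stimulus_frames: np.ndarray
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) array")
        if self.pixel_size_nm <= 0 or self.frame_interval_ms <= 0:
            raise ValueError("pixel_size_nm and frame_interval_ms must be > 0")
        self.stimulus_frames = np.asarray(self.stimulus_frames, dtype=int)
        if len(self.stimulus_frames):
            if (np.diff(self.stimulus_frames) <= 0).any():
                raise ValueError("stimulus frame indices must be strictly increasing")
            if self.stimulus_frames[0] < 0 or self.stimulus_frames[-1] >= len(self.frames):
                raise ValueError("stimulus frame indices out of movie range")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise ValueError("mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def pixel_to_nm(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices -> (x, y) nm at pixel centers."""
        return np.asarray(col) * self.pixel_size_nm, np.asarray(row) * self.pixel_size_nm

    # -- I/O -------------------------------------------------------------
    def write(self, tiff_path: str | Path, meta_path: str | Path | None = None) -> None:
        tiff_path = Path(tiff_path)
        tifffile.imwrite(tiff_path, self.frames)
        if meta_path is None:
            meta_path = tiff_path.with_suffix(".json")
        sidecar = {
            "pixel_size_nm": self.pixel_size_nm,
            "frame_interval_ms": self.frame_interval_ms,
            "stimulus_frames": self.stimulus_frames.tolist(),
            "meta": _jsonable(self.meta),
        }
        Path(meta_path).write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, tiff_path: str | Path, meta_path: str | Path | None = None) -> "DffMovie":
        tiff_path = Path(tiff_path)
        if meta_path is None:
            meta_path = tiff_path.with_suffix(".json")
        sidecar = json.loads(Path(meta_path).read_text())
        return cls(
            frames=tifffile.imread(tiff_path),
            pixel_size_nm=sidecar["pixel_size_nm"],
            frame_interval_ms=sidecar["frame_interval_ms"],
            stimulus_frames=np.asarray(sidecar["stimulus_frames"], dtype=int),
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
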