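"""File formats and run configuration.

TIFF stacks are read and written with tifffile; spatial/temporal calibration
always comes from the run configuration (YAML/JSON), never from TIFF tags,
because tag dialects across acquisition software are unreliable. All result
tables are CSV with stable column order; physical quantities carry explicit
_um/_s/_nm suffixes and coordinates are 0-based pixel indices.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import CalibratedImage, CellMask, ImageStack

__all__ = ["RunConfig", "read_stack", "write_stack", "read_mask", "write_mask",
           "write_labels", "write_results", "read_trace_csv"]

_KNOWN_KEYS = {
    "pixel_size_um", "frame_interval_s", "sectioning", "frap", "depletion",
    "md", "out_dir", "log_level", "seed",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated analysis configuration."""

    pixel_size_um: float = 0.1
    frame_interval_s: float = 4.0
    sectioning: dict = field(default_factory=dict)
    frap: dict = field(default_factory=dict)
    depletion: dict = field(default_factory=dict)
    md: dict = field(default_factory=dict)
    out_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("physical calibration values must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "sectioning": dict(self.sectioning),
            "frap": dict(self.frap),
            "depletion": dict(self.depletion),
            "md": dict(self.md),
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_stack(path: str | Path, config: RunConfig) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as a calibrated stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout with shape {arr.shape}; expected single- or "
            "multi-page grayscale (RGB/multichannel input is not supported)"
        )
    if arr.shape[-1] in (3, 4) and arr.ndim == 3 and arr.shape[0] not in (3, 4):
        # heuristics cannot distinguish tiny stacks from RGB; tifffile keeps
        # sample axis last, so a trailing 3/4 means interleaved color
        raise ValueError("RGB TIFF input is not supported; provide grayscale channels")
    frames = tuple(
        CalibratedImage(frame.astype(float), config.pixel_size_um) for frame in arr
    )
    return ImageStack(frames, config.frame_interval_s)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    arr = stack.as_array()
    tifffile.imwrite(path, np.round(arr).astype(np.uint16), photometric="minisblack")


def write_mask(mask: CellMask, path: str | Path) -> None:
    tifffile.imwrite(path, (mask.mask.astype(np.uint8)) * 255)


def read_mask(path: str | Path, pixel_size_um: float) -> CellMask:
    arr = tifffile.imread(path)
    return CellMask(arr > 0, pixel_size_um)


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    """Read a time-intensity trace CSV (columns time_s, intensity
    [, reference])."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "intensity" not in df.columns:
        raise ValueError("trace CSV must have columns time_s, intensity")
    return df


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
    masks: dict[str, CellMask] | None = None,
    labels: dict[str, np.ndarray] | None = None,
) -> dict:
    """Write CSV tables, mask/label TIFFs and a JSON manifest.

    The manifest lists every artifact plus the config hash and seed so a run
    is reproducible and auditable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        artifacts.append(p.name)
    for name, mask in (masks or {}).items():
        p = out / f"{name}.tif"
        write_mask(mask, p)
        artifacts.append(p.name)
    for name, lab in (labels or {}).items():
        p = out / f"{name}.tif"
        write_labels(lab, p)
        artifacts.append(p.name)
    manifest = {
        "artifacts": sorted(artifacts),
        "config_hash": config.config_hash() if config else None,
        "seed": config.seed if config else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
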