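"""Readers/writers and run configuration.

Images travel as multi-page TIFF (one page per z-plane) with a JSON sidecar
carrying the physical voxel sizes and channel name; localization tables as
CSV with header ``x_nm,y_nm,frame,label``. All outputs carry provenance
(config hash, seed, package version).
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

from .grids import VoxelGrid3D

PACKAGE_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_stack(grid: VoxelGrid3D, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write a volume as a multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, grid.intensities.astype(np.float32))
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "voxel_size_um": list(grid.voxel_size),
        "channel_name": grid.channel_name,
        "shape_zyx": list(grid.shape),
        "axes": "ZYX",
    }, indent=1))
    return path


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> VoxelGrid3D:
    """Read a multi-page TIFF into a :class:`VoxelGrid3D`.

    Voxel sizes come from the JSON sidecar (``<stem>.json`` next to the TIFF
    unless given explicitly); a missing ``voxel_size_um`` key is an error.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # truncated / unreadable file: no partial grid
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise IOError(f"{path}: expected a z-stack of equal-shape pages, got ndim={data.ndim}")

    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    if not sidecar.exists():
        raise IOError(f"missing sidecar {sidecar} (need key 'voxel_size_um')")
    meta = json.loads(sidecar.read_text())
    if "voxel_size_um" not in meta:
        raise IOError(f"{sidecar}: missing required key 'voxel_size_um'")
    vs = tuple(float(v) for v in meta["voxel_size_um"])
    return VoxelGrid3D(np.asarray(data, dtype=np.float64), vs,
                       channel_name=meta.get("channel_name", path.stem))


# ---------------------------------------------------------------------------
# localization tables
# ---------------------------------------------------------------------------

def write_localizations(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in ("x_nm", "y_nm", "frame", "label") if c in df.columns]
    df[cols].to_csv(path, index=False)
    return path


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm"):
        if col not in df.columns:
            raise IOError(f"{path}: missing required column '{col}'")
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"workflow", "seed", "out_dir", "cells", "simulate", "layer",
             "reference_surface", "spot_diameter_um", "storm", "stats",
             "background_subtract"}
_LAYER_KEYS = {"mode", "thickness_um"}
_STORM_KEYS = {"csv", "region", "reps", "max_levels", "seed"}
_STATS_KEYS = {"test", "reference", "csv"}
_CELL_KEYS = {"id", "dna", "lamina", "h3k9me2", "lad_fish", "nonlad_fish", "signal"}


@dataclass
class RunConfig:
    """Validated key-value run configuration for the CLI workflows."""

    workflow: str = "spots"
    seed: int = 0
    out_dir: str = "periscope_out"
    cells: list[dict] = field(default_factory=list)
    simulate: dict = field(default_factory=dict)
    layer: dict = field(default_factory=lambda: {"mode": "measured", "thickness_um": 0.4})
    reference_surface: str = "lamina"
    spot_diameter_um: float = 0.25
    storm: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    background_subtract: bool = True
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.workflow not in ("simulate", "quantify", "spots", "storm-cluster", "stats"):
            raise ValueError(f"unknown workflow {self.workflow!r}")
        if self.reference_surface not in ("lamina", "dna-edge"):
            raise ValueError("reference_surface must be 'lamina' or 'dna-edge'")
        if self.spot_diameter_um <= 0:
            raise ValueError("spot_diameter_um must be positive")
        mode = self.layer.get("mode", "measured")
        if mode not in ("measured", "configured"):
            raise ValueError("layer.mode must be 'measured' or 'configured'")
        t = self.layer.get("thickness_um", 0.4)
        if not t or t <= 0:
            raise ValueError("layer.thickness_um must be positive")
        if set(self.layer) - _LAYER_KEYS:
            raise ValueError(f"unknown layer keys: {set(self.layer) - _LAYER_KEYS}")
        if set(self.storm) - _STORM_KEYS:
            raise ValueError(f"unknown storm keys: {set(self.storm) - _STORM_KEYS}")
        if set(self.stats) - _STATS_KEYS:
            raise ValueError(f"unknown stats keys: {set(self.stats) - _STATS_KEYS}")
        for cell in self.cells:
            extra = set(cell) - _CELL_KEYS
            if extra:
                raise ValueError(f"unknown cell keys: {extra}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: v for k, v in d.items() if k in _TOP_KEYS}
        cfg = cls(**kwargs, raw=dict(d))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls.from_dict(d)
        # referenced files must exist at load time
        base = Path(path).parent
        for cell in cfg.cells:
            for key, val in cell.items():
                if key == "id":
                    continue
                p = (base / val) if not Path(val).is_absolute() else Path(val)
                if not p.exists():
                    raise FileNotFoundError(f"cell {cell.get('id', '?')}: {key} file {p} not found")
        if cfg.storm.get("csv"):
            p = base / cfg.storm["csv"]
            if not Path(cfg.storm["csv"]).is_absolute() and not p.exists() \
                    and not Path(cfg.storm["csv"]).exists():
                raise FileNotFoundError(f"storm csv {cfg.storm['csv']} not found")
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.raw or self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed,
                "version": PACKAGE_VERSION}


def write_csv_with_provenance(df: pd.DataFrame, path: str | Path, prov: dict) -> Path:
    """CSV with '# key: value' provenance header lines (pandas: comment='#')."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
    return path


def write_json_with_provenance(obj: dict, path: str | Path, prov: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"provenance": prov, **obj}, indent=1, default=float))
    return path
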