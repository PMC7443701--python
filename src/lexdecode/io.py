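"""File formats and run configuration.

Events travel as BIDS-style TSV, volumes as NIfTI-1, pattern sets as a TSV
matrix plus a metadata TSV sidecar, configuration as YAML, results as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .decoding import DecodingConfig
from .design import EVENT_COLUMNS, TimingConfig
from .simulate import EffectSpec, PatternSet

PathLike = Union[str, Path]


class IOError_(ValueError):
    pass


# --------------------------------------------------------------------------
# Events TSV
# --------------------------------------------------------------------------


def write_events_tsv(events: pd.DataFrame, path: PathLike) -> None:
    """BIDS-style events TSV; onsets/durations in seconds, 3-decimal fixed."""
    df = events.copy()
    df["meaning"] = df["meaning"].fillna("n/a")
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_events_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"meaning": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"events file {path} is missing columns: {missing}")
    df = df[EVENT_COLUMNS]
    df["meaning"] = df["meaning"].replace("n/a", np.nan)
    df["meaning"] = df["meaning"].where(df["meaning"].notna(), None)
    for run, grp in df.groupby("run"):
        onsets = grp["onset"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise IOError_(f"onsets are not strictly increasing within run {run}")
    return df


# --------------------------------------------------------------------------
# NIfTI volumes
# --------------------------------------------------------------------------


def save_nifti(data: np.ndarray, affine: np.ndarray, path: PathLike) -> None:
    if data.ndim not in (3, 4):
        raise IOError_("NIfTI export expects a 3-D or 4-D array")
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_nifti(path: PathLike) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def timeseries_to_volume(data: np.ndarray, grid: Optional[tuple[int, int, int]] = None) -> np.ndarray:
    """Arrange a voxels x volumes matrix on a synthetic 3-D grid -> 4-D array."""
    V, T = data.shape
    if grid is None:
        side = int(np.ceil(V ** (1.0 / 3.0)))
        grid = (side, side, side)
    n_cells = int(np.prod(grid))
    if n_cells < V:
        raise IOError_(f"grid {grid} too small for {V} voxels")
    vol = np.zeros((n_cells, T))
    vol[:V] = data
    return vol.reshape(*grid, T)


# --------------------------------------------------------------------------
# Pattern sets
# --------------------------------------------------------------------------


def save_pattern_set(ps: PatternSet, prefix: PathLike) -> None:
    """Write <prefix>_patterns.tsv (matrix) and <prefix>_meta.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ps.patterns).to_csv(
        f"{prefix}_patterns.tsv", sep="\t", index=False, header=False
    )
    meta = ps.metadata.copy()
    meta["estimate_kind"] = ps.estimate_kind
    meta.to_csv(f"{prefix}_meta.tsv", sep="\t", index=False)


def load_pattern_set(prefix: PathLike) -> PatternSet:
    patterns = pd.read_csv(f"{prefix}_patterns.tsv", sep="\t", header=None).to_numpy()
    meta = pd.read_csv(f"{prefix}_meta.tsv", sep="\t")
    meta["meaning"] = meta["meaning"].where(meta["meaning"].notna(), None)
    kind = str(meta.pop("estimate_kind").iloc[0])
    return PatternSet(patterns, meta, estimate_kind=kind)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end analysis."""

    seed: int = 0
    n_participants: int = 12
    mode: str = "patterns"  # "patterns" (direct) | "bold" (time-series + GLM)
    tasks: tuple[str, ...] = ("semantic",)
    timing: TimingConfig = field(default_factory=TimingConfig)
    rois: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {"roi1": {}}
    )  # region name -> EffectSpec overrides
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    n_perm: int = 100
    n_iter: int = 100_000
    alpha: float = 0.05
    fdr_q: float = 0.05

    def effect_spec(self, roi: str, participant_pattern_seed: int) -> EffectSpec:
        params = dict(self.rois[roi])
        params["participant_pattern_seed"] = participant_pattern_seed
        return EffectSpec(**params)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["tasks"] = list(self.tasks)
        d["decoding"]["C_grid"] = list(self.decoding.C_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "timing" in d and isinstance(d["timing"], dict):
            d["timing"] = TimingConfig(**d["timing"])
        if "decoding" in d and isinstance(d["decoding"], dict):
            dec = dict(d["decoding"])
            if "C_grid" in dec:
                dec["C_grid"] = tuple(dec["C_grid"])
            d["decoding"] = DecodingConfig(**dec)
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_config(config: RunConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config(path: PathLike) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def write_json(obj: Any, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")
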