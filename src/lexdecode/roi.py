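"""ROI construction from probabilistic atlas maps and pattern extraction.

Regions are defined by thresholding a probabilistic map (voxels with > 30%
probability of belonging to the region), optionally combined with a spatial
cutoff in millimetre space — e.g. for pars orbitalis, dropping voxels more
medial than x = -30 to exclude medial orbitofrontal cortex. A
maximum-probability check reports how many mask voxels are more likely to
belong to the target region than to any competitor.

No atlas files are bundled: ``synthetic_prob_map`` builds small smooth
probability volumes for testing, and real atlas NIfTI maps can be loaded
with :func:`load_prob_map`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .simulate import PatternSet

DEFAULT_THRESHOLD = 0.30


class RoiError(ValueError):
    pass


@dataclass
class ProbMap:
    """Probabilistic region map on a 3-D grid with a grid-to-mm affine."""

    data: np.ndarray
    affine: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise RoiError("probability map must be 3-D")
        if self.data.min() < 0 or self.data.max() > 1:
            raise RoiError("probabilities must lie in [0, 1]")
        if not np.all(np.isfinite(self.affine)):
            raise RoiError("affine must be finite")

    def voxel_mm_coords(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates of all voxels, C-scan order."""
        idx = np.indices(self.data.shape).reshape(3, -1).T
        return nib.affines.apply_affine(self.affine, idx)


@dataclass
class ROIMask:
    data: np.ndarray  # boolean grid
    affine: np.ndarray
    name: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def voxel_indices(self) -> np.ndarray:
        """Flat indices of mask voxels in C-scan order (stable extraction order)."""
        return np.flatnonzero(self.data.ravel(order="C"))


def medial_x_cutoff(x_max_mm: float = -30.0) -> Callable[[np.ndarray], np.ndarray]:
    """Spatial rule keeping left-hemisphere voxels at mm-space x <= x_max.

    Voxels more medial than x_max (x > x_max) are removed; the boundary is
    retained.
    """

    def rule(mm: np.ndarray) -> np.ndarray:
        return mm[:, 0] <= x_max_mm

    rule.description = f"keep x <= {x_max_mm} mm"  # type: ignore[attr-defined]
    return rule


def make_roi_mask(
    prob_map: ProbMap,
    threshold: float = DEFAULT_THRESHOLD,
    spatial_cutoff: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> ROIMask:
    """Threshold a probabilistic map into a boolean ROI.

    A voxel is included iff its probability is strictly greater than
    ``threshold`` (a literal reading of "> 30%": exactly 0.30 is excluded)
    and it passes the spatial cutoff, if any.
    """
    keep = prob_map.data > threshold
    if spatial_cutoff is not None:
        ok = spatial_cutoff(prob_map.voxel_mm_coords()).reshape(prob_map.data.shape)
        keep = keep & ok
    if not keep.any():
        raise RoiError(
            f"empty ROI mask for region {prob_map.name!r} at threshold {threshold}"
        )
    return ROIMask(
        data=keep,
        affine=prob_map.affine.copy(),
        name=prob_map.name,
        provenance={
            "threshold": threshold,
            "spatial_cutoff": getattr(spatial_cutoff, "description", None),
        },
    )


def max_probability_fraction(
    mask: ROIMask, target_map: ProbMap, competitor_maps: Sequence[ProbMap]
) -> float:
    """Fraction of mask voxels whose target probability strictly exceeds
    every competitor's — consistency with maximum-probability-map ROIs."""
    for m in list(competitor_maps) + [target_map]:
        if m.data.shape != mask.data.shape or not np.allclose(m.affine, mask.affine):
            raise RoiError(f"grid mismatch between mask and map {m.name!r}")
    sel = mask.data
    if not competitor_maps:
        return 1.0
    competitor = np.max(np.stack([m.data for m in competitor_maps]), axis=0)
    wins = target_map.data[sel] > competitor[sel]
    return float(wins.mean())


def extract_roi_patterns(
    trial_volumes: np.ndarray,
    mask: ROIMask,
    metadata: Optional[pd.DataFrame] = None,
    estimate_kind: str = "t",
) -> PatternSet:
    """Extract one row per trial volume over the mask voxels.

    ``trial_volumes`` is (n_trials, nx, ny, nz) aligned to the mask grid.
    Voxel order is the C-scan order of the grid, so repeated extraction is
    bit-identical.
    """
    vols = np.asarray(trial_volumes, dtype=float)
    if vols.ndim != 4 or vols.shape[1:] != mask.data.shape:
        raise RoiError(
            f"trial volumes {vols.shape} are not aligned to mask grid {mask.data.shape}"
        )
    flat = vols.reshape(vols.shape[0], -1)
    patterns = flat[:, mask.voxel_indices()]
    if metadata is None:
        metadata = pd.DataFrame(index=range(vols.shape[0]))
    return PatternSet(patterns, metadata.reset_index(drop=True), estimate_kind=estimate_kind)


def synthetic_prob_map(
    shape: tuple[int, int, int] = (16, 16, 16),
    center: Optional[tuple[float, float, float]] = None,
    width_vox: float = 2.5,
    voxel_size_mm: float = 2.4,
    name: str = "synthetic",
    seed: Optional[int] = None,
) -> ProbMap:
    """Small synthetic probability blob for tests (no atlas download).

    A Gaussian bump, peak 1.0, at ``center`` (grid coords; random if a seed
    is given). The affine places the grid with x spanning negative (left
    hemisphere) mm coordinates, mirroring radiological atlas conventions.
    """
    if center is None:
        rng = np.random.default_rng(seed)
        center = tuple(rng.uniform(s * 0.25, s * 0.75) for s in shape)  # type: ignore[assignment]
    grids = np.indices(shape).astype(float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    data = np.exp(-d2 / (2.0 * width_vox**2))
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 1.0  # x,y,z start negative
    return ProbMap(data=data, affine=affine, name=name)


def load_prob_map(path: str, name: str = "") -> ProbMap:
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.max() > 1.0:  # atlases often store percent
        data = data / 100.0
    return ProbMap(data=data, affine=img.affine, name=name or str(path))


def save_mask(mask: ROIMask, path: str) -> None:
    """Write the mask as NIfTI plus a JSON sidecar recording provenance
    (threshold and spatial cutoff)."""
    import json
    from pathlib import Path

    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), path)
    p = Path(path)
    sidecar = p.with_name(p.name.split(".")[0] + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"name": mask.name, **mask.provenance}, fh, indent=2, sort_keys=True)
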