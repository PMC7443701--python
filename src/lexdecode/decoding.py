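"""Cross-validated linear decoding of trial patterns.

Two classification analyses run on each region's trial t-patterns, both with
leave-one-run-out cross-validation and a linear support-vector machine whose
regularisation parameter C is picked per training fold by nested
leave-one-run-out cross-validation over a decade grid spanning 1e-4..1e3:

* relatedness decoding — related vs. unrelated trials across all targets.
  Trial patterns are mean-centred first, so the classifier cannot exploit
  overall activation-level differences between conditions (which the
  univariate analysis shows exist); only the spatial pattern remains.
* meaning decoding — for each homonym separately, which of its two meanings
  was primed (related homonym trials only: 8 trials, one per meaning per
  run), averaged over the five homonyms. No mean-centring by default.

A searchlight variant repeats the relatedness decoder in a moving sphere to
map local information content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.svm import LinearSVC

from .simulate import PatternSet

logger = logging.getLogger("lexdecode")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class DecodingError(ValueError):
    pass


@dataclass(frozen=True)
class DecodingConfig:
    """Decoding options; defaults follow the ROI analysis protocol."""

    C_grid: tuple[float, ...] = tuple(10.0 ** np.arange(-4, 4))
    nested_cv: bool = True
    fixed_C: float = 1.0  # used when nested_cv is False
    center_trials: bool = True  # relatedness classifier
    center_meaning_trials: bool = False  # meaning classifier
    searchlight_radius_mm: float = 12.0
    smoothing_fwhm_mm: float = 4.0

    def __post_init__(self) -> None:
        grid = tuple(float(c) for c in self.C_grid)
        if not grid or any(c <= 0 for c in grid) or list(grid) != sorted(grid):
            raise DecodingError("C_grid must be nonempty, positive and ascending")
        object.__setattr__(self, "C_grid", grid)


@dataclass
class DecodingResult:
    accuracy: float
    fold_accuracies: list[float]
    fold_sizes: list[int]
    chosen_C: list[float]
    n_trials: int
    per_homonym: Optional[dict[str, float]] = None


def mean_center_trials(patterns: PatternSet) -> PatternSet:
    """Subtract each trial row's across-voxel mean (row means become 0)."""
    if patterns.n_voxels < 1:
        raise DecodingError("need at least one voxel")
    centred = patterns.patterns - patterns.patterns.mean(axis=1, keepdims=True)
    return PatternSet(centred, patterns.metadata.copy(), patterns.estimate_kind)


def train_linear_classifier(X: np.ndarray, y: np.ndarray, C: float) -> LinearSVC:
    """Fit a linear SVM (LIBLINEAR, primal squared-hinge: deterministic)."""
    if len(np.unique(y)) < 2:
        raise DecodingError("training set contains a single class")
    clf = LinearSVC(C=C, loss="squared_hinge", dual=False, tol=1e-6, max_iter=20000)
    return clf.fit(X, y)


def select_C_nested(
    X: np.ndarray,
    y: np.ndarray,
    runs: np.ndarray,
    grid: Sequence[float],
) -> float:
    """C maximising inner leave-one-run-out accuracy; ties take the smallest
    C (strongest regularisation)."""
    inner_runs = np.unique(runs)
    if len(inner_runs) < 2:
        raise DecodingError("nested C selection needs >= 2 training runs")
    correct = np.zeros(len(grid), dtype=int)
    for r in inner_runs:
        val = runs == r
        Xtr, ytr = X[~val], y[~val]
        for j, C in enumerate(grid):
            clf = train_linear_classifier(Xtr, ytr, C)
            correct[j] += int((clf.predict(X[val]) == y[val]).sum())
    return float(grid[int(np.argmax(correct))])  # argmax returns first (= smallest) max


def cross_validated_decode(
    X: np.ndarray,
    y: np.ndarray,
    runs: np.ndarray,
    config: DecodingConfig,
    center: bool = False,
) -> DecodingResult:
    """Outer leave-one-run-out decoding with optional nested C selection.

    The held-out run never enters training or the inner cross-validation of
    its fold. Accuracy is the proportion of correctly classified test trials
    pooled over folds (classes are balanced by design).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    runs = np.asarray(runs)
    if not (len(X) == len(y) == len(runs)):
        raise DecodingError("patterns, labels and runs must align")
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    fold_acc: list[float] = []
    fold_sizes: list[int] = []
    chosen: list[float] = []
    for r in np.unique(runs):
        test = runs == r
        if config.nested_cv:
            C = select_C_nested(X[~test], y[~test], runs[~test], config.C_grid)
        else:
            C = config.fixed_C
        clf = train_linear_classifier(X[~test], y[~test], C)
        pred = clf.predict(X[test])
        fold_acc.append(float((pred == y[test]).mean()))
        fold_sizes.append(int(test.sum()))
        chosen.append(C)
    total = sum(fold_sizes)
    accuracy = float(np.dot(fold_acc, fold_sizes) / total)
    return DecodingResult(accuracy, fold_acc, fold_sizes, chosen, total)


def relatedness_labels(metadata: pd.DataFrame) -> np.ndarray:
    """'related'/'unrelated' per trial from the condition column."""
    if "condition" not in metadata:
        raise DecodingError("metadata lacks a 'condition' column")
    return metadata["condition"].str.split("-").str[0].to_numpy()


def decode_relatedness(patterns: PatternSet, config: DecodingConfig = DecodingConfig()) -> DecodingResult:
    """Related vs. unrelated decoding over one task's runs (mean-centred by
    default so mean activation differences cannot drive the result)."""
    meta = patterns.metadata
    if "run" not in meta:
        raise DecodingError("metadata lacks a 'run' column")
    y = relatedness_labels(meta)
    return cross_validated_decode(
        patterns.patterns, y, meta["run"].to_numpy(), config, center=config.center_trials
    )


def decode_meanings(patterns: PatternSet, config: DecodingConfig = DecodingConfig()) -> DecodingResult:
    """Meaning 1 vs. 2 decoding per homonym, averaged over homonyms.

    Expects the related homonym trials of one task: per homonym, one trial
    of each meaning per run (train 6, test 2 in each fold).
    """
    meta = patterns.metadata
    sub = meta["condition"] == "related-ambiguous"
    ps = patterns.subset(sub.to_numpy())
    if ps.n_trials == 0:
        raise DecodingError("no related homonym trials present")
    per_hom: dict[str, float] = {}
    details: list[DecodingResult] = []
    for word in sorted(ps.metadata["target"].unique()):
        hp = ps.subset((ps.metadata["target"] == word).to_numpy())
        _check_meaning_balance(hp.metadata, word)
        res = cross_validated_decode(
            hp.patterns,
            hp.metadata["meaning"].to_numpy(),
            hp.metadata["run"].to_numpy(),
            config,
            center=config.center_meaning_trials,
        )
        per_hom[word] = res.accuracy
        details.append(res)
    accuracy = float(np.mean(list(per_hom.values())))  # unweighted over homonyms
    return DecodingResult(
        accuracy=accuracy,
        fold_accuracies=[a for d in details for a in d.fold_accuracies],
        fold_sizes=[s for d in details for s in d.fold_sizes],
        chosen_C=[c for d in details for c in d.chosen_C],
        n_trials=sum(d.n_trials for d in details),
        per_homonym=per_hom,
    )


def _check_meaning_balance(meta: pd.DataFrame, word: str) -> None:
    for run, grp in meta.groupby("run"):
        if sorted(grp["meaning"]) != sorted(meta["meaning"].unique()):
            raise DecodingError(
                f"homonym {word!r} is missing a meaning in run {run}: "
                f"{sorted(grp['meaning'])}"
            )


# --------------------------------------------------------------------------
# Searchlight
# --------------------------------------------------------------------------


def sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer grid offsets within a Euclidean radius (centre included)."""
    if radius_mm < 0 or voxel_size_mm <= 0:
        raise DecodingError("radius must be >= 0 and voxel size > 0")
    r_vox = int(np.floor(radius_mm / voxel_size_mm))
    axis = np.arange(-r_vox, r_vox + 1)
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(grid * voxel_size_mm, axis=1)
    return grid[dist <= radius_mm + 1e-9]


def searchlight_map(
    trial_volumes: np.ndarray,
    brain_mask: np.ndarray,
    labels: np.ndarray,
    runs: np.ndarray,
    config: DecodingConfig = DecodingConfig(),
    voxel_size_mm: float = 2.4,
    center: bool = True,
) -> np.ndarray:
    """Accuracy volume from decoding within a sphere around each mask voxel.

    ``trial_volumes`` is (n_trials, nx, ny, nz). Out-of-mask voxels are NaN;
    a sphere with no in-mask voxels is left NaN and logged.
    """
    vols = np.asarray(trial_volumes, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if vols.ndim != 4 or vols.shape[1:] != mask.shape:
        raise DecodingError("trial volumes are not aligned to the brain mask")
    offsets = sphere_offsets(config.searchlight_radius_mm, voxel_size_mm)
    shape = np.array(mask.shape)
    out = np.full(mask.shape, np.nan)
    centres = np.argwhere(mask)
    flat = vols.reshape(vols.shape[0], -1)
    for c in centres:
        pos = c[None, :] + offsets
        ok = np.all((pos >= 0) & (pos < shape[None, :]), axis=1)
        pos = pos[ok]
        in_mask = mask[pos[:, 0], pos[:, 1], pos[:, 2]]
        pos = pos[in_mask]
        if len(pos) == 0:
            logger.warning("searchlight sphere at %s contains no in-mask voxels", tuple(c))
            continue
        cols = np.ravel_multi_index((pos[:, 0], pos[:, 1], pos[:, 2]), mask.shape)
        res = cross_validated_decode(flat[:, cols], labels, runs, config, center=center)
        out[tuple(c)] = res.accuracy
    return out


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float = 2.4) -> np.ndarray:
    """Separable Gaussian smoothing; sigma = FWHM / (2 sqrt(2 ln 2))."""
    if fwhm_mm < 0:
        raise DecodingError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma_vox, mode="constant")
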