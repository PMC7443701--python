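"""Permutation-based group inference for decoding accuracies.

Chance performance of a cross-validated decoder is not exactly 50% in finite
samples, so significance is assessed empirically, following the Monte-Carlo
group scheme of Stelzer-style permutation inference adapted to ROI data:

1. per participant, re-run the identical decoding pipeline on label-permuted
   data to build a participant null distribution of accuracies (random
   within-run permutations for the relatedness classifier; the exhaustive
   set of within-run meaning swaps — 7 per homonym over 4 runs — for the
   meaning classifier);
2. draw one value per participant (for the meaning classifier, one per
   homonym per participant, averaged within participant), average across
   participants, and repeat many times to form the group null of the mean
   accuracy;
3. the empirical p-value is the fraction of group-null values at or above
   the observed group mean, floored at 1/n_iter.

A classifier-by-region interaction test applies the same machinery to the
difference of accuracy differences, and Benjamini-Hochberg FDR corrects
over the family of ROI tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .decoding import DecodingConfig, cross_validated_decode, relatedness_labels
from .simulate import PatternSet

DEFAULT_N_PERM = 100
DEFAULT_N_ITER = 100_000


class InferenceError(ValueError):
    pass


@dataclass
class NullSet:
    """One participant's permuted accuracies.

    ``values`` is 1-D (n_perm,) for the relatedness classifier and 2-D
    (n_homonyms, 7) for the meaning classifier.
    """

    values: np.ndarray
    kind: str  # "relatedness" | "meaning"
    scheme: str
    participant: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise InferenceError("empty null set")
        if np.any((self.values < 0) | (self.values > 1)):
            raise InferenceError("null accuracies must lie in [0, 1]")


@dataclass
class GroupResult:
    observed: float
    null_sample: np.ndarray
    p: float
    n_iter: int


def enumerate_meaning_relabelings(n_runs: int) -> list[tuple[bool, ...]]:
    """Distinct non-identity meaning relabelings for one homonym.

    Each run holds one trial per meaning, so the only label changes that
    preserve the design are within-run swaps: a sign pattern over runs.
    Exchanging both labels globally leaves a binary decoder's accuracy
    unchanged, so patterns are collapsed modulo a global flip (fix the first
    run unswapped) and the identity class is excluded:
    2**(n_runs - 1) - 1 relabelings (7 for 4 runs).
    """
    if n_runs < 1:
        raise InferenceError("n_runs must be >= 1")
    out = []
    for rest in product((False, True), repeat=n_runs - 1):
        pattern = (False,) + rest
        if any(pattern):
            out.append(pattern)
    return out


def _permute_within_runs(
    y: np.ndarray, runs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = y.copy()
    for r in np.unique(runs):
        idx = np.flatnonzero(runs == r)
        out[idx] = y[idx[rng.permutation(len(idx))]]
    return out


def participant_null_relatedness(
    patterns: PatternSet,
    config: DecodingConfig = DecodingConfig(),
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    participant: Optional[int] = None,
) -> NullSet:
    """Relatedness-classifier null: random within-run label permutations,
    each decoded by the identical pipeline."""
    if n_perm < 1:
        raise InferenceError("n_perm must be >= 1")
    meta = patterns.metadata
    y = relatedness_labels(meta)
    runs = meta["run"].to_numpy()
    X = patterns.patterns
    rng = np.random.default_rng(seed)
    values = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = _permute_within_runs(y, runs, rng)
        res = cross_validated_decode(X, y_perm, runs, config, center=config.center_trials)
        values[i] = res.accuracy
    return NullSet(values, "relatedness", "random within-run label permutation", participant)


def participant_null_meanings(
    patterns: PatternSet,
    config: DecodingConfig = DecodingConfig(),
    participant: Optional[int] = None,
) -> NullSet:
    """Meaning-classifier null: the exhaustive within-run meaning swaps.

    For each homonym, every non-identity relabeling is decoded, giving
    7 values per homonym over 4 runs (35 per participant); no randomness is
    involved, so the null set is seed-independent.
    """
    meta = patterns.metadata
    sub = (meta["condition"] == "related-ambiguous").to_numpy()
    ps = patterns.subset(sub)
    if ps.n_trials == 0:
        raise InferenceError("no related homonym trials present")
    words = sorted(ps.metadata["target"].unique())
    rows = []
    for word in words:
        hp = ps.subset((ps.metadata["target"] == word).to_numpy())
        runs = hp.metadata["run"].to_numpy()
        run_ids = np.unique(runs)
        relabelings = enumerate_meaning_relabelings(len(run_ids))
        y = hp.metadata["meaning"].to_numpy()
        m1, m2 = np.unique(y)
        swap = {m1: m2, m2: m1}
        vals = []
        for pattern in relabelings:
            y_new = y.copy()
            for flip, r in zip(pattern, run_ids):
                if flip:
                    idx = runs == r
                    y_new[idx] = [swap[v] for v in y[idx]]
            res = cross_validated_decode(
                hp.patterns, y_new, runs, config, center=config.center_meaning_trials
            )
            vals.append(res.accuracy)
        rows.append(vals)
    return NullSet(
        np.asarray(rows), "meaning", "exhaustive within-run meaning swaps", participant
    )


def group_null(
    nulls: Sequence[NullSet],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    scheme: str = "simple",
) -> np.ndarray:
    """Monte-Carlo group null of the mean accuracy.

    ``simple``: one value drawn per participant, averaged. ``per_item``: one
    value per homonym per participant, averaged within participant then
    across participants (the meaning-classifier scheme).
    """
    if len(nulls) < 2:
        raise InferenceError("group null needs >= 2 participants")
    rng = np.random.default_rng(seed)
    if scheme == "simple":
        vals = np.stack([np.ravel(n.values) for n in nulls])  # (P, n_perm)
        idx = rng.integers(0, vals.shape[1], size=(n_iter, len(nulls)))
        return vals[np.arange(len(nulls))[None, :], idx].mean(axis=1)
    if scheme == "per_item":
        vals = np.stack([np.atleast_2d(n.values) for n in nulls])  # (P, H, K)
        P, H, K = vals.shape
        out = np.empty(n_iter)
        chunk = max(1, min(n_iter, 20_000))
        for start in range(0, n_iter, chunk):
            n = min(chunk, n_iter - start)
            idx = rng.integers(0, K, size=(n, P, H))
            draw = np.take_along_axis(vals[None, :, :, :], idx[:, :, :, None], axis=3)
            out[start : start + n] = draw[..., 0].mean(axis=(1, 2))
        return out
    raise InferenceError(f"unknown scheme {scheme!r}")


def empirical_p(observed: float, null_sample: np.ndarray) -> float:
    """Position of the observed value in the null: p = #{null >= obs} / n,
    floored at 1/n so p is never zero. An observed value exceeding 99 of
    100 null values gives p = 0.01."""
    null_sample = np.asarray(null_sample, dtype=float)
    n = null_sample.size
    if n == 0:
        raise InferenceError("empty null sample")
    count = int(np.sum(null_sample >= observed))
    return max(count, 1) / n


def group_test(
    observed_accuracies: Sequence[float],
    nulls: Sequence[NullSet],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    scheme: str = "simple",
) -> GroupResult:
    """Observed group mean vs. its Monte-Carlo group null."""
    if len(observed_accuracies) != len(nulls):
        raise InferenceError("one observed accuracy per participant required")
    observed = float(np.mean(observed_accuracies))
    null_sample = group_null(nulls, n_iter=n_iter, seed=seed, scheme=scheme)
    return GroupResult(observed, null_sample, empirical_p(observed, null_sample), n_iter)


def interaction_p(
    observed: dict[tuple[str, str], float],
    nulls: dict[tuple[str, str], Sequence[NullSet]],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    schemes: Optional[dict[str, str]] = None,
) -> tuple[float, float, np.ndarray]:
    """Two-sided permutation test of a 2-region x 2-classifier interaction.

    ``observed`` and ``nulls`` are keyed by (region, classifier) with two
    regions (A, B) and two classifiers (c1, c2); the statistic is
    (A_c1 - A_c2) - (B_c1 - B_c2). Null interactions are built by drawing a
    group-null value for each cell per iteration. Returns (p, observed
    interaction, null sample); p = 2 * min(upper, lower tail), capped at 1.
    """
    keys = sorted(observed)
    if len(keys) != 4 or sorted(nulls) != keys:
        raise InferenceError(f"need all four (region, classifier) cells, got {keys}")
    regions = sorted({r for r, _ in keys})
    classifiers = sorted({c for _, c in keys})
    if len(regions) != 2 or len(classifiers) != 2:
        raise InferenceError("cells must form a 2 x 2 (region x classifier) layout")
    (ra, rb), (c1, c2) = regions, classifiers
    obs = (observed[(ra, c1)] - observed[(ra, c2)]) - (
        observed[(rb, c1)] - observed[(rb, c2)]
    )
    schemes = schemes or {}
    ss = np.random.SeedSequence(seed).spawn(4)
    cell_null = {}
    for cell, child in zip(keys, ss):
        scheme = schemes.get(cell[1], "simple")
        cell_null[cell] = group_null(
            nulls[cell], n_iter=n_iter, seed=int(child.generate_state(1)[0] % 2**31), scheme=scheme
        )
    null_int = (cell_null[(ra, c1)] - cell_null[(ra, c2)]) - (
        cell_null[(rb, c1)] - cell_null[(rb, c2)]
    )
    p_hi = empirical_p(obs, null_int)
    p_lo = max(int(np.sum(null_int <= obs)), 1) / n_iter
    return min(1.0, 2.0 * min(p_hi, p_lo)), obs, null_int


def fdr_bh(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((pvals <= 0) | (pvals > 1)):
        raise InferenceError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj
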