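"""Synthetic per-participant voxel data with controllable signal structure.

Generates trial-by-voxel patterns (direct mode) or BOLD time series
(time-series mode) carrying three separable signals the analyses target:

* a univariate offset per condition (mean activation differences),
* a shared multi-voxel pattern distinguishing related from unrelated trials
  (what the relatedness classifier reads), and
* one multi-voxel pattern per homonym meaning (what the meaning classifier
  reads),

plus Gaussian noise. Patterns are redrawn per participant: all decoding is
within-participant, and group inference only averages accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .design import TimingConfig

PATTERN_META_COLUMNS = ["run", "target", "condition", "meaning", "task"]


class SimulationError(ValueError):
    pass


@dataclass
class PatternSet:
    """Trials x voxels matrix with aligned per-trial metadata.

    The unit of all decoding. ``estimate_kind`` records whether rows are GLM
    t-values, betas, or directly simulated patterns.
    """

    patterns: np.ndarray
    metadata: pd.DataFrame
    estimate_kind: str = "simulated"  # "t" | "beta" | "simulated"

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 2:
            raise SimulationError("patterns must be a 2-D trials x voxels array")
        if len(self.metadata) != self.patterns.shape[0]:
            raise SimulationError(
                f"metadata rows ({len(self.metadata)}) must align with "
                f"pattern rows ({self.patterns.shape[0]})"
            )
        if not np.all(np.isfinite(self.patterns)):
            raise SimulationError("patterns contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def subset(self, mask: np.ndarray) -> "PatternSet":
        mask = np.asarray(mask)
        return PatternSet(
            self.patterns[mask],
            self.metadata.loc[mask].reset_index(drop=True),
            self.estimate_kind,
        )


def concat_pattern_sets(sets: list[PatternSet]) -> PatternSet:
    kinds = {s.estimate_kind for s in sets}
    if len(kinds) != 1:
        raise SimulationError(f"cannot concatenate mixed estimate kinds: {kinds}")
    return PatternSet(
        np.vstack([s.patterns for s in sets]),
        pd.concat([s.metadata for s in sets], ignore_index=True),
        kinds.pop(),
    )


@dataclass(frozen=True)
class EffectSpec:
    """Signal recipe for one participant's voxel data in one region.

    Amplitudes are in units of the voxel noise SD. The default is a pure
    noise (null) region; analyses plant effects explicitly. ``ar_rho`` and
    ``drift_amplitude`` only affect time-series mode.
    """

    n_voxels: int = 60
    univariate_offsets: Mapping[str, float] = field(default_factory=dict)
    meaning_amplitude: float = 0.0
    relatedness_amplitude: float = 0.0
    noise_sd: float = 1.0
    participant_pattern_seed: int = 0
    ar_rho: float = 0.3
    drift_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise SimulationError("n_voxels must be >= 2")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be > 0")
        if self.meaning_amplitude < 0 or self.relatedness_amplitude < 0:
            raise SimulationError("amplitudes must be >= 0")

    def offset_for(self, condition: str) -> float:
        """Univariate offset for a condition; keys may be full condition
        labels ('related-ambiguous') or relatedness statuses ('related')."""
        if condition in self.univariate_offsets:
            return float(self.univariate_offsets[condition])
        status = condition.split("-")[0]
        if status in self.univariate_offsets:
            return float(self.univariate_offsets[status])
        if condition not in (
            "related-ambiguous",
            "related-unambiguous",
            "unrelated-ambiguous",
            "unrelated-unambiguous",
        ):
            raise SimulationError(f"unknown condition label {condition!r}")
        return 0.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_meaning_patterns(
    effect_spec: EffectSpec, homonyms: Mapping[str, tuple[str, str]]
) -> dict[tuple[str, str], np.ndarray]:
    """Unit-norm random pattern per (homonym, meaning), drawn independently.

    In high-dimensional voxel space independent draws are near-orthogonal, so
    the two meanings of a homonym are coded by distinct directions.
    """
    rng = np.random.default_rng(effect_spec.participant_pattern_seed)
    out: dict[tuple[str, str], np.ndarray] = {}
    for word in sorted(homonyms):
        for meaning in homonyms[word]:
            out[(word, meaning)] = _unit(rng.standard_normal(effect_spec.n_voxels))
    return out


def make_status_pattern(effect_spec: EffectSpec) -> np.ndarray:
    """Unit-norm pattern shared by all related trials (sign-flipped for
    unrelated), independent of the meaning patterns."""
    ss = np.random.SeedSequence([int(effect_spec.participant_pattern_seed), 1])
    rng = np.random.default_rng(ss)
    return _unit(rng.standard_normal(effect_spec.n_voxels))


def _homonym_meanings_from_events(events: pd.DataFrame) -> dict[str, tuple[str, str]]:
    rel = events[(events["trial_type"] == "target") & events["meaning"].notna()]
    out: dict[str, tuple[str, str]] = {}
    for word, grp in rel.groupby("target"):
        meanings = tuple(sorted(grp["meaning"].unique()))
        if len(meanings) == 2:
            out[word] = meanings  # type: ignore[assignment]
    return out


def trial_signal_patterns(
    events: pd.DataFrame, effect_spec: EffectSpec
) -> tuple[np.ndarray, pd.DataFrame]:
    """Noise-free signal pattern for every target trial (the ground truth)."""
    targets = events[events["trial_type"] == "target"].reset_index(drop=True)
    if targets.empty:
        raise SimulationError("events contain no target rows")
    meanings = _homonym_meanings_from_events(events)
    mpats = make_meaning_patterns(effect_spec, meanings)
    spat = make_status_pattern(effect_spec)
    V = effect_spec.n_voxels
    signal = np.zeros((len(targets), V))
    for i, row in targets.iterrows():
        mu = np.full(V, effect_spec.offset_for(row["condition"]))
        status_sign = 1.0 if row["condition"].startswith("related") else -1.0
        mu += effect_spec.relatedness_amplitude * status_sign * spat
        if row["meaning"] is not None and not pd.isna(row["meaning"]):
            mu += effect_spec.meaning_amplitude * mpats[(row["target"], row["meaning"])]
        signal[i] = mu
    meta = targets[PATTERN_META_COLUMNS].reset_index(drop=True)
    return signal, meta


def simulate_pattern_set(
    events: pd.DataFrame, effect_spec: EffectSpec, seed: int
) -> PatternSet:
    """Direct-mode stand-in for trial t-maps: signal + iid Gaussian noise."""
    signal, meta = trial_signal_patterns(events, effect_spec)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(signal.shape) * effect_spec.noise_sd
    return PatternSet(signal + noise, meta, estimate_kind="simulated")


@dataclass
class Timeseries:
    """Simulated BOLD for one run: voxels x volumes, with ground truth."""

    data: np.ndarray  # (n_voxels, n_volumes)
    tr_s: float
    run: int
    true_amplitudes: np.ndarray  # (n_target_trials, n_voxels)
    events: pd.DataFrame

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, rho: float
) -> np.ndarray:
    """AR(1) noise along the time axis with stationary SD ``sd``."""
    white = rng.standard_normal(shape)
    out = np.empty(shape)
    out[:, 0] = white[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, shape[1]):
        out[:, t] = rho * out[:, t - 1] + scale * white[:, t]
    return sd * out


def simulate_bold(
    events: pd.DataFrame,
    effect_spec: EffectSpec,
    timing: TimingConfig = TimingConfig(),
    seed: int = 0,
) -> Timeseries:
    """Time-series mode: HRF-convolved events + drift + AR(1) noise.

    Target trials carry the same voxelwise signal amplitudes as direct mode;
    primes drive a uniform unit response. Uses the same convolution as the
    GLM design builder, so a noiseless run is recovered exactly by OLS.
    """
    from .glm import canonical_hrf, event_regressor  # local import: no cycle at module load

    if (events["onset"] + events["duration"]).max() > timing.run_duration_s:
        raise SimulationError("event beyond run end")
    signal, _meta = trial_signal_patterns(events, effect_spec)
    targets = events[events["trial_type"] == "target"].reset_index(drop=True)
    primes = events[events["trial_type"] == "prime"].reset_index(drop=True)

    hrf = canonical_hrf(timing.tr_s / 16.0)
    V = effect_spec.n_voxels
    data = np.zeros((V, timing.n_volumes))
    # one 2-s boxcar regressor per target trial, scaled by its voxel amplitude
    for i, row in targets.iterrows():
        reg = event_regressor(
            np.array([row["onset"]]), np.array([2.0]), timing.tr_s, timing.n_volumes, hrf
        )
        data += np.outer(signal[i], reg)
    if len(primes):
        reg = event_regressor(
            primes["onset"].to_numpy(), np.zeros(len(primes)), timing.tr_s, timing.n_volumes, hrf
        )
        data += reg[None, :]  # uniform unit prime response

    rng = np.random.default_rng(seed)
    if effect_spec.drift_amplitude > 0:
        t = np.arange(timing.n_volumes) * timing.tr_s
        period = rng.uniform(200.0, 400.0, size=V)
        phase = rng.uniform(0, 2 * np.pi, size=V)
        data += effect_spec.drift_amplitude * np.cos(
            2 * np.pi * t[None, :] / period[:, None] + phase[:, None]
        )
    data += _ar1_noise(rng, data.shape, effect_spec.noise_sd, effect_spec.ar_rho)
    run = int(events["run"].iloc[0]) if "run" in events and len(events) else 0
    return Timeseries(data=data, tr_s=timing.tr_s, run=run, true_amplitudes=signal, events=events)


def meaning_amplitude_for_discriminability(
    d: float,
    n_voxels: int = 60,
    n_train_per_class: int = 3,
    noise_sd: float = 1.0,
) -> float:
    """Meaning amplitude giving a target cross-validated discriminability d.

    ``d`` is the signal-detection sensitivity of the held-out decision
    variable of a linear decoder trained on ``n_train_per_class`` trials per
    meaning, under the two-alternative convention PC = Phi(d/sqrt(2)) (each
    test run holds one trial of each meaning). The weight vector estimated
    from few trials in many voxels is noisy; that shrinkage is what makes the
    required amplitude grow with ``n_voxels / n_train_per_class``. With
    pattern separation D = ||mu1 - mu2|| / noise_sd, the held-out sensitivity
    is approximately D^2 / sqrt(D^2 + 2 n_voxels / n_train), and two
    independent unit-norm meaning patterns are ~orthogonal, so
    D ~= amplitude * sqrt(2) / noise_sd. Inverts that relation in closed form.
    """
    if d <= 0:
        raise SimulationError("d must be > 0")
    # solve u/2 = (d/sqrt(2)) * sqrt(u + 2V/n) for u = D^2
    v_term = 2.0 * n_voxels / n_train_per_class
    u = d**2 + np.sqrt(d**4 + 2 * d**2 * v_term)
    return float(noise_sd * np.sqrt(u / 2.0))
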