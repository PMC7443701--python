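"""First-level GLM: canonical HRF, design matrices, OLS fits, trial t-patterns.

Two design modes mirror the two analysis streams. The multivariate stream
models each of a run's 30 targets with its own regressor and extracts a
t-map per trial; the univariate stream models targets with four condition
regressors. In both, a single impulse regressor captures the primes, targets
are 2-s boxcars, and a discrete-cosine basis implements a 128-s high-pass.
Estimation is ordinary least squares per voxel, no prewhitening: the
resulting t-patterns are used comparatively, so a shared scale inflation
from temporal autocorrelation is harmless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import gamma

from .design import CONDITIONS, TimingConfig
from .simulate import PatternSet, Timeseries

TARGET_MODEL_DURATION_S = 2.0  # targets modelled as 2-s boxcars
OVERSAMPLE = 16  # microtime bins per TR for convolution


class GlmError(ValueError):
    pass


def canonical_hrf(dt_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalised to 1.

    Difference of gamma densities with the standard parameters
    (peak delay 6, undershoot delay 16, dispersions 1, undershoot ratio 1/6):
    peak near 5 s, undershoot around 15 s, zero at t = 0.
    """
    if dt_s <= 0:
        raise GlmError("dt_s must be > 0")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    h = gamma.pdf(t, a=6, scale=1.0) - gamma.pdf(t, a=16, scale=1.0) / 6.0
    return h / h.max()


def event_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    tr_s: float,
    n_volumes: int,
    hrf: Optional[np.ndarray] = None,
) -> np.ndarray:
    """HRF-convolved regressor sampled at volume acquisition times.

    Zero-duration events are unit-area impulses (their response is the HRF
    itself); positive durations are unit-height boxcars. Shared by the BOLD
    simulator and the design builder so the two are consistent by
    construction.
    """
    dt = tr_s / OVERSAMPLE
    if hrf is None:
        hrf = canonical_hrf(dt)
    n_hi = n_volumes * OVERSAMPLE
    u = np.zeros(n_hi)
    for onset, dur in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        i0 = int(round(onset / dt))
        if i0 >= n_hi:
            continue
        if dur <= 0:
            u[i0] += 1.0 / dt
        else:
            i1 = min(int(round((onset + dur) / dt)), n_hi)
            u[i0:i1] += 1.0
    conv = np.convolve(u, hrf)[:n_hi] * dt
    return conv[::OVERSAMPLE].copy()


def dct_drift_basis(n_volumes: int, tr_s: float, hp_cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis spanning frequencies below 1/cutoff Hz.

    Order K = floor(2 * run_duration / cutoff); columns are unit-norm
    cosines, excluding the constant (the intercept is a separate column).
    """
    total = n_volumes * tr_s
    k_max = int(np.floor(2.0 * total / hp_cutoff_s))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class DesignMatrix:
    frame: pd.DataFrame  # volumes x named columns
    tr_s: float
    target_columns: list[str]
    trial_info: Optional[pd.DataFrame] = None  # one row per trialwise column

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise GlmError(f"design matrix is rank-deficient; collinear columns: {bad}")


def build_design_matrix(
    events: pd.DataFrame,
    timing: TimingConfig = TimingConfig(),
    mode: str = "trialwise",
    hp_cutoff_s: float = 128.0,
    nuisance: Optional[pd.DataFrame] = None,
) -> DesignMatrix:
    """Design for a single run's events.

    ``trialwise``: one 2-s boxcar column per target event (pattern
    estimation). ``condition``: one column per experimental condition
    (univariate analysis). Both add one impulse regressor for all primes,
    the DCT drift basis, and an intercept. Optional nuisance columns (e.g.
    motion) are appended unmodified.
    """
    if mode not in ("trialwise", "condition"):
        raise GlmError(f"unknown design mode {mode!r}")
    if len(events) and (events["onset"] + events["duration"]).max() > timing.run_duration_s:
        raise GlmError("events extend beyond the run duration")

    hrf = canonical_hrf(timing.tr_s / OVERSAMPLE)
    targets = events[events["trial_type"] == "target"].reset_index(drop=True)
    primes = events[events["trial_type"] == "prime"]

    cols: dict[str, np.ndarray] = {}
    target_columns: list[str] = []
    trial_info: Optional[pd.DataFrame] = None
    if mode == "trialwise":
        for i, row in targets.iterrows():
            name = f"trial{i:02d}_{row['target']}"
            cols[name] = event_regressor(
                np.array([row["onset"]]),
                np.array([TARGET_MODEL_DURATION_S]),
                timing.tr_s,
                timing.n_volumes,
                hrf,
            )
            target_columns.append(name)
        if len(targets):
            trial_info = targets[["run", "target", "condition", "meaning", "task"]].copy()
            trial_info.insert(0, "column", target_columns)
    else:
        for cond in CONDITIONS:
            sub = targets[targets["condition"] == cond]
            if sub.empty:
                continue
            cols[cond] = event_regressor(
                sub["onset"].to_numpy(),
                np.full(len(sub), TARGET_MODEL_DURATION_S),
                timing.tr_s,
                timing.n_volumes,
                hrf,
            )
            target_columns.append(cond)
    if len(primes):
        cols["primes"] = event_regressor(
            primes["onset"].to_numpy(),
            np.zeros(len(primes)),
            timing.tr_s,
            timing.n_volumes,
            hrf,
        )
    drift = dct_drift_basis(timing.n_volumes, timing.tr_s, hp_cutoff_s)
    for k in range(drift.shape[1]):
        cols[f"drift_{k + 1}"] = drift[:, k]
    cols["intercept"] = np.ones(timing.n_volumes)
    if nuisance is not None:
        for name in nuisance.columns:
            cols[str(name)] = nuisance[name].to_numpy()

    frame = pd.DataFrame(cols)
    _check_full_rank(frame.to_numpy(), list(frame.columns))
    return DesignMatrix(frame=frame, tr_s=timing.tr_s, target_columns=target_columns, trial_info=trial_info)


@dataclass
class GlmFit:
    betas: np.ndarray  # (n_columns, n_voxels)
    resid_var: np.ndarray  # (n_voxels,) unbiased
    dof: int
    columns: list[str]
    xtx_inv_diag: np.ndarray  # (n_columns,)


def fit_glm(ts: Union[Timeseries, np.ndarray], design: DesignMatrix) -> GlmFit:
    """Per-voxel ordinary least squares."""
    data = ts.data if isinstance(ts, Timeseries) else np.asarray(ts, dtype=float)
    if data.ndim != 2:
        raise GlmError("time series must be 2-D (voxels x volumes)")
    if data.shape[1] != design.n_volumes:
        raise GlmError(
            f"time series has {data.shape[1]} volumes but design has {design.n_volumes}"
        )
    X = design.values
    _check_full_rank(X, list(design.frame.columns))
    rank = X.shape[1]
    dof = design.n_volumes - rank
    if dof <= 0:
        raise GlmError(f"non-positive residual dof ({dof})")
    Y = data.T  # volumes x voxels
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ X.T @ Y  # columns x voxels
    resid = Y - X @ betas
    resid_var = np.sum(resid**2, axis=0) / dof
    return GlmFit(
        betas=betas,
        resid_var=resid_var,
        dof=dof,
        columns=list(design.frame.columns),
        xtx_inv_diag=np.diag(xtx_inv).copy(),
    )


def trial_t_patterns(
    fit: GlmFit,
    design: DesignMatrix,
    voxels: Optional[np.ndarray] = None,
) -> PatternSet:
    """One t-value pattern per trial: t = beta / SE(beta) for each trial
    column, optionally restricted to a voxel index subset (an ROI)."""
    if design.trial_info is None or not design.target_columns:
        raise GlmError("trial t-patterns require a trialwise design")
    if fit.dof <= 0:
        raise GlmError("non-positive dof")
    idx = [fit.columns.index(c) for c in design.target_columns]
    se = np.sqrt(np.outer(fit.xtx_inv_diag[idx], fit.resid_var))
    t = fit.betas[idx] / se
    if voxels is not None:
        t = t[:, np.asarray(voxels)]
    meta = design.trial_info[["run", "target", "condition", "meaning", "task"]].reset_index(
        drop=True
    )
    return PatternSet(t, meta, estimate_kind="t")
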