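"""ROI-level univariate analysis: condition means, contrasts and ANOVAs.

The univariate stream averages condition beta estimates over an ROI's voxels
per participant, then asks whether ambiguity (homonym vs. unambiguous
target) and relatedness (related vs. unrelated prime) modulate activation,
and whether those effects differ across regions: region x ambiguity x
relatedness repeated-measures ANOVAs followed by paired t-tests per region.
A summary-statistics two-way ANOVA supports checks on published cell
means/SDs (e.g. stimulus relatedness ratings) without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .roi import ROIMask


class UnivariateError(ValueError):
    pass


CONDITION_TABLE_COLUMNS = ["participant", "roi", "task", "condition", "estimate"]


def roi_condition_means(
    condition_betas: Mapping[str, np.ndarray], mask: ROIMask
) -> dict[str, float]:
    """Unweighted mean over mask voxels of each condition's beta volume."""
    if mask.n_voxels == 0:
        raise UnivariateError(f"empty mask {mask.name!r}")
    out = {}
    for cond, vol in condition_betas.items():
        vol = np.asarray(vol, dtype=float)
        if vol.shape != mask.data.shape:
            raise UnivariateError(
                f"beta volume {vol.shape} not aligned to mask {mask.data.shape}"
            )
        out[cond] = float(vol[mask.data].mean())
    return out


def split_condition(table: pd.DataFrame) -> pd.DataFrame:
    """Add 'relatedness' and 'ambiguity' factor columns derived from the
    combined condition label ('related-ambiguous', ...)."""
    out = table.copy()
    parts = out["condition"].str.split("-")
    out["relatedness"] = parts.str[0]
    out["ambiguity"] = parts.str[1]
    return out


def rm_anova(
    table: pd.DataFrame,
    dv: str = "estimate",
    within: Sequence[str] = ("roi", "ambiguity", "relatedness"),
    subject: str = "participant",
) -> pd.DataFrame:
    """Classical repeated-measures ANOVA (participants as the random factor).

    Requires a complete within-participant crossing of the factors (cell
    means are taken if there are replicates). For a 2-level factor the F
    statistic equals the squared paired t on the participant-level
    difference. Returns a table with effect, F, df_num, df_den, p.
    """
    cols = [subject, *within, dv]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise UnivariateError(f"table lacks columns: {missing}")
    cells = table.groupby([subject, *within], observed=True)[dv].mean().reset_index()
    counts = cells.groupby(subject, observed=True).size()
    expected = int(np.prod([cells[f].nunique() for f in within]))
    bad = counts[counts != expected]
    if len(bad):
        missing_cells = _missing_cells(cells, subject, list(within))
        raise UnivariateError(f"incomplete within-participant crossing; missing cells: {missing_cells}")
    if np.ptp(cells[dv].to_numpy()) == 0:
        # degenerate: identical values everywhere -> no effect variance
        effects = _effect_names(list(within))
        return pd.DataFrame(
            [dict(effect=e, F=0.0, df_num=np.nan, df_den=np.nan, p=1.0) for e in effects]
        )
    res = AnovaRM(cells, depvar=dv, subject=subject, within=list(within)).fit()
    tab = res.anova_table
    return pd.DataFrame(
        {
            "effect": [i.replace(":", " x ") for i in tab.index],
            "F": tab["F Value"].to_numpy(),
            "df_num": tab["Num DF"].astype(int).to_numpy(),
            "df_den": tab["Den DF"].astype(int).to_numpy(),
            "p": tab["Pr > F"].to_numpy(),
        }
    )


def _effect_names(within: list[str]) -> list[str]:
    from itertools import combinations

    names = []
    for k in range(1, len(within) + 1):
        for combo in combinations(within, k):
            names.append(" x ".join(combo))
    return names


def _missing_cells(cells: pd.DataFrame, subject: str, within: list[str]) -> list[tuple]:
    levels = [cells[f].unique() for f in within]
    full = pd.MultiIndex.from_product([cells[subject].unique(), *levels])
    have = pd.MultiIndex.from_frame(cells[[subject, *within]])
    return list(full.difference(have))[:10]


def paired_contrast_t(
    table: pd.DataFrame,
    factor: str,
    level_a: str,
    level_b: str,
    dv: str = "estimate",
    subject: str = "participant",
) -> tuple[float, int, float]:
    """Paired t on participant-level (level_a - level_b) contrast scores.

    Returns (t, df, two-sided p) with df = n_participants - 1.
    """
    a = table[table[factor] == level_a].groupby(subject, observed=True)[dv].mean()
    b = table[table[factor] == level_b].groupby(subject, observed=True)[dv].mean()
    a, b = a.align(b, join="inner")
    if len(a) < 2:
        raise UnivariateError("paired contrast needs >= 2 participants")
    diff = a.to_numpy() - b.to_numpy()
    if np.allclose(diff, 0):
        return 0.0, len(diff) - 1, 1.0
    t, p = stats.ttest_rel(a.to_numpy(), b.to_numpy())
    return float(t), len(diff) - 1, float(p)


def anova2x2_from_summary(
    cell_means: np.ndarray,
    cell_sds: np.ndarray,
    cell_ns: np.ndarray,
    factor_names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Between-subjects 2x2 ANOVA from cell summaries (means, SDs, ns).

    Cells are a 2x2 array indexed [level of factor 1, level of factor 2].
    Uses unweighted marginal means for main effects (the Type-III-style
    hypothesis, appropriate for unbalanced cells) and the pooled within-cell
    variance as error. Returns effect, F, df_num, df_den, p.
    """
    m = np.asarray(cell_means, dtype=float).reshape(2, 2)
    s = np.asarray(cell_sds, dtype=float).reshape(2, 2)
    n = np.asarray(cell_ns, dtype=float).reshape(2, 2)
    if np.any(s <= 0):
        raise UnivariateError("cell SDs must be > 0")
    if np.any(n < 2):
        raise UnivariateError("each cell needs n >= 2")
    df_den = int(n.sum() - 4)
    mse = float(np.sum((n - 1) * s**2) / df_den)

    contrasts = {
        factor_names[0]: np.array([[0.5, 0.5], [-0.5, -0.5]]),
        factor_names[1]: np.array([[0.5, -0.5], [0.5, -0.5]]),
        f"{factor_names[0]} x {factor_names[1]}": np.array([[1.0, -1.0], [-1.0, 1.0]]),
    }
    rows = []
    for name, c in contrasts.items():
        est = float(np.sum(c * m))
        var = mse * float(np.sum(c**2 / n))
        F = est**2 / var
        p = float(stats.f.sf(F, 1, df_den))
        rows.append(dict(effect=name, F=F, df_num=1, df_den=df_den, p=p))
    return pd.DataFrame(rows)
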