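"""End-to-end orchestration: simulate -> first level -> decode -> infer.

Stages are plain functions over in-memory structures so the command-line
subcommands and :func:`run_pipeline` compose identically. Everything is
reproducible from (RunConfig, seed): all randomness flows through seeds
derived deterministically from the global seed.
"""

from __future__ import annotations

import logging
import time
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import design, glm, inference, simulate, univariate
from .decoding import DecodingConfig, decode_meanings, decode_relatedness
from .io import RunConfig

logger = logging.getLogger("lexdecode")

#: __version__ mirror kept here to avoid importing the package root.
VERSION = "0.1.0"


def _seed(config_seed: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(config_seed), *map(int, path)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_cohort(config: RunConfig) -> dict[str, Any]:
    """Generate events and per-ROI pattern sets for every participant.

    Returns {"events": {(participant, run): DataFrame},
             "patterns": {(participant, task, roi): PatternSet}}.
    """
    t0 = time.time()
    stim = design.build_stimulus_set(seed=_seed(config.seed, 0))
    trial_sets = design.build_trial_sets(stim)
    events: dict[tuple[int, int], pd.DataFrame] = {}
    patterns: dict[tuple[int, str, str], simulate.PatternSet] = {}
    for p in range(config.n_participants):
        plan = design.counterbalance(p)
        per_task: dict[tuple[str, str], list[simulate.PatternSet]] = {}
        for run_idx, (task, set_idx) in enumerate(plan):
            ev = design.schedule_run(
                trial_sets[set_idx - 1],
                task,
                config.timing,
                seed=design.run_seed(config.seed, p, run_idx),
            )
            ev = ev.assign(run=run_idx + 1)
            events[(p, run_idx + 1)] = ev
            if task not in config.tasks:
                continue
            for r, roi in enumerate(sorted(config.rois)):
                spec = config.effect_spec(roi, _seed(config.seed, 1, p, r))
                ps = _patterns_for_run(ev, spec, config, p, run_idx, r)
                per_task.setdefault((task, roi), []).append(ps)
        for (task, roi), chunks in per_task.items():
            patterns[(p, task, roi)] = simulate.concat_pattern_sets(chunks)
    logger.info("simulate: %d participants in %.1fs", config.n_participants, time.time() - t0)
    return {"events": events, "patterns": patterns}


def _patterns_for_run(
    ev: pd.DataFrame,
    spec: simulate.EffectSpec,
    config: RunConfig,
    p: int,
    run_idx: int,
    roi_idx: int,
) -> simulate.PatternSet:
    noise_seed = _seed(config.seed, 2, p, run_idx, roi_idx)
    if config.mode == "patterns":
        return simulate.simulate_pattern_set(ev, spec, seed=noise_seed)
    if config.mode == "bold":
        ts = simulate.simulate_bold(ev, spec, config.timing, seed=noise_seed)
        dm = glm.build_design_matrix(ev, config.timing, mode="trialwise")
        fit = glm.fit_glm(ts, dm)
        return glm.trial_t_patterns(fit, dm)
    raise ValueError(f"unknown simulation mode {config.mode!r}")


def decode_cohort(cohort: dict[str, Any], config: RunConfig) -> dict[str, Any]:
    """Observed accuracies and participant null sets for both classifiers."""
    t0 = time.time()
    out: dict[str, Any] = {}
    for (p, task, roi), ps in cohort["patterns"].items():
        key = f"task-{task}_roi-{roi}"
        cell = out.setdefault(key, {"relatedness": [], "meaning": []})
        rel = decode_relatedness(ps, config.decoding)
        rel_null = inference.participant_null_relatedness(
            ps, config.decoding, n_perm=config.n_perm, seed=_seed(config.seed, 3, p), participant=p
        )
        mea = decode_meanings(ps, config.decoding)
        mea_null = inference.participant_null_meanings(ps, config.decoding, participant=p)
        cell["relatedness"].append({"participant": p, "observed": rel.accuracy, "null": rel_null})
        cell["meaning"].append(
            {
                "participant": p,
                "observed": mea.accuracy,
                "per_homonym": mea.per_homonym,
                "null": mea_null,
            }
        )
    logger.info("decode: %d cells in %.1fs", len(out), time.time() - t0)
    return out


def infer_group(decoded: dict[str, Any], config: RunConfig) -> dict[str, Any]:
    """Group permutation tests per (task, ROI, classifier) + FDR per task."""
    t0 = time.time()
    results: dict[str, Any] = {}
    families: dict[str, list[tuple[str, str]]] = {}
    for key_idx, key in enumerate(sorted(decoded)):
        cell = decoded[key]
        task = key.split("_")[0].split("-", 1)[1]
        results[key] = {}
        for classifier, scheme in (("relatedness", "simple"), ("meaning", "per_item")):
            entries = cell[classifier]
            gr = inference.group_test(
                [e["observed"] for e in entries],
                [e["null"] for e in entries],
                n_iter=config.n_iter,
                seed=_seed(config.seed, 4, key_idx, 0 if classifier == "relatedness" else 1),
                scheme=scheme,
            )
            results[key][classifier] = {
                "observed": gr.observed,
                "p": gr.p,
                "n_perm": config.n_perm,
                "n_iter": config.n_iter,
                "seed": config.seed,
            }
            families.setdefault(task, []).append((key, classifier))
    for task, members in families.items():
        pvals = [results[k][c]["p"] for k, c in members]
        reject, p_adj = inference.fdr_bh(pvals, q=config.fdr_q)
        for (k, c), rj, pa in zip(members, reject, p_adj):
            results[k][c]["p_fdr"] = float(pa)
            results[k][c]["significant_fdr"] = bool(rj)
    logger.info("infer: %d cells in %.1fs", len(results), time.time() - t0)
    return results


def condition_table(cohort: dict[str, Any]) -> pd.DataFrame:
    """Participant x ROI x task x condition mean pattern amplitude table.

    The univariate estimate per cell is the mean over trials and voxels of
    the trial patterns, the pattern-level analogue of ROI-averaged condition
    betas.
    """
    rows = []
    for (p, task, roi), ps in cohort["patterns"].items():
        df = ps.metadata.assign(value=ps.patterns.mean(axis=1))
        for cond, grp in df.groupby("condition"):
            rows.append(
                dict(
                    participant=p,
                    roi=roi,
                    task=task,
                    condition=cond,
                    estimate=float(grp["value"].mean()),
                )
            )
    return pd.DataFrame(rows)


def univariate_stage(cohort: dict[str, Any], config: RunConfig) -> dict[str, Any]:
    """Per-task repeated-measures ANOVA (region x ambiguity x relatedness)."""
    table = univariate.split_condition(condition_table(cohort))
    out: dict[str, Any] = {"condition_table": table}
    for task in config.tasks:
        sub = table[table["task"] == task]
        within = ["roi", "ambiguity", "relatedness"] if sub["roi"].nunique() > 1 else ["ambiguity", "relatedness"]
        out[f"anova_{task}"] = univariate.rm_anova(sub, within=within)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Simulate -> (first level) -> decode -> group inference -> bundle."""
    cohort = simulate_cohort(config)
    decoded = decode_cohort(cohort, config)
    group = infer_group(decoded, config)
    uni = univariate_stage(cohort, config)
    bundle: dict[str, Any] = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": VERSION,
            "mode": config.mode,
            "n_participants": config.n_participants,
        },
        "decoding": {
            key: {
                clf: dict(stats)
                for clf, stats in cell.items()
            }
            for key, cell in group.items()
        },
        "observed_accuracies": {
            key: {
                clf: [e["observed"] for e in decoded[key][clf]]
                for clf in ("relatedness", "meaning")
            }
            for key in decoded
        },
        "univariate": {
            k: v.to_dict(orient="records")
            for k, v in uni.items()
            if k.startswith("anova_")
        },
    }
    return bundle
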