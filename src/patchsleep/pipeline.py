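"""End-to-end orchestration: simulate -> window -> featurize -> train -> evaluate.

Each stage is an importable function; :func:`run_pipeline` chains them and
writes plain CSV/JSON artifacts stamped with the config hash and seed, so a
rerun with the same config reproduces the same files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelSpec, RunConfig
from .evaluate import (
    compare_parameters,
    confusion_metrics,
    derive_sleep_parameters,
    f1_maximizing_threshold,
    kfold_cv,
    split_cohort,
    threshold_sweep,
)
from .features import (
    base_feature_names,
    build_feature_table,
    difference_features,
    feature_columns,
)
from .models import (
    apply_threshold,
    backward_greedy_selection,
    predict_sleep_probability,
    train_classifier,
)
from .simulate import iter_cohort_sessions
from .windows import NightRecord, assemble_windows

logger = logging.getLogger(__name__)

SLEEP_PARAMETERS = ("tst", "sol", "waso", "eff")


def with_master_seed(config: RunConfig, seed: int) -> RunConfig:
    """Derive all stage seeds from one master seed (kept below 2^31)."""
    base = int(seed) % (2**31 - 10)
    return dataclasses.replace(
        config,
        seed=base,
        simulation=dataclasses.replace(config.simulation, seed=base),
        split=dataclasses.replace(config.split, seed=base + 1),
        models=tuple(
            dataclasses.replace(m, seed=base + 2 + i) for i, m in enumerate(config.models)
        ),
    )


def process_cohort(config: RunConfig) -> list[tuple[str, NightRecord]]:
    """Simulate every participant-night and assemble its windows."""
    nights = []
    for group, session in iter_cohort_sessions(config.simulation):
        nights.append((group, assemble_windows(session, config.filters)))
    return nights


def windows_frame(nights: list[tuple[str, NightRecord]]) -> pd.DataFrame:
    rows = []
    for group, night in nights:
        for w in night.windows:
            rows.append(
                {
                    "participant": night.participant,
                    "group": group,
                    "night": night.night,
                    "window_index": w.index,
                    "start_s": w.start_time,
                    "n_acc_blocks": len(w.acc_blocks),
                    "has_ecg": w.ecg_block is not None,
                    "wake_epochs": w.wake_epoch_count,
                    "label": w.psg_label,
                    "valid": w.valid,
                }
            )
    return pd.DataFrame(rows)


def featurize(nights: list[tuple[str, NightRecord]], config: RunConfig) -> pd.DataFrame:
    """Base feature table over valid windows of usable nights."""
    return build_feature_table(nights, extended=config.extended_catalog)


def select_features(table: pd.DataFrame, train_ids: list[str], config: RunConfig):
    """Optional backwards greedy selection on the training participants only."""
    base = base_feature_names(config.extended_catalog)
    if not config.run_selection:
        return base, None
    train_table = table[table["participant"].isin(train_ids)]
    trace = backward_greedy_selection(
        train_table, base, seed=config.seed
    )
    logger.info(
        "selection kept %d/%d features", len(trace.final_subset), len(base)
    )
    return list(trace.final_subset), trace


def night_sleep_parameters(
    preds: pd.DataFrame, tau: float, onset_rule: str = "first"
) -> pd.DataFrame:
    """Device and PSG sleep parameters per night from thresholded predictions."""
    rows = []
    for (pid, night), g in preds.groupby(["participant", "night"]):
        g = g.sort_values("window_index")
        device = derive_sleep_parameters(
            apply_threshold(g["p_sleep"].to_numpy(), tau), onset_rule=onset_rule
        )
        psg = derive_sleep_parameters(g["label"].to_numpy(), onset_rule=onset_rule)
        rows.append(
            {
                "participant": pid,
                "night": night,
                "n_windows": len(g),
                **{f"device_{k}": getattr(device, k) for k in SLEEP_PARAMETERS},
                **{f"psg_{k}": getattr(psg, k) for k in SLEEP_PARAMETERS},
            }
        )
    return pd.DataFrame(rows)


def parameter_comparison_frame(params: pd.DataFrame) -> pd.DataFrame:
    """Bias/t/p/g/R² rows for TST, SOL, WASO and Eff across nights.

    Nights where either side lacks a sleep onset are dropped from the SOL and
    WASO rows (logged), since those parameters are undefined there.
    """
    rows = []
    for name in SLEEP_PARAMETERS:
        sub = params[[f"device_{name}", f"psg_{name}"]].dropna()
        dropped = len(params) - len(sub)
        if dropped and name in ("sol", "waso"):
            logger.info("%s: excluded %d night(s) without sleep onset", name, dropped)
        if len(sub) < 3:
            continue
        c = compare_parameters(
            sub[f"device_{name}"].to_numpy(), sub[f"psg_{name}"].to_numpy(), name
        )
        rows.append(dataclasses.asdict(c))
    return pd.DataFrame(rows)


def evaluate_model(
    spec: ModelSpec,
    table: pd.DataFrame,
    feature_cols: list[str],
    train_ids: list[str],
    test_ids: list[str],
    tau_grid: list[float],
    onset_rule: str = "first",
) -> dict:
    """Train one back-end and evaluate it on the held-out participants."""
    train_table = table[table["participant"].isin(train_ids)]
    test_table = table[table["participant"].isin(test_ids)]
    model = train_classifier(spec, train_table, feature_cols)
    preds = predict_sleep_probability(model, test_table)
    p = preds["p_sleep"].to_numpy()
    y = preds["label"].to_numpy()
    sweep = threshold_sweep(p, y, tau_grid)
    tau_star = f1_maximizing_threshold(p, y, tau_grid)
    metrics_at = {
        "0.5": confusion_metrics(apply_threshold(p, 0.5), y, p).as_dict(),
        "tau_star": confusion_metrics(apply_threshold(p, tau_star), y, p).as_dict(),
    }
    params = night_sleep_parameters(preds, tau_star, onset_rule)
    comparison = parameter_comparison_frame(params)
    return {
        "model": model,
        "predictions": preds,
        "sweep": sweep,
        "tau_star": tau_star,
        "metrics": metrics_at,
        "sleep_params": params,
        "comparison": comparison,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    logger.info("stage simulate+window: %d participants", config.simulation.n_participants)
    nights = process_cohort(config)
    wframe = windows_frame(nights)
    wframe.to_csv(out / "windows.csv", index=False)
    n_windows = len(wframe)
    n_valid = int(wframe["valid"].sum())
    sleep_frac = float((wframe.loc[wframe["valid"], "label"] == "sleep").mean())
    logger.info(
        "windows: %d total, %d valid (%.1f%%), %.1f%% of valid labeled sleep",
        n_windows, n_valid, 100 * n_valid / max(n_windows, 1), 100 * sleep_frac,
    )

    table = featurize(nights, config)
    participants = sorted(table["participant"].unique())
    train_ids, test_ids = split_cohort(participants, config.split)

    selected, trace = select_features(table, train_ids, config)
    table = difference_features(table, selected)
    # model inputs: the selected base features plus their lag differences
    diff_names = {f"{b}_d{k}" for b in selected for k in range(1, 6)}
    cols = [c for c in table.columns if c in selected or c in diff_names]
    table[["participant", "group", "night", "window_index", "label"] + cols].to_csv(
        out / "features.csv", index=False
    )

    report = {
        **stamp,
        "counts": {
            "participants": len(participants),
            "train_participants": len(train_ids),
            "test_participants": len(test_ids),
            "windows": n_windows,
            "valid_windows": n_valid,
            "sleep_fraction_valid": sleep_frac,
        },
        "selected_features": list(selected),
        "models": {},
    }
    if trace is not None:
        report["selection_trace"] = {
            "initial_score": trace.initial_score,
            "rounds": [list(r) for r in trace.rounds],
        }

    tau_grid = list(config.tau_grid)
    for spec in config.models:
        logger.info("stage train+evaluate: %s", spec.kind)
        result = evaluate_model(
            spec, table, cols, train_ids, test_ids, tau_grid, config.onset_rule
        )
        result["predictions"].to_csv(out / f"predictions_{spec.kind}.csv", index=False)
        result["sweep"].to_csv(out / f"sweep_{spec.kind}.csv", index=False)
        result["sleep_params"].to_csv(out / f"sleep_params_{spec.kind}.csv", index=False)
        result["comparison"].to_csv(out / f"comparison_{spec.kind}.csv", index=False)
        # model artifact schema: enough to validate any future prediction input
        (out / f"model_{spec.kind}.json").write_text(
            json.dumps(
                {
                    "kind": spec.kind,
                    "seed": spec.seed,
                    "threshold": spec.threshold,
                    "hyperparameters": dict(spec.hyperparameters),
                    "feature_names": result["model"].feature_names,
                    "training": result["model"].metadata,
                },
                indent=2,
                sort_keys=True,
            )
        )
        report["models"][spec.kind] = {
            "tau_star": result["tau_star"],
            "metrics": result["metrics"],
        }

    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def cohort_cv(config: RunConfig, k: int = 10) -> dict:
    """10-fold participant-level CV of the first configured model."""
    nights = process_cohort(config)
    table = featurize(nights, config)
    selected = base_feature_names(config.extended_catalog)
    table = difference_features(table, selected)
    cols = feature_columns(table)
    report = kfold_cv(table, cols, config.models[0], k=k, seed=config.seed)
    return {"summary": report.summary, "folds": [f.as_dict() for f in report.folds]}
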