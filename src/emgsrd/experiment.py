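"""Config-driven orchestration of the full SRD experiment grid.

Runs scenario x SRD x feature-set x classifier over a synthetic dataset,
collects per-cell scores in a tidy table, and summarizes mean accuracies and
Friedman statistics per (scenario, feature set, classifier). Cells already
written to ``output_dir/cells`` are reused on re-runs unless forced, so a
partially completed grid resumes where it stopped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .decode import ClassifierSpec, default_spec
from .evaluate import ExperimentResult, between_srd_eval, friedman_test, within_srd_eval
from .features import FeatureParams
from .preprocess import SRD_LENGTHS_S, SRDGroup, SegmentationParams, bandpass_notch
from .simulate import SimConfig, generate_dataset

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "scenario",
    "feature_set",
    "classifier",
    "srd_train_s",
    "srd_test_s",
    "subject_id",
    "ca",
    "mcc_macro",
    "n_test",
]


@dataclass
class ExperimentConfig:
    """Full experiment description; every field mirrors a config-file key."""

    sim: SimConfig = field(default_factory=SimConfig)
    srd_groups_s: tuple[float, ...] = SRD_LENGTHS_S
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    feature_sets: tuple[str, ...] = ("NTDF", "TD4", "RMS")
    classifiers: tuple[ClassifierSpec, ...] = ()
    scenario: str = "both"  # "within" | "between" | "both"
    strict_between: bool = False
    notch_hz: float = 50.0
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classifiers:
            self.classifiers = tuple(
                default_spec(kind, seed=self.seed) for kind in ("LDA", "KNN", "RF")
            )
        if self.scenario not in ("within", "between", "both"):
            raise ValueError("scenario must be 'within', 'between' or 'both'")
        if not self.feature_sets or not self.srd_groups_s:
            raise ValueError("feature_sets and srd_groups_s must be non-empty")
        if max(self.srd_groups_s) > self.sim.duration_s:
            raise ValueError("SRD group longer than simulated recordings")

    @property
    def scenarios(self) -> tuple[str, ...]:
        return ("within", "between") if self.scenario == "both" else (self.scenario,)

    @staticmethod
    def from_dict(d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "sim" in d:
            sim = dict(d["sim"])
            if "band" in sim:
                sim["band"] = tuple(sim["band"])
            d["sim"] = SimConfig(**sim)
        if "seg" in d:
            d["seg"] = SegmentationParams(**d["seg"])
        if "feature_params" in d:
            d["feature_params"] = FeatureParams(**d["feature_params"])
        if "classifiers" in d:
            d["classifiers"] = tuple(
                ClassifierSpec(**c) if isinstance(c, dict) else c for c in d["classifiers"]
            )
        if "srd_groups_s" in d:
            d["srd_groups_s"] = tuple(float(s) for s in d["srd_groups_s"])
        if "feature_sets" in d:
            d["feature_sets"] = tuple(d["feature_sets"])
        return ExperimentConfig(**d)

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        return ExperimentConfig.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["band"] = list(d["sim"]["band"])
        return d


def test_profile_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Quick desk-scale profile: 2 subjects at 1000 Hz, 50-tree forests."""
    sim = SimConfig(n_subjects=2, fs=1000.0, seed=seed)
    classifiers = (
        default_spec("LDA"),
        default_spec("KNN"),
        ClassifierSpec(kind="RF", hyperparams={"n_trees": 50, "seed": seed}),
    )
    return ExperimentConfig(sim=sim, classifiers=classifiers, seed=seed, **overrides)


def paper_profile_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Full-scale profile: 8 subjects at 4000 Hz with default classifiers."""
    return ExperimentConfig(sim=SimConfig(n_subjects=8, seed=seed), seed=seed, **overrides)


def _results_to_frame(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    rows = [
        {
            "scenario": r.scenario,
            "feature_set": r.feature_set,
            "classifier": r.classifier,
            "srd_train_s": r.srd_train_s,
            "srd_test_s": r.srd_test_s,
            "subject_id": r.subject_id,
            "ca": r.ca,
            "mcc_macro": r.mcc_macro,
            "n_test": r.n_test,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _cell_path(out: Path, scenario: str, feature: str, clf: str, srd: float) -> Path:
    return out / "cells" / f"{scenario}_{feature}_{clf}_srd{srd:g}.csv"


def run_experiment(
    config: ExperimentConfig, force: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Run the configured grid; returns (tidy results table, summary dict).

    A cell is one (scenario, feature set, classifier, srd_train) slice; its
    rows cover subjects (and srd_test for the between scenario). If
    ``config.output_dir`` is set, cells persist as CSV and completed cells
    are skipped on re-runs unless ``force``. A failing cell is logged and
    recorded as missing rather than aborting the grid.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        (out / "cells").mkdir(parents=True, exist_ok=True)

    dataset = [
        bandpass_notch(
            r, low_hz=config.sim.band[0], high_hz=config.sim.band[1], notch_hz=config.notch_hz
        )
        for r in generate_dataset(config.sim)
    ]

    frames: list[pd.DataFrame] = []
    missing: list[dict] = []
    for scenario in config.scenarios:
        for feature in config.feature_sets:
            for spec in config.classifiers:
                for srd_s in config.srd_groups_s:
                    cell = (scenario, feature, spec.kind, srd_s)
                    path = _cell_path(out, *cell) if out else None
                    if path and path.exists() and not force:
                        frames.append(pd.read_csv(path))
                        continue
                    t0 = time.perf_counter()
                    try:
                        if scenario == "within":
                            results = within_srd_eval(
                                dataset, SRDGroup(srd_s), feature, spec,
                                config.seg, config.feature_params,
                            )
                        else:
                            results = between_srd_eval(
                                dataset, SRDGroup(srd_s), feature, spec,
                                config.seg, config.feature_params,
                                srd_tests=[SRDGroup(s) for s in config.srd_groups_s],
                                strict=config.strict_between,
                            )
                    except Exception:
                        logger.exception("cell %s failed", cell)
                        missing.append(
                            {"scenario": scenario, "feature_set": feature,
                             "classifier": spec.kind, "srd_train_s": srd_s}
                        )
                        continue
                    frame = _results_to_frame(results)
                    logger.info("cell %s: %d rows in %.2f s", cell, len(frame),
                                time.perf_counter() - t0)
                    if path:
                        frame.to_csv(path, index=False)
                    frames.append(frame)

    results_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=RESULT_COLUMNS)
    )
    results_df = results_df.sort_values(RESULT_COLUMNS[:6], kind="mergesort").reset_index(
        drop=True
    )
    summary = summarize(results_df, missing=missing)
    if out:
        results_df.to_csv(out / "results.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    return results_df, summary


def summarize(results_df: pd.DataFrame, missing: Sequence[dict] = ()) -> dict:
    """Per-(scenario, feature, classifier) mean CA/MCC by training SRD plus
    a Friedman comparison of SRD groups across subjects."""
    summary: dict = {"missing_cells": list(missing), "scenarios": {}}
    if results_df.empty:
        return summary
    for (scenario, feature, clf), grp in results_df.groupby(
        ["scenario", "feature_set", "classifier"]
    ):
        # per (subject, srd_train): mean over srd_test (identity for within)
        per_subj = (
            grp.groupby(["subject_id", "srd_train_s"])[["ca", "mcc_macro"]]
            .mean()
            .reset_index()
        )
        table = per_subj.pivot(index="subject_id", columns="srd_train_s", values="ca")
        entry = {
            "mean_ca_by_srd_train": {
                f"{k:g}": float(v) for k, v in per_subj.groupby("srd_train_s")["ca"].mean().items()
            },
            "mean_mcc_by_srd_train": {
                f"{k:g}": float(v)
                for k, v in per_subj.groupby("srd_train_s")["mcc_macro"].mean().items()
            },
        }
        if table.shape[0] >= 2 and table.shape[1] >= 2 and not table.isna().any().any():
            stat, p = friedman_test(table.to_numpy())
            entry["friedman"] = {"statistic": stat, "p_value": p}
        summary["scenarios"].setdefault(scenario, {}).setdefault(feature, {})[clf] = entry
    return summary
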