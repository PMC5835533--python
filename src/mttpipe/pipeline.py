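"""End-to-end orchestration: simulate -> preprocess -> features ->
classification (+ cluster tests, subset power analysis) for each
hemisphere x task cell, with a consolidated, fully seeded report.

The space task is simulated as a second two-condition block whose effects
default to zero, reproducing the qualitative scenario of a time-task
separation in one hemisphere and null results elsewhere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess
from .classify import ElectrodeClassifier
from .cluster import cluster_test
from .containers import CONDITION_PAIRS
from .features import EARLY_WINDOW, LATE_WINDOW, features_for_dataset
from .io import write_epochs, write_evoked
from .subsets import subset_analysis
from .synthetic import GeneratorConfig, generate_dataset

__all__ = ["RunConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    time_generator: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(task="time"))
    space_generator: GeneratorConfig = field(
        default_factory=lambda: GeneratorConfig(task="space", early_effect=0.0, late_effect=0.0)
    )
    low_hz: float = 1.0
    high_hz: float = 120.0
    reject_z: float = 6.0
    baseline: bool = False
    early_window: tuple[float, float] = EARLY_WINDOW
    late_window: tuple[float, float] = LATE_WINDOW
    abs_auc: bool = False
    fold_safe_scaling: bool = False
    cluster_n_perm: int = 1000
    run_cluster_tests: bool = True
    run_subsets: bool = False
    n_hipp_subset: int = 5
    n_ltc_subset: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        # JSON-canonical form (tuples become lists) so the in-memory echo
        # compares equal to what round-trips through report files
        return json.loads(json.dumps(dataclasses.asdict(self)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("time_generator", "space_generator"):
            if key in d and isinstance(d[key], dict):
                g = dict(d[key])
                for tup in ("epoch_window", "effect_window_early", "effect_window_late"):
                    if tup in g:
                        g[tup] = tuple(g[tup])
                if "component_spec" in g:
                    g["component_spec"] = tuple(tuple(c) for c in g["component_spec"])
                d[key] = GeneratorConfig(**g)
        for tup in ("early_window", "late_window"):
            if tup in d:
                d[tup] = tuple(d[tup])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def _process_task(config: RunConfig, task: str) -> dict:
    gen = config.time_generator if task == "time" else config.space_generator
    gen = dataclasses.replace(gen, task=task, seed=int(gen.seed + config.seed))
    epochs, meta = _stage("simulate")(generate_dataset, gen)
    epochs = _stage("bandpass")(preprocess.bandpass, epochs, config.low_hz, config.high_hz)
    epochs = _stage("reject")(preprocess.reject_epochs, epochs, config.reject_z)
    if config.baseline:
        epochs = _stage("baseline")(preprocess.baseline_correct, epochs)
    evoked = _stage("average")(preprocess.average_evoked, epochs)
    features = _stage("features")(
        features_for_dataset, evoked, meta, config.early_window, config.late_window, config.abs_auc
    )
    return {"epochs": epochs, "meta": meta, "evoked": evoked, "features": features, "gen": gen}


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis grid; deterministic given ``config.seed``.

    Returns a report dict with one classification cell per
    hemisphere x task, the feature tables, per-electrode cluster-test
    summaries and (optionally) the subset power analysis. When ``out_dir``
    is given the report, feature tables and raw/evoked data are written
    there.
    """
    report: dict = {"config": config.to_dict(), "classification": {}, "cluster": {}, "features": {}}
    artifacts: dict = {}
    for task in ("time", "space"):
        stage = _process_task(config, task)
        artifacts[task] = stage
        report["features"][task] = stage["features"].to_dict(orient="records")
        cond_a, cond_b = CONDITION_PAIRS[task]
        for hemisphere in ("L", "R"):
            cell = f"{hemisphere}_{task}"
            try:
                model = ElectrodeClassifier(
                    stage["features"],
                    hemisphere=hemisphere,
                    task=task,
                    fold_safe_scaling=config.fold_safe_scaling,
                )
                res = model.fit(seed=config.seed)
                report["classification"][cell] = res.to_dict()
            except ValueError as exc:
                report["classification"][cell] = {"error": str(exc)}
        if config.run_cluster_tests:
            rows = []
            for k, eid in enumerate(stage["epochs"].electrode_ids):
                res = _stage("cluster_test")(
                    cluster_test,
                    stage["epochs"],
                    eid,
                    cond_a,
                    cond_b,
                    n_perm=config.cluster_n_perm,
                    seed=int((config.seed * 1009 + k) % (2**31 - 1)),
                )
                rows.append(res.to_dict())
            report["cluster"][task] = rows

    if config.run_subsets:
        stage = artifacts["time"]
        sub = _stage("subsets")(
            subset_analysis,
            stage["features"],
            stage["meta"],
            config.n_hipp_subset,
            config.n_ltc_subset,
            "L",
            "time",
        )
        report["subsets"] = {
            "n_subsets": sub.n_subsets,
            "frac_accuracy_above": sub.frac_accuracy_above,
            "frac_significant": sub.frac_significant,
            "per_subset": sub.per_subset.to_dict(orient="records"),
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        for task, stage in artifacts.items():
            write_epochs(stage["epochs"], stage["meta"], out / f"epochs_{task}")
            write_evoked(stage["evoked"], stage["meta"], out / f"evoked_{task}")
            stage["features"].to_csv(out / f"features_{task}.tsv", sep="\t", index=False)
    return report
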