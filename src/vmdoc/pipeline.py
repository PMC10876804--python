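"""End-to-end experiment orchestration.

One configured run goes: cohort (synthetic or loaded) -> preprocessing ->
feature extraction under up to three signal representations -> Kruskal-Wallis
feature selection -> cross-validated evaluation of up to four classifiers on
the full and the selected feature sets, for the binary (UWS vs MCS) and
3-class tasks -> comparison tables of relative and absolute accuracy
improvements.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as vio
from .classify import (CLASSIFIER_KINDS, ClassifierSpec, EvalReport,
                       absolute_improvement, relative_improvement, run_cv)
from .features import FeatureSpec, FeatureTable, extract_features
from .preprocess import (BROADBAND, CHANNELS_17, DEFAULT_BANDS, Recording,
                         preprocess_recording)
from .stats import SelectionResult, kw_mask, select_features
from .synth import CohortSpec, generate_cohort
from .vmd import VMDConfig

__all__ = ["ExperimentConfig", "run_experiment", "compute_improvements",
           "load_reference_accuracies", "load_reference_improvements"]

log = logging.getLogger("vmdoc")

TASKS = {"binary": ("UWS", "MCS"), "multiclass": ("coma", "UWS", "MCS")}


@dataclass
class ExperimentConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    data_dir: Optional[str] = None          # overrides the synthetic cohort
    data_format: str = "csv"
    approaches: Sequence[str] = ("raw", "bands", "vmd")
    tasks: Sequence[str] = ("binary", "multiclass")
    classifiers: Sequence[str] = CLASSIFIER_KINDS
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    vmd_config: VMDConfig = field(default_factory=VMDConfig)
    alpha: float = 0.05
    folds: int = 10
    seed: int = 0
    selection_in_folds: bool = False
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.approaches or not self.classifiers or not self.tasks:
            raise ValueError("need at least one approach, classifier and task")

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["approaches"] = list(self.approaches)
        d["tasks"] = list(self.tasks)
        d["classifiers"] = list(self.classifiers)
        d["cohort"]["channels"] = list(self.cohort.channels)
        d["cohort"]["bands"] = [[b.name, b.low_hz, b.high_hz] for b in self.cohort.bands]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name: str, t0: float, **info) -> None:
    detail = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s elapsed=%.1fs %s", name, time.time() - t0, detail)


def run_experiment(config: Optional[ExperimentConfig] = None) -> Dict:
    """Run the configured experiment; returns (and optionally writes) a bundle.

    The bundle maps ``reports[task][approach][feature_set][classifier]`` to
    an :class:`~vmdoc.classify.EvalReport`, plus ``selection[task][approach]``
    (:class:`~vmdoc.stats.SelectionResult`), an accuracy table and the
    improvement comparison table.  Fully deterministic for a fixed config.
    """
    if config is None:
        config = ExperimentConfig()
    t0 = time.time()

    if config.data_dir is not None:
        cohort = vio.read_recordings(config.data_dir, fmt=config.data_format)
    else:
        cohort = generate_cohort(config.cohort)
    _stage("cohort", t0, n=len(cohort),
           shape=f"{cohort[0].n_channels}x{cohort[0].n_samples}")

    cohort = [preprocess_recording(rec) for rec in cohort]
    _stage("preprocess", t0, broadband=BROADBAND)

    tables: Dict[str, FeatureTable] = {}
    for approach in config.approaches:
        tables[approach] = extract_features(
            cohort, approach=approach, spec=config.feature_spec,
            vmd_config=config.vmd_config, bands=list(config.cohort.bands))
        _stage("features", t0, approach=approach,
               n_features=tables[approach].n_features)

    reports: Dict[str, Dict[str, Dict[str, Dict[str, EvalReport]]]] = {}
    selection: Dict[str, Dict[str, SelectionResult]] = {}
    acc_rows = []
    for task in config.tasks:
        reports[task] = {}
        selection[task] = {}
        for approach in config.approaches:
            table = tables[approach].subset_classes(TASKS[task])
            sel = select_features(table, alpha=config.alpha)
            selection[task][approach] = sel
            variants: Dict[str, object] = {"all": (table, None)}
            if config.selection_in_folds:
                variants["selected"] = (
                    table, lambda x, y, a=config.alpha: kw_mask(x, y, a))
            else:
                variants["selected"] = (table.select_columns(sel.selected)
                                        if sel.n_selected else table, None)
            reports[task][approach] = {}
            for feat_set, (tbl, selector) in variants.items():
                reports[task][approach][feat_set] = {}
                for kind in config.classifiers:
                    spec = ClassifierSpec(kind=kind, random_seed=config.seed)
                    rep = run_cv(tbl, spec, k_folds=config.folds,
                                 seed=config.seed, feature_selector=selector)
                    reports[task][approach][feat_set][kind] = rep
                    acc_rows.append({"task": task, "approach": approach,
                                     "features": feat_set, "classifier": kind,
                                     "accuracy": rep.accuracy,
                                     "precision": rep.precision,
                                     "recall": rep.recall, "f1": rep.f1})
            _stage("evaluate", t0, task=task, approach=approach,
                   n_selected=sel.n_selected)

    accuracies = pd.DataFrame(acc_rows)
    improvements = compute_improvements(accuracies)
    bundle = {"config": config.to_dict(), "config_hash": config.config_hash(),
              "reports": reports, "selection": selection,
              "accuracies": accuracies, "improvements": improvements}
    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def compute_improvements(accuracies: pd.DataFrame) -> pd.DataFrame:
    """Accuracy-comparison table from a long-format accuracy table.

    For every task and classifier present: the relative improvement of the
    VMD representation over the band and raw representations (separately for
    the all-features and selected-features runs), and the absolute
    improvement of selection within the VMD representation.  Values are
    rounded to one decimal, matching report conventions.
    """
    def acc(task, approach, features, clf):
        m = accuracies[(accuracies.task == task) & (accuracies.approach == approach)
                       & (accuracies.features == features)
                       & (accuracies.classifier == clf)]
        return float(m.accuracy.iloc[0]) if len(m) else None

    rows = []
    for task in accuracies.task.unique():
        for clf in accuracies.classifier.unique():
            for feat, tag in (("all", "rel_all"), ("selected", "rel_sel")):
                v = acc(task, "vmd", feat, clf)
                for ref_ap in ("bands", "raw"):
                    r = acc(task, ref_ap, feat, clf)
                    if v is not None and r is not None and r > 0:
                        rows.append({"comparison": f"{tag}_vs_{ref_ap}",
                                     "task": task, "classifier": clf,
                                     "value": round(relative_improvement(v, r), 1)})
            v_all = acc(task, "vmd", "all", clf)
            v_sel = acc(task, "vmd", "selected", clf)
            if v_all is not None and v_sel is not None:
                rows.append({"comparison": "abs_sel_vs_all", "task": task,
                             "classifier": clf,
                             "value": round(absolute_improvement(v_sel, v_all), 1)})
    return pd.DataFrame(rows)


def _write_bundle(bundle: Dict, config: ExperimentConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = bundle["config_hash"]
    bundle["accuracies"].assign(config_hash=h).to_csv(out / "accuracies.csv", index=False)
    bundle["improvements"].assign(config_hash=h).to_csv(out / "improvements.csv", index=False)
    for task, per_ap in bundle["selection"].items():
        for approach, sel in per_ap.items():
            sel.to_csv(out / f"selection_{task}_{approach}.csv")
    summary = {"config": bundle["config"], "config_hash": h,
               "reports": {t: {a: {f: {c: r.as_dict() for c, r in per_c.items()}
                                   for f, per_c in per_f.items()}
                               for a, per_f in per_a.items()}
                           for t, per_a in bundle["reports"].items()}}
    vio.write_json(summary, out / "summary.json")


def load_reference_accuracies() -> pd.DataFrame:
    """Published accuracy tables (transcribed reference values) for the
    comparison arithmetic; never pipeline output."""
    with resources.files("vmdoc.data").joinpath("reference_accuracies.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_improvements() -> pd.DataFrame:
    """Published improvement figures matching :func:`load_reference_accuracies`."""
    with resources.files("vmdoc.data").joinpath("reference_improvements.csv").open() as fh:
        return pd.read_csv(fh)
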