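"""Canned study protocols: the full comparison run and calibration checks.

These drivers reproduce the package's headline analyses at desk scale on the
synthetic cohort: the three-representation comparison under the full
protocol (features -> Kruskal-Wallis selection -> cross-validated ensemble
bagged trees), the null calibration of the feature screen, and chance-level
checks of the classifiers.  Both the test suite and the acceptance script
run these.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np

from .classify import CLASSIFIER_KINDS, ClassifierSpec, run_cv
from .features import FeatureSpec, FeatureTable, extract_features
from .preprocess import preprocess_recording
from .stats import select_features
from .synth import CohortSpec, generate_cohort

__all__ = ["run_protocol", "null_selection_rate", "chance_level_accuracies",
           "sampen_class_means"]


def _feature_tables(spec: CohortSpec, window_s: float,
                    approaches: Sequence[str]) -> Dict[str, FeatureTable]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cohort = [preprocess_recording(r) for r in generate_cohort(spec)]
        fspec = FeatureSpec(analysis_window_s=window_s)
        return {ap: extract_features(cohort, ap, spec=fspec) for ap in approaches}


def sampen_class_means(table: FeatureTable) -> Dict[str, float]:
    """Mean raw-channel sample entropy per class (channel-averaged)."""
    cols = [j for j, n in enumerate(table.feature_names) if n.endswith("sampen")]
    labels = np.asarray(table.labels)
    return {lab: float(table.values[np.ix_(labels == lab, cols)].mean())
            for lab in sorted(set(table.labels))}


def run_protocol(seed: int = 0, n_per_class: int = 15, duration_s: float = 60.0,
                 window_s: float = 10.0, effect_size: float = 1.0,
                 approaches: Sequence[str] = ("raw", "bands", "vmd"),
                 classifier: str = "ensemble_bagged_tree",
                 alpha: float = 0.05) -> Dict:
    """Full protocol on one synthetic cohort; 3-class task.

    Returns per-approach selected-feature EBT accuracies, selection counts,
    the raw-channel sample-entropy class means, and the Spearman |rho|
    distribution of the selected VMD features against CRS-R.
    """
    spec = CohortSpec(n_per_class=n_per_class, duration_s=duration_s,
                      effect_size=effect_size, seed=seed)
    tables = _feature_tables(spec, window_s, approaches)
    out: Dict = {"seed": seed, "accuracy": {}, "accuracy_all": {},
                 "n_selected": {}, "n_features": {}}
    out["sampen_means"] = sampen_class_means(tables[approaches[0]]
                                             if "raw" not in tables
                                             else tables["raw"])
    for ap in approaches:
        tab = tables[ap]
        sel = select_features(tab, alpha=alpha)
        cspec = ClassifierSpec(kind=classifier, random_seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rep_all = run_cv(tab, cspec, seed=seed)
            tab_sel = tab.select_columns(sel.selected) if sel.n_selected else tab
            rep_sel = run_cv(tab_sel, cspec, seed=seed)
        out["accuracy"][ap] = rep_sel.accuracy
        out["accuracy_all"][ap] = rep_all.accuracy
        out["n_selected"][ap] = sel.n_selected
        out["n_features"][ap] = tab.n_features
        if ap == "vmd":
            rhos = np.array([abs(v) for v in sel.rho_crsr.values()])
            out["vmd_rho_abs"] = rhos
            out["vmd_rho_in_band"] = float(((rhos >= 0.2) & (rhos <= 0.5)).mean()) \
                if rhos.size else float("nan")
    return out


def null_selection_rate(seed: int = 0, n_replicates: int = 3,
                        n_per_class: int = 15, duration_s: float = 6.0,
                        window_s: float = 4.0, alpha: float = 0.05) -> Dict:
    """Type-I calibration of the Kruskal-Wallis screen on null cohorts.

    Generates ``n_replicates`` cohorts with ``effect_size = 0`` (classes
    exchangeable by construction) and pools the selection outcomes of all
    three representations' feature columns.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)
    n_sel = 0
    n_tot = 0
    for s in seeds:
        spec = CohortSpec(n_per_class=n_per_class, duration_s=duration_s,
                          effect_size=0.0, seed=int(s))
        tables = _feature_tables(spec, window_s, ("raw", "bands", "vmd"))
        for tab in tables.values():
            sel = select_features(tab, alpha=alpha)
            n_sel += sel.n_selected
            n_tot += tab.n_features
    rate = n_sel / n_tot
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_tot)
    return {"rate": rate, "n_columns": n_tot, "n_selected": n_sel,
            "interval": (alpha - half, alpha + half),
            "within_interval": bool(alpha - half <= rate <= alpha + half)}


def chance_level_accuracies(seed: int = 0, n_per_class: int = 15,
                            n_features: int = 40) -> Dict[str, float]:
    """Accuracy of every classifier on label-permuted noise features (3-class).

    The features are pure noise and the labels are permuted, so every
    classifier should sit at the 33.3% chance level (up to binomial noise).
    """
    rng = np.random.default_rng(seed)
    n = 3 * n_per_class
    labels = ["coma"] * n_per_class + ["UWS"] * n_per_class + ["MCS"] * n_per_class
    labels = list(rng.permutation(labels))
    table = FeatureTable(values=rng.standard_normal((n, n_features)),
                         feature_names=[f"f{i}" for i in range(n_features)],
                         labels=labels,
                         subject_ids=[f"s{i}" for i in range(n)])
    out = {}
    for kind in CLASSIFIER_KINDS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rep = run_cv(table, ClassifierSpec(kind=kind, random_seed=seed), seed=seed)
        out[kind] = rep.accuracy
    return out
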