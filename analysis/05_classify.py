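#!/usr/bin/env python
"""Cross-validated evaluation grid: task x approach x feature set x classifier.

Evaluates KNN, linear SVM, decision tree and ensemble bagged trees with
stratified 10-fold CV on each feature table, with and without the
Kruskal-Wallis-selected subset, and writes the long-format accuracy table
to results/accuracies.csv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

from vmdoc.classify import CLASSIFIER_KINDS, ClassifierSpec, run_cv
from vmdoc.features import FeatureTable
from vmdoc.stats import select_features

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

TASKS = {"multiclass": ("coma", "UWS", "MCS"), "binary": ("UWS", "MCS")}

rows = []
for approach in ("raw", "bands", "vmd"):
    table = FeatureTable.from_csv(RESULTS / f"features_{approach}.csv")
    for task, classes in TASKS.items():
        sub = table.subset_classes(classes)
        sel = select_features(sub, alpha=0.05)
        variants = {"all": sub,
                    "selected": sub.select_columns(sel.selected) if sel.n_selected else sub}
        for feat_set, tbl in variants.items():
            for kind in CLASSIFIER_KINDS:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    rep = run_cv(tbl, ClassifierSpec(kind=kind, random_seed=SEED),
                                 seed=SEED)
                rows.append({"task": task, "approach": approach,
                             "features": feat_set, "classifier": kind,
                             "accuracy": round(rep.accuracy, 1),
                             "precision": round(rep.precision, 1),
                             "recall": round(rep.recall, 1),
                             "f1": round(rep.f1, 1)})

acc = pd.DataFrame(rows)
acc.to_csv(RESULTS / "accuracies.csv", index=False)
ebt = acc[(acc.classifier == "ensemble_bagged_tree") & (acc.features == "selected")
          & (acc.task == "multiclass")]
print(acc.to_string(index=False))
print("\n3-class EBT with selected features:")
print(ebt[["approach", "accuracy"]].to_string(index=False))
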