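#!/usr/bin/env python
"""Kruskal-Wallis screening of every feature table, per task.

For the 3-class task (coma/UWS/MCS) and the binary task (UWS/MCS), screens
each feature at p < 0.05, attaches Dunn's pairwise p-values (3-class) and
Spearman correlations with CRS-R/GCS, and writes
results/selection_{task}_{approach}.csv.
"""

from pathlib import Path

from vmdoc.features import FeatureTable
from vmdoc.stats import select_features

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

TASKS = {"multiclass": ("coma", "UWS", "MCS"), "binary": ("UWS", "MCS")}

for approach in ("raw", "bands", "vmd"):
    table = FeatureTable.from_csv(RESULTS / f"features_{approach}.csv")
    for task, classes in TASKS.items():
        sub = table.subset_classes(classes)
        res = select_features(sub, alpha=0.05)
        out = RESULTS / f"selection_{task}_{approach}.csv"
        res.to_csv(out)
        rhos = [abs(v) for v in res.rho_crsr.values()]
        in_band = sum(0.2 <= r <= 0.5 for r in rhos)
        print(f"{task}/{approach}: {res.n_selected}/{table.n_features} selected"
              + (f", {in_band}/{len(rhos)} with |rho| vs CRS-R in [0.2, 0.5]"
                 if rhos else ""))
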