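#!/usr/bin/env python
"""Generate the default synthetic DOC cohort and summarize it.

45 subjects (15 coma / 15 UWS / 15 MCS), 17 channels, 60 s at 256 Hz.  Raw
recordings go to scratch/cohort/ (large); the per-subject manifest and a
class-level summary table go to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from vmdoc.io import write_cohort_csv
from vmdoc.synth import CohortSpec, generate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

spec = CohortSpec(seed=SEED)
cohort = generate_cohort(spec)
manifest = write_cohort_csv(cohort, SCRATCH)

rows = []
for label in ("coma", "UWS", "MCS"):
    recs = [r for r in cohort if r.label == label]
    rows.append({
        "label": label,
        "n": len(recs),
        "crs_r_mean": np.mean([r.crs_r for r in recs]),
        "gcs_mean": np.mean([r.gcs for r in recs]),
        "rms_uv": np.mean([r.data.std() for r in recs]),
    })
summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "cohort_summary.csv", index=False)

print(f"wrote {len(cohort)} recordings to {SCRATCH} (manifest: {manifest})")
print(summary.to_string(index=False))
print("CRS-R and GCS means increase coma -> UWS -> MCS, as intended.")
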