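#!/usr/bin/env python
"""End-to-end synthetic recovery: can the full pipeline separate injured
from healthy eyes it has never seen?

Ten master seeds, each generating a 40-scene cohort (20 healthy, 20
injured) at 24 spectral bands; every scene is calibrated, cropped, enhanced
and reduced to (mean, skewness); the SVM-GRBF (C=500, sigma=2.658) is
scored by pooled 10-fold cross-validated AUC.  Results go to
results/synthetic_recovery.csv.
"""

import time
from pathlib import Path

import numpy as np
import pandas as pd

from corneahsi import SpectrumModel, make_cohort
from corneahsi.pipeline import run_cohort

ROOT = Path(__file__).resolve().parents[1]

model = SpectrumModel(wavelengths=np.linspace(400, 1000, 24))
rows = []
for seed in range(10):
    t0 = time.perf_counter()
    scenes = make_cohort(20, 20, model, seed=seed, size=(100, 100))
    _, report = run_cohort(scenes, k_folds=10, seed=seed)
    rows.append({
        "master_seed": seed,
        "auc": report.auc,
        "accuracy": report.accuracy,
        "mse_error": report.mse_error,
        "seconds": round(time.perf_counter() - t0, 1),
    })
    print(f"master seed {seed}: AUC {report.auc:.4f}  accuracy {report.accuracy:.3f}")

table = pd.DataFrame(rows)
out = ROOT / "results"
out.mkdir(exist_ok=True)
table.to_csv(out / "synthetic_recovery.csv", index=False)
print(f"\nmean AUC over {len(table)} master seeds: {table.auc.mean():.4f} "
      f"(min {table.auc.min():.4f})")
print(f"wrote {out / 'synthetic_recovery.csv'}")
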