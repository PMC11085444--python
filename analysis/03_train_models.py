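#!/usr/bin/env python
"""Train the screening cascade on the synthetic training/calibration sets
and record the model diagnostics (R2X/R2Y, RMSECV per component count).

The fitted models are serialized to scratch/models.json for reuse by
04_screen_test_cohort.py.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import honeyscreen as hs
from honeyscreen.preprocess import assemble_matrix
from honeyscreen.workflow import train_workflow

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
LABEL = {"none": "N", "tadalafil": "T", "sildenafil": "S"}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    acq = hs.AcquisitionModel()
    training = hs.training_cohort(acq, seed=SEED)
    matrix = assemble_matrix(training.spectra)
    labels = [LABEL[m["adulterant"]] for m in matrix.meta]
    cal_t = hs.make_calibration_set("tadalafil", acq=acq, seed=SEED * 7)
    cal_s = hs.make_calibration_set("sildenafil", acq=acq, seed=SEED * 7 + 1)
    models = train_workflow(
        matrix,
        labels,
        (assemble_matrix([s for s, _ in cal_t]), np.array([c for _, c in cal_t])),
        (assemble_matrix([s for s, _ in cal_s]), np.array([c for _, c in cal_s])),
    )
    models.to_json(SCRATCH / "models.json")

    rows = [
        {
            "model": "PLS-DA I (N vs A)",
            "n_spectra": models.plsda_I.T.shape[0],
            "components": models.plsda_I.A,
            "R2X": round(models.plsda_I.diagnostics["R2X"], 3),
            "R2Y": round(models.plsda_I.diagnostics["R2Y"], 3),
        },
        {
            "model": "PLS-DA II (T vs S)",
            "n_spectra": models.plsda_II.T.shape[0],
            "components": models.plsda_II.A,
            "R2X": round(models.plsda_II.diagnostics["R2X"], 3),
            "R2Y": round(models.plsda_II.diagnostics["R2Y"], 3),
        },
        {
            "model": "PLS IV (tadalafil quant)",
            "n_spectra": models.pls_IV.T.shape[0],
            "components": models.pls_IV.A,
            "R2Y": round(models.pls_IV.diagnostics["R2Y"], 4),
            "RMSEE": round(models.pls_IV.diagnostics["RMSEE"], 3),
            "min_RMSECV": round(models.cv_IV.min_rmsecv, 3),
        },
        {
            "model": "PLS III (sildenafil quant)",
            "n_spectra": models.pls_III.T.shape[0],
            "components": models.pls_III.A,
            "R2Y": round(models.pls_III.diagnostics["R2Y"], 4),
            "RMSEE": round(models.pls_III.diagnostics["RMSEE"], 3),
            "min_RMSECV": round(models.cv_III.min_rmsecv, 3),
        },
    ]
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "model_diagnostics.csv", index=False)
    print(table.to_string(index=False))
    rmsecv_t = ", ".join(f"A={a + 1}: {v:.3f}" for a, v in enumerate(models.cv_IV.rmsecv))
    print(f"\ntadalafil RMSECV by component count: {rmsecv_t}")
    print(f"models -> {SCRATCH / 'models.json'}")


if __name__ == "__main__":
    main()
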