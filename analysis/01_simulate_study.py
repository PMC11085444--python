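#!/usr/bin/env python
"""Generate the synthetic study: training cohort, calibration standards and
a blind test cohort, with full ground truth.

Writes the per-sample truth tables under results/ and the raw spectra
under scratch/study/ (large files; regenerated on demand).
"""

from pathlib import Path

import honeyscreen as hs
from honeyscreen.preprocess import write_spectrum

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "study"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    acq = hs.AcquisitionModel()

    training = hs.training_cohort(acq, seed=SEED)  # 5 N / 9 T / 3 S, duplicates
    test = hs.test_cohort(acq, seed=SEED + 100)  # 2 N / 27 T / 2 S, duplicates
    cal_t = hs.make_calibration_set("tadalafil", acq=acq, seed=SEED * 7)
    cal_s = hs.make_calibration_set("sildenafil", acq=acq, seed=SEED * 7 + 1)

    training.truth.to_csv(RESULTS / "training_truth.csv")
    test.truth.to_csv(RESULTS / "test_truth.csv")

    for name, cohort in (("training", training), ("test", test)):
        d = SCRATCH / name
        d.mkdir(parents=True, exist_ok=True)
        for s in cohort.spectra:
            sid, rep = s.meta["sample_id"], s.meta.get("replicate", 1)
            write_spectrum(s, d / f"{sid}-r{rep}.csv")
    for comp, cal in (("tadalafil", cal_t), ("sildenafil", cal_s)):
        d = SCRATCH / f"calibration-{comp}"
        d.mkdir(parents=True, exist_ok=True)
        for i, (s, _) in enumerate(cal):
            write_spectrum(s, d / f"{i:03d}.csv")

    print(f"training: {training.n_samples} samples / {len(training.spectra)} spectra")
    print(f"test:     {test.n_samples} samples / {len(test.spectra)} spectra")
    print(f"calibration: {len(cal_t)} tadalafil + {len(cal_s)} sildenafil spectra")
    print(f"truth tables -> {RESULTS}, spectra -> {SCRATCH}")


if __name__ == "__main__":
    main()
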