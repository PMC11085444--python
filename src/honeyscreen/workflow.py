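"""Three-block screening cascade for honey-supplement extracts.

Block 1 (data handling) lives in :mod:`honeyscreen.preprocess`.  Block 2 is
qualitative: UV-PLS-DA model I separates non-adulterated (coded 0) from
adulterated (coded 1) fingerprints, with YPredPS thresholds 0.30/0.50
defining a borderline band; model II separates tadalafil (0) from
sildenafil (1) and gates projected samples through a 95% Hotelling T2
limit before nearest-centroid assignment.  Block 3 is quantitative:
centred PLS regressions on calibration standards restricted to the
adulterant signal regions predict mg/mL, converted to mg/packet via
Q = C_A * V * m_packet / m.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import (
    CVResult,
    LatentModel,
    cross_validate,
    fit_pls,
    fit_plsda,
    hotelling_limit,
    predict_y,
    project_scores,
)
from .preprocess import BinnedMatrix, Spectrum, assemble_matrix

__all__ = [
    "WorkflowModels",
    "ScreeningDecision",
    "QuantResult",
    "train_workflow",
    "classify_stage1",
    "classify_stage2",
    "quantify",
    "to_mg_per_packet",
    "screen",
    "report",
    "summarize_report",
    "THRESHOLDS",
    "QUANT_REGIONS",
]

#: Stage-1 YPredPS thresholds: below -> non-adulterated, inside (closed)
#: -> borderline, above -> adulterated.
THRESHOLDS = (0.30, 0.50)

#: Fingerprint sub-regions (ppm) used by the quantitative PLS models.
QUANT_REGIONS = {"tadalafil": (5.6, 6.4), "sildenafil": (8.10, 8.50)}

_MAX_QUANT_COMPONENTS = 5


@dataclass
class WorkflowModels:
    """The four fitted models plus everything stage 2/3 needs to decide."""

    plsda_I: LatentModel  # non-adulterated (0) vs adulterated (1)
    plsda_II: LatentModel  # tadalafil (0) vs sildenafil (1)
    pls_III: LatentModel  # sildenafil quantification (mg/mL)
    pls_IV: LatentModel  # tadalafil quantification (mg/mL)
    bin_centers: np.ndarray
    thresholds: tuple[float, float] = THRESHOLDS
    quant_regions: dict = field(default_factory=lambda: dict(QUANT_REGIONS))
    centroid_T: np.ndarray | None = None  # in SD-scaled score space
    centroid_S: np.ndarray | None = None
    n_train_II: int = 0
    cv_III: CVResult | None = None
    cv_IV: CVResult | None = None

    def __post_init__(self) -> None:
        lo, hi = self.thresholds
        if not lo < hi:
            raise ValueError("thresholds must satisfy lower < upper")

    def region_columns(self, adulterant: str) -> np.ndarray:
        lo, hi = self.quant_regions[adulterant]
        return np.where((self.bin_centers >= lo) & (self.bin_centers <= hi))[0]

    def to_json(self, path) -> None:
        d = {
            "plsda_I": self.plsda_I.to_dict(),
            "plsda_II": self.plsda_II.to_dict(),
            "pls_III": self.pls_III.to_dict(),
            "pls_IV": self.pls_IV.to_dict(),
            "bin_centers": self.bin_centers.tolist(),
            "thresholds": list(self.thresholds),
            "quant_regions": {k: list(v) for k, v in self.quant_regions.items()},
            "centroid_T": self.centroid_T.tolist(),
            "centroid_S": self.centroid_S.tolist(),
            "n_train_II": self.n_train_II,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "WorkflowModels":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            plsda_I=LatentModel.from_dict(d["plsda_I"]),
            plsda_II=LatentModel.from_dict(d["plsda_II"]),
            pls_III=LatentModel.from_dict(d["pls_III"]),
            pls_IV=LatentModel.from_dict(d["pls_IV"]),
            bin_centers=np.asarray(d["bin_centers"]),
            thresholds=tuple(d["thresholds"]),
            quant_regions={k: tuple(v) for k, v in d["quant_regions"].items()},
            centroid_T=np.asarray(d["centroid_T"]),
            centroid_S=np.asarray(d["centroid_S"]),
            n_train_II=d["n_train_II"],
        )


@dataclass
class QuantResult:
    """Concentration in the analysed extract and its per-packet dose."""

    C_A: float  # mg/mL
    Q: float  # mg/packet
    V: float
    m: float
    m_packet: float
    floored: bool = False


@dataclass
class ScreeningDecision:
    """Per-sample cascade outcome (replicates averaged at decision level)."""

    sample_id: str
    ypredps: float
    stage1: str  # non-adulterated | borderline | adulterated
    stage2: str = "not-evaluated"  # tadalafil | sildenafil | outlier | not-evaluated
    t2: float | None = None
    conc_mg_per_ml: float | None = None
    conc_sd: float | None = None
    dose_mg_per_packet: float | None = None
    dose_sd: float | None = None
    floored: bool = False


def train_workflow(
    training: BinnedMatrix,
    labels,
    calib_tadalafil: tuple[BinnedMatrix, np.ndarray],
    calib_sildenafil: tuple[BinnedMatrix, np.ndarray],
    n_components_da: int = 3,
) -> WorkflowModels:
    """Fit the four workflow models.

    ``labels`` holds one of N/T/S per training row.  PLS-DA I is fitted on
    the full fingerprint with UV scaling (N=0, adulterated=1, 3 components);
    PLS-DA II on the T/S rows only (T=0, S=1).  The quantitative models use
    centred (unscaled) bins restricted to the adulterant regions, with the
    component count chosen by minimum RMSECV (venetian blinds, up to 5).
    """
    labels = np.asarray([str(l) for l in labels])
    for cls in "NTS":
        if not np.any(labels == cls):
            raise ValueError(f"training set is missing class {cls!r}")
    if labels.size != len(training.sample_ids):
        raise ValueError("labels length does not match training matrix")

    y1 = np.where(labels == "N", "N", "A")
    plsda_I = fit_plsda(training.values, y1, A=n_components_da, scaling="uv", positive="A")

    mask = labels != "N"
    plsda_II = fit_plsda(
        training.values[mask], labels[mask], A=n_components_da, scaling="uv", positive="S"
    )
    sd = plsda_II.T.std(axis=0, ddof=1)
    scaled_T = plsda_II.T / sd
    lab2 = labels[mask]
    centroid_T = scaled_T[lab2 == "T"].mean(axis=0)
    centroid_S = scaled_T[lab2 == "S"].mean(axis=0)

    models = {}
    cvs = {}
    for adulterant, (calib, conc) in (
        ("tadalafil", calib_tadalafil),
        ("sildenafil", calib_sildenafil),
    ):
        conc = np.asarray(conc, dtype=float)
        if calib.values.shape[0] == 0:
            raise ValueError(f"empty {adulterant} calibration set")
        lo, hi = QUANT_REGIONS[adulterant]
        cols = calib.region_columns(lo, hi)
        Xq = calib.values[:, cols]
        a_max = min(_MAX_QUANT_COMPONENTS, Xq.shape[0] - 2, Xq.shape[1])
        cv = cross_validate(Xq, conc, A_max=a_max, scheme="venetian", scaling="center")
        models[adulterant] = fit_pls(Xq, conc, A=cv.chosen_A, scaling="center")
        cvs[adulterant] = cv

    return WorkflowModels(
        plsda_I=plsda_I,
        plsda_II=plsda_II,
        pls_III=models["sildenafil"],
        pls_IV=models["tadalafil"],
        bin_centers=training.bin_centers,
        centroid_T=centroid_T,
        centroid_S=centroid_S,
        n_train_II=int(mask.sum()),
        cv_III=cvs["sildenafil"],
        cv_IV=cvs["tadalafil"],
    )


def classify_stage1(models: WorkflowModels, bins: np.ndarray) -> tuple[float, str]:
    """YPredPS of one fingerprint row and its threshold class.

    Boundary values (exactly 0.30 or 0.50) fall in the borderline band.
    """
    y = float(predict_y(models.plsda_I, np.atleast_2d(bins))[0])
    return y, _stage1_class(y, models.thresholds)


def _stage1_class(y: float, thresholds: tuple[float, float]) -> str:
    lo, hi = thresholds
    if y < lo:
        return "non-adulterated"
    if y > hi:
        return "adulterated"
    return "borderline"


def classify_stage2(
    models: WorkflowModels,
    bins: np.ndarray,
    alpha: float = 0.05,
    stage1: str | None = None,
) -> tuple[str, float, np.ndarray]:
    """Project one (or the replicate-mean) fingerprint onto PLS-DA II.

    Returns (assignment, T2, SD-scaled score coordinates).  Samples outside
    the 95% Hotelling T2 region are flagged ``outlier``; otherwise the
    nearer training-class centroid wins, ties breaking to tadalafil.
    Passing the sample's stage-1 class enforces the cascade contract: only
    adulterated or borderline samples may be evaluated here.
    """
    if stage1 is not None and stage1 not in ("adulterated", "borderline"):
        raise ValueError(
            f"stage 2 must not be evaluated for stage-1 class {stage1!r}"
        )
    t = project_scores(models.plsda_II, np.atleast_2d(bins))[0]
    sd = models.plsda_II.T.std(axis=0, ddof=1)
    scaled = t / sd
    t2 = float((scaled**2).sum())
    limit = hotelling_limit(models.n_train_II, models.plsda_II.A, alpha)
    if t2 > limit:
        return "outlier", t2, scaled
    d_t = float(np.linalg.norm(scaled - models.centroid_T))
    d_s = float(np.linalg.norm(scaled - models.centroid_S))
    return ("tadalafil" if d_t <= d_s else "sildenafil"), t2, scaled


def quantify(models: WorkflowModels, bins: np.ndarray, adulterant: str) -> tuple[float, bool]:
    """Predicted concentration (mg/mL) from the region-restricted PLS model.

    Negative predictions are floored at 0 and flagged.
    """
    if adulterant == "tadalafil":
        model = models.pls_IV
    elif adulterant == "sildenafil":
        model = models.pls_III
    else:
        raise ValueError(f"unknown adulterant {adulterant!r}")
    cols = models.region_columns(adulterant)
    c = float(predict_y(model, np.atleast_2d(bins)[:, cols])[0])
    if c < 0:
        return 0.0, True
    return c, False


def to_mg_per_packet(C_A: float, V: float, m_packet: float, m: float) -> QuantResult:
    """Dose per packet: Q = C_A * V * m_packet / m."""
    if not (V > 0 and m_packet > 0 and m > 0):
        raise ValueError("V, m_packet and m must be > 0")
    return QuantResult(C_A=C_A, Q=C_A * V * m_packet / m, V=V, m=m, m_packet=m_packet)


def screen(
    models: WorkflowModels,
    spectra: list[Spectrum],
    metadata: pd.DataFrame | None = None,
) -> list[ScreeningDecision]:
    """Run the full cascade on raw spectra.

    Spectra are preprocessed (align/bin/standardize); replicates of a
    sample (same ``sample_id`` in their metadata) are averaged at the
    decision level: mean YPredPS, stage-2 on the mean fingerprint, and
    mean dose +/- SD over per-replicate quantifications.  ``metadata`` may
    supply ``m``, ``m_packet`` and ``V`` per sample_id; otherwise they are
    read from the spectrum metadata.
    """
    if not spectra:
        return []
    matrix = assemble_matrix(spectra)
    rows = pd.DataFrame(
        {"sample_id": matrix.sample_ids, "row": np.arange(len(matrix.sample_ids))}
    )
    decisions = []
    for sid, grp in rows.groupby("sample_id", sort=False):
        idx = grp["row"].to_numpy()
        X = matrix.values[idx]
        ypred = predict_y(models.plsda_I, X)
        y_mean = float(ypred.mean())
        stage1 = _stage1_class(y_mean, models.thresholds)
        dec = ScreeningDecision(sample_id=str(sid), ypredps=y_mean, stage1=stage1)
        if stage1 in ("adulterated", "borderline"):
            assignment, t2, _ = classify_stage2(models, X.mean(axis=0))
            dec.stage2 = assignment
            dec.t2 = t2
            if assignment in ("tadalafil", "sildenafil"):
                concs, floored = [], False
                for r in idx:
                    c, fl = quantify(models, matrix.values[r], assignment)
                    concs.append(c)
                    floored |= fl
                concs = np.asarray(concs)
                sm = _sample_meta(sid, matrix.meta[idx[0]], metadata)
                doses = np.array(
                    [
                        to_mg_per_packet(c, sm["V"], sm["m_packet"], sm["m"]).Q
                        for c in concs
                    ]
                )
                dec.conc_mg_per_ml = float(concs.mean())
                dec.conc_sd = float(concs.std(ddof=1)) if concs.size > 1 else 0.0
                dec.dose_mg_per_packet = float(doses.mean())
                dec.dose_sd = float(doses.std(ddof=1)) if doses.size > 1 else 0.0
                dec.floored = floored
        decisions.append(dec)
    return decisions


def _sample_meta(sid, spectrum_meta: dict, metadata: pd.DataFrame | None) -> dict:
    if metadata is not None and sid in metadata.index:
        row = metadata.loc[sid]
        return {"m": float(row["m"]), "m_packet": float(row["m_packet"]), "V": float(row["V"])}
    try:
        return {
            "m": float(spectrum_meta["m"]),
            "m_packet": float(spectrum_meta["m_packet"]),
            "V": float(spectrum_meta["V"]),
        }
    except KeyError as exc:
        raise ValueError(f"sample {sid!r}: missing mass/volume metadata ({exc})")


_REPORT_COLUMNS = [
    "sample_id",
    "ypredps",
    "stage1",
    "stage2",
    "adulterant_ref",
    "level_mg_per_packet",
    "level_sd",
    "pct_dev",
]


def report(
    decisions: list[ScreeningDecision],
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tabulate screening decisions (one row per sample).

    ``reference`` may carry per-sample reference quantification
    (columns ``adulterant`` and ``dose_mg_per_packet``, indexed by
    sample_id); when present, the percent deviation of the predicted level
    versus the reference is reported.
    """
    rows = []
    for d in decisions:
        ref_adult, pct = None, None
        if reference is not None and d.sample_id in reference.index:
            r = reference.loc[d.sample_id]
            ref_adult = r.get("adulterant")
            ref_dose = r.get("dose_mg_per_packet")
            if (
                d.dose_mg_per_packet is not None
                and ref_dose is not None
                and ref_dose > 0
            ):
                pct = 100.0 * (d.dose_mg_per_packet - ref_dose) / ref_dose
        rows.append(
            {
                "sample_id": d.sample_id,
                "ypredps": d.ypredps,
                "stage1": d.stage1,
                "stage2": d.stage2,
                "adulterant_ref": ref_adult,
                "level_mg_per_packet": d.dose_mg_per_packet,
                "level_sd": d.dose_sd,
                "pct_dev": pct,
            }
        )
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def summarize_report(table: pd.DataFrame) -> dict:
    """Summary statistics of a screening report table.

    Works on tables produced by :func:`report` or on externally transcribed
    reports with the same columns.  A sample disagrees with its reference
    identification when the reference names an adulterant and stage 2
    assigned a different one (or flagged it outlier), or when the reference
    is non-adulterated but stage 1 did not clear it.
    """
    t = table
    is_t = t["stage2"] == "tadalafil"
    is_s = t["stage2"] == "sildenafil"
    dev = pd.to_numeric(t["pct_dev"], errors="coerce")
    t_dev = dev[is_t & dev.notna()]
    adulterated = t["stage1"] == "adulterated"
    nonadult = t["stage1"] == "non-adulterated"

    disagreements = 0
    has_ref = t["adulterant_ref"].notna() & (t["adulterant_ref"] != "-")
    for _, row in t.iterrows():
        ref = row["adulterant_ref"]
        if ref is None or (isinstance(ref, float) and np.isnan(ref)):
            continue
        if ref == "-" or ref == "none":
            if row["stage1"] != "non-adulterated":
                disagreements += 1
        elif row["stage2"] != str(ref).lower():
            disagreements += 1

    summary = {
        "n_samples": int(len(t)),
        "n_tadalafil_assigned": int(is_t.sum()),
        "n_sildenafil_assigned": int(is_s.sum()),
        "n_outlier": int((t["stage2"] == "outlier").sum()),
        "n_non_adulterated": int(nonadult.sum()),
        "n_borderline": int((t["stage1"] == "borderline").sum()),
        "mean_tadalafil_pct_dev": float(t_dev.mean()) if len(t_dev) else np.nan,
        "sd_tadalafil_pct_dev": float(t_dev.std(ddof=1)) if len(t_dev) > 1 else np.nan,
        "n_abs_dev_gt_10": int((dev.abs() > 10).sum()),
        "min_adulterated_ypredps": float(t.loc[adulterated, "ypredps"].min())
        if adulterated.any()
        else np.nan,
        "mean_non_adulterated_ypredps": float(t.loc[nonadult, "ypredps"].mean())
        if nonadult.any()
        else np.nan,
        "n_disagreements": disagreements if has_ref.any() else None,
    }
    return summary
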