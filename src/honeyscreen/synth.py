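"""Synthetic benchtop (60 MHz) 1H NMR spectra of honey extracts.

This module generates spectra with known ground truth for the screening
workflow: calibration standards of tadalafil/sildenafil, honey-extract
samples with optional adulterant, matrix confusers (5-HMF, organic acids,
benzoate, flibanserin), a sugar/water background, and the TSP internal
standard.  Lines are rendered as finite-support Lorentzians whose discrete
integral is exact, so peak areas are strictly proportional to concentration
(the qNMR assumption the downstream chemometrics relies on).

Amplitudes are in arbitrary "area units": a compound's ``response`` is the
integrated area produced per (mg/mL) per proton, scaled so that the default
tadalafil H1 calibration slope is ~3158 area units per (mg/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import Spectrum

__all__ = [
    "PeakSpec",
    "CompoundTemplate",
    "AcquisitionModel",
    "SampleRecipe",
    "Cohort",
    "builtin_templates",
    "render_spectrum",
    "make_calibration_set",
    "make_honey_sample",
    "make_cohort",
    "training_cohort",
    "test_cohort",
    "TADALAFIL_LEVELS",
    "SILDENAFIL_LEVELS",
    "TRAINING_T_DOSES",
    "TRAINING_S_DOSES",
    "DEFAULT_TSP_AREA",
]

# Multiplicities and the number of J couplings each one requires.
_COUPLINGS_REQUIRED = {"s": 0, "d": 1, "dd": 2, "t": 1, "m": 0, "broad": 0}

#: Calibration level series for the two adulterants (mg/mL).
TADALAFIL_LEVELS = (0.1, 0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0, 5.0, 10.0)
SILDENAFIL_LEVELS = (2.0, 3.0, 4.0, 5.0, 10.0)

#: Training-set doses (mg/packet) emulating the study design: nine tadalafil
#: samples spanning ~12-79 mg/packet and three sildenafil samples.  Lists are
#: cycled verbatim by ``make_cohort``; a 2-tuple would mean a uniform range.
TRAINING_T_DOSES = [12.0, 18.0, 25.0, 33.0, 41.0, 50.0, 60.0, 70.0, 79.0]
TRAINING_S_DOSES = [111.0, 14.0, 201.0]

#: Default integrated area of the TSP internal-standard singlet (area units).
DEFAULT_TSP_AREA = 500.0

#: Lorentzian lines are truncated at +/- this many FWHM and renormalised so
#: the discrete integral over the support equals the nominal area exactly.
LINE_SUPPORT_FWHM = 6.0


@dataclass(frozen=True)
class PeakSpec:
    """One resonance of a compound.

    Parameters
    ----------
    center : float
        Chemical shift of the multiplet centre (ppm).
    multiplicity : str
        One of ``s``, ``d``, ``dd``, ``t``, ``m`` (envelope) or ``broad``.
    couplings : tuple of float
        J values in Hz; the length must match the multiplicity
        (0 for s/broad/m, 1 for d/t, 2 for dd).
    n_protons : int
        Number of protons contributing to the multiplet.
    label : str
        Free-text assignment, e.g. ``"tadalafil H1"``.
    width : float, optional
        Full width (ppm) for ``m`` envelopes (Gaussian) and ``broad``
        lines (Lorentzian FWHM); ignored for sharp multiplets.
    """

    center: float
    multiplicity: str
    couplings: tuple[float, ...] = ()
    n_protons: int = 1
    label: str = ""
    width: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise ValueError(f"peak center must be finite, got {self.center}")
        if self.multiplicity not in _COUPLINGS_REQUIRED:
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")
        need = _COUPLINGS_REQUIRED[self.multiplicity]
        if len(self.couplings) != need:
            raise ValueError(
                f"multiplicity {self.multiplicity!r} needs {need} couplings, "
                f"got {len(self.couplings)}"
            )
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if self.multiplicity in ("m", "broad") and self.width is None:
            raise ValueError(f"{self.multiplicity!r} peak requires a width")


@dataclass(frozen=True)
class CompoundTemplate:
    """A compound's peak list plus its area response.

    ``response`` is the integrated area per (mg/mL) per proton, in the
    generator's fixed arbitrary units.
    """

    name: str
    peaks: tuple[PeakSpec, ...]
    response: float

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError(f"template {self.name!r} has no peaks")
        if not self.response > 0:
            raise ValueError(f"template {self.name!r} response must be > 0")


@dataclass(frozen=True)
class AcquisitionModel:
    """Spectrometer / processing model for rendering.

    Defaults emulate a 59.7 MHz benchtop instrument: ~1.5 Hz Lorentzian
    lines after 0.3 Hz apodization, additive Gaussian noise, a slow cubic
    baseline drift, a small global chemical-shift jitter per spectrum, and
    a per-spectrum multiplicative gain scatter (receiver/pipetting
    variability) that dominates the quantification error budget.
    """

    frequency: float = 59.7  # MHz
    fwhm: float = 1.5  # Hz
    noise_sd: float = 800.0  # intensity units (SNR ~10 at 0.1 mg/mL H1)
    baseline_amp: float = 50.0  # intensity units (residual drift after correction)
    shift_jitter_sd: float = 0.003  # ppm
    gain_sd: float = 0.02  # relative receiver-gain scatter (whole spectrum)
    tsp_sd: float = 0.03  # relative scatter of the TSP spike (pipetting)
    ppm_grid: tuple[float, float, float] = (-0.5, 10.8, 0.0005)  # lo, hi, step

    def __post_init__(self) -> None:
        lo, hi, step = self.ppm_grid
        if not (self.frequency > 0 and self.fwhm > 0 and step > 0 and hi > lo):
            raise ValueError("invalid acquisition model")
        if self.noise_sd < 0 or self.gain_sd < 0 or self.tsp_sd < 0:
            raise ValueError("noise_sd, gain_sd and tsp_sd must be >= 0")

    def grid(self) -> np.ndarray:
        lo, hi, step = self.ppm_grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def noise_free(self) -> "AcquisitionModel":
        """Copy with every stochastic term switched off."""
        return replace(
            self,
            noise_sd=0.0,
            baseline_amp=0.0,
            shift_jitter_sd=0.0,
            gain_sd=0.0,
            tsp_sd=0.0,
        )


@dataclass(frozen=True)
class SampleRecipe:
    """Ground truth for one honey-extract sample.

    ``dose_mg_per_packet`` is the adulterant dose; the concentration in the
    rendered extract follows C_A = dose * m / (m_packet * V).  ``confusers``
    maps compound name to concentration (mg/mL for real compounds,
    arbitrary level units for the sugar/water/formulation backgrounds).
    """

    adulterant: str = "none"  # none|tadalafil|sildenafil|tadalafil+flibanserin
    dose_mg_per_packet: float = 0.0
    m_packet: float = 10.0  # g honey per packet
    m: float = 1.0  # g honey extracted
    V: float = 2.0  # mL extract analysed
    confusers: dict[str, float] = field(default_factory=dict)
    tsp_area: float = DEFAULT_TSP_AREA
    seed: int | None = None

    def __post_init__(self) -> None:
        allowed = {"none", "tadalafil", "sildenafil", "tadalafil+flibanserin"}
        if self.adulterant not in allowed:
            raise ValueError(f"unknown adulterant {self.adulterant!r}")
        if self.dose_mg_per_packet < 0:
            raise ValueError("dose must be >= 0")
        if not (self.m > 0 and self.m_packet > 0 and self.V > 0):
            raise ValueError("m, m_packet and V must be > 0")
        if not self.tsp_area > 0:
            raise ValueError("tsp_area must be > 0")

    @property
    def concentration(self) -> float:
        """Adulterant concentration C_A (mg/mL) in the analysed extract."""
        return self.dose_mg_per_packet * self.m / (self.m_packet * self.V)


def builtin_templates() -> dict[str, CompoundTemplate]:
    """Peak tables of every compound the generator knows about.

    Chemical shifts and couplings follow the assignments observed at
    59.7 MHz for honey-supplement extracts; responses are in the
    generator's fixed arbitrary area units.
    """
    P = PeakSpec
    t = {}
    t["tadalafil"] = CompoundTemplate(
        "tadalafil",
        (
            P(5.85, "s", (), 1, "H1"),
            P(6.22, "s", (), 1, "H8"),
            P(10.30, "broad", (), 1, "NH (H22)", width=0.15),
            P(7.00, "m", (), 7, "aromatic envelope H3/H5/H6/H18-H21", width=1.0),
        ),
        response=3158.0,
    )
    t["sildenafil"] = CompoundTemplate(
        "sildenafil",
        (
            P(8.33, "d", (2.1,), 1, "H15"),
            P(7.90, "dd", (8.7, 2.1), 1, "H17"),
            P(7.30, "d", (8.7,), 1, "H18"),
            P(2.42, "s", (), 2, "H29"),
            P(1.90, "m", (), 2, "H12", width=0.2),
            P(1.51, "t", (7.1,), 3, "H21"),
            P(0.99, "t", (6.8,), 3, "H13"),
        ),
        response=1137.0,
    )
    t["5-HMF"] = CompoundTemplate(
        "5-HMF",
        (
            P(9.52, "s", (), 1, "CHO"),
            P(7.35, "d", (3.6,), 1, "furan H"),
            P(6.58, "d", (3.6,), 1, "furan H"),
        ),
        response=2000.0,
    )
    t["formic acid"] = CompoundTemplate(
        "formic acid", (P(8.52, "s", (), 1, "HCOOH"),), response=2000.0
    )
    t["acetic acid"] = CompoundTemplate(
        "acetic acid", (P(1.97, "s", (), 3, "CH3"),), response=2000.0
    )
    t["2,3-butanediol"] = CompoundTemplate(
        "2,3-butanediol", (P(1.12, "d", (6.3,), 6, "CH3"),), response=2000.0
    )
    t["ethanol"] = CompoundTemplate(
        "ethanol", (P(1.17, "t", (7.1,), 3, "CH3"),), response=2000.0
    )
    t["benzoate"] = CompoundTemplate(
        "benzoate",
        (
            P(8.00, "m", (), 2, "ortho H", width=0.4),
            P(7.40, "m", (), 3, "meta/para H", width=0.2),
        ),
        response=2000.0,
    )
    t["flibanserin"] = CompoundTemplate(
        "flibanserin",
        (P(7.10, "broad", (), 8, "aromatic H", width=0.25),),
        response=2000.0,
    )
    t["TSP"] = CompoundTemplate(
        # Response 1/9 per proton: a "concentration" equal to the desired
        # reference area renders a 9H singlet of exactly that total area.
        "TSP",
        (P(0.00, "s", (), 9, "Si(CH3)3"),),
        response=1.0 / 9.0,
    )
    t["chloroform"] = CompoundTemplate(
        "chloroform", (P(7.65, "s", (), 1, "residual CHCl3"),), response=2000.0
    )
    t["sugar"] = CompoundTemplate(
        "sugar",
        (P(4.25, "m", (), 1, "sugar envelope 3.0-5.5 ppm", width=2.5),),
        response=5000.0,
    )
    t["water"] = CompoundTemplate(
        "water", (P(4.79, "broad", (), 1, "residual HDO", width=0.3),), response=5000.0
    )
    # Supplement formulation background: manufactured aphrodisiac pastes carry
    # herbal/excipient heteroaromatics that plain honey lacks; emulated as two
    # weak broad envelopes in the downfield fingerprint, clear of the
    # adulterant quantification regions.
    t["formulation"] = CompoundTemplate(
        "formulation",
        (
            P(8.72, "m", (), 1, "excipient heteroaromatics", width=0.24),
            P(8.93, "m", (), 1, "excipient heteroaromatics", width=0.16),
        ),
        response=2000.0,
    )
    return t


_TEMPLATES = builtin_templates()


def _line_positions(peak: PeakSpec, frequency: float) -> list[tuple[float, float]]:
    """Relative line offsets (ppm) and weights of a first-order multiplet."""
    to_ppm = 1.0 / frequency  # Hz -> ppm
    m = peak.multiplicity
    if m == "s":
        return [(0.0, 1.0)]
    if m == "d":
        j = peak.couplings[0] * to_ppm
        return [(-j / 2, 1.0), (j / 2, 1.0)]
    if m == "t":
        j = peak.couplings[0] * to_ppm
        return [(-j, 1.0), (0.0, 2.0), (j, 1.0)]
    if m == "dd":
        j1, j2 = (c * to_ppm for c in peak.couplings)
        return [
            (-j1 / 2 - j2 / 2, 1.0),
            (-j1 / 2 + j2 / 2, 1.0),
            (j1 / 2 - j2 / 2, 1.0),
            (j1 / 2 + j2 / 2, 1.0),
        ]
    raise AssertionError(m)


def _add_shape(
    grid: np.ndarray, out: np.ndarray, center: float, area: float, kind: str, width: float
) -> None:
    """Add a finite-support line of exact discrete area onto ``out``.

    kind "lorentz": ``width`` is the FWHM, support +/- LINE_SUPPORT_FWHM*FWHM.
    kind "gauss": ``width`` is the full envelope width, sigma = width/4,
    support +/- 3 sigma.
    """
    if kind == "lorentz":
        half_support = LINE_SUPPORT_FWHM * width
    else:
        half_support = 0.75 * width  # 3 sigma with sigma = width/4
    step = grid[1] - grid[0]
    i0 = max(0, int(np.ceil((center - half_support - grid[0]) / step)))
    i1 = min(len(grid) - 1, int(np.floor((center + half_support - grid[0]) / step)))
    if i1 - i0 < 2:
        return  # line entirely (or all but a sliver) outside the grid
    x = grid[i0 : i1 + 1]
    if kind == "lorentz":
        gamma = width / 2.0
        y = gamma / (np.pi * ((x - center) ** 2 + gamma**2))
    else:
        sigma = width / 4.0
        y = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    # cos^2 taper over the outer 20% of the support: the lineshape reaches
    # zero smoothly, so bin contents vary smoothly with sub-grid shifts.
    r = np.abs(x - center) / half_support
    taper = np.where(r > 0.8, np.cos(0.5 * np.pi * np.clip((r - 0.8) / 0.2, 0, 1)) ** 2, 1.0)
    y = y * taper
    raw = np.trapezoid(y, x)
    if raw > 0:
        out[i0 : i1 + 1] += y * (area / raw)


def render_spectrum(
    concentrations: dict[str, float],
    acq: AcquisitionModel | None = None,
    seed: int | np.random.Generator | None = None,
    templates: dict[str, CompoundTemplate] | None = None,
    meta: dict | None = None,
) -> Spectrum:
    """Render a mixture spectrum.

    Each compound contributes concentration x response x n_protons of
    integrated area per multiplet, split across first-order lines (1:1 for
    d, 1:2:1 for t, 1:1:1:1 for dd).  A single global chemical-shift jitter
    is applied to all lines (including TSP, so TSP alignment removes it),
    then a multiplicative gain factor, cubic baseline drift and additive
    Gaussian noise.
    """
    acq = acq or AcquisitionModel()
    templates = templates or _TEMPLATES
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = acq.grid()
    signal = np.zeros_like(grid)

    # Fixed draw order so identical seeds give bit-identical spectra.
    jitter = rng.normal(0.0, 1.0) * acq.shift_jitter_sd
    gain = 1.0 + rng.normal(0.0, 1.0) * acq.gain_sd
    tsp_factor = 1.0 + rng.normal(0.0, 1.0) * acq.tsp_sd
    base_coef = rng.normal(0.0, 1.0, 4) * acq.baseline_amp
    noise = rng.normal(0.0, 1.0, grid.size) * acq.noise_sd

    fwhm_ppm = acq.fwhm / acq.frequency
    for name, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if conc == 0:
            continue
        if name == "TSP":
            # Pipetting scatter of the internal-standard spike: independent
            # of the analytes, so it does NOT cancel under standardization.
            conc = conc * max(tsp_factor, 0.0)
        tpl = templates[name]
        for peak in tpl.peaks:
            area = conc * tpl.response * peak.n_protons
            center = peak.center + jitter
            if peak.multiplicity == "m":
                _add_shape(grid, signal, center, area, "gauss", peak.width)
            elif peak.multiplicity == "broad":
                _add_shape(grid, signal, center, area, "lorentz", peak.width)
            else:
                lines = _line_positions(peak, acq.frequency)
                wsum = sum(w for _, w in lines)
                for off, w in lines:
                    _add_shape(
                        grid, signal, center + off, area * w / wsum, "lorentz", fwhm_ppm
                    )

    u = (grid - grid.mean()) / (grid[-1] - grid[0]) * 2.0
    baseline = base_coef[0] + base_coef[1] * u + base_coef[2] * u**2 + base_coef[3] * u**3
    intensity = gain * signal + baseline + noise
    return Spectrum(ppm=grid, intensity=intensity, meta=dict(meta or {}))


def make_calibration_set(
    compound: str,
    levels: tuple[float, ...] | None = None,
    replicates: int | None = None,
    acq: AcquisitionModel | None = None,
    seed: int | None = 0,
) -> list[tuple[Spectrum, float]]:
    """TSP-containing calibration standards at known concentrations.

    Defaults reproduce the study's calibration design: tadalafil at
    0.1-10 mg/mL in quadruplicate (40 spectra) and sildenafil at
    2-10 mg/mL in triplicate (15 spectra).
    """
    if levels is None:
        if compound == "tadalafil":
            levels = TADALAFIL_LEVELS
        elif compound == "sildenafil":
            levels = SILDENAFIL_LEVELS
        else:
            raise ValueError(f"no default levels for {compound!r}")
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    if any(c <= 0 for c in levels):
        raise ValueError("calibration levels must be positive")
    if replicates is None:
        replicates = 4 if compound == "tadalafil" else 3
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    acq = acq or AcquisitionModel()
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(replicates):
        for level in levels:
            s = render_spectrum(
                {compound: level, "TSP": DEFAULT_TSP_AREA},
                acq,
                seed=rng,
                meta={
                    "sample_id": f"cal-{compound}-{level:g}-r{rep + 1}",
                    "compound": compound,
                    "concentration": level,
                },
            )
            out.append((s, level))
    return out


_ADULTERANT_COMPOUNDS = {
    "none": {},
    "tadalafil": {"tadalafil": 1.0},
    "sildenafil": {"sildenafil": 1.0},
    "tadalafil+flibanserin": {"tadalafil": 1.0},
}


def make_honey_sample(
    recipe: SampleRecipe,
    acq: AcquisitionModel | None = None,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "sample",
) -> tuple[Spectrum, dict]:
    """Render one honey-extract spectrum from its recipe.

    The adulterant concentration in the extract is
    ``C_A = dose * m / (m_packet * V)``; confusers and backgrounds are
    added at their recipe levels.  Returns the spectrum and a ground-truth
    record echoing the recipe.
    """
    acq = acq or AcquisitionModel()
    if seed is None:
        seed = recipe.seed
    conc: dict[str, float] = {"TSP": recipe.tsp_area}
    c_a = recipe.concentration
    for name, w in _ADULTERANT_COMPOUNDS[recipe.adulterant].items():
        conc[name] = conc.get(name, 0.0) + w * c_a
    if recipe.adulterant == "tadalafil+flibanserin":
        conc["flibanserin"] = recipe.confusers.get("flibanserin", 0.6)
    for name, level in recipe.confusers.items():
        if name == "flibanserin" and recipe.adulterant == "tadalafil+flibanserin":
            continue
        conc[name] = conc.get(name, 0.0) + level
    meta = {
        "sample_id": sample_id,
        "m": recipe.m,
        "m_packet": recipe.m_packet,
        "V": recipe.V,
        "adulterant": recipe.adulterant,
        "dose_mg_per_packet": recipe.dose_mg_per_packet,
    }
    spectrum = render_spectrum(conc, acq, seed=seed, meta=meta)
    truth = dict(meta)
    truth["concentration_mg_per_ml"] = c_a
    truth["confusers"] = dict(recipe.confusers)
    return spectrum, truth


@dataclass
class Cohort:
    """A labeled set of honey-extract spectra with per-sample ground truth."""

    spectra: list[Spectrum]
    truth: pd.DataFrame  # indexed by sample_id

    @property
    def n_samples(self) -> int:
        return len(self.truth)


def _default_confusers(rng: np.random.Generator, adulterated: bool) -> dict[str, float]:
    """Matrix composition for one sample: sugars/water always, organic-acid
    confusers sporadically, formulation background only in manufactured
    (adulterated) supplement samples."""
    conf: dict[str, float] = {
        "sugar": rng.uniform(0.5, 1.5),
        "water": rng.uniform(0.1, 0.3),
        "chloroform": rng.uniform(0.02, 0.05),
        # Ubiquitous sugar-degradation / fermentation markers (mg/mL):
        # every honey carries some, at bounded trace-to-moderate levels.
        "5-HMF": rng.uniform(0.02, 0.15),
        "formic acid": rng.uniform(0.01, 0.06),
        "acetic acid": rng.uniform(0.02, 0.20),
        "2,3-butanediol": rng.uniform(0.02, 0.20),
    }
    if adulterated:
        # Excipient level with wide scatter: its dispersion keeps the
        # ~10 mg/packet regime near the stage-1 decision boundary.
        conf["formulation"] = rng.uniform(0.35, 0.95)
    return conf


def _draw_dose(rng: np.random.Generator, spec, i: int) -> float:
    """A (lo, hi) tuple draws uniformly; a list of doses is cycled in order."""
    if isinstance(spec, tuple) and len(spec) == 2:
        lo, hi = spec
        return float(rng.uniform(lo, hi))
    seq = list(spec)
    return float(seq[i % len(seq)])


def make_cohort(
    n_none: int = 7,
    n_tadalafil: int = 38,
    n_sildenafil: int = 5,
    dose_ranges: dict | None = None,
    acq: AcquisitionModel | None = None,
    seed: int | None = 0,
    replicates: int = 1,
    id_prefix: str = "hs",
) -> Cohort:
    """Reproducible labeled cohort of honey samples.

    ``dose_ranges`` maps adulterant to either a (lo, hi) uniform range or an
    explicit dose sequence (mg/packet).  Defaults mimic the full study:
    7 non-adulterated, 38 tadalafil (12-84 mg/packet) and 5 sildenafil
    samples.  ``replicates`` renders each sample that many times (duplicate
    acquisitions share ground truth but not noise).
    """
    if min(n_none, n_tadalafil, n_sildenafil) < 0:
        raise ValueError("counts must be >= 0")
    acq = acq or AcquisitionModel()
    dose_ranges = dose_ranges or {}
    t_doses = dose_ranges.get("tadalafil", (12.0, 84.0))
    s_doses = dose_ranges.get("sildenafil", (14.0, 201.0))
    rng = np.random.default_rng(seed)

    plan: list[tuple[str, float]] = []
    for i in range(n_none):
        plan.append(("none", 0.0))
    for i in range(n_tadalafil):
        plan.append(("tadalafil", _draw_dose(rng, t_doses, i)))
    for i in range(n_sildenafil):
        plan.append(("sildenafil", _draw_dose(rng, s_doses, i)))

    spectra: list[Spectrum] = []
    rows = []
    for k, (adulterant, dose) in enumerate(plan):
        sid = f"{id_prefix}-{k + 1:03d}"
        recipe = SampleRecipe(
            adulterant=adulterant,
            dose_mg_per_packet=dose,
            m_packet=float(rng.uniform(9.5, 10.5)),
            m=1.0,
            V=2.0,
            confusers=_default_confusers(rng, adulterant != "none"),
        )
        truth = None
        for rep in range(replicates):
            s, truth = make_honey_sample(recipe, acq, seed=rng, sample_id=sid)
            s.meta["replicate"] = rep + 1
            spectra.append(s)
        row = {k2: v for k2, v in truth.items() if k2 != "confusers"}
        row["formulation"] = recipe.confusers.get("formulation", 0.0)
        row["hmf"] = recipe.confusers.get("5-HMF", 0.0)
        rows.append(row)
    truth_df = pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame(
        columns=["adulterant"], index=pd.Index([], name="sample_id")
    )
    return Cohort(spectra=spectra, truth=truth_df)


def training_cohort(
    acq: AcquisitionModel | None = None, seed: int | None = 0, replicates: int = 2
) -> Cohort:
    """Training-set mimic: 5 N / 9 T (12-79 mg/packet) / 3 S (111, 14,
    201 mg/packet), acquired in duplicate (34 spectra by default)."""
    return make_cohort(
        5,
        9,
        3,
        dose_ranges={"tadalafil": TRAINING_T_DOSES, "sildenafil": TRAINING_S_DOSES},
        acq=acq,
        seed=seed,
        replicates=replicates,
        id_prefix="train",
    )


def test_cohort(
    acq: AcquisitionModel | None = None,
    seed: int | None = 1,
    replicates: int = 2,
    n_tadalafil: int = 27,
    dose_range: tuple[float, float] = (12.0, 84.0),
) -> Cohort:
    """Blind test-set mimic: 2 N / 27 T / 2 S with doses in ``dose_range``."""
    return make_cohort(
        2,
        n_tadalafil,
        2,
        dose_ranges={"tadalafil": dose_range, "sildenafil": (60.0, 90.0)},
        acq=acq,
        seed=seed,
        replicates=replicates,
        id_prefix="test",
    )
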