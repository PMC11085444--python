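"""Spectrum I/O and fingerprint preprocessing.

A :class:`Spectrum` is the unit of I/O: a strictly ascending ppm axis, an
intensity vector and free-form metadata.  Preprocessing turns a set of
spectra into the standardized fingerprint matrix the chemometric models
consume: align the TSP reference to 0 ppm, integrate 0.01 ppm bins over the
5.6-9.0 ppm fingerprint (dropping the residual-chloroform window
7.55-7.75 ppm, leaving 320 bins) and divide by the TSP area.

Files are read/written as two-column CSV (``ppm,intensity``) or a minimal
JCAMP-DX subset (AFFN ``##XYDATA=(X++(Y..Y))``); metadata travels in a JSON
sidecar next to the spectrum file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "Spectrum",
    "BinnedMatrix",
    "ParseError",
    "AlignmentError",
    "read_spectrum",
    "write_spectrum",
    "align_to_tsp",
    "integrate",
    "bin_fingerprint",
    "fingerprint_bin_edges",
    "standardize_by_tsp",
    "tsp_area",
    "assemble_matrix",
    "FINGERPRINT_REGION",
    "CHLOROFORM_EXCLUSION",
    "TSP_WINDOW",
    "BIN_WIDTH",
]

FINGERPRINT_REGION = (5.6, 9.0)
CHLOROFORM_EXCLUSION = (7.55, 7.75)
TSP_WINDOW = (-0.05, 0.05)
BIN_WIDTH = 0.01


class ParseError(ValueError):
    """A spectrum file could not be parsed."""


class AlignmentError(ValueError):
    """No usable reference peak found in the alignment window."""


@dataclass
class Spectrum:
    """1D NMR spectrum: ppm axis, intensities and sample metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D and equal length")
        if self.ppm.size < 2:
            raise ValueError("spectrum needs at least two points")
        if np.any(~np.isfinite(self.ppm)) or np.any(~np.isfinite(self.intensity)):
            raise ValueError("spectrum contains non-finite values")
        if np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm axis must be strictly increasing")

    def shifted(self, delta: float) -> "Spectrum":
        """Copy with ``delta`` added to the whole ppm axis."""
        return Spectrum(self.ppm + delta, self.intensity.copy(), dict(self.meta))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_spectrum(spectrum: Spectrum, path: str | Path, format: str | None = None) -> None:
    """Write a spectrum as CSV or JCAMP-DX (+ JSON metadata sidecar)."""
    path = Path(path)
    format = format or _infer_format(path)
    if format == "csv":
        with open(path, "w") as fh:
            fh.write("ppm,intensity\n")
            for x, y in zip(spectrum.ppm, spectrum.intensity):
                fh.write(f"{x:.10g},{y:.10g}\n")
    elif format == "jcamp":
        _write_jcamp(spectrum, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if spectrum.meta:
        with open(_sidecar(path), "w") as fh:
            json.dump(spectrum.meta, fh, indent=1, default=str)


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".dx", ".jdx", ".jcamp"):
        return "jcamp"
    return "csv"


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a CSV or JCAMP-DX spectrum; the axis is re-sorted ascending."""
    path = Path(path)
    format = format or _infer_format(path)
    if format == "csv":
        ppm, intensity = _read_csv(path)
    elif format == "jcamp":
        ppm, intensity = _read_jcamp(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    order = np.argsort(ppm, kind="stable")
    ppm, intensity = ppm[order], intensity[order]
    if np.any(np.diff(ppm) == 0):
        dup = ppm[np.where(np.diff(ppm) == 0)[0][0]]
        raise ParseError(f"{path.name}: duplicated ppm value {dup:g}")
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Spectrum(ppm, intensity, meta)


def _read_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if lineno == 1 and not _is_number(parts[0]):
                continue  # header
            if len(parts) != 2 or not (_is_number(parts[0]) and _is_number(parts[1])):
                raise ParseError(f"{path.name}: malformed record at line {lineno}: {line!r}")
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
    if len(xs) < 2:
        raise ParseError(f"{path.name}: fewer than two data points")
    return np.array(xs), np.array(ys)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _write_jcamp(spectrum: Spectrum, path: Path) -> None:
    y = spectrum.intensity
    yfactor = max(np.abs(y).max(), 1e-300) / 1e9  # 10 significant-ish digits
    scaled = y / yfactor
    lines = [
        "##TITLE=" + str(spectrum.meta.get("sample_id", "honeyscreen spectrum")),
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##NPOINTS={y.size}",
        f"##FIRSTX={spectrum.ppm[0]:.10g}",
        f"##LASTX={spectrum.ppm[-1]:.10g}",
        "##XFACTOR=1",
        f"##YFACTOR={yfactor:.10g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_row = 6
    for i in range(0, y.size, per_row):
        chunk = scaled[i : i + per_row]
        lines.append(
            f"{spectrum.ppm[i]:.10g} " + " ".join(f"{v:.1f}" for v in chunk)
        )
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path) -> tuple[np.ndarray, np.ndarray]:
    header: dict[str, str] = {}
    yvals: list[float] = []
    in_data = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
            elif key == "END":
                in_data = False
            else:
                header[key] = val.strip()
            continue
        if in_data:
            toks = line.split()
            if len(toks) < 2 or not all(_is_number(t) for t in toks):
                raise ParseError(f"{path.name}: malformed XYDATA at line {lineno}: {line!r}")
            yvals.extend(float(t) for t in toks[1:])
    try:
        npoints = int(header["NPOINTS"])
        firstx = float(header["FIRSTX"])
        lastx = float(header["LASTX"])
        yfactor = float(header.get("YFACTOR", "1"))
        xfactor = float(header.get("XFACTOR", "1"))
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path.name}: missing or malformed JCAMP header record ({exc})")
    if len(yvals) != npoints:
        raise ParseError(
            f"{path.name}: NPOINTS={npoints} but {len(yvals)} Y values present"
        )
    x = np.linspace(firstx, lastx, npoints) * xfactor
    y = np.array(yvals) * yfactor
    return x, y


def align_to_tsp(
    spectrum: Spectrum, search_window: tuple[float, float] = (-0.3, 0.3)
) -> Spectrum:
    """Shift the axis so the TSP apex inside ``search_window`` sits at 0 ppm.

    The apex must stand out from the window's robust noise level
    (median + 5 * 1.4826 * MAD); a flat or empty window raises
    :class:`AlignmentError`.
    """
    lo, hi = search_window
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if mask.sum() < 3:
        raise AlignmentError("alignment window outside spectrum axis")
    y = spectrum.intensity[mask]
    x = spectrum.ppm[mask]
    med = np.median(y)
    mad = np.median(np.abs(y - med))
    threshold = med + 5.0 * 1.4826 * mad
    i = int(np.argmax(y))
    if not y[i] > threshold:
        raise AlignmentError("no reference peak above noise in alignment window")
    out = spectrum.shifted(-x[i])
    out.meta["tsp_shift_ppm"] = float(-x[i])
    return out


def _cumulative(spectrum: Spectrum) -> np.ndarray:
    return cumulative_trapezoid(spectrum.intensity, spectrum.ppm, initial=0.0)


def _integral_between(spectrum: Spectrum, cum: np.ndarray, lo: float, hi: float) -> float:
    return float(np.interp(hi, spectrum.ppm, cum) - np.interp(lo, spectrum.ppm, cum))


def integrate(spectrum: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the intensity over [lo, hi] ppm."""
    if lo > hi:
        raise ValueError("integration window has lo > hi")
    if lo < spectrum.ppm[0] or hi > spectrum.ppm[-1]:
        raise ValueError(
            f"integration window [{lo}, {hi}] outside axis "
            f"[{spectrum.ppm[0]:g}, {spectrum.ppm[-1]:g}]"
        )
    if lo == hi:
        return 0.0
    return _integral_between(spectrum, _cumulative(spectrum), lo, hi)


def fingerprint_bin_edges(
    bin_width: float = BIN_WIDTH,
    region: tuple[float, float] = FINGERPRINT_REGION,
    exclusions: tuple[tuple[float, float], ...] = (CHLOROFORM_EXCLUSION,),
) -> np.ndarray:
    """Left edges of the retained fingerprint bins (half-open [lo, lo+w))."""
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    lo, hi = region
    n = int(round((hi - lo) / bin_width))
    left = lo + bin_width * np.arange(n)
    keep = np.ones(n, dtype=bool)
    for ex_lo, ex_hi in exclusions:
        keep &= ~((left < ex_hi) & (left + bin_width > ex_lo))
    return left[keep]


def bin_fingerprint(
    spectrum: Spectrum,
    bin_width: float = BIN_WIDTH,
    region: tuple[float, float] = FINGERPRINT_REGION,
    exclusions: tuple[tuple[float, float], ...] = (CHLOROFORM_EXCLUSION,),
) -> tuple[np.ndarray, np.ndarray]:
    """Integrated area per 0.01 ppm bin over the fingerprint region.

    Bins are half-open [lo, lo+w); bins intersecting an exclusion interval
    are dropped (20 for the chloroform window, leaving 320 by default).
    Returns (bin_centers, areas); bin value is the integrated area, which
    preserves qNMR proportionality under grid changes.
    """
    left = fingerprint_bin_edges(bin_width, region, exclusions)
    if region[0] < spectrum.ppm[0] or region[1] > spectrum.ppm[-1]:
        raise ValueError("spectrum does not cover the fingerprint region")
    cum = _cumulative(spectrum)
    areas = np.array(
        [_integral_between(spectrum, cum, lo, lo + bin_width) for lo in left]
    )
    return left + bin_width / 2.0, areas


def standardize_by_tsp(bins: np.ndarray, tsp_area: float) -> np.ndarray:
    """Divide bin areas by the internal-standard (TSP) area."""
    if not tsp_area > 0:
        raise ValueError("tsp_area must be > 0")
    return np.asarray(bins, dtype=float) / tsp_area


def tsp_area(spectrum: Spectrum, window: tuple[float, float] = TSP_WINDOW) -> float:
    """Integrated TSP reference area around 0 ppm (after alignment)."""
    return integrate(spectrum, *window)


@dataclass
class BinnedMatrix:
    """Samples x fingerprint-bins table after align/bin/standardize."""

    sample_ids: list[str]
    bin_centers: np.ndarray
    values: np.ndarray  # (n_samples, n_bins)
    standardized: bool = True
    meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), self.bin_centers.size):
            raise ValueError("values shape does not match ids/bins")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("binned matrix contains non-finite values")

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{c:.3f}" for c in self.bin_centers],
        )

    def region_columns(self, lo: float, hi: float) -> np.ndarray:
        """Indices of bins whose centres fall inside [lo, hi] ppm."""
        return np.where((self.bin_centers >= lo) & (self.bin_centers <= hi))[0]


def assemble_matrix(
    spectra: list[Spectrum],
    bin_width: float = BIN_WIDTH,
    region: tuple[float, float] = FINGERPRINT_REGION,
    exclusions: tuple[tuple[float, float], ...] = (CHLOROFORM_EXCLUSION,),
    tsp_window: tuple[float, float] = TSP_WINDOW,
    align: bool = True,
) -> BinnedMatrix:
    """Align, bin and TSP-standardize a list of spectra into one matrix.

    Rows keep the input order; per-spectrum failures are re-raised with the
    offending sample id attached.
    """
    edges = fingerprint_bin_edges(bin_width, region, exclusions)
    centers = edges + bin_width / 2.0
    rows, ids, metas = [], [], []
    for k, s in enumerate(spectra):
        sid = str(s.meta.get("sample_id", f"sample-{k}"))
        try:
            aligned = align_to_tsp(s) if align else s
            ref = tsp_area(aligned, tsp_window)
            _, areas = bin_fingerprint(aligned, bin_width, region, exclusions)
            rows.append(standardize_by_tsp(areas, ref))
        except Exception as exc:
            raise type(exc)(f"sample {sid!r}: {exc}") from exc
        ids.append(sid)
        metas.append(dict(s.meta))
    values = np.vstack(rows) if rows else np.empty((0, centers.size))
    return BinnedMatrix(ids, centers, values, standardized=True, meta=metas)
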