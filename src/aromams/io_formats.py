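"""Readers and writers for every external representation the pipeline touches.

Formats handled here:

* MS runs — mzML (read, via pyteomics) or an internal long-format scan CSV
  with columns ``rt_min,mz,intensity`` (read/write).
* Selective-detector channel traces — two-column CSV ``rt_min,intensity``.
* Spectral libraries — MSP text (read/write), with ``Name`` / ``Num Peaks``
  blocks and optional ``CAS#`` / ``Formula`` / ``RI`` / ``RT`` fields.
* n-Alkane ladders — CSV ``carbon_number,rt_min``.
* Identification reports — CSV, JSON or Markdown.

Retention time is minutes everywhere inside the package; seconds found in
inputs (e.g. mzML scan start times) are converted at this boundary.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as _pt_mass
from pyteomics.auxiliary import PyteomicsError

from .errors import EmptyInputError, FormulaError, InputError, ParameterError

logger = logging.getLogger(__name__)

#: Selective-detector channel kinds understood by the pipeline.
DETECTOR_KINDS = ("NPD", "FPD_S", "PFPD")

#: Base-peak value every spectrum is scaled to (NIST convention).
BASE_PEAK = 999.0


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Scan:
    """One centroided mass spectrum at a single retention time."""

    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ParameterError("scan m/z and intensity arrays differ in length")
        if self.mz.size and self.mz.min() <= 0:
            raise ParameterError("scan contains non-positive m/z")
        if self.intensity.size and self.intensity.min() < 0:
            raise ParameterError("scan contains negative intensity")


@dataclass(eq=False)
class MSRun:
    """A time-ordered sequence of centroided scans plus free-form metadata."""

    scans: list[Scan]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt_min for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ParameterError("MSRun scans must be strictly increasing in RT")

    @property
    def rt(self) -> np.ndarray:
        return np.array([s.rt_min for s in self.scans], dtype=float)

    def tic(self) -> np.ndarray:
        """Total ion chromatogram: summed intensity per scan."""
        return np.array([s.intensity.sum() for s in self.scans], dtype=float)

    def __len__(self) -> int:
        return len(self.scans)


@dataclass(eq=False)
class ChannelTrace:
    """A selective detector's chromatogram (one intensity per time point)."""

    detector: str
    rt_min: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.detector not in DETECTOR_KINDS:
            raise ParameterError(
                f"unknown detector {self.detector!r}; expected one of {DETECTOR_KINDS}"
            )
        self.rt_min = np.asarray(self.rt_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt_min.shape != self.intensity.shape:
            raise ParameterError("trace rt and intensity arrays differ in length")
        if self.rt_min.size > 1 and np.any(np.diff(self.rt_min) <= 0):
            raise ParameterError("trace RT must be strictly increasing")
        if self.intensity.size and self.intensity.min() < 0:
            raise ParameterError("trace contains negative intensity")

    def __len__(self) -> int:
        return int(self.rt_min.size)


@dataclass(eq=False)
class LibraryEntry:
    """A reference EI spectrum with identity metadata.

    ``spectrum`` is an ``(n, 2)`` float array of (m/z, relative intensity)
    normalized so the base peak is exactly 999. ``ri_nonpolar`` is a Kovats
    style retention index on a non-polar column; ``expected_rt_min`` is only
    meaningful in user (targeted) libraries.
    """

    name: str
    spectrum: np.ndarray
    cas: str | None = None
    formula: str | None = None
    ri_nonpolar: float | None = None
    expected_rt_min: float | None = None

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.spectrum.ndim != 2 or self.spectrum.shape[1] != 2 or not self.spectrum.size:
            raise ParameterError(f"entry {self.name!r}: spectrum must be a non-empty (n, 2) array")
        self.spectrum = normalize_spectrum(self.spectrum)
        if self.formula is not None:
            parse_formula(self.formula)  # fail fast on unparseable formulas


@dataclass(eq=False)
class SpectralLibrary:
    """An ordered collection of :class:`LibraryEntry` objects."""

    entries: list[LibraryEntry]
    name: str = ""
    kind: str = "public"  # {user, public}

    def __post_init__(self) -> None:
        if self.kind not in ("user", "public"):
            raise ParameterError("library kind must be 'user' or 'public'")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ParameterError(f"duplicate entry names in library: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(eq=False)
class AlkaneLadder:
    """n-Alkane retention calibration points: carbon number vs RT."""

    carbon_numbers: np.ndarray
    rt_min: np.ndarray

    def __post_init__(self) -> None:
        self.carbon_numbers = np.asarray(self.carbon_numbers, dtype=int)
        self.rt_min = np.asarray(self.rt_min, dtype=float)
        if self.carbon_numbers.shape != self.rt_min.shape:
            raise ParameterError("ladder arrays differ in length")
        if self.carbon_numbers.size and self.carbon_numbers.min() < 5:
            raise ParameterError("alkane ladder carbon numbers must be >= 5")
        if np.any(np.diff(self.carbon_numbers) <= 0) or np.any(np.diff(self.rt_min) <= 0):
            raise ParameterError("ladder must be strictly increasing in C number and RT")

    def __len__(self) -> int:
        return int(self.carbon_numbers.size)


# ---------------------------------------------------------------------------
# Spectrum helpers
# ---------------------------------------------------------------------------

def normalize_spectrum(spectrum: np.ndarray) -> np.ndarray:
    """Scale a (m/z, intensity) array so its base peak equals 999.

    Idempotent; peaks with non-positive intensity are dropped.
    """
    spec = np.asarray(spectrum, dtype=float)
    if spec.ndim != 2 or spec.shape[1] != 2:
        raise ParameterError("spectrum must be an (n, 2) array")
    spec = spec[spec[:, 1] > 0]
    if not spec.size:
        raise ParameterError("spectrum has no positive-intensity peaks")
    out = spec.copy()
    out[:, 1] *= BASE_PEAK / out[:, 1].max()
    return out[np.argsort(out[:, 0])]


_FORMULA_TOKEN = re.compile(r"^(?:[A-Z][a-z]?\d*|\(|\)\d*)+$")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    Isotope labels and charges are not supported (not needed for EI work on
    small volatiles). Raises :class:`FormulaError` on anything unparseable.
    """
    text = (formula or "").strip()
    if not text or not _FORMULA_TOKEN.match(text):
        raise FormulaError(f"cannot parse molecular formula {formula!r}")
    try:
        comp = _pt_mass.Composition(formula=text)
    except PyteomicsError as exc:
        raise FormulaError(f"cannot parse molecular formula {formula!r}") from exc
    counts = {el: int(n) for el, n in comp.items() if n}
    if any(n < 0 for n in counts.values()):
        raise FormulaError(f"negative element count in {formula!r}")
    return counts


_NOMINAL_MASS = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "P": 31,
                 "F": 19, "Cl": 35, "Br": 79, "Si": 28}


def nominal_mass(formula: str) -> int:
    """Nominal (integer, most-abundant-isotope) molecular mass of a formula."""
    counts = parse_formula(formula)
    try:
        return sum(_NOMINAL_MASS[el] * n for el, n in counts.items())
    except KeyError as exc:
        raise FormulaError(f"no nominal mass table entry for element {exc}") from None


# ---------------------------------------------------------------------------
# MS runs
# ---------------------------------------------------------------------------

def read_msrun(path: str | Path, format: str = "auto") -> MSRun:
    """Read an MS run from mzML or the internal scan CSV.

    ``format`` may be ``mzml``, ``scan_csv`` or ``auto`` (by extension).
    Scans found out of RT order are sorted with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"MS run file not found: {path}")
    if format == "auto":
        format = "mzml" if path.suffix.lower() == ".mzml" else "scan_csv"
    if format == "mzml":
        scans = _read_mzml_scans(path)
    elif format == "scan_csv":
        scans = _read_scan_csv(path)
    else:
        raise ParameterError(f"unknown MS run format {format!r}")
    if not scans:
        raise EmptyInputError(f"no scans found in {path}")
    rts = [s.rt_min for s in scans]
    if any(b <= a for a, b in zip(rts, rts[1:])):
        logger.warning("scans in %s were out of RT order; sorting", path)
        scans.sort(key=lambda s: s.rt_min)
    return MSRun(scans=scans, metadata={"source": str(path), "format": format})


def _read_scan_csv(path: Path) -> list[Scan]:
    by_rt: dict[float, list[tuple[float, float]]] = {}
    order: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or row[0].strip().lower() in ("rt_min", "rt"):
                continue
            try:
                rt, mz, inten = float(row[0]), float(row[1]), float(row[2])
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}: bad scan row {i + 1}: {row!r}") from exc
            if rt not in by_rt:
                by_rt[rt] = []
                order.append(rt)
            by_rt[rt].append((mz, inten))
    scans = []
    for rt in order:
        peaks = sorted(by_rt[rt])
        mzs = np.array([p[0] for p in peaks])
        ints = np.array([p[1] for p in peaks])
        scans.append(Scan(rt_min=rt, mz=mzs, intensity=ints))
    return scans


#: mzML controlled-vocabulary accessions this reader understands
_MZML_CV = {
    "ms_level": "MS:1000511",
    "scan_start_time": "MS:1000016",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
    "float64": "MS:1000523",
    "float32": "MS:1000521",
    "no_compression": "MS:1000576",
    "zlib": "MS:1000574",
    "profile": "MS:1000128",
}


def _read_mzml_scans(path: Path) -> list[Scan]:
    """Minimal mzML reader for centroided (or locally-maximum-picked
    profile) MS1 spectra: base64 float32/float64 arrays, plain or
    zlib-compressed."""
    from lxml import etree

    def local(tag):
        return etree.QName(tag).localname

    scans: list[Scan] = []
    try:
        for _, spectrum in etree.iterparse(str(path), events=("end",),
                                           tag="{*}spectrum"):
            info = _parse_mzml_spectrum(spectrum, local)
            spectrum.clear(keep_tail=True)
            if info is None:
                continue
            rt, mz, inten, is_profile = info
            if is_profile:
                logger.info("centroiding profile spectrum at %.4f min by local maxima", rt)
                mz, inten = _centroid_profile(mz, inten)
            keep = inten > 0
            scans.append(Scan(rt_min=rt, mz=mz[keep], intensity=inten[keep]))
    except etree.XMLSyntaxError as exc:
        raise InputError(f"cannot parse mzML file {path}: {exc}") from exc
    return scans


def _parse_mzml_spectrum(spectrum, local):
    import base64
    import zlib

    accessions = {}
    for cv in spectrum.iter("{*}cvParam"):
        accessions[cv.get("accession")] = cv
    ms_level = accessions.get(_MZML_CV["ms_level"])
    if ms_level is not None and ms_level.get("value") not in ("", "1", None):
        return None
    rt_param = accessions.get(_MZML_CV["scan_start_time"])
    if rt_param is None:
        raise InputError("mzML spectrum lacks a scan start time")
    rt = float(rt_param.get("value"))
    if "second" in (rt_param.get("unitName") or "").lower():
        rt /= 60.0
    arrays = {}
    for bda in spectrum.iter("{*}binaryDataArray"):
        accs = {cv.get("accession") for cv in bda.iter("{*}cvParam")}
        binary = bda.find("{*}binary")
        raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
        if _MZML_CV["zlib"] in accs:
            raw = zlib.decompress(raw)
        dtype = "<f4" if _MZML_CV["float32"] in accs else "<f8"
        values = np.frombuffer(raw, dtype=dtype).astype(float)
        if _MZML_CV["mz_array"] in accs:
            arrays["mz"] = values
        elif _MZML_CV["intensity_array"] in accs:
            arrays["intensity"] = values
    if "mz" not in arrays or "intensity" not in arrays:
        raise InputError("mzML spectrum lacks m/z or intensity arrays")
    return rt, arrays["mz"], arrays["intensity"], _MZML_CV["profile"] in accessions


def _centroid_profile(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pick local maxima out of a profile-mode point series."""
    if mz.size < 3:
        return mz, inten
    is_max = (inten[1:-1] >= inten[:-2]) & (inten[1:-1] > inten[2:]) & (inten[1:-1] > 0)
    idx = np.where(is_max)[0] + 1
    return mz[idx], inten[idx]


def write_msrun(run: MSRun, path: str | Path) -> Path:
    """Write an MS run as the internal long-format scan CSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rt_min", "mz", "intensity"])
        for scan in run.scans:
            for mz, inten in zip(scan.mz, scan.intensity):
                writer.writerow([repr(float(scan.rt_min)), repr(float(mz)), repr(float(inten))])
    return path


# ---------------------------------------------------------------------------
# Channel traces
# ---------------------------------------------------------------------------

def read_channel_trace(path: str | Path, detector: str) -> ChannelTrace:
    """Read a two-column ``rt_min,intensity`` CSV as a detector trace."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"channel trace file not found: {path}")
    rts, ints = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or row[0].strip().lower() in ("rt_min", "rt"):
                continue
            try:
                rts.append(float(row[0]))
                ints.append(float(row[1]))
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}: non-numeric trace row {i + 1}: {row!r}") from exc
    if not rts:
        raise EmptyInputError(f"no points found in {path}")
    return ChannelTrace(detector=detector, rt_min=np.array(rts), intensity=np.array(ints))


def write_channel_trace(trace: ChannelTrace, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rt_min", "intensity"])
        for rt, inten in zip(trace.rt_min, trace.intensity):
            writer.writerow([repr(float(rt)), repr(float(inten))])
    return path


# ---------------------------------------------------------------------------
# Alkane ladders
# ---------------------------------------------------------------------------

def read_alkane_ladder(path: str | Path) -> AlkaneLadder:
    """Read a ``carbon_number,rt_min`` CSV alkane calibration table."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"alkane ladder file not found: {path}")
    carbons, rts = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or row[0].strip().lower() in ("carbon_number", "c", "carbon"):
                continue
            try:
                carbons.append(int(float(row[0])))
                rts.append(float(row[1]))
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}: bad ladder row {i + 1}: {row!r}") from exc
    if not carbons:
        raise EmptyInputError(f"no rungs found in {path}")
    return AlkaneLadder(carbon_numbers=np.array(carbons), rt_min=np.array(rts))


def write_alkane_ladder(ladder: AlkaneLadder, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["carbon_number", "rt_min"])
        for c, rt in zip(ladder.carbon_numbers, ladder.rt_min):
            writer.writerow([int(c), repr(float(rt))])
    return path


# ---------------------------------------------------------------------------
# MSP spectral libraries
# ---------------------------------------------------------------------------

_MSP_PEAK_PAIR = re.compile(r"(\d+(?:\.\d+)?)[\s:]+(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)")


def read_msp_library(path: str | Path, name: str | None = None,
                     kind: str = "public") -> SpectralLibrary:
    """Parse an MSP spectral library.

    Accepts both ``mz intensity; mz intensity;`` and one-pair-per-line
    (space or tab separated) peak styles; field names are case-insensitive.
    Entries whose peak count disagrees with ``Num Peaks``, or that carry no
    spectrum at all, are rejected with a warning rather than aborting the
    whole read.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"MSP library file not found: {path}")
    entries: list[LibraryEntry] = []
    for block in _msp_blocks(path):
        entry = _parse_msp_block(block, path)
        if entry is not None:
            entries.append(entry)
    if not entries:
        raise EmptyInputError(f"no parseable entries in MSP library {path}")
    return SpectralLibrary(entries=entries, name=name or path.stem, kind=kind)


def _msp_blocks(path: Path) -> Iterable[list[str]]:
    block: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.strip().lower().startswith("name:") and block:
                yield block
                block = []
            if line.strip():
                block.append(line)
        if block:
            yield block


def _parse_msp_block(lines: list[str], path: Path) -> LibraryEntry | None:
    fields: dict[str, str] = {}
    peak_lines: list[str] = []
    declared = None
    for line in lines:
        m = re.match(r"^\s*([A-Za-z][A-Za-z0-9 #_/.-]*?)\s*:\s*(.*)$", line)
        if m and not _MSP_PEAK_PAIR.fullmatch(line.strip().rstrip(";")):
            key = re.sub(r"[\s#_]", "", m.group(1)).lower()
            fields[key] = m.group(2).strip()
            if key == "numpeaks":
                declared = fields[key]
        else:
            peak_lines.append(line)
    entry_name = fields.get("name", "<unnamed>")
    pairs: list[tuple[float, float]] = []
    for line in peak_lines:
        for mz_s, int_s in _MSP_PEAK_PAIR.findall(line):
            pairs.append((float(mz_s), float(int_s)))
    if declared is not None:
        try:
            n_declared = int(declared)
        except ValueError:
            logger.warning("%s: entry %r has unreadable Num Peaks; rejected", path, entry_name)
            return None
        if n_declared != len(pairs):
            logger.warning(
                "%s: entry %r declares %d peaks but %d parsed; rejected",
                path, entry_name, n_declared, len(pairs))
            return None
    if not pairs or all(i <= 0 for _, i in pairs):
        logger.warning("%s: entry %r has no spectrum; rejected", path, entry_name)
        return None
    cas = fields.get("cas") or fields.get("casno") or None
    formula = fields.get("formula") or None
    if formula is not None:
        try:
            parse_formula(formula)
        except FormulaError:
            logger.warning("%s: entry %r has unparseable formula %r; dropping it",
                           path, entry_name, formula)
            formula = None
    ri = _maybe_float(fields.get("retentionindex") or fields.get("ri"))
    rt = _maybe_float(fields.get("rt") or fields.get("expectedrt"))
    try:
        return LibraryEntry(name=entry_name, spectrum=np.array(pairs), cas=cas,
                            formula=formula, ri_nonpolar=ri, expected_rt_min=rt)
    except ParameterError as exc:
        logger.warning("%s: entry %r rejected: %s", path, entry_name, exc)
        return None


def _maybe_float(text: str | None) -> float | None:
    if text is None or not text.strip():
        return None
    try:
        return float(text)
    except ValueError:
        return None


def write_msp_library(library: SpectralLibrary, path: str | Path) -> Path:
    """Write a library in MSP text format (one pair per line)."""
    path = Path(path)
    with open(path, "w") as fh:
        for entry in library.entries:
            fh.write(f"Name: {entry.name}\n")
            if entry.cas:
                fh.write(f"CAS#: {entry.cas}\n")
            if entry.formula:
                fh.write(f"Formula: {entry.formula}\n")
            if entry.ri_nonpolar is not None:
                fh.write(f"RI: {entry.ri_nonpolar:g}\n")
            if entry.expected_rt_min is not None:
                fh.write(f"RT: {entry.expected_rt_min:g}\n")
            fh.write(f"Num Peaks: {len(entry.spectrum)}\n")
            for mz, inten in entry.spectrum:
                fh.write(f"{mz:g} {inten:g}\n")
            fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

#: Column order of the tabular report; mirrors what the screening workflow
#: reports for each compound (RT, name, CAS, Match/RMatch/Probability, S/N,
#: area, RI check, detector indications).
REPORT_COLUMNS = (
    "rt_min", "name", "cas", "match", "reverse_match", "probability_pct",
    "snr", "area", "delta_ri", "ri_extrapolated", "verdict", "elements",
    "detector", "unidentified_channel_peak", "mode",
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isinf(value):
            return "inf"
        return f"{value:.6g}"
    return str(value)


def record_to_row(record) -> dict[str, str]:
    """Flatten an identification record into report cells (all strings)."""
    ver = getattr(record, "verification", None)
    elements = ""
    verdict = ""
    if ver is not None:
        verdict = ver.verdict
        elements = ";".join(f"{el}:{state}" for el, state in sorted(ver.elements.items()))
    return {
        "rt_min": _fmt(record.rt_min),
        "name": _fmt(record.name),
        "cas": _fmt(record.cas),
        "match": _fmt(record.match),
        "reverse_match": _fmt(record.reverse_match),
        "probability_pct": _fmt(record.probability_pct),
        "snr": _fmt(record.snr),
        "area": _fmt(record.area),
        "delta_ri": _fmt(record.delta_ri),
        "ri_extrapolated": _fmt(record.ri_extrapolated),
        "verdict": verdict,
        "elements": elements,
        "detector": _fmt(record.detector),
        "unidentified_channel_peak": _fmt(record.unidentified_channel_peak),
        "mode": _fmt(record.mode),
    }


def write_report(records: Sequence, mode: str, verified_only: bool,
                 path: str | Path, format: str = "csv") -> Path:
    """Write identification records, RT-sorted, in csv/json/markdown.

    ``verified_only`` is recorded in the report header/metadata; filtering
    to the verified view is the screening module's job.
    """
    if mode not in ("targeted", "nontargeted"):
        raise ParameterError(f"unknown mode {mode!r}")
    if format not in ("csv", "json", "markdown"):
        raise ParameterError(f"unknown report format {format!r}")
    path = Path(path)
    ordered = sorted(records, key=lambda r: (r.rt_min, r.name or ""))
    rows = [record_to_row(r) for r in ordered]
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(REPORT_COLUMNS))
            writer.writeheader()
            writer.writerows(rows)
    elif format == "json":
        payload = {
            "mode": mode,
            "verified_only": bool(verified_only),
            "records": [
                dict(row, alternates=getattr(rec, "alternates", None) or [])
                for rec, row in zip(ordered, rows)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        with open(path, "w") as fh:
            fh.write("| " + " | ".join(REPORT_COLUMNS) + " |\n")
            fh.write("|" + "---|" * len(REPORT_COLUMNS) + "\n")
            for row in rows:
                fh.write("| " + " | ".join(row[c] for c in REPORT_COLUMNS) + " |\n")
    return path
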