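"""Selective-detector verification of heteroatom-containing identifications.

A GC-MS/NPD/(P)FPD(S) system splits the column flow to detectors that
respond only to nitrogen (NPD) or sulfur (FPD in S mode, PFPD), recorded
in parallel with the MS. Because flows are constant, each channel lags the
MS by a stable, per-detector offset. A candidate identification whose
formula contains N or S is therefore checked by looking for a channel
peak at the component RT plus the channel lag, within a tolerance window;
heteroatom-free candidates are out of the detectors' reach and marked
not-applicable rather than verified.

Default channel timing follows the correlation windows used in practice
for this detector combination: NPD and FPD(S) lag the MS by 0.01 min,
the PFPD by 0.05 min (electronic gating delay), all with a +/- 0.02 min
tolerance.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .deconvolution import (DeconvolutionConfig, EIC, _safe_snr,
                            detect_trace_peaks, estimate_noise)
from .errors import InputError, ParameterError
from .io_formats import DETECTOR_KINDS, ChannelTrace, parse_formula

logger = logging.getLogger(__name__)

#: heteroatoms that element-selective detectors can report
VERIFIABLE_ELEMENTS = frozenset({"N", "S", "P"})

CONFIRMED = "confirmed"
NOT_CONFIRMED = "not_confirmed"
NO_CHANNEL = "no_channel"

VERIFIED = "verified"
REJECTED = "rejected"
NOT_APPLICABLE = "not_applicable"


@dataclass
class ChannelConfig:
    """Timing and element coverage of one selective-detector channel."""

    detector: str
    elements: frozenset[str]
    lag_min: float
    tolerance_min: float

    def __post_init__(self) -> None:
        if self.detector not in DETECTOR_KINDS:
            raise ParameterError(f"unknown detector {self.detector!r}")
        self.elements = frozenset(self.elements)
        if not self.elements:
            raise ParameterError("channel must cover at least one element")
        if self.tolerance_min <= 0:
            raise ParameterError("tolerance_min must be positive")


def default_channel_configs() -> dict[str, ChannelConfig]:
    """Per-detector defaults: lag 0.01/0.01/0.05 min, tolerance 0.02 min."""
    return {
        "NPD": ChannelConfig("NPD", frozenset({"N"}), lag_min=0.01, tolerance_min=0.02),
        "FPD_S": ChannelConfig("FPD_S", frozenset({"S"}), lag_min=0.01, tolerance_min=0.02),
        "PFPD": ChannelConfig("PFPD", frozenset({"S"}), lag_min=0.05, tolerance_min=0.02),
    }


@dataclass
class DetectorPeak:
    """An integrated peak in one selective-detector chromatogram."""

    detector: str
    apex_rt_min: float
    height: float
    area: float
    snr: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.area <= 0:
            raise ParameterError("detector peak height and area must be positive")


@dataclass
class VerificationResult:
    """Per-element confirmation states and the overall verdict."""

    elements: dict[str, str] = field(default_factory=dict)
    matched_peaks: list[DetectorPeak] = field(default_factory=list)
    verdict: str = NOT_APPLICABLE
    warning: str | None = None


# ---------------------------------------------------------------------------
# Channel peak integration
# ---------------------------------------------------------------------------

def integrate_channel(trace: ChannelTrace,
                      config: DeconvolutionConfig | None = None) -> list[DetectorPeak]:
    """Detect and integrate peaks in a selective-detector trace.

    Reuses the same prominence/shape peak perception as the MS traces and
    returns peaks sorted by apex RT.
    """
    config = config or DeconvolutionConfig()
    pseudo = EIC(mz=0.0, rt_min=trace.rt_min, intensity=trace.intensity)
    noise = estimate_noise(trace.intensity) if len(trace) >= 16 else 0.0
    peaks = detect_trace_peaks(pseudo, config, noise=noise)
    return [DetectorPeak(detector=trace.detector, apex_rt_min=p.apex_rt_min,
                         height=p.height, area=p.area,
                         snr=_safe_snr(p.height, p.noise))
            for p in sorted(peaks, key=lambda q: q.apex_rt_min)]


def read_detector_peaks(path: str | Path, detector: str | None = None) -> list[DetectorPeak]:
    """Import a pre-integrated channel peak list.

    CSV columns ``detector,apex_rt_min,height,area`` — the shape of an
    integrator's percent report — bypassing :func:`integrate_channel`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"detector peak list not found: {path}")
    peaks: list[DetectorPeak] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or row[0].strip().lower() == "detector":
                continue
            try:
                det = row[0].strip()
                rt, height, area = float(row[1]), float(row[2]), float(row[3])
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}: bad peak row {i + 1}: {row!r}") from exc
            if detector is not None and det != detector:
                continue
            peaks.append(DetectorPeak(detector=det, apex_rt_min=rt,
                                      height=height, area=area, snr=float("inf")))
    return sorted(peaks, key=lambda p: p.apex_rt_min)


# ---------------------------------------------------------------------------
# Formula -> heteroatoms
# ---------------------------------------------------------------------------

def heteroatoms(formula: str) -> frozenset[str]:
    """The verifiable heteroatoms (N, S, P) present in a molecular formula."""
    counts = parse_formula(formula)
    return frozenset(el for el in VERIFIABLE_ELEMENTS if counts.get(el, 0) >= 1)


# ---------------------------------------------------------------------------
# Alignment and verification
# ---------------------------------------------------------------------------

def align(component_rt_min: float, channel_peaks: list[DetectorPeak],
          config: ChannelConfig) -> DetectorPeak | None:
    """Match a component to the nearest channel peak under lag + tolerance.

    The expected channel RT is the component RT plus the channel lag; the
    peak minimizing the absolute residual wins if that residual is within
    the tolerance, with ties going to the earlier peak. Peaks are not
    consumed: one broad channel peak may vouch for several co-eluting
    components.
    """
    expected = component_rt_min + config.lag_min
    best: DetectorPeak | None = None
    best_residual = math.inf
    for peak in sorted(channel_peaks, key=lambda p: p.apex_rt_min):
        residual = abs(peak.apex_rt_min - expected)
        if residual > config.tolerance_min:
            continue
        # earlier peak wins residual ties (compared to sub-ns slack)
        if residual < best_residual - 1e-9:
            best, best_residual = peak, residual
    return best


def verify(component_rt_min: float, formula: str | None,
           channels: list[tuple[ChannelConfig, list[DetectorPeak]]],
           policy: str = "all_elements") -> VerificationResult:
    """Check a candidate's heteroatoms against the selective channels.

    Every heteroatom covered by at least one active channel is confirmed
    iff some covering channel has an aligned peak. Under the default
    ``all_elements`` policy the verdict is verified only when all covered
    heteroatoms are confirmed (a thiazole needs both the N and the S
    channel); ``any_element`` accepts a single confirmation. Formulas with
    no covered heteroatom — or missing formulas — yield not_applicable.
    """
    if policy not in ("all_elements", "any_element"):
        raise ParameterError(f"unknown verification policy {policy!r}")
    if formula is None:
        return VerificationResult(verdict=NOT_APPLICABLE,
                                  warning="candidate has no molecular formula")
    atoms = heteroatoms(formula)
    active = frozenset().union(*(cfg.elements for cfg, _ in channels)) if channels else frozenset()
    states: dict[str, str] = {}
    matched: list[DetectorPeak] = []
    for el in sorted(atoms):
        if el not in active:
            states[el] = NO_CHANNEL
            continue
        hit = None
        for cfg, peaks in channels:
            if el not in cfg.elements:
                continue
            hit = align(component_rt_min, peaks, cfg)
            if hit is not None:
                break
        if hit is not None:
            states[el] = CONFIRMED
            matched.append(hit)
        else:
            states[el] = NOT_CONFIRMED
    covered = [el for el in atoms if states.get(el) != NO_CHANNEL]
    if not covered:
        return VerificationResult(elements=states, verdict=NOT_APPLICABLE)
    confirmed = [el for el in covered if states[el] == CONFIRMED]
    if policy == "all_elements":
        verdict = VERIFIED if len(confirmed) == len(covered) else REJECTED
    else:
        verdict = VERIFIED if confirmed else REJECTED
    return VerificationResult(elements=states, matched_peaks=matched, verdict=verdict)
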