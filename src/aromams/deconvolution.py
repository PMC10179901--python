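"""TIC deconvolution: from raw scans to candidate compound components.

The algorithm is a deliberately transparent take on the classic
component-perception approach used by AMDIS-style tools:

1. rebin the run into nominal-mass extracted-ion chromatograms (EICs);
2. estimate per-trace noise from median absolute successive differences;
3. detect peaks per trace (prominence-over-noise gate plus a Gaussian
   shape-correlation gate), with boundaries at the flanking minima;
4. group trace peaks whose apexes coincide (within a small scan window)
   into components, subtract modeled contributions of adjacent components
   from shared traces, and emit each component's spectrum as the vector of
   member peak areas normalized to base peak 999.

Defaults mirror typical balanced settings for capillary GC-EI work:
component width 10 scans, adjacent-peak subtraction of one neighbor per
side, medium sensitivity (S/N >= 5), medium shape requirement
(correlation >= 0.7), high resolution (apex grouping window of 2 scans).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import ParameterError
from .io_formats import BASE_PEAK, MSRun

logger = logging.getLogger(__name__)

#: Sensitivity presets: minimum peak prominence over noise.
SENSITIVITY_SNR = {"low": 10.0, "medium": 5.0, "high": 2.5}

#: Shape-requirement presets: minimum correlation with a Gaussian model peak.
SHAPE_CORRELATION = {"low": 0.5, "medium": 0.7, "high": 0.85}

#: Scale between median |successive difference| and Gaussian sigma:
#: for iid N(0, s^2) noise, median|x[i+1]-x[i]| = s * sqrt(2) * PHI^-1(3/4).
_DIFF_TO_SIGMA = math.sqrt(2.0) * 0.674489750196082


@dataclass
class DeconvolutionConfig:
    """Settings controlling peak perception and component assembly."""

    component_width_scans: int = 10
    adjacent_subtraction_levels: int = 1
    sensitivity: str = "medium"
    shape_requirement: str = "medium"
    apex_grouping_window_scans: int = 2
    mz_bin_width: float = 1.0
    #: a component must be supported by at least this many m/z traces; a
    #: single-trace "component" is indistinguishable from a noise spike.
    min_member_traces: int = 2

    def __post_init__(self) -> None:
        if self.component_width_scans < 3:
            raise ParameterError("component_width_scans must be >= 3")
        if self.sensitivity not in SENSITIVITY_SNR:
            raise ParameterError(f"unknown sensitivity {self.sensitivity!r}")
        if self.shape_requirement not in SHAPE_CORRELATION:
            raise ParameterError(f"unknown shape requirement {self.shape_requirement!r}")
        if self.apex_grouping_window_scans < 1:
            raise ParameterError("apex_grouping_window_scans must be >= 1")
        if self.adjacent_subtraction_levels < 0:
            raise ParameterError("adjacent_subtraction_levels must be >= 0")
        if self.mz_bin_width <= 0:
            raise ParameterError("mz_bin_width must be positive")
        if self.min_member_traces < 1:
            raise ParameterError("min_member_traces must be >= 1")

    @property
    def snr_threshold(self) -> float:
        return SENSITIVITY_SNR[self.sensitivity]

    @property
    def shape_threshold(self) -> float:
        return SHAPE_CORRELATION[self.shape_requirement]

    @property
    def model_sigma_scans(self) -> float:
        """Sigma of the Gaussian model peak; component width spans ~4 sigma."""
        return self.component_width_scans / 4.0


@dataclass(eq=False)
class EIC:
    """One extracted-ion chromatogram covering the run's full RT axis."""

    mz: float
    rt_min: np.ndarray
    intensity: np.ndarray

    def __len__(self) -> int:
        return int(self.rt_min.size)


@dataclass
class TracePeak:
    """A single chromatographic peak in one m/z trace."""

    mz: float
    apex_idx: int
    apex_rt_min: float
    height: float
    area: float
    left_rt_min: float
    right_rt_min: float
    shape_score: float
    noise: float


@dataclass(eq=False)
class DeconvolvedComponent:
    """One eluting compound candidate with its extracted spectrum."""

    apex_rt_min: float
    spectrum: np.ndarray  # (n, 2): m/z, relative intensity (base peak 999)
    area: float
    height: float
    snr: float
    model_mzs: list[float] = field(default_factory=list)
    members: list[TracePeak] = field(default_factory=list)


# ---------------------------------------------------------------------------
# EIC extraction
# ---------------------------------------------------------------------------

def extract_eics(run: MSRun, mz_bin_width: float = 1.0) -> list[EIC]:
    """Rebin a run into per-m/z traces spanning the full RT axis.

    Bin centers are integer multiples of ``mz_bin_width`` (unit bins
    centered on nominal masses by default); scans that lack a bin
    contribute zero there, so every EIC has one point per scan and the sum
    of all EICs reproduces the TIC exactly.
    """
    if mz_bin_width <= 0:
        raise ParameterError("mz_bin_width must be positive")
    if not run.scans:
        raise ParameterError("cannot extract EICs from an empty run")
    rt = run.rt
    n = len(run)
    sizes = [scan.mz.size for scan in run.scans]
    if not any(sizes):
        return []
    all_mz = np.concatenate([scan.mz for scan in run.scans if scan.mz.size])
    all_int = np.concatenate([scan.intensity for scan in run.scans if scan.mz.size])
    scan_idx = np.repeat(np.arange(n), sizes)
    bins = np.rint(all_mz / mz_bin_width).astype(np.int64)
    uniq, col_idx = np.unique(bins, return_inverse=True)
    matrix = np.zeros((uniq.size, n))
    np.add.at(matrix, (col_idx, scan_idx), all_int)
    return [EIC(mz=float(b) * mz_bin_width, rt_min=rt, intensity=matrix[i])
            for i, b in enumerate(uniq)]


# ---------------------------------------------------------------------------
# Noise and per-trace peak detection
# ---------------------------------------------------------------------------

def estimate_noise(intensity: np.ndarray) -> float:
    """Robust noise amplitude of a trace.

    Median absolute successive difference scaled to the standard deviation
    it would imply for iid Gaussian noise. Peaks occupy few points, so
    they barely move the median; a constant trace returns exactly 0, and
    the estimate is invariant to adding any constant offset.
    """
    x = np.asarray(intensity, dtype=float)
    if x.size < 16:
        raise ParameterError("need at least 16 points to estimate noise")
    med = float(np.median(np.abs(np.diff(x))))
    return med / _DIFF_TO_SIGMA


def _flanking_minimum(x: np.ndarray, apex: int, step: int) -> int:
    """Walk from the apex until the trace stops descending (plateau-tolerant)."""
    i = apex
    last = x.size - 1
    while 0 < i < last if step < 0 else i < last:
        j = i + step
        if j < 0 or j > last:
            break
        if x[j] > x[i]:
            break
        i = j
    return i


def _gaussian_shape_score(x: np.ndarray, apex: int, sigma_scans: float) -> float:
    """Pearson correlation of the apex neighborhood with a Gaussian model."""
    half = max(2, int(round(2 * sigma_scans)))
    lo = max(0, apex - half)
    hi = min(x.size, apex + half + 1)
    seg = x[lo:hi].astype(float)
    if seg.size < 3 or np.ptp(seg) == 0:
        return 0.0
    offsets = np.arange(lo, hi) - apex
    model = np.exp(-0.5 * (offsets / sigma_scans) ** 2)
    r = np.corrcoef(seg, model)[0, 1]
    return float(r) if np.isfinite(r) else 0.0


def detect_trace_peaks(trace: EIC, config: DeconvolutionConfig | None = None,
                       noise: float | None = None) -> list[TracePeak]:
    """Find chromatographic peaks in one trace.

    A local maximum becomes a peak when its height above the trace
    baseline (the trace median — EICs are baseline almost everywhere)
    exceeds the sensitivity threshold times the trace noise, and its
    neighborhood correlates with a Gaussian of the configured width at
    or above the shape threshold. Boundaries sit at the flanking minima;
    the area is the trapezoidal integral above the linear baseline
    joining them. With zero estimated noise (an ideal noiseless trace)
    any positive prominence passes the sensitivity gate.
    """
    config = config or DeconvolutionConfig()
    x = np.asarray(trace.intensity, dtype=float)
    rt = np.asarray(trace.rt_min, dtype=float)
    if noise is None:
        noise = estimate_noise(x) if x.size >= 16 else 0.0
    apexes, _ = _signal.find_peaks(x)
    if not apexes.size:
        return []
    prominences = _signal.peak_prominences(x, apexes)[0]
    baseline_level = float(np.median(x))
    peaks: list[TracePeak] = []
    for apex, prom in zip(apexes, prominences):
        if prom <= 0:
            continue
        if noise > 0 and (x[apex] - baseline_level) < config.snr_threshold * noise:
            continue
        score = _gaussian_shape_score(x, int(apex), config.model_sigma_scans)
        if score < config.shape_threshold:
            continue
        left = _flanking_minimum(x, int(apex), -1)
        right = _flanking_minimum(x, int(apex), +1)
        if not (left < apex < right):
            continue
        seg_rt = rt[left:right + 1]
        seg = x[left:right + 1]
        baseline = np.linspace(x[left], x[right], seg.size)
        area = float(np.trapezoid(np.clip(seg - baseline, 0.0, None), seg_rt))
        if area <= 0:
            continue
        peaks.append(TracePeak(
            mz=trace.mz, apex_idx=int(apex), apex_rt_min=float(rt[apex]),
            height=float(prom), area=area,
            left_rt_min=float(rt[left]), right_rt_min=float(rt[right]),
            shape_score=score, noise=float(noise)))
    return peaks


# ---------------------------------------------------------------------------
# Component assembly
# ---------------------------------------------------------------------------

def _safe_snr(height: float, noise: float) -> float:
    """height/noise, treating vanishing noise as a noiseless trace."""
    if noise <= height * 1e-12:
        return float("inf")
    return height / noise


def _group_trace_peaks(peaks: list[TracePeak], window: int) -> list[list[TracePeak]]:
    """Cluster trace peaks by apex scan index.

    Groups are seeded by the tallest unassigned peak; each remaining peak
    joins the group whose seed apex is nearest (within ``window`` scans),
    with exact distance ties going to the earlier-RT group.
    """
    order = sorted(peaks, key=lambda p: (-p.height, p.apex_idx, p.mz))
    seeds: list[int] = []
    groups: list[list[TracePeak]] = []
    for peak in order:
        best = None
        best_key = None
        for gi, seed in enumerate(seeds):
            dist = abs(peak.apex_idx - seed)
            if dist > window:
                continue
            key = (dist, seed)  # nearer apex wins; ties -> earlier RT
            if best_key is None or key < best_key:
                best, best_key = gi, key
        if best is None:
            seeds.append(peak.apex_idx)
            groups.append([peak])
        else:
            groups[best].append(peak)
    return groups


def _gaussian_overlap_area(height: float, apex_rt: float, sigma_rt: float,
                           lo: float, hi: float) -> float:
    """Integral of height*exp(-(t-apex)^2 / 2 sigma^2) over [lo, hi]."""
    if sigma_rt <= 0:
        return 0.0
    z_lo = (lo - apex_rt) / (sigma_rt * math.sqrt(2.0))
    z_hi = (hi - apex_rt) / (sigma_rt * math.sqrt(2.0))
    return height * sigma_rt * math.sqrt(math.pi / 2.0) * (math.erf(z_hi) - math.erf(z_lo))


def _subtract_adjacent(groups: list[list[TracePeak]], config: DeconvolutionConfig,
                       scan_interval: float) -> list[list[TracePeak]]:
    """Remove modeled contributions of neighboring components from shared traces.

    Each neighbor's member peak is modeled as a Gaussian at its own apex
    with the configured model width; its integral over this component's
    peak window is subtracted from the member area. Members whose area is
    consumed entirely are dropped.
    """
    levels = config.adjacent_subtraction_levels
    if levels == 0 or len(groups) < 2:
        return groups
    sigma_rt = config.model_sigma_scans * scan_interval
    mz_maps = [{p.mz: p for p in g} for g in groups]
    adjusted: list[list[TracePeak]] = []
    for gi, group in enumerate(groups):
        kept: list[TracePeak] = []
        for peak in group:
            area = peak.area
            for gj in range(max(0, gi - levels), min(len(groups), gi + levels + 1)):
                if gj == gi:
                    continue
                other = mz_maps[gj].get(peak.mz)
                if other is None:
                    continue
                area -= _gaussian_overlap_area(
                    other.height, other.apex_rt_min, sigma_rt,
                    peak.left_rt_min, peak.right_rt_min)
            if area > 0:
                if area != peak.area:
                    peak = TracePeak(**{**peak.__dict__, "area": area})
                kept.append(peak)
        adjusted.append(kept)
    return adjusted


#: completed-spectrum inclusion threshold in integrated-noise sigmas
_COMPLETION_SIGMAS = 2.5

#: drop completed-spectrum entries below this relative intensity (sub-LSB
#: on the 0-999 scale)
_MIN_REL_INTENSITY = 0.5


def _complete_spectrum(group: list[TracePeak], apex_rt: float,
                       eics: list[EIC], noises: list[float],
                       neighbors: list[tuple[float, dict[float, TracePeak]]],
                       config: DeconvolutionConfig,
                       scan_interval: float) -> np.ndarray:
    """Read the full component spectrum back from the EIC matrix.

    Detected model peaks establish the apex; the spectrum itself is the
    per-m/z baseline-subtracted area over a fixed +/-2 sigma window around
    it, with the modeled Gaussian contribution of neighboring components
    removed from shared traces. This recovers fragments too weak to pass
    the per-trace detection gate (a real compound's minor ions) while a
    noise gate — 2.5 integrated-noise sigmas — keeps empty traces out.
    Detected members are always retained, falling back to their own peak
    area if neighbor subtraction consumes the windowed area.
    """
    rt = eics[0].rt_min
    sigma_rt = config.model_sigma_scans * scan_interval
    w = max(2, int(round(2 * config.model_sigma_scans)))
    apex_idx = int(np.clip(np.searchsorted(rt, apex_rt), 0, rt.size - 1))
    lo, hi = max(0, apex_idx - w), min(rt.size - 1, apex_idx + w)
    win_rt = rt[lo:hi + 1]
    member_by_mz = {p.mz: p for p in group}
    near = [(a_rt, members) for a_rt, members in neighbors
            if abs(a_rt - apex_rt) > 1e-12 and abs(a_rt - apex_rt) < 10 * sigma_rt]
    entries: list[tuple[float, float]] = []
    for eic, noise in zip(eics, noises):
        x = eic.intensity
        seg = np.clip(x[lo:hi + 1] - np.median(x), 0.0, None)
        area = float(np.trapezoid(seg, win_rt))
        for other_apex, members in near:
            p = members.get(eic.mz)
            if p is not None:
                # center the model on the neighbor's consensus apex: a single
                # member's apex can be a scan off under noise
                area -= _gaussian_overlap_area(p.height, other_apex, sigma_rt,
                                               float(win_rt[0]), float(win_rt[-1]))
        member = member_by_mz.get(eic.mz)
        if member is not None:
            entries.append((eic.mz, area if area > 0 else member.area))
        else:
            thresh = _COMPLETION_SIGMAS * noise * scan_interval * math.sqrt(win_rt.size)
            if area > thresh and area > 0:
                entries.append((eic.mz, area))
    spec = np.array(entries)
    spec[:, 1] *= BASE_PEAK / spec[:, 1].max()
    spec = spec[spec[:, 1] >= _MIN_REL_INTENSITY]
    return spec[np.argsort(spec[:, 0])]


def deconvolve(run: MSRun, config: DeconvolutionConfig | None = None) -> list[DeconvolvedComponent]:
    """Resolve a run into components, RT-sorted.

    Trace peaks across m/z bins whose apexes coincide within the grouping
    window form a component; its apex RT is the height-weighted mean of
    member apexes and its S/N the tallest member height over the largest
    member-trace noise. The reported spectrum is completed from the EIC
    matrix around the apex (see :func:`_complete_spectrum`), normalized
    to base peak 999.
    """
    config = config or DeconvolutionConfig()
    if not run.scans:
        return []
    eics = extract_eics(run, config.mz_bin_width)
    noises = [estimate_noise(e.intensity) if len(e) >= 16 else 0.0 for e in eics]
    all_peaks: list[TracePeak] = []
    for eic, noise in zip(eics, noises):
        all_peaks.extend(detect_trace_peaks(eic, config, noise=noise))
    if not all_peaks:
        return []
    groups = _group_trace_peaks(all_peaks, config.apex_grouping_window_scans)
    # one peak per m/z trace within a group: keep the taller on collision
    deduped: list[list[TracePeak]] = []
    for group in groups:
        by_mz: dict[float, TracePeak] = {}
        for p in group:
            cur = by_mz.get(p.mz)
            if cur is None or p.height > cur.height:
                by_mz[p.mz] = p
        deduped.append(list(by_mz.values()))
    deduped.sort(key=lambda g: min(p.apex_idx for p in g))
    rt = run.rt
    scan_interval = float(np.median(np.diff(rt))) if len(rt) > 1 else 1.0
    adjusted = _subtract_adjacent(deduped, config, scan_interval)
    adjusted = [g for g in adjusted if len(g) >= config.min_member_traces]
    apex_rts = [float(np.average([p.apex_rt_min for p in g],
                                 weights=[p.height for p in g])) for g in adjusted]
    neighbors = [(a_rt, {p.mz: p for p in g}) for a_rt, g in zip(apex_rts, adjusted)]
    components: list[DeconvolvedComponent] = []
    for group, apex_rt in zip(adjusted, apex_rts):
        heights = np.array([p.height for p in group])
        areas = np.array([p.area for p in group])
        mzs = np.array([p.mz for p in group])
        spectrum = _complete_spectrum(group, apex_rt, eics, noises, neighbors,
                                      config, scan_interval)
        snr = _safe_snr(float(heights.max()), max(p.noise for p in group))
        order = np.argsort(-areas)
        components.append(DeconvolvedComponent(
            apex_rt_min=apex_rt,
            spectrum=spectrum,
            area=float(areas.sum()),
            height=float(heights.max()),
            snr=snr,
            model_mzs=[float(m) for m in mzs[order]],
            members=sorted(group, key=lambda p: p.mz)))
    components.sort(key=lambda c: c.apex_rt_min)
    return components


def components_to_csv(components: list[DeconvolvedComponent], path) -> None:
    """Optional component-list export: one row per component."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["apex_rt_min", "area", "height", "snr", "spectrum"])
        for c in components:
            spec = " ".join(f"{mz:g}:{inten:.0f}" for mz, inten in c.spectrum)
            writer.writerow([f"{c.apex_rt_min:.6g}", f"{c.area:.6g}",
                             f"{c.height:.6g}",
                             "inf" if math.isinf(c.snr) else f"{c.snr:.6g}", spec])
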