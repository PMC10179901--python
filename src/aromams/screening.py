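"""Screening workflow: deconvolve, search, filter, verify, report.

Two operation modes share one pipeline. Non-targeted screening searches
every deconvolved component against a public library; targeted screening
searches a user library, optionally constraining each entry to a window
around its expected RT. In both, a component's rank-1 hit enters the
report only if it passes the acceptance rule

    (dRI present AND dRI < 100 AND Match > 700)
        OR (Match > 800 AND Probability > 20)

with strict inequalities throughout — the RI clause carries most of the
load, while the second clause rescues strong hits whose library entry has
no retention index. With verification enabled, heteroatom confirmation
annotates every record; the heteroatom-verified report view then keeps
only verified records (plus detector-only unknown rows), while the ALL
view keeps everything accepted — mirroring the "all compounds" vs
"N/S-confirmed" pair of summary reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import detector_verify as dv
from .deconvolution import DeconvolutionConfig, DeconvolvedComponent, deconvolve
from .errors import ParameterError
from .io_formats import AlkaneLadder, ChannelTrace, MSRun, SpectralLibrary
from .library_search import DEFAULT_TOP_K, PROBABILITY_K, LibraryHit, search
from .retention_index import RICalibration, calibrate, delta_ri, rt_to_ri

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds of the hit-acceptance rule (all strict inequalities)."""

    ri_tolerance: float = 100.0
    match_min: int = 700
    match_min_no_ri: int = 800
    probability_min_pct: float = 20.0

    def __post_init__(self) -> None:
        if self.match_min_no_ri < self.match_min:
            raise ParameterError("match_min_no_ri must be >= match_min")
        if not (0 <= self.match_min <= 999 and 0 <= self.match_min_no_ri <= 999):
            raise ParameterError("match thresholds must lie in 0..999")
        if self.ri_tolerance <= 0:
            raise ParameterError("ri_tolerance must be positive")


@dataclass
class IdentificationRecord:
    """One reportable row: component, hit, RI check and verification."""

    rt_min: float
    name: str | None = None
    cas: str | None = None
    match: int | None = None
    reverse_match: int | None = None
    probability_pct: float | None = None
    snr: float | None = None
    area: float | None = None
    delta_ri: float | None = None
    ri_extrapolated: bool | None = None
    verification: dv.VerificationResult | None = None
    mode: str = "nontargeted"
    detector: str | None = None
    unidentified_channel_peak: bool = False
    alternates: list[dict] = field(default_factory=list)


def accept_hit(hit: LibraryHit, dri: float | None, cfg: FilterConfig | None = None) -> bool:
    """Apply the acceptance rule to a scored hit.

    An absent delta-RI is not zero: the first clause simply cannot fire,
    and acceptance then requires the stricter no-RI clause.
    """
    cfg = cfg or FilterConfig()
    ri_clause = dri is not None and dri < cfg.ri_tolerance and hit.match > cfg.match_min
    no_ri_clause = (hit.match > cfg.match_min_no_ri
                    and hit.probability_pct > cfg.probability_min_pct)
    return ri_clause or no_ri_clause


# ---------------------------------------------------------------------------
# Shared pipeline pieces
# ---------------------------------------------------------------------------

ChannelsArg = list[tuple[dv.ChannelConfig, "ChannelTrace | list[dv.DetectorPeak]"]]


def _integrate_channels(channels: ChannelsArg | None,
                        deconv_config: DeconvolutionConfig
                        ) -> list[tuple[dv.ChannelConfig, list[dv.DetectorPeak]]]:
    out: list[tuple[dv.ChannelConfig, list[dv.DetectorPeak]]] = []
    for cfg, payload in channels or []:
        if isinstance(payload, ChannelTrace):
            peaks = dv.integrate_channel(payload, deconv_config)
        else:
            peaks = sorted(payload, key=lambda p: p.apex_rt_min)
        out.append((cfg, peaks))
    return out


def _record_from_hit(component: DeconvolvedComponent, hit: LibraryHit,
                     alternates: list[LibraryHit],
                     cal: RICalibration | None, mode: str) -> IdentificationRecord:
    dri = None
    extrapolated = None
    if cal is not None and hit.entry.ri_nonpolar is not None:
        ri, extrapolated = rt_to_ri(cal, component.apex_rt_min)
        dri = delta_ri(ri, hit.entry)
    return IdentificationRecord(
        rt_min=component.apex_rt_min,
        name=hit.entry.name,
        cas=hit.entry.cas,
        match=hit.match,
        reverse_match=hit.reverse_match,
        probability_pct=hit.probability_pct,
        snr=component.snr,
        area=component.area,
        delta_ri=dri,
        ri_extrapolated=extrapolated,
        mode=mode,
        alternates=[{"name": h.entry.name, "match": h.match,
                     "reverse_match": h.reverse_match,
                     "probability_pct": round(h.probability_pct, 2)}
                    for h in alternates],
    )


def _observed_dri(component: DeconvolvedComponent, hit: LibraryHit,
                  cal: RICalibration | None) -> float | None:
    if cal is None or hit.entry.ri_nonpolar is None:
        return None
    ri, _ = rt_to_ri(cal, component.apex_rt_min)
    return delta_ri(ri, hit.entry)


def _append_unknown_channel_rows(records: list[IdentificationRecord],
                                 components: list[DeconvolvedComponent],
                                 channels: list[tuple[dv.ChannelConfig, list[dv.DetectorPeak]]],
                                 mode: str) -> None:
    """Detector peaks matching no MS component become 'unidentified' rows."""
    for cfg, peaks in channels:
        for peak in peaks:
            expected_rts = [c.apex_rt_min + cfg.lag_min for c in components]
            if any(abs(peak.apex_rt_min - e) <= cfg.tolerance_min for e in expected_rts):
                continue
            records.append(IdentificationRecord(
                rt_min=peak.apex_rt_min, area=peak.area, snr=peak.snr,
                detector=cfg.detector, unidentified_channel_peak=True, mode=mode))


def _screen(run: MSRun, channels: ChannelsArg | None, library: SpectralLibrary,
            ladder: AlkaneLadder | None, verify_flag: bool, mode: str,
            deconv_config: DeconvolutionConfig, filter_config: FilterConfig,
            policy: str, top_k: int, probability_k: float,
            rt_window_min: float | None = None) -> list[IdentificationRecord]:
    if not len(library):
        raise ParameterError("cannot screen against an empty library")
    components = deconvolve(run, deconv_config)
    cal = calibrate(ladder) if ladder is not None else None
    channel_peaks = _integrate_channels(channels, deconv_config)
    records: list[IdentificationRecord] = []
    n_accepted = 0
    for component in components:
        if mode == "targeted" and rt_window_min is not None:
            sub = [e for e in library.entries
                   if e.expected_rt_min is None
                   or abs(e.expected_rt_min - component.apex_rt_min) <= rt_window_min]
            if not sub:
                continue
            cand = SpectralLibrary(entries=sub, name=library.name, kind=library.kind)
        else:
            cand = library
        hits = search(component.spectrum, cand, top_k=top_k, k=probability_k)
        if not hits:
            continue
        top = hits[0]
        dri = _observed_dri(component, top, cal)
        if not accept_hit(top, dri, filter_config):
            continue
        n_accepted += 1
        record = _record_from_hit(component, top, hits[1:], cal, mode)
        if verify_flag:
            record.verification = dv.verify(component.apex_rt_min, top.entry.formula,
                                            channel_peaks, policy=policy)
        records.append(record)
    if verify_flag:
        _append_unknown_channel_rows(records, components, channel_peaks, mode)
    records.sort(key=lambda r: (r.rt_min, r.name or ""))
    logger.info("%s screening: %d components, %d hits accepted, %d records",
                mode, len(components), n_accepted, len(records))
    return records


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def run_nontargeted(run: MSRun, channels: ChannelsArg | None,
                    library: SpectralLibrary, ladder: AlkaneLadder | None = None,
                    verify_flag: bool = True,
                    deconv_config: DeconvolutionConfig | None = None,
                    filter_config: FilterConfig | None = None,
                    policy: str = "all_elements",
                    top_k: int = DEFAULT_TOP_K,
                    probability_k: float = PROBABILITY_K) -> list[IdentificationRecord]:
    """Non-targeted screening against a public library.

    Verification (when enabled) annotates records and appends
    detector-only unknown rows; it never deletes an accepted record —
    the reduction to heteroatom-confirmed compounds happens in
    :func:`assemble_report`'s N/S view.
    """
    return _screen(run, channels, library, ladder, verify_flag, "nontargeted",
                   deconv_config or DeconvolutionConfig(),
                   filter_config or FilterConfig(), policy, top_k, probability_k)


def run_targeted(run: MSRun, channels: ChannelsArg | None,
                 user_library: SpectralLibrary, ladder: AlkaneLadder | None = None,
                 verify_flag: bool = True, rt_window_min: float = 0.1,
                 deconv_config: DeconvolutionConfig | None = None,
                 filter_config: FilterConfig | None = None,
                 policy: str = "all_elements",
                 top_k: int = DEFAULT_TOP_K,
                 probability_k: float = PROBABILITY_K) -> list[IdentificationRecord]:
    """Targeted screening against the user's own library.

    Entries carrying an expected RT are only considered for components
    within ``rt_window_min`` of it; entries without one behave as in
    non-targeted mode. The RI clause of the acceptance rule applies only
    to entries that carry a retention index.
    """
    if not len(user_library):
        raise ParameterError("targeted screening requires a non-empty user library")
    return _screen(run, channels, user_library, ladder, verify_flag, "targeted",
                   deconv_config or DeconvolutionConfig(),
                   filter_config or FilterConfig(), policy, top_k, probability_k,
                   rt_window_min=rt_window_min)


def assemble_report(records: list[IdentificationRecord]
                    ) -> tuple[list[IdentificationRecord], list[IdentificationRecord]]:
    """Split records into the two report views, both RT-sorted.

    ALL: every accepted identification (verification annotates but never
    removes; not-applicable records stay untouched). N/S-VERIFIED: only
    records whose verdict is verified, plus the unidentified
    detector-only rows.
    """
    ordered = sorted(records, key=lambda r: (r.rt_min, r.name or ""))
    all_view = [r for r in ordered if not r.unidentified_channel_peak]
    ns_view = [r for r in ordered
               if r.unidentified_channel_peak
               or (r.verification is not None and r.verification.verdict == dv.VERIFIED)]
    return all_view, ns_view
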