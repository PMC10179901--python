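"""Retention-index calibration and the delta-RI identity filter.

Retention times are mapped to the n-alkane index scale (C_n -> 100 n)
by piecewise-linear interpolation between ladder rungs — the van den
Dool–Kratz convention appropriate for temperature-programmed GC, rather
than the isothermal logarithmic Kovats formula. Outside the ladder the
terminal segments are extended linearly and the result is flagged
``extrapolated``: very volatile analytes (methanethiol and the like)
routinely elute before the first alkane, and their RI is still useful for
filtering as long as the flag travels with it into the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError
from .io_formats import AlkaneLadder, LibraryEntry


@dataclass(eq=False)
class RICalibration:
    """Piecewise-linear RT -> RI map built from an alkane ladder."""

    rt_knots: np.ndarray
    ri_knots: np.ndarray

    def __post_init__(self) -> None:
        self.rt_knots = np.asarray(self.rt_knots, dtype=float)
        self.ri_knots = np.asarray(self.ri_knots, dtype=float)
        if self.rt_knots.size < 2:
            raise CalibrationError("RI calibration needs at least 2 knots")
        if np.any(np.diff(self.rt_knots) <= 0) or np.any(np.diff(self.ri_knots) <= 0):
            raise CalibrationError("calibration knots must be strictly increasing")


def calibrate(ladder: AlkaneLadder) -> RICalibration:
    """Build an RT -> RI calibration from an alkane ladder (C_n at 100 n)."""
    if len(ladder) < 2:
        raise CalibrationError("alkane ladder needs at least 2 rungs to calibrate")
    return RICalibration(rt_knots=ladder.rt_min.copy(),
                         ri_knots=100.0 * ladder.carbon_numbers.astype(float))


def rt_to_ri(cal: RICalibration, rt_min: float) -> tuple[float, bool]:
    """Convert one retention time to (retention index, extrapolated flag).

    Exact at knots, linear between them, linearly extended from the
    terminal segments outside the ladder; monotone non-decreasing in RT.
    """
    rts, ris = cal.rt_knots, cal.ri_knots
    rt = float(rt_min)
    if rt < rts[0]:
        slope = (ris[1] - ris[0]) / (rts[1] - rts[0])
        return float(ris[0] + slope * (rt - rts[0])), True
    if rt > rts[-1]:
        slope = (ris[-1] - ris[-2]) / (rts[-1] - rts[-2])
        return float(ris[-1] + slope * (rt - rts[-1])), True
    return float(np.interp(rt, rts, ris)), False


def delta_ri(observed_ri: float, entry: LibraryEntry) -> float | None:
    """|observed RI - library RI|, or None when the entry carries no RI.

    An absent value is distinct from 0: the RI clause of the acceptance
    rule simply does not apply to entries without a reference index.
    """
    if entry.ri_nonpolar is None:
        return None
    return abs(float(observed_ri) - float(entry.ri_nonpolar))
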