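"""Synthetic multi-detector GC runs with exact ground truth.

Emulates what the real instrument produces — a TIC full of Gaussian
chromatographic peaks whose scans carry each compound's fragment pattern,
plus NPD / FPD(S) / PFPD traces in which only the N- or S-containing
compounds respond, lagged per detector — so every pipeline stage can be
tested against planted truth without instrument files.

Compounds are drawn from the bundled 55-entry synthetic roast-aroma
library (real names and formulas; fixed pseudo-random EI spectra).
Default geometry: 0.005 min scan interval and peak sigma 0.0125 min, so a
peak spans about 10 scans at its base — the canonical component width for
capillary GC. Default channel lags are the working values for this
detector combination (NPD and FPD(S) +0.01 min, PFPD +0.05 min). Rendered
traces carry additive Gaussian noise over a constant standing-current
baseline (five noise sigmas) so that difference-based noise estimation
sees the true sigma rather than a rectified half-distribution.
"""

from __future__ import annotations

import importlib.resources as _resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detector_verify import heteroatoms
from .errors import SceneError
from .io_formats import (AlkaneLadder, ChannelTrace, MSRun, Scan,
                         SpectralLibrary, read_msp_library)

#: expected RT offset of each selective channel relative to the MS, minutes
DEFAULT_LAGS = {"NPD": 0.01, "FPD_S": 0.01, "PFPD": 0.05}

#: baseline standing current expressed in noise sigmas
BASELINE_SIGMAS = 5.0

DEFAULT_SCAN_INTERVAL_MIN = 0.005
DEFAULT_PEAK_SIGMA_MIN = 0.0125
DEFAULT_MS_NOISE_SIGMA = 10.0
DEFAULT_CHANNEL_NOISE_SIGMA = 2.0


def bundled_library() -> SpectralLibrary:
    """Load the bundled synthetic roast-aroma reference library."""
    ref = _resources.files("aromams").joinpath("data/roast_aroma_synthetic.msp")
    with _resources.as_file(ref) as path:
        return read_msp_library(path, name="roast_aroma_synthetic", kind="public")


@dataclass(eq=False)
class PlantedCompound:
    """One compound planted in a scene, with every rendering parameter."""

    name: str
    formula: str
    spectrum: np.ndarray  # (n, 2) m/z, relative intensity (base 999)
    true_rt_min: float
    peak_sigma_min: float
    ms_height: float
    channel_responses: dict[str, float] = field(default_factory=dict)

    @property
    def heteroatoms(self) -> frozenset[str]:
        return heteroatoms(self.formula)


@dataclass(eq=False)
class GroundTruth:
    """A fully specified scene: compounds, channel lags, noise, seed."""

    compounds: list[PlantedCompound]
    lags: dict[str, float]
    ms_noise_sigma: float
    channel_noise_sigma: float
    rt_range_min: tuple[float, float]
    seed: int

    @property
    def ns_compounds(self) -> list[PlantedCompound]:
        return [c for c in self.compounds if c.heteroatoms & {"N", "S"}]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "rt_range_min": list(self.rt_range_min),
            "ms_noise_sigma": self.ms_noise_sigma,
            "channel_noise_sigma": self.channel_noise_sigma,
            "lags": self.lags,
            "compounds": [
                {
                    "name": c.name, "formula": c.formula,
                    "true_rt_min": c.true_rt_min,
                    "peak_sigma_min": c.peak_sigma_min,
                    "ms_height": c.ms_height,
                    "channel_responses": c.channel_responses,
                    "spectrum": [[float(m), float(i)] for m, i in c.spectrum],
                }
                for c in self.compounds
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def make_scene(n_compounds: int, frac_ns: float = 0.4,
               rt_range_min: tuple[float, float] = (1.0, 11.0),
               seed: int = 0,
               min_separation_min: float = 0.025,
               min_same_channel_separation_min: float = 0.06,
               snr_range: tuple[float, float] = (20.0, 200.0),
               channel_snr_range: tuple[float, float] = (50.0, 500.0),
               peak_sigma_min: float = DEFAULT_PEAK_SIGMA_MIN,
               ms_noise_sigma: float = DEFAULT_MS_NOISE_SIGMA,
               channel_noise_sigma: float = DEFAULT_CHANNEL_NOISE_SIGMA,
               lags: dict[str, float] | None = None,
               library: SpectralLibrary | None = None) -> GroundTruth:
    """Sample a deterministic scene from the bundled library.

    Exactly ``round(n_compounds * frac_ns)`` of the planted compounds
    contain N or S; retention times are uniform over ``rt_range_min``
    with an enforced minimum apex separation (default 2 peak sigmas).
    Compounds sharing a selective channel element (two N compounds, or
    two S compounds) additionally keep
    ``min_same_channel_separation_min`` apart, so their single-element
    channel peaks stay individually resolvable; scenes that deliberately
    share one broad channel peak can be built by lowering it. MS peak
    heights are drawn so the base-peak S/N against ``ms_noise_sigma``
    lies in ``snr_range``; N/S compounds additionally respond on every
    covering selective channel.
    """
    library = library or bundled_library()
    lags = dict(lags or DEFAULT_LAGS)
    if n_compounds < 1 or n_compounds > len(library):
        raise SceneError(f"n_compounds must be in 1..{len(library)}")
    if not 0.0 <= frac_ns <= 1.0:
        raise SceneError("frac_ns must lie in [0, 1]")
    lo, hi = rt_range_min
    span = hi - lo
    if span <= 0:
        raise SceneError("rt_range_min must be increasing")
    if (n_compounds - 1) * min_separation_min >= span:
        raise SceneError(
            f"cannot place {n_compounds} apexes {min_separation_min} min apart in {span} min")
    rng = np.random.default_rng(seed)
    ns_pool = [e for e in library.entries if e.formula and heteroatoms(e.formula) & {"N", "S"}]
    ns_ids = {id(e) for e in ns_pool}
    other_pool = [e for e in library.entries if id(e) not in ns_ids]
    n_ns = round(n_compounds * frac_ns)
    if n_ns > len(ns_pool) or (n_compounds - n_ns) > len(other_pool):
        raise SceneError("library pools too small for the requested composition")
    chosen = list(rng.choice(len(ns_pool), size=n_ns, replace=False))
    picked = [ns_pool[i] for i in chosen]
    chosen = list(rng.choice(len(other_pool), size=n_compounds - n_ns, replace=False))
    picked += [other_pool[i] for i in chosen]
    atom_sets = [heteroatoms(e.formula) if e.formula else frozenset() for e in picked]
    rts = None
    for _ in range(200):
        cand = _sample_separated_rts(rng, n_compounds, lo, hi, min_separation_min)
        if _same_channel_ok(cand, atom_sets, min_same_channel_separation_min):
            rts = cand
            break
    if rts is None:
        raise SceneError(
            "could not separate same-channel compounds by "
            f"{min_same_channel_separation_min} min in [{lo}, {hi}]")
    order = np.argsort(rts)
    compounds: list[PlantedCompound] = []
    for rank, idx in enumerate(order):
        entry = picked[idx]
        snr = rng.uniform(*snr_range)
        responses: dict[str, float] = {}
        atoms = heteroatoms(entry.formula) if entry.formula else frozenset()
        for det, covered in (("NPD", "N"), ("FPD_S", "S"), ("PFPD", "S")):
            if covered in atoms:
                responses[det] = float(rng.uniform(*channel_snr_range)
                                       * max(channel_noise_sigma, 1.0))
        compounds.append(PlantedCompound(
            name=entry.name, formula=entry.formula or "",
            spectrum=entry.spectrum.copy(),
            true_rt_min=float(rts[idx]),
            peak_sigma_min=peak_sigma_min,
            ms_height=float(snr * max(ms_noise_sigma, 1.0)),
            channel_responses=responses))
    return GroundTruth(compounds=compounds, lags=lags,
                       ms_noise_sigma=ms_noise_sigma,
                       channel_noise_sigma=channel_noise_sigma,
                       rt_range_min=(lo, hi), seed=int(seed))


def _same_channel_ok(rts: np.ndarray, atom_sets: list[frozenset[str]],
                     min_sep: float) -> bool:
    for element in ("N", "S"):
        shared = np.sort(rts[[element in a for a in atom_sets]])
        if shared.size > 1 and np.diff(shared).min() < min_sep:
            return False
    return True


def _sample_separated_rts(rng: np.random.Generator, n: int, lo: float, hi: float,
                          min_sep: float, max_tries: int = 500) -> np.ndarray:
    for _ in range(max_tries):
        rts = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.diff(rts).min() >= min_sep:
            return rts
    raise SceneError(
        f"could not place {n} apexes with separation >= {min_sep} min in [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render(scene: GroundTruth,
           scan_interval_min: float = DEFAULT_SCAN_INTERVAL_MIN,
           noise_sigma: float | None = None,
           channel_noise_sigma: float | None = None,
           rt_margin_min: float = 0.15) -> tuple[MSRun, dict[str, ChannelTrace]]:
    """Render a scene into an MS run and one trace per selective channel.

    Every compound contributes Gaussian peaks: in the MS, one per fragment
    m/z scaled by relative intensity x ``ms_height``; in channel ``d``, a
    single Gaussian at ``true_rt + lag[d]`` with the planted response
    height. Noise is additive Gaussian over a constant baseline of
    ``5 x sigma`` (zero when sigma is zero), clipped at zero. Fully
    deterministic for a given scene.
    """
    if scan_interval_min <= 0:
        raise SceneError("scan_interval_min must be positive")
    ms_sigma = scene.ms_noise_sigma if noise_sigma is None else noise_sigma
    ch_sigma = scene.channel_noise_sigma if channel_noise_sigma is None else channel_noise_sigma
    rng = np.random.default_rng([scene.seed, 0x5EED])
    lo, hi = scene.rt_range_min
    rt = np.arange(lo - rt_margin_min, hi + rt_margin_min + scan_interval_min,
                   scan_interval_min)
    n_scans = rt.size

    mz_bins = sorted({int(round(m)) for c in scene.compounds for m, _ in c.spectrum})
    bin_index = {b: i for i, b in enumerate(mz_bins)}
    matrix = np.zeros((n_scans, len(mz_bins)))
    for comp in scene.compounds:
        profile = np.exp(-0.5 * ((rt - comp.true_rt_min) / comp.peak_sigma_min) ** 2)
        for mz, rel in comp.spectrum:
            matrix[:, bin_index[int(round(mz))]] += profile * comp.ms_height * (rel / 999.0)
    if ms_sigma > 0:
        matrix += BASELINE_SIGMAS * ms_sigma
        matrix += rng.normal(0.0, ms_sigma, size=matrix.shape)
        np.clip(matrix, 0.0, None, out=matrix)
    mz_arr = np.array(mz_bins, dtype=float)
    scans = [Scan(rt_min=float(t), mz=mz_arr, intensity=matrix[i])
             for i, t in enumerate(rt)]
    run = MSRun(scans=scans, metadata={"synthetic": True, "seed": scene.seed})

    traces: dict[str, ChannelTrace] = {}
    for det, lag in scene.lags.items():
        signal = np.zeros(n_scans)
        for comp in scene.compounds:
            height = comp.channel_responses.get(det, 0.0)
            if height <= 0:
                continue
            center = comp.true_rt_min + lag
            signal += height * np.exp(-0.5 * ((rt - center) / comp.peak_sigma_min) ** 2)
        if ch_sigma > 0:
            signal += BASELINE_SIGMAS * ch_sigma
            signal += rng.normal(0.0, ch_sigma, size=n_scans)
            np.clip(signal, 0.0, None, out=signal)
        traces[det] = ChannelTrace(detector=det, rt_min=rt.copy(), intensity=signal)
    return run, traces


def make_ladder(rt_range_min: tuple[float, float] = (1.0, 11.0),
                carbons: tuple[int, int] = (5, 14)) -> AlkaneLadder:
    """An evenly spaced alkane ladder spanning (and slightly beyond) a run."""
    c_lo, c_hi = carbons
    n = c_hi - c_lo + 1
    rts = np.linspace(rt_range_min[0], rt_range_min[1], n)
    return AlkaneLadder(carbon_numbers=np.arange(c_lo, c_hi + 1), rt_min=rts)
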