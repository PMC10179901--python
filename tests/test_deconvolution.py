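import numpy as np
import pytest

import aromams as am
from aromams.deconvolution import DeconvolutionConfig, EIC
from aromams.errors import ParameterError
from aromams.synthgen import DEFAULT_LAGS, GroundTruth, PlantedCompound

from conftest import spectral_cosine


def _gauss_trace(n=400, apex=200, sigma=5.0, height=100.0, noise=0.0, seed=0, dt=0.005):
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    x = height * np.exp(-0.5 * ((idx - apex) / sigma) ** 2)
    if noise > 0:
        x += 5 * noise + rng.normal(0, noise, n)
        x = np.clip(x, 0, None)
    return EIC(mz=94.0, rt_min=idx * dt, intensity=x)


# ---------------------------------------------------------------------------
# extract_eics
# ---------------------------------------------------------------------------

def test_single_mz_run_gives_single_eic():
    scans = [am.Scan(rt_min=0.1 * i, mz=np.array([94.0]), intensity=np.array([10.0 + i]))
             for i in range(5)]
    eics = am.extract_eics(am.MSRun(scans=scans))
    assert len(eics) == 1 and eics[0].mz == 94.0
    assert eics[0].intensity.tolist() == [10.0, 11.0, 12.0, 13.0, 14.0]


def test_eics_conserve_tic(rendered20):
    run, _ = rendered20
    eics = am.extract_eics(run)
    total = np.sum([e.intensity for e in eics], axis=0)
    np.testing.assert_allclose(total, run.tic(), rtol=1e-9)


def test_eics_cover_planted_bins(scene20, clean_rendered20):
    run, _ = clean_rendered20
    eics = {int(e.mz) for e in am.extract_eics(run) if e.intensity.max() > 0}
    planted = {int(round(m)) for c in scene20.compounds for m, _ in c.spectrum}
    assert planted <= eics


def test_bad_bin_width():
    run, _ = am.render(am.make_scene(2, frac_ns=0.0, seed=1, rt_range_min=(1.0, 1.5)))
    with pytest.raises(ParameterError):
        am.extract_eics(run, mz_bin_width=0.0)


# ---------------------------------------------------------------------------
# estimate_noise
# ---------------------------------------------------------------------------

def test_noise_constant_trace_is_zero():
    assert am.estimate_noise(np.full(100, 7.0)) == 0.0


def test_noise_recovers_gaussian_sigma():
    rng = np.random.default_rng(42)
    x = rng.normal(0.0, 5.0, 10_000)
    assert am.estimate_noise(x) == pytest.approx(5.0, rel=0.10)


def test_noise_offset_invariant():
    rng = np.random.default_rng(7)
    x = rng.normal(0.0, 3.0, 2000)
    assert am.estimate_noise(x + 1e6) == pytest.approx(am.estimate_noise(x), rel=1e-9)


def test_noise_short_trace_rejected():
    with pytest.raises(ParameterError):
        am.estimate_noise(np.zeros(10))


# ---------------------------------------------------------------------------
# detect_trace_peaks
# ---------------------------------------------------------------------------

def test_single_planted_gaussian_snr50():
    trace = _gauss_trace(height=500.0, noise=10.0, seed=3)
    peaks = am.detect_trace_peaks(trace)
    assert len(peaks) == 1
    assert abs(peaks[0].apex_idx - 200) <= 1
    assert peaks[0].left_rt_min < peaks[0].apex_rt_min < peaks[0].right_rt_min


def test_flat_trace_no_peaks():
    trace = EIC(mz=50.0, rt_min=np.arange(100) * 0.005, intensity=np.zeros(100))
    assert am.detect_trace_peaks(trace) == []


def test_two_gaussians_well_separated():
    idx = np.arange(600)
    x = (100 * np.exp(-0.5 * ((idx - 200) / 5.0) ** 2)
         + 80 * np.exp(-0.5 * ((idx - 400) / 5.0) ** 2))
    trace = EIC(mz=50.0, rt_min=idx * 0.005, intensity=x)
    peaks = am.detect_trace_peaks(trace)
    assert len(peaks) == 2
    assert peaks[0].apex_rt_min < peaks[1].apex_rt_min


# ---------------------------------------------------------------------------
# deconvolve
# ---------------------------------------------------------------------------

def test_single_compound_clean_spectrum():
    scene = am.make_scene(1, frac_ns=0.0, seed=3, rt_range_min=(1.0, 2.0))
    run, _ = am.render(scene, noise_sigma=0.0)
    comps = am.deconvolve(run)
    assert len(comps) == 1
    assert spectral_cosine(comps[0].spectrum, scene.compounds[0].spectrum) >= 0.99
    assert abs(comps[0].apex_rt_min - scene.compounds[0].true_rt_min) <= 0.005


def test_coeluting_pair_two_sigma_apart(bundled):
    entries = {e.name: e for e in bundled.entries}
    a_entry, b_entry = entries["hexanal"], entries["benzaldehyde"]
    comps = [
        PlantedCompound("hexanal", a_entry.formula, a_entry.spectrum.copy(),
                        true_rt_min=1.50, peak_sigma_min=0.0125, ms_height=2000.0),
        PlantedCompound("benzaldehyde", b_entry.formula, b_entry.spectrum.copy(),
                        true_rt_min=1.525, peak_sigma_min=0.0125, ms_height=1500.0),
    ]
    scene = GroundTruth(compounds=comps, lags=dict(DEFAULT_LAGS), ms_noise_sigma=10.0,
                        channel_noise_sigma=2.0, rt_range_min=(1.3, 1.8), seed=11)
    run, _ = am.render(scene)
    out = am.deconvolve(run)
    assert len(out) == 2
    for planted in comps:
        nearest = min(out, key=lambda c: abs(c.apex_rt_min - planted.true_rt_min))
        assert spectral_cosine(nearest.spectrum, planted.spectrum) >= 0.95


def test_empty_run_gives_empty_list():
    assert am.deconvolve(am.MSRun(scans=[])) == []


def test_partial_overlap_minor_component_recovered(bundled):
    """A 10:1 pair only one peak-sigma apart still yields the minor compound."""
    entries = {e.name: e for e in bundled.entries}
    major, minor = entries["methyl acetate"], entries["1-methylpyrrole"]
    comps = [
        PlantedCompound("methyl acetate", major.formula, major.spectrum.copy(),
                        true_rt_min=2.226, peak_sigma_min=0.0125, ms_height=5000.0),
        PlantedCompound("1-methylpyrrole", minor.formula, minor.spectrum.copy(),
                        true_rt_min=2.2385, peak_sigma_min=0.0125, ms_height=500.0),
    ]
    scene = GroundTruth(compounds=comps, lags=dict(DEFAULT_LAGS), ms_noise_sigma=10.0,
                        channel_noise_sigma=2.0, rt_range_min=(2.0, 2.5), seed=7)
    run, _ = am.render(scene)
    out = am.deconvolve(run)
    assert len(out) == 2
    minor_comp = min(out, key=lambda c: abs(c.apex_rt_min - 2.2385))
    hit = am.search(minor_comp.spectrum, bundled)[0]
    assert hit.entry.name == "1-methylpyrrole"


def test_sensitivity_monotonicity():
    """Raising the S/N threshold never increases the component count."""
    for seed in (1, 2, 3):
        scene = am.make_scene(12, frac_ns=0.3, seed=seed, snr_range=(10.0, 60.0))
        run, _ = am.render(scene)
        counts = [len(am.deconvolve(run, DeconvolutionConfig(sensitivity=s)))
                  for s in ("high", "medium", "low")]  # thresholds 2.5 -> 5 -> 10
        assert counts[0] >= counts[1] >= counts[2]


def test_component_areas_bounded_by_tic_area(scene20, clean_rendered20):
    run, _ = clean_rendered20
    comps = am.deconvolve(run)
    total = sum(c.area for c in comps)
    tic_area = float(np.trapezoid(run.tic(), run.rt))
    assert total <= tic_area * (1 + 1e-6)
    assert total >= 0.8 * tic_area
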