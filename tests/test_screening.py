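import numpy as np
import pytest

import aromams as am
from aromams import detector_verify as dv
from aromams.errors import ParameterError
from aromams.library_search import LibraryHit

from conftest import channels_from_traces


def _hit(match, prob=50.0):
    entry = am.LibraryEntry(name="x", spectrum=np.array([[94.0, 999.0]]))
    return LibraryHit(entry=entry, match=match, reverse_match=match,
                      probability_pct=prob)


# ---------------------------------------------------------------------------
# accept_hit
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("match,dri,prob,expected", [
    (750, 50.0, 10.0, True),    # RI clause
    (820, None, 25.0, True),    # no-RI clause
    (700, 50.0, 99.0, False),   # strict >: match 700 fails the RI clause
    (750, 100.0, 99.0, False),  # strict <: dRI 100 fails
    (801, None, 21.0, True),
    (800, None, 99.0, False),
    (801, None, 20.0, False),
    (650, 0.0, 99.0, False),
    (999, None, 10.0, False),   # no RI and probability too low
])
def test_accept_hit_rule(match, dri, prob, expected):
    assert am.accept_hit(_hit(match, prob), dri) is expected


def test_accept_hit_absent_dri_is_not_zero():
    # dRI absent: RI clause cannot fire even with a perfect match
    assert am.accept_hit(_hit(750, 99.0), None) is False
    assert am.accept_hit(_hit(750, 99.0), 0.0) is True


def test_filter_config_validation():
    with pytest.raises(ParameterError):
        am.FilterConfig(match_min=800, match_min_no_ri=700)


# ---------------------------------------------------------------------------
# non-targeted screening
# ---------------------------------------------------------------------------

def test_nontargeted_recovery_verify_off(scene20, rendered20, bundled):
    run, _ = rendered20
    records = am.run_nontargeted(run, None, bundled, verify_flag=False)
    named = {r.name for r in records}
    planted = {c.name for c in scene20.compounds}
    assert len(named & planted) >= 18
    assert all(r.verification is None for r in records)
    rts = [r.rt_min for r in records]
    assert rts == sorted(rts)


def test_nontargeted_ns_view_is_exactly_planted_ns(scene20, clean_rendered20, bundled):
    run, traces = clean_rendered20
    records = am.run_nontargeted(run, channels_from_traces(traces), bundled,
                                 verify_flag=True)
    all_view, ns_view = am.assemble_report(records)
    identified = {r.name for r in all_view if r.name}
    ns_named = {r.name for r in ns_view if r.name}
    ns_truth = {c.name for c in scene20.ns_compounds}
    assert ns_named == ns_truth & identified
    assert ns_named <= identified  # the list-reduction direction


def test_verify_on_subset_of_verify_off(scene20, rendered20, bundled):
    run, traces = rendered20
    off = {r.name for r in am.run_nontargeted(run, None, bundled, verify_flag=False)}
    on = am.run_nontargeted(run, channels_from_traces(traces), bundled,
                            verify_flag=True)
    on_named = {r.name for r in on if r.name}
    assert on_named <= off


def test_empty_run_empty_report(bundled):
    assert am.run_nontargeted(am.MSRun(scans=[]), None, bundled, verify_flag=False) == []


# ---------------------------------------------------------------------------
# targeted screening
# ---------------------------------------------------------------------------

def _user_library(scene, names, rt_shift=0.0):
    entries = []
    for c in scene.compounds:
        if c.name in names:
            entries.append(am.LibraryEntry(
                name=c.name, spectrum=c.spectrum.copy(), formula=c.formula,
                expected_rt_min=c.true_rt_min + rt_shift))
    return am.SpectralLibrary(entries=entries, name="user", kind="user")


def test_targeted_finds_exactly_the_user_compounds(scene20, rendered20):
    run, _ = rendered20
    names = [c.name for c in scene20.compounds[:3]]
    lib = _user_library(scene20, names)
    records = am.run_targeted(run, None, lib, verify_flag=False)
    assert sorted({r.name for r in records}) == sorted(names)
    assert all(r.mode == "targeted" for r in records)


def test_targeted_rt_window_excludes_shifted_entry(scene20, rendered20):
    run, _ = rendered20
    name = scene20.compounds[0].name
    lib = _user_library(scene20, [name], rt_shift=0.5)
    records = am.run_targeted(run, None, lib, verify_flag=False, rt_window_min=0.1)
    assert name not in {r.name for r in records}


def test_targeted_empty_library_rejected(rendered20):
    run, _ = rendered20
    with pytest.raises(ParameterError):
        am.run_targeted(run, None, am.SpectralLibrary(entries=[], kind="user"),
                        verify_flag=False)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def test_ns_view_empty_when_no_ns_compounds(bundled):
    scene = am.make_scene(5, frac_ns=0.0, seed=9, rt_range_min=(1.0, 3.0))
    run, traces = am.render(scene, noise_sigma=0.0, channel_noise_sigma=0.0)
    records = am.run_nontargeted(run, channels_from_traces(traces), bundled,
                                 verify_flag=True)
    all_view, ns_view = am.assemble_report(records)
    assert all_view
    assert [r for r in ns_view if r.name] == []


def test_every_ns_record_is_in_all_view(scene20, clean_rendered20, bundled):
    run, traces = clean_rendered20
    records = am.run_nontargeted(run, channels_from_traces(traces), bundled,
                                 verify_flag=True)
    all_view, ns_view = am.assemble_report(records)
    all_names = {r.name for r in all_view}
    assert {r.name for r in ns_view if r.name} <= all_names


def test_unidentified_channel_peak_only_in_ns_view(bundled):
    """An S peak with no MS component shows up as a detector-only unknown."""
    scene = am.make_scene(4, frac_ns=0.0, seed=13, rt_range_min=(2.0, 4.0))
    run, traces = am.render(scene, noise_sigma=0.0, channel_noise_sigma=0.0)
    rt = traces["FPD_S"].rt_min
    # plant the orphan in the largest gap between MS components
    planted = sorted(c.true_rt_min for c in scene.compounds)
    candidates = np.arange(2.2, 3.8, 0.01)
    orphan_rt = max(candidates, key=lambda t: min(abs(t - p) for p in planted))
    orphan = 500.0 * np.exp(-0.5 * ((rt - orphan_rt) / 0.0125) ** 2)
    traces["FPD_S"] = am.ChannelTrace("FPD_S", rt, traces["FPD_S"].intensity + orphan)
    records = am.run_nontargeted(run, channels_from_traces(traces), bundled,
                                 verify_flag=True)
    all_view, ns_view = am.assemble_report(records)
    unknowns = [r for r in ns_view if r.unidentified_channel_peak]
    assert len(unknowns) == 1
    assert unknowns[0].detector == "FPD_S"
    assert abs(unknowns[0].rt_min - orphan_rt) < 0.01
    assert not any(r.unidentified_channel_peak for r in all_view)


def test_reports_are_deterministic(scene20, rendered20, bundled, tmp_path):
    run, traces = rendered20
    paths = []
    for i in (1, 2):
        records = am.run_nontargeted(run, channels_from_traces(traces), bundled,
                                     verify_flag=True)
        p = tmp_path / f"report{i}.csv"
        am.write_report(records, "nontargeted", False, p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()
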