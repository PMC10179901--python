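import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aromams as am
from aromams.errors import ParameterError
from aromams.library_search import LibraryHit


def brute_force_match(query, lib):
    """Independent weighted-cosine oracle: explicit loops, no shared code."""
    def binned(spec):
        out = {}
        for mz, inten in spec:
            if inten > 0:
                out[int(round(mz))] = out.get(int(round(mz)), 0.0) + inten
        return out

    q, l = binned(query), binned(lib)
    wq = {m: (i ** 0.6) * (m ** 3) for m, i in q.items()}
    wl = {m: (i ** 0.6) * (m ** 3) for m, i in l.items()}
    num = 0.0
    for m in wq:
        if m in wl:
            num += math.sqrt(wq[m] * wl[m])
    den = sum(wq.values()) * sum(wl.values())
    return int(round(999.0 * num * num / den)) if den else 0


def random_spectrum(rng, n_max=25):
    n = int(rng.integers(3, n_max))
    mzs = rng.choice(np.arange(26, 250), size=n, replace=False)
    intens = rng.uniform(1.0, 999.0, size=n)
    return np.column_stack([mzs.astype(float), intens])


# ---------------------------------------------------------------------------
# match factor
# ---------------------------------------------------------------------------

def test_identity_is_999(bundled):
    for entry in bundled.entries[:10]:
        assert am.match_factor(entry.spectrum, entry.spectrum) == 999


def test_disjoint_is_zero():
    q = np.array([[50.0, 999.0], [60.0, 100.0]])
    l = np.array([[70.0, 999.0], [80.0, 100.0]])
    assert am.match_factor(q, l) == 0


def test_match_against_bruteforce_example():
    q = np.array([[94.0, 999.0], [39.0, 400.0]])
    l = np.array([[94.0, 999.0], [39.0, 400.0], [51.0, 100.0]])
    assert am.match_factor(q, l) == brute_force_match(q, l)
    assert am.match_factor(q, l) < 999


def test_match_symmetric_and_agrees_with_bruteforce():
    rng = np.random.default_rng(2024)
    for _ in range(30):
        a, b = random_spectrum(rng), random_spectrum(rng)
        assert am.match_factor(a, b) == brute_force_match(a, b)
        assert am.match_factor(a, b) == am.match_factor(b, a)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.floats(1e-3, 1e3), st.integers(0, 2**31 - 1))
def test_match_scale_invariant(c, seed):
    rng = np.random.default_rng(seed)
    a, b = random_spectrum(rng), random_spectrum(rng)
    scaled = a.copy()
    scaled[:, 1] *= c
    assert am.match_factor(scaled, b) == am.match_factor(a, b)


def test_empty_spectrum_rejected():
    with pytest.raises(ParameterError):
        am.match_factor(np.empty((0, 2)), np.array([[50.0, 999.0]]))


# ---------------------------------------------------------------------------
# reverse match
# ---------------------------------------------------------------------------

def test_reverse_identity_and_superset():
    lib = np.array([[94.0, 999.0], [39.0, 400.0]])
    assert am.reverse_match(lib, lib) == 999
    noisy = np.vstack([lib, [[120.0, 50.0], [130.0, 30.0], [140.0, 20.0],
                             [150.0, 10.0], [160.0, 5.0]]])
    assert am.reverse_match(noisy, lib) == 999
    assert am.match_factor(noisy, lib) < 999


def test_reverse_geq_match_for_superset_queries():
    rng = np.random.default_rng(77)
    for _ in range(100):
        lib = random_spectrum(rng)
        extra = random_spectrum(rng)
        extra = extra[~np.isin(extra[:, 0], lib[:, 0])]
        query = np.vstack([lib, extra]) if extra.size else lib.copy()
        assert am.reverse_match(query, lib) >= am.match_factor(query, lib)


# ---------------------------------------------------------------------------
# probability
# ---------------------------------------------------------------------------

def _hit(match, entry=None):
    entry = entry or am.LibraryEntry(name=f"h{match}",
                                     spectrum=np.array([[50.0, 999.0]]))
    return LibraryHit(entry=entry, match=match, reverse_match=match)


def test_probability_single_hit_is_100():
    hits = am.probability([_hit(850)])
    assert hits[0].probability_pct == pytest.approx(100.0)


def test_probability_equal_hits_split_evenly():
    h1 = _hit(800)
    h2 = LibraryHit(entry=am.LibraryEntry(name="other",
                                          spectrum=np.array([[60.0, 999.0]])),
                    match=800, reverse_match=800)
    hits = am.probability([h1, h2])
    assert hits[0].probability_pct == pytest.approx(50.0)
    assert hits[1].probability_pct == pytest.approx(50.0)


def test_probability_matches_closed_form_softmax():
    h1, h2 = _hit(900), _hit(780)
    h2.entry = am.LibraryEntry(name="b", spectrum=np.array([[60.0, 999.0]]))
    hits = am.probability([h1, h2], k=60.0)
    expected_p1 = 100.0 / (1.0 + math.exp((780 - 900) / 60.0))
    assert hits[0].probability_pct == pytest.approx(expected_p1, abs=0.1)
    assert hits[0].probability_pct + hits[1].probability_pct == pytest.approx(100.0, abs=0.1)


def test_probability_invariant_to_zero_match_hit():
    h1, h2 = _hit(900), _hit(750)
    h2.entry = am.LibraryEntry(name="b", spectrum=np.array([[60.0, 999.0]]))
    before = [h.probability_pct for h in am.probability([h1, h2])]
    zero = LibraryHit(entry=am.LibraryEntry(name="z", spectrum=np.array([[70.0, 999.0]])),
                      match=0, reverse_match=0)
    after = am.probability([h1, h2, zero])
    assert [after[0].probability_pct, after[1].probability_pct] == pytest.approx(before)
    assert after[2].probability_pct == 0.0


def test_probability_empty_rejected():
    with pytest.raises(ParameterError):
        am.probability([])


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def test_rank1_identity_whole_library_sweep(bundled):
    for entry in bundled.entries:
        hits = am.search(entry.spectrum, bundled, top_k=5)
        assert hits[0].entry.name == entry.name
        assert hits[0].match == 999
        assert hits[0].rank == 1


def test_noisy_copy_still_rank1(bundled):
    rng = np.random.default_rng(5)
    for entry in bundled.entries[::7]:
        noisy = entry.spectrum.copy()
        noisy[:, 1] *= 1.0 + rng.uniform(-0.1, 0.1, size=len(noisy))
        hits = am.search(noisy, bundled)
        assert hits[0].entry.name == entry.name


def test_search_disjoint_returns_empty(bundled):
    q = np.array([[1000.0, 999.0], [1001.0, 500.0]])
    assert am.search(q, bundled) == []


def test_search_top_k(bundled):
    hits = am.search(bundled.entries[0].spectrum, bundled, top_k=3)
    assert len(hits) <= 3
    assert [h.rank for h in hits] == list(range(1, len(hits) + 1))
    assert sum(h.probability_pct for h in hits) == pytest.approx(100.0, abs=0.1)
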