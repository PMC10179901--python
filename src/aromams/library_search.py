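"""NIST-style spectral library search: Match, Reverse Match, Probability.

The match factor is the classical composite weighted cosine used for EI
library search, on nominal-mass (unit-binned) spectra:

    w(m/z, I) = I^0.6 * (m/z)^3
    MF = round(999 * (sum_shared sqrt(w_q * w_l))^2 / (sum w_q * sum w_l))

It is symmetric, scale-invariant in either spectrum's intensities, 999
exactly for spectra identical up to scale and 0 when no m/z is shared.
The reverse match is the same score computed after deleting query peaks at
m/z values absent from the library spectrum, so impurity peaks in the
query do not count against the candidate.

The Probability reported by the NIST software is proprietary and
undocumented; here it is a softmax over the match factors of the returned
hit list (temperature k = 60 match-factor units), which reproduces its
qualitative behavior — near 100 for an unambiguous top hit, split across
close alternatives — without claiming numerical equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io_formats import LibraryEntry, SpectralLibrary

#: intensity and m/z weighting exponents of the composite search score
INTENSITY_EXPONENT = 0.6
MZ_EXPONENT = 3.0

#: softmax temperature (match-factor units) for the probability substitute
PROBABILITY_K = 60.0

DEFAULT_TOP_K = 10


@dataclass
class LibraryHit:
    """One scored candidate identification from a library search."""

    entry: LibraryEntry
    match: int
    reverse_match: int
    probability_pct: float = 0.0
    rank: int = 0


def _nominal_bins(spectrum: np.ndarray) -> dict[int, float]:
    """Bin a (m/z, intensity) array to nominal mass, summing per bin."""
    spec = np.asarray(spectrum, dtype=float)
    if spec.ndim != 2 or spec.shape[1] != 2 or not spec.size:
        raise ParameterError("spectrum must be a non-empty (n, 2) array")
    bins: dict[int, float] = {}
    for mz, inten in spec:
        if inten <= 0:
            continue
        b = int(round(mz))
        bins[b] = bins.get(b, 0.0) + float(inten)
    if not bins:
        raise ParameterError("spectrum has no positive-intensity peaks")
    return bins


def _weights(bins: dict[int, float]) -> dict[int, float]:
    return {mz: (inten ** INTENSITY_EXPONENT) * (float(mz) ** MZ_EXPONENT)
            for mz, inten in bins.items()}


def _weighted_cosine_999(wq: dict[int, float], wl: dict[int, float]) -> int:
    shared = set(wq) & set(wl)
    if not shared:
        return 0
    num = sum(math.sqrt(wq[mz] * wl[mz]) for mz in shared) ** 2
    den = sum(wq.values()) * sum(wl.values())
    return int(round(999.0 * num / den))


def match_factor(query: np.ndarray, lib: np.ndarray) -> int:
    """Composite weighted-cosine match factor, 0-999."""
    return _weighted_cosine_999(_weights(_nominal_bins(query)),
                                _weights(_nominal_bins(lib)))


def reverse_match(query: np.ndarray, lib: np.ndarray) -> int:
    """Match factor ignoring query peaks absent from the library spectrum."""
    wq = _weights(_nominal_bins(query))
    wl = _weights(_nominal_bins(lib))
    wq_kept = {mz: w for mz, w in wq.items() if mz in wl}
    if not wq_kept:
        return 0
    return _weighted_cosine_999(wq_kept, wl)


def probability(hits: list[LibraryHit], k: float = PROBABILITY_K) -> list[LibraryHit]:
    """Assign softmax probabilities (percent) over a scored hit list.

    Probabilities are shared among hits with match > 0 and sum to 100;
    zero-match hits get exactly 0, so appending one never changes the
    probabilities of the others. The list is modified in place and
    returned for convenience.
    """
    if not hits:
        raise ParameterError("cannot assign probabilities to an empty hit list")
    scored = [h for h in hits if h.match > 0]
    if not scored:
        raise ParameterError("need at least one hit with match > 0")
    top = max(h.match for h in scored)
    expo = {id(h): math.exp((h.match - top) / k) for h in scored}
    total = sum(expo.values())
    for h in hits:
        h.probability_pct = 100.0 * expo[id(h)] / total if h.match > 0 else 0.0
    return hits


def search(spectrum: np.ndarray, library: SpectralLibrary,
           top_k: int = DEFAULT_TOP_K, k: float = PROBABILITY_K) -> list[LibraryHit]:
    """Rank library entries against a query spectrum.

    Hits are ordered by match factor (descending), ties broken by reverse
    match then library order; entries sharing no m/z with the query score
    0 and are omitted, so a query disjoint from the whole library returns
    an empty list. Probabilities are assigned over the returned (top-k)
    list.
    """
    if not len(library):
        raise ParameterError("cannot search an empty library")
    if top_k < 1:
        raise ParameterError("top_k must be >= 1")
    wq = _weights(_nominal_bins(spectrum))
    scored: list[tuple[int, int, int]] = []  # (match, reverse, library index)
    for i, entry in enumerate(library.entries):
        wl = _weights(_nominal_bins(entry.spectrum))
        m = _weighted_cosine_999(wq, wl)
        if m <= 0:
            continue
        wq_kept = {mz: w for mz, w in wq.items() if mz in wl}
        r = _weighted_cosine_999(wq_kept, wl) if wq_kept else 0
        scored.append((m, r, i))
    if not scored:
        return []
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    hits = [LibraryHit(entry=library.entries[i], match=m, reverse_match=r, rank=n + 1)
            for n, (m, r, i) in enumerate(scored[:top_k])]
    return probability(hits, k=k)
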