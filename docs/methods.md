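# Methods

This note documents the models and numerical choices behind `aromams`,
what its synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## Signal model

A GC–MS/NPD/(P)FPD(S) instrument splits one column flow to four detectors
recorded in parallel. The package models each eluting compound as a
Gaussian concentration profile of width σ (minutes): in the MS stream it
contributes that profile to every fragment m/z of its EI spectrum, scaled
by the fragment's relative intensity; in a selective channel it
contributes a single Gaussian at the compound RT plus a per-detector lag.
The lags are assumed constant over a run (constant column flow), which is
what makes RT alignment across detectors a pure offset-plus-tolerance
problem rather than a warping problem.

## Deconvolution

The deconvolver is a transparent re-statement of the classic
component-perception approach, not a port of any proprietary program.

1. **EIC extraction.** Scans are rebinned into unit-m/z traces centered on
   integers (nominal mass; EI quadrupole data). Every trace spans the full
   RT axis, so the sum of all EICs reproduces the TIC exactly.
2. **Noise.** Per trace, the noise scale is the median absolute successive
   difference divided by 0.9539 (its expectation for i.i.d. Gaussian noise
   of unit σ). The estimator sees only point-to-point scatter, so it is
   exactly invariant to baseline offsets, and peaks — occupying few
   points — barely bias the median. A constant trace yields exactly 0.
3. **Per-trace peaks.** Local maxima qualify when (a) the apex height
   above the trace baseline (the trace median — an EIC is baseline almost
   everywhere) is at least the sensitivity threshold times the noise, and
   (b) the neighborhood (±2 model σ) correlates with a Gaussian of the
   configured component width at or above the shape threshold. Peak-to-
   valley prominence was deliberately rejected as the sensitivity
   quantity: prominence spans from a +3σ noise excursion down into a −2σ
   valley and therefore passes ~3σ spikes at a nominal 5σ setting.
   Boundaries sit at the flanking minima (plateau-tolerant walk); the area
   is the trapezoidal integral above the linear baseline joining them.
   With zero estimated noise, any positive local maximum passes gate (a):
   a noiseless trace has no spurious maxima.
4. **Grouping.** Peaks across traces whose apexes fall within the apex
   grouping window (2 scans by default, "high resolution") form a
   component. Groups are seeded by the tallest unassigned peak; a peak
   eligible for several groups joins the nearest seed, distance ties going
   to the earlier-RT group. The component apex is the height-weighted mean
   of member apexes; the component S/N is the tallest member height over
   the largest member-trace noise. A component must be supported by at
   least two m/z traces (`min_member_traces`, configurable): a
   single-trace component is indistinguishable from a noise spike, and
   genuine EI spectra of volatiles always carry several fragments.
5. **Adjacent-peak subtraction.** For each member trace shared with a
   neighboring component (one neighbor per side by default), the
   neighbor's contribution — modeled as a Gaussian with the neighbor
   member's height at the neighbor component's apex — is integrated over
   the member's boundaries and subtracted from its area.
6. **Spectrum completion.** The detected members establish *where* the
   component is; the reported spectrum is then read back from the EIC
   matrix: for every m/z trace, the baseline-subtracted area over a fixed
   ±2σ window around the component apex, minus the modeled Gaussian
   contribution of nearby components sharing that trace. Traces that are
   not detected members enter the spectrum only when this corrected area
   exceeds 2.5 integrated-noise σ (noise · Δt · √W for a W-point window).
   Completion is what makes extracted spectra faithful for weak
   components: a compound whose base peak sits at S/N 10 has most of its
   minor fragments below any reasonable per-trace detection gate, yet
   those fragments are plainly present in the data at the established
   apex. The neighbor model is centered on the neighbor's consensus apex
   rather than the individual member's apex, which under noise can be a
   scan off — enough to leave a visible residue of a 10× stronger
   neighbor in a weak component's spectrum.

Defaults: component width 10 scans (model σ = width/4 = 2.5 scans),
sensitivity medium (S/N ≥ 5; low = 10, high = 2.5), shape requirement
medium (correlation ≥ 0.7; low = 0.5, high = 0.85), apex grouping window
2 scans, adjacent subtraction 1 neighbor per side. "Adjacent peak
subtraction = 1" is read as one neighbor on each side; levels are
configurable.

## Library search

Spectra are unit-binned to nominal mass and scaled to base peak 999. The
match factor is the composite weighted cosine with weights
`w = I^0.6 · (m/z)^3` — the classical exponents of the EI library-search
literature, emphasizing the heavy, structure-diagnostic ions. The score is
symmetric, invariant to rescaling either spectrum, 999 exactly for spectra
identical up to scale, and 0 for disjoint peak sets. The reverse match
deletes query peaks at m/z absent from the library entry before scoring,
so impurities and co-eluting residues in the extracted spectrum do not
penalize the candidate; for a query whose peaks are a superset of the
library entry's, reverse match ≥ match always.

The "Probability" of commercial search engines is proprietary and
undocumented; `aromams` substitutes a softmax over the match factors of
the returned hit list with temperature k = 60 match-factor units. A 120-
point lead then maps to ~88% — qualitatively matching how the commercial
number behaves (near-certain for unambiguous top hits, split across close
isomer candidates) without claiming numerical equivalence. Zero-match hits
receive exactly 0 and do not affect the others. The acceptance threshold
"Probability > 20" is applied to this substitute. Probabilities are
assigned over the returned top-k list (k = 10 by default); whether the
original tools normalize over the full library or the hit list is unknown,
and the hit list was chosen as the better-defined population.

## Retention indices

Ladder rungs (C_n at RT t_n) map to knots (t_n, 100 n); conversion is
piecewise-linear between knots (van den Dool–Kratz, correct for
temperature-programmed GC; the isothermal logarithmic Kovats form is not
used) and linearly extended from the terminal segments outside the ladder,
with an `extrapolated` flag that travels into the report. Extrapolated
values still participate in the ΔRI filter: very volatile analytes such as
methanethiol elute before the first alkane, and refusing them an RI would
silently disable the filter exactly where identifications are weakest.
ΔRI is `|observed − library|`; a library entry without an RI yields an
*absent* ΔRI, which is distinct from 0 — the RI clause of the acceptance
rule simply cannot fire, and the stricter no-RI clause
(Match > 800 and Probability > 20) takes over.

## Hit acceptance

`(ΔRI present and ΔRI < 100 and Match > 700) or
(Match > 800 and Probability > 20)`, every inequality strict. The
thresholds (ri_tolerance 100, match_min 700, match_min_no_ri 800,
probability_min_pct 20) are plain `FilterConfig` fields.

## Detector verification

Channel defaults: NPD covers {N} with lag +0.01 min; FPD(S) covers {S}
with lag +0.01 min; PFPD covers {S} with lag +0.05 min (electronic gating
delay); tolerance ±0.02 min everywhere. A candidate's heteroatoms come
from its molecular formula (Hill notation, parsed with pyteomics); for
each heteroatom covered by an active channel, confirmation requires a
channel peak whose apex lies within tolerance of the component RT plus the
lag, the nearest such peak winning and residual ties going to the earlier
peak. Channel peaks are *not* consumed by a match: several closely
co-eluting N compounds may legitimately share one broad NPD peak.
Compounds with no covered heteroatom (or no formula at all) are
`not_applicable` — they can never be "verified", and they also cannot be
rejected. For compounds with both N and S (thiazoles), the default
`all_elements` policy demands confirmation on both channels;
`any_element` is available because the correct logic is genuinely
ambiguous when detector sensitivities differ.

Verification annotates, it does not delete: the ALL report view keeps
every accepted identification with its verification state, and only the
N/S-VERIFIED view restricts to verified records — plus "unidentified"
rows for channel peaks that align with no MS component at all, which are
exactly the high-value leads this detector combination exists to surface.

## Synthetic data

The generator emulates the structure of real multi-detector runs: Gaussian
peaks (default σ 0.0125 min over a 0.005 min scan interval, so a peak
spans ~10 scans), fragment patterns from the bundled library, per-detector
channel lags equal to the pipeline's defaults, and additive Gaussian noise
over a constant baseline of 5 noise σ (a detector standing current;
without it, clipping intensities at zero halves the apparent noise and
biases difference-based estimation). MS peak heights are drawn so base-
peak S/N lies in (20, 200) by default; N/S compounds get channel responses
in a (50, 500) S/N range. Scenes place compounds uniformly in RT with a
minimum apex separation (default 0.025 min = 2σ); compounds sharing a
selective-channel element keep 0.06 min apart by default so that each has
its own resolvable channel peak — closer same-element pairs merge into
one channel peak whose apex cannot sit within the ±0.02 min window of
both, which is a real property of the physics, not a bug, and can be
studied by lowering the parameter or building `GroundTruth` directly.

What the generator does *not* emulate — and what passing tests therefore
do not demonstrate about real data: the bundled spectra are fixed
pseudo-random patterns, not measured EI spectra, so library search here is
easier than against a 300 000-entry commercial library full of near-
duplicate isomer spectra; scene RTs are random, so the synthetic runs do
not exercise the ΔRI clause end-to-end (it is tested directly with
constructed ladders); peak shapes are ideal Gaussians without tailing;
detector response is linear (the real FPD sulfur response is roughly
quadratic); and there are no matrix or column-bleed interferences beyond
white noise.

## Degenerate inputs and tie-breaks

Empty runs deconvolve to empty lists and screen to empty reports; empty
record lists produce header-only reports. Noise estimation requires ≥16
points and returns exactly 0 for constant traces; a zero-noise trace
passes any positive peak through the sensitivity gate and reports infinite
S/N (written as `inf`). Grouping ties go to the nearer, then earlier-RT
group; alignment ties to the earlier channel peak (compared with a 1 ns
slack so that floating-point representation cannot flip a tie); search
ties break by reverse match, then library order. Multiple components may
match the same library entry (isomers elute separately); only the rank-1
accepted hit is reported per component, with alternates preserved in the
JSON report.

## Limitations

The deconvolver assumes a roughly constant peak width across the run and
nominal-mass data; high-resolution accurate-mass workflows need different
binning. The Probability substitute is not the commercial algorithm and
its absolute values should not be compared across software. Quantitation
against reference standards, polar-column RI sets, phosphorus-mode FPD
and vendor file formats are out of scope.
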