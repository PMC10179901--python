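# aromams

Multi-detector GC–MS annotation of volatile aroma compounds.

Characterizing a food aroma (roasted meat, coffee, plant-based meat
substitutes, ...) by GC–MS alone is hard precisely where it matters most:
the nitrogen- and sulfur-containing volatiles that dominate odor are often
trace components, buried under abundant esters and aldehydes in a total-ion
chromatogram (TIC) with hundreds of partially separated peaks. Splitting the
column flow to element-selective detectors — a nitrogen–phosphorus detector
(NPD) and a (pulsed) flame photometric detector in sulfur mode
(FPD(S)/PFPD) — recorded in parallel with the MS gives clean, sparse
chromatograms in which every peak *must* contain N or S. `aromams`
implements the data-processing side of that experiment:

1. **Deconvolution** — the TIC is rebinned into nominal-mass extracted-ion
   chromatograms; per-trace peaks (S/N and Gaussian-shape gated) whose
   apexes coincide are grouped into components, and each component's
   spectrum is extracted from the EIC matrix around its apex with the
   modeled contribution of neighboring components removed.
2. **Library search** — each component spectrum is scored against an MSP
   library with the classical composite weighted cosine,
   `w(m/z, I) = I^0.6 · (m/z)^3`,
   `MF = 999 · (Σ_shared √(w_q w_l))² / (Σ w_q · Σ w_l)`,
   yielding Match and Reverse Match on the familiar 0–999 scale, plus a
   softmax-based Probability substitute (the vendor algorithm is
   proprietary).
3. **Retention-index filtering** — retention times are converted to the
   n-alkane index scale (C_n ↦ 100 n, van den Dool–Kratz piecewise-linear
   interpolation) and candidates are accepted by the rule
   **(ΔRI < 100 and Match > 700) or (Match > 800 and Probability > 20)**,
   all inequalities strict.
4. **Detector verification** — each accepted identification whose formula
   contains N or S is checked for a peak in the corresponding selective
   channel at the component RT plus the channel lag (defaults: NPD and
   FPD(S) +0.01 min, PFPD +0.05 min, tolerance ±0.02 min). The report comes
   in two views: ALL identifications, and the N/S-VERIFIED subset plus any
   detector-only unknown peaks.

Both non-targeted (public library) and targeted (user library with expected
RT windows) screening modes are supported. A synthetic-data module renders
complete multi-detector runs with exact ground truth from a bundled
55-entry library of roast-aroma volatiles (real names, formulas and CAS
numbers; fixed synthetic EI spectra — nothing proprietary is
redistributed), so the entire pipeline is testable without instrument
files.

## Worked example

Simulate a 12-compound run (40% N/S compounds) and screen it:

```sh
aromams simulate --n 12 --frac-ns 0.4 --seed 11 --out demo
aromams run --ms demo/ms_scan.csv --npd demo/npd.csv \
    --fpd demo/fpd_s.csv --pfpd demo/pfpd.csv \
    --library demo/library.msp --alkanes demo/ladder.csv --out demo/report
```

The log reports per-stage counts:

```
INFO aromams.screening: nontargeted screening: 12 components, 12 hits accepted, 12 records
INFO aromams: wrote 4 report files and demo/report_manifest.json
```

`demo/report_ns_verified.csv` then holds only the heteroatom-confirmed
rows, for example:

```
rt_min,name,cas,match,reverse_match,probability_pct,snr,area,...
1.83153,thiirane,,826,999,99.9936,45.7024,50.5439,...
3.35382,dimethyl disulfide,624-92-0,994,999,99.9664,28.1859,32.7489,...
```

Each row carries the component RT (min), the library name and CAS, the
Match/Reverse-Match scores (999 = identical spectra), the Probability (%),
the MS peak S/N and area, the ΔRI check, and the per-element verification
state (`S:confirmed`). A JSON manifest with input paths, the configuration
snapshot, the seed and SHA-256 checksums of every report accompanies each
run; re-running with the same inputs reproduces the reports byte for byte.

Single-spectrum queries work too:

```
$ aromams search --spectrum query.msp --library demo/library.msp --top-k 3
rank  match  rmatch   prob%  name
   1    999     999   100.0  pyrrole
   2     71     211     0.0  piperidine
   3     59     233     0.0  2-aminoethanol
```

All thresholds (acceptance rule, deconvolution sensitivity and shape,
channel lags and tolerances) are configurable through a TOML file passed
with `--config`; see `docs/methods.md` for every parameter, its default and
the reasoning behind it.

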