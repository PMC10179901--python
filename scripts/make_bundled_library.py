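"""Regenerate the bundled synthetic roast-aroma MSP library.

The bundled library (src/aromams/data/roast_aroma_synthetic.msp) carries
real compound names, formulas, CAS numbers and plausible non-polar
retention indices for 55 volatiles typical of roasted-food aroma work
(pyrazines, pyrroles, thiazoles, sulfides/thiols, aldehydes, furans,
esters), but its EI spectra are SYNTHETIC: fixed pseudo-random fragment
patterns seeded per compound. No proprietary library content is
redistributed. Run from the repository root:

    python scripts/make_bundled_library.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from aromams.io_formats import nominal_mass  # noqa: E402

MASTER_SEED = 20230501
OUT = Path(__file__).resolve().parents[1] / "src" / "aromams" / "data" / "roast_aroma_synthetic.msp"

# name, formula, non-polar RI (None = entry ships without an RI), CAS (optional)
COMPOUNDS = [
    ("methanethiol", "CH4S", 450, "74-93-1"),
    ("ethanethiol", "C2H6S", 510, None),
    ("dimethyl sulfide", "C2H6S", 520, "75-18-3"),
    ("thiirane", "C2H4S", None, None),
    ("dimethyl disulfide", "C2H6S2", 746, "624-92-0"),
    ("dimethyl trisulfide", "C2H6S3", 968, "3658-80-8"),
    ("dimethyl sulfone", "C2H6O2S", 920, None),
    ("methional", "C4H8OS", 909, None),
    ("2-furfurylthiol", "C5H6OS", 908, None),
    ("trimethylamine", "C3H9N", 420, "75-50-3"),
    ("2-aminoethanol", "C2H7NO", 670, None),
    ("2-(dimethylamino)ethanol", "C4H11NO", 760, None),
    ("pyrrole", "C4H5N", 750, "109-97-7"),
    ("1-methylpyrrole", "C5H7N", 740, None),
    ("2-methylpyrrole", "C5H7N", 800, None),
    ("2-acetylpyrrole", "C6H7NO", 1064, None),
    ("pyrrolidine", "C4H9N", None, None),
    ("piperidine", "C5H11N", 730, None),
    ("2-methylpiperidine", "C6H13N", None, None),
    ("pyrazine", "C4H4N2", 710, "290-37-9"),
    ("methylpyrazine", "C5H6N2", 820, None),
    ("2,5-dimethylpyrazine", "C6H8N2", 908, "123-32-0"),
    ("2,6-dimethylpyrazine", "C6H8N2", 912, None),
    ("2,3-dimethylpyrazine", "C6H8N2", 915, None),
    ("ethylpyrazine", "C6H8N2", 920, None),
    ("trimethylpyrazine", "C7H10N2", 1000, None),
    ("2-ethyl-3-methylpyrazine", "C7H10N2", 1002, None),
    ("tetramethylpyrazine", "C8H12N2", 1085, None),
    ("2-ethyl-3,5-dimethylpyrazine", "C8H12N2", 1078, None),
    ("thiazole", "C3H3NS", 730, "288-47-1"),
    ("2-methylthiazole", "C4H5NS", 790, None),
    ("4-methylthiazole", "C4H5NS", None, None),
    ("2-acetylthiazole", "C5H5NOS", 1020, None),
    ("benzothiazole", "C7H5NS", 1224, "95-16-9"),
    ("pentanal", "C5H10O", 695, None),
    ("2-methylbutanal", "C5H10O", 660, None),
    ("3-methylbutanal", "C5H10O", 650, None),
    ("hexanal", "C6H12O", 800, "66-25-1"),
    ("heptanal", "C7H14O", 901, None),
    ("octanal", "C8H16O", 1003, None),
    ("nonanal", "C9H18O", 1104, "124-19-6"),
    ("benzaldehyde", "C7H6O", 960, "100-52-7"),
    ("furfural", "C5H4O2", 830, "98-01-1"),
    ("2-furanmethanol", "C5H6O2", 850, None),
    ("2-acetylfuran", "C6H6O2", 910, None),
    ("2-pentylfuran", "C9H14O", 990, None),
    ("2,3-butanedione", "C4H6O2", 590, None),
    ("2-heptanone", "C7H14O", None, None),
    ("1-octen-3-ol", "C8H16O", None, None),
    ("butyrolactone", "C4H6O2", 915, None),
    ("methyl acetate", "C3H6O2", None, None),
    ("ethyl acetate", "C4H8O2", 610, "141-78-6"),
    ("methyl butanoate", "C5H10O2", 720, None),
    ("methyl hexanoate", "C7H14O2", 925, None),
    ("ethyl hexanoate", "C8H16O2", 1000, None),
]


def synth_spectrum(idx: int, formula: str) -> list[tuple[int, int]]:
    """Fixed pseudo-random EI fragment pattern for one compound."""
    rng = np.random.default_rng([MASTER_SEED, idx])
    mw = nominal_mass(formula)
    n_frag = int(rng.integers(6, 11))
    lo = 26
    pool = np.arange(lo, mw)
    frags = rng.choice(pool, size=min(n_frag - 1, pool.size), replace=False)
    mzs = np.concatenate([frags, [mw]])
    intens = rng.uniform(100.0, 950.0, size=mzs.size)
    intens *= 999.0 / intens.max()
    order = np.argsort(mzs)
    return [(int(m), int(round(i))) for m, i in zip(mzs[order], intens[order])]


def main() -> None:
    lines = []
    for idx, (name, formula, ri, cas) in enumerate(COMPOUNDS):
        peaks = synth_spectrum(idx, formula)
        lines.append(f"Name: {name}")
        lines.append("Comment: synthetic spectrum (fixed pseudo-random fragments); not a measured EI spectrum")
        if cas:
            lines.append(f"CAS#: {cas}")
        lines.append(f"Formula: {formula}")
        lines.append(f"MW: {nominal_mass(formula)}")
        if ri is not None:
            lines.append(f"RI: {ri}")
        lines.append(f"Num Peaks: {len(peaks)}")
        lines.extend(f"{m} {i}" for m, i in peaks)
        lines.append("")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text("\n".join(lines) + "\n")
    print(f"wrote {len(COMPOUNDS)} entries to {OUT}")


if __name__ == "__main__":
    main()
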