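"""Melt-curve Tm estimation and CD topology classification.

Simulates the with/without-K+ pair of thermal denaturation curves (midpoints
65 and 45 degrees C, 2% noise), estimates Tm by the derivative method with a
sigmoid-fit cross-check, and classifies band-rule CD spectra.  Also prints
the ThT enhancement and Beer-Lambert worked examples.
"""

import argparse
from pathlib import Path

import pandas as pd

from promscan.biophys import (
    classify_g4_topology,
    concentration_from_absorbance,
    estimate_tm,
    estimate_tm_sigmoid,
    tht_enhancement,
)
from promscan.simulate import make_cd_spectrum, make_melt_curve

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

rows = []
for label, midpoint in (("with_K", 65.0), ("without_K", 45.0)):
    curve, truth = make_melt_curve(midpoint, noise_sd=0.02, seed=args.seed)
    pd.DataFrame({"temperature_c": curve.temperature,
                  "signal": curve.signal}).to_csv(
        args.out_dir / f"melt_{label}.tsv", sep="\t", index=False)
    deriv = estimate_tm(curve)
    fit = estimate_tm_sigmoid(curve)
    flag = "ok" if abs(deriv.tm_c - fit.tm_c) <= 2.0 else "DISAGREE"
    rows.append({"condition": label, "planted_tm": truth,
                 "tm_derivative": round(deriv.tm_c, 2),
                 "tm_sigmoid_fit": round(fit.tm_c, 2), "cross_check": flag})
tm_table = pd.DataFrame(rows)
tm_table.to_csv(args.out_dir / "tm_estimates.tsv", sep="\t", index=False)
print(tm_table.to_string(index=False))
delta = rows[0]["tm_derivative"] - rows[1]["tm_derivative"]
print(f"K+-dependent Tm shift: {delta:.1f} C (planted 20.0)")

calls = {t: classify_g4_topology(make_cd_spectrum(t, noise_sd=0.01,
                                                  seed=args.seed))
         for t in ("parallel", "antiparallel", "hybrid")}
print("CD topology calls:", calls)

print(f"ThT enhancement F-F0 = {tht_enhancement(730.0, 10.0):.0f} a.u. "
      "(G4-forming oligo scale)")
print(f"ThT stock from A412 = 0.36: "
      f"{concentration_from_absorbance(0.36) * 1e6:.1f} uM")
print(f"wrote {args.out_dir}/melt_*.tsv and tm_estimates.tsv")
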