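"""Closed-form dating bias as a function of node age and calibration depth.

For the default saturation law (1 %/MY background, onset 20 MY, slope halved
every 10 MY beyond it) this tabulates the strict-clock age estimate against
the true age for single calibrations at 10, 30 and 60 MY.  The expected
pattern: Con10 dates everything up to 20 MY exactly and compresses older
nodes; Con30 and Con60 inflate young nodes (Con60 more than Con30) and
still compress the deepest ones.

Writes results/bias_profile.tsv and prints the sign pattern summary.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from satclock.saturation import CalibrationPoint, SaturationModel, bias_profile

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = SaturationModel()
    ages = np.arange(1.0, 71.0, 1.0)
    rows = []
    for cal_age in (10.0, 30.0, 60.0):
        cal = CalibrationPoint(cal_age, f"Con{cal_age:g}")
        for rec in bias_profile(model, ages, [cal]):
            rows.append(
                {"calibration": cal.label, "true_age": rec.true_age,
                 "estimated_age": round(rec.estimated_age, 4),
                 "deviation_pct": round(rec.deviation_pct, 2), "class": rec.cls}
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "bias_profile.tsv", sep="\t", index=False)

    for cal, sub in df.groupby("calibration"):
        young = sub[sub.true_age <= 20]
        old = sub[sub.true_age > 20]
        print(f"{cal}: nodes <=20 MY classes {sorted(young['class'].unique())}, "
              f">20 MY classes {sorted(old['class'].unique())}")
    con = {c: df[(df.calibration == c) & (df.true_age == 10)].estimated_age.iloc[0]
           for c in ("Con10", "Con30", "Con60")}
    print(f"true 10 MY node dated at: Con10 {con['Con10']:.2f}, "
          f"Con30 {con['Con30']:.2f}, Con60 {con['Con60']:.2f} MY "
          f"(overestimation grows with calibration depth)")


if __name__ == "__main__":
    main()
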