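"""Simulate the five-condition spent-medium assay for every interaction type
and tabulate the relative-AUC pattern grids (benign and inhibitory media).

The grid is the assay's core prediction: each row is one interaction type,
each column the responder's AUC rescaled so NC = 0 and MM = 1.
"""

from pathlib import Path

import pandas as pd

from smassay import CONDITION_ORDER, assay, build_scenario, labels_for
from smassay.features import auc_curve, relative_auc

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for env in ("benign", "inhibitory"):
    for label in labels_for(env):
        result = assay.run_sm_assay(build_scenario(label, env))
        aucs = {c: auc_curve(s.times, s.biomass[1]) for c, s in result.conditions.items()}
        rel = {c: relative_auc(aucs[c], aucs["NC"], aucs["MM"]) for c in CONDITION_ORDER}
        rows.append({"environment": env, "label": label,
                     **{c: round(rel[c], 4) for c in CONDITION_ORDER},
                     "sm_c3": round(result.sm_composition[2], 4),
                     "sm_c4": round(result.sm_composition[3], 4)})

grid = pd.DataFrame(rows)
grid.to_csv(OUT / "pattern_grids.csv", index=False)
print(grid.to_string(index=False))
print("\nBenign grid: EC empties the niche (SM, SM/2+NC at 0; SM/2+MM back at 1),")
print("NS leaves every condition at ~1, cross-feeding lifts SM above 1, and")
print("interference keeps SM/2+MM below 1 despite full carbon.")
print("Inhibitory grid: both NS+CF and NS+CD show SM above MM with BOTH")
print("replenished conditions below MM -- replenishing the medium replenishes")
print("the inhibitor, the signature that motivated the inhibitory model.")
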