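"""Interaction-type classification from the five-condition assay pattern.

The decision rules compare a responder's growth in the three spent-medium
conditions against the NC and MM controls:

* SM ≈ NC with no benefit in SM/2+NC: the producer emptied the responder's
  niche -- exploitative competition (EC); if replenishing carbon does not
  restore MM-level growth, interference is also at work (EC+IC).
* SM ≈ MM: the producer left the responder's niche untouched (NS).
* SM > MM: the spent medium outperforms fresh medium.  In a benign
  environment only cross-feeding can do this (NS+CF).  In an inhibitory
  environment both cross-feeding and cross-detoxification produce this
  signature together with replenished conditions falling below MM; the two
  are separated by :func:`cf_vs_cd` using the final yield and the diauxic
  bump (extra carbon raises the yield and produces a bump; removing an
  inhibitor does neither).
* SM intermediate between NC and MM: either the producer's leftovers feed
  the responder (EC+CF) or a secreted inhibitor delays it (NS+IC) -- the
  legendarily confusable pair, separated here by whether carbon
  replenishment (SM/2+MM) restores MM-level growth; both labels are kept in
  the ambiguity set.

When the explicit rules reach no leaf, the call falls back to
nearest-reference matching against the noise-free patterns simulated from the
scenario registry, which keeps the classifier consistent with the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

from . import assay as assay_mod
from . import features as feat
from .model import build_scenario, labels_for

#: Relative-AUC tolerance used to read symbols off noise-free simulations.
NOISE_FREE_TOL = 0.05

#: Practical-equivalence margin on the SM/MM final-yield ratio: differences
#: within this band are treated as "no yield difference" regardless of the
#: t-test, and a cross-feeding call requires exceeding it.
YIELD_EQUIVALENCE_MARGIN = 0.02


@dataclass
class InteractionCall:
    """Classified interaction with ambiguity set and diagnostics."""

    primary: str
    ambiguity: list[str]
    environment: str
    cfcd_verdict: str = "n/a"
    evidence: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.primary not in self.ambiguity:
            self.ambiguity = [self.primary, *self.ambiguity]


# ---------------------------------------------------------------------------
# reference patterns from the scenario registry

def _symbols_from_relative_aucs(rel: dict[str, float], tol: float = NOISE_FREE_TOL) -> dict:
    """Noise-free comparison symbols on the relative-AUC scale (NC=0, MM=1)."""
    symbols = {}
    for cond in feat.SM_CONDITIONS:
        for ref, ref_val in (("MM", 1.0), ("NC", 0.0)):
            diff = rel[cond] - ref_val
            symbols[(cond, ref)] = ">" if diff > tol else ("<" if diff < -tol else "≈")
    return symbols


@lru_cache(maxsize=None)
def reference_patterns(environment: str) -> dict[str, dict]:
    """Noise-free five-condition symbol patterns for every registry scenario."""
    out = {}
    for label in labels_for(environment):
        scenario = build_scenario(label, environment)
        result = assay_mod.run_sm_assay(scenario)
        aucs = {cond: feat.auc_curve(sim.times, sim.biomass[1])
                for cond, sim in result.conditions.items()}
        rel = {cond: feat.relative_auc(aucs[cond], aucs["NC"], aucs["MM"])
               for cond in assay_mod.CONDITION_ORDER}
        out[label] = _symbols_from_relative_aucs(rel)
    return out


def _nearest_reference(symbols: dict, environment: str) -> tuple[list[str], dict[str, int]]:
    refs = reference_patterns(environment)
    distances = {
        label: sum(symbols[key] != ref_syms[key] for key in ref_syms)
        for label, ref_syms in refs.items()
    }
    best = min(distances.values())
    return [lbl for lbl, d in distances.items() if d == best], distances


# ---------------------------------------------------------------------------
# decision tree

def classify(
    pattern: feat.PatternVector,
    environment: str,
    cfcd_verdict: str | None = None,
) -> InteractionCall:
    """Classify an interaction from its comparison pattern.

    A pure function of its inputs.  ``cfcd_verdict`` (from :func:`cf_vs_cd`)
    resolves the inhibitory CF-or-CD leaf; without it that leaf stays
    ambiguous.  A failed positive control (MM not above NC) yields
    ``unclassified`` with a diagnostic.
    """
    diagnostics: dict = {"notes": []}
    if not pattern.positive_control_ok():
        diagnostics["notes"].append(
            "positive control failed: mean AUC(MM) <= mean AUC(NC)"
        )
        return InteractionCall("unclassified", ["unclassified"], environment,
                               diagnostics=diagnostics)

    sym = pattern.symbol
    sm_mm = sym("SM", "MM")
    sm_nc = sym("SM", "NC")
    nc2_nc = sym("SM/2+NC", "NC")
    mm2_mm = sym("SM/2+MM", "MM")

    nearest, distances = _nearest_reference(pattern.symbols, environment)
    diagnostics["reference_distances"] = distances

    # niche emptied: no benefit from SM or from SM with salts replenished
    if sm_nc == "≈" and nc2_nc == "≈":
        if mm2_mm == "<":
            return InteractionCall("EC+IC", ["EC+IC"], environment,
                                   diagnostics=diagnostics)
        return InteractionCall("EC", ["EC"], environment, diagnostics=diagnostics)

    # niche untouched
    if sm_mm == "≈" and sm_nc == ">":
        return InteractionCall("NS", ["NS"], environment, diagnostics=diagnostics)

    # spent medium beats fresh medium
    if sm_mm == ">":
        if environment == "benign":
            return InteractionCall("NS+CF", ["NS+CF"], environment,
                                   cfcd_verdict="n/a", diagnostics=diagnostics)
        if cfcd_verdict == "CF":
            return InteractionCall("NS+CF", ["NS+CF", "NS+CD"], environment,
                                   cfcd_verdict="CF", diagnostics=diagnostics)
        if cfcd_verdict == "CD":
            return InteractionCall("NS+CD", ["NS+CF", "NS+CD"], environment,
                                   cfcd_verdict="CD", diagnostics=diagnostics)
        diagnostics["notes"].append(
            "SM > MM in an inhibitory environment: cross-feeding and "
            "cross-detoxification both fit; final-yield/bump evidence "
            + ("was ambiguous" if cfcd_verdict else "not supplied")
        )
        return InteractionCall(
            "unclassified", ["unclassified", "NS+CF", "NS+CD"], environment,
            cfcd_verdict=cfcd_verdict or "n/a", diagnostics=diagnostics,
        )

    # SM intermediate: leftovers cross-fed vs secreted inhibitor
    if sm_mm == "<" and sm_nc == ">":
        diagnostics["notes"].append(
            "intermediate SM growth: EC+CF and NS+IC are confusable; "
            "separated by whether carbon replenishment restores MM-level growth"
        )
        if mm2_mm == "<":
            return InteractionCall("NS+IC", ["NS+IC", "EC+CF"], environment,
                                   diagnostics=diagnostics)
        return InteractionCall("EC+CF", ["EC+CF", "NS+IC"], environment,
                               diagnostics=diagnostics)

    # no leaf: nearest simulated reference pattern(s)
    diagnostics["notes"].append(
        "no decision-tree leaf matched; used nearest simulated reference pattern"
    )
    return InteractionCall(nearest[0], list(nearest), environment,
                           diagnostics=diagnostics)


def residual_carbon_check(self_assay_pattern: feat.PatternVector) -> bool:
    """True when a producer grows significantly more in its own SM/2+MM
    (condition V) than in MM (condition II) -- leftover carbon in the spent
    medium, which can masquerade as cross-feeding to partners."""
    return self_assay_pattern.symbol("SM/2+MM", "MM") == ">"


# ---------------------------------------------------------------------------
# cross-feeding vs cross-detoxification

def cf_vs_cd(
    sm_curves: feat.GrowthCurveSet,
    mm_curves: feat.GrowthCurveSet,
    alpha: float = 0.05,
    equivalence_margin: float = YIELD_EQUIVALENCE_MARGIN,
) -> dict:
    """Separate cross-feeding from cross-detoxification on pure-SM curves.

    Requires that a positive SM effect is already established.  Two evidence
    bits are combined: (i) the final yield in SM significantly exceeds the MM
    yield by more than the practical-equivalence margin (extra carbon), and
    (ii) a diauxic bump appears in a majority of SM replicates and in no MM
    replicate (carbon-source switch).  Both bits pointing the same way give a
    CF or CD verdict; conflicting bits give ``ambiguous``.
    """
    sm_yields = np.array([feat.final_yield(sm_curves.times, row)
                          for row in sm_curves.corrected()])
    mm_yields = np.array([feat.final_yield(mm_curves.times, row)
                          for row in mm_curves.corrected()])
    ratio = float(sm_yields.mean() / mm_yields.mean())

    low_confidence = sm_yields.size < 2 or mm_yields.size < 2
    if low_confidence:
        yield_p = float("nan")
        yield_sig_greater = ratio > 1 + equivalence_margin
    else:
        yield_p = float(stats.ttest_ind(sm_yields, mm_yields, equal_var=True,
                                        alternative="greater").pvalue)
        yield_sig_greater = yield_p < alpha and ratio > 1 + equivalence_margin

    sm_bumps = [feat.detect_bump(sm_curves.times, row)["present"]
                for row in sm_curves.corrected()]
    mm_bumps = [feat.detect_bump(mm_curves.times, row)["present"]
                for row in mm_curves.corrected()]
    bump_sm_fraction = float(np.mean(sm_bumps))
    bump_mm_any = bool(np.any(mm_bumps))
    bump_majority = bump_sm_fraction > 0.5

    if yield_sig_greater:
        yield_bit = "CF"
    elif abs(ratio - 1.0) <= equivalence_margin:
        yield_bit = "CD"
    else:
        yield_bit = "neutral"
    if bump_majority and not bump_mm_any:
        bump_bit = "CF"
    elif not bump_majority:
        bump_bit = "CD"
    else:
        bump_bit = "neutral"

    bits = {yield_bit, bump_bit}
    if "CF" in bits and "CD" not in bits:
        verdict = "CF"
    elif "CD" in bits and "CF" not in bits:
        verdict = "CD"
    else:
        verdict = "ambiguous"

    return {
        "verdict": verdict,
        "yield_ratio": ratio,
        "yield_p": yield_p,
        "yield_evidence": yield_bit,
        "bump_sm": bump_sm_fraction,
        "bump_mm": bump_mm_any,
        "bump_evidence": bump_bit,
        "low_confidence": low_confidence,
    }


# ---------------------------------------------------------------------------
# end-to-end pipeline

def classify_assay(
    curves: dict[str, feat.GrowthCurveSet],
    environment: str,
    self_assay_curves: dict[str, feat.GrowthCurveSet] | None = None,
    alpha: float = 0.05,
) -> InteractionCall:
    """Full pipeline: replicate AUCs -> comparison pattern -> decision tree,
    with CF/CD resolution from the curves and an optional residual-carbon
    check from the producer's self-assay."""
    replicate_aucs = {cond: feat.auc(cs) for cond, cs in curves.items()}
    pattern = feat.compare_conditions(replicate_aucs, alpha=alpha)

    cfcd = None
    evidence: dict = {}
    if environment == "inhibitory" and "SM" in curves and "MM" in curves:
        evidence = cf_vs_cd(curves["SM"], curves["MM"], alpha=alpha)
        cfcd = evidence["verdict"]
    call = classify(pattern, environment, cfcd_verdict=cfcd)
    call.evidence = evidence

    if self_assay_curves is not None:
        self_aucs = {cond: feat.auc(cs) for cond, cs in self_assay_curves.items()}
        self_pattern = feat.compare_conditions(self_aucs, alpha=alpha)
        flag = residual_carbon_check(self_pattern)
        call.diagnostics["residual_carbon"] = flag
        if flag:
            call.diagnostics["notes"].append(
                "producer grew more in its own SM/2+MM than in MM: apparent "
                "cross-feeding may be residual carbon"
            )
            if "residual carbon" not in call.ambiguity:
                call.ambiguity.append("residual carbon")
    else:
        call.diagnostics["residual_carbon"] = None
        call.diagnostics["notes"].append("self-assay missing: residual-carbon check skipped")
    return call
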