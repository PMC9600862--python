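"""Cross-fed-candidate filtering for untargeted metabolomics tables.

Input tables are relative-abundance matrices (rows = metabolites, columns =
``<condition>_<replicate>``).  A candidate cross-fed compound must be
*produced* by the spent-medium producer (up in its SM versus fresh medium)
and then *consumed* by the responder (down in the SM after the responder grew
in it), with each change passing a linear fold-change gate (>= 10 by default)
and a one-factor ANOVA on log10-transformed abundances (p < 0.05).  No
multiple-testing correction is applied across metabolites by default, in
keeping with a raw p = 0.05 volcano threshold; a Bonferroni option is
exposed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def condition_columns(table: pd.DataFrame, condition: str) -> list[str]:
    """Columns of ``table`` belonging to ``condition`` (``<condition>_<rep>``)."""
    cols = [c for c in table.columns if c.rsplit("_", 1)[0] == condition]
    if not cols:
        raise KeyError(f"condition {condition!r} has no columns in the table")
    return cols


def pseudo_abundance(table: pd.DataFrame) -> float:
    """Half the smallest nonzero abundance: a rank-preserving floor for
    metabolites driven to zero by consumption."""
    values = table.to_numpy(dtype=float)
    nonzero = values[np.isfinite(values) & (values > 0)]
    if nonzero.size == 0:
        return 0.5
    return float(nonzero.min() / 2.0)


def log2_fc(
    table: pd.DataFrame,
    after_condition: str,
    before_condition: str,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Per-metabolite log2 fold change of condition means (after / before).

    Negative values mean the metabolite was consumed between the two states.
    Metabolites with no finite measurement in one condition are computed from
    the pseudo-abundance alone and flagged.
    """
    eps = pseudo_abundance(table) if pseudo is None else float(pseudo)
    after = table[condition_columns(table, after_condition)].mean(axis=1)
    before = table[condition_columns(table, before_condition)].mean(axis=1)
    flagged = after.isna() | before.isna()
    fc = np.log2(after.fillna(0.0) + eps) - np.log2(before.fillna(0.0) + eps)
    return pd.DataFrame({"log2_fc": fc, "flagged_missing": flagged})


def anova_log10(
    table: pd.DataFrame,
    metabolite,
    conditions: list[str],
    pseudo: float | None = None,
) -> float:
    """One-factor ANOVA p-value on log10(abundance + pseudo) across conditions."""
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    eps = pseudo_abundance(table) if pseudo is None else float(pseudo)
    groups = []
    for cond in conditions:
        vals = table.loc[metabolite, condition_columns(table, cond)].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")
        groups.append(np.log10(vals + eps))
    if all(g.var() == 0 for g in groups):
        means = [g.mean() for g in groups]
        if np.allclose(means, means[0]):
            return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = float(stats.f_oneway(*groups).pvalue)
    return 1.0 if np.isnan(p) else p


def filter_candidates(
    fcs: pd.Series | np.ndarray,
    ps: pd.Series | np.ndarray,
    min_fc: float = 10.0,
    alpha: float = 0.05,
    correct: bool = False,
) -> pd.DataFrame:
    """Apply the volcano gates: |linear fold change| >= ``min_fc`` and
    p < ``alpha``; direction from the sign of the log2 fold change.

    ``correct=True`` applies Bonferroni across metabolites (off by default).
    """
    fcs = pd.Series(fcs)
    ps = pd.Series(ps, index=fcs.index)
    if correct:
        ps = (ps * len(ps)).clip(upper=1.0)
    passes = (fcs.abs() >= np.log2(min_fc)) & (ps < alpha)
    direction = pd.Series("unchanged", index=fcs.index)
    direction[passes & (fcs < 0)] = "consumed"
    direction[passes & (fcs > 0)] = "produced"
    return pd.DataFrame({
        "log2_fc": fcs,
        "p": ps,
        "direction": direction,
        "passes_filter": passes,
    })


def crossfed_report(
    table: pd.DataFrame,
    fresh_mm: str = "fresh_mm",
    producer_sm: str = "producer_sm",
    producer_sm_after_responder: str = "sm_after_responder",
    min_fc: float = 10.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite production/consumption gates behind
    :func:`crossfed_candidates`."""
    for cond in (fresh_mm, producer_sm, producer_sm_after_responder):
        condition_columns(table, cond)  # raises naming the missing condition

    eps = pseudo_abundance(table)
    produced_fc = log2_fc(table, producer_sm, fresh_mm, pseudo=eps)["log2_fc"]
    consumed_fc = log2_fc(table, producer_sm_after_responder, producer_sm, pseudo=eps)["log2_fc"]
    produced_p = pd.Series(
        [anova_log10(table, m, [fresh_mm, producer_sm], pseudo=eps) for m in table.index],
        index=table.index,
    )
    consumed_p = pd.Series(
        [anova_log10(table, m, [producer_sm, producer_sm_after_responder], pseudo=eps)
         for m in table.index],
        index=table.index,
    )
    produced = filter_candidates(produced_fc, produced_p, min_fc, alpha)
    consumed = filter_candidates(consumed_fc, consumed_p, min_fc, alpha)
    return pd.DataFrame({
        "produced_log2_fc": produced["log2_fc"],
        "produced_p": produced["p"],
        "is_produced": produced["passes_filter"] & (produced["log2_fc"] > 0),
        "consumed_log2_fc": consumed["log2_fc"],
        "consumed_p": consumed["p"],
        "is_consumed": consumed["passes_filter"] & (consumed["log2_fc"] < 0),
    })


def crossfed_candidates(
    table: pd.DataFrame,
    fresh_mm: str = "fresh_mm",
    producer_sm: str = "producer_sm",
    producer_sm_after_responder: str = "sm_after_responder",
    min_fc: float = 10.0,
    alpha: float = 0.05,
) -> set:
    """Metabolites produced by the producer and then consumed by the
    responder: up in the producer's SM versus fresh medium and down again
    after the responder grew in that SM, both passing the fold-change and
    significance gates."""
    report = crossfed_report(
        table, fresh_mm, producer_sm, producer_sm_after_responder, min_fc, alpha
    )
    return set(report.index[report["is_produced"] & report["is_consumed"]])
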