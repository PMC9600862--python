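"""Growth-curve feature extraction and condition-level statistics.

The assay's scalar proxy for growth is the area under the OD600 curve (AUC),
which integrates lag, rate and yield without parametric curve fitting.  The
relative AUC maps the negative control (NC) to 0 and the positive control
(MM) to 1; values above 1 are possible (and diagnostic) under cross-feeding.
Lag time is operationalized as the first time the smoothed, blank-corrected
OD exceeds 1.5x its initial value -- a module convention, flagged as such in
output metadata.  The diauxic "bump" detector looks for an interior pause in
the specific growth rate that later recovers, the fingerprint of a switch
between carbon sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Documented operational definitions (carried in output metadata).
CONVENTIONS = {
    "lag_time": "first time smoothed blank-corrected OD exceeds 1.5x initial",
    "auc_scale": "linear blank-corrected OD",
}


@dataclass
class GrowthCurveSet:
    """Replicated OD600 time series for one assay condition.

    ``od`` has shape (n_replicates, n_times); times are shared across
    replicates and strictly increasing.  ``blank`` is the OD of sterile
    medium, subtracted (and clamped at zero) before any feature extraction.
    """

    condition: str
    times: np.ndarray
    od: np.ndarray
    blank: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.atleast_2d(np.asarray(self.od, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.od.shape[1] != self.times.size:
            raise ValueError("od and times are misaligned")

    @property
    def n_replicates(self) -> int:
        return self.od.shape[0]

    def corrected(self) -> np.ndarray:
        """Blank-corrected OD, clamped at zero."""
        return np.maximum(self.od - self.blank, 0.0)


def smooth(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the edges."""
    values = np.asarray(values, dtype=float)
    if window <= 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values)
    n = values.size
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = values[i - k:i + k + 1].mean()
    return out


# ---------------------------------------------------------------------------
# scalar features

def auc_curve(times: np.ndarray, od: np.ndarray, blank: float = 0.0) -> float:
    """Trapezoidal area under one blank-corrected OD curve."""
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(np.maximum(od - blank, 0.0), times))


def auc(curve_set: GrowthCurveSet) -> np.ndarray:
    """Per-replicate AUC of a curve set."""
    corr = curve_set.corrected()
    return np.array([float(np.trapezoid(row, curve_set.times)) for row in corr])


def relative_auc(auc_x: float, auc_nc: float, auc_mm: float) -> float:
    """Affine map sending the NC control to 0 and the MM control to 1.

    Values outside [0, 1] are legitimate (SM above MM under cross-feeding).
    """
    if auc_mm <= auc_nc:
        raise ValueError(
            f"positive control failed: AUC(MM)={auc_mm:.4g} <= AUC(NC)={auc_nc:.4g}"
        )
    return (auc_x - auc_nc) / (auc_mm - auc_nc)


def lag_time(
    times: np.ndarray,
    od: np.ndarray,
    blank: float = 0.0,
    fold_threshold: float = 1.5,
    smooth_window: int = 5,
) -> float | None:
    """First time the smoothed, blank-corrected OD exceeds
    ``fold_threshold`` times its initial value; ``None`` means no growth."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    times = np.asarray(times, dtype=float)
    corr = smooth(np.maximum(np.asarray(od, float) - blank, 0.0), smooth_window)
    initial = max(corr[0], 1e-6)
    above = np.nonzero(corr > fold_threshold * initial)[0]
    if above.size == 0:
        return None
    return float(times[above[0]])


def final_yield(
    times: np.ndarray,
    od: np.ndarray,
    blank: float = 0.0,
    tail_fraction: float = 0.05,
) -> float:
    """Mean blank-corrected OD over the last ``tail_fraction`` of time points."""
    od = np.maximum(np.asarray(od, float) - blank, 0.0)
    n_tail = max(1, int(np.ceil(tail_fraction * od.size)))
    return float(od[-n_tail:].mean())


def detect_bump(
    times: np.ndarray,
    od: np.ndarray,
    blank: float = 0.0,
    smooth_window: int = 5,
    rate_drop_fraction: float = 0.2,
    recover_fraction: float = 0.5,
    min_dip_duration: float = 0.5,
    growth_gate_fraction: float = 0.15,
    rate_support_fraction: float = 0.05,
) -> dict:
    """Detect a diauxic bump: an interior stationary interval between two
    growth phases.

    On the smoothed log-OD, a bump is an interval where the specific growth
    rate drops below ``rate_drop_fraction`` of the preceding running-maximum
    rate for at least ``min_dip_duration``, then recovers above
    ``recover_fraction`` of that running maximum, with meaningful growth both
    before the dip and after the recovery (``growth_gate_fraction`` of the
    total OD span).  The terminal plateau never qualifies because nothing
    grows after it.  Returns ``{"present": bool, "time": float | None}`` with
    ``time`` the dip midpoint.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 20:
        raise ValueError("need at least 20 time points")
    corr = np.maximum(np.asarray(od, float) - blank, 1e-3)
    s = smooth(corr, smooth_window)
    log_s = np.log(s)
    rate = smooth(np.gradient(log_s, times), smooth_window)

    s_init, s_final = s[0], float(np.mean(s[-max(1, s.size // 20):]))
    span = s_final - s_init
    if span <= 0.02:  # essentially no growth
        return {"present": False, "time": None}
    gate = s_init + growth_gate_fraction * span

    # Reference growth rate: running max of the rate, accumulated only where
    # the OD is meaningfully above its start -- the log-derivative is
    # noise-dominated near the detection floor and would inflate the maximum.
    supported = s >= s_init + rate_support_fraction * span
    runmax = np.maximum.accumulate(np.where(supported, rate, -np.inf))
    runmax = np.maximum(runmax, 0.0)
    absent = {"present": False, "time": None}
    i = 0
    n = times.size
    while i < n:
        pre_max = runmax[i]
        in_dip = (
            rate[i] < rate_drop_fraction * pre_max
            and s[i] >= gate
            and pre_max > 0
        )
        if not in_dip:
            i += 1
            continue
        t1 = times[i]
        j = i
        while j < n and rate[j] < recover_fraction * pre_max:
            j += 1
        if j >= n:
            return absent  # never recovered: that was the terminal plateau
        t2 = times[j]
        dip_long_enough = (t2 - t1) >= min_dip_duration
        post_gain = s_final - s[j]
        if dip_long_enough and post_gain >= growth_gate_fraction * span:
            return {"present": True, "time": float(0.5 * (t1 + t2))}
        i = j + 1
    return absent


# ---------------------------------------------------------------------------
# condition-level statistics

#: Spent-medium conditions compared against the two controls.
SM_CONDITIONS = ("SM/2+NC", "SM", "SM/2+MM")


@dataclass
class PatternVector:
    """Comparison symbols of each SM condition against the MM and NC controls.

    ``symbols[(condition, reference)]`` is one of ``"<"``, ``"≈"``, ``">"``;
    ``"≈"`` means not significant after Bonferroni correction over the
    family of comparisons for one producer/responder pair.
    """

    symbols: dict[tuple[str, str], str]
    p_raw: dict[tuple[str, str], float]
    p_adj: dict[tuple[str, str], float]
    means: dict[str, float]
    alpha: float = 0.05
    degenerate: list[tuple[str, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=lambda: dict(CONVENTIONS))

    def symbol(self, condition: str, reference: str) -> str:
        return self.symbols[(condition, reference)]

    def positive_control_ok(self) -> bool:
        return self.means.get("MM", 0.0) > self.means.get("NC", 0.0)


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Equal-variance two-sample t-test p-value, with degenerate handling."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 1.0, False
        return 0.0, True  # zero variance, unequal means: flagged degenerate
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue), False


def compare_conditions(
    replicate_aucs: dict[str, np.ndarray],
    references: tuple[str, ...] = ("MM", "NC"),
    alpha: float = 0.05,
) -> PatternVector:
    """Build the five-condition comparison pattern from replicate AUCs.

    Each spent-medium condition is compared to MM and to NC with two-sample
    equal-variance t-tests; Bonferroni correction is applied over the whole
    family of comparisons (one producer/responder pair); symbols follow the
    sign of the mean difference when significant, ``"≈"`` otherwise.
    """
    for name, vals in replicate_aucs.items():
        if np.asarray(vals).size < 2:
            raise ValueError(f"condition {name!r} needs >= 2 replicates")
    pairs = [
        (cond, ref)
        for cond in SM_CONDITIONS
        for ref in references
        if cond in replicate_aucs and ref in replicate_aucs
    ]
    raw = {}
    degenerate = []
    for cond, ref in pairs:
        pval, degen = _two_sample_t(replicate_aucs[cond], replicate_aucs[ref])
        raw[(cond, ref)] = pval
        if degen:
            degenerate.append((cond, ref))
    if raw:
        adj_vals = multipletests(list(raw.values()), alpha=alpha, method="bonferroni")[1]
    else:
        adj_vals = []
    adj = dict(zip(raw.keys(), (float(v) for v in adj_vals)))

    means = {name: float(np.mean(vals)) for name, vals in replicate_aucs.items()}
    symbols = {}
    for cond, ref in pairs:
        if adj[(cond, ref)] < alpha:
            symbols[(cond, ref)] = ">" if means[cond] > means[ref] else "<"
        else:
            symbols[(cond, ref)] = "≈"
    return PatternVector(
        symbols=symbols, p_raw=raw, p_adj=adj, means=means, alpha=alpha,
        degenerate=degenerate,
    )


def condition_features(
    curves: dict[str, GrowthCurveSet],
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Per-replicate feature table (AUC, lag, final yield, bump) with one row
    per (condition, replicate)."""
    rows = []
    for cond, cs in curves.items():
        corr = cs.corrected()
        for rep in range(cs.n_replicates):
            row = {
                "condition": cond,
                "replicate": rep,
                "auc": auc_curve(cs.times, corr[rep]),
                "lag_time": lag_time(cs.times, corr[rep], smooth_window=smooth_window),
                "final_yield": final_yield(cs.times, corr[rep]),
            }
            if cs.times.size >= 20:
                bump = detect_bump(cs.times, corr[rep], smooth_window=smooth_window)
                row["bump_present"] = bump["present"]
                row["bump_time"] = bump["time"]
            else:
                row["bump_present"] = False
                row["bump_time"] = None
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate-reader file formats

def write_plate_long(curves: dict[str, GrowthCurveSet], path) -> None:
    """Write curve sets as long-format CSV: time_h, condition, replicate, od600."""
    frames = []
    for cond, cs in curves.items():
        for rep in range(cs.n_replicates):
            frames.append(pd.DataFrame({
                "time_h": cs.times,
                "condition": cond,
                "replicate": rep,
                "od600": cs.od[rep],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_plate_long(path, blank: float = 0.0) -> dict[str, GrowthCurveSet]:
    """Read a long-format plate CSV back into curve sets."""
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, GrowthCurveSet] = {}
    for cond, grp in df.groupby("condition", sort=False):
        reps = []
        times = None
        for _, rep_grp in grp.groupby("replicate", sort=True):
            rep_grp = rep_grp.sort_values("time_h")
            t = rep_grp["time_h"].to_numpy()
            if times is None:
                times = t
            elif not np.allclose(times, t):
                raise ValueError(f"replicates of {cond!r} disagree on time grid")
            reps.append(rep_grp["od600"].to_numpy())
        out[str(cond)] = GrowthCurveSet(str(cond), times, np.vstack(reps), blank=blank)
    return out


def read_plate_wide(path, well_map_path, blank: float = 0.0) -> dict[str, GrowthCurveSet]:
    """Read a wide 96-well CSV (first column time, one column per well) plus a
    well-to-condition map CSV with columns well, condition[, replicate]."""
    wide = pd.read_csv(path, float_precision="round_trip")
    well_map = pd.read_csv(well_map_path)
    times = wide.iloc[:, 0].to_numpy(dtype=float)
    grouped: dict[str, list[np.ndarray]] = {}
    if "replicate" in well_map.columns:
        well_map = well_map.sort_values(["condition", "replicate"])
    for _, row in well_map.iterrows():
        well = str(row["well"])
        if well not in wide.columns:
            raise ValueError(f"well {well!r} missing from the plate file")
        grouped.setdefault(str(row["condition"]), []).append(
            wide[well].to_numpy(dtype=float)
        )
    return {
        cond: GrowthCurveSet(cond, times, np.vstack(rows), blank=blank)
        for cond, rows in grouped.items()
    }
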