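"""Seeded generators for plate-reader-like growth curves and metabolite
abundance tables with known ground truth.

The curve generator runs the in-silico spent-medium assay, samples the
responder's biomass on a plate-reader grid (10-minute sampling by default),
maps biomass to OD600 one-to-one plus a blank offset, and applies
plate-reader-style noise: a multiplicative term (proportional error) and an
additive term (instrument floor), truncated at zero.  The metabolome
generator spikes known produced / consumed / cross-fed compounds onto a
log-normal baseline.  Every output is a pure function of (spec, seed), and a
ground-truth sidecar JSON accompanies every file so downstream recovery is
self-checking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assay as assay_mod
from . import features as feat
from .model import Scenario


@dataclass
class NoiseModel:
    """Plate-reader noise: ``od_noisy = max(0, od*(1+m) + a)`` with
    ``m ~ N(0, multiplicative_sd)`` and ``a ~ N(0, additive_sd)`` drawn per
    measurement, plus a sterile-medium blank added to every well."""

    additive_sd: float = 0.005
    multiplicative_sd: float = 0.02
    blank: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def apply(self, od: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        mult = rng.normal(0.0, self.multiplicative_sd, size=od.shape) if self.multiplicative_sd else 0.0
        add = rng.normal(0.0, self.additive_sd, size=od.shape) if self.additive_sd else 0.0
        return np.maximum(od * (1.0 + mult) + add, 0.0)


@dataclass
class MetabolomeSpec:
    """Ground-truthed metabolome layout.

    ``crossfed`` metabolites rise by ``spike_fc`` in the producer's spent
    medium and fall back after the responder grows in it; ``produced``
    metabolites rise and stay; ``consumed`` metabolites start at baseline and
    fall.  All remaining metabolites are nuisance, wobbling by at most
    ``nuisance_fc`` between conditions.  The three id lists are disjoint.
    """

    n_metabolites: int = 50
    crossfed: list[int] = field(default_factory=list)
    produced: list[int] = field(default_factory=list)
    consumed: list[int] = field(default_factory=list)
    spike_fc: float = 20.0
    nuisance_fc: float = 2.0
    cv: float = 0.2
    n_replicates: int = 3
    baseline: float = 1000.0
    baseline_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        ids = self.crossfed + self.produced + self.consumed
        if len(set(ids)) != len(ids):
            raise ValueError("spiked id lists must be disjoint")
        if any(i < 0 or i >= self.n_metabolites for i in ids):
            raise ValueError("spike id out of range")
        if self.spike_fc <= 1:
            raise ValueError("spike fold change must be > 1")


# ---------------------------------------------------------------------------
# growth curves

def curves_from_assay(
    assay_result: assay_mod.AssayResult,
    noise: NoiseModel,
    n_rep: int = 3,
    interval: float | None = None,
    duration: float | None = None,
) -> dict[str, feat.GrowthCurveSet]:
    """Sample a deterministic assay onto a plate grid and add replicate noise."""
    rng = np.random.default_rng(noise.seed)
    out: dict[str, feat.GrowthCurveSet] = {}
    for cond in assay_mod.CONDITION_ORDER:
        sim = assay_result.conditions[cond]
        times, biomass = sim.times, sim.biomass[1]
        if interval is not None:
            t_max = duration if duration is not None else times[-1]
            n_steps = int(round(t_max / interval))
            if abs(n_steps * interval - t_max) > 1e-9:
                raise ValueError("interval must divide duration")
            grid = np.linspace(0.0, t_max, n_steps + 1)
            biomass = np.interp(grid, times, biomass)
            times = grid
        od_true = biomass + noise.blank
        reps = np.vstack([noise.apply(od_true, rng) for _ in range(n_rep)])
        out[cond] = feat.GrowthCurveSet(cond, times.copy(), reps, blank=noise.blank)
    return out


def generate_curves(
    scenario: Scenario,
    noise: NoiseModel,
    n_rep: int = 3,
    interval: float = 1.0 / 6.0,
    duration: float | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, feat.GrowthCurveSet]:
    """Run the five-condition assay for ``scenario`` and emit noisy replicated
    OD600 curves (optionally written as a long CSV plus a truth sidecar)."""
    duration = scenario.t_end if duration is None else float(duration)
    if abs(round(duration / interval) * interval - duration) > 1e-9:
        raise ValueError("interval must divide duration")
    result = assay_mod.run_sm_assay(scenario, t_end=duration, dt=interval)
    curves = curves_from_assay(result, noise, n_rep=n_rep)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        feat.write_plate_long(curves, out_dir / "curves.csv")
        truth = {
            "label": scenario.label,
            "environment": scenario.environment,
            "n_replicates": n_rep,
            "interval": interval,
            "duration": duration,
            "noise": {
                "additive_sd": noise.additive_sd,
                "multiplicative_sd": noise.multiplicative_sd,
                "blank": noise.blank,
                "seed": noise.seed,
            },
            "sm_composition": [float(x) for x in result.sm_composition],
        }
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return curves


def write_plate_wide(
    curves: dict[str, feat.GrowthCurveSet], plate_path, map_path
) -> None:
    """Write curves in the wide 96-well dialect plus a well-condition map."""
    wells = {}
    mapping = []
    col = 1
    for cond, cs in curves.items():
        for rep in range(cs.n_replicates):
            well = f"A{col}"
            wells[well] = cs.od[rep]
            mapping.append({"well": well, "condition": cond, "replicate": rep})
            col += 1
    first = next(iter(curves.values()))
    wide = pd.DataFrame({"time_h": first.times, **wells})
    wide.to_csv(plate_path, index=False, float_format="%.17g")
    pd.DataFrame(mapping).to_csv(map_path, index=False)


# ---------------------------------------------------------------------------
# metabolome tables

CONDITIONS = ("fresh_mm", "producer_sm", "sm_after_responder")


def generate_metabolome(
    spec: MetabolomeSpec,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Generate an abundance table with spiked ground truth.

    Replicate noise is log-normal with the requested coefficient of
    variation, mean-corrected so that group means sit exactly at
    baseline x spike factors when ``cv = 0``.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.baseline * rng.lognormal(0.0, spec.baseline_sigma, spec.n_metabolites)

    # per-condition deterministic means
    means = {cond: base.copy() for cond in CONDITIONS}
    for i in spec.crossfed:
        means["producer_sm"][i] *= spec.spike_fc
        # back to baseline after the responder consumed it
    for i in spec.produced:
        means["producer_sm"][i] *= spec.spike_fc
        means["sm_after_responder"][i] *= spec.spike_fc
    for i in spec.consumed:
        means["sm_after_responder"][i] /= spec.spike_fc
    spiked = set(spec.crossfed) | set(spec.produced) | set(spec.consumed)
    nuisance = [i for i in range(spec.n_metabolites) if i not in spiked]
    if spec.nuisance_fc > 1:
        log_max = np.log(spec.nuisance_fc)
        for cond in CONDITIONS[1:]:
            wobble = np.exp(rng.uniform(-log_max, log_max, len(nuisance)))
            means[cond][nuisance] *= wobble

    sigma = np.sqrt(np.log1p(spec.cv ** 2))
    columns = {}
    for cond in CONDITIONS:
        for rep in range(1, spec.n_replicates + 1):
            if sigma > 0:
                noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, spec.n_metabolites)
            else:
                noise = 1.0
            columns[f"{cond}_{rep}"] = means[cond] * noise
    table = pd.DataFrame(columns, index=[f"m{i:03d}" for i in range(spec.n_metabolites)])
    table.index.name = "metabolite"

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "metabolome.csv", float_format="%.17g")
        truth = {
            "crossfed": [f"m{i:03d}" for i in spec.crossfed],
            "produced": [f"m{i:03d}" for i in spec.produced],
            "consumed": [f"m{i:03d}" for i in spec.consumed],
            "spike_fc": spec.spike_fc,
            "nuisance_fc": spec.nuisance_fc,
            "cv": spec.cv,
            "n_replicates": spec.n_replicates,
            "seed": spec.seed,
        }
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return table
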