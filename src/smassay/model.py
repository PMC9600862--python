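"""Two-species, four-compound consumer-resource model with inhibitor-induced lags.

The model underlies the in-silico spent-medium assay.  Two species ``S1``
(the spent-medium producer) and ``S2`` (the responder) grow in batch culture
on four compounds:

* ``C1`` -- carbon source of species 1,
* ``C2`` -- carbon source of species 2 (identical to ``C1`` under
  exploitative competition),
* ``C3`` -- an inhibitory compound.  It does not kill; it prolongs the lag
  phase of a sensitive species in proportion to its concentration at
  inoculation.  A fresh inhibitory medium carries ``C3`` = 3.5; interference
  competition is the secretion of the same compound by species 1.
* ``C4`` -- a metabolic by-product of species 1 that species 2 can cross-feed
  on; it is always absent from fresh media.

Growth of species *i* on compound *j* follows Monod kinetics gated by a hard
lag::

    dS_i/dt = S_i * sum_j r[i,j] * c_j/(K[i,j]+c_j) * 1[t >= T[i,j]]

with lag time ``T[i,j] = sum_k l[i,j,k] * c_k(0)`` computed from the medium at
inoculation.  Compound balance combines consumption (scaled by the inverse
yield), production, and growth-independent uptake (the cross-detoxification
route, which confers no biomass)::

    dc_j/dt = sum_i [ -(r[i,j]/y[i,j]) * S_i * c_j/(K+c_j) * gate
                      - u[i,j] * S_i * c_j + p[i,j] * S_i ]

There is no death or maintenance term, so biomass is non-decreasing and a
compound neither produced nor consumed by the present species is conserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

N_COMPOUNDS = 4

#: Interaction labels: exploitative competition (EC), niche separation (NS),
#: optionally combined with interference competition (+IC), cross-feeding
#: (+CF) or cross-detoxification (+CD, inhibitory environments only).
BENIGN_LABELS = ("EC", "EC+IC", "EC+CF", "NS", "NS+IC", "NS+CF")
INHIBITORY_LABELS = BENIGN_LABELS + ("NS+CD",)
ENVIRONMENTS = ("benign", "inhibitory")

#: Default inhibitor concentration of a fresh 1x inhibitory medium.
C3_INHIBITORY_LEVEL = 3.5

#: Minimal-medium carbon sources, mirroring 15 mM glucose / 10 mM citric acid.
MM_C1 = 15.0
MM_C2 = 10.0


class ScenarioError(ValueError):
    """Raised for invalid scenario construction or overrides."""


class SimulationError(RuntimeError):
    """Raised when the integrator produces a non-finite or negative state."""


@dataclass
class SpeciesParams:
    """Per-species kinetic parameters, indexed by compound (0-based).

    ``r`` growth rate at saturation (1/time), ``K`` half-saturation
    (concentration), ``y`` biomass yield per unit compound, ``p`` production
    (compound per biomass per time), ``u`` growth-independent uptake (per
    biomass per time; carries cross-detoxification), ``l`` lag coefficients
    (time per unit concentration): ``l[j, k]`` is the lag of growth on
    compound *j* caused by compound *k*.
    """

    id: int
    r: np.ndarray = field(default_factory=lambda: np.zeros(N_COMPOUNDS))
    K: np.ndarray = field(default_factory=lambda: np.zeros(N_COMPOUNDS))
    y: np.ndarray = field(default_factory=lambda: np.zeros(N_COMPOUNDS))
    p: np.ndarray = field(default_factory=lambda: np.zeros(N_COMPOUNDS))
    u: np.ndarray = field(default_factory=lambda: np.zeros(N_COMPOUNDS))
    l: np.ndarray = field(default_factory=lambda: np.zeros((N_COMPOUNDS, N_COMPOUNDS)))

    def __post_init__(self) -> None:
        for name in ("r", "K", "y", "p", "u", "l"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr < 0):
                raise ScenarioError(f"species {self.id}: parameter {name} must be >= 0")
        if self.r.shape != (N_COMPOUNDS,) or self.l.shape != (N_COMPOUNDS, N_COMPOUNDS):
            raise ScenarioError("parameter arrays have the wrong shape")
        if np.any((self.r > 0) & (self.y <= 0)):
            raise ScenarioError(
                f"species {self.id}: r[i,j] > 0 requires y[i,j] > 0 (mass balance)"
            )

    def copy(self) -> "SpeciesParams":
        return SpeciesParams(
            id=self.id, r=self.r.copy(), K=self.K.copy(), y=self.y.copy(),
            p=self.p.copy(), u=self.u.copy(), l=self.l.copy(),
        )


@dataclass
class Scenario:
    """Full configuration of a pairwise interaction experiment."""

    label: str
    environment: str
    species: tuple[SpeciesParams, SpeciesParams]
    medium0: np.ndarray
    inoculum: np.ndarray
    c3_inhibitory_level: float = C3_INHIBITORY_LEVEL
    t_end: float = 72.0
    dt: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        self.medium0 = np.asarray(self.medium0, dtype=float)
        self.inoculum = np.asarray(self.inoculum, dtype=float)
        if self.medium0.shape != (N_COMPOUNDS,) or np.any(self.medium0 < 0):
            raise ScenarioError("medium0 must be four non-negative concentrations")
        if self.inoculum.shape != (2,) or np.any(self.inoculum < 0):
            raise ScenarioError("inoculum must be two non-negative biomasses")
        if self.environment not in ENVIRONMENTS:
            raise ScenarioError(f"unknown environment {self.environment!r}")

    def copy(self) -> "Scenario":
        return replace(
            self,
            species=(self.species[0].copy(), self.species[1].copy()),
            medium0=self.medium0.copy(),
            inoculum=self.inoculum.copy(),
        )


@dataclass
class SimulationResult:
    """Trajectories on a regular output grid."""

    times: np.ndarray
    biomass: np.ndarray      # (2, n)
    compounds: np.ndarray    # (4, n)
    stationary_time: float | None

    def total_biomass(self) -> np.ndarray:
        return self.biomass.sum(axis=0)


# ---------------------------------------------------------------------------
# scenario registry

# Registry defaults.  Growth/affinity/yield defaults are shared; production,
# uptake and lag coefficients are per scenario, chosen so each scenario's
# relative-AUC pattern reproduces the published qualitative grids.  The benign
# assay window (8 a.u.) sits in the interaction-limited regime: no condition
# exhausts its carbon within the window, so niche separation reads as "no
# effect" in every condition.  The inhibitory window (72 a.u.) is dominated by
# the inhibitor-induced lag (l = 14 => 49 a.u. of lag at C3 = 3.5).
_R_DEFAULT = 0.5
_K_DEFAULT = 0.05
_Y_DEFAULT = 1.0
_INOCULUM = 0.05
_P_IC = 0.1          # interference: C3 production by species 1
_L_IC_BENIGN = 0.8   # responder lag sensitivity to secreted C3 (benign)
_L_INHIBITORY = 14.0  # responder lag sensitivity to C3 (inhibitory env)
_T_END = {"benign": 8.0, "inhibitory": 72.0}

# cross-feeding defaults: producer C4 secretion rate / responder growth on C4
_CF_PARAMS = {
    ("EC+CF", "benign"): {"p14": 0.015, "r24": 0.5},
    ("NS+CF", "benign"): {"p14": 0.009, "r24": 0.3},
    ("EC+CF", "inhibitory"): {"p14": 0.09, "r24": 0.5},
    ("NS+CF", "inhibitory"): {"p14": 0.09, "r24": 0.5},
}
_U_CD = 0.03         # cross-detox: growth-independent uptake of C3 by species 1

_OVERRIDE_SCALAR_KEYS = {"t_end", "dt", "c3_inhibitory_level"}
_OVERRIDE_RE = re.compile(
    r"^([rKypul])\[?(\d)[,_]?(\d)(?:[,_]?(\d))?\]?$"
)


def labels_for(environment: str) -> tuple[str, ...]:
    return INHIBITORY_LABELS if environment == "inhibitory" else BENIGN_LABELS


def build_scenario(label: str, environment: str, overrides: dict | None = None) -> Scenario:
    """Construct a fully parameterized scenario from the registry.

    ``overrides`` maps parameter names to values and is applied last.  Keys:
    ``"p[1,4]"`` / ``"p14"`` style kinetic entries (1-based species and
    compound indices, three indices for lag coefficients ``l[i,j,k]``),
    ``"medium0[j]"``, ``"inoculum[i]"``, and the scalars ``t_end``, ``dt``,
    ``c3_inhibitory_level``.
    """
    if environment not in ENVIRONMENTS:
        raise ScenarioError(f"unknown environment {environment!r}")
    if label not in INHIBITORY_LABELS:
        raise ScenarioError(f"unknown interaction label {label!r}")
    if label == "NS+CD" and environment == "benign":
        raise ScenarioError(
            "NS+CD requires an inhibitory environment: cross-detoxification "
            "is only defined when an environmental inhibitor (C3) is present"
        )

    sp1 = SpeciesParams(id=1)
    sp2 = SpeciesParams(id=2)
    for sp in (sp1, sp2):
        sp.K[:] = _K_DEFAULT
        sp.y[:] = _Y_DEFAULT

    # carbon niches: producer always grows on C1; responder on C1 (EC family)
    # or C2 (NS family).
    responder_carbon = 0 if label.startswith("EC") else 1
    sp1.r[0] = _R_DEFAULT
    sp2.r[responder_carbon] = _R_DEFAULT

    if label.endswith("+IC"):
        sp1.p[2] = _P_IC
        sp2.l[responder_carbon, 2] = _L_IC_BENIGN
    if label.endswith("+CF"):
        cf = _CF_PARAMS[(label, environment)]
        sp1.p[3] = cf["p14"]
        sp2.r[3] = cf["r24"]
    if label.endswith("+CD"):
        sp1.u[2] = _U_CD

    medium0 = np.array([MM_C1, MM_C2, 0.0, 0.0])
    if environment == "inhibitory":
        medium0[2] = C3_INHIBITORY_LEVEL
        # the environment delays the responder's growth on its carbon source
        sp2.l[responder_carbon, 2] = _L_INHIBITORY

    scenario = Scenario(
        label=label,
        environment=environment,
        species=(sp1, sp2),
        medium0=medium0,
        inoculum=np.array([_INOCULUM, _INOCULUM]),
        t_end=_T_END[environment],
    )
    if overrides:
        scenario = apply_overrides(scenario, overrides)
    return scenario


def apply_overrides(scenario: Scenario, overrides: dict) -> Scenario:
    """Return a copy of ``scenario`` with the override map applied."""
    out = scenario.copy()
    for key, value in overrides.items():
        value = float(value)
        if key in _OVERRIDE_SCALAR_KEYS:
            if value <= 0 and key in ("t_end", "dt"):
                raise ScenarioError(f"override {key} must be positive")
            if value < 0:
                raise ScenarioError(f"negative override for {key}")
            setattr(out, key, value)
            continue
        if value < 0:
            raise ScenarioError(f"negative override for {key}: {value}")
        m = re.match(r"^medium0\[?(\d)\]?$", key)
        if m:
            out.medium0[int(m.group(1)) - 1] = value
            continue
        m = re.match(r"^inoculum\[?(\d)\]?$", key)
        if m:
            out.inoculum[int(m.group(1)) - 1] = value
            continue
        m = _OVERRIDE_RE.match(key)
        if m is None:
            raise ScenarioError(f"unrecognized override key {key!r}")
        name, i, j, k = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
        sp = out.species[i - 1]
        if name == "l":
            if k is None:
                raise ScenarioError(f"lag override {key!r} needs three indices l[i,j,k]")
            sp.l[j - 1, int(k) - 1] = value
        else:
            if k is not None:
                raise ScenarioError(f"override {key!r} takes two indices")
            getattr(sp, name)[j - 1] = value
    # re-validate cross-field invariants
    for sp in out.species:
        if np.any((sp.r > 0) & (sp.y <= 0)):
            raise ScenarioError("override broke invariant: r[i,j] > 0 requires y[i,j] > 0")
    return out


# ---------------------------------------------------------------------------
# lag rule and integration

def effective_lag(species: SpeciesParams, growth_compound: int, medium0: np.ndarray) -> float:
    """Lag time of ``species`` on ``growth_compound`` (0-based) in ``medium0``.

    The lag is linear in the inoculation medium: ``T = sum_k l[j,k] * c_k``.
    Zero coefficients give zero lag.
    """
    medium0 = np.asarray(medium0, dtype=float)
    return float(species.l[growth_compound] @ medium0)


def _lag_matrix(scenario: Scenario, medium0: np.ndarray) -> np.ndarray:
    T = np.zeros((2, N_COMPOUNDS))
    for i, sp in enumerate(scenario.species):
        for j in range(N_COMPOUNDS):
            T[i, j] = effective_lag(sp, j, medium0)
    return T


def simulate(
    scenario: Scenario,
    medium: np.ndarray | None = None,
    inoculum: np.ndarray | None = None,
    t_end: float | None = None,
    dt: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationResult:
    """Integrate the batch culture and return trajectories on a regular grid.

    ``medium`` and ``inoculum`` default to the scenario's.  Growth of species
    *i* on compound *j* is gated off before its lag time; the right-hand side
    is therefore integrated piecewise between lag breakpoints.  Negative
    excursions below ``-1e-9`` or non-finite states raise
    :class:`SimulationError`.
    """
    medium = scenario.medium0 if medium is None else np.asarray(medium, dtype=float)
    inoculum = scenario.inoculum if inoculum is None else np.asarray(inoculum, dtype=float)
    t_end = scenario.t_end if t_end is None else float(t_end)
    dt = scenario.dt if dt is None else float(dt)
    if dt <= 0 or t_end <= 0:
        raise ValueError("t_end and dt must be positive")
    if medium.shape != (N_COMPOUNDS,) or np.any(medium < 0) or not np.all(np.isfinite(medium)):
        raise ValueError("medium must be four finite non-negative concentrations")

    r = np.stack([sp.r for sp in scenario.species])
    K = np.stack([sp.K for sp in scenario.species])
    p = np.stack([sp.p for sp in scenario.species])
    u = np.stack([sp.u for sp in scenario.species])
    with np.errstate(divide="ignore", invalid="ignore"):
        ry = np.where(r > 0, r / np.stack([sp.y for sp in scenario.species]), 0.0)

    T = _lag_matrix(scenario, medium)
    breakpoints = sorted({t for t in T.ravel() if 0.0 < t < t_end})
    edges = [0.0, *breakpoints, t_end]

    n_steps = int(round(t_end / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    out = np.empty((6, times.size))
    out[:, 0] = np.concatenate([inoculum, medium])

    state = out[:, 0].copy()
    for t0, t1 in zip(edges[:-1], edges[1:]):
        gate = (T <= t0 + 1e-12).astype(float)

        def rhs(t, x, gate=gate):
            S = x[:2]
            c = np.maximum(x[2:], 0.0)
            monod = c / (K + c)
            growth = r * monod * gate          # (2, 4) per-compound growth rates
            dS = S * growth.sum(axis=1)
            # consumption for growth + no-growth uptake + production
            dc = (
                -(ry * monod * gate) * S[:, None]
                - u * S[:, None] * c[None, :]
                + p * S[:, None]
            ).sum(axis=0)
            return np.concatenate([dS, dc])

        mask = (times > t0 + 1e-12) & (times <= t1 + 1e-12)
        grid_pts = times[mask]
        t_eval = np.unique(np.concatenate([grid_pts, [t1]]))
        sol = solve_ivp(
            rhs, (t0, t1), state, method="LSODA", t_eval=t_eval,
            rtol=rtol, atol=atol, max_step=max((t1 - t0) / 4, dt),
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise SimulationError(
                f"integration failed in [{t0}, {t1}]: {sol.message}; last state {state}"
            )
        if grid_pts.size:
            # columns of sol.y matching the output grid points
            idx = np.searchsorted(sol.t, grid_pts)
            out[:, mask] = sol.y[:, idx]
        state = sol.y[:, -1].copy()

    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))
        raise SimulationError(f"non-finite state at output index {bad[0]}")
    if out.min() < -1e-9:
        idx = np.unravel_index(np.argmin(out), out.shape)
        raise SimulationError(
            f"negative state {out[idx]:.3e} at t={times[idx[1]]:.3f}"
        )
    out = np.maximum(out, 0.0)

    biomass = out[:2]
    compounds = out[2:]
    stationary = _stationary_time(times, biomass.sum(axis=0))
    return SimulationResult(times=times, biomass=biomass, compounds=compounds,
                            stationary_time=stationary)


def _stationary_time(times: np.ndarray, total: np.ndarray, threshold: float = 1e-4) -> float | None:
    """First time from which the relative biomass change stays < ``threshold``
    per unit time through the end of the trajectory."""
    if times.size < 2:
        return None
    dt = np.diff(times)
    rel_rate = np.abs(np.diff(total)) / np.maximum(total[:-1], 1e-300) / dt
    quiet = rel_rate < threshold
    # suffix scan: last index where quiet is violated
    not_quiet = np.nonzero(~quiet)[0]
    if not_quiet.size == 0:
        return float(times[0])
    first = not_quiet[-1] + 1
    if first >= quiet.size:
        return None
    return float(times[first])


# ---------------------------------------------------------------------------
# parameter sweep (Fig-S8-style)

SWEEPABLE = {"p[1,4]": "p14", "p14": "p14", "p[1,3]": "p13", "p13": "p13",
             "u[1,3]": "u13", "u13": "u13"}


def sweep_parameter(scenario: Scenario, parameter: str, values) -> "pandas.DataFrame":
    """Run the full five-condition assay for each parameter value.

    ``parameter`` is one of the producer's C3/C4 exchange rates ``p[1,4]``
    (cross-feeding), ``p[1,3]`` (interference) or ``u[1,3]``
    (cross-detoxification).  Returns one row per value with the responder's
    relative AUC under the five conditions, in input order.
    """
    import pandas as pd

    from . import assay, features

    if parameter not in SWEEPABLE:
        raise ValueError(
            f"parameter must be one of p[1,4], p[1,3], u[1,3]; got {parameter!r}"
        )
    key = SWEEPABLE[parameter]
    values = np.asarray(list(values), dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise ValueError("sweep values must be finite and >= 0")

    rows = []
    for v in values:
        sc = apply_overrides(scenario, {key: v})
        result = assay.run_sm_assay(sc)
        aucs = {cond: features.auc_curve(sim.times, sim.biomass[1])
                for cond, sim in result.conditions.items()}
        rel = {
            cond: features.relative_auc(aucs[cond], aucs["NC"], aucs["MM"])
            for cond in assay.CONDITION_ORDER
        }
        rows.append({"value": v, **rel})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config file round trip

def scenario_to_dict(scenario: Scenario) -> dict:
    def sp_dict(sp: SpeciesParams) -> dict:
        d: dict = {"id": sp.id}
        for name in ("r", "K", "y", "p", "u"):
            arr = getattr(sp, name)
            entries = {str(j + 1): float(arr[j]) for j in range(N_COMPOUNDS) if arr[j] != 0}
            if entries:
                d[name] = entries
        lag = {f"{j + 1},{k + 1}": float(sp.l[j, k])
               for j in range(N_COMPOUNDS) for k in range(N_COMPOUNDS) if sp.l[j, k] != 0}
        if lag:
            d["l"] = lag
        return d

    return {
        "label": scenario.label,
        "environment": scenario.environment,
        "species": [sp_dict(sp) for sp in scenario.species],
        "medium0": {f"c{j + 1}": float(scenario.medium0[j]) for j in range(N_COMPOUNDS)},
        "inoculum": [float(x) for x in scenario.inoculum],
        "c3_inhibitory_level": scenario.c3_inhibitory_level,
        "t_end": scenario.t_end,
        "dt": scenario.dt,
    }


def scenario_from_dict(data: dict) -> Scenario:
    species = []
    for sp_data in data["species"]:
        sp = SpeciesParams(id=int(sp_data["id"]))
        for name in ("r", "K", "y", "p", "u"):
            for j, val in sp_data.get(name, {}).items():
                getattr(sp, name)[int(j) - 1] = float(val)
        for jk, val in sp_data.get("l", {}).items():
            j, k = (int(x) for x in jk.replace("_", ",").split(","))
            sp.l[j - 1, k - 1] = float(val)
        sp.__post_init__()
        species.append(sp)
    medium0 = np.zeros(N_COMPOUNDS)
    for key, val in data.get("medium0", {}).items():
        medium0[int(key.lstrip("c")) - 1] = float(val)
    return Scenario(
        label=data["label"],
        environment=data["environment"],
        species=(species[0], species[1]),
        medium0=medium0,
        inoculum=np.asarray(data.get("inoculum", [_INOCULUM, _INOCULUM]), dtype=float),
        c3_inhibitory_level=float(data.get("c3_inhibitory_level", C3_INHIBITORY_LEVEL)),
        t_end=float(data.get("t_end", 72.0)),
        dt=float(data.get("dt", 1.0 / 6.0)),
    )


def load_scenario(path) -> Scenario:
    """Read a scenario from a YAML or JSON file."""
    import json

    import yaml

    text = open(path).read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return scenario_from_dict(data)


def save_scenario(scenario: Scenario, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)
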