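"""In-silico spent-medium assay protocol.

The protocol mirrors the bench version: grow the producer species alone in
minimal medium until stationary phase, remove the cells (filtration leaves
compounds untouched), and grow the responder species in five media:

I   NC       no-carbon medium (salts only; negative control)
II  MM       minimal medium (NC + carbon sources; positive control)
III SM/2+NC  spent medium diluted 1:1 with a 2x NC stock
IV  SM       pure spent medium
V   SM/2+MM  spent medium diluted 1:1 with a 2x MM stock

All steps operate on concentrations; culture volumes are abstracted away.
In an inhibitory environment every fresh medium carries the inhibitor C3 at
3.5 per 1x strength, so "replenishing" a spent medium also replenishes the
inhibitor -- the arithmetic behind the counter-intuitive result that
replenishment can make growth worse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (
    C3_INHIBITORY_LEVEL,
    MM_C1,
    MM_C2,
    N_COMPOUNDS,
    Scenario,
    SimulationResult,
    simulate,
)

#: The five conditions in protocol order (I--V).
CONDITION_ORDER = ("NC", "MM", "SM/2+NC", "SM", "SM/2+MM")

#: Default horizon for growing the producer to stationary phase.
HARVEST_T_END = 96.0


class AssayWarning(UserWarning):
    """Protocol deviations worth recording (e.g. harvest before stationary)."""


@dataclass
class MediumRecipe:
    """A named medium: compound vector at the given stock strength."""

    name: str
    compounds: np.ndarray
    strength: float = 1.0

    def __post_init__(self) -> None:
        self.compounds = np.asarray(self.compounds, dtype=float)
        if self.compounds.shape != (N_COMPOUNDS,) or np.any(self.compounds < 0):
            raise ValueError("compounds must be four non-negative concentrations")


@dataclass
class AssayResult:
    """Producer/responder ids, spent-medium composition, and the responder's
    trajectory in each of the five conditions (fixed order NC, MM, SM/2+NC,
    SM, SM/2+MM)."""

    producer: int
    responder: int
    sm_composition: np.ndarray
    media: dict[str, np.ndarray]
    conditions: dict[str, SimulationResult]
    harvest_time: float | None = None
    warnings: list[str] = field(default_factory=list)


def nc_medium(environment: str, strength: float = 1.0,
              c3_level: float = C3_INHIBITORY_LEVEL) -> MediumRecipe:
    """No-carbon base medium; carries the inhibitor in an inhibitory environment."""
    c = np.zeros(N_COMPOUNDS)
    if environment == "inhibitory":
        c[2] = c3_level * strength
    return MediumRecipe(name="NC", compounds=c, strength=strength)


def mm_medium(environment: str, strength: float = 1.0,
              c3_level: float = C3_INHIBITORY_LEVEL) -> MediumRecipe:
    """Minimal medium: the NC base plus the two carbon sources."""
    recipe = nc_medium(environment, strength, c3_level)
    c = recipe.compounds
    c[0] = MM_C1 * strength
    c[1] = MM_C2 * strength
    return MediumRecipe(name="MM", compounds=c, strength=strength)


def mix(a: np.ndarray, b: np.ndarray, fraction_a: float) -> np.ndarray:
    """Componentwise mixture ``fraction_a * a + (1 - fraction_a) * b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not 0.0 <= fraction_a <= 1.0:
        raise ValueError("fraction_a must be within [0, 1]")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("cannot mix media with negative concentrations")
    return fraction_a * a + (1.0 - fraction_a) * b


def five_conditions(sm: np.ndarray, environment: str,
                    c3_level: float = C3_INHIBITORY_LEVEL) -> list[MediumRecipe]:
    """Build the five assay media from a spent-medium compound vector."""
    sm = np.asarray(sm, dtype=float)
    nc1 = nc_medium(environment, 1.0, c3_level)
    mm1 = mm_medium(environment, 1.0, c3_level)
    nc2 = nc_medium(environment, 2.0, c3_level)
    mm2 = mm_medium(environment, 2.0, c3_level)
    return [
        nc1,
        mm1,
        MediumRecipe("SM/2+NC", mix(sm, nc2.compounds, 0.5)),
        MediumRecipe("SM", sm.copy()),
        MediumRecipe("SM/2+MM", mix(sm, mm2.compounds, 0.5)),
    ]


def harvest_sm(
    scenario: Scenario,
    producer: int = 1,
    medium: MediumRecipe | np.ndarray | None = None,
    t_end: float = HARVEST_T_END,
    dt: float | None = None,
) -> np.ndarray:
    """Grow the producer monoculture to stationary phase and return the
    cell-free compound vector of its spent medium.

    If stationary phase is not reached by ``t_end`` an :class:`AssayWarning`
    is issued and the end state is returned (mirroring a fixed-time harvest).
    """
    if producer != 1:
        raise ValueError("the producer is species 1 of the scenario")
    if medium is None:
        medium = mm_medium(scenario.environment, 1.0, scenario.c3_inhibitory_level)
    med = medium.compounds if isinstance(medium, MediumRecipe) else np.asarray(medium, float)
    inoc = np.array([scenario.inoculum[0], 0.0])
    sim = simulate(scenario, medium=med, inoculum=inoc, t_end=t_end, dt=dt)
    if sim.stationary_time is None:
        warnings.warn(
            f"producer not stationary by t={t_end}; harvesting the end state",
            AssayWarning,
        )
        return sim.compounds[:, -1].copy()
    idx = int(np.searchsorted(sim.times, sim.stationary_time))
    return sim.compounds[:, idx].copy()


def run_sm_assay(
    scenario: Scenario,
    t_end: float | None = None,
    dt: float | None = None,
    harvest_t_end: float = HARVEST_T_END,
) -> AssayResult:
    """Run the full five-condition assay for a scenario.

    Species 1 is the spent-medium producer; species 2 (the responder) is
    grown alone in each of the five conditions with an identical inoculum.
    """
    recorded: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", AssayWarning)
        sm = harvest_sm(scenario, t_end=harvest_t_end, dt=dt)
        recorded = [str(w.message) for w in caught if issubclass(w.category, AssayWarning)]

    media = five_conditions(sm, scenario.environment, scenario.c3_inhibitory_level)
    inoc = np.array([0.0, scenario.inoculum[1]])
    conditions: dict[str, SimulationResult] = {}
    media_map: dict[str, np.ndarray] = {}
    for recipe in media:
        conditions[recipe.name] = simulate(
            scenario, medium=recipe.compounds, inoculum=inoc, t_end=t_end, dt=dt
        )
        media_map[recipe.name] = recipe.compounds.copy()
    return AssayResult(
        producer=1,
        responder=2,
        sm_composition=sm,
        media=media_map,
        conditions=conditions,
        warnings=recorded,
    )


def serial_dilution_final_concs(
    stock_conc: float,
    n_wells: int,
    dilution_factor: float,
    final_mix_fraction: float,
) -> list[float]:
    """Concentrations of a serial dilution after the final culture mix.

    Well ``w`` (1-based) holds ``stock / factor**(w-1)`` before the culture is
    added; mixing with culture multiplies by ``final_mix_fraction``.  Returned
    in descending well order.
    """
    if stock_conc <= 0:
        raise ValueError("stock_conc must be positive")
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    return [
        stock_conc / dilution_factor ** w * final_mix_fraction
        for w in range(n_wells)
    ]
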