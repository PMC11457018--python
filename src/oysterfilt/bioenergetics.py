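"""Individual- and reef-level oyster clearance rates.

The clearance rate (CR) of an eastern oyster (*Crassostrea virginica*) is
the volume of water it strips of particles per unit time.  The model used
here is an allometric optimum rate scaled down by abiotic modifiers:

    CR = 8.02 · W^0.58 · f_T(T) · f_S(S) [· f_DO(DO) · f_TSS(TSS)]

with W the dry tissue weight in grams, so that a 1-g oyster under optimal
conditions clears 8.02 L h⁻¹.  Temperature and salinity modifiers are always
applied; dissolved-oxygen and seston modifiers are available behind a flag
(the reference configuration uses temperature and salinity only, those
being the variables a hydrodynamic model supplies per cell).

Shell height L (mm) is converted to dry tissue weight with the allometry
W = 0.0001 · L^2.1 fitted on wild Gulf-of-Mexico reefs.

Reef-level ("areal") rates sum individual rates over the size classes of a
demographic scenario: density (oysters m⁻² of reef) × CR per individual,
giving L h⁻¹ m⁻² of reef.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "AbioticState",
    "SizeClassSpec",
    "DemographicScenario",
    "NoQualifyingRecordsError",
    "dtw_from_shell_height",
    "temperature_modifier",
    "salinity_modifier",
    "oxygen_modifier",
    "seston_modifier",
    "individual_clearance_rate",
    "areal_clearance_rate",
    "build_demographic_scenario",
    "successful_restoration_scenario",
    "read_scenario",
    "write_scenario",
]

#: Optimum clearance rate coefficient: L h⁻¹ for a 1-g-DTW oyster under
#: optimal temperature and fully saturated salinity response.
CR_MAX_COEFF = 8.02
#: Allometric exponent of CR on dry tissue weight.
CR_MASS_EXP = 0.58

#: Shell-height → dry-tissue-weight allometry, W = DTW_COEFF · L^DTW_EXP.
DTW_COEFF = 1e-4
DTW_EXP = 2.1

#: Temperature optimum (°C) and Gaussian width of the thermal response.
T_OPT = 27.0
T_WIDTH = 0.015

#: Salinity at which the tanh response reaches half its asymptote (ppt).
S_HALF = 7.5

# Logistic dissolved-oxygen response: midpoint 2.11 mg/L, scale 0.7.
# Chosen to satisfy the documented behaviour of the hypoxia response:
# clearance collapses below ~2 mg/L and is essentially unaffected above it.
DO_MIDPOINT = 2.11
DO_SCALE = 0.7

_ArrayLike = Union[float, np.ndarray]


class NoQualifyingRecordsError(ValueError):
    """No survey record exceeds the restoration-success density threshold."""


@dataclass(frozen=True)
class AbioticState:
    """Abiotic conditions in one cell at one time step.

    Parameters
    ----------
    temperature:
        Water temperature, °C.
    salinity:
        Salinity, ppt.  Must be non-negative.
    dissolved_oxygen:
        Optional dissolved oxygen, mg/L.
    seston:
        Optional total suspended solids, mg/L.
    """

    temperature: float
    salinity: float
    dissolved_oxygen: Optional[float] = None
    seston: Optional[float] = None

    def __post_init__(self) -> None:
        if self.salinity < 0:
            raise ValueError(f"salinity must be >= 0, got {self.salinity}")
        if self.dissolved_oxygen is not None and self.dissolved_oxygen < 0:
            raise ValueError("dissolved_oxygen must be >= 0 when present")
        if self.seston is not None and self.seston < 0:
            raise ValueError("seston must be >= 0 when present")


@dataclass(frozen=True)
class SizeClassSpec:
    """One oyster size class: mean shell height (mm) and density (m⁻² of reef)."""

    label: str
    mean_shell_height: float
    density: float

    def __post_init__(self) -> None:
        if self.mean_shell_height <= 0:
            raise ValueError("mean_shell_height must be > 0")
        if self.density < 0:
            raise ValueError("density must be >= 0")


@dataclass(frozen=True)
class DemographicScenario:
    """A static reef-level demographic scenario (ordered size classes)."""

    classes: tuple[SizeClassSpec, ...]
    name: str = "scenario"

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("a scenario needs at least one size class")
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def total_density(self) -> float:
        """Total oyster density, individuals m⁻² of reef."""
        return float(sum(c.density for c in self.classes))


def dtw_from_shell_height(shell_height_mm: _ArrayLike) -> _ArrayLike:
    """Dry tissue weight (g) from shell height (mm): W = 0.0001 · L^2.1."""
    L = np.asarray(shell_height_mm, dtype=float)
    if np.any(L <= 0):
        raise ValueError("shell height must be > 0 mm")
    W = DTW_COEFF * L**DTW_EXP
    return float(W) if np.isscalar(shell_height_mm) else W


def temperature_modifier(temperature_c: _ArrayLike) -> _ArrayLike:
    """Unimodal thermal response exp(−0.015·(T−27)²), maximal at 27 °C."""
    T = np.asarray(temperature_c, dtype=float)
    out = np.exp(-T_WIDTH * (T - T_OPT) ** 2)
    return float(out) if np.isscalar(temperature_c) else out


def salinity_modifier(salinity_ppt: _ArrayLike) -> _ArrayLike:
    """Salinity response 0.5·(1 + tanh(S − 7.5)); half its asymptote at 7.5 ppt."""
    S = np.asarray(salinity_ppt, dtype=float)
    if np.any(S < 0):
        raise ValueError("salinity must be >= 0 ppt")
    out = 0.5 * (1.0 + np.tanh(S - S_HALF))
    return float(out) if np.isscalar(salinity_ppt) else out


def oxygen_modifier(do_mg_l: _ArrayLike) -> _ArrayLike:
    """Logistic hypoxia response 1/(1 + exp((2.11 − DO)/0.7)).

    Clearance collapses under hypoxia (DO below ~2 mg/L) and is essentially
    unaffected above it; the logistic midpoint sits at 2.11 mg/L with scale
    0.7 mg/L.
    """
    DO = np.asarray(do_mg_l, dtype=float)
    if np.any(DO < 0):
        raise ValueError("dissolved oxygen must be >= 0 mg/L")
    out = 1.0 / (1.0 + np.exp((DO_MIDPOINT - DO) / DO_SCALE))
    return float(out) if np.isscalar(do_mg_l) else out


def seston_modifier(tss_mg_l: _ArrayLike) -> _ArrayLike:
    """Piecewise seston response: 0.1 (<5), 1 (5–25), 0.2 (25–100], 0 (>100 mg/L)."""
    TSS = np.asarray(tss_mg_l, dtype=float)
    if np.any(TSS < 0):
        raise ValueError("seston must be >= 0 mg/L")
    out = np.select(
        [TSS < 5.0, TSS <= 25.0, TSS <= 100.0],
        [0.1, 1.0, 0.2],
        default=0.0,
    )
    return float(out) if np.isscalar(tss_mg_l) else out


def individual_clearance_rate(
    dry_tissue_weight_g: float,
    state: AbioticState,
    use_optional_modifiers: bool = False,
) -> float:
    """Clearance rate (L h⁻¹) of one oyster of weight W under `state`.

    The optional DO and TSS modifiers are applied only when
    ``use_optional_modifiers`` is set and the corresponding fields of
    `state` are present.
    """
    W = dry_tissue_weight_g
    if W <= 0:
        raise ValueError("dry tissue weight must be > 0 g")
    cr = (
        CR_MAX_COEFF
        * W**CR_MASS_EXP
        * temperature_modifier(state.temperature)
        * salinity_modifier(state.salinity)
    )
    if use_optional_modifiers:
        if state.dissolved_oxygen is not None:
            cr *= oxygen_modifier(state.dissolved_oxygen)
        if state.seston is not None:
            cr *= seston_modifier(state.seston)
    return float(cr)


def areal_clearance_rate(
    scenario: DemographicScenario,
    state: AbioticState,
    use_optional_modifiers: bool = False,
) -> float:
    """Reef-level clearance rate, L h⁻¹ per m² of reef.

    Sums density × individual CR over the scenario's size classes; linear
    in each class density.
    """
    total = 0.0
    for cls in scenario.classes:
        if cls.density == 0:
            continue
        W = dtw_from_shell_height(cls.mean_shell_height)
        total += cls.density * individual_clearance_rate(
            W, state, use_optional_modifiers
        )
    return total


def base_areal_rate(scenario: DemographicScenario) -> float:
    """Scenario's optimum areal rate Σ density·8.02·W^0.58 (L h⁻¹ m⁻²).

    The abiotic modifiers factor out of the size-class sum, so the realized
    areal rate is this constant times the (state-dependent) modifier
    product.  The filtration engine exploits that factorization.
    """
    return sum(
        c.density * CR_MAX_COEFF * dtw_from_shell_height(c.mean_shell_height) ** CR_MASS_EXP
        for c in scenario.classes
    )


def build_demographic_scenario(
    site_records: Sequence[tuple[float, Sequence[float]]],
    success_threshold: float = 15.0,
    class_labels: Sequence[str] = ("spat", "seed", "market"),
    mean_shell_heights: Sequence[float] = (16.0, 56.0, 98.0),
    round_densities: bool = False,
    name: str = "built",
) -> DemographicScenario:
    """Build a restoration scenario from reef survey records.

    Each record is ``(site_density, class_proportions)``.  Sites with
    density strictly greater than ``success_threshold`` (the
    restoration-success criterion, 15 oysters m⁻²) qualify; the scenario
    density is the arithmetic mean of qualifying site densities,
    partitioned by the mean class proportions of those sites.

    With ``round_densities`` each class density is truncated to a whole
    number of oysters (the convention under which the packaged default
    scenario of 61/125/34 oysters m⁻² arises from a 221 m⁻² mean).

    Raises
    ------
    NoQualifyingRecordsError
        If no record exceeds the threshold.
    """
    qualifying = [
        (d, np.asarray(props, dtype=float))
        for d, props in site_records
        if d > success_threshold
    ]
    if not qualifying:
        raise NoQualifyingRecordsError(
            f"no site record exceeds {success_threshold} oysters m^-2"
        )
    for _, props in qualifying:
        if len(props) != len(class_labels):
            raise ValueError("each record needs one proportion per size class")
        if not math.isclose(float(props.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("size-class proportions must sum to 1")
    mean_density = float(np.mean([d for d, _ in qualifying]))
    mean_props = np.mean([p for _, p in qualifying], axis=0)
    densities = mean_density * mean_props
    if round_densities:
        densities = np.floor(densities)
    classes = tuple(
        SizeClassSpec(label, sh, float(d))
        for label, sh, d in zip(class_labels, mean_shell_heights, densities)
    )
    return DemographicScenario(classes=classes, name=name)


def read_scenario(source: Union[str, Path, TextIO]) -> DemographicScenario:
    """Read a scenario from a CSV with columns label,mean_sh_mm,density_per_m2."""
    import pandas as pd

    df = pd.read_csv(source)
    required = {"label", "mean_sh_mm", "density_per_m2"}
    if not required.issubset(df.columns):
        raise ValueError(f"scenario file needs columns {sorted(required)}")
    classes = tuple(
        SizeClassSpec(str(r.label), float(r.mean_sh_mm), float(r.density_per_m2))
        for r in df.itertuples()
    )
    name = Path(source).stem if isinstance(source, (str, Path)) else "scenario"
    return DemographicScenario(classes=classes, name=name)


def write_scenario(scenario: DemographicScenario, dest: Union[str, Path]) -> None:
    """Write a scenario as CSV (label,mean_sh_mm,density_per_m2)."""
    import pandas as pd

    pd.DataFrame(
        {
            "label": [c.label for c in scenario.classes],
            "mean_sh_mm": [c.mean_shell_height for c in scenario.classes],
            "density_per_m2": [c.density for c in scenario.classes],
        }
    ).to_csv(dest, index=False)


def successful_restoration_scenario() -> DemographicScenario:
    """The packaged "successful restoration" scenario.

    Spat (<25 mm) at 16 mm / 61 m⁻², seed (25–75 mm) at 56 mm / 125 m⁻²,
    market (>75 mm) at 98 mm / 34 m⁻²: the mean demographics of northern
    Gulf-of-Mexico reefs that met the 15-oysters-m⁻² success criterion.
    """
    with resources.files("oysterfilt.data").joinpath(
        "successful_scenario.csv"
    ).open("r") as fh:
        scenario = read_scenario(fh)
    return DemographicScenario(
        classes=scenario.classes, name="successful-restoration"
    )
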