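"""Physical constants, extinction coefficients and unit conversions.

Concentrations are held in µM throughout the package and converted to mM
(second-order rate constants) or M (thermodynamics) only at reporting
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError

#: Gas constant in kcal mol^-1 K^-1 (thermodynamic relations use kcal units).
R_KCAL: float = 1.987e-3

#: Dissolved O2 in air-saturated aqueous buffer at 25 °C, µM.
O2_AIR_SATURATION_UM: float = 258.0

#: Mole fraction of O2 in air.
O2_AIR_FRACTION: float = 0.21


def o2_percent_to_uM(
    percent: float,
    air_saturation_uM: float = O2_AIR_SATURATION_UM,
    air_fraction: float = O2_AIR_FRACTION,
) -> float:
    """Convert a gas-mixture %O2 to a dissolved concentration in µM.

    Equilibration with a ``percent`` O2 / N2 mixture at 1 atm gives a
    dissolved concentration proportional to the partial pressure; the
    proportionality is anchored at the air-saturation value, which is the
    quantity usually known for a buffer at a given temperature.  Both
    anchors are configurable because the Henry's-law constant is
    temperature- and medium-dependent.
    """
    if percent < 0 or percent > 100:
        raise InputError(f"%O2 must lie in [0, 100], got {percent}")
    return percent / 100.0 * (air_saturation_uM / air_fraction)


@dataclass(frozen=True)
class ExtinctionEntry:
    """One molar absorptivity with its measurement context."""

    label: str
    wavelength_nm: float
    epsilon_per_M_cm: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.epsilon_per_M_cm <= 0:
            raise InputError("extinction coefficient must be positive")
        if not (200.0 <= self.wavelength_nm <= 800.0):
            raise InputError("wavelength outside the 200-800 nm range")


@dataclass
class ExtinctionTable:
    """Registry of (Δ)ε values used to convert absorbance slopes to rates."""

    entries: list[ExtinctionEntry] = field(default_factory=list)

    def add(self, entry: ExtinctionEntry) -> None:
        self.entries.append(entry)

    def get(self, label: str) -> ExtinctionEntry:
        for entry in self.entries:
            if entry.label == label:
                return entry
        raise KeyError(label)


#: Composite/direct Δε values for the assay wavelengths used with
#: 4-methoxybenzyl and 3-Cl-4-methoxybenzyl alcohols and benzoquinone.
DEFAULT_EXTINCTIONS = ExtinctionTable(
    entries=[
        ExtinctionEntry(
            "4-methoxybenzaldehyde_285", 285.0, 16950.0,
            "aldehyde production followed at 285 nm",
        ),
        ExtinctionEntry(
            "3-Cl-4-methoxybenzaldehyde_295", 295.0, 15000.0,
            "aldehyde production followed at 295 nm",
        ),
        ExtinctionEntry(
            "BQ_reduction_247", 247.0, 20200.0,
            "benzoquinone -> hydroquinone two-electron reduction",
        ),
        ExtinctionEntry(
            "BQ_assay_4-methoxybenzyl_247", 247.0, 17833.0,
            "composite Δε at 247 nm: BQ reduction corrected for "
            "4-methoxybenzaldehyde absorptivity",
        ),
        ExtinctionEntry(
            "BQ_assay_3-Cl-4-methoxybenzyl_247", 247.0, 18067.0,
            "composite Δε at 247 nm: BQ reduction corrected for "
            "3-Cl-4-methoxybenzaldehyde absorptivity",
        ),
    ]
)

#: Band-I molar absorptivity defaults for oxidized and (hydroquinone)
#: reduced FAD at 462 nm, M^-1 cm^-1.  The oxidized value is a typical
#: flavoprotein band-I magnitude; quantitative comparison against a
#: measured trace requires the user's own ε values.
EPSILON_462_OXIDIZED: float = 11300.0
EPSILON_462_REDUCED: float = 900.0


def absorbance_to_rate(
    dA_per_s: float,
    delta_eps_per_M_cm: float,
    pathlength_cm: float = 1.0,
) -> float:
    """Convert an absorbance slope (AU/s) to a chemical rate in µM/s.

    rate = dA/dt / (Δε · ℓ), rescaled from M/s to µM/s.
    """
    if delta_eps_per_M_cm <= 0:
        raise InputError("Δε must be strictly positive")
    if pathlength_cm <= 0:
        raise InputError("pathlength must be strictly positive")
    return dA_per_s / (delta_eps_per_M_cm * pathlength_cm) * 1e6
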