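"""Theoretical methane potential, residual methane potential units, and
free-ammonia speciation.

The theoretical methane potential (TMP) of a stream is the stoichiometric
maximum methane yield of its organic content.  For the bulk macromolecules
the standard Buswell-derived specific yields are used (0.42 L CH4/g
carbohydrate, 1.01 L CH4/g fat, 0.50 L CH4/g protein); for the volatile
fatty acids, per-mole methane equivalents follow from the Buswell element
balance ``CH4 = C/2 + H/8 - O/4`` applied to each acid's molecular
formula.

Gas volumes are normal litres (NL) at 273.2 K and 1.01325 bar, with a
molar volume of 22.414 NL/mol.

Free ammonia (NH3-N) is the un-ionized, membrane-permeant and inhibitory
fraction of total ammoniacal nitrogen; its share rises steeply with pH
and temperature through the NH4+/NH3 acid-base equilibrium.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .composition import FiberFractions, StreamComposition, total_carbohydrates

log = logging.getLogger(__name__)

#: Specific methane yields, NL CH4 per g macromolecule degraded.
CH4_PER_G = {"carbohydrate": 0.42, "fat": 1.01, "protein": 0.50}

#: Molar gas volume at 273.2 K / 1.01325 bar, NL/mol.
MOLAR_VOLUME = 22.414

#: Reference conditions for gas normalization.
STP_TEMPERATURE_K = 273.2
STP_PRESSURE_BAR = 1.01325

#: Elemental formulas (C, H, O) and molar masses (g/mol) of the supported
#: volatile fatty acids.  Branched isomers share the formula (and hence
#: the methane equivalent) of their linear counterpart.
VFA_FORMULAS: dict[str, tuple[int, int, int]] = {
    "acetic": (2, 4, 2),
    "propionic": (3, 6, 2),
    "n-butyric": (4, 8, 2),
    "isobutyric": (4, 8, 2),
    "n-valeric": (5, 10, 2),
    "isovaleric": (5, 10, 2),
    "n-caproic": (6, 12, 2),
    "isocaproic": (6, 12, 2),
}

VFA_MOLAR_MASS = {
    "acetic": 60.05,
    "propionic": 74.08,
    "n-butyric": 88.11,
    "isobutyric": 88.11,
    "n-valeric": 102.13,
    "isovaleric": 102.13,
    "n-caproic": 116.16,
    "isocaproic": 116.16,
}

#: Empirical acid-dissociation constants for the NH4+/NH3 equilibrium:
#: pKa(T) = 0.09018 + 2729.92 / T_K.
HANSEN_A = 0.09018
HANSEN_B = 2729.92


@dataclass(frozen=True)
class MethanePotential:
    """Theoretical methane potential of one stream, NL CH4 per kg ww."""

    tmp_macro: float
    tmp_vfa: float
    tmp_vs_basis: float | None = None  # NL CH4 / kg VS

    @property
    def tmp_total(self) -> float:
        return self.tmp_macro + self.tmp_vfa


@dataclass(frozen=True)
class RmpMeasurement:
    """One residual methane potential incubation result."""

    methane_volume: float      # litres, at observation conditions
    vs_added: float            # g VS in the incubated sample
    wet_mass_added: float      # kg wet weight incubated
    temperature_obs: float = STP_TEMPERATURE_K  # K
    pressure_obs: float = STP_PRESSURE_BAR      # bar

    def __post_init__(self) -> None:
        if self.vs_added <= 0 or self.wet_mass_added <= 0:
            raise ValueError("vs_added and wet_mass_added must be positive")
        if self.methane_volume < 0:
            raise ValueError("methane_volume must be non-negative")


def buswell_ch4_per_mol(c: int, h: int, o: int) -> float:
    """Methane moles per mole of CcHhOo fully converted to CH4 + CO2."""
    return c / 2.0 + h / 8.0 - o / 4.0


def vfa_ch4_equivalent(acid: str) -> float:
    """Methane equivalents (mol CH4 / mol acid) for a supported VFA."""
    key = acid.lower().strip()
    if key not in VFA_FORMULAS:
        raise ValueError(
            f"unknown acid {acid!r}; supported acids: {sorted(VFA_FORMULAS)}"
        )
    return buswell_ch4_per_mol(*VFA_FORMULAS[key])


def vfa_mg_per_l_to_mmol_per_l(acid: str, mg_per_l: float) -> float:
    """Convert a VFA concentration from mg/L to mmol/L via molar mass."""
    key = acid.lower().strip()
    if key not in VFA_MOLAR_MASS:
        raise ValueError(
            f"unknown acid {acid!r}; supported acids: {sorted(VFA_MOLAR_MASS)}"
        )
    return mg_per_l / VFA_MOLAR_MASS[key]


def macromolecule_tmp(carbohydrate: float, fat: float, protein: float) -> float:
    """TMP of the bulk macromolecules, NL CH4 per kg ww."""
    if min(carbohydrate, fat, protein) < 0:
        raise ValueError("macromolecule concentrations must be non-negative")
    return (
        CH4_PER_G["carbohydrate"] * carbohydrate
        + CH4_PER_G["fat"] * fat
        + CH4_PER_G["protein"] * protein
    )


def vfa_tmp(vfa: dict[str, float], density: float = 1.0) -> float:
    """TMP of a VFA profile (mmol/L per acid), NL CH4 per kg ww."""
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    total = 0.0
    for acid, mmol_per_l in vfa.items():
        if mmol_per_l < 0:
            raise ValueError(f"negative VFA concentration for {acid!r}")
        total += mmol_per_l * 1e-3 * vfa_ch4_equivalent(acid) * MOLAR_VOLUME
    return total / density


def stream_tmp(
    stream: StreamComposition,
    fiber: FiberFractions | None = None,
    density: float = 1.0,
) -> MethanePotential:
    """TMP of a whole stream from its macromolecule and VFA content.

    Carbohydrates are free sugars + hemicellulose + cellulose; lignin-like
    matter is excluded as recalcitrant.  If ``fiber`` is not supplied it
    is derived from the stream's NDF/ADF/ADL and sugar panel.
    """
    if stream.protein is None:
        raise ValueError("stream_tmp requires protein")
    if stream.crude_fat is None:
        raise ValueError("stream_tmp requires crude_fat")
    if fiber is None:
        fiber = stream.fiber_fractions()
    carb = total_carbohydrates(fiber)
    macro = macromolecule_tmp(carb, stream.crude_fat, stream.protein)
    vfa = vfa_tmp(stream.vfa, density=density)
    per_vs = None
    if stream.ts is not None and stream.vs_of_ts is not None and stream.vs_g_per_kg > 0:
        per_vs = (macro + vfa) / (stream.vs_g_per_kg / 1000.0)
    return MethanePotential(tmp_macro=macro, tmp_vfa=vfa, tmp_vs_basis=per_vs)


def tmp_red(tmp_substrate: float, tmp_stage_adjusted: float) -> float:
    """Fraction of the substrate TMP removed by digestion.

    The digestion-step TMP must be volume-adjusted to a per-kg-feed basis
    before calling (see :func:`digestate.balance.adjust_outflow`).
    """
    if tmp_substrate <= 0:
        raise ValueError(f"tmp_substrate must be positive, got {tmp_substrate}")
    return (tmp_substrate - tmp_stage_adjusted) / tmp_substrate


def normalize_gas_volume(volume: float, temperature: float, pressure: float) -> float:
    """Ideal-gas correction of a volume to 273.2 K and 1.01325 bar."""
    if temperature <= 0 or pressure <= 0:
        raise ValueError("temperature (K) and pressure (bar) must be positive")
    return volume * (STP_TEMPERATURE_K / temperature) * (pressure / STP_PRESSURE_BAR)


def rmp_specific(m: RmpMeasurement) -> tuple[float, float]:
    """Residual methane potential per kg VS and per kg wet weight (NL/kg)."""
    nl = normalize_gas_volume(m.methane_volume, m.temperature_obs, m.pressure_obs)
    per_kg_vs = nl / (m.vs_added / 1000.0)
    per_kg_ww = nl / m.wet_mass_added
    return per_kg_vs, per_kg_ww


def rmp_fraction_of_tmp(rmp_ww: float, tmp_digestate_ww: float) -> float:
    """Share of the digestate's TMP realized in the RMP incubation."""
    if tmp_digestate_ww <= 0:
        raise ValueError(f"tmp_digestate_ww must be positive, got {tmp_digestate_ww}")
    frac = rmp_ww / tmp_digestate_ww
    if frac > 1:
        log.warning(
            "RMP exceeds the digestate TMP (%.3g > %.3g): check units/inputs",
            rmp_ww,
            tmp_digestate_ww,
        )
    return frac


def free_ammonia(nh4_n: float, ph: float, temperature: float) -> float:
    """Free ammonia nitrogen (g NH3-N/kg) from TAN, pH and temperature.

    Speciation of total ammoniacal nitrogen (TAN, measured as NH4+-N)
    follows the temperature-dependent NH4+/NH3 equilibrium:

        NH3-N = TAN * [1 + 10^(-pH) / 10^(-(0.09018 + 2729.92/T_K))]^-1

    with ``T_K`` the absolute temperature.
    """
    if nh4_n < 0:
        raise ValueError(f"nh4_n must be non-negative, got {nh4_n}")
    if not 2.0 <= ph <= 12.0:
        raise ValueError(f"ph {ph} outside supported range [2, 12]")
    if not 0.0 <= temperature <= 80.0:
        raise ValueError(f"temperature {temperature} degC outside range [0, 80]")
    t_k = temperature + 273.15
    pka = HANSEN_A + HANSEN_B / t_k
    return nh4_n / (1.0 + 10.0 ** (-ph) / 10.0 ** (-pka))
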