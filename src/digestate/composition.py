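"""Stream composition model for anaerobic digestion mass balances.

A *stream* is any material flow in a biogas plant -- a substrate (or one
component of a substrate mixture), the digestate leaving a main digester,
or the digestate leaving a post-digester.  All concentrations are kept on
a single canonical basis: grams of analyte per kilogram of wet weight
(g/kg ww).  Liquids are assumed to have a density of 1 kg/L unless a
density is supplied, so mg/L quantities convert to g/kg by a factor of
1000.

The module also derives the standard compositional quantities used in
digestate characterization:

* raw (crude) protein from organic nitrogen, ``(Kjeldahl-N - NH4-N) x 6.25``;
* the Van Soest fiber partition of sequential NDF/ADF/ADL assays into
  hemicellulose, cellulose and lignin-like matter;
* free sugars as the excess of total sugar monomers over structural
  hemicellulose + cellulose;
* volume-weighted mixing of substrate components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

log = logging.getLogger(__name__)

#: Conventional nitrogen-to-protein conversion factor (g protein / g N).
PROTEIN_PER_NITROGEN = 6.25

#: Relative tolerance within which NDF/ADF/ADL ordering violations and
#: negative free sugars are treated as analytical noise and clamped;
#: larger violations are rejected as data corruption.
CLAMP_RTOL = 0.05

SUGAR_MONOMERS = ("xylose", "mannose", "glucose", "galactose", "arabinose")
VFA_ACIDS = (
    "acetic",
    "propionic",
    "isobutyric",
    "n-butyric",
    "isovaleric",
    "n-valeric",
    "isocaproic",
)


@dataclass
class StreamComposition:
    """One material stream on a g-per-kg-wet-weight basis.

    Mandatory process descriptors (``ts``, ``vs_of_ts``) are fractions;
    nitrogen and macromolecule concentrations are g/kg ww; sugar monomers
    are g/kg ww per monomer; VFAs are mmol/L per acid.  Optional assay
    fields (elements, EPS/SMP, viscosity, enzyme activities, DOC, C/N)
    are carried as data and never defaulted to zero: an absent field is
    ``None`` and any operation that needs it fails loudly.
    """

    ts: float | None = None                # fraction of wet weight
    vs_of_ts: float | None = None          # fraction of TS
    ph: float | None = None
    kjeldahl_n: float | None = None        # g N/kg ww
    nh4_n: float | None = None             # g N/kg ww
    protein: float | None = None           # g/kg ww
    crude_fat: float | None = None         # g/kg ww
    sugar_monomers: dict[str, float] = field(default_factory=dict)  # g/kg ww
    ndf: float | None = None               # g/kg ww
    adf: float | None = None               # g/kg ww
    adl: float | None = None               # g/kg ww
    vfa: dict[str, float] = field(default_factory=dict)             # mmol/L
    elements: dict[str, float] = field(default_factory=dict)        # mg/kg
    eps_p: float | None = None             # mg/L
    eps_c: float | None = None
    smp_p: float | None = None
    smp_c: float | None = None
    viscosity_20: float | None = None      # mPa.s at shear rate 20/s
    viscosity_100: float | None = None     # mPa.s at shear rate 100/s
    enzyme_activities: dict[str, float] = field(default_factory=dict)
    doc: float | None = None               # g/L
    c_n_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.ts is not None and not 0.0 <= self.ts <= 1.0:
            raise ValueError(f"ts must be a fraction of wet weight, got {self.ts}")
        if self.vs_of_ts is not None and not 0.0 <= self.vs_of_ts <= 1.0:
            raise ValueError(f"vs_of_ts must be a fraction of TS, got {self.vs_of_ts}")
        for name in ("kjeldahl_n", "nh4_n", "protein", "crude_fat", "ndf", "adf", "adl"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if (
            self.kjeldahl_n is not None
            and self.nh4_n is not None
            and self.nh4_n > self.kjeldahl_n * (1 + CLAMP_RTOL)
        ):
            raise ValueError(
                f"nh4_n ({self.nh4_n}) exceeds kjeldahl_n ({self.kjeldahl_n})"
            )
        for m, v in {**self.sugar_monomers, **self.vfa, **self.elements}.items():
            if v < 0:
                raise ValueError(f"negative concentration for {m!r}: {v}")

    @property
    def vs_g_per_kg(self) -> float:
        """Volatile solids concentration, g VS/kg ww."""
        if self.ts is None or self.vs_of_ts is None:
            raise ValueError("vs_g_per_kg requires both ts and vs_of_ts")
        return self.ts * self.vs_of_ts * 1000.0

    @property
    def total_sugar_monomers(self) -> float:
        """Sum of all measured sugar monomers, g/kg ww."""
        return float(sum(self.sugar_monomers.values()))

    @property
    def total_vfa_mmol_per_l(self) -> float:
        return float(sum(self.vfa.values()))

    def raw_protein_from_nitrogen(self) -> float:
        if self.kjeldahl_n is None or self.nh4_n is None:
            raise ValueError("raw protein requires kjeldahl_n and nh4_n")
        return raw_protein(self.kjeldahl_n, self.nh4_n)

    def fiber_fractions(self) -> "FiberFractions":
        """Full fiber partition including free sugars (needs NDF/ADF/ADL
        and the sugar monomer panel)."""
        if self.ndf is None or self.adf is None or self.adl is None:
            raise ValueError("fiber partition requires ndf, adf and adl")
        fib = fiber_partition(self.ndf, self.adf, self.adl)
        fs = free_sugars(self.total_sugar_monomers, fib.hemicellulose, fib.cellulose)
        return replace(fib, free_sugars=fs)


@dataclass(frozen=True)
class FiberFractions:
    """Structural carbohydrate partition of a stream, g/kg ww.

    ``hemicellulose = NDF - ADF``, ``cellulose = ADF - ADL`` and
    ``lignin_like = ADL`` follow from the sequential detergent assay;
    ``free_sugars`` is the non-structural remainder of the sugar
    monomer panel.
    """

    hemicellulose: float
    cellulose: float
    lignin_like: float
    free_sugars: float = 0.0

    def __post_init__(self) -> None:
        for name in ("hemicellulose", "cellulose", "lignin_like", "free_sugars"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SubstrateComponent:
    """One component of a substrate mixture, dosed by volume."""

    name: str
    volume_fraction: float
    composition: StreamComposition
    density: float = 1.0  # kg/L

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError(
                f"volume_fraction must lie in [0, 1], got {self.volume_fraction}"
            )


def raw_protein(kjeldahl_n: float, nh4_n: float) -> float:
    """Crude protein (g/kg) from organic nitrogen.

    The organically bound nitrogen is the Kjeldahl total minus the
    ammonium fraction; the conventional 6.25 g protein / g N factor
    converts it to protein mass.
    """
    if nh4_n < 0:
        raise ValueError(f"nh4_n must be non-negative, got {nh4_n}")
    if kjeldahl_n < nh4_n:
        raise ValueError(
            f"negative organic nitrogen: kjeldahl_n={kjeldahl_n} < nh4_n={nh4_n}"
        )
    return (kjeldahl_n - nh4_n) * PROTEIN_PER_NITROGEN


def _clamp_ordered(lo_name: str, lo: float, hi_name: str, hi: float) -> float:
    """Return ``lo`` clamped to at most ``hi``; tolerate small assay noise."""
    if lo <= hi:
        return lo
    scale = max(abs(hi), 1e-12)
    if (lo - hi) / scale > CLAMP_RTOL:
        raise ValueError(
            f"fiber ordering violated beyond tolerance: {lo_name}={lo} > {hi_name}={hi}"
        )
    log.warning("clamping %s from %g down to %s=%g", lo_name, lo, hi_name, hi)
    return hi


def fiber_partition(ndf: float, adf: float, adl: float) -> FiberFractions:
    """Partition sequential NDF/ADF/ADL assays into fiber fractions.

    Small ordering violations (within 5% relative) are clamped with a
    warning, reflecting assay noise; larger violations raise.
    """
    if min(ndf, adf, adl) < 0:
        raise ValueError("ndf, adf and adl must be non-negative")
    adl = _clamp_ordered("adl", adl, "adf", adf)
    adf = _clamp_ordered("adf", adf, "ndf", ndf)
    adl = min(adl, adf)
    return FiberFractions(
        hemicellulose=ndf - adf,
        cellulose=adf - adl,
        lignin_like=adl,
        free_sugars=0.0,
    )


def free_sugars(
    total_sugar_monomers: float, hemicellulose: float, cellulose: float
) -> float:
    """Non-structural sugars: total monomers minus structural fiber sugars.

    A negative balance (structural fiber exceeding the monomer total)
    is clamped to zero with a warning.
    """
    if min(total_sugar_monomers, hemicellulose, cellulose) < 0:
        raise ValueError("inputs must be non-negative")
    fs = total_sugar_monomers - hemicellulose - cellulose
    if fs < 0:
        log.warning(
            "free sugars clamped to 0 (monomers %g < hemicellulose %g + cellulose %g)",
            total_sugar_monomers,
            hemicellulose,
            cellulose,
        )
        return 0.0
    return fs


def total_carbohydrates(fiber: FiberFractions) -> float:
    """Total carbohydrates: free sugars + hemicellulose + cellulose.

    Lignin-like matter is excluded -- it is not a methane-yielding
    carbohydrate under anaerobic conditions.
    """
    return fiber.free_sugars + fiber.hemicellulose + fiber.cellulose


_SCALAR_CONC_FIELDS = (
    "kjeldahl_n",
    "nh4_n",
    "protein",
    "crude_fat",
    "ndf",
    "adf",
    "adl",
    "eps_p",
    "eps_c",
    "smp_p",
    "smp_c",
    "doc",
)
_MAP_CONC_FIELDS = ("sugar_monomers", "vfa", "elements")


def mix_streams(components: list[SubstrateComponent]) -> StreamComposition:
    """Mass-weighted mixture of substrate components dosed by volume.

    Each component contributes with weight ``volume_fraction x density``
    (mass per unit mixture volume).  Concentration fields present in every
    component are averaged; a field missing from any component is absent
    from the mixture.  pH combines through the weighted mean hydrogen-ion
    activity and is only reported when every component has a pH.
    """
    if not components:
        raise ValueError("mix_streams requires at least one component")
    fsum = sum(c.volume_fraction for c in components)
    if abs(fsum - 1.0) > 0.01:
        raise ValueError(f"volume fractions must sum to 1 +- 0.01, got {fsum}")
    weights = [c.volume_fraction * c.density for c in components]
    wtot = sum(weights)

    def wavg(values: list[float | None]) -> float | None:
        if any(v is None for v in values):
            return None
        return sum(w * v for w, v in zip(weights, values)) / wtot

    out: dict = {}
    out["ts"] = wavg([c.composition.ts for c in components])
    # VS must be combined on a VS-mass basis, not by averaging the TS ratio.
    if out["ts"] not in (None, 0.0) and all(
        c.composition.vs_of_ts is not None and c.composition.ts is not None
        for c in components
    ):
        vs_conc = wavg([c.composition.ts * c.composition.vs_of_ts for c in components])
        out["vs_of_ts"] = vs_conc / out["ts"]
    for name in _SCALAR_CONC_FIELDS:
        out[name] = wavg([getattr(c.composition, name) for c in components])
    for name in _MAP_CONC_FIELDS:
        keys = set().union(*(getattr(c.composition, name) for c in components))
        mixed = {}
        for k in sorted(keys):
            vals = [getattr(c.composition, name).get(k, 0.0) for c in components]
            mixed[k] = sum(w * v for w, v in zip(weights, vals)) / wtot
        out[name] = mixed
    phs = [c.composition.ph for c in components]
    if all(p is not None for p in phs):
        h = sum(w * 10.0 ** (-p) for w, p in zip(weights, phs)) / wtot
        out["ph"] = -math.log10(h)
    return StreamComposition(**{k: v for k, v in out.items() if v is not None})


BASES = ("g/kg_ww", "pct_ts", "pct_vs", "mg/L")


def convert_basis(
    value: float,
    from_basis: str,
    to_basis: str,
    ts: float | None = None,
    vs_of_ts: float | None = None,
    density: float = 1.0,
) -> float:
    """Convert a concentration between reporting bases.

    Supported bases: ``g/kg_ww`` (canonical), ``pct_ts`` (% of total
    solids), ``pct_vs`` (% of volatile solids) and ``mg/L``.  TS and VS
    bases require the stream's ``ts`` (and ``vs_of_ts``) fractions;
    ``mg/L`` requires a density (default 1 kg/L).
    """
    for b in (from_basis, to_basis):
        if b not in BASES:
            raise ValueError(f"unknown basis {b!r}; supported: {BASES}")

    def require(name: str, v: float | None) -> float:
        if v is None or v == 0:
            raise ValueError(f"conversion requires nonzero {name}")
        return v

    # to canonical g/kg ww
    if from_basis == "g/kg_ww":
        g_per_kg = value
    elif from_basis == "pct_ts":
        g_per_kg = value / 100.0 * require("ts", ts) * 1000.0
    elif from_basis == "pct_vs":
        g_per_kg = (
            value / 100.0 * require("ts", ts) * require("vs_of_ts", vs_of_ts) * 1000.0
        )
    else:  # mg/L
        g_per_kg = value / 1000.0 / require("density", density)

    if to_basis == "g/kg_ww":
        return g_per_kg
    if to_basis == "pct_ts":
        return g_per_kg / (require("ts", ts) * 1000.0) * 100.0
    if to_basis == "pct_vs":
        return g_per_kg / (require("ts", ts) * require("vs_of_ts", vs_of_ts) * 1000.0) * 100.0
    return g_per_kg * 1000.0 * require("density", density)
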