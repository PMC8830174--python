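"""Forward simulation of multi-stage biogas plants with known ground truth.

The generator mirrors the stationary mass balance used by the analysis
modules, in reverse: given true per-analyte degradation fractions it
produces substrate and digestate streams, biogas volumes and the implied
liquid-volume reduction, so that every pipeline stage can be exercised
against exact expectations without external data.

Model choices (see the methods documentation for rationale):

* Microbial growth converts 10% of the *net* degraded VS into new
  biomass, half of which is protein.  "Net" means VS destroyed as seen
  by a VS balance (degradation minus growth), which is what a plant
  operator can actually measure -- the biomass yield is therefore defined
  self-consistently as ``B = y (D - B)`` with ``y = 0.1`` and ``D`` the
  gross degraded VS.
* Biomass protein formed in one stage is carried through later stages
  undegraded (microbial biomass is recalcitrant on digester timescales).
* Methane from degraded macromolecules follows the Buswell specific
  yields; the accompanying CO2 volume is set to 100% of the CH4 volume
  for carbohydrates and protein and 43% for fat, approximating the
  stoichiometric CO2/CH4 ratios.  These constants only shape the gas
  mass and hence the volume reduction.
* VFAs are carried and degraded (with methane equivalents per mole) but
  excluded from the VS bookkeeping, as they largely evaporate during a
  TS assay.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .balance import (
    BIOMASS_PROTEIN_FRACTION,
    BIOMASS_YIELD,
    RHO_CH4,
    RHO_CO2,
    StageRecord,
)
from .composition import PROTEIN_PER_NITROGEN, StreamComposition
from .methane import CH4_PER_G, MOLAR_VOLUME, vfa_ch4_equivalent

log = logging.getLogger(__name__)

#: CO2 volume emitted per volume CH4, by substrate class.
CO2_PER_CH4 = {"carbohydrate": 1.0, "protein": 1.0, "fat": 0.43, "vfa": 1.0}

#: Analytes the simulator degrades; "other" is unassayed VS.
SIM_ANALYTES = (
    "protein",
    "crude_fat",
    "free_sugars",
    "hemicellulose",
    "cellulose",
    "lignin_like",
    "other",
    "vfa",
)
_CARB_LIKE = ("free_sugars", "hemicellulose", "cellulose", "lignin_like", "other")


@dataclass(frozen=True)
class StagePlan:
    """Operating point and true degradation ranges for one stage."""

    temperature: float          # degC
    hrt: float                  # days
    olr: float                  # kg VS / m3 / day
    ph_out: float
    deg_ranges: dict[str, tuple[float, float]]


@dataclass(frozen=True)
class PlantTemplate:
    """Category-typical composition priors and stage plan.

    ``vs_fractions`` give each macromolecule's share of substrate VS;
    whatever share is left is unassayed "other" VS.  ``cv`` is the
    between-plant lognormal coefficient of variation applied when
    sampling a concrete substrate from the template.
    """

    category: str
    ts: float                   # fraction ww
    vs_of_ts: float             # fraction of TS
    vs_fractions: dict[str, float]
    nh4_n: float                # g/kg ww
    ph: float
    vfa_mmol: dict[str, float]  # mmol/L
    stages: tuple[StagePlan, ...]
    cv: float = 0.15

    def __post_init__(self) -> None:
        total = sum(self.vs_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"macromolecule VS fractions sum to {total} > 1 "
                f"for template {self.category!r}"
            )
        if self.cv < 0:
            raise ValueError("cv must be non-negative")

    @property
    def other_fraction(self) -> float:
        return max(0.0, 1.0 - sum(self.vs_fractions.values()))


@dataclass
class SyntheticGroundTruth:
    """The generator's true parameters for one simulated plant."""

    plant: str
    category: str
    stage_deg: list[dict[str, float]]       # per stage: analyte -> fraction
    biomass_yield: float = BIOMASS_YIELD
    biomass_protein_fraction: float = BIOMASS_PROTEIN_FRACTION
    noise_cv: float = 0.0
    seed: int | None = None
    # filled by the simulator:
    stage_vol_red: list[float] = field(default_factory=list)
    stage_biomass_protein: list[float] = field(default_factory=list)  # g/kg substrate

    def overall_deg(self, analyte: str) -> float:
        """Overall true degradation across the chain: 1 - prod(1 - f_k)."""
        keep = 1.0
        for stage in self.stage_deg:
            keep *= 1.0 - stage[analyte]
        return 1.0 - keep


def _default_stage(
    temperature: float,
    hrt: float,
    olr: float,
    ph_out: float,
    protein: tuple[float, float],
    fat: tuple[float, float],
    free_sugars: tuple[float, float],
    hemicellulose: tuple[float, float],
    cellulose: tuple[float, float],
    lignin: tuple[float, float] = (0.0, 0.2),
    other: tuple[float, float] = (0.3, 0.6),
    vfa: tuple[float, float] = (0.85, 0.99),
) -> StagePlan:
    return StagePlan(
        temperature=temperature,
        hrt=hrt,
        olr=olr,
        ph_out=ph_out,
        deg_ranges={
            "protein": protein,
            "crude_fat": fat,
            "free_sugars": free_sugars,
            "hemicellulose": hemicellulose,
            "cellulose": cellulose,
            "lignin_like": lignin,
            "other": other,
            "vfa": vfa,
        },
    )


#: Category templates.  Compositions follow the worked plant examples
#: (food-waste substrate with VS ~120 g/kg split 22% protein / 32% fat /
#: 39% carbohydrate / 8% lignin; thermophilic dry digestion at VS ~180
#: g/kg; sewage sludge at low TS), with agricultural categories built
#: from their carbohydrate-rich, long-HRT character.
DEFAULT_TEMPLATES: dict[str, PlantTemplate] = {
    "FW": PlantTemplate(
        category="FW",
        ts=0.133,
        vs_of_ts=0.90,
        vs_fractions={
            "protein": 0.22,
            "crude_fat": 0.32,
            "free_sugars": 0.16,
            "hemicellulose": 0.10,
            "cellulose": 0.12,
            "lignin_like": 0.08,
        },
        nh4_n=1.0,
        ph=5.5,
        vfa_mmol={"acetic": 45.0, "propionic": 10.0},
        stages=(
            _default_stage(
                42, 35, 4.2, 7.8,
                protein=(0.20, 0.40), fat=(0.85, 0.95),
                free_sugars=(0.95, 1.0), hemicellulose=(0.70, 0.80),
                cellulose=(0.75, 0.85),
            ),
            _default_stage(
                41, 20, 1.0, 7.8,
                protein=(0.45, 0.65), fat=(0.40, 0.60),
                free_sugars=(0.5, 0.9), hemicellulose=(0.30, 0.50),
                cellulose=(0.30, 0.50),
            ),
        ),
    ),
    "FW-TD": PlantTemplate(
        category="FW-TD",
        ts=0.20,
        vs_of_ts=0.90,
        vs_fractions={
            "protein": 0.20,
            "crude_fat": 0.11,
            "free_sugars": 0.25,
            "hemicellulose": 0.15,
            "cellulose": 0.12,
            "lignin_like": 0.10,
        },
        nh4_n=1.5,
        ph=5.8,
        vfa_mmol={"acetic": 60.0, "propionic": 40.0},
        stages=(
            _default_stage(
                55, 27, 4.7, 7.8,
                protein=(0.35, 0.50), fat=(0.80, 0.92),
                free_sugars=(0.95, 1.0), hemicellulose=(0.60, 0.75),
                cellulose=(0.45, 0.60),
            ),
        ),
    ),
    "AW": PlantTemplate(
        category="AW",
        ts=0.30,
        vs_of_ts=0.92,
        vs_fractions={
            "protein": 0.12,
            "crude_fat": 0.04,
            "free_sugars": 0.20,
            "hemicellulose": 0.20,
            "cellulose": 0.20,
            "lignin_like": 0.15,
        },
        nh4_n=0.8,
        ph=4.8,
        vfa_mmol={"acetic": 30.0},
        stages=(
            _default_stage(
                38, 55, 5.8, 7.6,
                protein=(0.30, 0.55), fat=(0.80, 0.92),
                free_sugars=(0.90, 1.0), hemicellulose=(0.55, 0.75),
                cellulose=(0.60, 0.80),
            ),
            _default_stage(
                38, 40, 1.0, 7.5,
                protein=(0.30, 0.55), fat=(0.30, 0.55),
                free_sugars=(0.5, 0.9), hemicellulose=(0.25, 0.45),
                cellulose=(0.25, 0.45),
            ),
        ),
    ),
    "AWM": PlantTemplate(
        category="AWM",
        ts=0.15,
        vs_of_ts=0.85,
        vs_fractions={
            "protein": 0.15,
            "crude_fat": 0.06,
            "free_sugars": 0.08,
            "hemicellulose": 0.18,
            "cellulose": 0.18,
            "lignin_like": 0.18,
        },
        nh4_n=1.8,
        ph=7.0,
        vfa_mmol={"acetic": 20.0, "propionic": 5.0},
        stages=(
            _default_stage(
                38, 55, 3.4, 7.9,
                protein=(0.25, 0.45), fat=(0.75, 0.90),
                free_sugars=(0.85, 1.0), hemicellulose=(0.45, 0.65),
                cellulose=(0.50, 0.70),
            ),
        ),
    ),
    "WWTP": PlantTemplate(
        category="WWTP",
        ts=0.040,
        vs_of_ts=0.68,
        vs_fractions={
            "protein": 0.29,
            "crude_fat": 0.18,
            "free_sugars": 0.21,
            "hemicellulose": 0.14,
            "cellulose": 0.10,
            "lignin_like": 0.08,
        },
        nh4_n=0.3,
        ph=6.5,
        vfa_mmol={"acetic": 10.0},
        stages=(
            _default_stage(
                37, 17, 1.5, 7.2,
                protein=(0.45, 0.62), fat=(0.85, 0.90),
                free_sugars=(0.82, 0.88), hemicellulose=(0.45, 0.50),
                cellulose=(0.58, 0.65),
            ),
        ),
    ),
}


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def sample_substrate(
    template: PlantTemplate,
    seed: int | np.random.Generator = 0,
    cv: float | None = None,
) -> StreamComposition:
    """Draw one substrate stream from a category template.

    Analyte concentrations (g/kg ww) are lognormal around the template
    means; VS is rebuilt as the sum of the drawn organic pools, which
    keeps the macromolecule/VS/TS hierarchy consistent by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cv = template.cv if cv is None else cv
    vs_mean = template.ts * template.vs_of_ts * 1000.0
    if vs_mean <= 0:
        raise ValueError(f"infeasible template {template.category!r}: zero VS")
    pools: dict[str, float] = {}
    for name, frac in template.vs_fractions.items():
        pools[name] = vs_mean * frac * float(_lognormal_factor(rng, cv))
    pools["other"] = vs_mean * template.other_fraction * float(
        _lognormal_factor(rng, cv)
    )
    vs = sum(pools.values())
    ash = template.ts * (1.0 - template.vs_of_ts) * 1000.0 * float(
        _lognormal_factor(rng, cv)
    )
    ts = (vs + ash) / 1000.0
    if ts >= 1.0:
        raise ValueError(f"infeasible template {template.category!r}: TS >= 1")
    nh4 = template.nh4_n * float(_lognormal_factor(rng, cv))
    vfa = {
        acid: conc * float(_lognormal_factor(rng, cv))
        for acid, conc in template.vfa_mmol.items()
    }
    return _stream_from_pools(
        pools, ash=ash, vol_red=0.0, nh4_n=nh4, ph=template.ph, vfa=vfa
    )


def _stream_from_pools(
    pools: dict[str, float],
    ash: float,
    vol_red: float,
    nh4_n: float,
    ph: float,
    vfa: dict[str, float],
) -> StreamComposition:
    """Build a measured stream from per-feed masses (g per kg feed).

    Sugar monomers are assigned so the fiber partition inverts exactly:
    glucose carries free sugars + cellulose (glucan), xylose carries
    hemicellulose (xylan).
    """
    keep = 1.0 - vol_red
    c = {k: v / keep for k, v in pools.items()}
    vs = sum(c.values())
    ash_c = ash / keep
    ts = (vs + ash_c) / 1000.0
    return StreamComposition(
        ts=ts,
        vs_of_ts=vs / (vs + ash_c) if vs + ash_c > 0 else 0.0,
        ph=ph,
        kjeldahl_n=nh4_n / keep + c["protein"] / PROTEIN_PER_NITROGEN,
        nh4_n=nh4_n / keep,
        protein=c["protein"],
        crude_fat=c["crude_fat"],
        sugar_monomers={
            "glucose": c["free_sugars"] + c["cellulose"],
            "xylose": c["hemicellulose"],
        },
        ndf=c["hemicellulose"] + c["cellulose"] + c["lignin_like"],
        adf=c["cellulose"] + c["lignin_like"],
        adl=c["lignin_like"],
        vfa={acid: conc / keep for acid, conc in vfa.items()},
    )


def _pools_from_stream(stream: StreamComposition) -> tuple[dict[str, float], float]:
    """Invert a measured stream to per-kg masses (g/kg of that stream)."""
    fib = stream.fiber_fractions()
    pools = {
        "protein": stream.protein,
        "crude_fat": stream.crude_fat,
        "free_sugars": fib.free_sugars,
        "hemicellulose": fib.hemicellulose,
        "cellulose": fib.cellulose,
        "lignin_like": fib.lignin_like,
    }
    vs = stream.vs_g_per_kg
    pools["other"] = max(0.0, vs - sum(pools.values()))
    ash = stream.ts * 1000.0 - vs
    return pools, ash


def simulate_digestion(
    feed: StreamComposition,
    truth: SyntheticGroundTruth,
    stage_index: int = 0,
    biomass_protein_in: float = 0.0,
    plan: StagePlan | None = None,
    name: str | None = None,
) -> tuple[StageRecord, dict[str, float]]:
    """Simulate one digestion stage under known degradation fractions.

    ``biomass_protein_in`` is microbial protein (g per kg of this stage's
    feed) formed upstream; it rides along undegraded.  Returns the stage
    record (with exact ``vol_red`` plus the gas data it derives from) and
    the gas volumes per kg feed, including the outgoing biomass protein
    under the key ``"biomass_protein_out"``.
    """
    deg = truth.stage_deg[stage_index]
    pools, ash = _pools_from_stream(feed)
    pools["protein"] -= biomass_protein_in  # substrate-derived protein only
    if pools["protein"] < -1e-9:
        raise ValueError("biomass_protein_in exceeds the feed protein")

    degraded = {a: pools[a] * deg.get(a, 0.0) for a in pools}
    ch4_carb = CH4_PER_G["carbohydrate"] * sum(degraded[a] for a in _CARB_LIKE)
    ch4_fat = CH4_PER_G["fat"] * degraded["crude_fat"]
    ch4_prot = CH4_PER_G["protein"] * degraded["protein"]
    vfa_deg_mmol = {
        acid: conc * deg.get("vfa", 0.0) for acid, conc in feed.vfa.items()
    }
    ch4_vfa = sum(
        mmol * 1e-3 * vfa_ch4_equivalent(acid) * MOLAR_VOLUME
        for acid, mmol in vfa_deg_mmol.items()
    )
    ch4 = ch4_carb + ch4_fat + ch4_prot + ch4_vfa
    co2 = (
        CO2_PER_CH4["carbohydrate"] * ch4_carb
        + CO2_PER_CH4["fat"] * ch4_fat
        + CO2_PER_CH4["protein"] * ch4_prot
        + CO2_PER_CH4["vfa"] * ch4_vfa
    )
    gas_mass = ch4 * RHO_CH4 + co2 * RHO_CO2  # g per kg feed
    vol_red = gas_mass / 1000.0
    if vol_red >= 1.0:
        raise ValueError("unphysical template: gas mass exceeds the feed mass")

    # biomass growth, self-consistent with a net VS balance
    gross_vs_degraded = sum(degraded.values())
    biomass = truth.biomass_yield * gross_vs_degraded / (1.0 + truth.biomass_yield)
    new_biomass_protein = truth.biomass_protein_fraction * biomass

    out_pools = {a: pools[a] - degraded[a] for a in pools}
    biomass_protein_total = biomass_protein_in + new_biomass_protein
    out_pools["protein"] += biomass_protein_total
    out_pools["other"] += biomass - new_biomass_protein  # non-protein biomass

    mineralized_n = (
        degraded["protein"] - new_biomass_protein
    ) / PROTEIN_PER_NITROGEN
    nh4_in = (feed.nh4_n or 0.0)
    nh4_out = nh4_in + mineralized_n
    if nh4_out < 0:
        log.warning("nitrogen immobilization drove NH4-N below 0; clamping")
        nh4_out = 0.0

    keep = 1.0 - vol_red
    out = _stream_from_pools(
        out_pools,
        ash=ash,
        vol_red=vol_red,
        nh4_n=nh4_out,
        ph=plan.ph_out if plan is not None else (feed.ph or 7.5),
        vfa={
            acid: feed.vfa[acid] - vfa_deg_mmol[acid] for acid in feed.vfa
        },
    )
    specific_gas = ch4 + co2
    record = StageRecord(
        name=name or f"stage{stage_index + 1}",
        out=out,
        temperature=plan.temperature if plan else None,
        hrt=plan.hrt if plan else None,
        olr=plan.olr if plan else None,
        specific_gas=specific_gas,
        ch4_fraction=ch4 / specific_gas if specific_gas > 0 else 0.0,
        vol_red=vol_red,
    )
    gases = {
        "ch4": ch4,
        "co2": co2,
        "vol_red": vol_red,
        "biomass_protein_out": biomass_protein_total / keep,  # g/kg digestate
        "new_biomass_protein": new_biomass_protein,           # g/kg feed
    }
    return record, gases


def simulate_plant(
    substrate: StreamComposition,
    truth: SyntheticGroundTruth,
    plans: tuple[StagePlan, ...] | None = None,
) -> list[StageRecord]:
    """Chain :func:`simulate_digestion` over all stages of a ground truth.

    Fills ``truth.stage_vol_red`` and ``truth.stage_biomass_protein``
    (the latter in g per kg of original substrate) as a side effect.
    """
    stages: list[StageRecord] = []
    feed = substrate
    biomass_protein = 0.0  # g per kg current feed
    cum_keep = 1.0
    truth.stage_vol_red = []
    truth.stage_biomass_protein = []
    names = ("digester", "post_digester")
    for k in range(len(truth.stage_deg)):
        plan = plans[k] if plans is not None else None
        record, gases = simulate_digestion(
            feed,
            truth,
            stage_index=k,
            biomass_protein_in=biomass_protein,
            plan=plan,
            name=names[k] if k < len(names) else f"stage{k + 1}",
        )
        stages.append(record)
        truth.stage_vol_red.append(gases["vol_red"])
        truth.stage_biomass_protein.append(
            gases["new_biomass_protein"] * cum_keep
        )
        cum_keep *= 1.0 - gases["vol_red"]
        biomass_protein = gases["biomass_protein_out"]
        feed = record.out
    return stages


_NOISY_SCALARS = ("crude_fat", "nh4_n", "eps_p", "eps_c", "smp_p", "smp_c", "doc")


def add_noise(
    stream: StreamComposition, cv: float, seed: int | np.random.Generator = 0
) -> StreamComposition:
    """Apply multiplicative lognormal measurement noise to a stream.

    Noise acts on the underlying quantities (fiber fractions, organic
    nitrogen, VS pools) rather than on derived assay values, so invariants
    such as ``adl <= adf <= ndf`` and ``nh4_n <= kjeldahl_n`` survive by
    construction.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return replace(stream)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict = {}
    for name in _NOISY_SCALARS:
        v = getattr(stream, name)
        out[name] = None if v is None else v * float(_lognormal_factor(rng, cv))
    # protein and organic N jointly, keeping kjeldahl = nh4 + org N
    if stream.protein is not None:
        out["protein"] = stream.protein * float(_lognormal_factor(rng, cv))
        if stream.kjeldahl_n is not None:
            out["kjeldahl_n"] = (out["nh4_n"] or 0.0) + out["protein"] / PROTEIN_PER_NITROGEN
    if "kjeldahl_n" not in out and stream.kjeldahl_n is not None:
        # keep the nitrogen hierarchy valid when protein was not measured
        out["kjeldahl_n"] = max(stream.kjeldahl_n, out.get("nh4_n") or 0.0)
    # fiber trio via its underlying fractions
    if None not in (stream.ndf, stream.adf, stream.adl):
        hemi = (stream.ndf - stream.adf) * float(_lognormal_factor(rng, cv))
        cell = (stream.adf - stream.adl) * float(_lognormal_factor(rng, cv))
        lign = stream.adl * float(_lognormal_factor(rng, cv))
        out["ndf"], out["adf"], out["adl"] = hemi + cell + lign, cell + lign, lign
    out["sugar_monomers"] = {
        k: v * float(_lognormal_factor(rng, cv))
        for k, v in stream.sugar_monomers.items()
    }
    out["vfa"] = {
        k: v * float(_lognormal_factor(rng, cv)) for k, v in stream.vfa.items()
    }
    out["elements"] = {
        k: v * float(_lognormal_factor(rng, cv)) for k, v in stream.elements.items()
    }
    if stream.ts is not None:
        out["ts"] = min(stream.ts * float(_lognormal_factor(rng, cv)), 0.999)
        if stream.vs_of_ts is not None:
            out["vs_of_ts"] = min(
                stream.vs_of_ts * float(_lognormal_factor(rng, cv)), 1.0
            )
    out["ph"] = stream.ph
    out["viscosity_20"] = stream.viscosity_20
    out["viscosity_100"] = stream.viscosity_100
    out["enzyme_activities"] = dict(stream.enzyme_activities)
    out["c_n_ratio"] = stream.c_n_ratio
    return StreamComposition(**out)


@dataclass
class SyntheticPlant:
    """One simulated plant: substrate, stages, and its ground truth."""

    name: str
    category: str
    substrate: StreamComposition
    stages: list[StageRecord]
    truth: SyntheticGroundTruth


#: Category mix mirroring a nine-plant survey: four food-waste plants
#: (one thermophilic dry), two plant-based agricultural, one agricultural
#: + manure, two sewage-sludge plants.
DEFAULT_CATEGORIES = ("FW", "FW", "FW", "FW-TD", "AW", "AW", "AWM", "WWTP", "WWTP")


def generate_survey(
    n_plants: int = 9,
    categories: tuple[str, ...] | None = None,
    seed: int = 0,
    noise_cv: float = 0.0,
    templates: dict[str, PlantTemplate] | None = None,
) -> list[SyntheticPlant]:
    """Generate a reproducible synthetic survey of biogas plants.

    Each plant draws a substrate from its category template, samples true
    degradation fractions uniformly within the template's stage ranges,
    simulates the stage chain exactly, and (optionally) perturbs every
    *measured* stream with lognormal noise of the given CV.  The returned
    ground truths permit exact parameter-recovery assertions.
    """
    if n_plants < 2:
        raise ValueError("a survey needs at least 2 plants")
    templates = templates or DEFAULT_TEMPLATES
    if categories is None:
        categories = tuple(
            DEFAULT_CATEGORIES[i % len(DEFAULT_CATEGORIES)] for i in range(n_plants)
        )
    if len(categories) != n_plants:
        raise ValueError("categories must have one entry per plant")
    rng = np.random.default_rng(seed)
    plants: list[SyntheticPlant] = []
    counts: dict[str, int] = {}
    for i in range(n_plants):
        cat = categories[i]
        if cat not in templates:
            raise ValueError(f"unknown category {cat!r}; known: {sorted(templates)}")
        tpl = templates[cat]
        counts[cat] = counts.get(cat, 0) + 1
        name = f"{cat}{counts[cat]}"
        substrate = sample_substrate(tpl, rng)
        stage_deg = [
            {
                a: float(rng.uniform(lo, hi))
                for a, (lo, hi) in plan.deg_ranges.items()
            }
            for plan in tpl.stages
        ]
        truth = SyntheticGroundTruth(
            plant=name,
            category=cat,
            stage_deg=stage_deg,
            noise_cv=noise_cv,
            seed=seed,
        )
        stages = simulate_plant(substrate, truth, plans=tpl.stages)
        if noise_cv > 0:
            substrate = add_noise(substrate, noise_cv, rng)
            for st in stages:
                st.out = add_noise(st.out, noise_cv, rng)
        plants.append(
            SyntheticPlant(
                name=name,
                category=cat,
                substrate=substrate,
                stages=stages,
                truth=truth,
            )
        )
    return plants


def survey_feature_matrix(plants: list[SyntheticPlant]):
    """Main-digester feature table for the statistics layer.

    One row per plant, columns covering composition, operation and
    nitrogen chemistry of the main digester (the paper-style feature
    view of a survey).
    """
    import pandas as pd

    rows = {}
    for p in plants:
        d = p.stages[0]
        s = d.out
        fib = s.fiber_fractions()
        rows[p.name] = {
            "ts": s.ts,
            "vs_of_ts": s.vs_of_ts,
            "ph": s.ph,
            "nh4_n": s.nh4_n,
            "protein": s.protein,
            "crude_fat": s.crude_fat,
            "free_sugars": fib.free_sugars,
            "hemicellulose": fib.hemicellulose,
            "cellulose": fib.cellulose,
            "lignin_like": fib.lignin_like,
            "vfa_total": s.total_vfa_mmol_per_l,
            "temperature": d.temperature,
            "hrt": d.hrt,
            "olr": d.olr,
            "specific_gas": d.specific_gas,
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
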