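"""Volume-corrected mass balances across anaerobic digestion stages.

Gas leaving a digester removes mass from the liquid phase, so outgoing
digestate concentrations (g per kg digestate) overstate what remains per
kg of feed.  Every balance here therefore works on a *per-kg-feed* basis:
an outgoing concentration is multiplied by ``(1 - vol_red)``, where
``vol_red`` is the fraction of the feed mass carried off as biogas.

Quantities computed per stage chain:

* adjusted VS reduction (``1 - VS_out_adjusted / VS_in``);
* per-macromolecule degradation efficiencies, per stage and overall;
* degraded VS (g per kg feed and kg VS per m3 reactor per day);
* microbial biomass protein ``Y_prot`` (0.1 g biomass per g VS degraded,
  half of it protein) and the substrate-derived residual protein;
* nitrogen mineralization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .composition import StreamComposition, SubstrateComponent, mix_streams

log = logging.getLogger(__name__)

#: Ideal-gas densities at 273.2 K and 1.01325 bar, g per normal litre.
RHO_CH4 = 0.716
RHO_CO2 = 1.964

#: Microbial growth yield: g biomass formed per g VS degraded.
BIOMASS_YIELD = 0.1
#: Protein fraction of newly formed microbial biomass.
BIOMASS_PROTEIN_FRACTION = 0.5

#: Analytes carried through a chained balance, with the stream attribute
#: or fiber-fraction field they are read from.
CHAIN_ANALYTES = (
    "protein",
    "crude_fat",
    "free_sugars",
    "hemicellulose",
    "cellulose",
    "lignin_like",
    "carbohydrates",
)


@dataclass
class StageRecord:
    """One digestion step and its outgoing stream.

    ``specific_gas`` is the biogas production in NL per kg of feed to the
    stage; together with ``ch4_fraction`` it allows the liquid-volume
    reduction to be inferred from the gas mass when ``vol_red`` is not
    measured directly.
    """

    name: str
    out: StreamComposition
    temperature: float | None = None  # degC
    hrt: float | None = None          # days
    olr: float | None = None          # kg VS / m3 / day
    specific_gas: float | None = None  # NL biogas / kg feed
    ch4_fraction: float | None = None
    vol_red: float | None = None      # fraction of feed mass lost as gas

    def __post_init__(self) -> None:
        if self.vol_red is not None and not 0.0 <= self.vol_red < 1.0:
            raise ValueError(f"vol_red must lie in [0, 1), got {self.vol_red}")
        if self.temperature is not None and not 20.0 <= self.temperature <= 70.0:
            raise ValueError(
                f"temperature {self.temperature} degC outside plausible range [20, 70]"
            )
        if self.hrt is not None and self.hrt <= 0:
            raise ValueError(f"hrt must be positive, got {self.hrt}")

    def resolve_vol_red(self) -> float:
        """Stage volume reduction: measured, inferred from gas, or 0."""
        if self.vol_red is not None:
            return self.vol_red
        if self.specific_gas is not None and self.ch4_fraction is not None:
            return volume_reduction_from_gas(self.specific_gas, self.ch4_fraction)
        log.warning(
            "stage %r: no volume reduction or gas data; assuming vol_red = 0 "
            "(degradation efficiencies will be biased downward)",
            self.name,
        )
        return 0.0


@dataclass
class MassBalanceResult:
    """Outcome of a chained stage balance.

    ``per_stage_deg`` and ``overall_deg`` hold raw degradation
    efficiencies computed from the measured (volume-adjusted) stream
    concentrations.  ``deg_protein_substrate`` additionally credits the
    final digestate with the estimated microbial biomass protein
    ``y_prot``, isolating degradation of substrate-derived protein.
    """

    vs_red_adj: float | None = None
    per_stage_deg: dict[str, dict[str, float]] = field(default_factory=dict)
    overall_deg: dict[str, float] = field(default_factory=dict)
    degraded_vs_conc: float | None = None   # g VS / kg feed
    degraded_vs_rate: float | None = None   # kg VS / m3 / day
    y_prot: float | None = None             # g / kg feed
    protein_resid: float | None = None      # g / kg feed (substrate-derived)
    deg_protein_substrate: float | None = None
    n_mineralization: float | None = None
    stage_vol_red: dict[str, float] = field(default_factory=dict)


@dataclass
class PlantRecord:
    """One digestion line: a substrate mixture chained to 1-2 stages.

    Parallel digesters at the same site are separate records sharing the
    ``site`` label.
    """

    name: str
    substrate_components: list[SubstrateComponent]
    stages: list[StageRecord]
    site: str | None = None
    category: str | None = None

    @property
    def substrate(self) -> StreamComposition:
        if len(self.substrate_components) == 1:
            return self.substrate_components[0].composition
        return mix_streams(self.substrate_components)

    def balance(self) -> MassBalanceResult:
        return chain_stages(self.substrate, self.stages)


def volume_reduction_from_gas(specific_gas: float, ch4_fraction: float) -> float:
    """Fraction of feed mass removed as biogas.

    The biogas mass per kg feed is computed from ideal-gas densities at
    273.2 K / 1.01325 bar, treating everything that is not methane as
    carbon dioxide (trace H2S/H2/N2 are negligible on a mass basis).
    """
    if specific_gas < 0:
        raise ValueError(f"specific_gas must be non-negative, got {specific_gas}")
    if not 0.0 <= ch4_fraction <= 1.0:
        raise ValueError(f"ch4_fraction must lie in [0, 1], got {ch4_fraction}")
    gas_mass_g = specific_gas * (
        ch4_fraction * RHO_CH4 + (1.0 - ch4_fraction) * RHO_CO2
    )
    return gas_mass_g / 1000.0


def adjust_outflow(conc_out: float, vol_red: float) -> float:
    """Convert g per kg digestate to g per kg feed via the volume reduction."""
    if not 0.0 <= vol_red < 1.0:
        raise ValueError(f"vol_red must lie in [0, 1), got {vol_red}")
    return conc_out * (1.0 - vol_red)


def vs_reduction_adjusted(
    ts_in: float, vs_in: float, ts_out: float, vs_out: float, vol_red: float
) -> float:
    """Volume-adjusted VS reduction across a digestion step.

    The remaining fraction of ingoing VS is
    ``ts_out * vs_out * (1 - vol_red) / (ts_in * vs_in)``; the reduction
    is its complement.
    """
    denom = ts_in * vs_in
    if denom <= 0:
        raise ValueError("ingoing VS (ts_in * vs_in) must be positive")
    remaining = ts_out * vs_out * (1.0 - vol_red) / denom
    return 1.0 - remaining


def degradation_efficiency(x_in: float, x_out_per_feed: float) -> float:
    """Fraction of an ingoing analyte degraded: (X_in - X_out) / X_in.

    ``x_out_per_feed`` must already be on a per-kg-feed basis
    (see :func:`adjust_outflow`).  Negative efficiencies (accumulation,
    e.g. of microbial protein) are allowed and flagged.
    """
    if x_in <= 0:
        raise ValueError(f"x_in must be positive, got {x_in}")
    eff = (x_in - x_out_per_feed) / x_in
    if eff < 0:
        log.warning(
            "negative degradation efficiency %.3f (in %g -> out %g): accumulation",
            eff,
            x_in,
            x_out_per_feed,
        )
    return eff


def degraded_vs_conc(ts_in: float, vs_in: float, vs_red_adj: float) -> float:
    """Degraded VS in g per kg feed: TS_in * VS_in * 1000 * VS_red_adj."""
    return ts_in * vs_in * 1000.0 * vs_red_adj


def degraded_vs_rate(olr: float, vs_red_adj: float) -> float:
    """Degraded VS per reactor volume and day: OLR * VS_red_adj."""
    if olr < 0:
        raise ValueError(f"olr must be non-negative, got {olr}")
    return olr * vs_red_adj


def y_prot(degraded_vs: float) -> float:
    """Microbial biomass protein formed per kg feed.

    Growth is assumed to convert 10% of the degraded VS into new biomass,
    of which half is protein.
    """
    if degraded_vs < 0:
        raise ValueError(f"degraded_vs must be non-negative, got {degraded_vs}")
    return BIOMASS_YIELD * BIOMASS_PROTEIN_FRACTION * degraded_vs


def protein_residual(protein: float, y_prot_value: float) -> float:
    """Substrate-derived residual protein: measured protein minus Y_prot.

    Floored at zero with a warning -- a negative residual means the
    biomass estimate exceeds the measurement (seen at very high VS
    reduction, where Y_prot is likely overestimated).
    """
    if protein < 0 or y_prot_value < 0:
        raise ValueError("protein and y_prot must be non-negative")
    resid = protein - y_prot_value
    if resid < 0:
        log.warning(
            "residual protein floored at 0 (protein %g < Y_prot %g)",
            protein,
            y_prot_value,
        )
        return 0.0
    return resid


def nitrogen_mineralization(
    nh4_out: float, nh4_in: float, kjeldahl_out: float
) -> float:
    """Fraction of outgoing Kjeldahl-N newly mineralized to ammonium."""
    if kjeldahl_out <= 0:
        raise ValueError(f"kjeldahl_out must be positive, got {kjeldahl_out}")
    frac = (nh4_out - nh4_in) / kjeldahl_out
    if frac < 0:
        log.warning("negative nitrogen mineralization %.3f (immobilization)", frac)
    return frac


def analyte_concentrations(stream: StreamComposition) -> dict[str, float]:
    """Extract the chained-balance analyte map from a stream (g/kg ww).

    Fiber-derived analytes require the full NDF/ADF/ADL panel and the
    sugar monomer panel; analytes whose inputs are absent are omitted.
    """
    conc: dict[str, float] = {}
    if stream.protein is not None:
        conc["protein"] = stream.protein
    if stream.crude_fat is not None:
        conc["crude_fat"] = stream.crude_fat
    if None not in (stream.ndf, stream.adf, stream.adl) and stream.sugar_monomers:
        fib = stream.fiber_fractions()
        conc["free_sugars"] = fib.free_sugars
        conc["hemicellulose"] = fib.hemicellulose
        conc["cellulose"] = fib.cellulose
        conc["lignin_like"] = fib.lignin_like
        conc["carbohydrates"] = fib.free_sugars + fib.hemicellulose + fib.cellulose
    return conc


def chain_stages(
    substrate: StreamComposition, stages: list[StageRecord]
) -> MassBalanceResult:
    """Balance a substrate through one or two (or more) digestion stages.

    Stage ``k``'s feed is stage ``k-1``'s volume-adjusted outflow, so
    per-stage efficiencies compose multiplicatively into the overall
    efficiency, which uses the substrate input and the final outflow on a
    per-kg-substrate basis (cumulative product of ``1 - vol_red``).
    """
    if not stages:
        raise ValueError("chain_stages requires at least one stage")
    result = MassBalanceResult()

    sub_conc = analyte_concentrations(substrate)
    feed_conc = dict(sub_conc)  # per kg of original substrate
    cum_keep = 1.0              # product of (1 - vol_red) over stages

    for stage in stages:
        v = stage.resolve_vol_red()
        result.stage_vol_red[stage.name] = v
        out_conc = analyte_concentrations(stage.out)
        stage_deg: dict[str, float] = {}
        new_feed: dict[str, float] = {}
        for analyte, x_in in feed_conc.items():
            if analyte not in out_conc:
                log.warning(
                    "analyte %r missing from stage %r output; skipped",
                    analyte,
                    stage.name,
                )
                continue
            x_out = adjust_outflow(out_conc[analyte], v) * cum_keep
            new_feed[analyte] = x_out
            if x_in > 0:
                stage_deg[analyte] = degradation_efficiency(x_in, x_out)
        result.per_stage_deg[stage.name] = stage_deg
        feed_conc = new_feed
        cum_keep *= 1.0 - v

    for analyte, x_in in sub_conc.items():
        if analyte in feed_conc and x_in > 0:
            result.overall_deg[analyte] = degradation_efficiency(
                x_in, feed_conc[analyte]
            )

    final = stages[-1].out
    has_vs = None not in (
        substrate.ts,
        substrate.vs_of_ts,
        final.ts,
        final.vs_of_ts,
    )
    if has_vs:
        overall_vol_red = 1.0 - cum_keep
        result.vs_red_adj = vs_reduction_adjusted(
            substrate.ts, substrate.vs_of_ts, final.ts, final.vs_of_ts, overall_vol_red
        )
        result.degraded_vs_conc = degraded_vs_conc(
            substrate.ts, substrate.vs_of_ts, result.vs_red_adj
        )
        if stages[0].olr is not None:
            result.degraded_vs_rate = degraded_vs_rate(
                stages[0].olr, result.vs_red_adj
            )
        result.y_prot = y_prot(result.degraded_vs_conc)
        if "protein" in feed_conc:
            result.protein_resid = protein_residual(
                feed_conc["protein"], result.y_prot
            )
            if sub_conc.get("protein", 0) > 0:
                result.deg_protein_substrate = degradation_efficiency(
                    sub_conc["protein"], result.protein_resid
                )
    if None not in (final.nh4_n, substrate.nh4_n, final.kjeldahl_n):
        result.n_mineralization = nitrogen_mineralization(
            final.nh4_n, substrate.nh4_n, final.kjeldahl_n
        )
    return result
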