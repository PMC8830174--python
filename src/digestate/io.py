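"""Plant-table readers/writers, analysis configuration and reports.

A plant table is two delimited text files:

* a **streams** table, one row per material stream, with units embedded
  in the column headers (e.g. ``protein[g/kg_ww]``) -- silent unit
  guessing is forbidden, a header with the wrong unit is an error;
* an optional **analytes** table in long format (``plant, stream_id,
  group, analyte, value, unit``) carrying the per-monomer sugar panel,
  the per-acid VFA profile and element concentrations.

Roles within a plant: ``substrate`` (a premixed substrate),
``substrate_component`` (one component of a mixture, dosed by
``volume_fraction``), ``digester`` and ``post_digester``.  Parallel
digestion lines at one site are separate plants sharing the ``site``
column.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import balance as bal
from . import methane as mp
from .balance import MassBalanceResult, PlantRecord, StageRecord, chain_stages
from .composition import StreamComposition, SubstrateComponent
from .methane import vfa_mg_per_l_to_mmol_per_l

log = logging.getLogger(__name__)

#: Canonical stream-table columns: field name -> header (with unit).
STREAM_COLUMNS: dict[str, str] = {
    "site": "site",
    "plant": "plant",
    "stream_id": "stream_id",
    "role": "role",
    "component_name": "component_name",
    "volume_fraction": "volume_fraction[frac]",
    "density": "density[kg/L]",
    "temperature": "temperature[C]",
    "hrt": "hrt[d]",
    "olr": "olr[kgVS/m3/d]",
    "specific_gas": "specific_gas[NL/kg]",
    "ch4_fraction": "ch4_fraction[frac]",
    "vol_red": "vol_red[frac]",
    "vs_red_reported": "vs_red_reported[frac]",
    "ts": "ts[frac_ww]",
    "vs_of_ts": "vs_of_ts[frac_TS]",
    "ph": "ph[-]",
    "kjeldahl_n": "kjeldahl_n[g/kg_ww]",
    "nh4_n": "nh4_n[g/kg_ww]",
    "protein": "protein[g/kg_ww]",
    "crude_fat": "crude_fat[g/kg_ww]",
    "ndf": "ndf[g/kg_ww]",
    "adf": "adf[g/kg_ww]",
    "adl": "adl[g/kg_ww]",
}
_HEADER_TO_FIELD = {v: k for k, v in STREAM_COLUMNS.items()}

ROLES = ("substrate", "substrate_component", "digester", "post_digester")

#: Allowed units in the long analyte table, by analyte group.
ANALYTE_UNITS = {
    "sugar": ("g/kg_ww",),
    "vfa": ("mmol/L", "mg/L"),
    "element": ("mg/kg",),
}

ANALYTE_COLUMNS = ["plant", "stream_id", "group", "analyte", "value", "unit"]


@dataclass(frozen=True)
class PlantTableDialect:
    """Delimiter and format conventions of a plant table."""

    delimiter: str = "\t"
    comment: str = "#"


@dataclass
class AnalysisConfig:
    """Constants of the analysis pipeline, with their standard defaults.

    ``vol_red_policy`` selects how a stage's volume reduction is
    obtained: ``"given"`` (use the table value, infer from gas data when
    absent), ``"from_gas"`` (always infer from gas data) or ``"zero"``
    (ignore volume reduction).  Overrides of any constant are logged.
    """

    density: float = 1.0  # kg/L
    vol_red_policy: str = "given"
    biomass_yield: float = bal.BIOMASS_YIELD
    biomass_protein_fraction: float = bal.BIOMASS_PROTEIN_FRACTION
    tmp_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(mp.CH4_PER_G)
    )
    hansen_a: float = mp.HANSEN_A
    hansen_b: float = mp.HANSEN_B
    molar_volume: float = mp.MOLAR_VOLUME
    significance_thresholds: tuple[float, ...] = (0.1, 0.05, 0.01)

    def __post_init__(self) -> None:
        if self.vol_red_policy not in ("given", "from_gas", "zero"):
            raise ValueError(f"unknown vol_red_policy {self.vol_red_policy!r}")
        defaults = AnalysisConfig.__new__(AnalysisConfig)
        for f in dataclasses.fields(self):
            if f.default is not dataclasses.MISSING:
                default = f.default
            else:
                default = f.default_factory()  # type: ignore[misc]
            value = getattr(self, f.name)
            if value != default:
                log.info("config override: %s = %r (default %r)", f.name, value, default)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        ) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tmp_coefficients" in data:
            data["tmp_coefficients"] = dict(data["tmp_coefficients"])
        if "significance_thresholds" in data:
            data["significance_thresholds"] = tuple(data["significance_thresholds"])
        return cls(**data)


def _validate_headers(columns, path) -> dict[str, str]:
    """Map table headers to canonical fields; unknown columns warn."""
    mapping: dict[str, str] = {}
    for col in columns:
        if col in _HEADER_TO_FIELD:
            mapping[col] = _HEADER_TO_FIELD[col]
        elif col.split("[")[0] in STREAM_COLUMNS:
            raise ValueError(
                f"{path}: column {col!r} has a malformed or wrong unit; "
                f"expected {STREAM_COLUMNS[col.split('[')[0]]!r}"
            )
        else:
            log.warning("%s: unknown column %r preserved but ignored", path, col)
    for mandatory in ("plant", "stream_id", "role"):
        if STREAM_COLUMNS[mandatory] not in columns:
            raise ValueError(f"{path}: missing mandatory column {mandatory!r}")
    return mapping


def _opt(row, name: str):
    v = row.get(name)
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return v


_STREAM_FIELDS = (
    "ts",
    "vs_of_ts",
    "ph",
    "kjeldahl_n",
    "nh4_n",
    "protein",
    "crude_fat",
    "ndf",
    "adf",
    "adl",
)


def _row_stream(row: dict, extras: dict) -> StreamComposition:
    kwargs = {name: _opt(row, name) for name in _STREAM_FIELDS}
    kwargs.update(extras)
    return StreamComposition(**kwargs)


def _collect_analytes(
    analytes: pd.DataFrame | None, plant: str, stream_id: str
) -> dict[str, dict[str, float]]:
    """Sugar/VFA/element maps for one stream, converted to canonical units."""
    out: dict[str, dict[str, float]] = {
        "sugar_monomers": {},
        "vfa": {},
        "elements": {},
    }
    if analytes is None:
        return out
    sub = analytes[
        (analytes["plant"] == plant) & (analytes["stream_id"] == stream_id)
    ]
    for _, row in sub.iterrows():
        group, analyte = row["group"], row["analyte"]
        value, unit = float(row["value"]), row["unit"]
        where = f"plant {plant!r}, stream {stream_id!r}, analyte {analyte!r}"
        if group not in ANALYTE_UNITS:
            raise ValueError(f"unknown analyte group {group!r} at {where}")
        if unit not in ANALYTE_UNITS[group]:
            raise ValueError(
                f"unit {unit!r} not allowed for group {group!r} at {where}; "
                f"allowed: {ANALYTE_UNITS[group]}"
            )
        if group == "sugar":
            out["sugar_monomers"][analyte] = value
        elif group == "vfa":
            if unit == "mg/L":
                value = vfa_mg_per_l_to_mmol_per_l(analyte, value)
            out["vfa"][analyte] = value
        else:
            out["elements"][analyte] = value
    return out


def read_plant_table(
    streams_path: str | Path,
    analytes_path: str | Path | None = None,
    dialect: PlantTableDialect = PlantTableDialect(),
) -> list[PlantRecord]:
    """Parse a plant table into validated records on the canonical basis."""
    streams_path = Path(streams_path)
    df = pd.read_csv(streams_path, sep=dialect.delimiter, comment=dialect.comment)
    mapping = _validate_headers(df.columns, streams_path)
    df = df.rename(columns=mapping)[list(mapping.values())]

    analytes = None
    if analytes_path is not None:
        analytes = pd.read_csv(
            Path(analytes_path), sep=dialect.delimiter, comment=dialect.comment
        )
        missing = set(ANALYTE_COLUMNS) - set(analytes.columns)
        if missing:
            raise ValueError(f"{analytes_path}: missing columns {sorted(missing)}")

    records: list[PlantRecord] = []
    for plant, group in df.groupby("plant", sort=False):
        components: list[SubstrateComponent] = []
        staged: list[tuple[str, StageRecord]] = []
        site = None
        for _, prow in group.iterrows():
            row = prow.to_dict()
            stream_id = row["stream_id"]
            role = row["role"]
            site = _opt(row, "site") or site
            where = f"{streams_path}: plant {plant!r}, stream {stream_id!r}"
            if role not in ROLES:
                raise ValueError(f"{where}: unknown role {role!r}")
            try:
                stream = _row_stream(
                    row, _collect_analytes(analytes, plant, stream_id)
                )
            except ValueError as exc:
                raise ValueError(f"{where}: {exc}") from exc
            if role in ("substrate", "substrate_component"):
                components.append(
                    SubstrateComponent(
                        name=_opt(row, "component_name") or stream_id,
                        volume_fraction=float(_opt(row, "volume_fraction") or 1.0),
                        density=float(_opt(row, "density") or 1.0),
                        composition=stream,
                    )
                )
            else:
                staged.append(
                    (
                        role,
                        StageRecord(
                            name=stream_id,
                            out=stream,
                            temperature=_opt(row, "temperature"),
                            hrt=_opt(row, "hrt"),
                            olr=_opt(row, "olr"),
                            specific_gas=_opt(row, "specific_gas"),
                            ch4_fraction=_opt(row, "ch4_fraction"),
                            vol_red=_opt(row, "vol_red"),
                        ),
                    )
                )
        # main digesters precede post-digesters in the chain
        stages = [s for _, s in sorted(staged, key=lambda rs: rs[0] == "post_digester")]
        records.append(
            PlantRecord(
                name=str(plant),
                substrate_components=components,
                stages=stages,
                site=str(site) if site is not None else str(plant),
            )
        )
    return records


def write_plant_table(
    records: list[PlantRecord],
    streams_path: str | Path,
    analytes_path: str | Path | None = None,
    dialect: PlantTableDialect = PlantTableDialect(),
) -> None:
    """Write records back to the canonical two-file plant table."""
    srows, arows = [], []

    def stream_row(plant, site, stream_id, role, stream, **extra):
        row = {STREAM_COLUMNS["site"]: site, STREAM_COLUMNS["plant"]: plant,
               STREAM_COLUMNS["stream_id"]: stream_id, STREAM_COLUMNS["role"]: role}
        for name in _STREAM_FIELDS:
            row[STREAM_COLUMNS[name]] = getattr(stream, name)
        for k, v in extra.items():
            row[STREAM_COLUMNS[k]] = v
        srows.append(row)
        for group, attr, unit in (
            ("sugar", "sugar_monomers", "g/kg_ww"),
            ("vfa", "vfa", "mmol/L"),
            ("element", "elements", "mg/kg"),
        ):
            for analyte, value in sorted(getattr(stream, attr).items()):
                arows.append(
                    dict(
                        plant=plant, stream_id=stream_id, group=group,
                        analyte=analyte, value=value, unit=unit,
                    )
                )

    for rec in records:
        multi = len(rec.substrate_components) > 1
        for i, comp in enumerate(rec.substrate_components):
            stream_row(
                rec.name,
                rec.site or rec.name,
                f"{rec.name}-S{i + 1}" if multi else f"{rec.name}-S",
                "substrate_component" if multi else "substrate",
                comp.composition,
                component_name=comp.name,
                volume_fraction=comp.volume_fraction,
                density=comp.density,
            )
        for k, stage in enumerate(rec.stages):
            stream_row(
                rec.name,
                rec.site or rec.name,
                stage.name,
                "digester" if k == 0 else "post_digester",
                stage.out,
                temperature=stage.temperature,
                hrt=stage.hrt,
                olr=stage.olr,
                specific_gas=stage.specific_gas,
                ch4_fraction=stage.ch4_fraction,
                vol_red=stage.vol_red,
            )

    pd.DataFrame(srows).to_csv(streams_path, sep=dialect.delimiter, index=False)
    if analytes_path is not None:
        pd.DataFrame(arows, columns=ANALYTE_COLUMNS).to_csv(
            analytes_path, sep=dialect.delimiter, index=False
        )


# ---------------------------------------------------------------------------
# analysis driver and report generation
# ---------------------------------------------------------------------------


def analyze_plant(record: PlantRecord, config: AnalysisConfig | None = None) -> dict:
    """Run the full characterization of one plant record.

    Returns a dict with the chained mass balance (when the substrate
    carries analyte data), per-stream theoretical methane potentials, and
    free ammonia per digestion stage (when pH and temperature are known).
    """
    config = config or AnalysisConfig()
    out: dict = {"plant": record.name, "balance": None, "tmp": {}, "nh3": {}}
    stages = record.stages
    if config.vol_red_policy == "zero":
        stages = [dataclasses.replace(s, vol_red=0.0) for s in stages]
    elif config.vol_red_policy == "from_gas":
        stages = [dataclasses.replace(s, vol_red=None) for s in stages]

    substrate = record.substrate if record.substrate_components else None
    if substrate is not None and stages:
        try:
            out["balance"] = chain_stages(substrate, stages)
        except ValueError as exc:
            log.warning("plant %s: no mass balance (%s)", record.name, exc)

    named = [("substrate", substrate)] if substrate is not None else []
    named += [(s.name, s.out) for s in stages]
    for name, stream in named:
        try:
            out["tmp"][name] = mp.stream_tmp(stream, density=config.density)
        except ValueError:
            pass
    for stage in stages:
        s = stage.out
        if None not in (s.nh4_n, s.ph, stage.temperature):
            out["nh3"][stage.name] = mp.free_ammonia(s.nh4_n, s.ph, stage.temperature)
    return out


def _fmt(value, digits=3) -> str:
    if value is None:
        return "NA"
    return f"{value:.{digits}f}"


def write_report(results: list[dict], out_dir: str | Path) -> list[Path]:
    """Write TSV result tables and a human-readable summary.

    Output is deterministic: plants and analytes are emitted in sorted
    order with fixed float formatting, so identical inputs give identical
    bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    eff_rows, tmp_rows, nh3_rows, lines = [], [], [], []

    for res in sorted(results, key=lambda r: r["plant"]):
        plant = res["plant"]
        lines.append(f"== Plant {plant} ==")
        balr: MassBalanceResult | None = res["balance"]
        if balr is not None:
            for stage, degs in balr.per_stage_deg.items():
                for analyte, effv in sorted(degs.items()):
                    eff_rows.append((plant, stage, analyte, effv))
            for analyte, effv in sorted(balr.overall_deg.items()):
                eff_rows.append((plant, "overall", analyte, effv))
                lines.append(
                    f"overall {analyte} degradation: {effv * 100:.0f}%"
                )
            if balr.vs_red_adj is not None:
                lines.append(f"VS reduction (adjusted): {balr.vs_red_adj * 100:.0f}%")
            if balr.y_prot is not None:
                lines.append(f"Y_prot: {_fmt(balr.y_prot, 2)} g/kg")
            if balr.protein_resid is not None:
                lines.append(
                    f"residual substrate protein: {_fmt(balr.protein_resid, 2)} g/kg"
                )
            if balr.n_mineralization is not None:
                lines.append(
                    f"nitrogen mineralization: {balr.n_mineralization * 100:.0f}%"
                )
        for name, tmp in sorted(res["tmp"].items()):
            tmp_rows.append(
                (plant, name, tmp.tmp_macro, tmp.tmp_vfa, tmp.tmp_total,
                 tmp.tmp_vs_basis)
            )
            lines.append(f"TMP[{name}]: {tmp.tmp_total:.1f} NL CH4/kg ww")
        for name, nh3 in sorted(res["nh3"].items()):
            nh3_rows.append((plant, name, nh3))
            lines.append(f"NH3-N[{name}]: {nh3:.2f} g/kg")
        lines.append("")

    paths = []
    eff = out_dir / "efficiencies.tsv"
    pd.DataFrame(
        eff_rows, columns=["plant", "stage", "analyte", "degradation"]
    ).to_csv(eff, sep="\t", index=False, float_format="%.6f")
    tmpf = out_dir / "tmp.tsv"
    pd.DataFrame(
        tmp_rows,
        columns=["plant", "stream", "tmp_macro", "tmp_vfa", "tmp_total", "tmp_per_vs"],
    ).to_csv(tmpf, sep="\t", index=False, float_format="%.6f")
    nh3f = out_dir / "ammonia.tsv"
    pd.DataFrame(nh3_rows, columns=["plant", "stage", "nh3_n"]).to_csv(
        nh3f, sep="\t", index=False, float_format="%.6f"
    )
    rep = out_dir / "report.txt"
    rep.write_text("\n".join(lines))
    paths.extend([eff, tmpf, nh3f, rep])
    return paths
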