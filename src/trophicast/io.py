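"""Readers and writers for the pipeline's delimited tables.

Canonical on-disk schemas (UTF-8 CSV with a header row; ``.xlsx`` input is
accepted and normalized to the same schema on ingest):

``residues.csv``
    country, site_id, matrix, species, guild, tissue, chemical_cas,
    concentration, units, detected, lod, lipid_fraction
``chemicals.csv``
    cas, name, log_kow, log_kaw, half_life_days, rfd, osf, chem_class
``species.csv``
    species, guild, bw_kg, ir_kg_per_day, lipid_fraction, btf_liver,
    btf_muscle, btf_fat, w_muscle, w_fat, f_p, f_h, f_c
``plant_params.csv``
    chemical_cas, scenario, q_transpiration, kd, alh, g, kla, lambda_loss,
    mlh, t_air, rh_air
``distributions.csv``
    parameter, mean, cv

CAS numbers are read as strings (never coerced to floats or dates); a failing
CAS check digit is a warning, not a rejection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    ChemClass,
    ChemicalProfile,
    Guild,
    Matrix,
    ResidueRecord,
    SpeciesProfile,
    Tissue,
    Units,
    ValidationError,
    cas_checksum_ok,
)

logger = logging.getLogger(__name__)

RESIDUE_COLUMNS = [
    "country", "site_id", "matrix", "species", "guild", "tissue",
    "chemical_cas", "concentration", "units", "detected", "lod",
    "lipid_fraction",
]
CHEMICAL_COLUMNS = [
    "cas", "name", "log_kow", "log_kaw", "half_life_days", "rfd", "osf",
    "chem_class",
]
SPECIES_COLUMNS = [
    "species", "guild", "bw_kg", "ir_kg_per_day", "lipid_fraction",
    "btf_liver", "btf_muscle", "btf_fat", "w_muscle", "w_fat",
    "f_p", "f_h", "f_c",
]


@dataclass
class RejectedRow:
    row: int
    reason: str


def _load_frame(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing mandatory column(s) {missing}")
    return df


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("na", "nan"):
        return None
    return float(s)


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot interpret {value!r} as boolean")


def read_residue_table(
    path: str | Path,
) -> tuple[list[ResidueRecord], list[RejectedRow]]:
    """Read residue records, validating each row against the type invariants.

    Returns the accepted records and a list of per-row rejections (0-based
    data-row index plus reason).  Missing mandatory columns are a hard error.
    """
    df = _load_frame(path, RESIDUE_COLUMNS)
    records: list[ResidueRecord] = []
    rejected: list[RejectedRow] = []
    for i, row in df.iterrows():
        try:
            cas = str(row["chemical_cas"]).strip()
            if not cas_checksum_ok(cas):
                logger.warning("row %d: CAS %r fails checksum (kept)", i, cas)
            records.append(
                ResidueRecord(
                    country=str(row["country"]).strip(),
                    site_id=str(row["site_id"]).strip(),
                    matrix=Matrix(str(row["matrix"]).strip()),
                    species=str(row["species"]).strip() if pd.notna(row["species"]) else "",
                    guild=Guild(str(row["guild"]).strip()) if pd.notna(row["guild"]) else Guild.NONE,
                    tissue=Tissue(str(row["tissue"]).strip()) if pd.notna(row["tissue"]) else Tissue.NONE,
                    chemical_cas=cas,
                    concentration=float(row["concentration"]),
                    units=Units(str(row["units"]).strip()),
                    detected=_parse_bool(row["detected"]),
                    lod=_opt_float(row["lod"]),
                    lipid_fraction=_opt_float(row["lipid_fraction"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            rejected.append(RejectedRow(row=int(i), reason=str(exc)))
    for rej in rejected:
        logger.warning("residue row %d rejected: %s", rej.row, rej.reason)
    return records, rejected


def write_residue_table(records: Iterable[ResidueRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "country": r.country,
                "site_id": r.site_id,
                "matrix": r.matrix.value,
                "species": r.species,
                "guild": r.guild.value,
                "tissue": r.tissue.value,
                "chemical_cas": r.chemical_cas,
                "concentration": r.concentration,
                "units": r.units.value,
                "detected": r.detected,
                "lod": "" if r.lod is None else r.lod,
                "lipid_fraction": "" if r.lipid_fraction is None else r.lipid_fraction,
            }
        )
    pd.DataFrame(rows, columns=RESIDUE_COLUMNS).to_csv(path, index=False)


def read_chemical_table(path: str | Path) -> dict[str, ChemicalProfile]:
    """Read chemical profiles keyed by CAS."""
    df = _load_frame(path, CHEMICAL_COLUMNS)
    profiles: dict[str, ChemicalProfile] = {}
    for _, row in df.iterrows():
        cas = str(row["cas"]).strip()
        profiles[cas] = ChemicalProfile(
            cas=cas,
            name=str(row["name"]).strip(),
            log_kow=_opt_float(row["log_kow"]),
            log_kaw=_opt_float(row["log_kaw"]),
            half_life_days=_opt_float(row["half_life_days"]),
            rfd=_opt_float(row["rfd"]),
            osf=_opt_float(row["osf"]),
            chem_class=ChemClass(str(row["chem_class"]).strip())
            if pd.notna(row["chem_class"]) and str(row["chem_class"]).strip()
            else ChemClass.OTHER,
        )
    return profiles


def write_chemical_table(profiles: Iterable[ChemicalProfile], path: str | Path) -> None:
    rows = [
        {
            "cas": p.cas,
            "name": p.name,
            "log_kow": "" if p.log_kow is None else p.log_kow,
            "log_kaw": "" if p.log_kaw is None else p.log_kaw,
            "half_life_days": "" if p.half_life_days is None else p.half_life_days,
            "rfd": "" if p.rfd is None else p.rfd,
            "osf": "" if p.osf is None else p.osf,
            "chem_class": p.chem_class.value,
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=CHEMICAL_COLUMNS).to_csv(path, index=False)


def read_species_table(path: str | Path) -> dict[str, SpeciesProfile]:
    """Read species profiles keyed by species name.

    BTFs and prey-tissue weights are flattened into per-tissue columns; a
    blank cell means the tissue has no parameter for that species.
    """
    df = _load_frame(path, SPECIES_COLUMNS)
    profiles: dict[str, SpeciesProfile] = {}
    for _, row in df.iterrows():
        btf = {}
        for tissue in (Tissue.LIVER, Tissue.MUSCLE, Tissue.FAT):
            v = _opt_float(row[f"btf_{tissue.value}"])
            if v is not None:
                btf[tissue] = v
        weights = {}
        for tissue in (Tissue.MUSCLE, Tissue.FAT):
            w = _opt_float(row[f"w_{tissue.value}"])
            if w is not None:
                weights[tissue] = w
        name = str(row["species"]).strip()
        profiles[name] = SpeciesProfile(
            species=name,
            guild=Guild(str(row["guild"]).strip()),
            bw_kg=float(row["bw_kg"]),
            ir_kg_per_day=float(row["ir_kg_per_day"]),
            lipid_fraction=_opt_float(row["lipid_fraction"]),
            btf_by_tissue=btf,
            tissue_weights=weights,
            diet_fractions=(
                _opt_float(row["f_p"]) or 0.0,
                _opt_float(row["f_h"]) or 0.0,
                _opt_float(row["f_c"]) or 0.0,
            ),
        )
    return profiles


def write_species_table(profiles: Iterable[SpeciesProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "species": p.species,
            "guild": p.guild.value,
            "bw_kg": p.bw_kg,
            "ir_kg_per_day": p.ir_kg_per_day,
            "lipid_fraction": "" if p.lipid_fraction is None else p.lipid_fraction,
            "f_p": p.diet_fractions[0],
            "f_h": p.diet_fractions[1],
            "f_c": p.diet_fractions[2],
        }
        for tissue in (Tissue.LIVER, Tissue.MUSCLE, Tissue.FAT):
            v = p.btf_by_tissue.get(tissue)
            row[f"btf_{tissue.value}"] = "" if v is None else v
        for tissue in (Tissue.MUSCLE, Tissue.FAT):
            w = p.tissue_weights.get(tissue)
            row[f"w_{tissue.value}"] = "" if w is None else w
        rows.append(row)
    pd.DataFrame(rows, columns=SPECIES_COLUMNS).to_csv(path, index=False)


PLANT_PARAM_COLUMNS = [
    "chemical_cas", "scenario", "q_transpiration", "kd", "alh", "g", "kla",
    "lambda_loss", "mlh", "t_air", "rh_air",
]


def read_plant_param_table(path: str | Path, scenario: str | None = None):
    """Read plant-uptake parameters keyed by chemical CAS.

    When ``scenario`` is given only matching rows load; otherwise the first
    row per chemical wins.
    """
    from .plant import PlantUptakeParams

    df = _load_frame(path, PLANT_PARAM_COLUMNS)
    out: dict[str, PlantUptakeParams] = {}
    for _, row in df.iterrows():
        if scenario is not None and str(row["scenario"]).strip() != scenario:
            continue
        cas = str(row["chemical_cas"]).strip()
        if cas in out:
            continue
        out[cas] = PlantUptakeParams(
            q_transpiration=float(row["q_transpiration"]),
            kd=float(row["kd"]),
            alh=float(row["alh"]),
            g=float(row["g"]),
            kla=float(row["kla"]),
            lambda_loss=float(row["lambda_loss"]),
            mlh=float(row["mlh"]),
            t_air=float(row["t_air"]),
            rh_air=float(row["rh_air"]),
        )
    return out


def read_distribution_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read ``(mean, cv)`` per parameter name from distributions.csv."""
    df = _load_frame(path, ["parameter", "mean", "cv"])
    out: dict[str, tuple[float, float]] = {}
    for _, row in df.iterrows():
        out[str(row["parameter"]).strip()] = (float(row["mean"]), float(row["cv"]))
    return out


def write_distribution_table(
    specs: dict[str, tuple[float, float]], path: str | Path
) -> None:
    pd.DataFrame(
        [{"parameter": k, "mean": m, "cv": cv} for k, (m, cv) in specs.items()],
        columns=["parameter", "mean", "cv"],
    ).to_csv(path, index=False)
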