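"""Domain types and unit standardization.

The pipeline traces pesticide residues along a soil → plant → wildlife
continuum.  Everything downstream (contamination scoring, tiered dose
reconstruction, risk characterization) operates on the small set of record
types defined here, after all concentrations have been brought onto a common
mg·kg⁻¹ basis (wet weight for animal tissue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping


class Matrix(str, Enum):
    """Environmental compartment a residue measurement comes from."""

    SOIL = "soil"
    WILD_PLANT = "wild_plant"
    ANIMAL = "animal"


class Guild(str, Enum):
    """Dietary guild of a sampled animal (``NONE`` for abiotic matrices)."""

    HERBIVORE = "herbivore"
    CARNIVORE = "carnivore"
    OMNIVORE = "omnivore"
    NONE = "none"


class Tissue(str, Enum):
    LIVER = "liver"
    MUSCLE = "muscle"
    FAT = "fat"
    WHOLE = "whole"
    NONE = "none"


class Units(str, Enum):
    """Original reporting basis of a concentration.

    Animal tissues are compiled as ng·g⁻¹ lipid weight; soils as ng·g⁻¹ dry
    weight; plants as ng·g⁻¹ (fresh weight).  Dry- vs fresh-weight bases are
    carried as metadata and not inter-converted.
    """

    NG_PER_G_LIPID = "ng_per_g_lipid"
    NG_PER_G_DW = "ng_per_g_dw"
    NG_PER_G = "ng_per_g"


class ChemClass(str, Enum):
    POP = "POP"
    ORGANOPHOSPHATE = "organophosphate"
    NEONICOTINOID = "neonicotinoid"
    OTHER = "other"


class ValidationError(ValueError):
    """A record or parameter set violates a model invariant."""


def cas_checksum_ok(cas: str) -> bool:
    """Validate a CAS registry number's check digit.

    CAS numbers have the form ``NN...N-NN-C`` where ``C`` is the weighted sum
    of the preceding digits (rightmost weight 1) modulo 10.  Malformed strings
    return ``False``; callers treat a failure as a warning, not a rejection,
    because compiled literature data occasionally carry provisional codes.
    """
    parts = cas.strip().split("-")
    if len(parts) != 3 or not all(p.isdigit() for p in parts):
        return False
    digits = "".join(parts[:2])
    check = int(parts[2])
    total = sum(int(d) * w for w, d in enumerate(reversed(digits), start=1))
    return total % 10 == check


@dataclass(frozen=True)
class ResidueRecord:
    """One measured pesticide concentration with its sampling metadata.

    ``detected=False`` marks a non-detect; the limit of detection (``lod``,
    same units as ``concentration``; the quantification limit stands in when
    no LOD was reported) then substitutes for the value in the scoring
    formula's indicator arithmetic.
    """

    country: str
    site_id: str
    matrix: Matrix
    chemical_cas: str
    concentration: float
    units: Units
    detected: bool = True
    species: str = ""
    guild: Guild = Guild.NONE
    tissue: Tissue = Tissue.NONE
    lod: float | None = None
    lipid_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError(
                f"negative concentration {self.concentration} for {self.chemical_cas}"
            )
        if not self.detected and self.lod is None:
            raise ValidationError(
                f"non-detect without LOD/LOQ ({self.country}/{self.site_id}/{self.chemical_cas})"
            )
        if self.lod is not None and self.lod <= 0:
            raise ValidationError(f"LOD must be positive, got {self.lod}")
        if self.matrix is Matrix.ANIMAL:
            if not self.species or self.guild is Guild.NONE or self.tissue is Tissue.NONE:
                raise ValidationError(
                    "animal records require species, guild and tissue "
                    f"({self.country}/{self.site_id}/{self.chemical_cas})"
                )
        if self.lipid_fraction is not None and not 0 < self.lipid_fraction <= 1:
            raise ValidationError(
                f"lipid_fraction must be in (0, 1], got {self.lipid_fraction}"
            )


@dataclass(frozen=True)
class ChemicalProfile:
    """Physicochemical and toxicity benchmarks for one pesticide.

    ``rfd`` (oral reference dose, mg·kg⁻¹·day⁻¹) feeds the hazard quotient;
    ``osf`` (oral slope factor, (mg·kg⁻¹·day⁻¹)⁻¹) feeds the ecological
    carcinogenic risk.  Either may be absent when the corresponding metric is
    not computed for the chemical.
    """

    cas: str
    name: str
    log_kow: float | None = None
    log_kaw: float | None = None
    half_life_days: float | None = None
    rfd: float | None = None
    osf: float | None = None
    chem_class: ChemClass = ChemClass.OTHER

    def __post_init__(self) -> None:
        if self.rfd is not None and self.rfd <= 0:
            raise ValidationError(f"RfD must be positive, got {self.rfd} for {self.cas}")
        if self.osf is not None and self.osf <= 0:
            raise ValidationError(f"OSF must be positive, got {self.osf} for {self.cas}")
        if self.half_life_days is not None and self.half_life_days <= 0:
            raise ValidationError(f"half-life must be positive for {self.cas}")


@dataclass(frozen=True)
class SpeciesProfile:
    """Physiological parameters governing a species' exposure algebra.

    ``btf_by_tissue`` maps tissue → biotransformation factor, the steady-state
    tissue concentration per unit daily oral intake ((mg·kg⁻¹)/(mg·day⁻¹)).
    ``tissue_weights`` are the prey-tissue weighting factors w_tissue used
    when predators consume this species; ``diet_fractions`` (f_p, f_h, f_c)
    apply to omnivores and must sum to at most 1.
    """

    species: str
    guild: Guild
    bw_kg: float
    ir_kg_per_day: float
    btf_by_tissue: Mapping[Tissue, float] = field(default_factory=dict)
    lipid_fraction: float | None = None
    tissue_weights: Mapping[Tissue, float] = field(default_factory=dict)
    diet_fractions: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.bw_kg <= 0:
            raise ValidationError(f"body weight must be positive for {self.species}")
        if self.ir_kg_per_day <= 0:
            raise ValidationError(f"intake rate must be positive for {self.species}")
        for t, v in self.btf_by_tissue.items():
            if v <= 0:
                raise ValidationError(f"BTF[{t.value}] must be positive for {self.species}")
        for t, w in self.tissue_weights.items():
            if w < 0:
                raise ValidationError(
                    f"tissue weight[{t.value}] must be non-negative for {self.species}"
                )
        f_p, f_h, f_c = self.diet_fractions
        if any(not 0 <= f <= 1 for f in (f_p, f_h, f_c)):
            raise ValidationError(f"diet fractions must lie in [0, 1] for {self.species}")
        if f_p + f_h + f_c > 1 + 1e-12:
            raise ValidationError(
                f"diet fractions sum to {f_p + f_h + f_c:.4f} > 1 for {self.species}"
            )
        if self.lipid_fraction is not None and not 0 < self.lipid_fraction <= 1:
            raise ValidationError(f"lipid_fraction must be in (0, 1] for {self.species}")


@dataclass(frozen=True)
class StandardizedConcentration:
    """A concentration on the common mg·kg⁻¹ basis, with provenance."""

    value: float
    source_record: ResidueRecord

    def __post_init__(self) -> None:
        if self.value < 0 or not math.isfinite(self.value):
            raise ValidationError(f"standardized value must be finite and >= 0, got {self.value}")


#: ng·g⁻¹ → mg·kg⁻¹ (1 µg/kg = 1e-3 mg/kg)
NG_PER_G_TO_MG_PER_KG = 1e-3


def standardize_concentration(
    record: ResidueRecord, species: SpeciesProfile | None = None
) -> StandardizedConcentration:
    """Convert a residue record to mg·kg⁻¹ (wet weight for animal tissue).

    Soil and plant values in ng·g⁻¹ scale by 10⁻³.  Lipid-normalized animal
    values additionally multiply by the lipid fraction, taken from the record
    when present, else from the species profile.

    Parameters
    ----------
    record
        The measurement to convert.  Non-detects are converted on their LOD.
    species
        Species-level fallback for the lipid fraction.

    Raises
    ------
    ValidationError
        If a lipid-normalized record has no lipid fraction at either level,
        or the units enum is not recognized.
    """
    raw = record.concentration if record.detected else float(record.lod)  # type: ignore[arg-type]
    if record.units in (Units.NG_PER_G, Units.NG_PER_G_DW):
        value = raw * NG_PER_G_TO_MG_PER_KG
    elif record.units is Units.NG_PER_G_LIPID:
        f_lipid = record.lipid_fraction
        if f_lipid is None and species is not None:
            f_lipid = species.lipid_fraction
        if f_lipid is None:
            raise ValidationError(
                f"missing lipid fraction for lipid-normalized record "
                f"({record.country}/{record.site_id}/{record.chemical_cas})"
            )
        value = raw * f_lipid * NG_PER_G_TO_MG_PER_KG
    else:  # pragma: no cover - enum is closed, guards future additions
        raise ValidationError(f"unsupported units: {record.units}")
    return StandardizedConcentration(value=value, source_record=record)
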