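"""Tiered reconstruction of wildlife average daily doses (ADD).

Exposure is reconstructed with the most direct data available, falling back
tier by tier; uncertainty grows from Tier 1 to Tier 3:

Tier 1 — measured tissue (liver) concentrations exist: reverse dosimetry,
    ADD = C_tissue / (BTF_tissue · BW),
    inverting the steady-state biotransformation relation
    C_tissue = BTF_tissue · Intake.
Tier 2 — only measured plant concentrations exist: herbivores ingest plants,
    ADD_herb = C_plant · IR_herb / BW_herb,
    and concentrations propagate up the chain through per-tissue BTFs
    (C_tissue = BTF · IR · C_food), tissue-weighted prey means, and an
    omnivore diet mix (f_p, f_h, f_c).
Tier 3 — only soil data exist: the steady-state leaf model supplies a
    modeled plant concentration (C_plant = C_soil · BAF) which is pushed
    through the identical Tier-2 chain.

All relations are steady-state and linear in the source concentration, so
every downstream ADD is homogeneous of degree 1 in the measured input —
the substance of the trophic-magnification analysis lives entirely in the
BTF · IR products at each link.
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    Guild,
    Matrix,
    ResidueRecord,
    SpeciesProfile,
    Tissue,
    ValidationError,
    standardize_concentration,
)
from .plant import PlantUptakeParams, baf_plant, plant_conc_from_soil

logger = logging.getLogger(__name__)

#: prey tissues entering predator diet means (liver is the biomonitoring
#: tissue and is not consumed preferentially)
PREY_TISSUES = (Tissue.MUSCLE, Tissue.FAT)


@dataclass(frozen=True)
class ExposureEstimate:
    """A reconstructed average daily dose with tier provenance."""

    species: str
    guild: Guild
    chemical_cas: str
    add: float
    tier: int
    country: str = ""
    inputs_used: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.add < 0:
            raise ValidationError(f"ADD must be >= 0, got {self.add}")
        if self.tier not in (1, 2, 3):
            raise ValidationError(f"tier must be 1, 2 or 3, got {self.tier}")


def _check_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v <= 0:
            raise ValidationError(f"{name} must be strictly positive, got {v}")


def add_tier1(
    c_tissue: float,
    btf: float,
    bw: float,
    *,
    species: str = "",
    guild: Guild = Guild.NONE,
    chemical_cas: str = "",
    country: str = "",
) -> ExposureEstimate:
    """Reverse dosimetry: ADD = C_tissue / (BTF · BW).

    ``c_tissue`` in mg·kg⁻¹ wet weight, ``btf`` in (mg·kg⁻¹)/(mg·day⁻¹),
    ``bw`` in kg.
    """
    _check_positive(btf=btf, bw=bw)
    if c_tissue < 0:
        raise ValidationError(f"tissue concentration must be >= 0, got {c_tissue}")
    return ExposureEstimate(
        species=species, guild=guild, chemical_cas=chemical_cas, country=country,
        add=c_tissue / (btf * bw), tier=1,
        inputs_used={"c_tissue": c_tissue, "btf": btf, "bw": bw},
    )


def add_herbivore_tier2(
    c_plant: float,
    ir: float,
    bw: float,
    *,
    species: str = "",
    chemical_cas: str = "",
    country: str = "",
    tier: int = 2,
) -> ExposureEstimate:
    """Plant-ingestion dose: ADD = C_plant · IR / BW."""
    _check_positive(ir=ir, bw=bw)
    if c_plant < 0:
        raise ValidationError(f"plant concentration must be >= 0, got {c_plant}")
    return ExposureEstimate(
        species=species, guild=Guild.HERBIVORE, chemical_cas=chemical_cas,
        country=country, add=c_plant * ir / bw, tier=tier,
        inputs_used={"c_plant": c_plant, "ir": ir, "bw": bw},
    )


def herbivore_tissue_from_plant(
    btf_by_tissue: Mapping[Tissue, float],
    ir: float,
    c_plant: float,
    tissues: Sequence[Tissue] = PREY_TISSUES,
) -> dict[Tissue, float]:
    """Forward model: C_tissue = BTF_tissue · IR · C_plant per prey tissue."""
    _check_positive(ir=ir)
    if c_plant < 0:
        raise ValidationError(f"plant concentration must be >= 0, got {c_plant}")
    out: dict[Tissue, float] = {}
    for t in tissues:
        if t not in btf_by_tissue:
            raise ValidationError(f"missing BTF for tissue '{t.value}'")
        out[t] = btf_by_tissue[t] * ir * c_plant
    return out


def weighted_tissue_mean(
    tissue_conc: Mapping[Tissue, float], weights: Mapping[Tissue, float]
) -> float:
    """Prey-mean concentration: Σ C_t · w_t / Σ w_t over shared tissues."""
    common = [t for t in tissue_conc if t in weights]
    if not common:
        raise ValidationError("no tissue shared between concentrations and weights")
    total_w = sum(weights[t] for t in common)
    if total_w <= 0:
        raise ValidationError("degenerate weights: all tissue weights are zero")
    return sum(tissue_conc[t] * weights[t] for t in common) / total_w


def add_carnivore_tier2(
    c_bar_herb: float,
    ir: float,
    bw: float,
    *,
    species: str = "",
    chemical_cas: str = "",
    country: str = "",
    tier: int = 2,
) -> ExposureEstimate:
    """Predator dose from the herbivore prey mean: ADD = C̄_herb · IR / BW."""
    _check_positive(ir=ir, bw=bw)
    if c_bar_herb < 0:
        raise ValidationError(f"prey mean must be >= 0, got {c_bar_herb}")
    return ExposureEstimate(
        species=species, guild=Guild.CARNIVORE, chemical_cas=chemical_cas,
        country=country, add=c_bar_herb * ir / bw, tier=tier,
        inputs_used={"c_bar_herbivores": c_bar_herb, "ir": ir, "bw": bw},
    )


def carnivore_tissue(
    btf_by_tissue: Mapping[Tissue, float],
    ir: float,
    c_bar_herb: float,
    tissues: Sequence[Tissue] = PREY_TISSUES,
) -> dict[Tissue, float]:
    """Forward model one link up: C_tissue = BTF_tissue · IR · C̄_herb."""
    return herbivore_tissue_from_plant(btf_by_tissue, ir, c_bar_herb, tissues)


def add_omnivore(
    c_plant: float,
    c_bar_herb: float,
    c_bar_carn: float,
    diet: tuple[float, float, float],
    ir: float,
    bw: float,
    *,
    species: str = "",
    chemical_cas: str = "",
    country: str = "",
    tier: int = 2,
) -> ExposureEstimate:
    """Diet-weighted omnivore dose.

    ADD = (f_p · C_plant + f_h · C̄_herb + f_c · C̄_carn) · IR / BW with
    f_p + f_h + f_c ≤ 1.
    """
    _check_positive(ir=ir, bw=bw)
    f_p, f_h, f_c = diet
    if any(not 0 <= f <= 1 for f in diet):
        raise ValidationError(f"diet fractions must lie in [0, 1], got {diet}")
    if f_p + f_h + f_c > 1 + 1e-12:
        raise ValidationError(f"diet fractions sum to {f_p + f_h + f_c:.4f} > 1")
    if min(c_plant, c_bar_herb, c_bar_carn) < 0:
        raise ValidationError("diet compartment concentrations must be >= 0")
    mix = f_p * c_plant + f_h * c_bar_herb + f_c * c_bar_carn
    return ExposureEstimate(
        species=species, guild=Guild.OMNIVORE, chemical_cas=chemical_cas,
        country=country, add=mix * ir / bw, tier=tier,
        inputs_used={
            "c_plant": c_plant, "c_bar_herbivores": c_bar_herb,
            "c_bar_carnivores": c_bar_carn, "f_p": f_p, "f_h": f_h, "f_c": f_c,
            "ir": ir, "bw": bw,
        },
    )


def _renormalized_diet(
    diet: tuple[float, float, float], available: tuple[bool, bool, bool], species: str
) -> tuple[float, float, float]:
    """Shift diet mass off missing compartments, keeping the total fraction."""
    if all(a or f == 0 for f, a in zip(diet, available)):
        return diet
    total = sum(diet)
    kept = [f if a else 0.0 for f, a in zip(diet, available)]
    kept_sum = sum(kept)
    if kept_sum == 0:
        raise ValidationError(f"no diet compartment available for omnivore {species}")
    scale = total / kept_sum
    logger.warning(
        "omnivore %s: renormalizing diet over available compartments %s", species, available
    )
    return tuple(f * scale for f in kept)  # type: ignore[return-value]


def run_foodchain(
    c_plant: float,
    species_profiles: Mapping[str, SpeciesProfile],
    *,
    tier: int,
    chemical_cas: str = "",
    country: str = "",
    extra_inputs: Mapping[str, float] | None = None,
) -> list[ExposureEstimate]:
    """Propagate one plant concentration through every roster species.

    Herbivores feed directly; carnivores feed on the roster-mean herbivore
    prey concentration; omnivores mix all three compartments.  Used for both
    Tier 2 (measured plant) and Tier 3 (modeled plant) — the chain is
    identical, only the plant input and tier tag differ.
    """
    herbs = [p for p in species_profiles.values() if p.guild is Guild.HERBIVORE]
    carns = [p for p in species_profiles.values() if p.guild is Guild.CARNIVORE]
    omnis = [p for p in species_profiles.values() if p.guild is Guild.OMNIVORE]
    extra = dict(extra_inputs or {})

    estimates: list[ExposureEstimate] = []
    for h in herbs:
        est = add_herbivore_tier2(
            c_plant, h.ir_kg_per_day, h.bw_kg,
            species=h.species, chemical_cas=chemical_cas, country=country, tier=tier,
        )
        estimates.append(_with_extra(est, extra))

    prey_means = []
    for h in herbs:
        if h.tissue_weights and all(t in h.btf_by_tissue for t in PREY_TISSUES):
            tissues = herbivore_tissue_from_plant(h.btf_by_tissue, h.ir_kg_per_day, c_plant)
            prey_means.append(weighted_tissue_mean(tissues, h.tissue_weights))
    c_bar_herb = statistics.fmean(prey_means) if prey_means else None

    carn_means = []
    for c in carns:
        if c_bar_herb is None:
            continue
        est = add_carnivore_tier2(
            c_bar_herb, c.ir_kg_per_day, c.bw_kg,
            species=c.species, chemical_cas=chemical_cas, country=country, tier=tier,
        )
        estimates.append(_with_extra(est, extra))
        if c.tissue_weights and all(t in c.btf_by_tissue for t in PREY_TISSUES):
            tissues = carnivore_tissue(c.btf_by_tissue, c.ir_kg_per_day, c_bar_herb)
            carn_means.append(weighted_tissue_mean(tissues, c.tissue_weights))
    c_bar_carn = statistics.fmean(carn_means) if carn_means else None

    for o in omnis:
        diet = _renormalized_diet(
            o.diet_fractions,
            (True, c_bar_herb is not None, c_bar_carn is not None),
            o.species,
        )
        est = add_omnivore(
            c_plant, c_bar_herb or 0.0, c_bar_carn or 0.0, diet,
            o.ir_kg_per_day, o.bw_kg,
            species=o.species, chemical_cas=chemical_cas, country=country, tier=tier,
        )
        estimates.append(_with_extra(est, extra))
    return estimates


def _with_extra(est: ExposureEstimate, extra: Mapping[str, float]) -> ExposureEstimate:
    if not extra:
        return est
    return ExposureEstimate(
        species=est.species, guild=est.guild, chemical_cas=est.chemical_cas,
        add=est.add, tier=est.tier, country=est.country,
        inputs_used={**est.inputs_used, **extra},
    )


def run_tier3_chain(
    c_soil: float,
    uptake_params: PlantUptakeParams,
    species_profiles: Mapping[str, SpeciesProfile],
    *,
    chemical_cas: str = "",
    country: str = "",
) -> list[ExposureEstimate]:
    """Soil → modeled plant → full food chain, all estimates tagged tier 3."""
    baf = baf_plant(uptake_params)
    c_plant_model = plant_conc_from_soil(c_soil, baf)
    return run_foodchain(
        c_plant_model, species_profiles, tier=3,
        chemical_cas=chemical_cas, country=country,
        extra_inputs={"c_soil": c_soil, "baf_plant": baf},
    )


def select_tier(has_tissue: bool, has_plant: bool, has_soil: bool) -> int | None:
    """Most-direct-data rule: tissue → 1, else plant → 2, else soil → 3."""
    if has_tissue:
        return 1
    if has_plant:
        return 2
    if has_soil:
        return 3
    return None


# ---------------------------------------------------------------------------
# dataset-level reconstruction


def _median_standardized(
    records: Sequence[ResidueRecord],
    species_profiles: Mapping[str, SpeciesProfile],
) -> float:
    """Median standardized concentration; non-detects enter at LOD."""
    values = [
        standardize_concentration(
            r, species_profiles.get(r.species)
        ).value
        for r in records
    ]
    return statistics.median(values)


def reconstruct_doses(
    records: Iterable[ResidueRecord],
    species_profiles: Mapping[str, SpeciesProfile],
    plant_params: Mapping[str, PlantUptakeParams] | None = None,
) -> list[ExposureEstimate]:
    """Reconstruct ADDs for every country × chemical with the tier rule.

    Tier selection is per country × guild × chemical: species with liver data
    get Tier-1 reverse dosimetry; guilds without any liver data fall back to
    the measured-plant chain (Tier 2), then to the soil-modeled chain
    (Tier 3, requiring uptake parameters for the chemical).  Multiple records
    for one (country, species/matrix, chemical) collapse to their median
    standardized concentration before entering the equations.
    """
    plant_params = plant_params or {}
    liver: dict[tuple[str, str, str], list[ResidueRecord]] = defaultdict(list)
    plant: dict[tuple[str, str], list[ResidueRecord]] = defaultdict(list)
    soil: dict[tuple[str, str], list[ResidueRecord]] = defaultdict(list)
    for r in records:
        if r.matrix is Matrix.ANIMAL and r.tissue is Tissue.LIVER:
            liver[(r.country, r.species, r.chemical_cas)].append(r)
        elif r.matrix is Matrix.WILD_PLANT:
            plant[(r.country, r.chemical_cas)].append(r)
        elif r.matrix is Matrix.SOIL:
            soil[(r.country, r.chemical_cas)].append(r)

    countries = sorted(
        {k[0] for k in liver} | {k[0] for k in plant} | {k[0] for k in soil}
    )
    chemicals = sorted(
        {k[2] for k in liver} | {k[1] for k in plant} | {k[1] for k in soil}
    )

    estimates: list[ExposureEstimate] = []
    for country in countries:
        for cas in chemicals:
            tier1_species: set[str] = set()
            for (ctry, species, chem), recs in liver.items():
                if ctry != country or chem != cas:
                    continue
                profile = species_profiles.get(species)
                if profile is None or Tissue.LIVER not in profile.btf_by_tissue:
                    logger.warning(
                        "no liver BTF for %s; skipping Tier 1 for %s/%s",
                        species, country, cas,
                    )
                    continue
                c_liver = _median_standardized(recs, species_profiles)
                estimates.append(
                    add_tier1(
                        c_liver, profile.btf_by_tissue[Tissue.LIVER], profile.bw_kg,
                        species=species, guild=profile.guild,
                        chemical_cas=cas, country=country,
                    )
                )
                tier1_species.add(species)

            guilds_covered = {
                species_profiles[s].guild for s in tier1_species if s in species_profiles
            }
            fallback_guilds = {
                p.guild
                for p in species_profiles.values()
                if p.guild not in guilds_covered and p.guild is not Guild.NONE
            }
            if not fallback_guilds:
                continue

            has_plant = (country, cas) in plant
            has_soil = (country, cas) in soil
            tier = select_tier(False, has_plant, has_soil)
            # the chain runs over the full roster (predator links need prey
            # profiles even when the prey guild itself is Tier-1 covered);
            # only estimates for uncovered guilds are kept
            if tier == 2:
                c_plant = _median_standardized(plant[(country, cas)], species_profiles)
                chain = run_foodchain(
                    c_plant, species_profiles, tier=2, chemical_cas=cas, country=country
                )
            elif tier == 3:
                if cas not in plant_params:
                    logger.warning(
                        "no plant-uptake parameters for %s; gap at %s", cas, country
                    )
                    continue
                c_soil = _median_standardized(soil[(country, cas)], species_profiles)
                chain = run_tier3_chain(
                    c_soil, plant_params[cas], species_profiles,
                    chemical_cas=cas, country=country,
                )
            else:
                logger.info("no usable data for %s/%s beyond Tier 1", country, cas)
                continue
            estimates.extend(e for e in chain if e.guild in fallback_guilds)
    return estimates


def estimates_to_frame(estimates: Sequence[ExposureEstimate]) -> pd.DataFrame:
    """Tabulate dose estimates (columns match the `expose` CLI output)."""
    return pd.DataFrame(
        [
            {
                "country": e.country,
                "species": e.species,
                "guild": e.guild.value,
                "chemical_cas": e.chemical_cas,
                "tier": e.tier,
                "add_mg_kg_day": e.add,
                "provenance": ";".join(f"{k}={v:.6g}" for k, v in e.inputs_used.items()),
            }
            for e in estimates
        ]
    )
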