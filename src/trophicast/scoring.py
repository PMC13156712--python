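"""Country-level contamination scores.

The score ``S`` for a country × matrix stratum is a two-level mean of log10
deviations from each pesticide's global central tendency::

    S = (1/M) Σ_m  (1/N_m) Σ_n [ log10(C_eff(n, m)) − log10 C̄_n ]

where ``m`` runs over the country's M sampling sites, ``n`` over the N_m
pesticide measurements at site m, and ``C_eff`` is the measured concentration
for detects or the full detection limit (LOD; LOQ standing in when no LOD was
reported) for non-detects.  ``log10 C̄_n`` is the arithmetic mean of log10
concentrations over all Q global points of that pesticide within the same
matrix stratum, i.e. the log of the global geometric mean.

``S`` is a relative, dimensionless index: S > 0 flags levels above the global
average, S ≤ 0 levels similar to or below it.  It carries no toxicological
meaning.  Because every term is a within-chemical log-ratio, S is invariant
to rescaling any chemical's global concentrations and to site/chemical
ordering.

Strata: soil and wild-plant records score as their own matrices; animal
records score per dietary guild on liver (the biomonitoring tissue), with
baselines computed within each stratum so compartments are never mixed.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
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


class ScoreStratum(str, Enum):
    """A scored compartment: abiotic/producer matrix, or animal guild."""

    SOIL = "soil"
    WILD_PLANT = "wild_plant"
    HERBIVORE = "herbivore"
    CARNIVORE = "carnivore"
    OMNIVORE = "omnivore"


@dataclass(frozen=True)
class GlobalBaseline:
    """Global log10 central tendency of one pesticide within one stratum."""

    chemical_cas: str
    log_mean: float
    q_points: int

    def __post_init__(self) -> None:
        if self.q_points < 1:
            raise ValidationError("baseline requires at least one global point")


@dataclass(frozen=True)
class ScoreResult:
    country: str
    stratum: ScoreStratum
    score: float
    n_sites: int
    n_chemical_terms: int
    per_site_terms: tuple[float, ...]

    @property
    def flag(self) -> str:
        """'above_average' when S > 0, else 'at_or_below_average'."""
        return "above_average" if self.score > 0 else "at_or_below_average"

    @property
    def percent_above(self) -> float:
        """Diagnostic reading of S as a percent excess: (10^S − 1) × 100."""
        return (10.0 ** self.score - 1.0) * 100.0


def stratum_of(record: ResidueRecord) -> ScoreStratum | None:
    """Assign a record to its scoring stratum.

    Animal records contribute through liver only; non-liver tissues return
    ``None`` (they exist for the food-chain equations, not for scoring).
    """
    if record.matrix is Matrix.SOIL:
        return ScoreStratum.SOIL
    if record.matrix is Matrix.WILD_PLANT:
        return ScoreStratum.WILD_PLANT
    if record.tissue is not Tissue.LIVER:
        return None
    return ScoreStratum(record.guild.value)


def effective_concentration(
    record: ResidueRecord, species: SpeciesProfile | None = None
) -> float:
    """Standardized mg·kg⁻¹ value entering the score: C for detects, LOD else.

    The indicator arithmetic C·I(C) + LOD·I(LOD) reduces to this selection
    because the indicators are complementary.
    """
    value = standardize_concentration(record, species).value
    if value <= 0:
        raise ValidationError(
            f"non-positive concentration not log-transformable "
            f"({record.country}/{record.site_id}/{record.chemical_cas})"
        )
    return value


def global_log_mean(
    records: Sequence[ResidueRecord],
    chemical_cas: str,
    species_profiles: Mapping[str, SpeciesProfile] | None = None,
) -> GlobalBaseline:
    """Arithmetic mean of log10 concentrations over all global points.

    Non-detects enter at their LOD, mirroring the site-term substitution so
    that baselines and deviations are computed on the same basis.
    """
    logs = []
    for r in records:
        if r.chemical_cas != chemical_cas:
            continue
        sp = (species_profiles or {}).get(r.species)
        logs.append(math.log10(effective_concentration(r, sp)))
    if not logs:
        raise ValidationError(f"no global points for chemical {chemical_cas}")
    return GlobalBaseline(
        chemical_cas=chemical_cas,
        log_mean=sum(logs) / len(logs),
        q_points=len(logs),
    )


def site_term(
    site_records: Sequence[ResidueRecord],
    baselines: Mapping[str, GlobalBaseline],
    species_profiles: Mapping[str, SpeciesProfile] | None = None,
) -> float:
    """Mean log10 deviation from baseline over the pesticides at one site."""
    if not site_records:
        raise ValidationError("empty site")
    deviations = []
    for r in site_records:
        if r.chemical_cas not in baselines:
            raise ValidationError(f"no global baseline for chemical {r.chemical_cas}")
        sp = (species_profiles or {}).get(r.species)
        c = effective_concentration(r, sp)
        deviations.append(math.log10(c) - baselines[r.chemical_cas].log_mean)
    return sum(deviations) / len(deviations)


def contamination_score(
    country: str,
    stratum: ScoreStratum,
    country_records: Sequence[ResidueRecord],
    baselines: Mapping[str, GlobalBaseline],
    species_profiles: Mapping[str, SpeciesProfile] | None = None,
) -> ScoreResult:
    """Score one country × stratum: mean of site terms over its M sites."""
    if not country_records:
        raise ValidationError(f"no sites for {country}/{stratum.value}")
    by_site: dict[str, list[ResidueRecord]] = defaultdict(list)
    for r in country_records:
        by_site[r.site_id].append(r)
    terms = [
        site_term(recs, baselines, species_profiles) for recs in by_site.values()
    ]
    return ScoreResult(
        country=country,
        stratum=stratum,
        score=sum(terms) / len(terms),
        n_sites=len(terms),
        n_chemical_terms=sum(len(v) for v in by_site.values()),
        per_site_terms=tuple(terms),
    )


def score_dataset(
    records: Iterable[ResidueRecord],
    species_profiles: Mapping[str, SpeciesProfile] | None = None,
) -> list[ScoreResult]:
    """Score every country × stratum present in a residue dataset.

    Baselines are stratified: each chemical's global mean is computed from the
    records of that stratum only, pooled across all countries.
    """
    by_stratum: dict[ScoreStratum, list[ResidueRecord]] = defaultdict(list)
    for r in records:
        s = stratum_of(r)
        if s is not None:
            by_stratum[s].append(r)

    results: list[ScoreResult] = []
    for stratum, recs in by_stratum.items():
        baselines = {
            cas: global_log_mean(recs, cas, species_profiles)
            for cas in sorted({r.chemical_cas for r in recs})
        }
        by_country: dict[str, list[ResidueRecord]] = defaultdict(list)
        for r in recs:
            by_country[r.country].append(r)
        for country in sorted(by_country):
            results.append(
                contamination_score(
                    country, stratum, by_country[country], baselines, species_profiles
                )
            )
    return results


def scores_to_frame(results: Sequence[ScoreResult]) -> pd.DataFrame:
    """Tabulate score results (one row per country × stratum)."""
    return pd.DataFrame(
        [
            {
                "country": r.country,
                "matrix": r.stratum.value,
                "score": r.score,
                "n_sites": r.n_sites,
                "flag": r.flag,
            }
            for r in results
        ]
    )
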