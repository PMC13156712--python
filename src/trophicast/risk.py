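"""Hazard-quotient and ecological-carcinogenic-risk characterization.

Two screening metrics per dose estimate:

    HQ  = ADD / RfD        (non-carcinogenic; HQ > 1 flags potential hazard)
    ECR = ADD × OSF        (lifetime carcinogenic probability)

ECR fences follow the usual screening convention: ≤ 1e-6 negligible,
> 1e-4 unacceptable, intermediate in between.  Boundaries belong to the
lower category (the flags use strict ">").  Both metrics are reported on
log10 scale alongside the natural scale; log10(0) is carried as -inf in
memory and exported as an empty cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import ChemicalProfile, ValidationError
from .exposure import ExposureEstimate

ECR_NEGLIGIBLE = 1e-6
ECR_UNACCEPTABLE = 1e-4
#: log10 fence for elevated carcinogenic risk (log10 of the 1e-4 threshold)
LOG_ECR_ELEVATED = -4.0


class HQFlag(str, Enum):
    NEGLIGIBLE = "negligible"
    POTENTIAL = "potential"


class ECRFlag(str, Enum):
    NEGLIGIBLE = "negligible"
    INTERMEDIATE = "intermediate"
    UNACCEPTABLE = "unacceptable"


def _log10_or_neg_inf(x: float) -> float:
    return math.log10(x) if x > 0 else -math.inf


@dataclass(frozen=True)
class RiskResult:
    """HQ and/or ECR for one dose estimate (None where no benchmark exists)."""

    species: str
    guild: str
    chemical_cas: str
    country: str
    tier: int
    add: float
    hq: float | None = None
    ecr: float | None = None

    @property
    def log_hq(self) -> float | None:
        return None if self.hq is None else _log10_or_neg_inf(self.hq)

    @property
    def log_ecr(self) -> float | None:
        return None if self.ecr is None else _log10_or_neg_inf(self.ecr)

    @property
    def hq_flag(self) -> HQFlag | None:
        if self.hq is None:
            return None
        return HQFlag.POTENTIAL if self.hq > 1.0 else HQFlag.NEGLIGIBLE

    @property
    def ecr_flag(self) -> ECRFlag | None:
        if self.ecr is None:
            return None
        if self.ecr > ECR_UNACCEPTABLE:
            return ECRFlag.UNACCEPTABLE
        if self.ecr > ECR_NEGLIGIBLE:
            return ECRFlag.INTERMEDIATE
        return ECRFlag.NEGLIGIBLE


def hazard_quotient(add: float, rfd: float) -> float:
    """HQ = ADD / RfD (both mg·kg⁻¹·day⁻¹; dimensionless ratio)."""
    if rfd <= 0:
        raise ValidationError(f"RfD must be strictly positive, got {rfd}")
    if add < 0:
        raise ValidationError(f"ADD must be >= 0, got {add}")
    return add / rfd


def carcinogenic_risk(add: float, osf: float) -> float:
    """ECR = ADD × OSF (dimensionless lifetime probability)."""
    if osf <= 0:
        raise ValidationError(f"OSF must be strictly positive, got {osf}")
    if add < 0:
        raise ValidationError(f"ADD must be >= 0, got {add}")
    return add * osf


def characterize(
    estimates: Iterable[ExposureEstimate],
    chemicals: Mapping[str, ChemicalProfile],
) -> list[RiskResult]:
    """Attach HQ/ECR to every estimate whose chemical has benchmarks.

    Estimates for chemicals with neither an RfD nor an OSF are skipped.
    """
    results: list[RiskResult] = []
    for e in estimates:
        profile = chemicals.get(e.chemical_cas)
        if profile is None or (profile.rfd is None and profile.osf is None):
            continue
        results.append(
            RiskResult(
                species=e.species,
                guild=e.guild.value,
                chemical_cas=e.chemical_cas,
                country=e.country,
                tier=e.tier,
                add=e.add,
                hq=None if profile.rfd is None else hazard_quotient(e.add, profile.rfd),
                ecr=None if profile.osf is None else carcinogenic_risk(e.add, profile.osf),
            )
        )
    return results


def risks_to_frame(results: Sequence[RiskResult]) -> pd.DataFrame:
    """Tabulate risk results; -inf logs become empty cells on export."""
    rows = []
    for r in results:
        rows.append(
            {
                "country": r.country,
                "species": r.species,
                "guild": r.guild,
                "chemical_cas": r.chemical_cas,
                "tier": r.tier,
                "add_mg_kg_day": r.add,
                "hq": r.hq,
                "ecr": r.ecr,
                "log_hq": None if r.log_hq in (None, -math.inf) else r.log_hq,
                "log_ecr": None if r.log_ecr in (None, -math.inf) else r.log_ecr,
                "hq_flag": None if r.hq_flag is None else r.hq_flag.value,
                "ecr_flag": None if r.ecr_flag is None else r.ecr_flag.value,
            }
        )
    return pd.DataFrame(rows)


def summarize_risk(
    results: Sequence[RiskResult],
    group_by: Sequence[str] = ("species", "chemical_cas"),
) -> pd.DataFrame:
    """Group-median log10 HQ / log10 ECR table.

    ``group_by`` columns come from the tabulated results (e.g.
    ``("species", "chemical_cas")`` or ``("country", "guild")``).  Groups with
    no finite values for a metric report NaN there; risk flags follow the
    medians (log HQ > 0, log ECR > -4).
    """
    df = risks_to_frame(results)
    if df.empty:
        raise ValidationError("no risk results to summarize")
    grouped = (
        df.groupby(list(group_by), dropna=False)[["log_hq", "log_ecr"]]
        .median()
        .reset_index()
        .rename(columns={"log_hq": "median_log_hq", "log_ecr": "median_log_ecr"})
    )
    grouped["hq_risk"] = grouped["median_log_hq"] > 0.0
    grouped["ecr_risk"] = grouped["median_log_ecr"] > LOG_ECR_ELEVATED
    return grouped
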