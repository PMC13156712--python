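"""Country-level aggregation, property–risk regressions, and exports.

The regression stage asks whether screening risk tracks intrinsic chemical
properties: per-chemical median log10 HQ (pooled across species) is
regressed by ordinary least squares on log Kow, log Kaw and log10 half-life
separately.  The export stage writes long-format country tables suitable for
joining onto any administrative boundary layer; countries without data get
explicit NA rows so map gaps are visible rather than silent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import ChemicalProfile, ValidationError
from .risk import RiskResult, risks_to_frame
from .scoring import ScoreResult, scores_to_frame

logger = logging.getLogger(__name__)

PREDICTORS = ("log_kow", "log_kaw", "log_half_life")


@dataclass(frozen=True)
class RegressionSummary:
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValidationError(f"R² out of range: {self.r_squared}")
        if self.n < 3:
            raise ValidationError("regression needs at least 3 chemicals")


def chemical_median_log_hq(results: Sequence[RiskResult]) -> pd.Series:
    """Per-chemical median log10 HQ pooled across species and countries."""
    df = risks_to_frame(results)
    df = df.dropna(subset=["log_hq"])
    if df.empty:
        raise ValidationError("no finite log HQ values")
    return df.groupby("chemical_cas")["log_hq"].median()


def property_regression(
    median_log_hq: Mapping[str, float] | pd.Series,
    chemicals: Mapping[str, ChemicalProfile],
) -> list[RegressionSummary]:
    """OLS of median log HQ on each physicochemical predictor separately.

    Half-life enters as log10(half-life in days).  Chemicals missing either
    the response or a predictor drop from that predictor's fit; fewer than
    three remaining points is an error for that predictor.
    """
    response = dict(median_log_hq)
    summaries: list[RegressionSummary] = []
    for predictor in PREDICTORS:
        xs, ys = [], []
        for cas, y in response.items():
            profile = chemicals.get(cas)
            if profile is None or not math.isfinite(y):
                continue
            if predictor == "log_kow":
                x = profile.log_kow
            elif predictor == "log_kaw":
                x = profile.log_kaw
            else:
                x = (
                    math.log10(profile.half_life_days)
                    if profile.half_life_days is not None
                    else None
                )
            if x is None:
                continue
            xs.append(x)
            ys.append(y)
        if len(xs) < 3:
            raise ValidationError(
                f"insufficient data for predictor {predictor}: {len(xs)} points"
            )
        if np.ptp(xs) == 0:
            logger.warning("predictor %s is constant; skipping its regression", predictor)
            continue
        X = sm.add_constant(np.asarray(xs))
        fit = sm.OLS(np.asarray(ys), X).fit()
        summaries.append(
            RegressionSummary(
                predictor=predictor,
                slope=float(fit.params[1]),
                intercept=float(fit.params[0]),
                r_squared=float(fit.rsquared),
                n=len(xs),
            )
        )
    return summaries


def regressions_to_frame(summaries: Sequence[RegressionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "predictor": s.predictor,
                "slope": s.slope,
                "intercept": s.intercept,
                "r_squared": s.r_squared,
                "n": s.n,
            }
            for s in summaries
        ]
    )


def export_country_layers(
    scores: Sequence[ScoreResult],
    risks: Sequence[RiskResult],
    outdir: str | Path,
    all_countries: Iterable[str] | None = None,
) -> Path:
    """Write a long-format (country, layer, metric, value) CSV.

    One layer per score stratum plus per-guild median log HQ / log ECR
    layers.  ``all_countries`` extends the key set so data gaps appear as
    explicit NA rows; a country never emits both an NA and a numeric row for
    the same layer × metric.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows: list[dict[str, object]] = []
    sdf = scores_to_frame(scores) if scores else pd.DataFrame(
        columns=["country", "matrix", "score"]
    )
    for _, r in sdf.iterrows():
        rows.append(
            {
                "country": r["country"], "layer": f"score_{r['matrix']}",
                "metric": "contamination_score", "value": r["score"],
            }
        )
    rdf = risks_to_frame(risks) if risks else pd.DataFrame(
        columns=["country", "guild", "log_hq", "log_ecr"]
    )
    if not rdf.empty:
        med = rdf.groupby(["country", "guild"])[["log_hq", "log_ecr"]].median()
        for (country, guild), vals in med.iterrows():
            for metric in ("log_hq", "log_ecr"):
                if pd.notna(vals[metric]):
                    rows.append(
                        {
                            "country": country, "layer": f"risk_{guild}",
                            "metric": metric, "value": vals[metric],
                        }
                    )

    df = pd.DataFrame(rows, columns=["country", "layer", "metric", "value"])
    layers = sorted(set(zip(df["layer"], df["metric"]))) if not df.empty else []
    countries = set(df["country"]) | set(all_countries or [])
    na_rows = [
        {"country": c, "layer": layer, "metric": metric, "value": math.nan}
        for c in sorted(countries)
        for layer, metric in layers
        if df[(df["country"] == c) & (df["layer"] == layer) & (df["metric"] == metric)].empty
    ]
    na_df = pd.DataFrame(na_rows, columns=["country", "layer", "metric", "value"])
    frames = [f for f in (df, na_df) if not f.empty]
    out = pd.concat(frames, ignore_index=True) if frames else df
    out = out.sort_values(["layer", "metric", "country"]).reset_index(drop=True)
    path = outdir / "country_layers.csv"
    out.to_csv(path, index=False)
    return path
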