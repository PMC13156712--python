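"""Steady-state soil → herbaceous-leaf transfer (Tier-3 plant model).

A single well-mixed leaf compartment at steady state: transpiration-driven
uptake from soil pore water balances air-side exchange and total in-leaf
loss (photodegradation, metabolism, growth dilution).  The bioaccumulation
factor — the dimensionless ratio of leaf to soil concentration — is

    BAF = Q · (1/k_d) / (A_LH · g · 1000 / K_LA + λ · M_LH)

with Q the per-leaf transpiration rate (a function of air temperature and
relative humidity, supplied precomputed or via a user hook), k_d the
soil–water distribution coefficient, A_LH the leaf surface area, g the leaf
vapor conductance, K_LA the leaf–air distribution coefficient, λ the total
first-order in-leaf loss rate (day⁻¹) and M_LH the single-leaf mass.  The
literal 1000 is a unit-harmonization factor of the model as published;
parameters must be supplied in one consistent unit system with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .core import ValidationError

#: unit-harmonization constant in the air-side conductance term
AIR_SIDE_UNIT_FACTOR = 1000.0


@dataclass(frozen=True)
class PlantUptakeParams:
    """Parameters of the steady-state leaf uptake model.

    ``q_transpiration`` may be given directly, or computed from
    (``t_air``, ``rh_air``) by passing ``transpiration_fn`` to
    :func:`resolve_transpiration`.
    """

    q_transpiration: float
    kd: float
    alh: float
    g: float
    kla: float
    lambda_loss: float
    mlh: float
    t_air: float = 20.0
    rh_air: float = 0.5

    def __post_init__(self) -> None:
        positive = {
            "q_transpiration": self.q_transpiration,
            "kd": self.kd,
            "alh": self.alh,
            "g": self.g,
            "kla": self.kla,
            "mlh": self.mlh,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {v}")
        if self.lambda_loss < 0:
            raise ValidationError(f"lambda_loss must be >= 0, got {self.lambda_loss}")
        if not 0 <= self.rh_air <= 1:
            raise ValidationError(f"rh_air must be in [0, 1], got {self.rh_air}")


def resolve_transpiration(
    params: PlantUptakeParams,
    transpiration_fn: Callable[[float, float], float] | None = None,
) -> PlantUptakeParams:
    """Replace ``q_transpiration`` using a user-supplied Q(T_air, RH_air).

    The functional form of the transpiration model is site- and
    parameterization-specific, so it is injected rather than fixed here.
    """
    if transpiration_fn is None:
        return params
    q = transpiration_fn(params.t_air, params.rh_air)
    if q <= 0:
        raise ValidationError(f"transpiration function returned non-positive Q: {q}")
    return PlantUptakeParams(
        q_transpiration=q, kd=params.kd, alh=params.alh, g=params.g,
        kla=params.kla, lambda_loss=params.lambda_loss, mlh=params.mlh,
        t_air=params.t_air, rh_air=params.rh_air,
    )


def baf_plant(params: PlantUptakeParams) -> float:
    """Leaf bioaccumulation factor (dimensionless plant/soil ratio).

    Strictly increasing in Q and K_LA; strictly decreasing in k_d, A_LH, g,
    λ and M_LH.  λ → ∞ drives BAF → 0 (loss dominates accumulation).
    """
    denom = params.alh * params.g * AIR_SIDE_UNIT_FACTOR / params.kla \
        + params.lambda_loss * params.mlh
    if denom <= 0:
        raise ValidationError("degenerate leaf parameters: zero loss and exchange terms")
    return params.q_transpiration * (1.0 / params.kd) / denom


def plant_conc_from_soil(c_soil: float, baf: float) -> float:
    """Modeled leaf concentration (mg·kg⁻¹) from soil concentration and BAF."""
    if c_soil < 0:
        raise ValidationError(f"soil concentration must be >= 0, got {c_soil}")
    if baf < 0:
        raise ValidationError(f"BAF must be >= 0, got {baf}")
    return c_soil * baf


def kd_from_koc(f_oc: float, koc: float) -> float:
    """Optional helper: soil–water distribution coefficient as f_oc · K_oc.

    Off the default path — use only when no measured chemical-specific k_d is
    available, with a K_oc from an external log Kow regression.
    """
    if f_oc <= 0 or koc <= 0:
        raise ValidationError("f_oc and koc must be strictly positive")
    return f_oc * koc
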