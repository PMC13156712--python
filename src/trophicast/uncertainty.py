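"""Probabilistic risk analysis: Monte Carlo, Pearson screening, Sobol indices.

Every uncertain input is modeled as a log-normal distribution, matching the
right-skew typical of environmental concentration and physiological data.
Distributions are specified by their arithmetic (natural-scale) mean and
coefficient of variation and moment-matched on the log scale:

    sigma² = ln(1 + cv²),   mu = ln(mean) − sigma²/2

so that the sampled arithmetic mean converges to ``mean``.  Where no
variability is reported, a fallback cv of 0.30 applies.

Hazard-quotient uncertainty propagates the full deterministic tier + HQ
pipeline through 10,000 draws by default.  Variance attribution uses Pearson
correlation screening (|ρ| ≥ 0.4 flags an influential parameter) and
variance-based Sobol decomposition: first-order indices S1 (direct effects)
and total-effect indices ST (direct plus interactions), with ST − S1
measuring interaction strength.  Estimation uses Sobol'-sequence paired
matrices with the Saltelli-2010 first-order and Jansen total-order
estimators; 95% confidence intervals come from bootstrap resampling of
design rows.  The quasi-random design requires power-of-two base sample
sizes, so requested iteration counts round up to the next power of two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import ValidationError

DEFAULT_CV = 0.30


@dataclass(frozen=True)
class LognormalSpec:
    """Log-normal input distribution, moment-matched from (mean, cv)."""

    mean: float
    cv: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValidationError(f"mean must be strictly positive, got {self.mean}")
        if self.cv <= 0:
            raise ValidationError(f"cv must be strictly positive, got {self.cv}")

    @property
    def sigma(self) -> float:
        """Log-scale standard deviation: sqrt(ln(1 + cv²))."""
        return math.sqrt(math.log1p(self.cv**2))

    @property
    def mu(self) -> float:
        """Log-scale location: ln(mean) − sigma²/2."""
        return math.log(self.mean) - 0.5 * self.sigma**2

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def frozen(self) -> stats.rv_continuous:
        """The equivalent frozen scipy distribution."""
        return stats.lognorm(s=self.sigma, scale=math.exp(self.mu))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(mean=self.mu, sigma=self.sigma, size=n)


def lognormal_from_mean_cv(mean: float, cv: float) -> LognormalSpec:
    """Build a moment-matched log-normal spec from arithmetic mean and cv."""
    return LognormalSpec(mean=mean, cv=cv)


@dataclass(frozen=True)
class MCConfig:
    """Simulation settings; the seed is recorded in every output."""

    n_iterations: int = 10_000
    seed: int = 0
    cv_default: float = DEFAULT_CV
    bootstrap_reps: int = 1_000

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")


@dataclass(frozen=True)
class MCSummary:
    """Summary of a Monte-Carlo HQ distribution."""

    median: float
    mean: float
    p_exceed_unity: float
    log10_grid: np.ndarray
    log10_density: np.ndarray | None
    n_iterations: int
    seed: int
    samples: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _draw_inputs(
    specs: Mapping[str, LognormalSpec | float],
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    draws: dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        if isinstance(spec, LognormalSpec):
            draws[name] = spec.sample(rng, n)
        else:
            value = float(spec)
            if value <= 0:
                raise ValidationError(f"fixed parameter {name} must be positive")
            draws[name] = np.full(n, value)
    return draws


def monte_carlo_hq(
    model: Callable[[Mapping[str, np.ndarray]], np.ndarray],
    specs: Mapping[str, LognormalSpec | float],
    config: MCConfig,
) -> MCSummary:
    """Propagate input distributions through a deterministic HQ model.

    ``model`` receives a name → draws mapping (each an array of length
    ``n_iterations``) and returns the HQ per draw.  Fixed (certain) inputs
    are passed as plain floats.  Returns summary statistics plus a kernel
    density estimate of the log10 HQ distribution (None when the output is
    degenerate, e.g. all inputs fixed).
    """
    rng = np.random.default_rng(config.seed)
    draws = _draw_inputs(specs, config.n_iterations, rng)
    hq = np.asarray(model(draws), dtype=float)
    if hq.shape != (config.n_iterations,):
        raise ValidationError(
            f"model returned shape {hq.shape}, expected ({config.n_iterations},)"
        )
    if np.any(hq <= 0) or not np.all(np.isfinite(hq)):
        raise ValidationError("model produced non-positive or non-finite HQ values")

    log_hq = np.log10(hq)
    grid = np.linspace(log_hq.min() - 0.5, log_hq.max() + 0.5, 256)
    if np.ptp(log_hq) > 1e-12:
        density = stats.gaussian_kde(log_hq)(grid)
    else:
        density = None
    return MCSummary(
        median=float(np.median(hq)),
        mean=float(np.mean(hq)),
        p_exceed_unity=float(np.mean(hq > 1.0)),
        log10_grid=grid,
        log10_density=density,
        n_iterations=config.n_iterations,
        seed=config.seed,
        samples=hq,
    )


@dataclass(frozen=True)
class PearsonScreenResult:
    parameter: str
    rho: float
    flagged: bool
    note: str = ""


PEARSON_FLAG_THRESHOLD = 0.4


def pearson_screen(
    samples: Mapping[str, np.ndarray],
    outputs: np.ndarray,
    threshold: float = PEARSON_FLAG_THRESHOLD,
) -> list[PearsonScreenResult]:
    """Flag parameters with |Pearson ρ| ≥ threshold against the output.

    Constant input columns have no defined correlation; they are reported
    unflagged with a note rather than erroring, since fixed parameters are a
    legitimate part of a screening design.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.size < 3:
        raise ValidationError("need at least 3 samples for correlation screening")
    results: list[PearsonScreenResult] = []
    for name, col in samples.items():
        col = np.asarray(col, dtype=float)
        if col.shape != outputs.shape:
            raise ValidationError(f"parameter {name}: shape mismatch with outputs")
        if np.ptp(col) < 1e-15:
            results.append(
                PearsonScreenResult(name, math.nan, False, "constant column; rho undefined")
            )
            continue
        rho = stats.pearsonr(col, outputs).statistic
        results.append(PearsonScreenResult(name, float(rho), bool(abs(rho) >= threshold)))
    return results


@dataclass(frozen=True)
class SobolResult:
    """First-order and total-effect variance shares for one parameter.

    Monte-Carlo estimates may fall slightly outside [0, 1] (or below S1);
    they are stored unclamped.
    """

    parameter: str
    s1: float
    st: float
    s1_ci: tuple[float, float]
    st_ci: tuple[float, float]

    @property
    def interaction(self) -> float:
        return self.st - self.s1


def _next_pow2(n: int) -> int:
    return 1 << max(0, (n - 1).bit_length())


def _sobol_estimates(
    f_a: np.ndarray, f_b: np.ndarray, f_ab: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Saltelli-2010 first-order and Jansen total-order estimators.

    ``f_a``/``f_b`` are the outputs on the two base matrices (length n),
    ``f_ab`` the (d, n) outputs on A with column i replaced from B.
    """
    var = np.var(np.concatenate([f_a, f_b]))
    s1 = np.mean(f_b * (f_ab - f_a), axis=1) / var
    st = 0.5 * np.mean((f_a - f_ab) ** 2, axis=1) / var
    return s1, st


def sobol_sensitivity(
    model: Callable[[np.ndarray], np.ndarray],
    specs: Mapping[str, LognormalSpec | stats.distributions.rv_frozen],
    config: MCConfig,
) -> list[SobolResult]:
    """Sobol S1/ST per parameter with bootstrap 95% CIs.

    ``model`` maps a parameter matrix of shape ``(d, n)`` (rows ordered as
    ``specs``) to a vector of n scalar outputs; it must be deterministic.
    Sampling uses a scrambled Sobol' sequence over 2d dimensions split into
    the paired base matrices A and B; the base sample size is
    ``n_iterations`` rounded up to a power of two, for ``n_base × (d + 2)``
    model evaluations in total.  Confidence intervals are percentile
    bootstrap over resampled design rows.
    """
    names = list(specs.keys())
    dists = [
        s.frozen() if isinstance(s, LognormalSpec) else s for s in specs.values()
    ]
    d = len(dists)
    n_base = _next_pow2(config.n_iterations)
    rng = np.random.default_rng(config.seed)

    u = stats.qmc.Sobol(d=2 * d, scramble=True, seed=rng).random(n_base)
    # clip away exact 0/1 so unbounded ppf stays finite
    eps = np.finfo(float).eps
    u = np.clip(u, eps, 1 - eps)
    a = np.vstack([dists[i].ppf(u[:, i]) for i in range(d)])
    b = np.vstack([dists[i].ppf(u[:, d + i]) for i in range(d)])

    f_a = np.asarray(model(a), dtype=float)
    f_b = np.asarray(model(b), dtype=float)
    f_ab = np.empty((d, n_base))
    for i in range(d):
        ab = a.copy()
        ab[i] = b[i]
        f_ab[i] = np.asarray(model(ab), dtype=float)

    if float(np.var(np.concatenate([f_a, f_b]))) < 1e-30:
        raise ValidationError("variance too small for decomposition")

    s1, st = _sobol_estimates(f_a, f_b, f_ab)

    boot_s1 = np.empty((config.bootstrap_reps, d))
    boot_st = np.empty((config.bootstrap_reps, d))
    for k in range(config.bootstrap_reps):
        idx = rng.integers(0, n_base, n_base)
        boot_s1[k], boot_st[k] = _sobol_estimates(f_a[idx], f_b[idx], f_ab[:, idx])
    s1_lo, s1_hi = np.percentile(boot_s1, [2.5, 97.5], axis=0)
    st_lo, st_hi = np.percentile(boot_st, [2.5, 97.5], axis=0)

    return [
        SobolResult(
            parameter=names[i],
            s1=float(s1[i]),
            st=float(st[i]),
            s1_ci=(float(s1_lo[i]), float(s1_hi[i])),
            st_ci=(float(st_lo[i]), float(st_hi[i])),
        )
        for i in range(d)
    ]


def sobol_to_frame(results: Sequence[SobolResult]):
    """Tabulate Sobol results."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "s1": r.s1,
                "st": r.st,
                "s1_ci_low": r.s1_ci[0],
                "s1_ci_high": r.s1_ci[1],
                "st_ci_low": r.st_ci[0],
                "st_ci_high": r.st_ci[1],
                "interaction": r.interaction,
            }
            for r in results
        ]
    )
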