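"""Synthetic plate-reader data with known ground truth.

Every analysis stage can be exercised without measured data: noisy
absorbance progress curves are generated from the cascade simulator plus
Beer-Lambert conversion and additive Gaussian read noise (default sigma
0.002 AU at 60 s sampling, the cadence of a kinetic plate-reader run);
Michaelis-Menten titrations come from the rate law plus multiplicative
noise; and closed-form lag curves

    P(t) = v_ss * (t - tau * (1 - exp(-t/tau)))

provide progress curves with an exactly known transient time (tau = 0
degenerates to the straight line v_ss * t, the strong-channeling limit).
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field

from .cascade import AssayConditions, CascadeSpec, SimResult, mm_rate, simulate
from .enzymes import MMParams
from .progress import ProgressCurve, RateDataset

__all__ = ["NoiseModel", "gen_progress_curve", "gen_mm_dataset", "gen_lag_curve"]


class NoiseModel(BaseModel):
    """Additive absorbance read noise and sampling cadence."""

    sigma_abs: float = Field(ge=0, default=0.002)  # AU
    sample_dt: float = Field(gt=0, default=60.0)  # s
    seed: int = 0


def gen_progress_curve(
    spec: CascadeSpec,
    conditions: AssayConditions,
    enzyme_concs: dict[str, float],
    noise: NoiseModel | None = None,
    context: str = "free",
) -> tuple[ProgressCurve, SimResult]:
    """Simulate a cascade and emit its monitored species as a noisy
    absorbance trace, returning the noiseless ground truth alongside."""
    noise = noise or NoiseModel()
    cond = conditions.model_copy(update={"sample_dt": noise.sample_dt})
    truth = simulate(spec, cond, enzyme_concs, context=context)
    rng = np.random.default_rng(noise.seed)
    absorbance = (
        truth.monitored() * 1e-6 * cond.epsilon_nadh * cond.path_length_cm
        + rng.normal(0.0, noise.sigma_abs, size=truth.time.size)
    )
    curve = ProgressCurve(truth.time.copy(), absorbance, "absorbance",
                          label=f"{spec.name}:{context}")
    return curve, truth


def gen_mm_dataset(
    params: MMParams,
    enzyme_conc: float,
    substrate_levels: np.ndarray | None = None,
    reps: int = 3,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> RateDataset:
    """Initial-rate titration from the MM law with multiplicative noise.

    Default substrate levels span 0.2-5x KM (8 points, log-spaced); each
    level is measured ``reps`` times (triplicate by default) and the
    replicate mean and spread are returned.
    """
    if substrate_levels is None:
        substrate_levels = np.geomspace(0.2 * params.km, 5.0 * params.km, 8)
    substrate_levels = np.asarray(substrate_levels, dtype=float)
    if substrate_levels.size < 4:
        raise ValueError("need at least 4 substrate levels")
    rng = np.random.default_rng(seed)
    true = np.array([mm_rate(params, enzyme_conc, s) for s in substrate_levels])
    draws = true[:, None] * (1.0 + noise_frac * rng.standard_normal((true.size, reps)))
    rates = draws.mean(axis=1)
    spread = draws.std(axis=1, ddof=1) if reps > 1 else np.zeros_like(rates)
    return RateDataset(substrate_concs=substrate_levels, initial_rates=rates,
                       rate_stderr=spread / np.sqrt(reps) if reps > 1 else None)


def gen_lag_curve(
    v_ss: float,
    tau: float,
    t_end: float,
    noise: NoiseModel | None = None,
    epsilon: float = 6220.0,
    path_length_cm: float = 1.0,
) -> ProgressCurve:
    """Closed-form lag curve P(t) = v_ss*(t - tau*(1 - exp(-t/tau))), in uM.

    The late-time asymptote v_ss*(t - tau) crosses zero at exactly t = tau.
    Absorbance-scale noise (sigma_abs, AU) is converted to concentration
    through the Beer-Lambert factor before being added.
    """
    if v_ss <= 0:
        raise ValueError("v_ss must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    noise = noise or NoiseModel()
    t = np.arange(0.0, t_end + noise.sample_dt / 2, noise.sample_dt)
    if tau == 0:
        p = v_ss * t
    else:
        p = v_ss * (t - tau * (1.0 - np.exp(-t / tau)))
    if noise.sigma_abs > 0:
        rng = np.random.default_rng(noise.seed)
        sigma_uM = noise.sigma_abs / (epsilon * path_length_cm) * 1e6
        p = p + rng.normal(0.0, sigma_uM, size=t.size)
    return ProgressCurve(t, p, "concentration", label=f"lag(tau={tau:g})")
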