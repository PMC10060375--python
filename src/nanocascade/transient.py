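"""Transient (lag) time of sequential enzyme cascades.

A sequential Michaelis-Menten cascade approaches its steady-state product
flux only after each intermediate pool has filled. For a cascade with N
intermediate-consuming steps the transient time is

    tau = sum_j KM_j / (V_j - v0),

where KM_j and V_j are the Michaelis constant and maximal velocity of the
j-th downstream step and v0 is the first enzyme's velocity at the assay
substrate concentration. Empirically, tau is the x-intercept of the
late-time linear portion of a progress curve; in the strong channeling
limit tau -> 0.

This module computes tau both ways and evaluates the diffusion-limited
regime criterion: encounter rates scale as min([E]^(2/3), [I]^(2/3)) * D,
so channeling is observable when the catalytic rate exceeds that scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cascade import CascadeSpec, mm_rate
from .progress import ProgressCurve

__all__ = [
    "TransientEstimate",
    "RegimeReport",
    "LinearRegionPolicy",
    "NoLinearRegionError",
    "tau_analytic",
    "detect_linear_region",
    "tau_empirical",
    "channeling_regime",
]

#: molecules per um^3 at 1 uM
_N_PER_UM3_PER_UM = 602.214


class NoLinearRegionError(RuntimeError):
    """No window of the curve satisfies the linearity policy."""


@dataclass
class TransientEstimate:
    """Empirical transient time from the linear asymptote of a curve."""

    tau: float  # s
    tau_stderr: float  # s
    v_ss: float  # steady-state slope, uM/s
    window: tuple[float, float]  # (t_start, t_end) of the fitted region, s


@dataclass
class RegimeReport:
    """Diffusion-limited-regime evaluation for one enzyme/intermediate pair."""

    e_conc: float  # uM
    i_conc: float  # uM
    diffusion_const: float  # um^2/s
    encounter_scale: float  # 1/s, min([E],[I])^(2/3) * D after unit conversion
    catalytic_scale: float  # 1/s (kcat)
    ratio: float  # catalytic / encounter (dimensionless)
    channeling_potential: bool


@dataclass
class LinearRegionPolicy:
    """Maximal-slope linear-window rule.

    Windows spanning at least ``min_frac`` of the curve with linear-fit
    R^2 >= ``r2_min`` are candidates; the steepest wins, earliest start on
    ties. ``curvature_max`` caps the fraction of a window's rise
    attributable to the quadratic term of a local parabola fit - short
    stretches of a smoothly accelerating curve can look locally straight by
    R^2 alone, and this gate is what makes a lag curve that never reaches
    steady state report "no linear region".
    """

    r2_min: float = 0.995
    min_frac: float = 0.20
    length_fracs: tuple[float, ...] = (0.20, 0.25, 0.30, 0.40, 0.50, 0.60, 0.75)
    curvature_max: float = 0.02


def tau_analytic(
    spec: CascadeSpec,
    enzyme_concs: dict[str, float],
    substrate_conc: float,
    context: str = "free",
) -> tuple[list[tuple[str, float]], float, float]:
    """Analytic per-step transient times and their sum.

    Returns ``(per_step, tau_total, v0)`` where ``per_step`` is a list of
    (enzyme abbreviation, tau_j) over the intermediate-consuming steps.
    A step whose Vmax does not exceed v0 cannot reach steady state; its
    tau_j is reported as ``inf`` (and so is the total).
    """
    first = spec.steps[0]
    p0 = first.enzyme.params(context)
    site_conc0 = first.enzyme.subunits * enzyme_concs[first.enzyme.abbreviation]
    v0 = mm_rate(p0, site_conc0, substrate_conc)

    per_step: list[tuple[str, float]] = []
    for step in spec.steps[1:]:
        ab = step.enzyme.abbreviation
        p = step.enzyme.params(context)
        vmax = p.kcat * step.enzyme.subunits * enzyme_concs[ab]
        tau_j = p.km / (vmax - v0) if vmax > v0 else math.inf
        per_step.append((ab, tau_j))
    total = sum(t for _, t in per_step)
    return per_step, total, v0


def _window_stats(t: np.ndarray, y: np.ndarray, w: int):
    """Slope, intercept and R^2 of the LS line for every window of length w."""
    n = t.size
    starts = np.arange(n - w + 1)

    def rolling(v):
        c = np.concatenate(([0.0], np.cumsum(v)))
        return c[w:] - c[:-w]

    sx, sy = rolling(t), rolling(y)
    sxx, syy, sxy = rolling(t * t), rolling(y * y), rolling(t * y)
    denom_x = w * sxx - sx * sx
    denom_y = w * syy - sy * sy
    cov = w * sxy - sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cov / denom_x
        r2 = np.where(denom_y > 0, cov * cov / (denom_x * denom_y), 1.0)
    intercept = (sy - slope * sx) / w
    return starts, slope, intercept, r2


def detect_linear_region(
    curve: ProgressCurve, policy: LinearRegionPolicy | None = None
) -> tuple[int, int]:
    """Find the maximal-slope linear window; returns (i_start, i_stop) indices.

    Raises :class:`NoLinearRegionError` when no window satisfies the policy -
    the condition seen for free-enzyme controls that never reach a
    steady-state flux within the assay.
    """
    policy = policy or LinearRegionPolicy()
    t, y = curve.time, curve.value
    n = t.size
    if n < 20:
        raise ValueError(f"need at least 20 samples, got {n}")

    def window_ok(i0: int, i1: int, check_r2: bool = False) -> bool:
        tt, yy = t[i0:i1], y[i0:i1]
        tc = tt - tt.mean()
        c2, c1, _ = np.polyfit(tc, yy, 2)
        if c1 == 0:
            return False
        span = tt[-1] - tt[0]
        if abs(c2) * span / (4 * abs(c1)) > policy.curvature_max:
            return False
        if check_r2:
            pred = np.polyval(np.polyfit(tt, yy, 1), tt)
            ss = float(np.sum((yy - yy.mean()) ** 2))
            if ss > 0 and 1.0 - float(np.sum((yy - pred) ** 2)) / ss < policy.r2_min:
                return False
        return True

    lengths = sorted({max(20, int(round(f * n))) for f in policy.length_fracs
                      if f >= policy.min_frac and int(round(f * n)) <= n})
    best = None  # (slope, start, stop)
    for w in lengths:
        starts, slope, _, r2 = _window_stats(t, y, w)
        ok = np.flatnonzero(r2 >= policy.r2_min)
        if ok.size == 0:
            continue
        # steepest first; the curvature gate is checked lazily
        for k in ok[np.argsort(slope[ok])[::-1][:50]]:
            i0, i1 = int(starts[k]), int(starts[k] + w)
            if best is not None and slope[k] <= best[0]:
                break
            if window_ok(i0, i1):
                cand = (float(slope[k]), i0, i1)
                if best is None or cand[0] > best[0] or (
                    cand[0] == best[0] and cand[1] < best[1]
                ):
                    best = cand
                break
    if best is None:
        raise NoLinearRegionError(
            f"no window of >= {policy.min_frac:.0%} of the curve reaches "
            f"R^2 >= {policy.r2_min} ({curve.label or 'unlabelled curve'})"
        )

    # extend toward late time while linearity holds: the asymptote only gets
    # straighter to the right, and the extra samples damp the noise bias of
    # picking the steepest window
    i0, i1 = best[1], best[2]
    step = max(1, (i1 - i0) // 5)
    while i1 + step <= n and window_ok(i0, i1 + step, check_r2=True):
        i1 += step
    while i1 < n and window_ok(i0, i1 + 1, check_r2=True):
        i1 += 1
    return i0, i1


def tau_empirical(
    curve: ProgressCurve, policy: LinearRegionPolicy | None = None
) -> TransientEstimate:
    """Transient time as the x-intercept of the late linear region.

    The linear window is fitted by least squares on the raw values;
    tau = -intercept/slope and its standard error follows from the fit
    covariance. The curve must be rising (production readout); negate a
    consumption trace before calling.
    """
    if curve.value_kind != "concentration":
        raise ValueError("convert the curve to concentration units first")
    i0, i1 = detect_linear_region(curve, policy)
    t = curve.time[i0:i1]
    y = curve.value[i0:i1]

    (m, b), cov = np.polyfit(t, y, 1, cov=True)
    if m <= 0:
        raise ValueError("fitted linear region has non-positive slope")
    tau = -b / m
    var = (b / m**2) ** 2 * cov[0, 0] + (1 / m) ** 2 * cov[1, 1] \
        - 2 * (b / m**3) * cov[0, 1]
    stderr = float(np.sqrt(max(var, 0.0)))
    return TransientEstimate(
        tau=float(tau), tau_stderr=stderr, v_ss=float(m),
        window=(float(t[0]), float(t[-1])),
    )


def channeling_regime(
    e_conc: float,
    i_conc: float,
    diffusion_const: float,
    kcat: float,
    crossover_factor: float = 1.0,
) -> RegimeReport:
    """Evaluate whether conditions sit in the diffusion-limited regime.

    Parameters
    ----------
    e_conc, i_conc : float
        Enzyme and intermediate concentrations, uM.
    diffusion_const : float
        Intermediate diffusion constant, um^2/s (~500 for small metabolites).
    kcat : float
        Catalytic rate, s^-1.
    crossover_factor : float
        The regime criterion is a proportionality, so absolute boundaries
        are order-of-magnitude; the flag is raised when
        catalytic/encounter > crossover_factor.
    """
    if diffusion_const <= 0 or kcat <= 0:
        raise ValueError("diffusion constant and kcat must be positive")
    if e_conc < 0 or i_conc < 0:
        raise ValueError("concentrations must be non-negative")
    n_min = min(e_conc, i_conc) * _N_PER_UM3_PER_UM  # molecules / um^3
    encounter = n_min ** (2.0 / 3.0) * diffusion_const  # 1/s
    ratio = math.inf if encounter == 0 else kcat / encounter
    return RegimeReport(
        e_conc=e_conc, i_conc=i_conc, diffusion_const=diffusion_const,
        encounter_scale=encounter, catalytic_scale=kcat, ratio=ratio,
        channeling_potential=bool(ratio > crossover_factor),
    )
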