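"""Plate-reader progress-curve processing and Michaelis-Menten fitting.

Absorbance traces (NADH at 340 nm) are converted to concentration with the
Beer-Lambert law, initial rates are extracted as the slope of the early
linear portion of each curve, and substrate/rate titrations are fitted to
the Michaelis-Menten equation by nonlinear least squares. Fold-enhancement
tables compare bound (on-nanoparticle) versus free kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

from .enzymes import MMParams

__all__ = [
    "ProgressCurve",
    "RateDataset",
    "MMFit",
    "WindowPolicy",
    "absorbance_to_concentration",
    "initial_rate",
    "fit_mm",
    "enhancement_table",
    "read_progress_csv",
    "write_progress_csv",
]


@dataclass
class ProgressCurve:
    """Time series for one well/condition.

    ``value_kind`` is 'absorbance' (AU) or 'concentration' (uM); time is in
    seconds and must be strictly increasing with at least 3 samples.
    """

    time: np.ndarray
    value: np.ndarray
    value_kind: str
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.size != self.value.size:
            raise ValueError("time and value must have equal length")
        if self.time.size < 3:
            raise ValueError("a progress curve needs at least 3 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.value_kind not in ("absorbance", "concentration"):
            raise ValueError("value_kind must be 'absorbance' or 'concentration'")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class RateDataset:
    """Initial-rate titration: substrate levels (uM) and rates (uM/s)."""

    substrate_concs: np.ndarray
    initial_rates: np.ndarray
    rate_stderr: np.ndarray | None = None

    def __post_init__(self):
        self.substrate_concs = np.asarray(self.substrate_concs, dtype=float)
        self.initial_rates = np.asarray(self.initial_rates, dtype=float)
        if self.substrate_concs.size != self.initial_rates.size:
            raise ValueError("substrate_concs and initial_rates must match")
        if np.any(self.substrate_concs < 0):
            raise ValueError("substrate concentrations must be non-negative")
        if self.rate_stderr is not None:
            self.rate_stderr = np.asarray(self.rate_stderr, dtype=float)


@dataclass
class MMFit:
    """Michaelis-Menten fit result."""

    params: MMParams
    vmax: float  # uM/s
    vmax_stderr: float
    km_stderr: float
    kcat_stderr: float
    residual_rms: float
    n_points: int

    @property
    def efficiency(self) -> float:
        """kcat/KM in mM^-1 s^-1."""
        return self.params.efficiency


@dataclass
class WindowPolicy:
    """Early-window selection rule for initial rates.

    Earliest contiguous window with at least ``min_points`` samples, linear
    fit R^2 >= ``r2_min``, and value change within ``max_depletion`` of the
    total curve span (a proxy for <=10% substrate consumed).
    """

    min_points: int = 10
    r2_min: float = 0.99
    max_depletion: float = 0.10


def absorbance_to_concentration(
    curve: ProgressCurve, epsilon: float = 6220.0, path_length_cm: float = 1.0
) -> ProgressCurve:
    """Beer-Lambert conversion A -> C = A/(eps*l), returned in uM."""
    if curve.value_kind != "absorbance":
        raise ValueError("curve is already in concentration units")
    if epsilon <= 0 or path_length_cm <= 0:
        raise ValueError("epsilon and path length must be positive")
    conc_uM = curve.value / (epsilon * path_length_cm) * 1e6
    return ProgressCurve(curve.time.copy(), conc_uM, "concentration", curve.label)


def concentration_to_absorbance(
    curve: ProgressCurve, epsilon: float = 6220.0, path_length_cm: float = 1.0
) -> ProgressCurve:
    """Inverse Beer-Lambert conversion (uM -> AU)."""
    if curve.value_kind != "concentration":
        raise ValueError("curve is already in absorbance units")
    a = curve.value * 1e-6 * epsilon * path_length_cm
    return ProgressCurve(curve.time.copy(), a, "absorbance", curve.label)


def _linfit(t: np.ndarray, y: np.ndarray):
    """Least-squares line; returns slope, intercept, stderr(slope), R^2."""
    res = stats.linregress(t, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:  # perfectly flat
        return 0.0, float(y[0]), 0.0, 1.0
    pred = res.slope * t + res.intercept
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return float(res.slope), float(res.intercept), stderr, r2


def initial_rate(
    curve: ProgressCurve, policy: WindowPolicy | None = None
) -> tuple[float, float]:
    """Initial rate (uM/s) and its standard error from the early linear window."""
    if curve.value_kind != "concentration":
        raise ValueError("convert the curve to concentration units first")
    policy = policy or WindowPolicy()
    t, y = curve.time, curve.value
    n = len(curve)
    if n < policy.min_points:
        raise ValueError(
            f"too few points ({n}) for the window policy ({policy.min_points})"
        )
    span = float(np.ptp(y))
    if span == 0.0:
        return 0.0, 0.0

    # grow the earliest window while it stays linear and shallow
    best = None
    for end in range(policy.min_points, n + 1):
        tt, yy = t[:end], y[:end]
        depletion = float(abs(yy[-1] - yy[0])) / span
        slope, _, stderr, r2 = _linfit(tt, yy)
        if r2 >= policy.r2_min and depletion <= policy.max_depletion:
            best = (slope, stderr)
        elif best is not None:
            break
    if best is None:
        # fall back to the minimal early window
        slope, _, stderr, _ = _linfit(t[: policy.min_points], y[: policy.min_points])
        best = (slope, stderr)
    return best


def _mm_model(s, vmax, km):
    return vmax * s / (km + s)


def fit_mm(dataset: RateDataset, enzyme_conc: float) -> MMFit:
    """Fit Vmax and KM by nonlinear least squares; derive kcat = Vmax/E.

    ``enzyme_conc`` is the active-site concentration in uM, so kcat comes out
    per monomer matching the enzyme-table convention.
    """
    s, v = dataset.substrate_concs, dataset.initial_rates
    if np.all(v == 0):
        raise ValueError("all rates are zero; nothing to fit")
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be positive")
    n_levels = np.unique(s[s > 0]).size
    if n_levels < 4:
        warnings.warn(
            f"only {n_levels} distinct substrate levels; KM is poorly constrained",
            stacklevel=2,
        )

    model = Model(_mm_model)
    params = model.make_params(
        vmax=float(np.max(v)), km=float(np.median(s[s > 0])) if n_levels else 1.0
    )
    params["vmax"].set(min=1e-12)
    params["km"].set(min=1e-9)
    weights = None
    if dataset.rate_stderr is not None and np.all(dataset.rate_stderr > 0):
        weights = 1.0 / dataset.rate_stderr
    out = model.fit(v, params, s=s, weights=weights)
    if not out.success:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {out.message}")

    vmax = float(out.params["vmax"].value)
    km = float(out.params["km"].value)
    vmax_se = float(out.params["vmax"].stderr or np.nan)
    km_se = float(out.params["km"].stderr or np.nan)
    kcat = vmax / enzyme_conc
    kcat_se = vmax_se / enzyme_conc if np.isfinite(vmax_se) else np.nan

    fitted_km = km
    if not (np.any(s < fitted_km) and np.any(s > fitted_km)):
        warnings.warn(
            "substrate levels do not span the fitted KM; estimates may be "
            "poorly identified",
            stacklevel=2,
        )

    return MMFit(
        params=MMParams(kcat=kcat, km=km),
        vmax=vmax, vmax_stderr=vmax_se, km_stderr=km_se, kcat_stderr=kcat_se,
        residual_rms=float(np.sqrt(np.mean(out.residual**2))),
        n_points=int(s.size),
    )


def _ratio_with_ns(
    num: float, num_se: float, den: float, den_se: float, z: float = 1.96
) -> tuple[float, bool]:
    """Fold change num/den and whether its ~95% CI includes 1 (NS)."""
    ratio = num / den
    rel = 0.0
    for val, se in ((num, num_se), (den, den_se)):
        if np.isfinite(se) and val != 0:
            rel += (se / val) ** 2
    if rel == 0.0:
        return ratio, bool(np.isclose(ratio, 1.0))
    half = z * np.sqrt(rel)
    lo, hi = ratio * np.exp(-half), ratio * np.exp(half)
    return ratio, bool(lo <= 1.0 <= hi)


def enhancement_table(
    free_fits: dict[str, MMFit], bound_fits: dict[str, MMFit]
) -> pd.DataFrame:
    """Per-enzyme bound/free fold changes in kcat, KM and kcat/KM.

    A fold change is flagged 'NS' when the 95% interval of the ratio
    (log-normal error propagation from the fit standard errors) includes 1.
    """
    missing = set(free_fits) ^ set(bound_fits)
    if missing:
        raise ValueError(f"free/bound enzyme keys do not match: {sorted(missing)}")
    rows = []
    for ab in free_fits:
        f, b = free_fits[ab], bound_fits[ab]
        kcat_fold, kcat_ns = _ratio_with_ns(
            b.params.kcat, b.kcat_stderr, f.params.kcat, f.kcat_stderr
        )
        km_fold, km_ns = _ratio_with_ns(
            b.params.km, b.km_stderr, f.params.km, f.km_stderr
        )
        eff_fold = b.efficiency / f.efficiency
        rows.append({
            "enzyme": ab,
            "kcat_fold": kcat_fold, "kcat_ns": kcat_ns,
            "km_fold": km_fold, "km_ns": km_ns,
            "efficiency_fold": eff_fold,
            "efficiency_ns": kcat_ns and km_ns,
        })
    return pd.DataFrame(rows).set_index("enzyme")


# ---------------------------------------------------------------------------
# CSV I/O

def read_progress_csv(path) -> list[ProgressCurve]:
    """Read plate-reader exports.

    Tidy dialect: columns time_s, label, value, value_kind.
    Wide dialect: a time_s column plus one absorbance column per well.
    The dialect is auto-detected from the header.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("progress CSV must have a time_s column")
    if {"label", "value"} <= set(df.columns):
        kind_col = "value_kind" in df.columns
        curves = []
        for label, grp in df.groupby("label", sort=False):
            kind = str(grp["value_kind"].iloc[0]) if kind_col else "absorbance"
            curves.append(
                ProgressCurve(grp["time_s"].to_numpy(), grp["value"].to_numpy(),
                              kind, str(label))
            )
        return curves
    wells = [c for c in df.columns if c != "time_s"]
    return [
        ProgressCurve(df["time_s"].to_numpy(), df[w].to_numpy(), "absorbance", w)
        for w in wells
    ]


def write_progress_csv(curves: list[ProgressCurve] | ProgressCurve, path) -> None:
    """Write curves in the tidy dialect."""
    if isinstance(curves, ProgressCurve):
        curves = [curves]
    frames = [
        pd.DataFrame({"time_s": c.time, "label": c.label, "value": c.value,
                      "value_kind": c.value_kind})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
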