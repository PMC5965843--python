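"""Initial-velocity extraction and Michaelis-Menten parameter estimation.

The analysis chain mirrors a standard fluorogenic phosphatase assay:
product signal is read at fixed intervals, the initial velocity at each
substrate concentration is the least-squares slope of the progress curve
over an early time window, and the velocities are fit to the
Michaelis-Menten rate law

    v = Vmax * S / (KM + S)

either by nonlinear least squares or from a Lineweaver-Burk (double-
reciprocal) line. kcat is derived from Vmax and the enzyme concentration
with explicit unit conversion (Vmax in uM/min, [E] in nM, kcat in 1/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ProgressCurve",
    "VelocityPoint",
    "MMFit",
    "michaelis_menten_velocity",
    "initial_velocity",
    "initial_velocities",
    "fit_mm",
    "efficiency_ratio",
    "ph_profile",
    "SubstrateDepletionWarning",
]


class SubstrateDepletionWarning(UserWarning):
    """Product formed in the fit window exceeds 10% of S0, so the
    initial-rate assumption is strained."""


def michaelis_menten_velocity(s_mM: float | np.ndarray, vmax: float,
                              km_mM: float) -> float | np.ndarray:
    """Michaelis-Menten rate law v = Vmax*S/(KM+S); S and KM in mM."""
    s = np.asarray(s_mM, float)
    out = vmax * s / (km_mM + s)
    return float(out) if out.ndim == 0 else out


@dataclass
class ProgressCurve:
    """Time course of product signal at one substrate concentration."""

    times_min: np.ndarray
    signal: np.ndarray
    substrate_uM: float
    enzyme_nM: float
    pH: float = 5.0
    temperature_C: float = 20.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, float)
        self.signal = np.asarray(self.signal, float)
        if self.times_min.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        if not np.all(np.diff(self.times_min) > 0):
            raise ValueError("time points must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")


@dataclass
class VelocityPoint:
    substrate_mM: float
    v0: float  # uM/min (or signal units/min when uncalibrated)

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError("initial velocity must be non-negative for a "
                             "product-accumulation assay")


@dataclass
class MMFit:
    """Michaelis-Menten parameter estimate with fit diagnostics."""

    vmax: float            # uM/min (signal units/min when uncalibrated)
    km_mM: float
    kcat: float            # s^-1 (signal units when uncalibrated)
    kcat_over_km: float    # s^-1 mM^-1
    vmax_se: float
    km_se: float
    method: str
    rss: float
    calibrated: bool = True
    n_points: int = 0
    hill_coefficient: float | None = None

    def __post_init__(self) -> None:
        if self.km_mM <= 0 or self.vmax <= 0:
            raise ValueError("fitted KM and Vmax must be positive")

    @classmethod
    def from_parameters(cls, kcat: float, km_mM: float, enzyme_nM: float = 10.0,
                        method: str = "reported") -> "MMFit":
        """Assemble an MMFit from published (kcat, KM) for ratio arithmetic."""
        vmax = vmax_from_kcat(kcat, enzyme_nM)
        return cls(vmax=vmax, km_mM=km_mM, kcat=kcat,
                   kcat_over_km=kcat / km_mM, vmax_se=float("nan"),
                   km_se=float("nan"), method=method, rss=0.0)


def kcat_from_vmax(vmax_uM_min: float, enzyme_nM: float) -> float:
    """kcat (1/s) from Vmax (uM/min) and enzyme concentration (nM)."""
    return vmax_uM_min * 1000.0 / (enzyme_nM * 60.0)


def vmax_from_kcat(kcat_s: float, enzyme_nM: float) -> float:
    """Inverse of :func:`kcat_from_vmax` (exact round-trip)."""
    return kcat_s * enzyme_nM * 60.0 / 1000.0


def initial_velocity(pc: ProgressCurve, window: tuple[float, float] = (2.0, 10.0),
                     calibration: float | None = None) -> VelocityPoint:
    """Least-squares slope of signal vs time over the window (inclusive).

    ``calibration`` converts signal units to uM product per signal unit;
    when omitted the signal is taken to be product concentration in uM.
    """
    t0, t1 = window
    mask = (pc.times_min >= t0) & (pc.times_min <= t1)
    if mask.sum() < 2:
        raise ValueError(f"window {window} contains fewer than 2 points")
    t = pc.times_min[mask]
    y = pc.signal[mask]
    slope = float(np.polyfit(t, y, 1)[0])
    if calibration is not None:
        slope *= calibration
        product = (y.max() - y.min()) * calibration
    else:
        product = y.max() - y.min()
    if product > 0.10 * pc.substrate_uM:
        warnings.warn(
            f"product ({product:.1f} uM) exceeds 10% of S0 "
            f"({pc.substrate_uM:.0f} uM) within the fit window",
            SubstrateDepletionWarning, stacklevel=2)
    return VelocityPoint(substrate_mM=pc.substrate_uM / 1000.0,
                         v0=max(slope, 0.0))


def initial_velocities(curves: Sequence[ProgressCurve],
                       window: tuple[float, float] = (2.0, 10.0),
                       calibration: float | None = None) -> list[VelocityPoint]:
    return [initial_velocity(pc, window, calibration) for pc in curves]


def fit_mm(points: Sequence[VelocityPoint], enzyme_nM: float,
           method: str = "nonlinear", calibrated: bool = True,
           free_hill: bool = False) -> MMFit:
    """Estimate (Vmax, KM, kcat, kcat/KM) from initial velocities.

    ``nonlinear`` minimizes squared residuals of the rate law directly
    (deterministic start values: Vmax0 = max v, KM0 = S at half-max by
    interpolation). ``lineweaver-burk`` fits the unweighted double-
    reciprocal line 1/v = (KM/Vmax)(1/S) + 1/Vmax. ``free_hill`` adds a
    diagnostic fit with the Hill exponent released (reported via
    ``hill_coefficient``; Vmax/KM still come from the fixed-exponent fit).
    """
    if len({p.substrate_mM for p in points}) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    s = np.array([p.substrate_mM for p in points])
    v = np.array([p.v0 for p in points])
    if np.any(v <= 0) and method == "lineweaver-burk":
        raise ValueError("double-reciprocal fit requires positive velocities")

    vmax0 = float(v.max())
    order = np.argsort(s)
    km0 = float(np.interp(vmax0 / 2.0, v[order], s[order]))
    km0 = km0 if km0 > 0 else float(np.median(s))

    if method == "nonlinear":
        popt, pcov = optimize.curve_fit(
            michaelis_menten_velocity, s, v, p0=[vmax0, km0],
            maxfev=20000, ftol=1e-10, xtol=1e-12)
        vmax, km = float(popt[0]), float(popt[1])
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 2
        resid = v - michaelis_menten_velocity(s, vmax, km)
    elif method == "lineweaver-burk":
        res = stats.linregress(1.0 / s, 1.0 / v)
        if res.intercept <= 0:
            raise ValueError("double-reciprocal intercept non-positive; fit failed")
        vmax = 1.0 / res.intercept
        km = res.slope * vmax
        # delta-method standard errors from the line fit
        vmax_se = res.intercept_stderr / res.intercept ** 2 if res.intercept_stderr else np.nan
        km_se = np.hypot(res.stderr * vmax, res.slope * vmax_se) if res.stderr else np.nan
        perr = [vmax_se, km_se]
        resid = v - michaelis_menten_velocity(s, vmax, km)
    else:
        raise ValueError(f"unknown method {method!r}")

    if km <= 0 or vmax <= 0:
        raise ValueError(f"fit failed: non-positive parameters "
                         f"(Vmax={vmax:.3g}, KM={km:.3g})")

    hill = None
    if free_hill:
        def hill_eq(sv, vm, k, h):
            return vm * sv ** h / (k ** h + sv ** h)
        try:
            hopt, _ = optimize.curve_fit(hill_eq, s, v, p0=[vmax, km, 1.0],
                                         maxfev=20000)
            hill = float(hopt[2])
        except RuntimeError:
            hill = None

    # uncalibrated fits carry signal units through the same arithmetic;
    # the flag tags the units rather than changing them
    kcat = kcat_from_vmax(vmax, enzyme_nM)
    return MMFit(vmax=vmax, km_mM=km, kcat=kcat, kcat_over_km=kcat / km,
                 vmax_se=float(perr[0]), km_se=float(perr[1]), method=method,
                 rss=float(np.sum(resid ** 2)), calibrated=calibrated,
                 n_points=len(points), hill_coefficient=hill)


def efficiency_ratio(fit_a: MMFit, fit_b: MMFit) -> float:
    """Fold-change in catalytic efficiency, (kcat/KM)_a / (kcat/KM)_b."""
    if fit_b.kcat_over_km == 0:
        raise ZeroDivisionError("denominator efficiency is zero")
    return fit_a.kcat_over_km / fit_b.kcat_over_km


def ph_profile(curves: Sequence[ProgressCurve],
               window: tuple[float, float] = (2.0, 10.0)) -> pd.DataFrame:
    """Descriptive per-pH activity table with the optimum flagged.

    No titration model is fitted; activity is the initial velocity at each
    pH and the optimum is simply the argmax.
    """
    rows = [{"pH": pc.pH, "v0": initial_velocity(pc, window).v0} for pc in curves]
    df = pd.DataFrame(rows).sort_values("pH").reset_index(drop=True)
    df["optimum"] = df["v0"] == df["v0"].max()
    return df


def read_progress_curves(path) -> list[ProgressCurve]:
    """Read a tidy CSV/TSV of progress curves.

    Expected columns: time_min, signal, substrate_uM, enzyme_nM and
    optionally pH, temp_C, replicate. One curve per (substrate_uM,
    replicate) group.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"time_min", "signal", "substrate_uM", "enzyme_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"progress-curve table missing columns: {sorted(missing)}")
    group_cols = ["substrate_uM"]
    if "replicate" in df.columns:
        group_cols.append("replicate")
    curves = []
    for _, g in df.groupby(group_cols, sort=True):
        g = g.sort_values("time_min")
        curves.append(ProgressCurve(
            times_min=g["time_min"].to_numpy(),
            signal=g["signal"].to_numpy(),
            substrate_uM=float(g["substrate_uM"].iloc[0]),
            enzyme_nM=float(g["enzyme_nM"].iloc[0]),
            pH=float(g["pH"].iloc[0]) if "pH" in g.columns else 5.0,
            temperature_C=float(g["temp_C"].iloc[0]) if "temp_C" in g.columns else 20.0,
        ))
    return curves
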