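"""Static-chamber gas fluxes and efflux isotope enrichment.

A dark 1.2 L chamber is closed over a vegetation-free 11 cm collar and the
headspace is sampled at 0, 10, 20 and 30 minutes.  The flux is the ordinary
least-squares slope of concentration against time converted to a molar
area flux:

    flux = slope * (V / A) * P / (R * T)

with slope in mol-fraction per hour, V the chamber volume, A the collar
area, and P/(R T) the molar density of air.  A linear (not exponential)
headspace model is used: four points cannot constrain curvature and the
accumulation stays near-linear over 30 minutes.  The ~1.25 % headspace
dilution from each 15 mL sample draw is ignored (known small bias).

The last sampling point also carries the isotope value of the headspace.
That value is a two-pool mixture of ambient air trapped at closure and
soil-emitted gas; :func:`efflux_enrichment` inverts the mixture with the
chamber's own t0 and t30 concentrations (a single mass balance, not a
Keeling regression) and subtracts the same quantity computed on matched
unlabelled-control chambers, giving the atom percent excess of the emitted
gas itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import (
    CHAMBER_VOLUME_L,
    DEFAULT_PRESSURE_KPA,
    DEFAULT_TEMPERATURE_K,
    GAS_COLLAR_AREA_M2,
    R_GAS,
)
from .isotope import delta_to_atom_percent

__all__ = ["ChamberSeries", "FluxResult", "chamber_flux", "efflux_enrichment"]

_TIMES_MIN = (0.0, 10.0, 20.0, 30.0)


@dataclass(frozen=True)
class ChamberSeries:
    """One chamber deployment: four timed concentrations plus last-point deltas.

    Concentrations are mol-fraction in the unit native to the gas (ppm for
    CO2, ppb for N2O); ``unit`` is the factor to mol fraction (1e6 or 1e9).
    """

    concentrations: tuple[float, float, float, float]
    unit: float = 1e6
    times_min: tuple[float, float, float, float] = _TIMES_MIN
    delta_last: float | None = None
    element: str = "C"
    temperature_K: float = DEFAULT_TEMPERATURE_K
    pressure_kPa: float = DEFAULT_PRESSURE_KPA
    chamber_volume_L: float = CHAMBER_VOLUME_L
    collar_area_m2: float = GAS_COLLAR_AREA_M2

    def __post_init__(self) -> None:
        if len(self.concentrations) != 4 or len(self.times_min) != 4:
            raise ValueError("a chamber series has exactly 4 timed concentrations")


@dataclass(frozen=True)
class FluxResult:
    """Flux in µmol m-2 h-1 with its linear-fit diagnostics."""

    flux_umol_m2_h: float | None
    slope_per_min: float | None  # in concentration units per minute
    r_squared: float | None
    n_points: int
    qc_flag: str | None = None


def chamber_flux(series: ChamberSeries) -> FluxResult:
    """OLS slope of the headspace series converted to a molar area flux.

    Points that are NaN are dropped; fewer than 3 usable points yields a
    missing flux with a reason.  R² below 0.9 with a non-near-zero slope is
    flagged (nonlinear accumulation, leak, or ebullition); a near-zero slope
    with undefined R² is reported as zero flux.
    """
    t = np.asarray(series.times_min, dtype=float)
    c = np.asarray(series.concentrations, dtype=float)
    ok = np.isfinite(t) & np.isfinite(c)
    if ok.sum() < 3:
        return FluxResult(None, None, None, int(ok.sum()), qc_flag="fewer than 3 usable points")
    t, c = t[ok], c[ok]
    slope, intercept = np.polyfit(t, c, 1)
    fitted = slope * t + intercept
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = None if ss_tot == 0 else float(1.0 - np.sum((c - fitted) ** 2) / ss_tot)

    molar_density = (series.pressure_kPa * 1000.0) / (R_GAS * series.temperature_K)  # mol m-3
    vol_m3 = series.chamber_volume_L / 1000.0
    # slope [unit min-1] -> mol fraction h-1 -> µmol m-2 h-1
    flux = slope / series.unit * 60.0 * (vol_m3 / series.collar_area_m2) * molar_density * 1e6

    scale = max(abs(c).max(), 1.0)
    near_zero = abs(slope) * (t.max() - t.min()) < 1e-9 * scale
    flag = None
    if r2 is None:
        flag = "constant concentration; R^2 undefined" if near_zero else None
    elif r2 < 0.9 and not near_zero:
        flag = f"poor linear fit (R^2 = {r2:.3f})"
    return FluxResult(float(flux), float(slope), r2, int(ok.sum()), qc_flag=flag)


def _source_atom_percent(series: ChamberSeries, ambient_delta: float) -> float:
    """Atom percent of the emitted gas from the last-point two-pool mixture."""
    if series.delta_last is None:
        raise ValueError("series has no last-point delta value")
    c0 = float(series.concentrations[0])
    c_last = float(series.concentrations[-1])
    if c_last <= c0:
        raise ValueError("no concentration rise; emitted-gas composition is undetermined")
    a_mix = delta_to_atom_percent(series.delta_last, series.element)
    a_amb = delta_to_atom_percent(ambient_delta, series.element)
    return (c_last * a_mix - c0 * a_amb) / (c_last - c0)


def efflux_enrichment(
    series: ChamberSeries,
    baseline_series: Sequence[ChamberSeries],
    ambient_delta: float,
) -> float:
    """Atom percent excess of the emitted gas over unlabelled controls.

    Both the sample chamber and each baseline chamber are inverted to the
    atom percent of their emitted gas; the excess is the difference from the
    mean of the baselines.  Missing delta values propagate as ValueError.
    """
    a_src = _source_atom_percent(series, ambient_delta)
    a_base = float(np.mean([_source_atom_percent(b, ambient_delta) for b in baseline_series]))
    return a_src - a_base
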