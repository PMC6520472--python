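"""Plot-level N2O flux from a closed-chamber concentration time series.

The flux is the OLS slope of headspace concentration against time,
scaled by air molar density and the chamber volume-to-area ratio::

    F = dC/dt * rho * V / A      [nmol N2O m-2 s-1]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .units import air_molar_density

__all__ = [
    "ChamberGeometry",
    "AirState",
    "GasSampleSeries",
    "FluxObservation",
    "SlopeFit",
    "fit_dcdt",
    "compute_flux",
    "fluxes_from_concentration_table",
]


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber headspace volume (m3) and enclosed ground area (m2)."""

    volume: float
    area: float

    def __post_init__(self) -> None:
        if not (self.volume > 0 and self.area > 0):
            raise ValueError("volume and area must be > 0")

    @property
    def height(self) -> float:
        """Effective headspace height V/A in m."""
        return self.volume / self.area

    @classmethod
    def cylinder(cls, diameter_m: float, height_m: float) -> "ChamberGeometry":
        area = np.pi * (diameter_m / 2.0) ** 2
        return cls(volume=area * height_m, area=area)

    @classmethod
    def box(cls, length_m: float, width_m: float, height_m: float) -> "ChamberGeometry":
        area = length_m * width_m
        return cls(volume=area * height_m, area=area)


@dataclass(frozen=True)
class AirState:
    """Molar density of chamber air, either given or from T and P."""

    rho: Optional[float] = None
    temperature_k: Optional[float] = None
    pressure_pa: float = 101325.0

    def __post_init__(self) -> None:
        if self.rho is None and self.temperature_k is None:
            raise ValueError("provide rho or temperature_k")
        if self.rho is not None and self.rho <= 0:
            raise ValueError("rho must be > 0")

    @property
    def molar_density(self) -> float:
        if self.rho is not None:
            return self.rho
        return air_molar_density(self.temperature_k, self.pressure_pa)


@dataclass(frozen=True)
class GasSampleSeries:
    """Headspace samples: times (s since closure) and N2O mole fraction
    (nmol mol-1)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("need at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass
class FluxObservation:
    """One plot-level flux at one time point."""

    site: str
    event: int
    treatment: str
    plot: str
    day: float
    flux: float
    qc_flag: str = ""


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of concentration on time with its standard error."""

    slope: float
    stderr: float
    r_squared: float
    n: int
    qc_flag: str = ""


def fit_dcdt(series: GasSampleSeries) -> SlopeFit:
    """Least-squares d[C]/dt in nmol mol-1 s-1.

    With only two samples the slope is the difference quotient and the
    standard error is undefined (NaN, flagged "two_point").
    """
    t, c = series.times, series.concentrations
    if t.size == 2:
        slope = (c[1] - c[0]) / (t[1] - t[0])
        return SlopeFit(slope=float(slope), stderr=float("nan"), r_squared=float("nan"),
                        n=2, qc_flag="two_point")
    res = stats.linregress(t, c)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    flag = "" if r2 >= 0.9 else "low_r2"
    if np.allclose(c, c[0]):
        r2, flag = 1.0, "constant"
        return SlopeFit(slope=0.0, stderr=0.0, r_squared=r2, n=int(t.size), qc_flag=flag)
    return SlopeFit(slope=float(res.slope), stderr=float(res.stderr),
                    r_squared=r2, n=int(t.size), qc_flag=flag)


def compute_flux(series: GasSampleSeries, chamber: ChamberGeometry, air: AirState) -> float:
    """Chamber flux = slope * rho * V / A, nmol N2O m-2 s-1."""
    fit = fit_dcdt(series)
    return fit.slope * air.molar_density * chamber.height


def fluxes_from_concentration_table(
    conc: pd.DataFrame,
    chambers: pd.DataFrame,
) -> pd.DataFrame:
    """Compute one flux per chamber from long-format concentration data.

    ``conc`` needs columns chamber_id, time_s, n2o_nmol_mol; ``chambers``
    needs chamber_id, volume_m3, area_m2 and either rho_mol_m3 or
    temperature_k (plus optional pressure_pa).  Returns a table with one
    row per chamber_id: flux_nmol_m2_s, slope, stderr, r_squared, qc_flag.
    """
    need = {"chamber_id", "time_s", "n2o_nmol_mol"}
    if missing := need - set(conc.columns):
        raise ValueError(f"concentration table missing columns: {sorted(missing)}")
    meta = chambers.set_index("chamber_id")
    rows = []
    for cid, grp in conc.groupby("chamber_id", sort=True):
        grp = grp.sort_values("time_s")
        series = GasSampleSeries(grp["time_s"].to_numpy(), grp["n2o_nmol_mol"].to_numpy())
        m = meta.loc[cid]
        geom = ChamberGeometry(volume=float(m["volume_m3"]), area=float(m["area_m2"]))
        if "rho_mol_m3" in m.index and pd.notna(m.get("rho_mol_m3")):
            air = AirState(rho=float(m["rho_mol_m3"]))
        else:
            air = AirState(temperature_k=float(m["temperature_k"]),
                           pressure_pa=float(m.get("pressure_pa", 101325.0)))
        fit = fit_dcdt(series)
        rows.append({
            "chamber_id": cid,
            "flux_nmol_m2_s": fit.slope * air.molar_density * geom.height,
            "slope_nmol_mol_s": fit.slope,
            "slope_stderr": fit.stderr,
            "r_squared": fit.r_squared,
            "qc_flag": fit.qc_flag,
        })
    return pd.DataFrame(rows)
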