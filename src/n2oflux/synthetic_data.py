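"""Synthetic chamber campaigns with the statistical structure the
analysis assumes.

Each event draws plot-level fluxes as (log-normal emission pulse) +
(log-normal background): treatment plots get both terms, control plots
the background only.  Draws are independent across plots and days —
the fitted model has no persistence term, so neither does the
generator.  Fluxes are written in field units (nmol N2O m-2 s-1) so
generated files look like real campaign data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chamber_flux import AirState, ChamberGeometry, GasSampleSeries
from .lognormal_model import TemporalParams, temporal_mean
from .units import NMOL_M2_S_TO_KGN_HA_DAY

__all__ = [
    "TruthSpec", "SamplingSchedule", "CampaignLayout", "EventPreset",
    "PRESETS", "daily_then_alternate_schedule", "weekly_taper_schedule",
    "simulate_event", "simulate_concentration_series", "write_campaign",
]


@dataclass(frozen=True)
class TruthSpec:
    """Ground-truth emission parameters for one synthetic event."""

    delta: float = math.log(3.0)
    k: float = 0.6
    omega: float = 0.01
    sigma_log: float = 0.8
    n_in: float = 70.0
    background_mu: float = 0.4          # nmol N2O m-2 s-1, mean control flux
    background_sigma_log: float = 0.8

    def __post_init__(self) -> None:
        vals = asdict(self)
        if not all(np.isfinite(v) for v in vals.values()):
            raise ValueError("TruthSpec parameters must be finite")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if not 0 <= self.omega < 1:
            raise ValueError("omega must be in [0, 1)")
        if self.sigma_log < 0 or self.background_sigma_log < 0:
            raise ValueError("log-scales must be >= 0")
        if self.n_in < 0 or self.background_mu < 0:
            raise ValueError("n_in and background_mu must be >= 0")

    def temporal_params(self) -> TemporalParams:
        return TemporalParams(delta=self.delta, k=self.k, omega=self.omega,
                              sigma_log=self.sigma_log, n_in=self.n_in)


@dataclass(frozen=True)
class SamplingSchedule:
    """Measurement days since application, within the event window."""

    measurement_days: tuple
    window_days: float = 30.0

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.measurement_days)
        object.__setattr__(self, "measurement_days", days)
        if len(days) == 0:
            raise ValueError("schedule must contain at least one day")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("measurement days must be strictly increasing")
        if days[0] <= 0 or days[-1] > self.window_days:
            raise ValueError("days must lie in (0, window_days]")


@dataclass(frozen=True)
class CampaignLayout:
    n_treatment_plots: int = 4
    n_control_plots: int = 4
    treatments: tuple = ("AN", "Ur", "UI")

    def __post_init__(self) -> None:
        if self.n_treatment_plots < 1 or self.n_control_plots < 1:
            raise ValueError("plot counts must be >= 1")
        if len(self.treatments) < 1:
            raise ValueError("at least one treatment label required")


def daily_then_alternate_schedule(window_days: float = 30.0) -> SamplingSchedule:
    """Daily for two weeks, then every second day to the window end."""
    days = list(range(1, 15)) + list(range(16, int(window_days) + 1, 2))
    return SamplingSchedule(tuple(d for d in days if d <= window_days), window_days)


def weekly_taper_schedule(window_days: float = 30.0) -> SamplingSchedule:
    """Three visits/week for two weeks, two/week for two weeks, then weekly."""
    days = [2, 4, 6, 9, 11, 13, 17, 20, 24, 27, 30]
    return SamplingSchedule(tuple(d for d in days if d <= window_days), window_days)


@dataclass(frozen=True)
class EventPreset:
    """Site-flavoured bundle of truth, schedule, layout and chamber."""

    site: str
    truth: TruthSpec
    schedule: SamplingSchedule
    layout: CampaignLayout
    chamber: ChamberGeometry
    air: AirState


PRESETS = {
    # cylindrical chambers (38 cm ID, 22 cm high), dense manual sampling
    "EB": EventPreset("EB", TruthSpec(n_in=70.0), daily_then_alternate_schedule(),
                      CampaignLayout(), ChamberGeometry.cylinder(0.38, 0.22),
                      AirState(temperature_k=283.15)),
    "UJ": EventPreset("UJ", TruthSpec(n_in=70.0), daily_then_alternate_schedule(),
                      CampaignLayout(), ChamberGeometry.cylinder(0.38, 0.22),
                      AirState(temperature_k=283.15)),
    # box chambers (50 x 50 cm, ~17.5 cm headspace), tapering schedule
    "HF": EventPreset("HF", TruthSpec(n_in=90.0), weekly_taper_schedule(),
                      CampaignLayout(), ChamberGeometry.box(0.5, 0.5, 0.175),
                      AirState(temperature_k=284.15)),
    "NW": EventPreset("NW", TruthSpec(n_in=90.0), weekly_taper_schedule(),
                      CampaignLayout(), ChamberGeometry.box(0.5, 0.5, 0.175),
                      AirState(temperature_k=285.15)),
}


def _lognormal_draws(mean, sigma_log, size, rng):
    """Draws from a log-normal with the given arithmetic mean; zeros if
    the mean is zero."""
    if mean == 0:
        return 0.0 if size is None else np.zeros(size)
    mu_log = math.log(mean) - 0.5 * sigma_log**2
    if sigma_log == 0:
        return mean if size is None else np.full(size, mean)
    return rng.lognormal(mu_log, sigma_log, size)


def simulate_event(
    truth: TruthSpec,
    schedule: SamplingSchedule | None = None,
    layout: CampaignLayout | None = None,
    seed: int = 0,
    site: str = "SYN",
    event: int = 1,
) -> pd.DataFrame:
    """One fertilisation event as a long-format observation table.

    Treatment-plot fluxes are pulse + background; control plots
    background only.  Deterministic for a given seed.
    """
    schedule = schedule or daily_then_alternate_schedule()
    layout = layout or CampaignLayout()
    rng = np.random.default_rng(seed)
    days = np.asarray(schedule.measurement_days)
    params = truth.temporal_params()
    # mean pulse flux per day in field units
    mu_t_nmol = np.asarray(temporal_mean(days, params)) / NMOL_M2_S_TO_KGN_HA_DAY

    rows = []
    for treatment in layout.treatments:
        for p in range(1, layout.n_treatment_plots + 1):
            for d, mu in zip(days, mu_t_nmol):
                pulse = float(_lognormal_draws(mu, truth.sigma_log, None, rng))
                bg = float(_lognormal_draws(truth.background_mu,
                                            truth.background_sigma_log, None, rng))
                rows.append((site, event, treatment, f"{treatment}{p}", d, pulse + bg))
    for p in range(1, layout.n_control_plots + 1):
        for d in days:
            bg = float(_lognormal_draws(truth.background_mu,
                                        truth.background_sigma_log, None, rng))
            rows.append((site, event, "control", f"C{p}", d, bg))
    return pd.DataFrame(rows, columns=["site", "event", "treatment", "plot",
                                       "day", "flux_nmol_m2_s"])


def simulate_concentration_series(
    flux: float,
    chamber: ChamberGeometry,
    air: AirState,
    sample_times,
    noise_sd: float = 0.0,
    seed: int | None = None,
    c0: float = 330.0,
) -> GasSampleSeries:
    """Headspace concentration series implied by a constant soil flux.

    Inverts the chamber flux formula: C(t) = c0 + flux * A / (rho * V) * t,
    plus optional iid Gaussian analyser noise.  A zero-noise series is
    recovered exactly by ``compute_flux``.
    """
    t = np.asarray(sample_times, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 sample times")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    slope = flux / (air.molar_density * chamber.height)
    conc = c0 + slope * t
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        conc = conc + rng.normal(0.0, noise_sd, t.size)
    return GasSampleSeries(times=t, concentrations=conc)


def write_campaign(df: pd.DataFrame, out_dir, truth: TruthSpec | None = None,
                   stem: str = "fluxes") -> Path:
    """Write a campaign CSV (and a JSON truth sidecar for recovery tests)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}.csv"
    df.to_csv(path, index=False)
    if truth is not None:
        (out_dir / f"{stem}_truth.json").write_text(
            json.dumps(asdict(truth), indent=2) + "\n")
    return path
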