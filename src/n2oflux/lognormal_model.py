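"""Log-normal flux model: spatial density, temporal mean curve and
closed-form cumulative emission.

The model assumes that at any time ``t`` after fertiliser application
the spatial distribution of plot-level fluxes is log-normal, and that
the spatial *mean* flux follows a log-normal-shaped pulse in time::

    mean_rate(t) = N_in * omega * lognorm_pdf(t; delta, k)

so the emission pulse integrates to ``N_in * omega`` (the emitted
fraction of applied nitrogen) and the cumulative emission to time ``t``
has the closed form ``N_in * omega * Phi((ln t - delta) / k)``.

Units: ``temporal_mean`` and ``cumulative_flux`` work in
kg N ha-1 (day-1); observed chamber fluxes in nmol N2O m-2 s-1 are
converted at the likelihood boundary with
:data:`~n2oflux.units.NMOL_M2_S_TO_KGN_HA_DAY`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr

from .units import NMOL_M2_S_TO_KGN_HA_DAY

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: default left-censoring floor for background-adjusted fluxes,
#: nmol N2O m-2 s-1
DEFAULT_FLOOR_NMOL = 1.0e-4

__all__ = [
    "SpatialParams",
    "TemporalParams",
    "spatial_pdf",
    "spatial_logpdf",
    "lognormal_mean",
    "temporal_mean",
    "mu_log_at_t",
    "cumulative_flux",
    "log_likelihood",
    "log_likelihood_arrays",
    "DEFAULT_FLOOR_NMOL",
]


@dataclass(frozen=True)
class SpatialParams:
    """Location/scale of the log-flux distribution at a fixed time."""

    mu_log: float
    sigma_log: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_log) or self.sigma_log < 0:
            raise ValueError(f"sigma_log must be >= 0, got {self.sigma_log}")

    @property
    def mu(self) -> float:
        """Arithmetic-scale mean, exp(mu_log + sigma_log^2 / 2)."""
        return lognormal_mean(self.mu_log, self.sigma_log)


@dataclass(frozen=True)
class TemporalParams:
    """Parameters of the emission pulse.

    delta
        natural log of the delay (days) between application and peak flux
    k
        decay-scale of the pulse (dimensionless, > 0)
    omega
        fraction of applied N emitted as N2O-N as t -> infinity
    sigma_log
        spatial log-scale of plot-to-plot variability
    n_in
        applied fertiliser nitrogen, kg N ha-1
    """

    delta: float
    k: float
    omega: float
    sigma_log: float
    n_in: float = field(default=70.0)

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (np.isfinite(self.omega) and self.omega >= 0):
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if not (np.isfinite(self.sigma_log) and self.sigma_log >= 0):
            raise ValueError(f"sigma_log must be >= 0, got {self.sigma_log}")
        if not (np.isfinite(self.n_in) and self.n_in >= 0):
            raise ValueError(f"n_in must be >= 0, got {self.n_in}")


def lognormal_mean(mu_log, sigma_log):
    """Arithmetic mean of lnN(mu_log, sigma_log^2): exp(mu_log + sigma_log^2/2)."""
    return np.exp(np.asarray(mu_log, dtype=float) + 0.5 * np.square(sigma_log))


def spatial_logpdf(flux, params: SpatialParams):
    """Log of the log-normal spatial density; -inf for flux <= 0."""
    if params.sigma_log <= 0:
        raise ValueError("spatial density requires sigma_log > 0")
    arr = np.asarray(flux, dtype=float)
    scalar = arr.ndim == 0
    f = np.atleast_1d(arr)
    out = np.full(f.shape, -np.inf)
    pos = f > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        lf = np.log(np.where(pos, f, 1.0))
        z = (lf - params.mu_log) / params.sigma_log
        val = -_LOG_SQRT_2PI - math.log(params.sigma_log) - lf - 0.5 * z * z
    out[pos] = val[pos]
    return float(out[0]) if scalar else out


def spatial_pdf(flux, params: SpatialParams):
    """Log-normal spatial probability density; 0 for flux <= 0."""
    with np.errstate(over="ignore"):
        return np.exp(spatial_logpdf(flux, params))


def temporal_mean(t, params: TemporalParams):
    """Spatial-mean emission rate at time t, kg N ha-1 day-1.

    A log-normal pdf in t (location delta, scale k) times n_in * omega,
    so the rate integrates to n_in * omega over (0, inf).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    z = (np.log(t) - params.delta) / params.k
    pdf = np.exp(-0.5 * z * z) / (math.sqrt(2.0 * math.pi) * params.k * t)
    out = pdf * params.n_in * params.omega
    return out if out.shape else float(out)


def mu_log_at_t(t, params: TemporalParams):
    """Location parameter of the flux distribution at time t.

    Chosen so that lnN(mu_log_t, sigma_log^2) has arithmetic mean equal
    to ``temporal_mean(t)``; -inf when the mean rate is zero (degenerate
    point mass at zero flux).
    """
    mt = np.asarray(temporal_mean(t, params), dtype=float)
    with np.errstate(divide="ignore"):
        out = np.log(mt) - 0.5 * params.sigma_log**2
    return out if out.shape else float(out)


def cumulative_flux(t, params: TemporalParams):
    """Cumulative emission to time t, kg N ha-1.

    Closed form Phi((ln t - delta)/k) * n_in * omega; 0 at t = 0,
    monotone, bounded by n_in * omega.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    with np.errstate(divide="ignore"):
        z = np.where(t > 0, (np.log(np.where(t > 0, t, 1.0)) - params.delta) / params.k, -np.inf)
    out = ndtr(z) * params.n_in * params.omega
    return out if out.shape else float(out)


def log_likelihood_arrays(
    days: np.ndarray,
    flux_nmol: np.ndarray,
    params: TemporalParams,
    background_rate: float = 0.0,
    floor_nmol: float = DEFAULT_FLOOR_NMOL,
) -> float:
    """Log-likelihood of plot-level fluxes under the temporal model.

    ``flux_nmol`` are raw chamber fluxes in nmol N2O m-2 s-1, converted
    to kg N ha-1 day-1.  The constant ``background_rate`` (same units)
    enters as a mean offset: at time t the flux is modelled as
    log-normal with arithmetic mean ``temporal_mean(t) +
    background_rate``, which keeps the likelihood well specified when
    the pulse has decayed and only background remains.  Fluxes at or
    below the floor are treated as left-censored at the floor and
    contribute the log-CDF there, keeping the likelihood finite for
    zero or negative measured fluxes.
    """
    days = np.asarray(days, dtype=float)
    flux_nmol = np.asarray(flux_nmol, dtype=float)
    if days.size == 0:
        raise ValueError("empty observation set")
    if np.any(days <= 0):
        raise ValueError("all observation days must be > 0")
    if params.sigma_log <= 0:
        raise ValueError("likelihood requires sigma_log > 0")

    y = flux_nmol * NMOL_M2_S_TO_KGN_HA_DAY
    floor = floor_nmol * NMOL_M2_S_TO_KGN_HA_DAY
    mean_t = np.asarray(temporal_mean(days, params), dtype=float) + background_rate
    with np.errstate(divide="ignore"):
        mu_log_t = np.log(mean_t) - 0.5 * params.sigma_log**2
    sig = params.sigma_log

    censored = y <= floor
    total = 0.0
    if np.any(censored):
        with np.errstate(invalid="ignore"):
            z = (math.log(floor) - mu_log_t[censored]) / sig
        # mu_log_t = -inf (dead pulse) => z = +inf => logCDF = 0
        total += float(np.sum(log_ndtr(np.where(np.isnan(z), np.inf, z))))
    if np.any(~censored):
        ly = np.log(y[~censored])
        with np.errstate(invalid="ignore"):
            z = (ly - mu_log_t[~censored]) / sig
        z = np.where(np.isnan(z), np.inf, z)  # dead pulse, positive obs
        total += float(
            np.sum(-_LOG_SQRT_2PI - math.log(sig) - ly - 0.5 * z * z)
        )
    return total


def log_likelihood(
    observations,
    params: TemporalParams,
    background_rate: float = 0.0,
    floor_nmol: float = DEFAULT_FLOOR_NMOL,
) -> float:
    """Log-likelihood of a long-format observation table.

    ``observations`` is a pandas DataFrame with ``day`` and
    ``flux_nmol_m2_s`` columns (the pipeline's standard long format).
    """
    return log_likelihood_arrays(
        observations["day"].to_numpy(),
        observations["flux_nmol_m2_s"].to_numpy(),
        params,
        background_rate=background_rate,
        floor_nmol=floor_nmol,
    )
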