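"""Diagnostic plots: flux time series with posterior ribbon, pooled EF pdfs."""

from __future__ import annotations

import numpy as np

from .bayes_inference import PosteriorChains
from .lognormal_model import TemporalParams, temporal_mean
from .units import NMOL_M2_S_TO_KGN_HA_DAY


def plot_event_fit(observations, chains: PosteriorChains, ax=None,
                   n_curve_draws: int = 500, background_rate: float | None = None):
    """Observed plot fluxes vs the posterior mean-flux curve with a 95%
    credible ribbon, in field units (nmol N2O m-2 s-1)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.linspace(0.2, chains.window_days, 200)
    flat = chains.flat
    idx = np.linspace(0, len(flat) - 1, min(n_curve_draws, len(flat))).astype(int)
    bg = (background_rate if background_rate is not None
          else chains.background_cumulative / chains.window_days)
    curves = np.empty((idx.size, t.size))
    for i, j in enumerate(idx):
        p = TemporalParams(delta=flat[j, 0], k=flat[j, 1], omega=flat[j, 2],
                           sigma_log=flat[j, 3], n_in=chains.n_in)
        curves[i] = (temporal_mean(t, p) + bg) / NMOL_M2_S_TO_KGN_HA_DAY
    lo, mid, hi = np.percentile(curves, [2.5, 50, 97.5], axis=0)
    ax.fill_between(t, lo, hi, alpha=0.3, label="95% credible interval")
    ax.plot(t, mid, label="posterior median")
    ax.scatter(observations["day"], observations["flux_nmol_m2_s"], s=12,
               color="k", zorder=3, label="chamber fluxes")
    ax.axhline(bg / NMOL_M2_S_TO_KGN_HA_DAY, color="r", ls="--", lw=1,
               label="background")
    ax.set_xlabel("days since application")
    ax.set_ylabel("N2O flux (nmol m$^{-2}$ s$^{-1}$)")
    ax.legend(fontsize=8)
    return ax


def plot_pooled_efs(pooled_by_treatment: dict, ax=None):
    """Overlay pooled posterior EF densities per treatment.

    ``pooled_by_treatment`` maps label -> output of pooled_posterior_pdf.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, pooled in pooled_by_treatment.items():
        ax.plot(pooled["grid"], pooled["density"], label=label)
    ax.set_xlabel("emission factor (% of applied N)")
    ax.set_ylabel("posterior density")
    ax.legend()
    return ax
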