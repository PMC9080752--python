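"""Plot helpers: topographic maps and psychometric curves."""

from __future__ import annotations

import numpy as np

from .psychophysics import PsychometricFit, ThresholdEstimate
from .retinal_topography import DensityMap


def plot_density_map(dmap: DensityMap, ax=None, n_levels: int = 8):
    """Iso-density contour map, labelled in densities ×10³ cells/mm²."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xx, yy = np.meshgrid(dmap.x, dmap.y)
    cs = ax.contour(xx, yy, dmap.density / 1e3, levels=n_levels, colors="black")
    ax.clabel(cs, fmt="%.0f")
    bx, by = dmap.outline.exterior.xy
    ax.plot(bx, by, color="black", lw=1.5)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)  T →")
    ax.set_ylabel("y (mm)  V ↓")
    ax.set_title("density ×10³ cells mm⁻²")
    return ax


def plot_psychometric(fit: PsychometricFit, threshold: ThresholdEstimate | None = None,
                      frequencies=None, proportions=None, ax=None):
    """Fitted curve with optional data points and threshold vertical + CI bar."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if frequencies is not None:
        lo, hi = min(frequencies), max(frequencies)
    else:
        lo, hi = fit.alpha - 3 / abs(fit.beta), fit.alpha + 3 / abs(fit.beta)
    xs = np.linspace(lo, hi, 200)
    ax.plot(xs, fit.psi(xs), color="black")
    if frequencies is not None and proportions is not None:
        ax.plot(frequencies, proportions, "o", color="grey")
    if threshold is not None:
        ax.axvline(threshold.threshold_cpd, ls="--", color="black")
        if threshold.ci_low is not None:
            ax.errorbar([threshold.threshold_cpd], [fit.guess_rate + 0.02],
                        xerr=[[threshold.threshold_cpd - threshold.ci_low],
                              [threshold.ci_high - threshold.threshold_cpd]],
                        fmt="none", color="black", capsize=3)
    ax.set_xlabel("spatial frequency (cpd)")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(fit.guess_rate - 0.05, 1.02)
    return ax
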