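"""Quick-look figures: psychometric functions and model-comparison scatters."""

from __future__ import annotations

import numpy as np

from .bayes_model import ModelFit
from .psychometrics import PsychometricData, PsychometricFit


def plot_psychometric(data: PsychometricData, fit: PsychometricFit | None = None, ax=None):
    """Observed proportions per level with the fitted cumulative Gaussian."""
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(data.levels, data.proportions, "ko", label="data")
    if fit is not None and fit.converged:
        grid = np.linspace(data.levels[0], data.levels[-1], 200)
        ax.plot(grid, norm.cdf((grid - fit.mu) / fit.sigma), "b-",
                label=f"fit: PSE={fit.mu:.2f}, threshold={fit.sigma:.2f}")
        ax.axvline(fit.mu, color="b", ls=":", lw=0.8)
    ax.axhline(0.5, color="gray", ls=":", lw=0.8)
    ax.set_xlabel("test speed (deg/s)")
    ax.set_ylabel('P("test faster")')
    ax.set_ylim(-0.03, 1.03)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_model_comparison(cohort_table, fits: dict[str, ModelFit]):
    """Predicted-vs-measured ratio scatter, one panel per model."""
    import matplotlib.pyplot as plt

    measured = cohort_table["ratio"].to_numpy()
    fig, axes = plt.subplots(1, len(fits), figsize=(4 * len(fits), 3.6),
                             sharex=False, sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (name, fit) in zip(axes, fits.items()):
        ax.plot(fit.predictions, measured, "ko", ms=4)
        lims = [min(fit.predictions.min(), measured.min()) - 0.05,
                max(fit.predictions.max(), measured.max()) + 0.05]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlim(lims); ax.set_ylim(lims)
        ax.set_title(f"{name}\nk={fit.k:.4g}, RMSE={fit.rmse:.3f}, MAD={fit.mad:.3f}",
                     fontsize=9)
        ax.set_xlabel("predicted $V_A/V_B$")
    axes[0].set_ylabel("measured $V_A/V_B$")
    fig.tight_layout()
    return fig
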