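"""Figures for the two analyses: caterpillar plots of posterior presence
probabilities, functional-response curves over the trial data, and parameter
estimates with their 95% intervals."""

from __future__ import annotations

import numpy as np

from .cooccur import PosteriorChains, predictions_table
from .fr_core import FRParams, TrialContext, rogers_expected
from .fr_fit import FRFit, TrialDataset

_CATEGORY_COLORS = {"none": "#1f77b4", "small": "#ff7f0e", "large": "#d62728"}
_CLASS_COLORS = {"small": "#ff7f0e", "large": "#d62728"}


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def caterpillar_plot(chains: PosteriorChains):
    """Posterior presence probability (median, 95% CrI) per species and
    predator category."""
    plt = _plt()
    table = predictions_table(chains)
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(table) + 1.5))
    ypos = np.arange(len(table))[::-1]
    for y, row in zip(ypos, table.itertuples(index=False)):
        color = _CATEGORY_COLORS.get(row.category, "grey")
        ax.plot([row.lower, row.upper], [y, y], color=color, lw=2)
        ax.plot(row.point, y, "o", color=color)
    ax.set_yticks(ypos)
    ax.set_yticklabels([f"{r.species} / {r.category}" for r in table.itertuples(index=False)])
    ax.set_xlabel("posterior probability of prey presence")
    ax.set_xlim(0, 1)
    fig.tight_layout()
    return fig


def response_plot(data: TrialDataset, fits: dict[str, FRFit]):
    """Consumed vs initial prey density with fitted expected-consumption
    curves per predator class."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    durations = {t.duration for t in data}
    T = durations.pop() if len(durations) == 1 else 3.0
    densities = np.arange(1, max(t.n_initial for t in data) + 2)
    for cls, fit in fits.items():
        color = _CLASS_COLORS.get(cls, "grey")
        sub = [t for t in data if t.predator_class == cls]
        jitter = 0.06 if cls == "small" else -0.06
        ax.scatter(
            [t.n_initial + jitter for t in sub],
            [t.n_consumed for t in sub],
            color=color,
            alpha=0.6,
            label=f"{cls} (trials)",
        )
        curve = [
            rogers_expected(TrialContext(n0=int(n), T=T), fit.params_hat)
            for n in densities
        ]
        ax.plot(densities, curve, color=color, label=f"{cls} (fit)")
    ax.set_xlabel("initial prey density")
    ax.set_ylabel(f"prey consumed in {T:g} days")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def estimate_plot(fits: dict[str, FRFit], param: str = "a"):
    """Point estimates with 95% intervals for one parameter across classes."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3))
    for x, (cls, fit) in enumerate(fits.items()):
        color = _CLASS_COLORS.get(cls, "grey")
        est = fit.params_hat.a if param == "a" else fit.params_hat.h
        iv = fit.intervals.get(param)
        if iv is not None:
            ax.plot([x, x], [iv.lower, iv.upper], color=color, lw=2)
        ax.plot(x, est, "o", color=color)
    ax.set_xticks(range(len(fits)))
    ax.set_xticklabels(list(fits))
    label = "attack rate a (day$^{-1}$)" if param == "a" else "handling time h (days)"
    ax.set_ylabel(label)
    fig.tight_layout()
    return fig
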