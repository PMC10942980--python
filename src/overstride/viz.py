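"""Plotting helpers for fitted models and stride tables."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_coefficients", "plot_stride_frequency_trends"]


def plot_coefficients(results, ax=None, skip_intercept=True):
    """Forest plot of fixed-effect estimates with 95% CIs.

    Parameters
    ----------
    results : RandomInterceptResults
    ax : matplotlib axes, optional
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ci = results.conf_int()
    names = [n for n in results.params.index
             if not (skip_intercept and n == "Intercept")]
    y = np.arange(len(names))[::-1]
    for yi, name in zip(y, names):
        ax.plot([ci.loc[name, "lower"], ci.loc[name, "upper"]], [yi, yi],
                color="0.3")
        ax.plot(results.params[name], yi, "o", color="C0")
    ax.axvline(0.0, color="0.8", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(names)
    ax.set_xlabel("standardized coefficient (95% CI)")
    return ax


def plot_stride_frequency_trends(table, metrics=("overstriding_m", "pbf_bw"),
                                 axes=None):
    """Condition-mean trends of stride metrics across treadmill SF levels."""
    import matplotlib.pyplot as plt

    tm = table[table["condition"].str.startswith("TM")]
    if axes is None:
        _, axes = plt.subplots(1, len(metrics),
                               figsize=(4 * len(metrics), 3))
    means = tm.groupby("condition")[list(metrics)].mean().sort_index()
    sf = [float(c.split("SF")[1]) for c in means.index]
    for ax, metric in zip(np.atleast_1d(axes), metrics):
        ax.plot(sf, means[metric], "o-")
        ax.set_xlabel("stride frequency (strides/min)")
        ax.set_ylabel(metric)
    return axes
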