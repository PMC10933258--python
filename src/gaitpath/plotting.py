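"""Diagnostic plots for fitted pipelines."""

from __future__ import annotations

import pandas as pd


def plot_learning_curve(lc: pd.DataFrame, ax=None, label: str = "MV"):
    """Plot a learning curve from :func:`gaitpath.classify.learning_curve_data`.

    Expects columns ``n_samples``, ``score_mean``, ``score_std``; the shaded
    band is one standard deviation across CV folds.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(lc["n_samples"], lc["score_mean"], marker="o", label=label)
    ax.fill_between(lc["n_samples"],
                    lc["score_mean"] - lc["score_std"],
                    lc["score_mean"] + lc["score_std"], alpha=0.2)
    ax.set_xlabel("number of samples")
    ax.set_ylabel("macro balanced accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    return ax


def plot_vote_weights(weights: dict[str, float], ax=None):
    """Bar chart of the soft-voting weights per member model."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.bar(list(weights), list(weights.values()))
    ax.set_ylabel("voting weight")
    ax.set_ylim(0, 1)
    return ax
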