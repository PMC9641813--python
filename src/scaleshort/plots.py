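"""Plots for the D-study projection and item/test information curves."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gpcm import item_information, test_information
from .simulate import ItemBank


def plot_d_study(d_table: pd.DataFrame, ax=None):
    """D-study indices (G, phi, error variances) versus number of items."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(d_table["n_items"], d_table["G"], marker="o", label="G")
    ax.plot(d_table["n_items"], d_table["phi"], marker="s", label=r"$\varphi$")
    ax.plot(d_table["n_items"], d_table["rel_err"], marker="^",
            label=r"$\sigma^2_\delta$ (relative error)")
    ax.plot(d_table["n_items"], d_table["abs_err"], marker="v",
            label=r"$\sigma^2_\Delta$ (absolute error)")
    ax.axhline(0.70, color="grey", lw=0.8, ls="--")
    ax.axhline(0.20, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("number of items")
    ax.set_ylabel("index value")
    ax.legend()
    return ax


def plot_item_information(bank: ItemBank, theta_range=(-3.0, 3.0), ax=None):
    """Item information curves, one line per item."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(*theta_range, 121)
    for it in bank:
        ax.plot(grid, item_information(it, grid), label=it.item_id)
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("item information")
    ax.legend(ncol=2, fontsize="small")
    return ax


def plot_test_information(bank: ItemBank, subsets: dict, theta_range=(-3.0, 3.0), ax=None):
    """Test information curves for named item subsets (e.g. full vs short form)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(*theta_range, 121)
    for label, items in subsets.items():
        ax.plot(grid, test_information(bank, items, grid), label=label)
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("test information")
    ax.legend()
    return ax
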