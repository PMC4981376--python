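"""Tornado and acceptability-curve plots."""
from __future__ import annotations

import pandas as pd


def plot_tornado(tornado_df: pd.DataFrame, ax=None, top: int = 10):
    """Horizontal bar chart of the most influential one-way inputs."""
    import matplotlib.pyplot as plt

    df = tornado_df.dropna(subset=["impact"]).head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    lo = df[["icer_low", "icer_high"]].astype(float).min(axis=1)
    hi = df[["icer_low", "icer_high"]].astype(float).max(axis=1)
    ax.barh(df["input"], hi - lo, left=lo, color="steelblue")
    ax.set_xlabel("ICER (US$ per DALY averted)")
    ax.set_title("One-way sensitivity (tornado)")
    return ax


def plot_ceac(ceac_df: pd.DataFrame, ax=None):
    """Acceptability curves: P(highest net benefit) vs willingness to pay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for col in ceac_df.columns:
        if col == "wtp":
            continue
        ax.plot(ceac_df["wtp"], ceac_df[col], label=col)
    ax.set_xlabel("Willingness to pay (US$ per DALY averted)")
    ax.set_ylabel("Probability highest net benefit")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return ax
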