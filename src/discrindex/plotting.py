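"""Timeline line charts (optional; requires matplotlib)."""

from __future__ import annotations

import pandas as pd

_CONTINENT_COLORS = {
    "Africa": "tab:orange",
    "Asia": "tab:red",
    "Europe": "tab:blue",
    "North America": "tab:green",
    "Oceania": "tab:brown",
    "South America": "tab:purple",
}


def plot_timelines(timeline: pd.DataFrame, ax=None, color_by: str = "continent"):
    """Plot daily discrimination curves, one line per country, colored by
    continent (or any column of the timeline table)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 5))
    for (cc, group), sub in timeline.groupby(["country_code", color_by]):
        sub = sub.sort_values("date")
        ax.plot(sub["date"], sub["value"],
                color=_CONTINENT_COLORS.get(group), label=cc, lw=1)
    ax.set_ylabel("discrimination index")
    ax.set_xlabel("date")
    ax.set_ylim(bottom=0)
    return ax
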