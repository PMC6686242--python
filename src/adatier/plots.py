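"""Figure helpers: exposure-by-visit panels and tumor spider plots."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_exposure", "plot_tumor_spider"]

_GROUP_COLORS = {
    "negative": "0.6",
    "non-TE positive": "tab:blue",
    "TE positive": "tab:red",
}


def plot_exposure(
    exposure: pd.DataFrame, path: Optional[Union[str, Path]] = None
) -> plt.Figure:
    """One panel per regimen: mean concentration per visit by ADA group."""
    regimens = sorted(exposure["regimen"].unique()) if len(exposure) else []
    n = max(1, len(regimens))
    fig, axes = plt.subplots(n, 1, figsize=(7, 3 * n), squeeze=False)
    for ax, regimen in zip(axes.ravel(), regimens or [None]):
        if regimen is None:
            continue
        sub = exposure[exposure["regimen"] == regimen]
        for group, g in sub.groupby("ada_group"):
            order = g.sort_values("visit_label")
            ax.plot(
                order["visit_label"],
                order["mean_conc"],
                marker="o",
                label=group,
                color=_GROUP_COLORS.get(group),
            )
        ax.set_title(regimen)
        ax.set_ylabel("concentration (µg/mL)")
        ax.set_yscale("log")
        ax.tick_params(axis="x", rotation=45)
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_tumor_spider(
    series: pd.DataFrame,
    per_patient: pd.DataFrame,
    path: Optional[Union[str, Path]] = None,
) -> plt.Figure:
    """Longitudinal percent tumor-size change, colored by ADA group."""
    fig, ax = plt.subplots(figsize=(7, 5))
    groups = dict(zip(per_patient["patient_id"], per_patient["ada_group"]))
    for pid, g in series.groupby("patient_id"):
        group = groups.get(pid, "negative")
        ordered = g.sort_values("time_days")
        ax.plot(
            ordered["time_days"],
            ordered["change_pct"],
            color=_GROUP_COLORS.get(group, "0.6"),
            alpha=0.3 if group == "negative" else 0.9,
            lw=0.8 if group == "negative" else 1.6,
        )
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("days since first dose")
    ax.set_ylabel("change in tumor size from baseline (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
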