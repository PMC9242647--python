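"""Figure-style QC plots of PM-index series."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["PanelSpec", "plot_series"]


class ReportingError(ValueError):
    pass


def _hms(seconds: float, _pos=None) -> str:
    seconds = int(round(seconds))
    return f"{seconds // 3600}:{seconds % 3600 // 60:02d}:{seconds % 60:02d}"


@dataclass
class PanelSpec:
    """Selection and styling for one time-course panel.

    ``y_convention`` chooses the plotted column: ``norm_pm_index`` for
    normalized panels, ``pm_index`` for plain ones. ``aggregate`` draws a
    mean +/- spread band per channel instead of per-ROI traces.
    """

    channels: list[str] = field(default_factory=list)
    rois: list[str] = field(default_factory=list)
    y_convention: str = "norm_pm_index"     # norm_pm_index | pm_index
    event_times_s: list[float] = field(default_factory=list)
    event_labels: list[str] = field(default_factory=list)
    aggregate: bool = False
    spread: str = "sd"                       # sd | sem
    title: str = ""


def plot_series(table: pd.DataFrame, panel: PanelSpec, out_path: str | Path) -> Path:
    """Render selected series to an image file; never mutates ``table``.

    Time is ticked in h:min:sec. Deterministic: identical inputs produce
    byte-identical files.
    """
    if panel.y_convention not in {"norm_pm_index", "pm_index"}:
        raise ValueError(f"unknown y_convention {panel.y_convention!r}")
    sel = table
    if panel.channels:
        sel = sel[sel["channel"].isin(panel.channels)]
    if panel.rois:
        sel = sel[sel["roi"].isin(panel.rois)]
    sel = sel[np.isfinite(sel[panel.y_convention])]
    if sel.empty:
        raise ReportingError("panel selection matched no valid series")

    fig, ax = plt.subplots(figsize=(6, 4))
    for channel, by_ch in sel.groupby("channel", sort=True):
        if panel.aggregate:
            g = by_ch.groupby("time_s")[panel.y_convention]
            mean = g.mean()
            spread = g.std(ddof=1) if panel.spread == "sd" else g.sem(ddof=1)
            spread = spread.fillna(0.0)
            ax.plot(mean.index, mean.values, label=channel)
            ax.fill_between(mean.index, mean - spread, mean + spread, alpha=0.25)
        else:
            for roi, tr in by_ch.groupby("roi", sort=True):
                tr = tr.sort_values("time_s")
                ax.plot(tr["time_s"], tr[panel.y_convention],
                        label=f"{channel}/{roi}", lw=0.9)
    for i, t_ev in enumerate(panel.event_times_s):
        ax.axvline(t_ev, color="0.4", ls="--", lw=0.8)
        if i < len(panel.event_labels):
            ax.annotate(panel.event_labels[i], (t_ev, ax.get_ylim()[1]),
                        ha="left", va="top", fontsize=8, rotation=90)
    ax.xaxis.set_major_formatter(matplotlib.ticker.FuncFormatter(_hms))
    ax.set_xlabel("time (h:min:s)")
    ax.set_ylabel("Normalized PM Index" if panel.y_convention == "norm_pm_index"
                  else "PM Index")
    if panel.title:
        ax.set_title(panel.title)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, metadata=_deterministic_metadata(out_path))
    plt.close(fig)
    return out_path


def _deterministic_metadata(path: Path) -> dict | None:
    suffix = path.suffix.lower()
    if suffix == ".png":
        return {"Software": "pmindex"}
    if suffix == ".svg":
        return {"Date": None}
    return None
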