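"""Optional plain plot export (requires matplotlib).

One figure style: observed discrimination performance against test
concentration with both fitted models overlaid.  Plots are a convenience
layer; every figure's underlying numbers are also written as CSV so no
analysis result depends on an image.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .choice_data import PerformanceRecord
from .fitting import FitResult
from .psychometric import predict_performance


def performance_plot_table(
    records: Sequence[PerformanceRecord],
    fits: dict[str, FitResult],
    standard: float = 20.0,
    n_grid: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed points and fitted curves as DataFrames (the plot's data)."""
    obs = pd.DataFrame(
        {
            "test_conc": [r.x if r.a == standard else r.a for r in records],
            "performance": [r.performance for r in records],
            "n_total": [r.n_total for r in records],
        }
    )
    lo = min(obs["test_conc"].min(), standard) * 0.9
    hi = max(obs["test_conc"].max(), standard) * 1.05
    grid = np.linspace(lo, hi, n_grid)
    curves = {"test_conc": grid}
    for name, fit in fits.items():
        curves[name] = [predict_performance(x, standard, fit.params) for x in grid]
    return obs, pd.DataFrame(curves)


def save_performance_plot(
    records: Sequence[PerformanceRecord],
    fits: dict[str, FitResult],
    path: str | Path,
    standard: float = 20.0,
    title: str = "",
) -> None:
    """Write <path>.png and the matching <path>.csv pair."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs, curves = performance_plot_table(records, fits, standard)
    path = Path(path)
    obs.to_csv(path.with_suffix(".points.csv"), index=False)
    curves.to_csv(path.with_suffix(".curves.csv"), index=False)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(obs["test_conc"], obs["performance"], "ko", label="observed")
    styles = ["-", "-.", "--", ":"]
    for style, name in zip(styles, [c for c in curves.columns if c != "test_conc"]):
        ax.plot(curves["test_conc"], curves[name], style, label=name)
    ax.axvline(standard, linestyle="--", color="grey", linewidth=0.8)
    ax.axhline(0.5, linestyle=":", color="grey", linewidth=0.8)
    ax.set_xlabel("test concentration (% w/w)")
    ax.set_ylabel("discrimination performance")
    ax.set_ylim(0.0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path.with_suffix(".png"), dpi=150)
    plt.close(fig)
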