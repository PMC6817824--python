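"""Cross-replicate summaries: mean and quartile bands, survival assembly, plots.

Replicate metric tables are aligned on their time grid and summarized per
metric by the mean and the first/third quartiles (linear-interpolation
quartile convention).  Contact times across replicates assemble into the
empirical time-to-food survival curve.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pipeline import contact_time_from_table
from .spots import SurvivalCurve, survival_curve

__all__ = ["summarize_replicates", "assemble_survival", "plot_summary"]

_META_COLS = {"frame", "time_min"}


def summarize_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-time mean, Q1 and Q3 across replicates for every metric column.

    All replicates must share the same time grid.  Quartiles use linear
    interpolation between order statistics.
    """
    if len(tables) == 0:
        raise ValueError("no replicate tables")
    t0 = tables[0]["time_min"].to_numpy()
    for i, df in enumerate(tables[1:], start=1):
        if not np.array_equal(df["time_min"].to_numpy(), t0):
            raise ValueError(f"replicate {i} has an inconsistent time grid")
    cols = [c for c in tables[0].columns
            if c not in _META_COLS and pd.api.types.is_numeric_dtype(tables[0][c])]
    out = {"time_min": t0}
    for c in cols:
        stack = np.stack([df[c].to_numpy(dtype=float) for df in tables])
        out[f"{c}_mean"] = np.nanmean(stack, axis=0)
        out[f"{c}_q1"] = np.nanquantile(stack, 0.25, axis=0)
        out[f"{c}_q3"] = np.nanquantile(stack, 0.75, axis=0)
    return pd.DataFrame(out)


def assemble_survival(
    tables: Sequence[pd.DataFrame], threshold_mm: float = 0.0
) -> SurvivalCurve:
    """Empirical time-to-food curve from the replicates' distance columns."""
    times, cens = [], []
    for df in tables:
        t, c = contact_time_from_table(df, threshold_mm)
        times.append(t)
        cens.append(c)
    horizon = max(float(df["time_min"].iloc[-1]) for df in tables)
    return survival_curve(times, cens, horizon_min=horizon)


def plot_summary(summary: pd.DataFrame, out_dir: str | Path,
                 metrics: Sequence[str] | None = None) -> list[Path]:
    """Mean curves with Q1-Q3 bands, one PNG per metric."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if metrics is None:
        metrics = sorted({c[:-5] for c in summary.columns if c.endswith("_mean")})
    t = summary["time_min"] / 60.0
    paths = []
    for m in metrics:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(t, summary[f"{m}_mean"], lw=1.5)
        ax.fill_between(t, summary[f"{m}_q1"], summary[f"{m}_q3"], alpha=0.3)
        ax.set_xlabel("time (h)")
        ax.set_ylabel(m.replace("_", " "))
        fig.tight_layout()
        p = out / f"{m}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
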