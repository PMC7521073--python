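"""Figure and summary generation from experiment result CSVs.

Report generation is a pure function of the records CSV — nothing is
retrained here.  Curves show the per-epoch mean across replicates with a
shaded min–max band, one line per condition: test accuracy versus epoch,
and training/test loss versus epoch with an optional zoomed panel of the
first epochs where early-learning differences between dropout doses are
visible.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["load_records", "plot_curves", "summary_table"]

REQUIRED_COLUMNS = ["condition", "replicate", "epoch",
                    "train_loss", "test_loss", "test_accuracy"]


class ReportError(ValueError):
    """Raised for malformed or empty result files."""


def load_records(path: str) -> pd.DataFrame:
    """Read and validate a records CSV."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ReportError(f"{path}: empty results file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ReportError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ReportError(f"{path}: no data rows")
    bad = df[df["test_accuracy"].isna() | (df["test_accuracy"] < 0)
             | (df["test_accuracy"] > 1)]
    if not bad.empty:
        raise ReportError(
            f"{path}: invalid test_accuracy at row {int(bad.index[0])}"
        )
    return df


def _mean_band(df: pd.DataFrame, metric: str):
    g = df.groupby(["condition", "epoch"])[metric]
    return g.mean().unstack(0), g.min().unstack(0), g.max().unstack(0)


def plot_curves(df: pd.DataFrame, metric: str, out_path: str,
                title: str | None = None, zoom_epochs: int | None = None,
                ) -> None:
    """Plot mean ± (min, max) curves per condition for one metric.

    ``zoom_epochs`` adds a side panel restricted to the first N epochs.
    """
    mean, lo, hi = _mean_band(df, metric)
    n_panels = 2 if zoom_epochs else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(6 * n_panels, 4.2),
                             squeeze=False)
    for ax, limit in zip(axes[0], (None, zoom_epochs)):
        for cond in mean.columns:
            m = mean[cond] if limit is None else mean[cond].iloc[:limit]
            ax.plot(m.index, m.values, label=cond)
            l = (lo[cond] if limit is None else lo[cond].iloc[:limit])
            h = (hi[cond] if limit is None else hi[cond].iloc[:limit])
            ax.fill_between(m.index, l.values, h.values, alpha=0.2)
        ax.set_xlabel("epoch")
        ax.set_ylabel(metric.replace("_", " "))
        if limit is not None:
            ax.set_title(f"first {limit} epochs")
    axes[0][0].legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def summary_table(df: pd.DataFrame) -> pd.DataFrame:
    """Final-epoch mean and across-replicate range per condition."""
    last = df[df["epoch"] == df["epoch"].max()]
    rows = []
    for cond, grp in last.groupby("condition"):
        row = {"condition": cond, "n_replicates": len(grp)}
        for metric in ("test_accuracy", "train_loss", "test_loss"):
            row[f"{metric}_mean"] = grp[metric].mean()
            row[f"{metric}_min"] = grp[metric].min()
            row[f"{metric}_max"] = grp[metric].max()
        rows.append(row)
    return pd.DataFrame(rows)
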