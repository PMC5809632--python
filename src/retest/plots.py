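"""Optional figure generation (matplotlib imported lazily so the
numeric pipeline carries no plotting dependency).

Two figure families: Bland-Altman scatter with bias and limits of
agreement, and cross-dataset strip panels where each point is one
region's value of a metric for a given dataset/method.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bland_altman import BlandAltmanSummary

__all__ = ["plot_bland_altman", "plot_metric_panel"]


def _get_pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_bland_altman(
    summary: BlandAltmanSummary, path: str | Path, title: str | None = None
) -> Path:
    """Scatter of per-subject (mean, difference) with bias and limits."""
    plt = _get_pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(summary.means, summary.differences, color="k", zorder=3)
    ax.axhline(summary.bias, color="C0", label=f"bias = {summary.bias:.3g}")
    for lim, lab in (
        (summary.loa_lower, "lower limit"),
        (summary.loa_upper, "upper limit"),
    ):
        ax.axhline(lim, color="C3", linestyle="--", label=f"{lab} = {lim:.3g}")
    ax.set_xlabel("pair mean")
    ax.set_ylabel(f"difference ({summary.sign_convention})")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_metric_panel(
    report: pd.DataFrame, metric: str, path: str | Path
) -> Path:
    """Strip panel of one metric across datasets, one point per region,
    methods dodged within each dataset."""
    plt = _get_pyplot()
    datasets = sorted(report["dataset_id"].astype(str).unique())
    methods = sorted(report["method_id"].astype(str).unique())
    fig, ax = plt.subplots(figsize=(1.6 * max(len(datasets), 3), 4))
    width = 0.8 / max(len(methods), 1)
    for mi, method in enumerate(methods):
        sub = report[report["method_id"].astype(str) == method]
        for di, ds in enumerate(datasets):
            vals = sub.loc[sub["dataset_id"].astype(str) == ds, metric].dropna()
            if len(vals) == 0:
                continue
            x = di + (mi - (len(methods) - 1) / 2) * width
            jitter = (np.arange(len(vals)) - (len(vals) - 1) / 2) * 0.004
            ax.plot(
                np.full(len(vals), x) + jitter,
                vals,
                "o",
                ms=4,
                color=f"C{mi}",
                label=method if di == 0 else None,
            )
    ax.set_xticks(range(len(datasets)))
    ax.set_xticklabels(datasets)
    ax.set_ylabel(metric)
    ax.legend(title="method", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
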