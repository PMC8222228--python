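"""Plots: SEP-set means with per-time confidence whiskers, per-gene
grouped summaries, and the joint peak-time bubble matrix."""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data_model import GeneAnnotation
from .sep_core import SEP
from .sep_sets import PeakMatrix, SEPSet, sep_set_summary

__all__ = ["plot_sep_sets", "plot_peak_matrix", "gene_summary", "plot_gene_summary"]

_DEFAULT_COLORS = ("tab:red", "tab:blue", "tab:gray", "tab:green", "tab:orange")


def plot_sep_sets(
    sets: list[SEPSet],
    colors: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Mean SEP per set over the time grid with t-based CI whiskers."""
    if not sets:
        raise ValueError("no SEP sets to plot")
    colors = colors or _DEFAULT_COLORS
    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 4.5))
    for i, s in enumerate(sets):
        summ = sep_set_summary(s, alpha=alpha)
        c = colors[i % len(colors)]
        ax.plot(summ["time"], summ["mean"], "-o", color=c, label=f"{s.label} (k={s.k})")
        ax.vlines(summ["time"], summ["ci_low"], summ["ci_high"], color=c, lw=1)
    ax.set_xlabel("time")
    ax.set_ylabel("mean standardized expression")
    ax.axhline(0.0, color="0.8", lw=0.8, zorder=0)
    ax.legend(frameon=False)
    return ax


def plot_peak_matrix(pm: PeakMatrix, ax: plt.Axes | None = None) -> plt.Axes:
    """Bubble matrix of joint peak-time percentages for two accessions."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 6))
    pct = pm.percentages
    for ta in pm.times:
        for tb in pm.times:
            v = float(pct.loc[ta, tb])
            if v > 0:
                ax.scatter(ta, tb, s=40 * v, color="tab:purple", alpha=0.6)
                ax.annotate(f"{v:.2f}", (ta, tb), fontsize=7, ha="center", va="bottom")
    ax.plot(pm.times, pm.times, "--", color="tab:green", lw=1)
    ax.set_xlabel(f"peak time in {pm.acc_a}")
    ax.set_ylabel(f"peak time in {pm.acc_b}")
    ax.set_title(f"{pm.total_genes} shared genes")
    return ax


def gene_summary(
    gene_id: str, store: list[SEP], annot: GeneAnnotation | None = None
) -> dict:
    """Numeric summary of one gene's SEPs grouped by accession type.

    Returns the per-type mean profile, each member's model and peak time,
    and the overall mean profile.
    """
    mine = [s for s in store if s.gene_id == gene_id]
    if not mine:
        raise KeyError(f"gene {gene_id!r} has no SEP in the store")
    if len({s.acc_key for s in mine}) == 1:
        warnings.warn(f"gene {gene_id!r} found in a single accession only", stacklevel=2)
    times = mine[0].times
    by_type: dict[str, np.ndarray] = {}
    for typ in sorted({s.acc_type for s in mine}):
        vals = np.vstack([s.values for s in mine if s.acc_type == typ])
        by_type[typ] = vals.mean(axis=0)
    members = pd.DataFrame(
        {
            "acc_key": [s.acc_key for s in mine],
            "acc_type": [s.acc_type for s in mine],
            "model": [s.model for s in mine],
            "time_max_exp": [s.time_max_exp for s in mine],
        }
    )
    out = {
        "gene_id": gene_id,
        "times": times,
        "group_means": by_type,
        "overall_mean": np.vstack([s.values for s in mine]).mean(axis=0),
        "members": members,
    }
    if annot is not None and gene_id in annot.table.index:
        out["descr"] = str(annot.table.loc[gene_id, "descr"])
    return out


def plot_gene_summary(summary: dict, ax: plt.Axes | None = None) -> plt.Axes:
    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 4.5))
    times = summary["times"]
    for typ, mean in summary["group_means"].items():
        ax.plot(times, mean, "-o", label=f"type {typ}")
    ax.plot(times, summary["overall_mean"], "--", color="black", label="overall")
    ax.set_xlabel("time")
    ax.set_ylabel("mean standardized expression")
    title = summary.get("descr", summary["gene_id"])
    ax.set_title(f"{summary['gene_id']}: {title}" if "descr" in summary else summary["gene_id"])
    ax.legend(frameon=False)
    return ax
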