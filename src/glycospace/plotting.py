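"""Figures for the pipeline outputs: RMSD distributions, cumulative
p-value fraction curves, GDT charts and substructure similarity profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_CLASS_COLORS = {"homologous": "tab:red", "non_homologous": "tab:blue", "background": "black"}
_GDT_COLORS = ["#1a9641", "#a6d96a", "#fdae61", "#f46d43", "#d7191c"]


def rmsd_distribution_figure(report, ax=None):
    """Histogram of pair RMSDs by class against the random background."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    table = report.pair_table()
    bg = np.concatenate([t.backgrounds["rmsd"] for t in report.topologies.values()])
    bins = np.linspace(0, max(bg.max(), table.rmsd.max()) * 1.05, 40)
    for label in ("homologous", "non_homologous"):
        sub = table[table.label == label]
        if len(sub):
            ax.hist(sub.rmsd, bins=bins, density=True, histtype="step",
                    color=_CLASS_COLORS[label], label=label.replace("_", "-"))
    ax.hist(bg, bins=bins, density=True, histtype="step",
            color=_CLASS_COLORS["background"], label="random background")
    ax.set_xlabel("RMSD (Å)")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    return ax


def cumulative_fraction_figure(report, measure="p_rmsd", ax=None):
    """Cumulative fraction of pairs below each p-value threshold, by
    class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    table = report.pair_table()
    for label in ("homologous", "non_homologous"):
        sub = table[table.label == label]
        if len(sub):
            p = np.sort(sub[measure].to_numpy())
            ax.step(p, np.arange(1, p.size + 1) / p.size,
                    color=_CLASS_COLORS[label], label=label.replace("_", "-"))
    ax.axvline(0.05, ls=":", color="gray", lw=0.8)
    ax.set_xlabel("p-value")
    ax.set_ylabel("cumulative fraction")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    return ax


def gdt_chart_figure(chart, ax=None):
    """GDT chart: one horizontal bar per pair, ring atoms in chain order
    (1->6 branch last), coloured by deviation bin."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bins = chart["bins"]
    n_pairs, n_atoms = bins.shape
    order = np.argsort(bins.mean(axis=1))
    img = bins[order]
    cmap = matplotlib.colors.ListedColormap(_GDT_COLORS)
    ax.imshow(img, aspect="auto", cmap=cmap, vmin=0, vmax=4, interpolation="nearest")
    edge = np.flatnonzero(chart["one_six_mask"])
    if edge.size:
        ax.axvline(edge[0] - 0.5, color="red", ls="--", lw=1.0)
    ax.set_xlabel("ring atom (1→6 branch right of dashed line)")
    ax.set_ylabel("structure pair")
    return ax


def substructure_profile_figure(report, ax=None):
    """Mean substructure RMSD against residue distance, by class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    table = report.pair_table()
    names = [c for c in table.columns if c.startswith("sub_") and c.endswith("_rmsd")]
    for label in ("homologous", "non_homologous"):
        sub = table[table.label == label]
        if not len(sub):
            continue
        xs, ys = [], []
        for name in sorted(names):
            d = int(name.split("_")[1][1])
            if "no16" in name:
                continue
            xs.append(d)
            ys.append(sub[name].mean())
        xs.append(max(xs) + 1)
        ys.append(sub.rmsd.mean())  # full glycan as the rightmost point
        ax.plot(xs, ys, "o-", color=_CLASS_COLORS[label], label=label.replace("_", "-"))
    ax.set_xlabel("residue distance from Asn")
    ax.set_ylabel("mean substructure RMSD (Å)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def save_report_figures(report, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, fn in (
        ("rmsd_distributions", rmsd_distribution_figure),
        ("cumulative_fraction", cumulative_fraction_figure),
        ("substructure_profile", substructure_profile_figure),
    ):
        ax = fn(report)
        ax.figure.savefig(out / f"{name}.png", dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    for topo, tr in report.topologies.items():
        if tr.gdt_chart is not None:
            ax = gdt_chart_figure(tr.gdt_chart)
            safe = "".join(ch if ch.isalnum() else "_" for ch in topo)[:40]
            ax.figure.savefig(out / f"gdt_chart_{safe}.png", dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
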