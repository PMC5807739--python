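"""Optional static plots of the three report tables.

Rendering failures degrade to a logged warning and never abort a run; the
tables themselves are the primary output and feed any plotting front-end.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COLOR_MAP = {"green": "#2ca02c", "red": "#d62728", "yellow": "#e6b800"}


def composition_barplot(composition_long: pd.DataFrame, path: Path) -> None:
    """Stacked per-species bars of whole-proteome amino-acid percentages."""
    df = composition_long[composition_long["feature_class"] == "proteome"]
    if df.empty:
        df = composition_long
    pivot = df.pivot_table(
        index="species", columns="amino_acid", values="percentage"
    ).fillna(0.0)
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(pivot)), 5))
    bottom = np.zeros(len(pivot))
    cmap = plt.get_cmap("tab20")
    for i, aa in enumerate(pivot.columns):
        ax.bar(pivot.index, pivot[aa], bottom=bottom, label=aa, color=cmap(i % 20))
        bottom += pivot[aa].to_numpy()
    ax.set_ylabel("amino acid usage (%)")
    ax.legend(ncol=2, fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def linker_domain_scatter(pairwise_usage: pd.DataFrame, path: Path) -> None:
    """Linker-vs-domain usage scatter with bisect and twofold guide lines."""
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ax.scatter(
        pairwise_usage["pct_domain"], pairwise_usage["pct_linker"], s=12, alpha=0.6
    )
    hi = 1.05 * max(
        pairwise_usage["pct_domain"].max(), pairwise_usage["pct_linker"].max()
    )
    xs = np.linspace(0, hi, 50)
    ax.plot(xs, xs, "k--", lw=1)            # bisect
    ax.plot(xs, 2 * xs, "--", color="grey", lw=1)   # twice in linkers
    ax.plot(xs, xs / 2, "--", color="grey", lw=1)   # twice in domains
    ax.set_xlim(0, hi)
    ax.set_ylim(0, hi)
    ax.set_xlabel("usage in domains (%)")
    ax.set_ylabel("usage in linkers (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def feature_background_dotplot(dotplot_data: pd.DataFrame, path: Path) -> None:
    """Per-amino-acid feature-vs-background dots, colored by match-count warning."""
    features = sorted(dotplot_data["feature"].unique())
    fig, axes = plt.subplots(
        1, len(features), figsize=(6 * len(features), 5), squeeze=False
    )
    for ax, feature in zip(axes[0], features):
        sub = dotplot_data[dotplot_data["feature"] == feature]
        for color_name, grp in sub.groupby("color"):
            ax.scatter(
                grp["background_pct"],
                grp["feature_pct"],
                s=14,
                color=_COLOR_MAP.get(color_name, "grey"),
                label=color_name,
                alpha=0.7,
            )
        hi = 1.05 * max(sub["background_pct"].max(), sub["feature_pct"].max())
        xs = np.linspace(0, hi, 10)
        ax.plot(xs, xs, "k--", lw=1)
        ax.set_title(feature)
        ax.set_xlabel("background (%)")
        ax.set_ylabel("selected feature (%)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_plots(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Render whichever plots the available tables support; never raises."""
    out_dir = Path(out_dir)
    written: list[Path] = []
    jobs = [
        ("composition_long", composition_barplot, "composition_bars.png"),
        ("pairwise_usage", linker_domain_scatter, "linker_vs_domain.png"),
        ("dotplot_data", feature_background_dotplot, "feature_vs_background.png"),
    ]
    for table_name, fn, filename in jobs:
        table = tables.get(table_name)
        if table is None:
            continue
        if len(table) == 0:
            logger.warning("table %s is empty; skipping plot %s", table_name, filename)
            continue
        target = out_dir / filename
        try:
            fn(table, target)
            written.append(target)
        except Exception as exc:  # plotting must never fail a run
            logger.warning("could not render %s: %s", filename, exc)
    return written
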