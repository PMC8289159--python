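"""Static figure export: CNV heatmap, embedding scatter, composition bars,
Kaplan-Meier curves.  Visualization only — no analysis happens here."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def cnv_heatmap(arm, labels, path: Path) -> None:
    order = np.argsort(labels.values.astype(str), kind="stable")
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(arm.arm_score.values[order], aspect="auto", cmap="RdBu_r",
                   vmin=-0.5, vmax=0.5)
    ax.set_xticks(range(len(arm.arms)))
    ax.set_xticklabels(arm.arms, rotation=90, fontsize=5)
    ax.set_ylabel("cells (grouped by CNV subgroup)")
    fig.colorbar(im, label="arm score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def embedding_scatter(coords: pd.DataFrame, labels, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in pd.unique(labels):
        sel = labels.values == lab
        ax.scatter(coords.values[sel, 0], coords.values[sel, 1], s=6, label=str(lab))
    ax.legend(fontsize=6, markerscale=2, ncol=2)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def composition_bars(comp: pd.DataFrame, path: Path, variable: str = "cell_type") -> None:
    block = comp[comp["variable"] == variable]
    pivot = block.pivot_table(index="sector", columns="value", values="fraction",
                              fill_value=0.0)
    ax = pivot.plot(kind="bar", stacked=True, figsize=(8, 4), width=0.85)
    ax.set_ylabel("fraction")
    ax.legend(fontsize=6, ncol=2)
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_curves(km_tables: dict[str, pd.DataFrame], path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, tbl in km_tables.items():
        ax.step(tbl["time"], tbl["survival"], where="post", label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_all(out: Path, arm, subgroups, coords, clusters, comp, surv_res) -> None:
    cnv_heatmap(arm, subgroups, out / "fig_cnv_heatmap.png")
    embedding_scatter(coords, clusters, out / "fig_embedding.png")
    composition_bars(comp, out / "fig_composition.png")
    km_curves(surv_res.km_tables, out / "fig_km.png")
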