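"""Report rendering: assemblage heatmaps, proportion heatmaps, association maps.

Every figure is written alongside a CSV twin holding exactly the plotted
numbers, so results are regenerable and machine-readable without the figures.
Taxa are ordered lexicographically by taxonomic label by default; a
user-supplied Newick tree (tip order) may override the ordering for display.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data import TaxonomyTable
from .posterior import PosteriorEnsemble, association_map

__all__ = ["otu_display_order", "render_reports"]


def otu_display_order(otu_ids, taxonomy: TaxonomyTable | None = None,
                      newick_path=None) -> list:
    """Display order of OTUs: Newick tip order if given, else by taxonomy."""
    otu_ids = [str(o) for o in otu_ids]
    if newick_path is not None:
        import io
        from Bio import Phylo

        tree = Phylo.read(str(newick_path), "newick")
        tips = [t.name for t in tree.get_terminals() if t.name in set(otu_ids)]
        rest = [o for o in otu_ids if o not in set(tips)]
        return tips + rest
    if taxonomy is not None:
        return sorted(otu_ids, key=lambda o: (taxonomy.label(o), o))
    return otu_ids


def _heatmap(ax, data, xticks, yticks, cmap="viridis", vmax=None):
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmax=vmax)
    ax.set_xticks(range(len(xticks)))
    ax.set_xticklabels(xticks, rotation=90, fontsize=6)
    ax.set_yticks(range(len(yticks)))
    ax.set_yticklabels(yticks, fontsize=6)
    return im


def render_reports(ens: PosteriorEnsemble, taxonomy: TaxonomyTable | None,
                   outdir, anchors=None, min_edge: float = 0.01,
                   newick_path=None) -> dict:
    """Write the three standard visualizations plus their CSV twins.

    1. assemblage OTU-frequency heatmap (taxa in display order),
    2. assemblage-proportion heatmap over subjects and time with the Bayes
       factor table for perturbation effects,
    3. per-anchor association maps (edges with score < ``min_edge`` hidden).

    Returns a manifest {artifact name: path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    otus = [str(o) for o in ens.otu_ids]
    order = otu_display_order(otus, taxonomy, newick_path)
    if taxonomy is not None:
        missing = [o for o in otus if str(o) not in taxonomy.labels]
        if missing:
            import warnings

            warnings.warn(f"no taxonomy for {len(missing)} OTUs; using ids as labels")
    labels = [taxonomy.label(o) if taxonomy else o for o in order]
    col = [otus.index(o) for o in order]
    names = [f"A{int(k)}" for k in ens.retained]

    theta_df = pd.DataFrame(ens.theta[:, col].T, index=labels, columns=names)
    theta_csv = outdir / "assemblages.csv"
    theta_df.to_csv(theta_csv)
    fig, ax = plt.subplots(figsize=(max(4, len(names) * 0.3), max(4, len(order) * 0.12)))
    _heatmap(ax, theta_df.to_numpy(), names, labels)
    fig.tight_layout()
    fig.savefig(outdir / "assemblages.pdf")
    plt.close(fig)
    manifest["assemblages"] = str(outdir / "assemblages.pdf")
    manifest["assemblages_csv"] = str(theta_csv)

    rows = []
    for si, s in enumerate(ens.subjects):
        for ti, t in enumerate(ens.timepoints):
            for ki, name in enumerate(names):
                rows.append({"subject": str(s), "time": float(t),
                             "assemblage": name,
                             "proportion": float(ens.beta_mean[si, ti, ki])})
    beta_df = pd.DataFrame(rows)
    beta_csv = outdir / "proportions.csv"
    beta_df.to_csv(beta_csv, index=False)
    bf_csv = outdir / "bayes_factors.csv"
    ens.bf_table().to_csv(bf_csv, index=False)
    S = len(ens.subjects)
    fig, axes = plt.subplots(1, S, figsize=(3 * S + 1, max(3, len(names) * 0.25)),
                             squeeze=False)
    for si, s in enumerate(ens.subjects):
        mat = ens.beta_mean[si].T  # (K, T)
        _heatmap(axes[0][si], mat, [f"{t:g}" for t in ens.timepoints], names)
        axes[0][si].set_title(str(s), fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "proportions.pdf")
    plt.close(fig)
    manifest["proportions"] = str(outdir / "proportions.pdf")
    manifest["proportions_csv"] = str(beta_csv)
    manifest["bayes_factors_csv"] = str(bf_csv)

    for anchor in anchors or []:
        edges = association_map(ens, anchor, min_edge=min_edge)
        stem = f"association_{anchor}"
        edges.to_csv(outdir / f"{stem}.csv", index=False)
        fig, ax = plt.subplots(figsize=(5, 5))
        n = len(edges)
        ax.scatter([0], [0], s=300, c="tab:red", zorder=3)
        ax.annotate(str(anchor), (0, 0), ha="center", fontsize=8, zorder=4)
        for i, row in edges.iterrows():
            ang = 2 * np.pi * i / max(n, 1)
            xy = (np.cos(ang), np.sin(ang))
            ax.plot([0, xy[0]], [0, xy[1]], lw=row.alpha * 20, c="gray", zorder=1)
            ax.scatter(*xy, s=100 + 2000 * row.partner_abundance, c="tab:blue", zorder=2)
            ax.annotate(row.partner, xy, ha="center", fontsize=6, zorder=4)
        ax.set_axis_off()
        fig.savefig(outdir / f"{stem}.pdf")
        plt.close(fig)
        manifest[stem] = str(outdir / f"{stem}.pdf")
        manifest[f"{stem}_csv"] = str(outdir / f"{stem}.csv")
    return manifest
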