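"""Score plots with confidence ellipses, oblique-axis plots and spider
diagrams of loading signatures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .decompose import inter_axis_angle, oblique_scores
from .evaluate import confidence_ellipse

_COLOURS = plt.cm.tab10.colors


def score_plot(scores2d, labels, ax=None, title="", ellipse_level=0.95):
    """2-D score scatter coloured by cluster, with chi-square confidence
    ellipses where a cluster has enough points."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    scores2d = np.asarray(scores2d)
    labels = np.asarray(labels)
    for idx, lab in enumerate(pd.unique(labels)):
        pts = scores2d[labels == lab]
        colour = _COLOURS[idx % len(_COLOURS)]
        ax.scatter(pts[:, 0], pts[:, 1], s=24, color=colour, label=str(lab))
        if len(pts) >= 3:
            ell = confidence_ellipse(pts, ellipse_level)
            if not ell.degenerate:
                t = np.linspace(0, 2 * np.pi, 200)
                circ = np.column_stack(
                    [ell.semi_axes[0] * np.cos(t), ell.semi_axes[1] * np.sin(t)]
                )
                ang = np.radians(ell.rotation_deg)
                rot = np.array(
                    [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
                )
                path = circ @ rot.T + ell.center
                ax.plot(path[:, 0], path[:, 1], color=colour, lw=1, alpha=0.7)
    ax.set_title(title)
    ax.legend(fontsize=7)
    return ax


def oblique_score_plot(decomposition, comp_pair, labels, ax=None, title=""):
    """NMF scores of two non-orthogonal components plotted in scalene
    coordinates with the loading inter-axis angle."""
    i, j = comp_pair
    u = decomposition.loadings[i - 1]
    v = decomposition.loadings[j - 1]
    alpha = inter_axis_angle(u, v)
    pts = oblique_scores(decomposition.scores[:, [i - 1, j - 1]], alpha)
    ax = score_plot(pts, labels, ax=ax,
                    title=title or f"components {i},{j} (alpha={alpha:.1f} deg)")
    return ax, alpha


def spider_plot(signature: pd.DataFrame, ax=None, title=""):
    """Radar chart of a loading-signature table (components x windows)."""
    cols = list(signature.columns)
    angles = np.linspace(0, 2 * np.pi, len(cols), endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    for comp in signature.index:
        vals = signature.loc[comp].to_numpy(dtype=float)
        ax.plot(np.append(angles, angles[0]), np.append(vals, vals[0]),
                lw=1, label=f"comp {comp}")
    ax.set_xticks(angles)
    ax.set_xticklabels([str(c) for c in cols], fontsize=6)
    ax.set_title(title)
    ax.legend(fontsize=6, loc="upper right", bbox_to_anchor=(1.3, 1.1))
    return ax


def save_run_figures(config, report, artifacts, figdir) -> None:
    """Best-plane score plots for every report row that has a stored
    decomposition."""
    figdir = Path(figdir)
    figdir.mkdir(parents=True, exist_ok=True)
    from .pipeline import apply_label_scheme

    taxa = artifacts["taxa"]
    for _, row in report.iterrows():
        key = (row.method, row.dataset, row.masking)
        dec = artifacts["decompositions"].get(key)
        if dec is None:
            continue
        scores = dec.Q if hasattr(dec, "Q") else dec.scores
        keep, labels = apply_label_scheme(taxa, row.label_scheme)
        j, i = (int(x) for x in row.best_plane.split("-"))
        fig, ax = plt.subplots(figsize=(5, 4))
        score_plot(
            scores[keep][:, [i - 1, j - 1]],
            labels,
            ax=ax,
            title=f"{row.method} {row.dataset} ({row.masking}), "
                  f"plane {j}-{i}, Sil={row.best_plane_sil_pct:.0f}%",
        )
        stem = f"{row.method}_{row.dataset}_{row.masking}".replace("+", "")
        fig.savefig(figdir / f"{stem}.svg", bbox_inches="tight")
        plt.close(fig)
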