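"""Cluster-separation statistics for taxon-labelled score plots.

The central quantity is a silhouette variant in which b_i is the mean
distance from point i to ALL points outside its cluster (not, as in the
classical silhouette, the mean distance to the nearest other cluster).  With
very few clusters and highly unbalanced cluster sizes -- the regime of
score plots over a handful of taxa -- this all-outsiders convention is the
natural reading, and a ``classical`` flag restores the textbook definition
for comparison.  Silhouettes are scanned over all component planes (pairs of
score columns) and over arbitrary component subspaces, and 2-D score clouds
get chi-square confidence ellipses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "SilhouetteReport",
    "PlaneScan",
    "ConfidenceEllipse",
    "silhouette",
    "scan_planes",
    "subspace_silhouette",
    "confidence_ellipse",
]


@dataclass
class SilhouetteReport:
    a: np.ndarray
    b: np.ndarray
    s: np.ndarray
    cluster_means: dict
    sil: float
    sil_macro: float
    sil_micro: float
    variant: str
    labels: np.ndarray

    @property
    def sil_percent(self) -> float:
        return 100.0 * self.sil


@dataclass
class PlaneScan:
    """Silhouette over every unordered pair of score columns ("planes",
    1-based component numbers, e.g. the 2-1 plane) and the best pair."""

    table: pd.DataFrame
    best_plane: tuple[int, int]
    best_sil: float


@dataclass
class ConfidenceEllipse:
    center: np.ndarray
    semi_axes: np.ndarray  # descending
    rotation_deg: float
    level: float
    degenerate: bool = False


def silhouette(points, labels, variant: str = "macro",
               classical: bool = False) -> SilhouetteReport:
    """Silhouette of labelled points under the Euclidean metric.

    a_i is the mean distance from point i to the other members of its
    cluster (0 for singletons); b_i is the mean distance to all points
    outside the cluster (or, with ``classical=True``, to the nearest other
    cluster); s_i = (b_i - a_i)/max(a_i, b_i), set to 0 when both vanish.
    ``variant="macro"`` averages per-cluster mean silhouettes over clusters;
    ``"micro"`` averages s_i over all points.  Values lie in [-1, 1]:
    -1 no cluster structure, 0 overlapping clusters, +1 distinct compact
    clusters.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.ndim != 2 or X.size == 0:
        raise ValueError("points must be a non-empty 2-D array")
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("one label per point is required")
    if variant not in ("macro", "micro"):
        raise ValueError("variant must be 'macro' or 'micro'")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")

    D = squareform(pdist(X)) if X.shape[0] > 1 else np.zeros((1, 1))
    n = X.shape[0]
    a = np.zeros(n)
    b = np.zeros(n)
    for i in range(n):
        same = labels == labels[i]
        same[i] = False
        other = labels != labels[i]
        a[i] = D[i, same].mean() if same.any() else 0.0
        if classical:
            b[i] = min(
                D[i, labels == lab].mean() for lab in uniq if lab != labels[i]
            )
        else:
            b[i] = D[i, other].mean()
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)

    cluster_means = {lab: float(s[labels == lab].mean()) for lab in uniq}
    sil_macro = float(np.mean(list(cluster_means.values())))
    sil_micro = float(s.mean())
    return SilhouetteReport(
        a=a,
        b=b,
        s=s,
        cluster_means=cluster_means,
        sil=sil_macro if variant == "macro" else sil_micro,
        sil_macro=sil_macro,
        sil_micro=sil_micro,
        variant=variant,
        labels=labels,
    )


def scan_planes(scores, labels, variant: str = "macro") -> PlaneScan:
    """Silhouette on every unordered pair of score columns; ties for the best
    plane break toward the lexicographically smallest (i, j)."""
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2:
        raise ValueError("scan_planes requires at least 2 score columns")
    rows = []
    for i, j in combinations(range(S.shape[1]), 2):
        rep = silhouette(S[:, [i, j]], labels, variant)
        rows.append({"component_i": i + 1, "component_j": j + 1, "sil": rep.sil})
    table = pd.DataFrame(rows)
    best_idx = table.sil.round(15).idxmax()  # idxmax takes the first maximum
    best = table.loc[best_idx]
    return PlaneScan(
        table=table,
        best_plane=(int(best.component_i), int(best.component_j)),
        best_sil=float(best.sil),
    )


def subspace_silhouette(scores, dims, labels, variant: str = "macro") -> float:
    """Silhouette in the Euclidean metric of the selected (1-based) score
    columns; with a single pair this equals the corresponding plane value."""
    S = np.asarray(scores, dtype=float)
    dims = list(dims)
    if not dims:
        raise ValueError("dims must be non-empty")
    if any(not 1 <= d <= S.shape[1] for d in dims):
        raise ValueError(f"dims out of range 1..{S.shape[1]}")
    return silhouette(S[:, [d - 1 for d in dims]], labels, variant).sil


def confidence_ellipse(points2d, level: float = 0.95) -> ConfidenceEllipse:
    """Mean-centred covariance ellipse of 2-D points, scaled by the
    chi-square quantile with 2 degrees of freedom at the given level.

    Degenerate (collinear) clouds are flagged and returned as a line segment
    (zero minor semi-axis).
    """
    X = np.asarray(points2d, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points2d must be n x 2")
    if X.shape[0] < 3:
        raise ValueError("confidence ellipse requires at least 3 points")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    q = stats.chi2.ppf(level, df=2)
    degenerate = evals[0] <= 0 or evals[1] / evals[0] < 1e-12
    semi = np.sqrt(np.clip(evals, 0.0, None) * q)
    if degenerate:
        semi[1] = 0.0
    rotation = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return ConfidenceEllipse(
        center=center,
        semi_axes=semi,
        rotation_deg=rotation,
        level=level,
        degenerate=bool(degenerate),
    )
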