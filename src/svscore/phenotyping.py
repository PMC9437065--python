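"""Cell- and pixel-level unsupervised clustering and rule-based typing.

Clustering follows the common single-cell recipe: z-score the feature
matrix, build a k-nearest-neighbor graph, and run Leiden community
detection at a given resolution and seed.  Pixel clustering adds the
pixel-specific front end (downsample, per-channel min-max, background
drop) and a hierarchical merge of cluster centroids by cosine distance.

Cell typing is deliberately simple and deterministic: each composite rule
scores a cell as ``weight x mean expression over its member markers`` and
the argmax wins, ties resolving to the first rule in config order.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from skimage.measure import regionprops
from sklearn.neighbors import NearestNeighbors

from .datamodel import CellTable, CompositeRule, LabelMask, MultiplexROI
from .preprocess import downsample as _downsample

__all__ = [
    "ClusterResult",
    "PixelFeatureTable",
    "extract_cell_features",
    "cluster_cells",
    "cluster_pixels",
    "composite_scores",
    "assign_cell_types",
]


@dataclass
class ClusterResult:
    """Cluster ids (contiguous 0..k-1; -1 = dropped/background) plus
    per-cluster mean expression."""

    assignments: np.ndarray
    n_clusters: int
    mean_expression_per_cluster: np.ndarray
    embedding: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        kept = self.assignments[self.assignments >= 0]
        ids = np.unique(kept)
        if self.n_clusters and not np.array_equal(
                ids, np.arange(self.n_clusters)):
            raise ValueError("cluster ids must be contiguous 0..k-1")
        if self.mean_expression_per_cluster.shape[0] != self.n_clusters:
            raise ValueError("mean matrix rows != n_clusters")


@dataclass
class PixelFeatureTable:
    """Retained (non-background) pixels in downsampled coordinates with
    min-max-normalized intensity vectors."""

    df: pd.DataFrame  # columns: y, x, then one column per marker

    def __len__(self) -> int:
        return len(self.df)


def extract_cell_features(roi: MultiplexROI, mask: LabelMask) -> CellTable:
    """Per-label centroids, areas, and per-channel mean intensities.

    Centroids are the unweighted mean of the label's pixel coordinates
    (x = column, y = row); micron centroids apply the panel resolution.
    """
    mask.check_matches(roi)
    res = roi.panel.resolution_um_per_px
    names = roi.panel.names
    intensity = np.moveaxis(roi.stack, 0, -1)  # H x W x C for regionprops
    rows = []
    for prop in regionprops(mask.labels, intensity_image=intensity):
        cy, cx = prop.centroid
        rec = {
            "cell_id": int(prop.label),
            "centroid_x_px": float(cx),
            "centroid_y_px": float(cy),
            "centroid_x_um": float(cx) * res,
            "centroid_y_um": float(cy) * res,
            "area_px": int(prop.area),
        }
        means = np.asarray(prop.intensity_mean, dtype=float)
        for name, v in zip(names, means):
            rec[f"mean_{name}"] = float(v)
        rows.append(rec)
    if not rows:
        df = pd.DataFrame(columns=[
            "cell_id", "centroid_x_px", "centroid_y_px",
            "centroid_x_um", "centroid_y_um", "area_px",
            *[f"mean_{n}" for n in names]])
    else:
        df = pd.DataFrame(rows)
    return CellTable(df=df, marker_names=list(names))


def zscore_columns(x: np.ndarray) -> np.ndarray:
    """Column z-score; zero-variance columns map to all zeros."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.zeros_like(x)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - mu[nz]) / sd[nz]
    return out


def _leiden_on_features(features: np.ndarray, n_neighbors: int,
                        resolution: float, seed: int) -> np.ndarray:
    """k-NN graph + Leiden (RB modularity) on a feature matrix."""
    n = features.shape[0]
    if n <= n_neighbors:
        raise ValueError(
            f"{n} items but n_neighbors={n_neighbors}; use a smaller k")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(features)
    _, idx = nn.kneighbors(features)
    edges = {(min(i, j), max(i, j))
             for i, row in enumerate(idx) for j in row[1:]}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed))
    return np.asarray(part.membership, dtype=int)


def _relabel_by_size(assign: np.ndarray) -> np.ndarray:
    """Renumber clusters 0..k-1 by decreasing size (stable, deterministic)."""
    kept = assign[assign >= 0]
    ids, counts = np.unique(kept, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    out = assign.copy()
    for old, new in remap.items():
        out[assign == old] = new
    return out


def _cluster_means(features: np.ndarray, assign: np.ndarray,
                   n_clusters: int) -> np.ndarray:
    means = np.zeros((n_clusters, features.shape[1]))
    for k in range(n_clusters):
        means[k] = features[assign == k].mean(axis=0)
    return means


def cluster_cells(cell_table: CellTable,
                  markers_subset: list[str] | None = None,
                  n_neighbors: int = 15,
                  resolution: float = 1.0,
                  seed: int = 0) -> ClusterResult:
    """Leiden phenotype clustering of cells on z-scored marker means.

    ``markers_subset`` restricts the feature matrix (phenotyping panels are
    commonly clustered on a lineage-marker subset); defaults to all markers.
    Deterministic for a fixed seed.
    """
    names = cell_table.marker_names
    if markers_subset is None:
        markers_subset = list(names)
    unknown = set(markers_subset) - set(names)
    if unknown:
        raise ValueError(f"markers not in table: {sorted(unknown)}")
    cols = [names.index(m) for m in markers_subset]
    feats = zscore_columns(cell_table.mean_expr[:, cols])
    if np.allclose(feats, 0):
        # degenerate: identical rows -> a single cluster
        assign = np.zeros(len(cell_table), dtype=int)
    else:
        assign = _leiden_on_features(feats, n_neighbors, resolution, seed)
    assign = _relabel_by_size(assign)
    k = int(assign.max()) + 1 if len(assign) else 0
    means = _cluster_means(cell_table.mean_expr, assign, k)
    return ClusterResult(assignments=assign, n_clusters=k,
                         mean_expression_per_cluster=means)


def merge_clusters_by_cosine(means: np.ndarray,
                             merge_threshold_frac: float = 0.25
                             ) -> np.ndarray:
    """Average-linkage merge of cluster means at cosine distance.

    The dendrogram is cut at ``merge_threshold_frac`` times the maximum
    pairwise cosine distance; returns an old-id -> new-id mapping with
    contiguous new ids.  Never increases the cluster count.
    """
    k = means.shape[0]
    if k <= 1:
        return np.arange(k)
    # cosine distance of a zero vector is undefined; treat zeros as distant
    safe = means.copy()
    zero = ~np.any(safe, axis=1)
    safe[zero] = 1e-12
    dist = pdist(safe, metric="cosine")
    dmax = dist.max()
    if dmax == 0:
        return np.zeros(k, dtype=int)
    z = linkage(dist, method="average")
    flat = fcluster(z, t=merge_threshold_frac * dmax, criterion="distance")
    # renumber contiguously by first appearance
    remap: dict[int, int] = {}
    out = np.empty(k, dtype=int)
    for i, f in enumerate(flat):
        out[i] = remap.setdefault(f, len(remap))
    return out


def cluster_pixels(roi: MultiplexROI,
                   downsample_factor: int = 2,
                   bg_threshold: float = 0.3,
                   merge_threshold_frac: float = 0.25,
                   seed: int = 0,
                   n_neighbors: int = 15,
                   resolution: float = 1.0
                   ) -> tuple[ClusterResult, PixelFeatureTable]:
    """Pixel phenotype clustering.

    Pipeline: block-mean downsample -> per-channel min-max to [0, 1] ->
    drop pixels with every marker below ``bg_threshold`` -> Leiden on the
    retained feature rows -> merge clusters whose mean expressions are
    within ``merge_threshold_frac`` of the maximum pairwise cosine
    distance.  An all-background ROI returns an empty result, not an error.
    """
    small = _downsample(roi.stack, downsample_factor)
    c, h, w = small.shape
    flat = small.reshape(c, -1).T  # (H*W, C)
    mins = flat.min(axis=0)
    maxs = flat.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    norm = (flat - mins) / span
    norm[:, maxs == mins] = 0.0
    keep = np.any(norm >= bg_threshold, axis=1)
    ys, xs = np.divmod(np.flatnonzero(keep), w)
    feats = norm[keep]
    names = roi.panel.names
    table = PixelFeatureTable(df=pd.DataFrame(
        {"y": ys, "x": xs, **{n: feats[:, i] for i, n in enumerate(names)}}))
    assign_full = np.full(flat.shape[0], -1, dtype=int)
    if feats.shape[0] == 0:
        empty = ClusterResult(assignments=assign_full, n_clusters=0,
                              mean_expression_per_cluster=np.zeros((0, c)))
        return empty, table
    if feats.shape[0] <= n_neighbors:
        assign = np.zeros(feats.shape[0], dtype=int)
    else:
        assign = _leiden_on_features(feats, n_neighbors, resolution, seed)
    assign = _relabel_by_size(assign)
    k = int(assign.max()) + 1
    means = _cluster_means(feats, assign, k)
    mapping = merge_clusters_by_cosine(means, merge_threshold_frac)
    assign = mapping[assign]
    assign = _relabel_by_size(assign)
    k = int(assign.max()) + 1
    means = _cluster_means(feats, assign, k)
    assign_full[keep] = assign
    result = ClusterResult(assignments=assign_full, n_clusters=k,
                           mean_expression_per_cluster=means)
    return result, table


def composite_scores(cell_table: CellTable,
                     rules: list[CompositeRule]) -> np.ndarray:
    """(n_cells, n_rules) matrix of ``weight x mean member expression``."""
    if not rules:
        raise ValueError("no composite rules given")
    names = cell_table.marker_names
    expr = cell_table.mean_expr
    scores = np.empty((len(cell_table), len(rules)))
    for j, rule in enumerate(rules):
        cols = [names.index(m) for m in rule.member_markers]
        scores[:, j] = rule.weight * expr[:, cols].mean(axis=1)
    return scores


def assign_cell_types(cell_table: CellTable,
                      rules: list[CompositeRule]) -> CellTable:
    """Argmax composite typing; ties break to the first rule in order.

    Expects ``mean_expr`` computed on intensity-scaled channels (with the
    CD8a plane median-denoised upstream if desired; see
    :func:`svscore.spatialscore.score_roi` for the assembled pipeline).
    """
    scores = composite_scores(cell_table, rules)
    # np.argmax returns the first maximum, which is exactly the
    # first-rule-in-config-order tie-break.
    winners = np.argmax(scores, axis=1)
    types = [rules[i].type_name for i in winners]
    return cell_table.with_types(types)
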