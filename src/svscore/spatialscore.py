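"""Spatial proximity network and the spatially variant infiltration scores.

Cell level
----------
Typed cell centroids become nodes of an undirected radius graph (edge iff
centroid distance <= 30 um, inclusive).  The ROI is tiled with 25 um
patches; for patch *i* and types A, B the module computes

* densities ``P_i,type = n_i,type / n_i,cell`` (0 for empty patches),
* directed link counts ``L_i,A->B`` = over cells of type A in patch i, the
  number of their type-B graph neighbors anywhere, and
* a pair score in [0, 1]: realized A-B edges touching patch i divided by
  the number of possible in-patch A-B pairs (clipped at 1; 0 when the
  denominator is 0).

The per-ROI score for a pair is the mean patch score over non-empty
patches, scaled by 10 onto [0, 10], where fixed bins stratify the ROI into
the immune continuum (cold / suppressed / inflamed).

Pixel level
-----------
The scaled stack is tiled with n x n pixel patches (default 5); each patch
takes the composite type with the highest weighted mean intensity, or
background when every type mean is below 0.1.  Densities and an adjacency
immunoscore (fraction of 4-connected patch pairs realizing a type pair)
summarize the resulting max-projection map.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .datamodel import (CellTable, CompositeRule, LabelMask, MarkerPanel,
                        MultiplexROI, ScoreReport, pair_key, validate_rules)
from .phenotyping import assign_cell_types, extract_cell_features
from .preprocess import ScalingSpec, downsample, median_denoise, scale_intensity

__all__ = [
    "ProximityGraph",
    "PatchStats",
    "MaxProjectionMap",
    "DEFAULT_STRATUM_BINS",
    "build_proximity_graph",
    "compute_patch_stats",
    "roi_scores",
    "stratify",
    "stratify_scores",
    "classify_patches_pixel",
    "pixel_pair_scores",
    "m2_m1_ratio",
    "score_roi",
]

#: Fixed CD8-T score bins delimiting low / medium / high infiltration,
#: applied half-open as (lo, hi].
DEFAULT_STRATUM_BINS = ((-0.001, 2.255), (2.255, 6.695), (6.695, 10.0))


# ---------------------------------------------------------------------------
# Proximity graph
# ---------------------------------------------------------------------------

@dataclass
class ProximityGraph:
    """Radius graph over typed cell centroids (distances in um)."""

    graph: nx.Graph
    radius_um: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_types(self) -> dict[int, str]:
        return nx.get_node_attributes(self.graph, "cell_type")

    def positions_um(self) -> dict[int, tuple[float, float]]:
        return nx.get_node_attributes(self.graph, "pos_um")


def build_proximity_graph(cell_table: CellTable,
                          radius_um: float = 30.0) -> ProximityGraph:
    """Connect every pair of cells whose centroids lie within ``radius_um``.

    The boundary is inclusive: two cells exactly ``radius_um`` apart are
    neighbors.  Fewer than two cells simply yields an edgeless graph.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    df = cell_table.df
    if df["cell_type"].isna().any():
        raise ValueError("cell_table has untyped cells; run typing first")
    g = nx.Graph()
    ids = df["cell_id"].to_numpy()
    xy = cell_table.centroids_um
    for cid, (x, y), t in zip(ids, xy, df["cell_type"]):
        g.add_node(int(cid), pos_um=(float(x), float(y)), cell_type=str(t))
    if len(ids) >= 2:
        tree = cKDTree(xy)
        for i, j in tree.query_pairs(r=radius_um):  # r is inclusive
            g.add_edge(int(ids[i]), int(ids[j]))
    return ProximityGraph(graph=g, radius_um=float(radius_um))


# ---------------------------------------------------------------------------
# Patch statistics
# ---------------------------------------------------------------------------

@dataclass
class PatchStats:
    """Per-patch counts, densities, link counts and pair scores.

    Grids are (gy, gx) arrays indexed by patch row/column.  ``link_counts``
    maps ordered type pairs (A, B) to the L_i,A->B grid; ``pair_scores``
    maps canonical unordered pairs to score grids in [0, 1].
    """

    roi_id: str
    patch_um: float
    grid_shape: tuple[int, int]
    type_order: tuple[str, ...]
    n_cell: np.ndarray
    counts: dict[str, np.ndarray]
    densities: dict[str, np.ndarray]
    link_counts: dict[tuple[str, str], np.ndarray]
    pair_scores: dict[tuple[str, str], np.ndarray]


def _patch_index(coord_um: np.ndarray, patch_um: float, n: int) -> np.ndarray:
    # half-open bins [k*p, (k+1)*p); the last patch absorbs the far edge
    return np.minimum((coord_um // patch_um).astype(int), n - 1)


def compute_patch_stats(pgraph: ProximityGraph,
                        patch_um: float = 25.0,
                        roi_size_um: float | tuple[float, float] = 1500.0,
                        type_order: tuple[str, ...] | None = None,
                        roi_id: str = "roi") -> PatchStats:
    """Bin cells into a ``patch_um`` grid and score every type pair per patch.

    ``roi_size_um`` may be a scalar (square ROI) or (width, height).  Link
    counts follow the directed definition (neighbors may lie outside the
    patch); the pair score numerator counts each realized A-B edge once per
    patch it touches through a qualifying endpoint, and the denominator is
    the number of in-patch A-B pairs.
    """
    if patch_um <= 0:
        raise ValueError("patch_um must be > 0")
    if np.isscalar(roi_size_um):
        w_um = h_um = float(roi_size_um)  # type: ignore[arg-type]
    else:
        w_um, h_um = map(float, roi_size_um)  # type: ignore[misc]
    gx = max(1, math.ceil(w_um / patch_um - 1e-9))
    gy = max(1, math.ceil(h_um / patch_um - 1e-9))

    g = pgraph.graph
    types_map = pgraph.node_types()
    pos = pgraph.positions_um()
    if type_order is None:
        type_order = tuple(sorted(set(types_map.values())))
    nodes = list(g.nodes)
    px = {}
    py = {}
    for n in nodes:
        x, y = pos[n]
        px[n] = min(int(x // patch_um), gx - 1)
        py[n] = min(int(y // patch_um), gy - 1)

    n_cell = np.zeros((gy, gx), dtype=int)
    counts = {t: np.zeros((gy, gx), dtype=int) for t in type_order}
    for n in nodes:
        t = types_map[n]
        n_cell[py[n], px[n]] += 1
        if t in counts:
            counts[t][py[n], px[n]] += 1

    densities = {}
    nonempty = n_cell > 0
    for t in type_order:
        d = np.zeros((gy, gx))
        d[nonempty] = counts[t][nonempty] / n_cell[nonempty]
        densities[t] = d

    # Directed link counts: L_i,A->B sums, over type-A cells in patch i,
    # their type-B neighbors anywhere in the graph.
    link_counts = {(a, b): np.zeros((gy, gx), dtype=int)
                   for a in type_order for b in type_order}
    for n in nodes:
        ta = types_map[n]
        if ta not in counts:
            continue
        i, j = py[n], px[n]
        for m in g.neighbors(n):
            tb = types_map[m]
            if tb in counts:
                link_counts[(ta, tb)][i, j] += 1

    # Realized-edge numerators per unordered pair.
    pairs = [pair_key(a, b, type_order)
             for a, b in itertools.combinations_with_replacement(type_order, 2)]
    realized = {p: np.zeros((gy, gx), dtype=int) for p in pairs}
    for u, v in g.edges:
        tu, tv = types_map[u], types_map[v]
        if tu not in counts or tv not in counts:
            continue
        key = pair_key(tu, tv, type_order)
        pu = (py[u], px[u])
        pv = (py[v], px[v])
        realized[key][pu] += 1
        if pv != pu:
            realized[key][pv] += 1

    pair_scores = {}
    for a, b in itertools.combinations_with_replacement(type_order, 2):
        key = pair_key(a, b, type_order)
        if a == b:
            possible = counts[a] * (counts[a] - 1) / 2
        else:
            possible = counts[key[0]] * counts[key[1]]
        score = np.zeros((gy, gx))
        ok = possible > 0
        score[ok] = np.minimum(realized[key][ok] / possible[ok], 1.0)
        pair_scores[key] = score

    return PatchStats(roi_id=roi_id, patch_um=float(patch_um),
                      grid_shape=(gy, gx), type_order=tuple(type_order),
                      n_cell=n_cell, counts=counts, densities=densities,
                      link_counts=link_counts, pair_scores=pair_scores)


# ---------------------------------------------------------------------------
# ROI aggregation and stratification
# ---------------------------------------------------------------------------

def roi_scores(stats: PatchStats,
               scale_factor: float = 10.0,
               bins=DEFAULT_STRATUM_BINS) -> ScoreReport:
    """Aggregate patch pair scores to one report per ROI.

    The raw pair score is the mean patch score over non-empty patches
    (0 when every patch is empty, which also yields the ``cold`` stratum);
    scaled scores are ``scale_factor x raw`` clipped to [0, 10].
    """
    nonempty = stats.n_cell > 0
    raw = {}
    scaled = {}
    for key, grid in stats.pair_scores.items():
        r = float(grid[nonempty].mean()) if nonempty.any() else 0.0
        raw[key] = r
        scaled[key] = float(np.clip(scale_factor * r, 0.0, 10.0))
    total = int(stats.n_cell.sum())
    densities = {t: (int(stats.counts[t].sum()) / total if total else 0.0)
                 for t in stats.type_order}
    report = ScoreReport(
        roi_id=stats.roi_id,
        type_order=stats.type_order,
        raw_scores=raw,
        scaled_scores=scaled,
        densities=densities,
        heatmaps={k: v.copy() for k, v in stats.pair_scores.items()},
        config={"patch_um": stats.patch_um,
                "scale_factor": scale_factor,
                "grid_shape": list(stats.grid_shape)},
    )
    needed = [pair_key("Tumor", t, stats.type_order)
              for t in ("CD8", "M1", "M2")]
    if all(k in scaled for k in needed):
        report.stratum = stratify(report, bins=bins)
    return report


def stratify_scores(cd8_tumor: float, tumor_m1: float, tumor_m2: float,
                    bins=DEFAULT_STRATUM_BINS) -> str:
    """Map scaled scores to a stratum on the immune continuum.

    The CD8-Tumor score decides low -> ``cold`` and high -> ``inflamed``
    directly; in the medium bin the macrophage balance breaks the tie
    (``suppressed`` when Tumor-M2 >= Tumor-M1, else ``inflamed``).  Bin
    intervals are half-open (lo, hi].
    """
    for name, v in (("CD8-Tumor", cd8_tumor), ("Tumor-M1", tumor_m1),
                    ("Tumor-M2", tumor_m2)):
        if not 0.0 <= v <= 10.0:
            raise ValueError(f"{name} score {v} outside [0, 10]")
    (lo0, hi0), (lo1, hi1), (lo2, hi2) = bins
    if lo0 < cd8_tumor <= hi0:
        return "cold"
    if lo1 < cd8_tumor <= hi1:
        return "suppressed" if tumor_m2 >= tumor_m1 else "inflamed"
    if lo2 < cd8_tumor <= hi2:
        return "inflamed"
    raise ValueError(f"CD8-Tumor score {cd8_tumor} outside bins {bins}")


def stratify(report: ScoreReport, bins=DEFAULT_STRATUM_BINS) -> str:
    """Stratify a score report by its three Tumor-pair scaled scores."""
    return stratify_scores(report.scaled("CD8", "Tumor"),
                           report.scaled("Tumor", "M1"),
                           report.scaled("Tumor", "M2"),
                           bins=bins)


# ---------------------------------------------------------------------------
# Pixel-level classification and immunoscore
# ---------------------------------------------------------------------------

@dataclass
class MaxProjectionMap:
    """Patch-type grid from max-mean-intensity assignment.

    ``grid`` holds rule indices into ``type_order``; -1 marks background
    patches (every composite mean below the background threshold).
    """

    grid: np.ndarray
    type_order: tuple[str, ...]
    patch_px: int
    bg_threshold: float

    @property
    def n_patches(self) -> int:
        return int(self.grid.size)

    def type_grid(self) -> np.ndarray:
        """Grid of type-name strings with 'background' for -1."""
        lut = np.array(list(self.type_order) + ["background"], dtype=object)
        return lut[self.grid]


def classify_patches_pixel(roi_scaled: MultiplexROI | np.ndarray,
                           rules: list[CompositeRule],
                           panel: MarkerPanel | None = None,
                           patch_px: int = 5,
                           bg_threshold: float = 0.1) -> MaxProjectionMap:
    """Assign each n x n pixel patch to its maximum-mean-intensity type.

    Expects intensities already rescaled to [0, 1].  Per patch and rule the
    composite mean is ``weight x mean over member channels of the patch
    mean``; a patch where every composite mean is below ``bg_threshold``
    is background.  The grid is ceil(H / patch_px) x ceil(W / patch_px),
    edge patches averaging only the pixels they contain.
    """
    if patch_px < 1 or int(patch_px) != patch_px:
        raise ValueError("patch_px must be a positive integer")
    if isinstance(roi_scaled, MultiplexROI):
        stack = roi_scaled.stack
        panel = roi_scaled.panel
    else:
        stack = np.asarray(roi_scaled)
        if panel is None:
            raise ValueError("panel required when passing a bare stack")
    if not rules:
        raise ValueError("no composite rules given")
    validate_rules(rules, panel)
    patch_means = downsample(stack, int(patch_px))  # C x gy x gx
    comp = np.stack([
        r.weight * patch_means[[panel.index_of(m)
                                for m in r.member_markers]].mean(axis=0)
        for r in rules
    ])  # n_rules x gy x gx
    grid = np.argmax(comp, axis=0).astype(np.int64)  # first max = rule order
    grid[np.all(comp < bg_threshold, axis=0)] = -1
    return MaxProjectionMap(grid=grid,
                            type_order=tuple(r.type_name for r in rules),
                            patch_px=int(patch_px),
                            bg_threshold=float(bg_threshold))


def pixel_pair_scores(pmap: MaxProjectionMap,
                      connectivity: int = 4,
                      include_background_pairs: bool = True
                      ) -> tuple[dict[str, float],
                                 dict[tuple[str, str], float]]:
    """Per-type patch densities and per-pair adjacency immunoscores.

    Density is patches of a type over all patches (background included in
    the denominator).  The immunoscore of {A, B} is the number of adjacent
    patch pairs realizing that type pair over the total number of adjacent
    pairs in the grid (4-connectivity by default; 8 adds diagonals;
    ``include_background_pairs=False`` drops pairs touching background from
    the denominator).  A 1 x 1 grid has no adjacent pairs, so every
    immunoscore is 0.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    grid = pmap.grid
    total = grid.size
    densities = {t: float(np.count_nonzero(grid == i) / total)
                 for i, t in enumerate(pmap.type_order)}
    densities["background"] = float(np.count_nonzero(grid == -1) / total)

    pairs_a = [grid[:, :-1].ravel(), grid[:, 1:].ravel()]
    pairs_b = [grid[:-1, :].ravel(), grid[1:, :].ravel()]
    a = np.concatenate([pairs_a[0], pairs_b[0]])
    b = np.concatenate([pairs_a[1], pairs_b[1]])
    if connectivity == 8:
        a = np.concatenate([a, grid[:-1, :-1].ravel(), grid[:-1, 1:].ravel()])
        b = np.concatenate([b, grid[1:, 1:].ravel(), grid[1:, :-1].ravel()])
    if not include_background_pairs:
        keep = (a >= 0) & (b >= 0)
        a, b = a[keep], b[keep]
    n_adjacent = a.size
    scores: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations_with_replacement(
            range(len(pmap.type_order)), 2):
        key = pair_key(pmap.type_order[i], pmap.type_order[j],
                       pmap.type_order)
        if n_adjacent == 0:
            scores[key] = 0.0
        elif i == j:
            scores[key] = float(np.count_nonzero((a == i) & (b == i))
                                / n_adjacent)
        else:
            hits = ((a == i) & (b == j)) | ((a == j) & (b == i))
            scores[key] = float(np.count_nonzero(hits) / n_adjacent)
    return densities, scores


def m2_m1_ratio(source) -> float:
    """M2-to-M1 ratio from counts, densities, or a score report.

    Accepts a mapping with ``"M1"`` / ``"M2"`` entries or a
    :class:`ScoreReport` (whose densities are used).  A zero M1 component
    returns ``+inf`` with a warning rather than raising.
    """
    if isinstance(source, ScoreReport):
        source = source.densities
    try:
        m1 = float(source["M1"])
        m2 = float(source["M2"])
    except (KeyError, TypeError) as exc:
        raise ValueError("source must provide 'M1' and 'M2'") from exc
    if m1 == 0:
        warnings.warn("M1 component is zero; M2/M1 ratio is +inf",
                      RuntimeWarning, stacklevel=2)
        return math.inf
    return m2 / m1


# ---------------------------------------------------------------------------
# Assembled cell-level pipeline
# ---------------------------------------------------------------------------

def score_roi(roi: MultiplexROI,
              mask: LabelMask,
              rules: list[CompositeRule],
              radius_um: float = 30.0,
              patch_um: float = 25.0,
              scaling: ScalingSpec | None = None,
              cd8_denoise: bool = True,
              scale_factor: float = 10.0
              ) -> tuple[CellTable, ProximityGraph, PatchStats, ScoreReport]:
    """Run the full cell-level pipeline on one ROI.

    Steps: optional median denoise of the CD8 rule's member channels ->
    percentile intensity scaling -> per-cell feature extraction -> argmax
    composite typing -> 30 um proximity graph -> 25 um patch statistics ->
    per-ROI scores and stratum.
    """
    validate_rules(rules, roi.panel)
    mask.check_matches(roi)
    stack = roi.stack.astype(np.float64, copy=True)
    if cd8_denoise:
        for rule in rules:
            if rule.type_name == "CD8":
                for m in rule.member_markers:
                    ch = roi.panel.index_of(m)
                    stack[ch] = median_denoise(stack[ch], disk_radius_px=1)
    scaled = scale_intensity(stack, scaling or ScalingSpec.per_image())
    scaled_roi = MultiplexROI(roi_id=roi.roi_id, stack=scaled,
                              panel=roi.panel)
    table = extract_cell_features(scaled_roi, mask)
    table = assign_cell_types(table, rules)
    pgraph = build_proximity_graph(table, radius_um=radius_um)
    res = roi.panel.resolution_um_per_px
    h_um = roi.stack.shape[1] * res
    w_um = roi.stack.shape[2] * res
    type_order = tuple(r.type_name for r in rules)
    stats = compute_patch_stats(pgraph, patch_um=patch_um,
                                roi_size_um=(w_um, h_um),
                                type_order=type_order, roi_id=roi.roi_id)
    report = roi_scores(stats, scale_factor=scale_factor)
    report.config.update({"radius_um": radius_um,
                          "cd8_denoise": cd8_denoise,
                          "scaling_mode": (scaling or
                                           ScalingSpec.per_image()).mode})
    return table, pgraph, stats, report
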