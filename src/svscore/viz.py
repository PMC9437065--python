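"""Deterministic raster renders: network overlays, score heatmaps, pseudo-H&E.

All renderers return ``uint8`` RGB arrays and are pure functions of their
inputs, so repeated calls are bitwise identical.  Colors follow the field's
usual convention for these maps: tumor magenta, stroma yellow, CD8 green,
M1 red, M2 cyan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from skimage.draw import disk as draw_disk, line as draw_line

from .datamodel import MultiplexROI
from .spatialscore import ProximityGraph

__all__ = [
    "RenderSpec",
    "DEFAULT_TYPE_COLORS",
    "render_network_overlay",
    "render_infiltration_heatmap",
    "pseudo_hne",
]

logger = logging.getLogger("svscore")

DEFAULT_TYPE_COLORS: dict[str, tuple[int, int, int]] = {
    "Tumor": (255, 0, 255),   # magenta
    "Stroma": (255, 255, 0),  # yellow
    "CD8": (0, 255, 0),       # green
    "M1": (255, 0, 0),        # red
    "M2": (0, 255, 255),      # cyan
}


@dataclass(frozen=True)
class RenderSpec:
    """Colors and geometry for network rendering."""

    type_colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_COLORS))
    size_px: tuple[int, int] = (500, 500)  # (height, width)
    node_radius_px: int = 3
    edge_color: tuple[int, int, int] = (180, 180, 180)
    overlay_alpha: float = 1.0
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlay_alpha <= 1.0:
            raise ValueError("overlay_alpha must be in [0, 1]")
        for t, c in self.type_colors.items():
            if len(c) != 3 or any(not 0 <= v <= 255 for v in c):
                raise ValueError(f"invalid RGB color for {t!r}: {c}")


def render_network_overlay(pgraph: ProximityGraph,
                           spec: RenderSpec = RenderSpec(),
                           background: np.ndarray | None = None
                           ) -> np.ndarray:
    """Draw the proximity network: edges first, then type-colored nodes.

    Unknown types render white.  With ``background`` (H x W x 3 uint8) the
    network is alpha-blended on top; otherwise the canvas starts black.
    """
    h, w = spec.size_px
    canvas = np.zeros((h, w, 3), dtype=np.float64)
    pos = pgraph.positions_um()
    types = pgraph.node_types()

    def to_px(p):
        x, y = p
        return (int(round(y / spec.um_per_px)), int(round(x / spec.um_per_px)))

    for u, v in sorted(pgraph.graph.edges):
        r0, c0 = to_px(pos[u])
        r1, c1 = to_px(pos[v])
        rr, cc = draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[ok], cc[ok]] = spec.edge_color
    for n in sorted(pgraph.graph.nodes):
        r, c = to_px(pos[n])
        color = spec.type_colors.get(types[n], (255, 255, 255))
        rr, cc = draw_disk((r, c), max(spec.node_radius_px, 1), shape=(h, w))
        canvas[rr, cc] = color
    if background is not None:
        bg = np.asarray(background, dtype=np.float64)
        if bg.shape != (h, w, 3):
            raise ValueError("background shape must match spec.size_px")
        drawn = canvas.any(axis=-1, keepdims=True)
        a = spec.overlay_alpha
        canvas = np.where(drawn, a * canvas + (1 - a) * bg, bg)
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


def render_infiltration_heatmap(score_grid: np.ndarray,
                                cmap_name: str = "viridis",
                                nan_color: tuple[int, int, int] = (128, 128, 128)
                                ) -> np.ndarray:
    """Map a patch grid of scores in [0, 1] through a monotone colormap.

    NaN (empty) patches render in ``nan_color``.  One output pixel per
    patch; upscale for presentation as needed.
    """
    grid = np.asarray(score_grid, dtype=np.float64)
    finite = np.isfinite(grid)
    if finite.any() and (grid[finite].min() < 0 or grid[finite].max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    cmap = colormaps[cmap_name]
    rgba = cmap(np.where(finite, grid, 0.0))
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    rgb[~finite] = nan_color
    return rgb


# --- pseudo-H&E -----------------------------------------------------------

#: Markers averaged for each compartment of the reconstruction.  The
#: nuclear set covers chromatin / nuclear factors plus the Ir DNA
#: intercalators; the cytosol set covers abundant cytoplasmic markers.
HNE_NUCLEAR_MARKERS = ("Histone3", "H3K9me3", "Ki67", "FoxP3",
                       "Ir191", "Ir193")
HNE_CYTOSOL_MARKERS = ("Vimentin", "CD68", "HLA-DR", "GranzymeB", "CD20",
                       "ECadherin", "PanKeratin")

_N_QUANT = 256


def _half_colormap(name: str) -> np.ndarray:
    """Upper half of a named colormap as an (N, 3) RGB float table."""
    cmap = colormaps[name]
    levels = np.linspace(0.5, 1.0, _N_QUANT)
    return cmap(levels)[:, :3]


def _layer(mean_img: np.ndarray, colors: np.ndarray,
           alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quantize a [0, 1] mean image into per-pixel color and alpha."""
    q = np.clip((mean_img * (_N_QUANT - 1)).astype(int), 0, _N_QUANT - 1)
    return colors[q], alpha[q]


def pseudo_hne(roi: MultiplexROI,
               nuclear_markers=HNE_NUCLEAR_MARKERS,
               cytosol_markers=HNE_CYTOSOL_MARKERS) -> np.ndarray:
    """Reconstruct an H&E-like RGB image from averaged marker channels.

    The nuclei layer averages the available nuclear channels and maps them
    through the upper (blue-purple) half of a blue-red diverging colormap
    with alpha running linearly 0 -> 1; the cytosol layer averages the
    cytosolic channels through the upper (pink) half of a pink-green
    diverging colormap with alpha 0.5 -> 1.  The nuclei layer is
    alpha-composited over the cytosol layer:
    ``out = a_n * c_n + (1 - a_n) * a_c * c_c``.

    Markers listed but absent from the panel are skipped with a warning;
    an entirely unavailable set raises.  Intensities should already be
    scaled to [0, 1].
    """
    def planes(markers, what):
        avail = [m for m in markers if m in roi.panel.names]
        missing = sorted(set(markers) - set(avail))
        if missing:
            logger.warning("pseudo-H&E: skipping absent %s markers %s",
                           what, missing)
        if not avail:
            raise ValueError(f"no {what} markers available in panel")
        return np.mean([roi.channel(m) for m in avail], axis=0)

    nuc = np.clip(planes(nuclear_markers, "nuclear"), 0, 1)
    cyt = np.clip(planes(cytosol_markers, "cytosol"), 0, 1)

    nuc_colors = _half_colormap("bwr_r")
    cyt_colors = _half_colormap("PiYG_r")
    nuc_alpha = np.linspace(0.0, 1.0, _N_QUANT)
    cyt_alpha = np.linspace(0.5, 1.0, _N_QUANT)

    c_n, a_n = _layer(nuc, nuc_colors, nuc_alpha)
    c_c, a_c = _layer(cyt, cyt_colors, cyt_alpha)
    out = a_n[..., None] * c_n + (1 - a_n)[..., None] * (a_c[..., None] * c_c)
    return np.clip(np.rint(out * 255), 0, 255).astype(np.uint8)
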