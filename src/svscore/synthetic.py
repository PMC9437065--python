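"""Synthetic multichannel ROIs with known cells, types and infiltration.

The generator emulates what the scoring pipeline consumes: disk-shaped
cells (default diameter 10 px at 1 um/px) scattered with a minimum spacing,
each expressing the member markers of its true composite type at high
intensity (lognormal per-pixel signal) on top of low Poisson background in
every channel, with nuclear-role markers lit in every cell so the fallback
segmenter has something to work with.

Archetypes encode the immune continuum: an ``inflamed`` ROI is rich in CD8
and M1 cells preferentially placed near tumor cells, a ``suppressed`` ROI
is M2-dominated, and a ``cold`` ROI has scarce, unattracted immune cells.
Only the rank order of the resulting scores is meaningful; the generator
makes no attempt at realistic tissue morphology (glands, vessels, staining
artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import (CompositeRule, LabelMask, MarkerPanel, MultiplexROI,
                        default_panel, default_rules, validate_rules)

__all__ = [
    "TissueArchetype",
    "GroundTruth",
    "PlacementError",
    "ARCHETYPES",
    "generate_roi",
    "generate_cohort",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be packed at the requested spacing."""

TYPE_ORDER = ("Tumor", "Stroma", "CD8", "M1", "M2")
IMMUNE_TYPES = ("CD8", "M1", "M2")


@dataclass(frozen=True)
class TissueArchetype:
    """Cell-type composition plus tumor-attraction of immune cells.

    ``composition`` gives the expected fraction of each type (sums to 1);
    ``attraction`` gives, per immune type, the probability that a cell of
    that type is placed within the interaction radius of a tumor cell
    rather than uniformly.
    """

    name: str
    composition: dict[str, float]
    attraction: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, not 1")
        for t, f in self.composition.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {t} outside [0, 1]")
        for t, a in self.attraction.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"attraction for {t} outside [0, 1]")


#: Shipped archetypes.  Compositions mirror the qualitative continuum
#: (inflamed: CD8/M1-rich; suppressed: M2-dominated; cold: immune-poor);
#: attraction probabilities are the generator's knob for tumor-proximal
#: placement and were fixed once at values giving clearly ordered scores.
ARCHETYPES: dict[str, TissueArchetype] = {
    "inflamed": TissueArchetype(
        "inflamed",
        composition={"Tumor": 0.45, "Stroma": 0.25,
                     "CD8": 0.15, "M1": 0.10, "M2": 0.05},
        attraction={"CD8": 0.9, "M1": 0.8, "M2": 0.3},
    ),
    "suppressed": TissueArchetype(
        "suppressed",
        composition={"Tumor": 0.45, "Stroma": 0.25,
                     "CD8": 0.05, "M1": 0.05, "M2": 0.20},
        attraction={"CD8": 0.35, "M1": 0.3, "M2": 0.85},
    ),
    "cold": TissueArchetype(
        "cold",
        composition={"Tumor": 0.55, "Stroma": 0.38,
                     "CD8": 0.03, "M1": 0.02, "M2": 0.02},
        attraction={"CD8": 0.2, "M1": 0.2, "M2": 0.2},
    ),
}


@dataclass
class GroundTruth:
    """What the generator actually drew: one row per cell plus ROI metadata."""

    roi_id: str
    archetype: str
    seed: int
    cells: pd.DataFrame  # columns: cell_id, true_type, x_px, y_px, radius_px

    def type_of(self) -> pd.Series:
        return self.cells.set_index("cell_id")["true_type"]


def _place_cells(rng: np.random.Generator, n_cells: int, types: np.ndarray,
                 size_px: int, radius_px: float, min_spacing_px: float,
                 attraction: dict[str, float], interaction_radius_px: float,
                 max_attempts_per_cell: int) -> np.ndarray:
    """Dart-throwing placement honoring min spacing and tumor attraction."""
    lo, hi = radius_px, size_px - radius_px
    if hi <= lo:
        raise ValueError("ROI too small for the cell radius")
    placed = np.empty((n_cells, 2))
    tumor_xy: list[np.ndarray] = []
    sp2 = min_spacing_px ** 2
    for i, t in enumerate(types):
        near_tumor = (t in attraction and tumor_xy
                      and rng.random() < attraction[t])
        for _ in range(max_attempts_per_cell):
            if near_tumor:
                anchor = tumor_xy[rng.integers(len(tumor_xy))]
                ang = rng.uniform(0, 2 * np.pi)
                # uniform over the disk of the interaction radius
                rad = interaction_radius_px * np.sqrt(rng.random())
                cand = anchor + rad * np.array([np.cos(ang), np.sin(ang)])
                if not (lo <= cand[0] <= hi and lo <= cand[1] <= hi):
                    continue
            else:
                cand = rng.uniform(lo, hi, size=2)
            if i and np.min(np.sum((placed[:i] - cand) ** 2, axis=1)) < sp2:
                continue
            placed[i] = cand
            break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{n_cells} after "
                f"{max_attempts_per_cell} attempts; reduce n_cells or "
                "min spacing"
            )
        if t == "Tumor":
            tumor_xy.append(placed[i])
    return placed


def generate_roi(archetype: str | TissueArchetype = "inflamed",
                 n_cells: int = 400,
                 size_um: float = 500.0,
                 resolution_um: float = 1.0,
                 panel: MarkerPanel | None = None,
                 rules: list[CompositeRule] | None = None,
                 seed: int = 0,
                 *,
                 cell_diameter_px: float = 10.0,
                 min_spacing_px: float = 12.0,
                 interaction_radius_um: float = 30.0,
                 signal_mu: float = 3.0,
                 signal_sigma: float = 0.3,
                 background_lambda: float = 0.5,
                 max_attempts_per_cell: int = 2000,
                 roi_id: str | None = None,
                 ) -> tuple[MultiplexROI, LabelMask, GroundTruth]:
    """Draw one synthetic ROI with ground-truth cells.

    All randomness flows from ``seed``; two calls with identical arguments
    produce bitwise-identical stacks and masks.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if isinstance(archetype, str):
        try:
            archetype = ARCHETYPES[archetype]
        except KeyError:
            raise ValueError(
                f"unknown archetype {archetype!r}; "
                f"choose from {sorted(ARCHETYPES)}") from None
    if panel is None:
        panel = default_panel(resolution_um_per_px=resolution_um)
    elif panel.resolution_um_per_px != resolution_um:
        panel = replace(panel, resolution_um_per_px=resolution_um)
    if rules is None:
        rules = default_rules()
    validate_rules(rules, panel)
    members = {r.type_name: r.member_markers for r in rules}
    missing = [t for t in archetype.composition if t not in members]
    if missing:
        raise ValueError(f"archetype types {missing} have no composite rule")

    rng = np.random.default_rng(seed)
    size_px = int(round(size_um / resolution_um))
    radius_px = cell_diameter_px / 2.0

    type_names = [t for t in TYPE_ORDER if t in archetype.composition]
    probs = np.array([archetype.composition[t] for t in type_names])
    types = rng.choice(type_names, size=n_cells, p=probs / probs.sum())
    # Tumor cells first so immune attraction has anchors to draw near.
    types = np.array(sorted(types, key=lambda t: TYPE_ORDER.index(t)))

    xy = _place_cells(rng, n_cells, types, size_px, radius_px,
                      min_spacing_px, archetype.attraction,
                      interaction_radius_um / resolution_um,
                      max_attempts_per_cell)

    C = len(panel)
    stack = rng.poisson(background_lambda,
                        size=(C, size_px, size_px)).astype(np.float64)
    labels = np.zeros((size_px, size_px), dtype=np.int32)
    nuclear_idx = [panel.index_of(n) for n in panel.names_with_role("nuclear")]

    yy, xx = np.mgrid[0:size_px, 0:size_px]
    for cid, (t, (cx, cy)) in enumerate(zip(types, xy), start=1):
        y0 = max(int(np.floor(cy - radius_px)) - 1, 0)
        y1 = min(int(np.ceil(cy + radius_px)) + 2, size_px)
        x0 = max(int(np.floor(cx - radius_px)) - 1, 0)
        x1 = min(int(np.ceil(cx + radius_px)) + 2, size_px)
        in_disk = ((xx[y0:y1, x0:x1] - cx) ** 2
                   + (yy[y0:y1, x0:x1] - cy) ** 2) <= radius_px ** 2
        npix = int(in_disk.sum())
        labels[y0:y1, x0:x1][in_disk] = cid
        signal_channels = sorted(
            {panel.index_of(m) for m in members[t]} | set(nuclear_idx))
        for ch in signal_channels:
            sig = rng.lognormal(signal_mu, signal_sigma, size=npix)
            plane = stack[ch, y0:y1, x0:x1]
            plane[in_disk] += sig

    rid = roi_id or f"{archetype.name}-s{seed}"
    roi = MultiplexROI(roi_id=rid, stack=stack, panel=panel)
    mask = LabelMask(labels=labels)
    cells = pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),
        "true_type": types,
        "x_px": xy[:, 0],
        "y_px": xy[:, 1],
        "radius_px": np.full(n_cells, radius_px),
    })
    truth = GroundTruth(roi_id=rid, archetype=archetype.name,
                        seed=seed, cells=cells)
    return roi, mask, truth


def generate_cohort(archetype_list: list[str],
                    n_rois: int | None = None,
                    seed: int = 0,
                    **roi_kwargs,
                    ) -> tuple[list[tuple[MultiplexROI, LabelMask, GroundTruth]],
                               pd.DataFrame]:
    """Generate a cohort of ROIs, one per entry of ``archetype_list``.

    If ``n_rois`` is given the archetype list is cycled to that length.
    Per-ROI seeds derive deterministically from the master seed, so the
    whole cohort is reproducible from ``seed`` alone.
    """
    if not archetype_list:
        raise ValueError("archetype_list must be non-empty")
    if n_rois is None:
        n_rois = len(archetype_list)
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    names = [archetype_list[i % len(archetype_list)] for i in range(n_rois)]
    seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in seq.spawn(n_rois)]
    out = []
    rows = []
    for i, (name, s) in enumerate(zip(names, child_seeds)):
        rid = f"roi{i:03d}-{name}"
        roi, mask, truth = generate_roi(archetype=name, seed=s,
                                        roi_id=rid, **roi_kwargs)
        out.append((roi, mask, truth))
        rows.append({"roi_id": rid, "archetype": name, "seed": s})
    return out, pd.DataFrame(rows)
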