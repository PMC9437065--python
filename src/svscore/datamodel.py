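"""Core domain types and file I/O for multiplexed-imaging ROIs.

The pipeline works on one region of interest (ROI) at a time: a C x H x W
stack of per-marker intensity planes (imaging mass cytometry and similar,
~1 um/px), an integer label mask of segmented cells, and a marker panel with
named composite cell-type rules (Tumor, Stroma, CD8, M1, M2).

Conventions
-----------
* Pixel coordinates are 0-based with ``x = column`` and ``y = row``; the
  centroid of a labelled region is the unweighted mean of its pixel
  coordinates.  Micron centroids are pixel centroids times the panel
  resolution.
* Label masks are compacted on load: labels are renumbered 1..n preserving
  their original order, so cell tables join safely against masks.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.segmentation import relabel_sequential

__all__ = [
    "MarkerDef",
    "MarkerPanel",
    "CompositeRule",
    "MultiplexROI",
    "LabelMask",
    "CellTable",
    "ScoreReport",
    "default_panel",
    "default_rules",
    "read_panel_config",
    "write_panel_config",
    "read_roi",
    "write_roi",
    "read_label_mask",
    "write_label_mask",
    "read_cell_table",
    "write_cell_table",
    "read_score_report",
    "write_score_report",
]

MARKER_ROLES = ("nuclear", "cytosol", "functional")

#: Default stratum names along the immune continuum.
STRATA = ("inflamed", "suppressed", "cold")


# ---------------------------------------------------------------------------
# Panel and composite rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerDef:
    """One channel of the antibody panel."""

    name: str
    channel_index: int
    metal_tag: str | None = None
    role: str = "functional"

    def __post_init__(self) -> None:
        if self.role not in MARKER_ROLES:
            raise ValueError(
                f"marker {self.name!r}: role must be one of {MARKER_ROLES}, "
                f"got {self.role!r}"
            )
        if self.channel_index < 0:
            raise ValueError(f"marker {self.name!r}: negative channel index")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker metadata plus the physical resolution of the stack."""

    markers: tuple[MarkerDef, ...]
    resolution_um_per_px: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names in panel")
        idx = sorted(m.channel_index for m in self.markers)
        if idx != list(range(len(self.markers))):
            raise ValueError(
                "channel indices must be unique and contiguous from 0, "
                f"got {idx}"
            )
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution_um_per_px must be > 0")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def names(self) -> list[str]:
        """Marker names in channel order."""
        return [m.name for m in sorted(self.markers, key=lambda m: m.channel_index)]

    def index_of(self, name: str) -> int:
        for m in self.markers:
            if m.name == name:
                return m.channel_index
        raise KeyError(f"marker {name!r} not in panel")

    def names_with_role(self, role: str) -> list[str]:
        if role not in MARKER_ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [m.name for m in sorted(self.markers, key=lambda m: m.channel_index)
                if m.role == role]


@dataclass(frozen=True)
class CompositeRule:
    """A named cell type defined by member markers competing in an argmax.

    ``weight`` multiplies the mean member expression; the Tumor rule ships
    with weight 0.6 to compensate for epithelial overstaining.
    """

    type_name: str
    member_markers: tuple[str, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_markers", tuple(self.member_markers))
        if not self.member_markers:
            raise ValueError(f"rule {self.type_name!r}: no member markers")
        if not self.weight > 0:
            raise ValueError(f"rule {self.type_name!r}: weight must be > 0")


def validate_rules(rules: Sequence[CompositeRule], panel: MarkerPanel) -> None:
    """Raise if rules reference unknown markers or repeat type names."""
    names = set()
    for r in rules:
        if r.type_name in names:
            raise ValueError(f"duplicate composite type name {r.type_name!r}")
        names.add(r.type_name)
        for m in r.member_markers:
            if m not in panel.names:
                raise ValueError(
                    f"rule {r.type_name!r} references marker {m!r} "
                    "absent from panel"
                )


# Markers named in the main-text panel; the full 26-plex lives in
# supplementary tables and is user-overridable via a config file.
_DEFAULT_MARKERS = [
    # name, metal tag, role
    ("Ir191", "191Ir", "nuclear"),
    ("Ir193", "193Ir", "nuclear"),
    ("Histone3", None, "nuclear"),
    ("H3K9me3", None, "nuclear"),
    ("Ki67", None, "nuclear"),
    ("FoxP3", None, "nuclear"),
    ("ECadherin", None, "cytosol"),
    ("PanKeratin", None, "cytosol"),
    ("Vimentin", None, "cytosol"),
    ("CD20", None, "cytosol"),
    ("GranzymeB", None, "cytosol"),
    ("CD68", None, "cytosol"),
    ("HLA-DR", None, "cytosol"),
    ("CD8a", None, "functional"),
    ("CD163", None, "functional"),
    ("CD206", None, "functional"),
    ("Col1", None, "functional"),
    ("SMA", None, "functional"),
    ("CD3", None, "functional"),
    ("CD4", None, "functional"),
]

_DEFAULT_RULES = [
    # Rule order doubles as the deterministic argmax tie-break order.
    ("Tumor", ("ECadherin", "PanKeratin"), 0.6),
    ("Stroma", ("Col1", "SMA"), 1.0),
    ("CD8", ("CD8a",), 1.0),
    ("M1", ("CD68", "HLA-DR"), 1.0),
    ("M2", ("CD68", "CD163", "CD206"), 1.0),
]


def default_panel(resolution_um_per_px: float = 1.0) -> MarkerPanel:
    """The shipped panel: the markers named in the main text, in a fixed order."""
    markers = tuple(
        MarkerDef(name=n, channel_index=i, metal_tag=tag, role=role)
        for i, (n, tag, role) in enumerate(_DEFAULT_MARKERS)
    )
    return MarkerPanel(markers=markers, resolution_um_per_px=resolution_um_per_px)


def default_rules() -> list[CompositeRule]:
    """The five shipped composite rules (Tumor weighted 0.6)."""
    return [CompositeRule(t, m, w) for t, m, w in _DEFAULT_RULES]


def write_panel_config(path: str | os.PathLike,
                       panel: MarkerPanel,
                       rules: Sequence[CompositeRule]) -> None:
    """Serialize a panel + rule set as a JSON config file."""
    payload = {
        "resolution_um_per_px": panel.resolution_um_per_px,
        "markers": [
            {"name": m.name, "channel_index": m.channel_index,
             "metal_tag": m.metal_tag, "role": m.role}
            for m in sorted(panel.markers, key=lambda m: m.channel_index)
        ],
        "rules": [
            {"type_name": r.type_name,
             "member_markers": list(r.member_markers),
             "weight": r.weight}
            for r in rules
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_panel_config(path: str | os.PathLike
                      ) -> tuple[MarkerPanel, list[CompositeRule]]:
    """Parse a JSON panel config; validates panel and rule invariants."""
    with open(path) as fh:
        payload = json.load(fh)
    markers = tuple(
        MarkerDef(name=m["name"], channel_index=int(m["channel_index"]),
                  metal_tag=m.get("metal_tag"),
                  role=m.get("role", "functional"))
        for m in payload["markers"]
    )
    panel = MarkerPanel(markers=markers,
                        resolution_um_per_px=float(
                            payload.get("resolution_um_per_px", 1.0)))
    rules = [
        CompositeRule(type_name=r["type_name"],
                      member_markers=tuple(r["member_markers"]),
                      weight=float(r.get("weight", 1.0)))
        for r in payload.get("rules", [])
    ]
    validate_rules(rules, panel)
    return panel, rules


# ---------------------------------------------------------------------------
# ROI stack and label mask
# ---------------------------------------------------------------------------

@dataclass
class MultiplexROI:
    """A C x H x W stack of non-negative marker intensities."""

    roi_id: str
    stack: np.ndarray
    panel: MarkerPanel

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3:
            raise ValueError("stack must be C x H x W")
        if self.stack.shape[0] != len(self.panel):
            raise ValueError(
                f"stack has {self.stack.shape[0]} channels but panel "
                f"defines {len(self.panel)}"
            )
        if self.stack.shape[1] < 1 or self.stack.shape[2] < 1:
            raise ValueError("stack spatial dims must be >= 1")
        if np.any(self.stack < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.stack.shape

    def channel(self, marker: str) -> np.ndarray:
        """The 2-D plane for one marker, by name."""
        return self.stack[self.panel.index_of(marker)]


@dataclass
class LabelMask:
    """Integer cell mask: 0 = background, positive ints = cell ids.

    Labels are compacted (renumbered 1..n preserving order) at
    construction, so downstream tables can assume a gap-free label set.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")
        if labels.min() < 0:
            raise ValueError("label mask must be non-negative")
        self.labels, _, _ = relabel_sequential(labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def check_matches(self, roi: MultiplexROI) -> None:
        if self.shape != roi.stack.shape[1:]:
            raise ValueError(
                f"mask shape {self.shape} does not match ROI "
                f"{roi.stack.shape[1:]}"
            )


def read_roi(path: str | os.PathLike, panel: MarkerPanel,
             roi_id: str | None = None) -> MultiplexROI:
    """Read an ROI stack from a multichannel TIFF or a per-marker directory.

    A directory must contain one single-channel TIFF per panel marker whose
    filename stem equals the marker name (e.g. ``CD8a.tiff``).
    """
    path = os.fspath(path)
    rid = roi_id or os.path.splitext(os.path.basename(path))[0]
    if os.path.isdir(path):
        by_stem: dict[str, str] = {}
        for fn in sorted(os.listdir(path)):
            stem, ext = os.path.splitext(fn)
            if ext.lower() in (".tif", ".tiff"):
                by_stem[stem] = os.path.join(path, fn)
        planes = []
        for name in panel.names:
            if name not in by_stem:
                raise FileNotFoundError(
                    f"no TIFF for marker {name!r} in {path}"
                )
            plane = tifffile.imread(by_stem[name])
            if plane.ndim != 2:
                raise ValueError(f"{by_stem[name]} is not single-channel 2-D")
            planes.append(plane)
        shapes = {p.shape for p in planes}
        if len(shapes) > 1:
            raise ValueError(f"channel shape mismatch across files: {shapes}")
        stack = np.stack(planes)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise ValueError(f"{path}: expected a C x H x W TIFF")
        if stack.shape[0] != len(panel):
            raise ValueError(
                f"{path} has {stack.shape[0]} channels, panel defines "
                f"{len(panel)}"
            )
    # Intensities are used unchanged; only the dtype is widened to float.
    return MultiplexROI(roi_id=rid, stack=stack.astype(np.float64),
                        panel=panel)


def write_roi(roi: MultiplexROI, path: str | os.PathLike) -> None:
    """Write the stack as a multichannel TIFF (dtype preserved)."""
    tifffile.imwrite(os.fspath(path), roi.stack)


def read_label_mask(path: str | os.PathLike) -> LabelMask:
    arr = tifffile.imread(os.fspath(path))
    return LabelMask(labels=np.asarray(arr).astype(np.int32))


def write_label_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    labels = mask.labels
    dtype = np.uint16 if labels.max() < 2 ** 16 else np.int32
    tifffile.imwrite(os.fspath(path), labels.astype(dtype))


# ---------------------------------------------------------------------------
# Cell table
# ---------------------------------------------------------------------------

_CELL_BASE_COLS = [
    "cell_id", "centroid_x_px", "centroid_y_px",
    "centroid_x_um", "centroid_y_um", "area_px",
]


@dataclass
class CellTable:
    """Per-cell features: centroids, areas, mean marker expression, labels.

    Backed by a :class:`pandas.DataFrame` with one row per cell; marker
    means live in ``mean_<marker>`` columns in panel channel order.
    """

    df: pd.DataFrame
    marker_names: list[str]

    def __post_init__(self) -> None:
        for col in _CELL_BASE_COLS:
            if col not in self.df.columns:
                raise ValueError(f"cell table missing column {col!r}")
        for name in self.marker_names:
            if f"mean_{name}" not in self.df.columns:
                raise ValueError(f"cell table missing column mean_{name!r}")
        if self.df["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_ids")
        if "cluster_id" not in self.df.columns:
            self.df["cluster_id"] = pd.Series([pd.NA] * len(self.df),
                                              dtype="Int64")
        if "cell_type" not in self.df.columns:
            self.df["cell_type"] = pd.Series([pd.NA] * len(self.df),
                                             dtype="string")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mean_expr(self) -> np.ndarray:
        """(n_cells, C) matrix of per-marker mean expression."""
        cols = [f"mean_{n}" for n in self.marker_names]
        return self.df[cols].to_numpy(dtype=float)

    @property
    def centroids_um(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) centroids in microns."""
        return self.df[["centroid_x_um", "centroid_y_um"]].to_numpy(float)

    def with_types(self, types: Sequence[str]) -> "CellTable":
        out = self.df.copy()
        out["cell_type"] = pd.array(list(types), dtype="string")
        return CellTable(df=out, marker_names=list(self.marker_names))


def write_cell_table(table: CellTable, path: str | os.PathLike) -> None:
    """CSV with header; floats written to 10 significant figures."""
    table.df.to_csv(os.fspath(path), index=False, float_format="%.10g")


def read_cell_table(path: str | os.PathLike) -> CellTable:
    """Read a cell table CSV; malformed rows raise with their line number."""
    try:
        df = pd.read_csv(os.fspath(path))
    except pd.errors.ParserError as exc:  # carries the offending line number
        raise ValueError(f"malformed cell table {path}: {exc}") from exc
    marker_names = [c[len("mean_"):] for c in df.columns
                    if c.startswith("mean_")]
    num_cols = _CELL_BASE_COLS + [f"mean_{n}" for n in marker_names]
    for col in num_cols:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: 1-based line numbering plus the header line
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{path}: malformed value in column {col!r} at line {line}"
            )
        df[col] = coerced
    if len(df):
        df["cell_id"] = df["cell_id"].astype(int)
        df["area_px"] = df["area_px"].astype(int)
    if "cluster_id" in df.columns:
        df["cluster_id"] = pd.array(
            pd.to_numeric(df["cluster_id"], errors="coerce"), dtype="Int64")
    if "cell_type" in df.columns:
        df["cell_type"] = df["cell_type"].astype("string")
    return CellTable(df=df, marker_names=marker_names)


# ---------------------------------------------------------------------------
# Score report
# ---------------------------------------------------------------------------

def pair_key(a: str, b: str, order: Sequence[str] | None = None
             ) -> tuple[str, str]:
    """Canonical unordered pair key; sorted by ``order`` if given else
    lexicographically."""
    if order is not None:
        rank = {t: i for i, t in enumerate(order)}
        return tuple(sorted((a, b), key=lambda t: rank.get(t, len(rank))))  # type: ignore[return-value]
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass
class ScoreReport:
    """Per-ROI spatial neighboring scores.

    ``raw_scores`` / ``scaled_scores`` map canonical unordered type pairs
    (including self pairs) to the mean per-patch pair score in [0, 1] and
    its 0-10 scaled version.  ``heatmaps`` optionally carries the per-pair
    patch-grid score arrays used for visualization.
    """

    roi_id: str
    type_order: tuple[str, ...]
    raw_scores: dict[tuple[str, str], float]
    scaled_scores: dict[tuple[str, str], float]
    densities: dict[str, float] = field(default_factory=dict)
    stratum: str | None = None
    heatmaps: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.raw_scores.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"raw score {k} = {v} outside [0, 1]")
        for k, v in self.scaled_scores.items():
            if not (0.0 <= v <= 10.0):
                raise ValueError(f"scaled score {k} = {v} outside [0, 10]")
        if self.stratum is not None and self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")

    def raw(self, a: str, b: str) -> float:
        return self.raw_scores[pair_key(a, b, self.type_order)]

    def scaled(self, a: str, b: str) -> float:
        return self.scaled_scores[pair_key(a, b, self.type_order)]

    @property
    def ranking_key(self) -> float | None:
        """The CD8-Tumor scaled score used to rank ROIs on the immune
        continuum, if both types are present."""
        key = pair_key("CD8", "Tumor", self.type_order)
        return self.scaled_scores.get(key)


def write_score_report(report: ScoreReport, path: str | os.PathLike) -> None:
    """Write pair scores as CSV plus a JSON sidecar with provenance.

    The CSV holds one row per unordered type pair (self pairs included) in
    deterministic order; the sidecar records densities, the stratum, the
    ranking key and the run configuration (radius, patch size, thresholds).
    """
    path = os.fspath(path)
    rows = []
    for a, b in itertools.combinations_with_replacement(report.type_order, 2):
        key = pair_key(a, b, report.type_order)
        rows.append({
            "type_a": key[0], "type_b": key[1],
            "raw_score": report.raw_scores[key],
            "scaled_score": report.scaled_scores[key],
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "roi_id": report.roi_id,
        "type_order": list(report.type_order),
        "densities": report.densities,
        "stratum": report.stratum,
        "ranking_key_cd8_tumor": report.ranking_key,
        "config": report.config,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def _sidecar_path(csv_path: str) -> str:
    base, _ = os.path.splitext(csv_path)
    return base + ".json"


def read_score_report(path: str | os.PathLike) -> ScoreReport:
    path = os.fspath(path)
    df = pd.read_csv(path)
    with open(_sidecar_path(path)) as fh:
        sidecar = json.load(fh)
    order = tuple(sidecar["type_order"])
    raw = {}
    scaled = {}
    for _, row in df.iterrows():
        key = pair_key(row["type_a"], row["type_b"], order)
        raw[key] = float(row["raw_score"])
        scaled[key] = float(row["scaled_score"])
    return ScoreReport(
        roi_id=sidecar["roi_id"],
        type_order=order,
        raw_scores=raw,
        scaled_scores=scaled,
        densities={k: float(v) for k, v in sidecar["densities"].items()},
        stratum=sidecar["stratum"],
        config=sidecar.get("config", {}),
    )
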