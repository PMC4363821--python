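"""Junctional ribbon quantification of tight-junction protein localization.

The measurement this module automates: in a mosaic monolayer containing
both control and knockout cells, trace thin ribbons (default 0.5 um wide)
along the tight-junction marker signal, classify each cell-cell side as
control/control, knockout/knockout, or a control-knockout boundary from
the genotypes of the two flanking cells, and compare the target-protein
signal between the classes.

Two ratio statistics are produced:

* ``rel_ko = D_KO / D_CTL`` — how much target signal remains at junctions
  between two knockout cells, relative to control junctions.
* ``rel_boundary = (D_Boundary - D_KO) / (D_CTL - D_KO)`` — the
  background-corrected efficiency with which the target localises at
  junctions between a control and a knockout cell (1 = like control,
  0 = indistinguishable from knockout background).

Densities entering the cross-class ratios are integrated densities per
unit ROI area (sum of pixel values / ROI pixel count) so that ribbons of
unequal length are comparable.  Manual tracing is replaced by an
operator-free default: Otsu threshold of the Gaussian-smoothed marker
channel, morphological skeletonization, and splitting at tricellular
nodes (degree >= 3 skeleton pixels, excluded with a 0.5-um guard zone).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as _draw
from skimage import filters as _filters
from skimage import morphology as _morphology

from .errors import DegenerateDesignError, NoJunctionError, OutOfRangeError

__all__ = [
    "MonolayerImage",
    "GenotypeField",
    "RibbonROI",
    "QuantResult",
    "extract_junction_skeleton",
    "build_ribbon",
    "classify_ribbon",
    "integrated_density",
    "relative_intensity",
    "boundary_relative_intensity",
    "quantify_image",
    "genotype_from_reporter",
    "path_length_um",
    "BOUNDARY_CLASSES",
]

BOUNDARY_CLASSES = ("CTL_CTL", "KO_KO", "BOUNDARY")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MonolayerImage:
    """Multichannel 2-D image with physical pixel size and channel roles."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    channel_roles: dict[str, str]

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise OutOfRangeError("pixel_size_um must be positive")
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise OutOfRangeError(f"channels have mismatched shapes: {shapes}")
        for role in ("tj_marker", "target"):
            if role not in self.channel_roles:
                raise OutOfRangeError(f"channel role {role!r} missing")
            if self.channel_roles[role] not in self.channels:
                raise OutOfRangeError(
                    f"role {role!r} maps to unknown channel {self.channel_roles[role]!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        return self.channels[self.channel_roles[role]]


@dataclass
class GenotypeField:
    """Per-pixel genotype labels: 0 control, 1 knockout, 2 other/rescue."""

    labels: np.ndarray
    provenance: str = "ground_truth"  # or "thresholded_reporter"

    def __post_init__(self) -> None:
        extra = set(np.unique(self.labels)) - {0, 1, 2}
        if extra:
            raise OutOfRangeError(f"unexpected genotype labels {sorted(extra)}")


@dataclass
class RibbonROI:
    """A ribbon mask around one junction segment.

    The boolean mask is stored on a cropped window (``origin`` is the
    (row, col) of its upper-left corner in field coordinates) to keep
    memory proportional to ribbon size; :meth:`full_mask` expands it.
    """

    path: np.ndarray  # (N, 2) float, field (row, col) pixel coordinates
    width_um: float
    mask: np.ndarray  # cropped boolean window
    origin: tuple[int, int]
    field_shape: tuple[int, int]
    area_px: int
    boundary_class: Optional[str] = None

    @property
    def slices(self) -> tuple[slice, slice]:
        r0, c0 = self.origin
        return (slice(r0, r0 + self.mask.shape[0]), slice(c0, c0 + self.mask.shape[1]))

    def full_mask(self) -> np.ndarray:
        out = np.zeros(self.field_shape, dtype=bool)
        out[self.slices] = self.mask
        return out


@dataclass
class QuantResult:
    """Per-image class densities and the two relative-intensity statistics.

    Densities are per-class means of per-area integrated densities
    (a.u. per pixel).  ``None`` marks a class with no classified segments.
    """

    d_ctl: Optional[float]
    d_ko: Optional[float]
    d_boundary: Optional[float]
    rel_ko: Optional[float]
    rel_boundary: Optional[float]
    n_sides_per_class: int
    seed: int
    image_id: str = ""
    shortfall: dict = field(default_factory=dict)
    ribbon_table: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# skeleton extraction
# ---------------------------------------------------------------------------

_NBR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def _order_path(coords: np.ndarray) -> np.ndarray:
    """Order the pixels of a thin connected segment into a walkable path."""
    pts = [tuple(p) for p in coords]
    pset = set(pts)
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r, c in pts:
        nbrs = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in pset:
                    nbrs.append(q)
        adj[(r, c)] = sorted(nbrs)
    endpoints = sorted(p for p, nb in adj.items() if len(nb) <= 1)
    start = endpoints[0] if endpoints else min(pts)
    path = [start]
    visited = {start}
    current = start
    while True:
        nxt = [q for q in adj[current] if q not in visited]
        if not nxt:
            break
        # prefer 4-connected steps for a smoother walk
        nxt.sort(key=lambda q: (abs(q[0] - current[0]) + abs(q[1] - current[1]), q))
        current = nxt[0]
        path.append(current)
        visited.add(current)
    return np.asarray(path, dtype=float)


def path_length_um(path: np.ndarray, pixel_size_um: float) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.diff(np.asarray(path, dtype=float), axis=0)
    return float(np.sqrt((steps**2).sum(axis=1)).sum() * pixel_size_um)


def extract_junction_skeleton(
    marker_field: np.ndarray,
    pixel_size_um: float,
    threshold_method: str = "otsu",
    smooth_sigma_um: float = 0.2,
    min_length_um: float = 1.0,
    node_exclusion_um: float = 0.5,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Single-pixel skeleton of the marker signal, split at tricellular nodes.

    Returns a list of ordered polylines (float (N, 2) arrays of (row, col))
    and the array of node pixels (degree >= 3).  Segments shorter than
    ``min_length_um`` are discarded; skeleton pixels within
    ``node_exclusion_um`` of a node are removed before splitting so that
    tricellular corners, where three cells meet, never enter a ribbon.
    """
    marker = np.asarray(marker_field, dtype=float)
    if marker.max() == marker.min():
        raise NoJunctionError("marker channel is constant: no junctions to trace")
    if pixel_size_um <= 0:
        raise OutOfRangeError("pixel_size_um must be positive")
    sigma_px = smooth_sigma_um / pixel_size_um
    smooth = ndimage.gaussian_filter(marker, sigma_px) if sigma_px > 0 else marker
    if threshold_method == "otsu":
        thresh = _filters.threshold_otsu(smooth)
    elif threshold_method == "li":
        thresh = _filters.threshold_li(smooth)
    else:
        raise OutOfRangeError(f"unknown threshold_method {threshold_method!r}")
    skel = _morphology.skeletonize(smooth > thresh)
    if not skel.any():
        raise NoJunctionError("empty skeleton after thresholding")

    nbrs = ndimage.convolve(skel.astype(np.uint8), _NBR_KERNEL, mode="constant")
    nodes = skel & (nbrs >= 3)
    keep = skel.copy()
    if nodes.any():
        dist_to_node = ndimage.distance_transform_edt(~nodes)
        keep &= dist_to_node > node_exclusion_um / pixel_size_um

    labeled, n_seg = ndimage.label(keep, structure=np.ones((3, 3), dtype=int))
    polylines: list[np.ndarray] = []
    for idx in range(1, n_seg + 1):
        coords = np.argwhere(labeled == idx)
        path = _order_path(coords)
        if path_length_um(path, pixel_size_um) >= min_length_um:
            polylines.append(path)
    if not polylines:
        raise NoJunctionError("no junction segment longer than the minimum length")
    return polylines, np.argwhere(nodes)


# ---------------------------------------------------------------------------
# ribbons
# ---------------------------------------------------------------------------

def build_ribbon(
    polyline: np.ndarray,
    width_um: float,
    pixel_size_um: float,
    field_shape: tuple[int, int],
    boundary_class: Optional[str] = None,
) -> RibbonROI:
    """Euclidean dilation of a polyline to a ribbon of the given width.

    The mask contains every pixel within ``width_um / 2`` of the rasterised
    polyline.  Vertices outside the field are clipped with a warning.
    """
    if width_um <= 0:
        raise OutOfRangeError("width_um must be positive")
    path = np.asarray(polyline, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or len(path) == 0:
        raise OutOfRangeError("polyline must be a non-empty (N, 2) array")

    nrow, ncol = field_shape
    if (path < -0.5).any() or (path[:, 0] > nrow - 0.5).any() or (path[:, 1] > ncol - 0.5).any():
        warnings.warn("polyline extends outside the field; ribbon clipped", stacklevel=2)
        path = path.copy()
        path[:, 0] = np.clip(path[:, 0], 0, nrow - 1)
        path[:, 1] = np.clip(path[:, 1], 0, ncol - 1)

    radius_px = 0.5 * width_um / pixel_size_um
    pad = int(math.ceil(radius_px)) + 1
    r0 = max(0, int(math.floor(path[:, 0].min())) - pad)
    r1 = min(nrow, int(math.ceil(path[:, 0].max())) + pad + 1)
    c0 = max(0, int(math.floor(path[:, 1].min())) - pad)
    c1 = min(ncol, int(math.ceil(path[:, 1].max())) + pad + 1)

    line = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    verts = np.round(path).astype(int)
    if len(verts) == 1:
        line[verts[0, 0] - r0, verts[0, 1] - c0] = True
    for a, b in zip(verts[:-1], verts[1:]):
        rr, cc = _draw.line(a[0] - r0, a[1] - c0, b[0] - r0, b[1] - c0)
        line[rr, cc] = True
    dist = ndimage.distance_transform_edt(~line)
    mask = dist <= radius_px
    return RibbonROI(
        path=path,
        width_um=width_um,
        mask=mask,
        origin=(r0, c0),
        field_shape=tuple(field_shape),
        area_px=int(mask.sum()),
        boundary_class=boundary_class,
    )


def classify_ribbon(
    ribbon: RibbonROI,
    genotype_field: GenotypeField,
    pixel_size_um: float,
    offset_um: Optional[float] = None,
) -> Optional[str]:
    """Boundary class of a ribbon from the genotypes of its flanking cells.

    The path is offset by +/- ``offset_um`` (default: the ribbon width)
    along local normals and the genotype labels are sampled on both sides;
    the per-side majority labels decide the class.  Returns ``None`` when a
    side cannot be sampled (image edge) or involves labels outside {0, 1}.
    """
    labels = genotype_field.labels
    if labels.shape != ribbon.field_shape:
        raise OutOfRangeError("genotype field shape does not match the image")
    path = ribbon.path
    if len(path) < 2:
        return None
    off_px = (offset_um if offset_um is not None else ribbon.width_um) / pixel_size_um

    tangents = np.gradient(path, axis=0)
    norms = np.linalg.norm(tangents, axis=1)
    norms[norms == 0] = 1.0
    tangents /= norms[:, None]
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)

    side_labels = []
    for sign in (+1.0, -1.0):
        pts = np.round(path + sign * off_px * normals).astype(int)
        ok = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] < labels.shape[0])
            & (pts[:, 1] >= 0)
            & (pts[:, 1] < labels.shape[1])
        )
        pts = pts[ok]
        if len(pts) == 0:
            return None
        vals = labels[pts[:, 0], pts[:, 1]]
        counts = np.bincount(vals, minlength=3)
        side_labels.append(int(np.argmax(counts)))

    a, b = sorted(side_labels)
    if (a, b) == (0, 0):
        return "CTL_CTL"
    if (a, b) == (1, 1):
        return "KO_KO"
    if (a, b) == (0, 1):
        return "BOUNDARY"
    return None


# ---------------------------------------------------------------------------
# densities and ratios
# ---------------------------------------------------------------------------

def integrated_density(
    target_field: np.ndarray,
    ribbon: RibbonROI,
    per_area: bool = False,
) -> float:
    """Sum of target-channel pixel values over the ribbon mask.

    ``per_area=True`` divides by the pixel count, giving the mean gray
    value -- the form used for cross-class comparisons so ribbons of
    different lengths are commensurable.
    """
    if ribbon.area_px == 0:
        raise DegenerateDesignError("empty ribbon mask")
    crop = np.asarray(target_field, dtype=float)[ribbon.slices]
    total = float(crop[ribbon.mask].sum())
    return total / ribbon.area_px if per_area else total


def relative_intensity(d_ko: float, d_ctl: float) -> float:
    """D_KO / D_CTL."""
    if d_ctl <= 0:
        raise DegenerateDesignError(f"D_CTL must be positive, got {d_ctl}")
    return d_ko / d_ctl


def boundary_relative_intensity(d_boundary: float, d_ko: float, d_ctl: float) -> float:
    """(D_Boundary - D_KO) / (D_CTL - D_KO).

    The knockout-junction density subtracts as a nonspecific background:
    the statistic is 1 when boundary junctions look like control junctions
    and 0 when they are indistinguishable from knockout background.
    """
    if d_ctl <= d_ko:
        raise DegenerateDesignError(
            f"degenerate denominator: D_CTL ({d_ctl}) must exceed D_KO ({d_ko})"
        )
    return (d_boundary - d_ko) / (d_ctl - d_ko)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def quantify_image(
    image: MonolayerImage,
    genotype_field: GenotypeField,
    n_sides: int = 5,
    seed: int = 0,
    width_um: float = 0.5,
    image_id: str = "",
    **skeleton_kwargs,
) -> QuantResult:
    """Skeletonize, build ribbons, classify, sample sides, and form ratios.

    ``n_sides`` segments per class are drawn uniformly at random under
    ``seed``; when a class has fewer classified segments the available
    count is used and recorded in ``shortfall``.  Deterministic for a
    fixed (image, genotype field, seed).
    """
    if n_sides < 1:
        raise OutOfRangeError("n_sides must be >= 1")
    px = image.pixel_size_um
    marker = image.channel("tj_marker")
    target = image.channel("target")
    polylines, _nodes = extract_junction_skeleton(marker, px, **skeleton_kwargs)

    ribbons: list[RibbonROI] = []
    for poly in polylines:
        rib = build_ribbon(poly, width_um, px, image.shape)
        if rib.area_px == 0:
            continue
        rib.boundary_class = classify_ribbon(rib, genotype_field, px)
        ribbons.append(rib)

    by_class: dict[str, list[int]] = {cls: [] for cls in BOUNDARY_CLASSES}
    for i, rib in enumerate(ribbons):
        if rib.boundary_class in by_class:
            by_class[rib.boundary_class].append(i)

    rng = np.random.default_rng(seed)
    sampled: dict[str, list[int]] = {}
    shortfall: dict[str, int] = {}
    densities: dict[str, Optional[float]] = {}
    for cls in BOUNDARY_CLASSES:
        avail = by_class[cls]
        if not avail:
            densities[cls] = None
            shortfall[cls] = n_sides
            sampled[cls] = []
            continue
        k = min(n_sides, len(avail))
        if k < n_sides:
            shortfall[cls] = n_sides - k
        chosen = sorted(rng.choice(len(avail), size=k, replace=False).tolist())
        sampled[cls] = [avail[j] for j in chosen]
        densities[cls] = float(
            np.mean([integrated_density(target, ribbons[i], per_area=True) for i in sampled[cls]])
        )

    d_ctl, d_ko, d_bnd = densities["CTL_CTL"], densities["KO_KO"], densities["BOUNDARY"]
    rel_ko = rel_bnd = None
    if d_ctl is not None and d_ko is not None:
        try:
            rel_ko = relative_intensity(d_ko, d_ctl)
        except DegenerateDesignError:
            rel_ko = None
        if d_bnd is not None:
            try:
                rel_bnd = boundary_relative_intensity(d_bnd, d_ko, d_ctl)
            except DegenerateDesignError:
                rel_bnd = None

    sampled_flat = {i for idxs in sampled.values() for i in idxs}
    table = pd.DataFrame(
        {
            "segment_id": range(len(ribbons)),
            "boundary_class": [r.boundary_class for r in ribbons],
            "length_um": [path_length_um(r.path, px) for r in ribbons],
            "area_px": [r.area_px for r in ribbons],
            "density_per_px": [integrated_density(target, r, per_area=True) for r in ribbons],
            "sampled": [i in sampled_flat for i in range(len(ribbons))],
        }
    )
    return QuantResult(
        d_ctl=d_ctl,
        d_ko=d_ko,
        d_boundary=d_bnd,
        rel_ko=rel_ko,
        rel_boundary=rel_bnd,
        n_sides_per_class=n_sides,
        seed=seed,
        image_id=image_id,
        shortfall=shortfall,
        ribbon_table=table,
    )


def genotype_from_reporter(
    reporter_field: np.ndarray,
    pixel_size_um: float,
    closing_um: float = 0.5,
) -> GenotypeField:
    """Threshold a genotype-reporter channel (e.g. EGFP in knockout cells)
    into per-pixel labels: reporter-positive pixels become label 1."""
    rep = np.asarray(reporter_field, dtype=float)
    if rep.max() == rep.min():
        raise NoJunctionError("reporter channel is constant: cannot threshold genotypes")
    mask = rep > _filters.threshold_otsu(rep)
    radius = max(1, int(round(closing_um / pixel_size_um)))
    mask = _morphology.closing(mask, _morphology.disk(radius))
    mask = ndimage.binary_fill_holes(mask)
    return GenotypeField(labels=mask.astype(np.int32), provenance="thresholded_reporter")
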