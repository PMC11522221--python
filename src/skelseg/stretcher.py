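"""Geometric removal of the scanner stretcher (patient couch) from axial CT.

The couch shows up as a high-attenuation curved band near one image edge and
would otherwise be confused with cortical bone by any intensity-based method.
Working in a frame where the couch faces the LEFT edge, the algorithm:

1. binarizes a reference slice at 98 HU;
2. estimates three vertical separating lines between the couch's inner edge
   and the body — ``i1`` for the central rows, ``i2`` for the inclined zones,
   ``i3`` for the extremes — each the integer midpoint of its local gap;
3. splits the image height into eight equal bands R1–R8 and builds a margin
   polyline following the column schedule i3 (R1–R2), i2 (R3), i1 (R4–R5),
   i2 (R6), i3 (R7–R8), extended vertically to the top and bottom rows;
4. fills everything left of (and on) the polyline into a stretcher mask;
5. adapts that mask to every slice of the volume by dilation plus absorption
   of couch accessories (connected components mostly inside the dilated
   mask), and zeroes the masked voxels.

Coordinates are 0-based, rows top-to-bottom, bands half-open ``[r_{k-1}, r_k)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import NoStretcherError
from .volume_io import CTVolume, MaskRole, MaskVolume

__all__ = [
    "MarginLines",
    "RegionBands",
    "MarginPolyline",
    "binarize_slice",
    "locate_margin_lines",
    "build_margin_polyline",
    "fill_stretcher_mask",
    "adapt_mask_to_slice",
    "remove_stretcher",
    "DEFAULT_BINARIZE_HU",
    "DEFAULT_GAP",
    "DEFAULT_DILATION_RADIUS",
    "DEFAULT_ACCESSORY_FRACTION",
]

logger = logging.getLogger(__name__)

DEFAULT_BINARIZE_HU = 98.0
DEFAULT_GAP = 5
DEFAULT_DILATION_RADIUS = 3
DEFAULT_ACCESSORY_FRACTION = 0.5

# 8-connectivity: the couch shell may be one pixel thick on a diagonal.
_CONN8 = np.ones((3, 3), dtype=bool)

N_BANDS = 8
# Band -> separating line schedule, R1..R8.
_BAND_SCHEDULE = ("i3", "i3", "i2", "i1", "i1", "i2", "i3", "i3")
_LINE_BANDS = {"i1": (3, 4), "i2": (2, 5), "i3": (1, 6)}  # 0-based band indices


@dataclass(frozen=True)
class MarginLines:
    """The three vertical separating columns, ``i3 <= i2 <= i1`` (left frame)."""

    i1: int
    i2: int
    i3: int
    width: int

    def __post_init__(self) -> None:
        if not (0 <= self.i3 <= self.i2 <= self.i1 < self.width):
            raise ValueError(
                f"margin lines must satisfy 0 <= i3 <= i2 <= i1 < width, "
                f"got i1={self.i1}, i2={self.i2}, i3={self.i3}, width={self.width}"
            )


@dataclass(frozen=True)
class RegionBands:
    """Nine row indices r0..r8 splitting the height into 8 near-equal bands."""

    boundaries: tuple[int, ...]

    @classmethod
    def from_height(cls, height: int) -> "RegionBands":
        if height < N_BANDS:
            raise ValueError(f"image height {height} < {N_BANDS} bands")
        return cls(tuple((k * height) // N_BANDS for k in range(N_BANDS + 1)))

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) != N_BANDS + 1 or b[0] != 0 or any(b[k] >= b[k + 1] for k in range(N_BANDS)):
            raise ValueError(f"invalid band boundaries {b!r}")
        heights = [b[k + 1] - b[k] for k in range(N_BANDS)]
        if max(heights) - min(heights) > 1:
            raise ValueError(f"band heights differ by more than 1: {heights!r}")

    @property
    def height(self) -> int:
        return self.boundaries[-1]

    def band_of(self, row: int) -> int:
        """0-based band index of a row."""
        return int(np.searchsorted(self.boundaries, row, side="right") - 1)

    def rows_of(self, band: int) -> range:
        return range(self.boundaries[band], self.boundaries[band + 1])


@dataclass(frozen=True)
class MarginPolyline:
    """Margin separating the stretcher from the body, top to bottom.

    ``points`` are the polyline vertices (row strictly increasing, first row 0,
    last row height-1); ``labels`` attaches the eight intersection points
    Pe1—Pi1—Pi3—Pe3—Pe4—Pi4—Pi2—Pe2 in traversal order when the three lines
    are distinct; ``columns[r]`` is the rasterized margin column for row r.
    """

    points: tuple[tuple[int, int], ...]
    columns: tuple[int, ...]
    labels: tuple[tuple[str, tuple[int, int]], ...] = field(default=())

    @property
    def height(self) -> int:
        return len(self.columns)


def binarize_slice(slice_hu: np.ndarray, threshold: float = DEFAULT_BINARIZE_HU) -> np.ndarray:
    """Binarize a 2D HU slice: 1 exactly where HU >= threshold."""
    slice_hu = np.asarray(slice_hu)
    if slice_hu.ndim != 2:
        raise ValueError(f"expected a 2D slice, got {slice_hu.ndim} axes")
    if not np.all(np.isfinite(slice_hu)):
        raise ValueError("slice contains non-finite values")
    return (slice_hu >= threshold).astype(np.uint8)


def _stretcher_component(binary: np.ndarray):
    """Label map and the label of the couch candidate (leftmost component).

    The candidate is the connected component whose leftmost pixel is closest
    to the left margin, restricted to components starting in the left third.
    Returns ``(labels, stretcher_label)`` or raises :class:`NoStretcherError`.
    """
    labels, n = ndi.label(binary, structure=_CONN8)
    if n == 0:
        raise NoStretcherError("binarized slice contains no foreground")
    width = binary.shape[1]
    objects = ndi.find_objects(labels)
    best = None
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        min_col = sl[1].start
        if min_col >= width / 3:
            continue
        area = int(np.sum(labels[sl] == lab))
        key = (min_col, -area)
        if best is None or key < best[0]:
            best = (key, lab)
    if best is None:
        raise NoStretcherError("no foreground component starts in the left third")
    return labels, best[1]


def locate_margin_lines(
    binary: np.ndarray, gap: int = DEFAULT_GAP
) -> MarginLines:
    """Estimate the three vertical separating lines from a binarized slice.

    For each line's designated row bands, the couch's inner edge is the
    rightmost column of the left-attached (couch) component and the body
    limit is the leftmost other-component foreground column lying more than
    ``gap`` pixels right of that edge; the line is their integer midpoint.
    """
    binary = np.asarray(binary).astype(bool)
    height, width = binary.shape
    labels, stretcher_label = _stretcher_component(binary)
    bands = RegionBands.from_height(height)

    stretcher = labels == stretcher_label
    other = binary & ~stretcher
    cols = np.arange(width)

    global_inner = int(cols[stretcher.any(axis=0)].max())
    other_cols_global = cols[other.any(axis=0)]
    beyond = other_cols_global[other_cols_global > global_inner + gap]
    global_body = int(beyond.min()) if beyond.size else width - 1

    def _line_for(band_ids) -> int:
        rows = np.zeros(height, dtype=bool)
        for b in band_ids:
            rows[bands.boundaries[b] : bands.boundaries[b + 1]] = True
        strip = stretcher[rows]
        inner = int(cols[strip.any(axis=0)].max()) if strip.any() else global_inner
        body_strip = other[rows]
        body_cols = cols[body_strip.any(axis=0)]
        body_cols = body_cols[body_cols > inner + gap]
        body = int(body_cols.min()) if body_cols.size else global_body
        if body <= inner:
            body = min(width - 1, inner + gap + 1)
        return (inner + body) // 2

    i1 = _line_for(_LINE_BANDS["i1"])
    i2 = min(_line_for(_LINE_BANDS["i2"]), i1)
    i3 = min(_line_for(_LINE_BANDS["i3"]), i2)
    return MarginLines(i1=i1, i2=i2, i3=i3, width=width)


def build_margin_polyline(lines: MarginLines, bands: RegionBands) -> MarginPolyline:
    """Connect the separating lines across the eight bands into the margin.

    The rasterized column follows the band schedule i3,i3,i2,i1,i1,i2,i3,i3;
    at each band boundary where the column changes, the polyline passes
    through the larger of the two adjacent columns (one vertex per boundary),
    and extends vertically on i3 to rows 0 and height-1.
    """
    height = bands.height
    line_cols = {"i1": lines.i1, "i2": lines.i2, "i3": lines.i3}
    if lines.width < 1 or max(line_cols.values()) >= lines.width:
        raise ValueError("margin lines exceed image width")

    sched = [line_cols[name] for name in _BAND_SCHEDULE]
    columns = np.empty(height, dtype=np.int64)
    for b in range(N_BANDS):
        columns[bands.boundaries[b] : bands.boundaries[b + 1]] = sched[b]

    points: list[tuple[int, int]] = [(0, sched[0])]
    change_rows: list[int] = []
    for b in range(1, N_BANDS):
        if sched[b] != sched[b - 1]:
            r = bands.boundaries[b]
            c = max(sched[b], sched[b - 1])
            columns[r] = c
            points.append((r, c))
            change_rows.append(r)
    points.append((height - 1, sched[-1]))

    labels: tuple[tuple[str, tuple[int, int]], ...] = ()
    if len(change_rows) == 4:
        # Distinct lines: attach the paper-order intersection labels, two per
        # boundary (outer line Pe, inner line Pi), traversed top to bottom.
        rA, rB, rC, rD = change_rows
        labels = (
            ("Pe1", (rA, lines.i3)),
            ("Pi1", (rA, lines.i2)),
            ("Pi3", (rB, lines.i2)),
            ("Pe3", (rB, lines.i1)),
            ("Pe4", (rC, lines.i1)),
            ("Pi4", (rC, lines.i2)),
            ("Pi2", (rD, lines.i2)),
            ("Pe2", (rD, lines.i3)),
        )

    return MarginPolyline(
        points=tuple(points), columns=tuple(int(c) for c in columns), labels=labels
    )


def fill_stretcher_mask(polyline: MarginPolyline, shape: tuple[int, int]) -> np.ndarray:
    """Fill everything left of (and on) the margin into a binary mask.

    Each row of the output is a left-anchored run of ``columns[r] + 1`` ones.
    """
    rows, cols = shape
    if polyline.height != rows:
        raise ValueError(
            f"polyline spans {polyline.height} rows but the image has {rows}"
        )
    mask = np.zeros((rows, cols), dtype=np.uint8)
    col_idx = np.arange(cols)
    margin = np.asarray(polyline.columns)[:, None]
    mask[col_idx[None, :] <= margin] = 1
    return mask


def adapt_mask_to_slice(
    reference_mask: np.ndarray,
    slice_binary: np.ndarray,
    dilation_radius: int,
    accessory_fraction: float = DEFAULT_ACCESSORY_FRACTION,
) -> np.ndarray:
    """Adapt the reference stretcher mask to one slice.

    The reference is dilated by a square structuring element of the given
    radius; any connected component of the binarized slice whose overlap
    fraction with the dilated mask exceeds ``accessory_fraction`` (a couch
    accessory, or the couch itself) is absorbed into the output.
    """
    reference_mask = np.asarray(reference_mask).astype(bool)
    slice_binary = np.asarray(slice_binary).astype(bool)
    if reference_mask.shape != slice_binary.shape:
        raise ValueError("reference mask and slice shapes differ")
    if dilation_radius < 0:
        raise ValueError("dilation radius must be >= 0")
    if dilation_radius > 0:
        structure = np.ones((2 * dilation_radius + 1,) * 2, dtype=bool)
        dilated = ndi.binary_dilation(reference_mask, structure=structure)
    else:
        dilated = reference_mask.copy()

    out = dilated.copy()
    labels, n = ndi.label(slice_binary, structure=_CONN8)
    if n:
        overlap = ndi.sum_labels(dilated, labels, index=np.arange(1, n + 1))
        sizes = ndi.sum_labels(np.ones_like(slice_binary), labels, index=np.arange(1, n + 1))
        absorbed = np.flatnonzero(overlap / sizes > accessory_fraction) + 1
        if absorbed.size:
            out |= np.isin(labels, absorbed)
    return out.astype(np.uint8)


def remove_stretcher(
    volume: CTVolume,
    reference_slice: int | str = "auto",
    dilation_radius: int = DEFAULT_DILATION_RADIUS,
    threshold: float = DEFAULT_BINARIZE_HU,
    gap: int = DEFAULT_GAP,
    accessory_fraction: float = DEFAULT_ACCESSORY_FRACTION,
) -> tuple[CTVolume, MaskVolume]:
    """Strip the stretcher from every slice of a CT volume.

    One margin is computed on a reference slice ("auto" picks the slice with
    the largest couch cross-section) and adapted to every slice; masked
    voxels are set to 0 HU.  Slices without a couch candidate get an empty
    mask; if no slice has one, the volume is returned unchanged with a
    warning.
    """
    if volume.slice_count == 0:
        raise ValueError("empty volume")
    binaries = [binarize_slice(s, threshold) for s in volume.voxels]

    candidates: dict[int, int] = {}
    for idx, binary in enumerate(binaries):
        try:
            labels, lab = _stretcher_component(binary)
        except NoStretcherError:
            continue
        candidates[idx] = int(np.sum(labels == lab))

    out = volume.copy()
    empty = np.zeros(volume.shape, dtype=np.uint8)
    if not candidates:
        logger.warning(
            "no stretcher candidate found in any slice of patient %r; volume unchanged",
            volume.patient_id,
        )
        return out, MaskVolume(
            voxels=empty, role=MaskRole.STRETCHER,
            spacing=volume.spacing, patient_id=volume.patient_id,
        )

    if reference_slice == "auto":
        ref_idx = max(candidates, key=lambda i: (candidates[i], -i))
    else:
        ref_idx = int(reference_slice)
        if not 0 <= ref_idx < volume.slice_count:
            raise ValueError(f"reference slice {ref_idx} out of range")

    lines = locate_margin_lines(binaries[ref_idx], gap=gap)
    bands = RegionBands.from_height(volume.shape[1])
    polyline = build_margin_polyline(lines, bands)
    reference_mask = fill_stretcher_mask(polyline, volume.shape[1:])

    mask = empty
    for idx in range(volume.slice_count):
        if idx not in candidates:
            continue
        mask[idx] = adapt_mask_to_slice(
            reference_mask, binaries[idx], dilation_radius, accessory_fraction
        )
        out.voxels[idx][mask[idx] == 1] = 0
    stretcher_mask = MaskVolume(
        voxels=mask, role=MaskRole.STRETCHER,
        spacing=volume.spacing, patient_id=volume.patient_id,
    )
    return out, stretcher_mask
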