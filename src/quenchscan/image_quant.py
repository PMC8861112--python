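"""Cell segmentation and membrane-proximity (ρ) quantification.

Cells are detected on the mCherry channel (a cytosolic transfection marker):
a 3×3 median filter, Otsu binarization and hole filling give a cell mask,
which a distance-transform-seeded watershed splits into individual cells.
Per-cell geometry drives a set of quality-control filters; intensities are
normalized per plate to the median of WT-expressing cells, and the membrane
proximity is

    ρ = <normalized YFP in a 1.08 µm band inside the cell border>
        / <normalized mCherry over the whole cell>,

a per-cell proxy for the fraction of the YFP-tagged channel at or near the
plasma membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import footprint_rectangle
from skimage.segmentation import watershed

__all__ = [
    "ImagePair",
    "CellRecord",
    "QCRules",
    "background_correct",
    "segment_cells",
    "cell_properties",
    "qc_filter",
    "membrane_band",
    "normalize_to_plate_wt",
    "compute_rho",
    "quantify_image_pair",
    "DEFAULT_PIXEL_SIZE",
]

#: Placeholder pixel size for a 20x widefield system (µm/pixel); a required
#: calibration input for real data, not an instrument-asserted value.
DEFAULT_PIXEL_SIZE = 0.656


@dataclass
class ImagePair:
    """One field of view: co-registered mCherry and YFP 16-bit images."""

    mcherry: np.ndarray
    yfp: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    plate: str = ""
    well: str = ""
    field: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.mcherry = np.asarray(self.mcherry)
        self.yfp = np.asarray(self.yfp)
        if self.mcherry.shape != self.yfp.shape:
            raise ValueError("channel images must have equal dimensions")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class CellRecord:
    """Geometry and intensity measurements for one segmented cell."""

    label: int
    area: float                # µm²
    major_axis: float          # µm
    perimeter: float           # µm
    touches_border: bool
    mean_yfp_cell: float = np.nan
    mean_mcherry_cell: float = np.nan
    mean_yfp_band: float = np.nan
    rho: float = np.nan
    plate: str = ""
    genotype: str = ""
    qc_flags: tuple[str, ...] = ()

    def with_(self, **kw) -> "CellRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class QCRules:
    """Cell-level quality-control thresholds (µm-based).

    Defaults follow the screen's rules: area outside [108, 5400] µm², major
    axis above 32.4 µm, area/perimeter ratio outside [ap_min, ap_max] µm, or
    touching the image border removes a cell, as does a negative mean
    normalized intensity in either channel. The default lower area/perimeter
    bound is 2.5 µm: for any planar shape A/P ≤ sqrt(A/4π), so with the area
    and axis caps above no cell can reach A/P = 25 µm — a lower bound at that
    value would empty every dataset. 2.5 µm removes sub-cellular debris
    (equivalent disk diameter below ~10 µm) while remaining consistent with
    the other rules; pass ``ap_min=25.0`` to apply the literal screen value.
    """

    area_min: float = 108.0
    area_max: float = 5400.0
    major_axis_max: float = 32.4
    ap_min: float = 2.5
    ap_max: float = 300.0
    exclude_border: bool = True
    min_intensity: float = 0.0


def background_correct(image: np.ndarray, cell_mask: np.ndarray) -> np.ndarray:
    """Subtract the background level estimated from non-cell pixels.

    The background is the median intensity outside ``cell_mask``; after
    correction the non-cell median is ≈ 0. Returns a float image (may carry
    negative pixels where noise undershoots the background).
    """
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != image.shape:
        raise ValueError("mask and image must have the same shape")
    outside = ~cell_mask
    if not outside.any():
        raise ValueError("mask covers every pixel: no background to estimate")
    return image - float(np.median(image[outside]))


def segment_cells(
    mcherry: np.ndarray,
    *,
    min_seed_distance: int = 5,
    min_object_px: int = 16,
) -> np.ndarray:
    """Watershed segmentation of the binarized mCherry image.

    Median-filtered (3×3) image → Otsu threshold → hole filling → distance
    transform; local maxima of the distance map (≥ ``min_seed_distance`` px
    apart) seed a watershed that separates touching cells. Background is
    label 0. A blank image yields zero labels.
    """
    img = np.asarray(mcherry, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    smooth = median_filter(img, footprint_rectangle((3, 3)))
    if np.allclose(smooth, smooth.flat[0]):
        return np.zeros(img.shape, dtype=np.int32)
    mask = smooth > threshold_otsu(smooth)
    # a signal-free field splits its noise at the Otsu point; require real
    # foreground/background contrast before accepting any object
    fg, bg = smooth[mask], smooth[~mask]
    if fg.size == 0 or bg.size == 0 or (fg.mean() - bg.mean()) < 5.0 * max(bg.std(), 1e-12):
        return np.zeros(img.shape, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)
    # drop speckle far below any plausible cell footprint
    lab, _ = ndi.label(mask)
    sizes = np.bincount(lab.ravel())
    mask &= ~np.isin(lab, np.flatnonzero(sizes < min_object_px))
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    seeds_xy = peak_local_max(
        distance, min_distance=min_seed_distance, labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seeds_xy, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(mask)
    labels = watershed(-distance, markers, mask=mask)
    # renumber contiguously
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def cell_properties(label_map: np.ndarray, pixel_size: float) -> list[CellRecord]:
    """Geometry of every labeled cell, in µm units.

    Area is pixel count × pixel_size²; the major axis is that of the
    intensity-equivalent ellipse; the perimeter is the boundary length; a
    cell touches the border when any of its pixels lies on the image edge.
    """
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    label_map = np.asarray(label_map)
    h, w = label_map.shape
    records = []
    for rp in regionprops(label_map):
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        records.append(
            CellRecord(
                label=int(rp.label),
                area=float(rp.area) * pixel_size**2,
                major_axis=float(rp.axis_major_length) * pixel_size,
                # 1-px objects have zero skimage perimeter; floor at one pixel
                perimeter=max(float(rp.perimeter) * pixel_size, pixel_size),
                touches_border=bool(touches),
            )
        )
    return records


def qc_filter(
    cells: list[CellRecord],
    rules: QCRules = QCRules(),
) -> tuple[list[CellRecord], list[CellRecord]]:
    """Apply the cell-level QC rules; returns (retained, removed).

    Every violated rule is recorded in ``qc_flags`` on the removed record,
    so filter decisions stay auditable.
    """
    retained, removed = [], []
    for cell in cells:
        flags = []
        if cell.area < rules.area_min:
            flags.append("area_small")
        if cell.area > rules.area_max:
            flags.append("area_large")
        if cell.major_axis > rules.major_axis_max:
            flags.append("major_axis")
        ap = cell.area / cell.perimeter if cell.perimeter > 0 else 0.0
        if ap < rules.ap_min:
            flags.append("ap_low")
        if ap > rules.ap_max:
            flags.append("ap_high")
        if rules.exclude_border and cell.touches_border:
            flags.append("border")
        for value, name in ((cell.mean_yfp_cell, "yfp_negative"),
                            (cell.mean_mcherry_cell, "mcherry_negative")):
            if np.isfinite(value) and value < rules.min_intensity:
                flags.append(name)
        if flags:
            removed.append(cell.with_(qc_flags=tuple(flags)))
        else:
            retained.append(cell)
    return retained, removed


def membrane_band(cell_mask: np.ndarray, width: float = 1.08,
                  pixel_size: float = DEFAULT_PIXEL_SIZE) -> np.ndarray:
    """Membrane-proximal zone: a ``width`` µm band inside the cell border.

    The band is the cell mask minus its erosion by a Euclidean disk of
    round(width/pixel_size) pixels (minimum 1), computed via the distance
    transform. Cells thinner than twice the band width erode to nothing, in
    which case the band is the whole cell. Band and eroded interior always
    partition the mask.
    """
    if width <= 0:
        raise ValueError("band width must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    n_px = max(int(round(width / pixel_size)), 1)
    interior = ndi.distance_transform_edt(cell_mask) > n_px
    return cell_mask & ~interior


def normalize_to_plate_wt(
    cells_by_plate: dict[str, list[CellRecord]],
    wt_genotype: str = "WT",
) -> dict[str, list[CellRecord]]:
    """Normalize per-cell intensities to the plate's WT medians.

    For each plate and channel, intensities are divided by the median over
    WT-expressing cells on that plate, so WT medians map to 1.0 and plate-
    to-plate gain differences cancel. A plate without WT cells is a hard
    error — nothing on it can be normalized.
    """
    out: dict[str, list[CellRecord]] = {}
    for plate, cells in cells_by_plate.items():
        wt = [c for c in cells if c.genotype == wt_genotype]
        if not wt:
            raise ValueError(f"plate {plate!r} has no {wt_genotype!r} cells to normalize to")
        med_yfp = float(np.median([c.mean_yfp_cell for c in wt]))
        med_mch = float(np.median([c.mean_mcherry_cell for c in wt]))
        if med_yfp <= 0 or med_mch <= 0:
            raise ValueError(f"plate {plate!r}: non-positive WT median intensity")
        out[plate] = [
            c.with_(
                mean_yfp_cell=c.mean_yfp_cell / med_yfp,
                mean_yfp_band=c.mean_yfp_band / med_yfp,
                mean_mcherry_cell=c.mean_mcherry_cell / med_mch,
            )
            for c in cells
        ]
    return out


def compute_rho(cell: CellRecord) -> float:
    """ρ = mean normalized YFP in the membrane band over mean normalized
    mCherry in the whole cell. Cells with non-positive mCherry are excluded
    upstream (negative-intensity QC rule); here they raise."""
    if not np.isfinite(cell.mean_mcherry_cell) or cell.mean_mcherry_cell <= 0:
        raise ValueError("cell mCherry mean must be positive to form rho")
    return float(cell.mean_yfp_band / cell.mean_mcherry_cell)


def quantify_image_pair(
    pair: ImagePair,
    *,
    band_width: float = 1.08,
    qc_rules: QCRules | None = None,
) -> list[CellRecord]:
    """Segment one field and measure raw (un-normalized) per-cell intensities.

    Runs segmentation on mCherry, background-corrects both channels against
    the cell mask, measures geometry plus cell/band mean intensities, and
    applies the geometric QC rules (intensity rules re-apply after plate
    normalization). Returned intensities are raw; pass the records through
    :func:`normalize_to_plate_wt` and :func:`compute_rho` to obtain ρ.
    """
    labels = segment_cells(pair.mcherry)
    mask = labels > 0
    if not mask.any():
        return []
    mch = background_correct(pair.mcherry, mask)
    yfp = background_correct(pair.yfp, mask)
    records = []
    for rec in cell_properties(labels, pair.pixel_size):
        cell_mask = labels == rec.label
        band = membrane_band(cell_mask, band_width, pair.pixel_size)
        if not band.any():
            band = cell_mask
        records.append(
            rec.with_(
                mean_yfp_cell=float(yfp[cell_mask].mean()),
                mean_mcherry_cell=float(mch[cell_mask].mean()),
                mean_yfp_band=float(yfp[band].mean()),
                plate=pair.plate,
                genotype=pair.genotype,
            )
        )
    retained, _ = qc_filter(records, qc_rules or QCRules())
    return retained
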