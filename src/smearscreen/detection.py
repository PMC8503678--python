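"""Pre-screening of smear images for candidate cancer-cell clusters.

The screening stage works entirely in the HSV saturation channel, where
hyperchromatic (dark-blue) nuclei stand out against the pale smear
background: the channel is binarized, morphologically closed so that
touching cells merge into one aggregate, and 8-connected components become
candidate clusters.  Two geometric filters then discard confounders: an
aggregate is kept only when its surface area exceeds ``min_area_px``
(default 60000 pixels, strict) and when it fills at least
``min_fill_ratio`` (default 30%, inclusive) of its minimum-area rotated
bounding rectangle — single cells and small clumps fail the first test,
thin streak artifacts the second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import MultiPoint
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.measure import regionprops
from skimage.morphology import closing as _closing
from skimage.morphology import disk

STATUS_ACCEPTED = "accepted"
STATUS_REJECTED_AREA = "rejected_area"
STATUS_REJECTED_FILL = "rejected_fill"

MIN_AREA_PX = 60_000
MIN_FILL_RATIO = 0.30


@dataclass(frozen=True)
class DetectionConfig:
    """Settings of the pre-screening stage.

    ``binarization`` is ``"otsu"`` (parameter-free, computed on a 256-bin
    saturation histogram) or ``"fixed"`` with ``fixed_threshold`` in [0, 1].
    ``rect_mode`` selects the minimum-area rotated rectangle (``"rotated"``,
    the literal minimum) or an axis-aligned box (``"axis"``).
    """

    binarization: str = "otsu"
    fixed_threshold: float | None = None
    closing_radius_px: int = 5
    min_area_px: int = MIN_AREA_PX
    min_fill_ratio: float = MIN_FILL_RATIO
    rect_mode: str = "rotated"

    def __post_init__(self) -> None:
        if self.binarization not in ("otsu", "fixed"):
            raise ValueError("binarization must be 'otsu' or 'fixed'")
        if self.binarization == "fixed":
            if self.fixed_threshold is None:
                raise ValueError("fixed binarization requires fixed_threshold")
            if not 0.0 <= self.fixed_threshold <= 1.0:
                raise ValueError("fixed_threshold must lie in [0, 1]")
        if self.closing_radius_px < 0:
            raise ValueError("closing_radius_px must be >= 0")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")
        if not 0.0 <= self.min_fill_ratio <= 1.0:
            raise ValueError("min_fill_ratio must lie in [0, 1]")
        if self.rect_mode not in ("rotated", "axis"):
            raise ValueError("rect_mode must be 'rotated' or 'axis'")


@dataclass(frozen=True)
class MinRect:
    """Minimum bounding rectangle: centre (row, col), sides, rotation (deg)."""

    center: tuple[float, float]
    width: float
    height: float
    angle_deg: float

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass
class CandidateCluster:
    """One connected high-saturation aggregate.

    ``mask`` is stored bbox-local; ``bbox`` is half-open
    ``(row0, col0, row1, col1)`` in 0-based image coordinates.
    """

    cluster_id: int
    mask: np.ndarray
    area_px: int
    bbox: tuple[int, int, int, int]
    min_rect: MinRect
    fill_ratio: float
    status: str | None = None

    def __post_init__(self) -> None:
        if self.area_px != int(self.mask.sum()):
            raise ValueError("area_px must equal the mask pixel count")
        if not 0.0 < self.fill_ratio <= 1.0:
            raise ValueError("fill_ratio must lie in (0, 1]")

    @classmethod
    def from_mask(cls, mask: np.ndarray, cluster_id: int = 0,
                  rect_mode: str = "rotated") -> "CandidateCluster":
        """Build a candidate from a full-frame boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        if rows.size == 0:
            raise ValueError("mask is empty")
        bbox = (int(rows[0]), int(cols[0]), int(rows[-1] + 1), int(cols[-1] + 1))
        local = mask[bbox[0]:bbox[2], bbox[1]:bbox[3]]
        coords = np.argwhere(mask)
        area = int(mask.sum())
        rect = min_area_rect(coords, mode=rect_mode)
        fill = _fill_ratio(area, rect)
        return cls(cluster_id, local, area, bbox, rect, fill)

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass
class DetectionResult:
    """Accepted candidates plus the full provenance of the run."""

    accepted: list[CandidateCluster]
    rejected: list[CandidateCluster]
    saturation_threshold: float

    @property
    def all_candidates(self) -> list[CandidateCluster]:
        return sorted(self.accepted + self.rejected,
                      key=lambda c: c.cluster_id)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def saturation_channel(image: np.ndarray) -> np.ndarray:
    """HSV saturation of an 8-bit RGB image: S = (max - min) / max, 0 at black."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB image of shape (H, W, 3)")
    as_float = image.astype(np.float64)
    cmax = as_float.max(axis=2)
    cmin = as_float.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(cmax > 0, (cmax - cmin) / cmax, 0.0)
    return sat


def binarize_saturation(sat: np.ndarray, method: str = "otsu",
                        fixed_threshold: float | None = None
                        ) -> tuple[np.ndarray, float]:
    """Threshold a saturation map; pixels strictly above threshold are kept.

    Returns the boolean mask and the threshold used.  Otsu is computed on a
    256-bin histogram of the map; a constant map yields an empty mask.
    """
    sat = np.asarray(sat, dtype=np.float64)
    if sat.min() < -1e-12 or sat.max() > 1.0 + 1e-12:
        raise ValueError("saturation values must lie in [0, 1]")
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed binarization requires a threshold value")
        t = float(fixed_threshold)
    elif method == "otsu":
        if sat.min() == sat.max():
            return np.zeros(sat.shape, dtype=bool), float(sat.max())
        t = float(threshold_otsu(sat, nbins=256))
    else:
        raise ValueError("method must be 'otsu' or 'fixed'")
    return sat > t, t


def min_area_rect(coords: np.ndarray, mode: str = "rotated") -> MinRect:
    """Minimum bounding rectangle of a pixel set.

    Pixels are treated as unit squares (each pixel (r, c) covers
    [r, r+1) x [c, c+1)), so the rectangle area is always >= the pixel count
    and a one-pixel-wide line still has positive width.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (N, 2) array")
    offsets = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    corners = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    if mode == "axis":
        lo = corners.min(axis=0)
        hi = corners.max(axis=0)
        center = tuple((lo + hi) / 2.0)
        return MinRect(center, float(hi[0] - lo[0]), float(hi[1] - lo[1]), 0.0)
    if mode != "rotated":
        raise ValueError("mode must be 'rotated' or 'axis'")
    hull = ConvexHull(corners)
    hull_pts = corners[hull.vertices]
    rect = MultiPoint(hull_pts).minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4]
    e1 = xy[1] - xy[0]
    e2 = xy[2] - xy[1]
    w = float(np.hypot(*e1))
    h = float(np.hypot(*e2))
    center = tuple(xy[:4].mean(axis=0))
    angle = float(np.degrees(np.arctan2(e1[1], e1[0])))
    return MinRect(center, w, h, angle)


def _fill_ratio(area_px: int, rect: MinRect) -> float:
    fill = area_px / rect.area
    if fill > 1.0 + 1e-9:
        raise ValueError("fill ratio exceeds 1 beyond numerical slack")
    return min(fill, 1.0)


def extract_components(mask: np.ndarray, closing_radius_px: int = 5,
                       rect_mode: str = "rotated") -> list[CandidateCluster]:
    """Morphological closing followed by 8-connected component labelling."""
    mask = np.asarray(mask, dtype=bool)
    if closing_radius_px > 0:
        mask = _closing(mask, disk(closing_radius_px))
    labelled = _cc_label(mask, connectivity=2)
    out: list[CandidateCluster] = []
    for prop in regionprops(labelled):
        r0, c0, r1, c1 = prop.bbox
        rect = min_area_rect(prop.coords, mode=rect_mode)
        area = int(prop.area)
        out.append(CandidateCluster(
            cluster_id=int(prop.label),
            mask=prop.image.copy(),
            area_px=area,
            bbox=(int(r0), int(c0), int(r1), int(c1)),
            min_rect=rect,
            fill_ratio=_fill_ratio(area, rect),
        ))
    return out


def filter_candidates(candidates: list[CandidateCluster],
                      min_area_px: int = MIN_AREA_PX,
                      min_fill_ratio: float = MIN_FILL_RATIO
                      ) -> list[CandidateCluster]:
    """Set accept/reject status: area strictly above the cutoff AND fill
    ratio at least the cutoff; the area test is checked first."""
    out = []
    for cand in candidates:
        if cand.area_px <= min_area_px:
            status = STATUS_REJECTED_AREA
        elif cand.fill_ratio < min_fill_ratio:
            status = STATUS_REJECTED_FILL
        else:
            status = STATUS_ACCEPTED
        out.append(replace_status(cand, status))
    return out


def replace_status(cand: CandidateCluster, status: str) -> CandidateCluster:
    return CandidateCluster(cand.cluster_id, cand.mask, cand.area_px,
                            cand.bbox, cand.min_rect, cand.fill_ratio, status)


def detect(image: np.ndarray,
           config: DetectionConfig | None = None) -> DetectionResult:
    """Full pre-screening: saturation -> binarize -> components -> filters."""
    config = config or DetectionConfig()
    sat = saturation_channel(image)
    mask, threshold = binarize_saturation(sat, config.binarization,
                                          config.fixed_threshold)
    candidates = extract_components(mask, config.closing_radius_px,
                                    config.rect_mode)
    candidates = filter_candidates(candidates, config.min_area_px,
                                   config.min_fill_ratio)
    accepted = [c for c in candidates if c.status == STATUS_ACCEPTED]
    rejected = [c for c in candidates if c.status != STATUS_ACCEPTED]
    return DetectionResult(accepted, rejected, threshold)
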