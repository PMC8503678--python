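"""Seeded generator of bone-marrow-smear-like scenes with exact ground truth.

Real Wright-Giemsa aspirate smears show a pale background sprinkled with small
hematopoietic cells; metastatic carcinoma appears as cohesive clumps of large
atypical cells with hyperchromatic (dark-blue, highly saturated) nuclei and
vacuolated cytoplasm, alongside confounders such as red-cell clumps and thin
staining artifacts.  This module emulates exactly those scene elements with
anti-aliased ellipse rendering, so that the saturation-based detector and the
tile scorer downstream can be exercised against a known per-cluster truth
without any external data.

Every random draw flows from the single ``seed`` in :class:`SmearSpec`;
identical specs produce byte-identical images and identical ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _ellipse
from skimage.draw import polygon as _polygon

LABEL_CANCER = "cancer"
LABEL_BENIGN = "benign_aggregate"
LABEL_ARTIFACT = "artifact"
VALID_LABELS = (LABEL_CANCER, LABEL_BENIGN, LABEL_ARTIFACT)

# Palette (R, G, B).  Chosen so that cancer nuclei are high-saturation and
# dark, cytoplasm and benign material low-saturation, background pale.
_BG_DEFAULT = (236, 230, 233)
_CANCER_NUCLEUS = (45, 35, 112)
_CANCER_CYTOPLASM = (178, 176, 214)
_CANCER_VACUOLE = (216, 216, 236)
_RBC = (232, 186, 192)
_RBC_DARK = (220, 166, 174)
_HEMATO_CYTO = (206, 192, 219)
_HEMATO_NUCLEUS = (152, 118, 182)
_ARTIFACT = (66, 52, 126)


class PlacementError(RuntimeError):
    """Raised when a requested object cannot be placed in the image."""


@dataclass(frozen=True)
class SmearSpec:
    """Parameters of one synthetic smear scene.

    Defaults describe the standard study scene: a 1600x1200 field holding a
    few large cancer clusters (80k-120k px footprints, comfortably above the
    60000 px detection filter), scattered small hematopoietic cells, red-cell
    clumps well below the area filter, and thin dark artifacts.
    """

    width_px: int = 1600
    height_px: int = 1200
    background_rgb: tuple[int, int, int] = _BG_DEFAULT
    background_noise_sd: float = 3.0
    n_hematopoietic: int = 150
    hematopoietic_radius_px: tuple[float, float] = (4.0, 9.0)
    n_cancer_clusters: int = 3
    cells_per_cluster: tuple[int, int] = (20, 80)
    cancer_cell_radius_px: tuple[float, float] = (24.0, 40.0)
    cluster_cohesion: float = 0.6
    n_rbc_clumps: int = 3
    n_artifacts: int = 4
    target_cluster_area_px: tuple[int, int] = (80_000, 120_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        for name in ("n_hematopoietic", "n_cancer_clusters", "n_rbc_clumps",
                     "n_artifacts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("hematopoietic_radius_px", "cancer_cell_radius_px",
                     "cells_per_cluster", "target_cluster_area_px"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min must be <= max")
            if lo <= 0:
                raise ValueError(f"{name}: values must be positive")
        if not 0.0 <= self.cluster_cohesion <= 1.0:
            raise ValueError("cluster_cohesion must lie in [0, 1]")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if any(not 0 <= v <= 255 for v in self.background_rgb):
            raise ValueError("background_rgb components must lie in [0, 255]")


@dataclass
class ClusterRecord:
    cluster_id: int
    label: str
    area_px: int
    centroid: tuple[float, float]  # (row, col)

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown cluster label {self.label!r}")


@dataclass
class GroundTruth:
    """Per-cluster truth: records plus an 8-bit label raster (0 = background)."""

    clusters: list[ClusterRecord]
    label_map: np.ndarray  # uint8, same H x W as the image

    def __post_init__(self) -> None:
        ids = [c.cluster_id for c in self.clusters]
        if len(ids) != len(set(ids)):
            raise ValueError("cluster ids must be unique")

    def mask(self, cluster_id: int) -> np.ndarray:
        return self.label_map == cluster_id

    def ids_with_label(self, label: str) -> list[int]:
        return [c.cluster_id for c in self.clusters if c.label == label]

    def cancer_mask(self) -> np.ndarray:
        ids = self.ids_with_label(LABEL_CANCER)
        return np.isin(self.label_map, ids) if ids else np.zeros_like(
            self.label_map, dtype=bool)

    def to_json(self) -> str:
        payload = {
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "label": c.label,
                    "area_px": c.area_px,
                    "centroid": [c.centroid[0], c.centroid[1]],
                }
                for c in self.clusters
            ]
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str, label_map: np.ndarray) -> "GroundTruth":
        payload = json.loads(text)
        clusters = [
            ClusterRecord(c["cluster_id"], c["label"], c["area_px"],
                          (c["centroid"][0], c["centroid"][1]))
            for c in payload["clusters"]
        ]
        return cls(clusters, label_map)


# --------------------------------------------------------------------------
# rendering primitives
# --------------------------------------------------------------------------

@dataclass
class _Cell:
    row: float
    col: float
    r_row: float
    r_col: float
    rotation: float


def _cell_footprint(cell: _Cell, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return _ellipse(cell.row, cell.col, cell.r_row, cell.r_col,
                    shape=shape, rotation=cell.rotation)


def _paint(canvas: np.ndarray, rr: np.ndarray, cc: np.ndarray,
           color: tuple[float, float, float]) -> None:
    canvas[rr, cc] = color


def _jitter(rng: np.random.Generator, color: tuple[int, int, int],
            sd: float = 6.0) -> tuple[float, float, float]:
    c = np.asarray(color, float) + rng.normal(0.0, sd, size=3)
    return tuple(np.clip(c, 0, 255))


def _make_cell(rng: np.random.Generator, row: float, col: float,
               radius: float) -> _Cell:
    return _Cell(row, col,
                 radius * rng.uniform(0.88, 1.12),
                 radius * rng.uniform(0.88, 1.12),
                 rng.uniform(0.0, np.pi))


def _grow_clump(rng: np.random.Generator, center: tuple[float, float],
                radius_range: tuple[float, float], cohesion: float,
                target_area: float, n_min: int, shape: tuple[int, int],
                what: str, forbidden: np.ndarray, max_extent: float,
                max_tries: int = 6000) -> tuple[list[_Cell], np.ndarray]:
    """Accrete overlapping cells around ``center`` until the union footprint
    reaches ``target_area``.  Cohesion sets how deeply a new cell overlaps its
    anchor (0 = tangent, 1 = centre separation shrunk by the smaller radius).
    Cells never touch ``forbidden`` pixels (already-claimed objects) and stay
    within ``max_extent`` of the centre, which keeps objects disjoint and
    clumps compact."""
    rmin, rmax = radius_range
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    first = _make_cell(rng, center[0], center[1], rng.uniform(rmin, rmax))
    cells = [first]
    rr, cc = _cell_footprint(first, shape)
    mask[rr, cc] = True
    area = int(mask.sum())
    tries = 0
    while (area < target_area or len(cells) < n_min):
        tries += 1
        if tries > max_tries:
            raise PlacementError(f"could not grow {what} to the requested area")
        anchor = cells[int(rng.integers(len(cells)))]
        ra = max(anchor.r_row, anchor.r_col)
        r = rng.uniform(rmin, rmax)
        d = (ra + r) - cohesion * min(ra, r)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        row = anchor.row + d * np.sin(theta)
        col = anchor.col + d * np.cos(theta)
        if not (r < row < H - r and r < col < W - r):
            continue
        if np.hypot(row - center[0], col - center[1]) + r > max_extent:
            continue
        cell = _make_cell(rng, row, col, r)
        rr, cc = _cell_footprint(cell, shape)
        if rr.size == 0 or forbidden[rr, cc].any():
            continue
        cells.append(cell)
        area += int((~mask[rr, cc]).sum())
        mask[rr, cc] = True
    return cells, mask


def _render_cancer_cluster(rng: np.random.Generator, canvas: np.ndarray,
                           cells: list[_Cell]) -> None:
    shape = canvas.shape[:2]
    for cell in cells:  # cytoplasm first so every nucleus stays visible
        rr, cc = _cell_footprint(cell, shape)
        _paint(canvas, rr, cc, _jitter(rng, _CANCER_CYTOPLASM))
    for cell in cells:
        nucleus = _Cell(cell.row, cell.col, cell.r_row * 0.92,
                        cell.r_col * 0.92, cell.rotation)
        rr, cc = _cell_footprint(nucleus, shape)
        _paint(canvas, rr, cc, _jitter(rng, _CANCER_NUCLEUS))
        for _ in range(int(rng.integers(0, 3))):  # cytoplasmic vacuoles
            vr = max(cell.r_row, cell.r_col) * rng.uniform(0.08, 0.16)
            off = rng.uniform(-0.45, 0.45, size=2) * min(cell.r_row, cell.r_col)
            vac = _Cell(cell.row + off[0], cell.col + off[1], vr, vr, 0.0)
            rr, cc = _cell_footprint(vac, shape)
            _paint(canvas, rr, cc, _jitter(rng, _CANCER_VACUOLE, sd=4.0))


def _render_rbc_clump(rng: np.random.Generator, canvas: np.ndarray,
                      cells: list[_Cell]) -> None:
    shape = canvas.shape[:2]
    for cell in cells:
        rr, cc = _cell_footprint(cell, shape)
        _paint(canvas, rr, cc, _jitter(rng, _RBC, sd=5.0))
        inner = _Cell(cell.row, cell.col, cell.r_row * 0.55,
                      cell.r_col * 0.55, cell.rotation)
        rr, cc = _cell_footprint(inner, shape)
        _paint(canvas, rr, cc, _jitter(rng, _RBC_DARK, sd=5.0))


def _render_hematopoietic(rng: np.random.Generator, canvas: np.ndarray,
                          cell: _Cell) -> None:
    shape = canvas.shape[:2]
    rr, cc = _cell_footprint(cell, shape)
    _paint(canvas, rr, cc, _jitter(rng, _HEMATO_CYTO, sd=8.0))
    nucleus = _Cell(cell.row, cell.col, cell.r_row * 0.6, cell.r_col * 0.6,
                    cell.rotation)
    rr, cc = _cell_footprint(nucleus, shape)
    _paint(canvas, rr, cc, _jitter(rng, _HEMATO_NUCLEUS, sd=8.0))


def _streak_mask(rng: np.random.Generator, shape: tuple[int, int],
                 start: tuple[float, float]) -> np.ndarray:
    """Thin multi-segment dark streak (a staining artifact)."""
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    row, col = start
    theta = rng.uniform(0.0, 2.0 * np.pi)
    width = rng.uniform(3.0, 8.0)
    for _ in range(int(rng.integers(2, 4))):
        length = rng.uniform(80.0, 250.0)
        r2 = np.clip(row + length * np.sin(theta), 1, H - 2)
        c2 = np.clip(col + length * np.cos(theta), 1, W - 2)
        n = np.array([-(c2 - col), r2 - row], float)
        norm = np.hypot(*n)
        if norm > 0:
            n = n / norm * (width / 2.0)
            pr = np.array([row - n[0], row + n[0], r2 + n[0], r2 - n[0]])
            pc = np.array([col - n[1], col + n[1], c2 + n[1], c2 - n[1]])
            rr, cc = _polygon(pr, pc, shape=shape)
            mask[rr, cc] = True
        row, col = float(r2), float(c2)
        theta += rng.uniform(-0.9, 0.9)
    return mask


# --------------------------------------------------------------------------
# scene assembly
# --------------------------------------------------------------------------

def _place_center(rng: np.random.Generator, occupied: np.ndarray,
                  radius: float, what: str, attempts: int = 300
                  ) -> tuple[float, float]:
    """Rejection-sample a centre whose bounding box is free and in-frame;
    falls back to a deterministic grid scan before giving up."""
    H, W = occupied.shape
    r = int(np.ceil(radius))
    if 2 * r >= H or 2 * r >= W:
        raise PlacementError(f"{what} does not fit in a {H}x{W} image")
    for _ in range(attempts):
        row = rng.uniform(r, H - r)
        col = rng.uniform(r, W - r)
        r0, c0 = int(row) - r, int(col) - r
        if not occupied[r0:r0 + 2 * r, c0:c0 + 2 * r].any():
            return row, col
    step = max(r // 2, 8)
    for r0 in range(0, H - 2 * r, step):
        for c0 in range(0, W - 2 * r, step):
            if not occupied[r0:r0 + 2 * r, c0:c0 + 2 * r].any():
                return float(r0 + r), float(c0 + r)
    raise PlacementError(f"could not place {what} after {attempts} attempts")


def _claim(occupied: np.ndarray, mask: np.ndarray, margin: int = 12) -> None:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return
    r0 = max(rows[0] - margin, 0)
    r1 = rows[-1] + margin + 1
    c0 = max(cols[0] - margin, 0)
    c1 = cols[-1] + margin + 1
    occupied[r0:r1, c0:c1] = True


def generate_smear(spec: SmearSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one smear scene and its exact ground truth.

    Returns an 8-bit RGB image of the requested size and a
    :class:`GroundTruth` whose label raster marks every cancer cluster,
    red-cell clump and artifact with its own integer id.  Identical specs
    (including the seed) yield byte-identical output.

    Raises
    ------
    PlacementError
        If a requested object cannot fit or be placed without colliding with
        already-placed objects; the message names the first offender.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px
    shape = (H, W)
    canvas = np.empty((H, W, 3), dtype=float)
    canvas[:] = spec.background_rgb
    label_map = np.zeros(shape, dtype=np.uint8)
    occupied = np.zeros(shape, dtype=bool)
    records: list[ClusterRecord] = []
    next_id = 1

    n_objects = spec.n_cancer_clusters + spec.n_rbc_clumps + spec.n_artifacts
    if n_objects > 255:
        raise ValueError("at most 255 labelled objects per scene")

    amin, amax = spec.target_cluster_area_px
    rmin, rmax = spec.cancer_cell_radius_px
    max_cell_area = np.pi * rmax * rmax
    for k in range(spec.n_cancer_clusters):
        what = f"cancer cluster {k}"
        target = rng.uniform(amin, max(amin, amax - max_cell_area))
        extent = np.sqrt(amax / np.pi) + 2.0 * rmax
        center = _place_center(rng, occupied, np.sqrt(amax / np.pi), what)
        cells, mask = _grow_clump(rng, center, (rmin, rmax),
                                  spec.cluster_cohesion, target,
                                  spec.cells_per_cluster[0], shape, what,
                                  forbidden=occupied, max_extent=extent)
        _render_cancer_cluster(rng, canvas, cells)
        label_map[mask] = next_id
        _claim(occupied, mask)
        rows, cols = np.nonzero(mask)
        records.append(ClusterRecord(next_id, LABEL_CANCER, int(mask.sum()),
                                     (float(rows.mean()), float(cols.mean()))))
        next_id += 1

    for k in range(spec.n_rbc_clumps):
        what = f"rbc clump {k}"
        target = rng.uniform(8_000, 25_000)
        extent = np.sqrt(25_000 / np.pi) + 30.0
        center = _place_center(rng, occupied, 60.0, what)
        cells, mask = _grow_clump(rng, center, (8.0, 14.0), 0.5, target,
                                  5, shape, what, forbidden=occupied,
                                  max_extent=extent)
        _render_rbc_clump(rng, canvas, cells)
        label_map[mask] = next_id
        _claim(occupied, mask)
        rows, cols = np.nonzero(mask)
        records.append(ClusterRecord(next_id, LABEL_BENIGN, int(mask.sum()),
                                     (float(rows.mean()), float(cols.mean()))))
        next_id += 1

    for k in range(spec.n_artifacts):
        what = f"artifact {k}"
        if rng.uniform() < 0.5:  # speck
            r = rng.uniform(5.0, 14.0)
            center = _place_center(rng, occupied, r + 4, what)
            cell = _make_cell(rng, center[0], center[1], r)
            mask = np.zeros(shape, dtype=bool)
            rr, cc = _cell_footprint(cell, shape)
            mask[rr, cc] = True
        else:  # thin streak
            center = _place_center(rng, occupied, 40.0, what)
            mask = _streak_mask(rng, shape, center)
            mask &= ~occupied
            if not mask.any():
                raise PlacementError(f"could not place {what}")
        canvas[mask] = _jitter(rng, _ARTIFACT)
        label_map[mask] = next_id
        _claim(occupied, mask, margin=6)
        rows, cols = np.nonzero(mask)
        records.append(ClusterRecord(next_id, LABEL_ARTIFACT, int(mask.sum()),
                                     (float(rows.mean()), float(cols.mean()))))
        next_id += 1

    hmin, hmax = spec.hematopoietic_radius_px
    for k in range(spec.n_hematopoietic):
        r = rng.uniform(hmin, hmax)
        try:
            center = _place_center(rng, occupied, r + 2,
                                   f"hematopoietic cell {k}", attempts=50)
        except PlacementError:
            continue  # background cells are scenery; skip crowded spots
        cell = _make_cell(rng, center[0], center[1], r)
        _render_hematopoietic(rng, canvas, cell)

    if spec.background_noise_sd > 0:
        canvas += rng.normal(0.0, spec.background_noise_sd, size=canvas.shape)
    canvas = gaussian_filter(canvas, sigma=(0.7, 0.7, 0.0))
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return image, GroundTruth(records, label_map)


# --------------------------------------------------------------------------
# tile datasets
# --------------------------------------------------------------------------

@dataclass
class TileDataset:
    """Balanced, labelled square tiles cut from generated smears."""

    tiles: list[np.ndarray]
    labels: np.ndarray  # 1 = cancer, 0 = non-cancer
    provenance: list[tuple[int, int, int]] = field(default_factory=list)
    # provenance entries: (smear seed, row0, col0)

    def __len__(self) -> int:
        return len(self.tiles)


def _child_seed(seed: int, i: int) -> int:
    return int((seed * 1_000_003 + 7919 * i + 1) % (2**31))


def generate_tile_dataset(spec: SmearSpec, tile_size_px: int,
                          n_tiles_per_class: int,
                          min_inside_fraction: float = 0.5) -> TileDataset:
    """Cut balanced cancer / non-cancer tiles from a stream of smears.

    A tile is labelled cancer when at least ``min_inside_fraction`` of its
    pixels lie inside a cancer-cluster mask (the same inside-fraction rule the
    scoring stage uses to keep boundary tiles); non-cancer tiles contain no
    cancer pixels at all but may hold any other scene element.
    """
    if tile_size_px <= 0:
        raise ValueError("tile_size_px must be positive")
    if n_tiles_per_class <= 0:
        raise ValueError("n_tiles_per_class must be positive")
    if tile_size_px > spec.width_px or tile_size_px > spec.height_px:
        raise ValueError("tile_size_px exceeds the image dimensions")

    s = tile_size_px
    rng = np.random.default_rng(_child_seed(spec.seed, 0))
    pos: list[tuple[np.ndarray, tuple[int, int, int]]] = []
    neg: list[tuple[np.ndarray, tuple[int, int, int]]] = []
    smear_idx = 0
    max_smears = 40 + 4 * n_tiles_per_class
    while (len(pos) < n_tiles_per_class or len(neg) < n_tiles_per_class):
        if smear_idx >= max_smears:
            raise PlacementError(
                "could not harvest the requested tile counts; increase the "
                "cancer content of the spec or lower n_tiles_per_class")
        seed_i = _child_seed(spec.seed, smear_idx + 1)
        image, gt = generate_smear(dataclasses.replace(spec, seed=seed_i))
        cancer = gt.cancer_mask()
        H, W = cancer.shape
        if len(pos) < n_tiles_per_class:
            coords = []
            for cid in gt.ids_with_label(LABEL_CANCER):
                rows = np.flatnonzero((gt.label_map == cid).any(axis=1))
                cols = np.flatnonzero((gt.label_map == cid).any(axis=0))
                for r0 in range(rows[0], rows[-1] + 1, s):
                    for c0 in range(cols[0], cols[-1] + 1, s):
                        r0c = min(r0, H - s)
                        c0c = min(c0, W - s)
                        frac = cancer[r0c:r0c + s, c0c:c0c + s].mean()
                        if frac >= min_inside_fraction:
                            coords.append((r0c, c0c))
            rng.shuffle(coords)
            for r0, c0 in coords:
                if len(pos) >= n_tiles_per_class:
                    break
                pos.append((image[r0:r0 + s, c0:c0 + s].copy(),
                            (seed_i, r0, c0)))
        while len(neg) < n_tiles_per_class:
            needed = n_tiles_per_class - len(neg)
            got = 0
            for _ in range(20 * needed):
                r0 = int(rng.integers(0, H - s + 1))
                c0 = int(rng.integers(0, W - s + 1))
                if not cancer[r0:r0 + s, c0:c0 + s].any():
                    neg.append((image[r0:r0 + s, c0:c0 + s].copy(),
                                (seed_i, r0, c0)))
                    got += 1
                    if len(neg) >= n_tiles_per_class:
                        break
            if got == 0:
                break  # scene too crowded; move to the next smear
        smear_idx += 1

    tiles = [t for t, _ in pos] + [t for t, _ in neg]
    labels = np.array([1] * len(pos) + [0] * len(neg), dtype=int)
    provenance = [p for _, p in pos] + [p for _, p in neg]
    return TileDataset(tiles, labels, provenance)
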