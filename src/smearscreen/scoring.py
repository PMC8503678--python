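"""Tile-mean-score classification of candidate clusters.

Each accepted cluster is partitioned into fixed-size square sections, every
section receives a cancer-probability score in [0, 1], and the cluster is
called cancerous when the arithmetic mean of the section scores strictly
exceeds the classification threshold.  Two operating thresholds matter in
practice: 0.426 for high-specificity screening and 0.046 for
high-sensitivity screening (the low threshold is also printed elsewhere as
0.045 and 0.0459; any value in [0, 1] is accepted here).

The scorer itself is pluggable.  The reference implementation is a logistic
model over hand-crafted morphology proxies (saturation, darkness, dark-blob
geometry, vacuole holes, texture) trained on labelled synthetic tiles; a
convolutional scorer can stand behind the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label as _cc_label
from sklearn.linear_model import LogisticRegression

from .detection import CandidateCluster, DetectionConfig, detect, saturation_channel

THRESHOLD_HIGH_SPECIFICITY = 0.426
THRESHOLD_HIGH_SENSITIVITY = 0.046

LABEL_CANCER = "cancer"
LABEL_NON_CANCER = "non_cancer"

FEATURE_NAMES = (
    "mean_saturation",
    "mean_darkness",
    "dark_blob_count",
    "dark_blob_mean_area_px",
    "large_cell_fraction",
    "vacuole_proxy",
    "texture_sd",
)

DEFAULT_TILE_SIZE = 128
DEFAULT_MIN_INSIDE_FRACTION = 0.5
DARKNESS_THRESHOLD = 0.45
LARGE_BLOB_MIN_AREA = 200


@dataclass(frozen=True)
class TileWindow:
    """Square section [row0, row0+height) x [col0, col0+width); height and
    width equal ``size_px`` except where clipped at the image edge."""

    row0: int
    col0: int
    size_px: int
    height: int
    width: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height),
                slice(self.col0, self.col0 + self.width))


@dataclass(frozen=True)
class TileFeatureVector:
    mean_saturation: float
    mean_darkness: float
    dark_blob_count: float
    dark_blob_mean_area_px: float
    large_cell_fraction: float
    vacuole_proxy: float
    texture_sd: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass
class ClusterDecision:
    cluster_id: int
    tile_scores: list[float]
    mean_score: float
    threshold: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in (LABEL_CANCER, LABEL_NON_CANCER):
            raise ValueError(f"unknown decision label {self.label!r}")


# --------------------------------------------------------------------------
# tiling
# --------------------------------------------------------------------------

def tile_cluster(cluster: CandidateCluster, image_shape: tuple[int, int],
                 size_px: int = DEFAULT_TILE_SIZE,
                 min_inside_fraction: float = DEFAULT_MIN_INSIDE_FRACTION
                 ) -> list[TileWindow]:
    """Partition a cluster into fixed-size sections.

    A regular grid of ``size_px`` windows is anchored at the cluster's bbox
    origin; windows that would overhang the image are shifted back inside.
    A window is kept when at least ``min_inside_fraction`` of its pixels lie
    on the cluster mask; if no window qualifies the best-covered one is kept,
    so every cluster yields at least one section.  A bbox smaller than the
    tile in either dimension yields a single window clipped at the image
    edge.
    """
    if size_px <= 0:
        raise ValueError("tile size must be positive")
    H, W = image_shape
    r0, c0, r1, c1 = cluster.bbox

    def _starts(origin: int, extent: int, limit: int) -> list[int]:
        n = max(1, -(-extent // size_px))
        starts = []
        for i in range(n):
            s = origin + i * size_px
            if s + size_px > limit:
                s = max(0, limit - size_px)
            starts.append(s)
        return sorted(set(starts))

    windows: list[TileWindow] = []
    for rs in _starts(r0, r1 - r0, H):
        for cs in _starts(c0, c1 - c0, W):
            h = min(size_px, H - rs)
            w = min(size_px, W - cs)
            windows.append(TileWindow(rs, cs, size_px, h, w))

    full = cluster.full_mask((H, W))
    kept, best, best_frac = [], None, -1.0
    for win in windows:
        region = full[win.slices]
        frac = float(region.mean()) if region.size else 0.0
        if frac >= min_inside_fraction:
            kept.append(win)
        if frac > best_frac:
            best, best_frac = win, frac
    return kept if kept else [best]


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------

def extract_tile_features(image: np.ndarray, tile: TileWindow,
                          darkness_threshold: float = DARKNESS_THRESHOLD,
                          large_blob_min_area: int = LARGE_BLOB_MIN_AREA
                          ) -> TileFeatureVector:
    """Morphology proxies for one section.

    Dark blobs (candidate hyperchromatic nuclei) are pixels whose darkness
    1 - V exceeds ``darkness_threshold``, labelled with 8-connectivity;
    ``large_cell_fraction`` is the share of dark pixels in blobs at least
    ``large_blob_min_area`` px; ``vacuole_proxy`` counts bright holes fully
    enclosed by dark blobs.
    """
    crop = image[tile.slices]
    if crop.size == 0:
        raise ValueError("tile lies outside the image")
    sat = saturation_channel(np.ascontiguousarray(crop))
    value = crop.astype(np.float64).max(axis=2) / 255.0
    darkness = 1.0 - value
    gray = crop.astype(np.float64).mean(axis=2) / 255.0

    dark = darkness > darkness_threshold
    labelled = _cc_label(dark, connectivity=2)
    n_blobs = int(labelled.max())
    if n_blobs:
        areas = np.bincount(labelled.ravel())[1:]
        mean_area = float(areas.mean())
        large = float(areas[areas >= large_blob_min_area].sum() / areas.sum())
    else:
        mean_area = 0.0
        large = 0.0
    holes = binary_fill_holes(dark) & ~dark
    n_holes = int(_cc_label(holes, connectivity=2).max())

    return TileFeatureVector(
        mean_saturation=float(sat.mean()),
        mean_darkness=float(darkness.mean()),
        dark_blob_count=float(n_blobs),
        dark_blob_mean_area_px=mean_area,
        large_cell_fraction=large,
        vacuole_proxy=float(n_holes),
        texture_sd=float(gray.std()),
    )


# --------------------------------------------------------------------------
# scorer
# --------------------------------------------------------------------------

@dataclass
class ScorerModel:
    """Logistic map from standardized tile features to a score in [0, 1]."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    metadata: dict = field(default_factory=dict)

    def score_features(self, features: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(features) - self.feature_means) / self.feature_sds
        z = x @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def score_tile(self, image: np.ndarray, tile: TileWindow) -> float:
        vec = extract_tile_features(image, tile).as_array()
        return float(self.score_features(vec)[0])

    def to_json(self) -> str:
        return json.dumps({
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "metadata": self.metadata,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScorerModel":
        d = json.loads(text)
        return cls(tuple(d["feature_names"]), np.array(d["weights"]),
                   d["intercept"], np.array(d["feature_means"]),
                   np.array(d["feature_sds"]), d["metadata"])


def features_from_tiles(tiles: list[np.ndarray]) -> np.ndarray:
    rows = []
    for t in tiles:
        win = TileWindow(0, 0, t.shape[0], t.shape[0], t.shape[1])
        rows.append(extract_tile_features(t, win).as_array())
    return np.array(rows)


def train_reference_scorer(tiles, labels=None, seed: int = 0,
                           holdout_fraction: float = 0.25,
                           tile_size_px: int | None = None) -> ScorerModel:
    """Fit the logistic reference scorer on labelled tiles.

    ``tiles`` is either a :class:`~smearscreen.synthetic.TileDataset` or a
    pair of (feature matrix, labels).  Both classes must be present.  An
    internal seeded split reports held-out accuracy in the model metadata.
    """
    if labels is None:  # TileDataset
        dataset = tiles
        features = features_from_tiles(dataset.tiles)
        labels = np.asarray(dataset.labels, dtype=int)
        if tile_size_px is None and dataset.tiles:
            tile_size_px = int(dataset.tiles[0].shape[0])
    else:
        features = np.asarray(tiles, dtype=float)
        labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes to be present")

    means = features.mean(axis=0)
    sds = features.std(axis=0)
    sds[sds == 0] = 1.0
    x = (features - means) / sds

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(labels))
    n_holdout = int(round(holdout_fraction * len(labels)))
    hold, fit = perm[:n_holdout], perm[n_holdout:]
    if len(np.unique(labels[fit])) < 2:  # tiny datasets: fit on everything
        hold, fit = np.array([], dtype=int), perm

    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(x[fit], labels[fit])
    holdout_acc = (float(np.mean(clf.predict(x[hold]) == labels[hold]))
                   if len(hold) else None)

    model = ScorerModel(
        feature_names=FEATURE_NAMES,
        weights=clf.coef_[0].astype(float),
        intercept=float(clf.intercept_[0]),
        feature_means=means.astype(float),
        feature_sds=sds.astype(float),
        metadata={
            "training_seed": int(seed),
            "tile_size_px": tile_size_px,
            "n_training_tiles": int(len(fit)),
            "holdout_accuracy": holdout_acc,
            "version": 1,
        },
    )
    return model


# --------------------------------------------------------------------------
# decisions
# --------------------------------------------------------------------------

def classify_cluster(scores, threshold: float,
                     cluster_id: int = 0) -> ClusterDecision:
    """Mean of section scores vs threshold: cancer iff mean > threshold."""
    scores = [float(s) for s in scores]
    if not scores:
        raise ValueError("at least one tile score is required")
    if any(not 0.0 <= s <= 1.0 for s in scores):
        raise ValueError("tile scores must lie in [0, 1]")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mean = float(np.mean(scores))
    label = LABEL_CANCER if mean > threshold else LABEL_NON_CANCER
    return ClusterDecision(cluster_id, scores, mean, float(threshold), label)


def score_cluster(image: np.ndarray, cluster: CandidateCluster,
                  scorer: ScorerModel, threshold: float,
                  tile_size_px: int = DEFAULT_TILE_SIZE,
                  min_inside_fraction: float = DEFAULT_MIN_INSIDE_FRACTION
                  ) -> ClusterDecision:
    tiles = tile_cluster(cluster, image.shape[:2], tile_size_px,
                         min_inside_fraction)
    scores = [scorer.score_tile(image, t) for t in tiles]
    return classify_cluster(scores, threshold, cluster.cluster_id)


def score_slide(image: np.ndarray, detection_config: DetectionConfig | None,
                scorer: ScorerModel, threshold: float,
                tile_size_px: int = DEFAULT_TILE_SIZE,
                min_inside_fraction: float = DEFAULT_MIN_INSIDE_FRACTION
                ) -> list[ClusterDecision]:
    """End-to-end: detect candidate clusters, then score and classify each."""
    result = detect(image, detection_config)
    return [score_cluster(image, c, scorer, threshold, tile_size_px,
                          min_inside_fraction) for c in result.accepted]
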