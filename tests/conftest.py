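from __future__ import annotations

import numpy as np
import pytest

from smearscreen import (CandidateCluster, SmearSpec, generate_smear,
                         generate_tile_dataset, train_reference_scorer)


@pytest.fixture(scope="session")
def default_scene():
    """One study-condition smear scene reused across read-only tests."""
    spec = SmearSpec(seed=202)
    image, truth = generate_smear(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def trained_scorer():
    """Reference scorer fit on tiles from study-condition smears."""
    spec = SmearSpec(seed=31)
    dataset = generate_tile_dataset(spec, tile_size_px=128,
                                    n_tiles_per_class=80)
    return train_reference_scorer(dataset, seed=31)


def truth_clusters(seed: int, n_clusters: int):
    """Ground-truth clusters (cancer and benign aggregates) harvested from a
    stream of study-condition smears, as (image, candidate, is_cancer)."""
    out = []
    smear_idx = 0
    while len(out) < n_clusters:
        spec = SmearSpec(seed=(seed * 9973 + smear_idx) % (2**31))
        image, truth = generate_smear(spec)
        for rec in truth.clusters:
            if rec.label == "artifact" or len(out) >= n_clusters:
                continue
            cand = CandidateCluster.from_mask(truth.mask(rec.cluster_id),
                                              rec.cluster_id)
            out.append((image, cand, rec.label == "cancer"))
        smear_idx += 1
    return out


def random_blob_mask(rng: np.random.Generator, shape=(64, 64),
                     density: float = 0.35) -> np.ndarray:
    """Random blobby binary mask (smoothed noise thresholded at a quantile)."""
    from scipy.ndimage import gaussian_filter

    noise = gaussian_filter(rng.normal(size=shape), sigma=3.0)
    mask = noise > np.quantile(noise, 1.0 - density)
    return mask
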