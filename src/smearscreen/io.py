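"""Readers and writers for the formats the pipeline touches.

Images travel as 8-bit PNG/TIFF, masks as single-channel 8-bit PNG, ground
truth / candidates / metrics / models as JSON with sorted keys (so reruns
are byte-identical), decisions and summary rows as comma-separated UTF-8
CSV with a header row.  Every JSON report carries the package version and
the config hash that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .detection import CandidateCluster, DetectionResult
from .scoring import ClusterDecision
from .synthetic import GroundTruth


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as 8-bit RGB (alpha, if any, is dropped)."""
    with Image.open(path) as img:
        img = img.convert("RGB")
        return np.asarray(img, dtype=np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image).save(path)


def write_label_map(label_map: np.ndarray, path: str | Path) -> None:
    if label_map.dtype != np.uint8:
        raise ValueError("label maps are 8-bit rasters")
    Image.fromarray(label_map, mode="L").save(path)


def read_label_map(path: str | Path) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img.convert("L"), dtype=np.uint8)


def _stamp(payload: dict, config_hash: str | None) -> dict:
    from . import __version__
    payload["package_version"] = __version__
    if config_hash is not None:
        payload["config_hash"] = config_hash
    return payload


def write_json(payload: dict, path: str | Path,
               config_hash: str | None = None) -> None:
    Path(path).write_text(
        json.dumps(_stamp(dict(payload), config_hash), sort_keys=True,
                   indent=1, default=float) + "\n")


def write_ground_truth(gt: GroundTruth, json_path: str | Path,
                       mask_path: str | Path | None = None) -> None:
    payload = json.loads(gt.to_json())
    write_json(payload, json_path)
    if mask_path is not None:
        write_label_map(gt.label_map, mask_path)


def read_ground_truth(json_path: str | Path,
                      mask_path: str | Path) -> GroundTruth:
    label_map = read_label_map(mask_path)
    return GroundTruth.from_json(Path(json_path).read_text(), label_map)


def candidate_to_dict(cand: CandidateCluster) -> dict:
    return {
        "cluster_id": cand.cluster_id,
        "area_px": cand.area_px,
        "bbox": list(cand.bbox),
        "min_rect": {
            "center": list(cand.min_rect.center),
            "width": cand.min_rect.width,
            "height": cand.min_rect.height,
            "angle_deg": cand.min_rect.angle_deg,
        },
        "fill_ratio": cand.fill_ratio,
        "status": cand.status,
    }


def write_candidates(result: DetectionResult, path: str | Path,
                     config_hash: str | None = None) -> None:
    payload = {
        "saturation_threshold": result.saturation_threshold,
        "candidates": [candidate_to_dict(c) for c in result.all_candidates],
    }
    write_json(payload, path, config_hash)


def decisions_to_frame(decisions: list[ClusterDecision]) -> pd.DataFrame:
    return pd.DataFrame({
        "cluster_id": [d.cluster_id for d in decisions],
        "n_tiles": [len(d.tile_scores) for d in decisions],
        "mean_score": [d.mean_score for d in decisions],
        "threshold": [d.threshold for d in decisions],
        "label": [d.label for d in decisions],
    })


def write_decisions(decisions: list[ClusterDecision], path: str | Path,
                    config_hash: str | None = None) -> None:
    from . import __version__
    header = f"# smearscreen {__version__}"
    if config_hash:
        header += f" config {config_hash}"
    frame = decisions_to_frame(decisions)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, index=False)


def read_decisions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """CSV with an ``item_id`` column plus score and/or label columns."""
    frame = pd.read_csv(path, comment="#")
    if "item_id" not in frame.columns:
        raise ValueError(f"{path}: expected an 'item_id' column")
    return frame


def read_summary_rows(path: str | Path) -> list[dict]:
    """CSV mirroring a printed summary table: label, n, sens, spec, acc and
    optional ppv, npv, kappa, dp, positives columns."""
    frame = pd.read_csv(path, comment="#")
    required = {"label", "n", "sens", "spec", "acc"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for _, rec in frame.iterrows():
        row = {"label": str(rec["label"]), "n": int(rec["n"]),
               "sens": float(rec["sens"]), "spec": float(rec["spec"]),
               "acc": float(rec["acc"])}
        for opt in ("ppv", "npv", "kappa"):
            if opt in frame.columns and pd.notna(rec[opt]):
                row[opt] = float(rec[opt])
        if "dp" in frame.columns and pd.notna(rec["dp"]):
            row["dp"] = int(rec["dp"])
        if "positives" in frame.columns and pd.notna(rec["positives"]):
            row["positives"] = int(rec["positives"])
        rows.append(row)
    return rows
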