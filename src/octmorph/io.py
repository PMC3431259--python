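"""Reading and writing the package's on-disk formats.

Images are 8-bit greyscale PNG/TIFF/JPEG; ground truth and landmarks
travel as JSON sidecars (coordinates in mm and px); boundaries as CSV
(surface, column_mm, depth_mm); cohorts as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import BoundarySet, LandmarkSet, OCTImage

_LANDMARK_FIELDS = ("spur_left", "spur_right", "graft_ant_left", "graft_ant_right",
                    "graft_post_left", "graft_post_right")


def write_image(img: OCTImage, path) -> None:
    Image.fromarray(img.intensities.astype(np.uint8), mode="L").save(path)


def read_image(path, px_size_lateral: float, px_size_axial: float,
               dewarped: bool = False) -> OCTImage:
    arr = np.asarray(Image.open(path).convert("L"))
    return OCTImage(arr, px_size_lateral, px_size_axial, dewarped=dewarped,
                    source_id=str(path))


def write_truth_sidecar(path, geometry, landmarks: LandmarkSet,
                        landmarks_px: dict = None) -> None:
    """JSON sidecar (`<image>.truth.json`) with true parameters and landmarks."""
    payload = {
        "true_parameters_mm": {
            "pcal": geometry.true_pcal, "acw": geometry.true_acw,
            "agal": geometry.true_agal, "agcl": geometry.true_agcl,
            "pgal": geometry.true_pgal, "pgcl": geometry.true_pgcl,
            "curvature": geometry.posterior_radius,
            "thickness_um": geometry.graft_thickness_mm * 1000.0,
        },
        "landmarks_mm": {f: (getattr(landmarks, f).tolist()
                             if getattr(landmarks, f) is not None else None)
                         for f in _LANDMARK_FIELDS},
        "landmarks_px": landmarks_px or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    payload = {f: (getattr(landmarks, f).tolist()
                   if getattr(landmarks, f) is not None else None)
               for f in _LANDMARK_FIELDS}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_landmarks(path) -> LandmarkSet:
    payload = json.loads(Path(path).read_text())
    if "landmarks_mm" in payload:  # accept truth sidecars too
        payload = payload["landmarks_mm"]
    return LandmarkSet(**{f: (np.asarray(v, dtype=float) if v is not None else None)
                          for f, v in payload.items() if f in _LANDMARK_FIELDS})


def write_boundaries(boundaries: BoundarySet, path) -> None:
    rows = []
    for name in ("epithelium", "endothelium", "graft_anterior_interface",
                 "graft_posterior", "iris_anterior"):
        poly = getattr(boundaries, name)
        for x, z in poly:
            rows.append({"surface": name, "column_mm": x, "depth_mm": z})
    pd.DataFrame(rows, columns=["surface", "column_mm", "depth_mm"]).to_csv(
        path, index=False)


def read_boundaries(path) -> BoundarySet:
    df = pd.read_csv(path)
    polys = {}
    for name in ("epithelium", "endothelium", "graft_anterior_interface",
                 "graft_posterior", "iris_anterior"):
        sub = df[df["surface"] == name]
        polys[name] = sub[["column_mm", "depth_mm"]].to_numpy(dtype=float)
    return BoundarySet(**polys)


def write_qc_jsonl(qc_results, path) -> None:
    with open(path, "w") as fh:
        for q in qc_results:
            fh.write(json.dumps(dataclasses.asdict(q)) + "\n")
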