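"""Batch analysis: run the pipeline over a directory of B-scans.

Emits one area measurement per image per mode, in deterministic filename
order.  Per-image failures do not stop the batch: they appear in the
``error`` column with an empty area, so an exception in one scan never
silently drops the rest of a session's measurements.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import OCTGraftError
from .io import load_image
from .metrics import compute_area
from .phantom import truth_from_dict
from .segmentation import segment_automated, snap_to_truth

__all__ = ["run_batch"]

log = logging.getLogger("octgraft.batch")

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def run_batch(image_dir: str | Path, config: RunConfig = RunConfig(),
              semi_automated: bool = True) -> pd.DataFrame:
    """Analyse every PNG/TIFF in ``image_dir``.

    Columns: image_id, mode, area_um2, error.  The automated mode is run on
    every image; when a ``<stem>.truth.json`` sidecar (phantom ground
    truth) is present and ``semi_automated`` is set, the automated
    segmentation is additionally refined onto the truth curves — the
    ideal-observer semi-automated reading — and reported as a second row.
    """
    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.iterdir()
                   if p.suffix.lower() in _IMAGE_SUFFIXES)
    rows = []
    for path in paths:
        t0 = time.perf_counter()
        image_id = path.stem
        truth = None
        sidecar = path.parent / f"{path.stem}.truth.json"
        if semi_automated and sidecar.exists():
            truth = truth_from_dict(json.loads(sidecar.read_text()))
        seg = None
        try:
            image = load_image(path, config.calibration)
            seg = segment_automated(image, config)
            area = compute_area(seg, config.calibration, image_id=image_id)
            rows.append({"image_id": image_id, "mode": "automated",
                         "area_um2": area.area_um2, "error": ""})
        except (OCTGraftError, OSError) as exc:
            rows.append({"image_id": image_id, "mode": "automated",
                         "area_um2": np.nan, "error": str(exc)})
        if truth is not None:
            try:
                if seg is None:
                    raise OCTGraftError("automated segmentation unavailable to refine")
                semi = snap_to_truth(seg, truth)
                area = compute_area(semi, config.calibration, image_id=image_id)
                rows.append({"image_id": image_id, "mode": "semi_automated",
                             "area_um2": area.area_um2, "error": ""})
            except OCTGraftError as exc:
                rows.append({"image_id": image_id, "mode": "semi_automated",
                             "area_um2": np.nan, "error": str(exc)})
        log.info("processed %s in %.3f s", path.name, time.perf_counter() - t0)
    return pd.DataFrame(rows, columns=["image_id", "mode", "area_um2", "error"])
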