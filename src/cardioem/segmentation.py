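"""Baseline intensity segmentation, mask cleanup, external mask ingestion,
and the pixelwise accuracy evaluator.

The extracellular space in heavy-metal-stained EM appears as a distinct
intensity phase and is segmented by thresholding (fixed value, automatic
bimodal valley, or quantile).  Organelle masks produced by external tools
(e.g. a deep-learning segmenter) are ingested through
:func:`ingest_label_volume` and scored against annotated truth with
:func:`evaluate_segmentation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from . import io as cio
from .geometry import VolumeGeometry
from .volumes import LabelVolume, VoxelVolume, CLASS_IGNORE

log = logging.getLogger(__name__)

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def segment_extracellular(volume: VoxelVolume, method: str = "bimodal-valley",
                          threshold: float | None = None,
                          quantile: float | None = None,
                          ec_is_bright: bool = True) -> np.ndarray:
    """Binary extracellular mask from intensity.

    method='fixed'
        ``threshold`` required; the mask is exactly the voxels on the EC side
        of the threshold (> t when ``ec_is_bright``, < t otherwise).
    method='bimodal-valley'
        Otsu valley between the two histogram modes; raises if the smoothed
        histogram is not bimodal (advise a fixed threshold instead).
    method='quantile'
        ``quantile`` = target EC fraction q; the brightest (or darkest)
        q-fraction of voxels is selected.
    """
    data = volume.data
    if data.size == 0:
        raise ValueError("cannot segment an empty volume")
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        return data > threshold if ec_is_bright else data < threshold
    if method == "quantile":
        if quantile is None or not (0.0 <= quantile <= 1.0):
            raise ValueError("method='quantile' requires quantile in [0, 1]")
        if quantile == 0.0:
            return np.zeros(data.shape, dtype=bool)
        q = 1.0 - quantile if ec_is_bright else quantile
        t = float(np.quantile(data, q))
        return data > t if ec_is_bright else data < t
    if method == "bimodal-valley":
        _require_bimodal(data)
        t = float(threshold_otsu(data.ravel()))
        return data > t if ec_is_bright else data < t
    raise ValueError(f"unknown method {method!r}")


def _require_bimodal(data: np.ndarray) -> None:
    hist, _ = np.histogram(data, bins=64)
    smooth = ndimage.gaussian_filter1d(hist.astype(float), 2.0)
    peaks, props = find_peaks(smooth, prominence=0.02 * smooth.max())
    if len(peaks) < 2:
        raise ValueError(
            "intensity histogram is not bimodal; use method='fixed' with an "
            "explicit threshold")


def cleanup_mask(mask: np.ndarray, min_object_voxels: int = 0,
                 closing_radius: int = 0, fill_holes: bool = True) -> np.ndarray:
    """Morphological cleanup: closing → hole fill → small-object removal.

    Connectivity for object removal is 26-neighbor.  The operation is
    idempotent: applying it twice equals applying it once.
    """
    if closing_radius < 0:
        raise ValueError("closing radius must be >= 0")
    if min_object_voxels < 0:
        raise ValueError("minimum object size must be >= 0")
    out = np.asarray(mask, dtype=bool).copy()
    if closing_radius > 0:
        st = ndimage.generate_binary_structure(3, 1)
        out = ndimage.binary_closing(out, structure=st,
                                     iterations=closing_radius)
    if fill_holes:
        out = ndimage.binary_fill_holes(out)
    if min_object_voxels > 1:
        # components strictly smaller than min_object_voxels are removed
        out = remove_small_objects(out, max_size=min_object_voxels - 1,
                                   connectivity=3)
    return out


def ingest_label_volume(path: str | Path, class_map: Mapping[int, str],
                        geometry: VolumeGeometry | None = None) -> LabelVolume:
    """Read and validate an externally produced class mask (NRRD or TIFF).

    Any voxel value not declared in ``class_map`` raises with the offending
    values listed.  Per-class voxel counts are logged for provenance.
    """
    labels = cio.read_label_volume(path, class_map, geometry)
    counts = labels.class_counts()
    log.info("ingested %s: %s", path,
             {class_map[c]: n for c, n in counts.items() if n})
    return labels


@dataclass
class SegmentationAccuracy:
    """Pixelwise agreement between a predicted and a truth label volume.

    ``per_class_pct`` holds truth-class recall in percent (correct voxels of
    a truth class over that class's voxel count); classes absent from the
    truth are reported as ``None`` (undefined), not 0.  ``confusion`` counts
    (truth, predicted) pairs and sums to ``n_pixels``.
    """

    per_class_pct: dict[int, float | None]
    overall_pct: float
    confusion: dict[tuple[int, int], int]
    n_pixels: int

    def to_dict(self) -> dict:
        return {
            "per_class_pct": {str(k): v for k, v in self.per_class_pct.items()},
            "overall_pct": self.overall_pct,
            "n_pixels": self.n_pixels,
            "confusion": {f"{t}->{p}": n for (t, p), n in self.confusion.items()},
        }


def evaluate_segmentation(predicted: LabelVolume, truth: LabelVolume,
                          classes: list[int] | None = None) -> SegmentationAccuracy:
    """Score a predicted label volume against annotated truth.

    Voxels carrying the ignore class (in either volume) are excluded.
    Invariant to consistent relabeling of classes through the class map.
    """
    if predicted.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs truth {truth.shape}")
    if classes is None:
        classes = sorted(c for c in truth.class_map if c != CLASS_IGNORE)
    keep = (truth.data != CLASS_IGNORE) & (predicted.data != CLASS_IGNORE)
    t = truth.data[keep].ravel()
    p = predicted.data[keep].ravel()
    n = int(t.size)
    if n == 0:
        raise ValueError("no voxels to evaluate after excluding the ignore class")
    pairs, counts = np.unique(np.stack([t, p]), axis=1, return_counts=True)
    confusion = {(int(a), int(b)): int(c)
                 for (a, b), c in zip(pairs.T, counts)}
    per_class: dict[int, float | None] = {}
    for c in classes:
        total = int(np.sum(t == c))
        if total == 0:
            per_class[c] = None
            continue
        correct = confusion.get((c, c), 0)
        per_class[c] = 100.0 * correct / total
    overall = 100.0 * float(np.sum(t == p)) / n
    return SegmentationAccuracy(per_class, overall, confusion, n)
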