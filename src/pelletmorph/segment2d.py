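"""Marker-controlled watershed segmentation of pellet micrographs.

The pipeline mirrors a stereomicroscope workflow for pellet suspensions:
pellets are bright, roughly circular objects on a dark background with the
best contrast in the red channel. Stages:

1. red-channel extraction;
2. opening-by-reconstruction (disk radius 10 px) to remove small bright
   noise without damaging pellet contours, followed by
   closing-by-reconstruction (disk radius 5 px) to fill small dark holes;
3. regional grey-level maxima of the filtered image as pellet markers and
   a binarized pellet mask;
4. marker-controlled watershed on the negated Euclidean distance transform
   of the pellet mask to split touching pellets;
5. post-filtering: pellets intersecting the image border are removed, as
   are objects whose area-equivalent diameter falls outside 100–3000 µm.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, erosion, local_maxima, reconstruction
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

#: default post-filter: diameters outside this range are unlikely to be
#: single pellets
D_MIN_UM = 100.0
D_MAX_UM = 3000.0

#: default structuring-element radii (px) for the reconstruction filter
OPEN_SE_PX = 10
CLOSE_SE_PX = 5


@dataclass
class ImageSample:
    """A calibrated RGB micrograph."""

    rgb: np.ndarray
    pixel_size: float  # µm per pixel
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError("pixel_size must be positive and finite")
        if self.rgb.ndim != 3 or self.rgb.shape[2] < 3:
            raise ValueError("rgb must be an H×W×3 image")


@dataclass
class PelletRecord:
    """One segmented pellet."""

    label: int
    area_px: int
    area_um2: float
    equivalent_diameter_um: float
    centroid: tuple[float, float]  # (row, col) px
    touches_border: bool = False
    source: str = "auto"  # or "manual"
    sample_id: str = ""


@dataclass
class PelletPopulation:
    """Pellets from one replicate flask (possibly pooled over images)."""

    records: list[PelletRecord]
    condition: object = None
    replicate_id: str = ""

    @property
    def diameters(self) -> np.ndarray:
        return np.array([r.equivalent_diameter_um for r in self.records], dtype=float)

    def __len__(self) -> int:
        return len(self.records)


def equivalent_diameter(area_um2: float) -> float:
    """Area-equivalent diameter: the circle of equal area, d = 2·sqrt(A/π)."""
    if area_um2 < 0:
        raise ValueError("area must be >= 0")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def reconstruct_filter(
    grey: np.ndarray, open_se_px: int = OPEN_SE_PX, close_se_px: int = CLOSE_SE_PX
) -> np.ndarray:
    """Opening- then closing-by-reconstruction with disk structuring elements.

    Opening-by-reconstruction erodes with a disk of radius ``open_se_px``
    and reconstructs by dilation under the original, removing bright
    objects smaller than the disk while preserving the contours of the
    survivors. Closing-by-reconstruction (dilation followed by
    reconstruction by erosion) then fills dark holes smaller than
    ``close_se_px``.
    """
    grey = np.asarray(grey, dtype=float)
    if grey.size == 0:
        raise ValueError("empty image")
    if min(open_se_px, close_se_px) < 1:
        raise ValueError("structuring-element radii must be >= 1")
    if 2 * max(open_se_px, close_se_px) + 1 > min(grey.shape):
        raise ValueError("structuring element larger than image")
    conn8 = np.ones((3, 3))  # 8-connected propagation, the 2D morphology default
    eroded = erosion(grey, disk(open_se_px))
    opened = reconstruction(eroded, grey, method="dilation", footprint=conn8)
    dilated = dilation(opened, disk(close_se_px))
    closed = reconstruction(dilated, opened, method="erosion", footprint=conn8)
    return closed


def detect_markers(
    filtered: np.ndarray, threshold: str | float = "otsu"
) -> tuple[np.ndarray, np.ndarray]:
    """Regional maxima (markers) and binarized pellet mask of the filtered image.

    Markers are 8-connected plateaus with no brighter neighbour, restricted
    to the pellet mask. ``threshold`` is either ``"otsu"`` or a float
    quantile in (0, 1) of the non-zero intensities.
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.max() == filtered.min():
        empty = np.zeros(filtered.shape, dtype=bool)
        return empty, empty.copy()
    if threshold == "otsu":
        thr = threshold_otsu(filtered)
    else:
        nonzero = filtered[filtered > 0]
        thr = float(np.quantile(nonzero, float(threshold))) if nonzero.size else np.inf
    pellet_mask = filtered > thr
    maxima = local_maxima(filtered, connectivity=2)
    marker_mask = maxima & pellet_mask
    return marker_mask, pellet_mask


def watershed_split(pellet_mask: np.ndarray, marker_mask: np.ndarray) -> np.ndarray:
    """Split the pellet mask by marker-controlled watershed.

    The Euclidean distance transform of the mask is negated and flooded
    from the marker components (minima imposition); every masked pixel is
    assigned to exactly one marker basin, so k markers yield k labels.
    Markers outside the mask are ignored with a warning.
    """
    pellet_mask = np.asarray(pellet_mask, dtype=bool)
    marker_mask = np.asarray(marker_mask, dtype=bool)
    if pellet_mask.shape != marker_mask.shape:
        raise ValueError("mask shapes differ")
    outside = marker_mask & ~pellet_mask
    if outside.any():
        logger.warning("ignoring %d marker pixels outside the pellet mask",
                       int(outside.sum()))
    markers, n = ndi.label(marker_mask & pellet_mask,
                           structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros(pellet_mask.shape, dtype=np.int32)
    edt = ndi.distance_transform_edt(pellet_mask)
    return watershed(-edt, markers=markers, mask=pellet_mask, connectivity=2).astype(np.int32)


def postfilter(
    labels: np.ndarray,
    pixel_size: float,
    d_min: float = D_MIN_UM,
    d_max: float = D_MAX_UM,
    sample_id: str = "",
) -> list[PelletRecord]:
    """Remove border-touching labels and out-of-range diameters.

    Returns surviving pellets as records sorted by label; the area-equivalent
    diameter is computed from the label area in µm².
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    labels = np.asarray(labels)
    border = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :]))
    border |= set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
    border.discard(0)
    records: list[PelletRecord] = []
    for prop in regionprops(labels):
        if prop.label in border:
            continue
        area_um2 = prop.area * pixel_size**2
        ed = equivalent_diameter(area_um2)
        if not d_min <= ed <= d_max:
            continue
        records.append(
            PelletRecord(
                label=int(prop.label),
                area_px=int(prop.area),
                area_um2=float(area_um2),
                equivalent_diameter_um=float(ed),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                touches_border=False,
                source="auto",
                sample_id=sample_id,
            )
        )
    records.sort(key=lambda r: r.label)
    return records


@dataclass
class PipelineResult:
    population: PelletPopulation
    labels: np.ndarray = field(repr=False, default=None)
    report: dict = field(default_factory=dict)


def run_pipeline(
    sample: ImageSample,
    open_se_px: int = OPEN_SE_PX,
    close_se_px: int = CLOSE_SE_PX,
    d_min: float = D_MIN_UM,
    d_max: float = D_MAX_UM,
    threshold: str | float = "otsu",
    return_labels: bool = False,
) -> PelletPopulation | PipelineResult:
    """Full segmentation of one image: red channel → filter → markers →
    watershed → post-filter. Deterministic for fixed input."""
    report: dict = {"sample_id": sample.sample_id, "stages": {}, "warnings": [],
                    "params": {"open_se_px": open_se_px, "close_se_px": close_se_px,
                               "d_min_um": d_min, "d_max_um": d_max,
                               "pixel_size_um": sample.pixel_size,
                               "threshold": threshold}}

    def staged(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except Exception as exc:  # annotate the failing stage
            raise RuntimeError(f"segmentation stage '{name}' failed: {exc}") from exc
        report["stages"][name] = round(time.perf_counter() - t0, 4)
        return out

    red = sample.rgb[..., 0].astype(float)
    filtered = staged("reconstruct_filter", reconstruct_filter, red, open_se_px, close_se_px)
    marker_mask, pellet_mask = staged("detect_markers", detect_markers, filtered, threshold)
    labels = staged("watershed_split", watershed_split, pellet_mask, marker_mask)
    records = staged("postfilter", postfilter, labels, sample.pixel_size,
                     d_min, d_max, sample.sample_id)
    report["n_records"] = len(records)
    population = PelletPopulation(records=records, replicate_id=sample.sample_id)
    if return_labels:
        return PipelineResult(population=population, labels=labels, report=report)
    return population


def run_replicate(samples: list[ImageSample], replicate_id: str = "", **kwargs) -> PelletPopulation:
    """Pool pellet records from the images of one replicate flask.

    The imaging protocol measures each sample twice (two aliquots, two
    images); records are pooled under the originating sub-sample ids.
    """
    records: list[PelletRecord] = []
    for sample in samples:
        records.extend(run_pipeline(sample, **kwargs).records)
    return PelletPopulation(records=records, replicate_id=replicate_id)


# ---------------------------------------------------------------------------
# I/O

RECORD_COLUMNS = [
    "sample_id", "label", "area_px", "area_um2", "ed_um",
    "centroid_r", "centroid_c", "touches_border", "source",
]


def records_to_frame(population: PelletPopulation) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "label": r.label,
            "area_px": r.area_px,
            "area_um2": r.area_um2,
            "ed_um": r.equivalent_diameter_um,
            "centroid_r": r.centroid[0],
            "centroid_c": r.centroid[1],
            "touches_border": r.touches_border,
            "source": r.source,
        }
        for r in population.records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(population: PelletPopulation, path: str | Path) -> None:
    records_to_frame(population).to_csv(path, index=False)


def read_records(path: str | Path) -> PelletPopulation:
    """Read a records CSV (``source`` may include manual re-measurements)."""
    df = pd.read_csv(path)
    records = [
        PelletRecord(
            label=int(row.label),
            area_px=int(row.area_px),
            area_um2=float(row.area_um2),
            equivalent_diameter_um=float(row.ed_um),
            centroid=(float(row.centroid_r), float(row.centroid_c)),
            touches_border=bool(row.touches_border),
            source=str(row.source),
            sample_id=str(row.sample_id),
        )
        for row in df.itertuples()
    ]
    return PelletPopulation(records=records, replicate_id=Path(path).stem)


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str))
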