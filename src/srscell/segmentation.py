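"""Cell outlining and lipid-droplet detection from component images.

The phasor stage yields a nuclei map and a lipid map; together with the
whole-cell (DC) image these drive a classical seeded-watershed pipeline:
nuclei are thresholded, size-filtered and split by a distance-transform
watershed; cells are grown from nucleus seeds over the whole-cell foreground;
droplets are thresholded, watershed-split puncta assigned to the cell
containing their centroid.  This re-implements the interactive
image-cytometry stage of the original workflow as deterministic code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from .errors import IncompatibilityError

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMaps",
    "segment_nuclei",
    "outline_cells",
    "detect_droplets",
    "segment_field",
]


@dataclass
class LabelMaps:
    """Integer-labelled nuclei, cell and droplet masks on one spatial grid.

    Invariants (checked by :meth:`validate`): labels are consecutive positive
    integers with 0 = background, each cell contains exactly one nucleus, and
    every droplet lies inside its assigned cell.
    """

    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    droplet_labels: np.ndarray
    droplet_to_cell: pd.DataFrame

    def validate(self) -> None:
        for cell_id in np.unique(self.cell_labels):
            if cell_id == 0:
                continue
            nuclei_in = np.unique(self.nuclei_labels[self.cell_labels == cell_id])
            nuclei_in = nuclei_in[nuclei_in != 0]
            if len(nuclei_in) != 1:
                raise ValueError(
                    f"cell {cell_id} contains {len(nuclei_in)} nuclei, expected 1"
                )
        for row in self.droplet_to_cell.itertuples():
            region = self.droplet_labels == row.droplet_id
            owners = np.unique(self.cell_labels[region])
            if not np.all(owners == row.cell_id):
                raise ValueError(f"droplet {row.droplet_id} leaks outside its cell")


def _auto_threshold(image: np.ndarray) -> float:
    vals = image[np.isfinite(image)]
    if vals.size == 0 or np.all(vals == vals.flat[0]):
        return float("inf")  # nothing segmentable
    return float(threshold_otsu(vals))


def segment_nuclei(
    nuclei_image: np.ndarray,
    min_area: int = 30,
    max_area: int = 10_000,
    threshold: float | None = None,
) -> np.ndarray:
    """Label nuclei: threshold, split touching discs, size-filter.

    Touching nuclei are separated by a watershed on the inverted distance
    transform seeded at distance maxima.  ``threshold`` defaults to Otsu on
    the image (background-0 component maps separate cleanly).
    """
    if min_area >= max_area:
        raise ValueError("min_area must be < max_area")
    nuclei_image = np.asarray(nuclei_image, dtype=float)
    if threshold is None:
        threshold = _auto_threshold(nuclei_image)
    mask = nuclei_image > threshold
    if not mask.any():
        return np.zeros(nuclei_image.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    min_sep = max(3, int(round(0.8 * np.sqrt(min_area / np.pi))))
    peaks = peak_local_max(
        distance, min_distance=min_sep, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        labels = cc_label(mask)
    else:
        labels = watershed(-distance, markers, mask=mask)

    # size filter, then renumber consecutively
    counts = np.bincount(labels.ravel())
    bad = np.flatnonzero((counts < min_area) | (counts > max_area))
    labels[np.isin(labels, bad[bad != 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def outline_cells(
    whole_cell_image: np.ndarray,
    nuclei_labels: np.ndarray,
    threshold: float | None = None,
) -> np.ndarray:
    """Grow cell regions from nucleus seeds over the foreground mask.

    The foreground is the Otsu-thresholded whole-cell image (override with
    ``threshold``); the watershed topography is the inverted intensity, so
    boundaries between neighbouring cells fall along dim valleys.  Nuclei
    outside the foreground trigger a warning but their cells are still grown
    from the seed pixels.
    """
    whole_cell_image = np.asarray(whole_cell_image, dtype=float)
    if whole_cell_image.shape != nuclei_labels.shape:
        raise IncompatibilityError("whole-cell image and nuclei labels differ in shape")
    if nuclei_labels.max() == 0:
        return np.zeros(whole_cell_image.shape, dtype=np.int32)
    if threshold is None:
        threshold = _auto_threshold(whole_cell_image)
    foreground = whole_cell_image > threshold
    outside = (nuclei_labels > 0) & ~foreground
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} nucleus pixels fall outside the foreground; "
            "cells grown from seeds anyway",
            stacklevel=2,
        )
        foreground |= nuclei_labels > 0
    cells = watershed(-whole_cell_image, nuclei_labels, mask=foreground)
    return cells.astype(np.int32)


def detect_droplets(
    lipid_image: np.ndarray,
    cell_labels: np.ndarray,
    min_diameter: float = 3.0,
    intensity_floor: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Detect lipid-droplet puncta and assign each to a cell.

    Droplets are connected components of ``lipid_image > intensity_floor``,
    split by a distance-transform watershed where merged, and dropped when
    smaller than a ``min_diameter`` disc (sub-resolution specks) or when
    their centroid lies on background.  A droplet straddling a cell boundary
    is assigned to its centroid's cell only and clipped to that cell, so
    every droplet region lies inside its assigned cell.  Returns the droplet
    label image and a table ``droplet_id, cell_id, area_px, centroid_row,
    centroid_col``.
    """
    lipid_image = np.asarray(lipid_image, dtype=float)
    if lipid_image.shape != cell_labels.shape:
        raise IncompatibilityError("lipid image and cell labels differ in shape")
    mask = lipid_image > intensity_floor
    cols = ["droplet_id", "cell_id", "area_px", "centroid_row", "centroid_col"]
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32), pd.DataFrame(columns=cols)

    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=max(1, int(round(min_diameter))),
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask) if len(peaks) else cc_label(mask)

    min_area = np.pi * (min_diameter / 2.0) ** 2
    rows = []
    keep = np.zeros(mask.shape, dtype=np.int32)
    new_id = 0
    n_dropped = 0
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        cy, cx = region.centroid
        owner = int(cell_labels[int(round(cy)), int(round(cx))])
        if owner == 0:
            n_dropped += 1
            continue
        new_id += 1
        clipped = (labels == region.label) & (cell_labels == owner)
        keep[clipped] = new_id
        rows.append(
            {
                "droplet_id": new_id,
                "cell_id": owner,
                "area_px": int(clipped.sum()),
                "centroid_row": cy,
                "centroid_col": cx,
            }
        )
    if n_dropped:
        logger.info("dropped %d droplets with background centroid", n_dropped)
    return keep, pd.DataFrame(rows, columns=cols)


def segment_field(
    nuclei_image: np.ndarray,
    whole_cell_image: np.ndarray,
    lipid_image: np.ndarray,
    min_nucleus_area: int = 30,
    max_nucleus_area: int = 10_000,
    min_droplet_diameter: float = 3.0,
    droplet_floor: float = 0.0,
    nucleus_threshold: float | None = None,
    cell_threshold: float | None = None,
) -> LabelMaps:
    """Convenience pipeline: nuclei -> cells -> droplets on one field.

    Thresholds default to Otsu; pass ``cell_threshold`` explicitly when
    bright droplets dominate the DC histogram (Otsu then lands above the
    cytoplasm level).
    """
    nuclei = segment_nuclei(
        nuclei_image, min_nucleus_area, max_nucleus_area, threshold=nucleus_threshold
    )
    cells = outline_cells(whole_cell_image, nuclei, threshold=cell_threshold)
    droplets, mapping = detect_droplets(
        lipid_image, cells, min_droplet_diameter, droplet_floor
    )
    return LabelMaps(
        nuclei_labels=nuclei,
        cell_labels=cells,
        droplet_labels=droplets,
        droplet_to_cell=mapping,
    )
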