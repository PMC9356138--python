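"""The metabolic index: fatty-acid uptake relative to glucose anabolism.

For paired single-cell measurements of FA-uptake signal F (a deuterated-FA
C-D metric, or the alkyne C#C metric in the dual-probe experiment) and
glucose-derived signal G (the glucose-d7 C-D metric), the metabolic index is

    M = F / (F + G),  a dimensionless number in [0, 1].

Higher M means the cell leans on fatty-acid uptake rather than
glucose-derived anabolism — the metabolic signature that tracks platinum
resistance.  M is scale-invariant (M(cF, cG) = M(F, G)), so it is robust to
global imaging-power changes; cells where neither probe is detected carry no
index and are excluded with a logged count rather than silently scored 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IncompatibilityError

logger = logging.getLogger(__name__)

__all__ = [
    "IndexResult",
    "AggregateIndex",
    "compute_index",
    "index_from_dual_probe",
    "aggregate_sample",
]


def compute_index(F, G):
    """M = F / (F + G) for non-negative inputs, elementwise.

    Where ``F + G == 0`` the index is undefined and returned as NaN (the
    caller excludes those cells); it is never silently reported as 0.
    """
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if np.any(F < 0) or np.any(G < 0):
        raise ValueError("F and G must be non-negative")
    total = F + G
    out = np.full(np.broadcast(F, G).shape, np.nan)
    np.divide(F, total, out=out, where=total > 0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class AggregateIndex:
    """Per-sample summary of per-cell indices.

    ``sem_defined`` is False for single-cell samples, where the SEM is
    reported as 0 by convention.
    """

    mean: float
    sem: float
    n: int
    sem_defined: bool = True


def aggregate_sample(per_cell_M) -> AggregateIndex:
    """Arithmetic mean and SEM (sd / sqrt(n), sample sd) of per-cell indices."""
    m = np.asarray(per_cell_M, dtype=float)
    m = m[~np.isnan(m)]
    if m.size == 0:
        raise ValueError("aggregate_sample needs at least one defined index")
    n = m.size
    if n == 1:
        return AggregateIndex(mean=float(m[0]), sem=0.0, n=1, sem_defined=False)
    sem = float(np.std(m, ddof=1) / np.sqrt(n))
    return AggregateIndex(mean=float(m.mean()), sem=sem, n=n)


@dataclass
class IndexResult:
    """Per-cell indices for one imaged sample plus the sample summary."""

    per_cell: pd.DataFrame  # cell_id, F, G, M
    mean: float
    sem: float
    n_cells: int
    n_excluded: int
    metric: str


def index_from_dual_probe(
    cc_image: np.ndarray,
    cd_image: np.ndarray,
    cell_labels: np.ndarray,
    metric: str = "area_fraction",
    floors: tuple[float, float] = (0.0, 0.0),
) -> IndexResult:
    """Per-cell metabolic index from co-registered C#C and C-D images.

    For every cell, F is the chosen ``metric`` of the C#C (FA-uptake) image
    inside the cell and G the same metric of the C-D (glucose) image:

    * ``"area_fraction"`` — pixels above the floor / cell area (the default,
      matching how C-D signal is reported as area fraction);
    * ``"integrated"`` — summed intensity above the floor;
    * ``"mean"`` — integrated / pixels above floor (0 when none).

    Cells with F + G = 0 are excluded and counted in ``n_excluded``.
    """
    from scipy import ndimage as ndi

    cc_image = np.asarray(cc_image, dtype=float)
    cd_image = np.asarray(cd_image, dtype=float)
    cell_labels = np.asarray(cell_labels)
    if cc_image.shape != cell_labels.shape or cd_image.shape != cell_labels.shape:
        raise IncompatibilityError("probe images and cell labels differ in shape")
    if metric not in ("area_fraction", "integrated", "mean"):
        raise KeyError(f"unknown metric {metric!r}")

    n_cells = int(cell_labels.max())
    if n_cells == 0:
        raise ValueError("no cells in label image")
    ids = np.arange(1, n_cells + 1)
    area = ndi.sum_labels(np.ones_like(cell_labels, dtype=float), cell_labels, ids)

    def per_cell_metric(img: np.ndarray, floor: float) -> np.ndarray:
        sig = img > floor
        n_sig = ndi.sum_labels(sig.astype(float), cell_labels, ids)
        if metric == "area_fraction":
            return n_sig / area
        integ = ndi.sum_labels(np.where(sig, img, 0.0), cell_labels, ids)
        if metric == "integrated":
            return integ
        return np.where(n_sig > 0, integ / np.maximum(n_sig, 1), 0.0)

    F = per_cell_metric(cc_image, floors[0])
    G = per_cell_metric(cd_image, floors[1])
    M = compute_index(F, G)
    per_cell = pd.DataFrame({"cell_id": ids, "F": F, "G": G, "M": M})
    defined = per_cell[~per_cell["M"].isna()]
    n_excluded = len(per_cell) - len(defined)
    if n_excluded:
        logger.info("excluded %d cells with no probe signal", n_excluded)
    if len(defined) == 0:
        raise ValueError("no cell has probe signal above the floors")
    agg = aggregate_sample(defined["M"].to_numpy())
    return IndexResult(
        per_cell=per_cell,
        mean=agg.mean,
        sem=agg.sem,
        n_cells=agg.n,
        n_excluded=n_excluded,
        metric=metric,
    )
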