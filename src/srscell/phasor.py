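"""Spectral-phasor transform, phasor-plane clustering and probe unmixing.

Each pixel's spectrum ``I_k`` (k = 0..N-1) is embedded at its first-harmonic
Fourier coordinates normalized by total intensity:

    g = sum_k I_k cos(2 pi h k / N) / sum_k I_k
    s = sum_k I_k sin(2 pi h k / N) / sum_k I_k

Pixels with similar spectra cluster on the (g, s) plane regardless of their
absolute brightness, so clustering there and mapping clusters back to the
image plane segments an image into chemical components (nuclei vs lipid, or
the C#C and C-D probe channels) without per-channel thresholds.

For the dual-probe experiment a least-squares route is also provided:
per-pixel non-negative unmixing against reference spectra, which serves as
the cross-check of the phasor segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConditioningError, IncompatibilityError, InsufficientDataError
from .io import HyperspectralStack

__all__ = [
    "PhasorField",
    "PhasorClustering",
    "UnmixResult",
    "phasor_transform",
    "spectrum_phasor",
    "estimate_dc_floor",
    "cluster_phasor",
    "map_clusters_to_images",
    "unmix_dual_probe",
]


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates plus total (DC) intensity.

    ``valid`` marks pixels whose DC exceeds the background floor; invalid
    pixels carry (g, s) = (0, 0) by convention and are excluded from
    clustering.  For non-negative spectra every valid pixel satisfies
    ``g**2 + s**2 <= 1``.
    """

    g: np.ndarray
    s: np.ndarray
    dc: np.ndarray
    valid: np.ndarray
    harmonic: int = 1
    n_channels: int = 0


@dataclass
class PhasorClustering:
    """Pixel assignments on the phasor plane.

    ``assignments`` holds cluster ids (0 = unassigned/background); ids are
    ordered by descending total DC.  ``component_map`` names clusters
    semantically ("nuclei", "lipid", "CC", "CD", ...).
    """

    method: str
    assignments: np.ndarray
    centroids: np.ndarray | None = None
    gates: list[np.ndarray] | None = None
    component_map: dict[int, str] = field(default_factory=dict)

    def cluster_of(self, component: str) -> int:
        for cid, name in self.component_map.items():
            if name == component:
                return cid
        raise KeyError(f"no cluster mapped to component {component!r}")


def spectrum_phasor(spectrum: np.ndarray, harmonic: int = 1) -> tuple[float, float]:
    """Phasor coordinates of a single spectrum (e.g. a reference)."""
    spectrum = np.asarray(spectrum, dtype=float)
    n = spectrum.size
    if n < 2:
        raise ValueError("spectrum needs >= 2 channels")
    total = spectrum.sum()
    if total == 0:
        raise ValueError("spectrum has zero total intensity")
    k = np.arange(n)
    ang = 2.0 * np.pi * harmonic * k / n
    return float(spectrum @ np.cos(ang) / total), float(spectrum @ np.sin(ang) / total)


def estimate_dc_floor(dc: np.ndarray, corner_fraction: float = 0.1) -> float:
    """Robust background floor from the four image corners.

    floor = median(corner DC) + 5 * 1.4826 * MAD(corner DC) — five times the
    robust noise scale above the background level.  The corner regions stand
    in for a user-marked background when none is given.
    """
    h, w = dc.shape
    ch = max(2, int(corner_fraction * h))
    cw = max(2, int(corner_fraction * w))
    corners = np.concatenate(
        [
            dc[:ch, :cw].ravel(),
            dc[:ch, -cw:].ravel(),
            dc[-ch:, :cw].ravel(),
            dc[-ch:, -cw:].ravel(),
        ]
    )
    med = float(np.median(corners))
    mad = float(np.median(np.abs(corners - med)))
    return med + 5.0 * 1.4826 * mad


def phasor_transform(
    stack: HyperspectralStack,
    harmonic: int = 1,
    dc_floor: float | None = None,
) -> PhasorField:
    """Transform every pixel spectrum to (g, s) phasor coordinates.

    ``dc_floor`` defaults to :func:`estimate_dc_floor` on the DC image;
    pixels at or below the floor are flagged invalid.
    """
    n = stack.n_channels
    if n < 2:
        raise ValueError("phasor transform needs >= 2 channels")
    if not isinstance(harmonic, (int, np.integer)) or harmonic < 1:
        raise ValueError("harmonic must be a positive integer")
    data = np.asarray(stack.data, dtype=np.float64)
    dc = data.sum(axis=0)
    if dc_floor is None:
        dc_floor = estimate_dc_floor(dc)
    valid = dc > dc_floor
    k = np.arange(n)
    ang = 2.0 * np.pi * harmonic * k / n
    num_g = np.tensordot(np.cos(ang), data, axes=(0, 0))
    num_s = np.tensordot(np.sin(ang), data, axes=(0, 0))
    g = np.zeros_like(dc)
    s = np.zeros_like(dc)
    np.divide(num_g, dc, out=g, where=valid)
    np.divide(num_s, dc, out=s, where=valid)
    return PhasorField(g=g, s=s, dc=dc, valid=valid, harmonic=harmonic, n_channels=n)


def cluster_phasor(
    field: PhasorField,
    method: str = "gmm",
    k: int | None = None,
    gates: Sequence[np.ndarray] | None = None,
    seed: int = 0,
    references: Mapping[str, tuple[float, float]] | None = None,
    component_names: Sequence[str] | None = None,
    dc_weighted: bool = True,
    max_fit_points: int = 20000,
) -> PhasorClustering:
    """Cluster valid pixels on the phasor plane.

    method "kmeans" or "gmm" need ``k``; "polygon" needs ``gates`` (each a
    (m, 2) vertex array in (g, s), non-self-intersecting).  Cluster ids are
    relabelled 1..k by descending total DC; 0 stays background.  When
    ``references`` maps component names to reference (g, s) phasors, each
    cluster is named after the reference nearest its centroid; otherwise
    ``component_names`` (if given) are applied in DC order.

    GMM/KMeans fits are DC-weighted by fitting on a seeded resample of valid
    pixels drawn with probability proportional to DC, then predicting all
    valid pixels; this keeps bright, information-bearing pixels in charge of
    the cluster shapes.
    """
    pts = np.column_stack([field.g[field.valid], field.s[field.valid]])
    assignments = np.zeros(field.g.shape, dtype=np.int32)
    if method in ("kmeans", "gmm"):
        if k is None or k < 1:
            raise ValueError("parametric clustering needs k >= 1")
        if pts.shape[0] < k:
            raise InsufficientDataError(
                f"{pts.shape[0]} valid pixels < k={k} clusters"
            )
        fit_pts = pts
        if dc_weighted and pts.shape[0] > 1:
            rng = np.random.default_rng(seed)
            weights = field.dc[field.valid]
            p = weights / weights.sum()
            idx = rng.choice(pts.shape[0], size=min(pts.shape[0], max_fit_points), p=p)
            fit_pts = pts[idx]
        if method == "kmeans":
            from sklearn.cluster import KMeans

            model = KMeans(n_clusters=k, n_init=10, random_state=seed)
            model.fit(fit_pts)
            labels = model.predict(pts)
            centroids = model.cluster_centers_
        else:
            from sklearn.mixture import GaussianMixture

            model = GaussianMixture(
                n_components=k, random_state=seed, n_init=3, reg_covar=1e-9
            )
            model.fit(fit_pts)
            labels = model.predict(pts)  # max responsibility; sklearn breaks ties low
            centroids = model.means_
        assignments[field.valid] = labels + 1
    elif method == "polygon":
        if gates is None:
            raise ValueError("polygon clustering needs gates")
        from shapely.geometry import Polygon
        from shapely import contains_xy

        centroids_list = []
        labels = np.zeros(pts.shape[0], dtype=np.int32)
        for i, verts in enumerate(gates, start=1):
            poly = Polygon(np.asarray(verts, dtype=float))
            if not poly.is_valid:
                raise ValueError(f"gate {i - 1} is self-intersecting or degenerate")
            inside = contains_xy(poly, pts[:, 0], pts[:, 1])
            labels[inside & (labels == 0)] = i  # earlier gates win overlaps
            centroids_list.append(np.asarray(poly.centroid.coords[0]))
        assignments[field.valid] = labels
        centroids = np.array(centroids_list)
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    assignments, centroids = _relabel_by_dc(assignments, centroids, field.dc)
    component_map = _name_clusters(centroids, references, component_names)
    return PhasorClustering(
        method=method,
        assignments=assignments,
        centroids=centroids,
        gates=[np.asarray(g, dtype=float) for g in gates] if gates else None,
        component_map=component_map,
    )


def _relabel_by_dc(
    assignments: np.ndarray, centroids: np.ndarray, dc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stable-order cluster ids 1..k by descending total DC."""
    ids = [int(i) for i in np.unique(assignments) if i != 0]
    if not ids:
        return assignments, centroids
    totals = {i: float(dc[assignments == i].sum()) for i in ids}
    order = sorted(ids, key=lambda i: (-totals[i], i))
    out = np.zeros_like(assignments)
    new_centroids = np.zeros((len(order), 2))
    for new_id, old_id in enumerate(order, start=1):
        out[assignments == old_id] = new_id
        if centroids is not None and old_id - 1 < len(centroids):
            new_centroids[new_id - 1] = centroids[old_id - 1]
    return out, new_centroids


def _name_clusters(centroids, references, component_names) -> dict[int, str]:
    if centroids is None or len(centroids) == 0:
        return {}
    if references:
        # one-to-one greedy matching: closest (cluster, reference) pair first,
        # so component names stay unique; leftover clusters keep generic names
        mapping: dict[int, str] = {}
        pairs = [
            ((c[0] - gs[0]) ** 2 + (c[1] - gs[1]) ** 2, cid, name)
            for cid, c in enumerate(centroids, start=1)
            for name, gs in references.items()
        ]
        used_names: set[str] = set()
        for _, cid, name in sorted(pairs):
            if cid in mapping or name in used_names:
                continue
            mapping[cid] = name
            used_names.add(name)
        for cid in range(1, len(centroids) + 1):
            mapping.setdefault(cid, f"cluster_{cid}")
        return mapping
    if component_names:
        return {
            cid: name
            for cid, name in zip(range(1, len(centroids) + 1), component_names)
        }
    return {cid: f"cluster_{cid}" for cid in range(1, len(centroids) + 1)}


def map_clusters_to_images(
    clustering: PhasorClustering,
    field: PhasorField,
    names: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Map phasor clusters back to per-component intensity images.

    Each component image equals the per-pixel DC intensity where the pixel
    belongs to that component and 0 elsewhere, so the component images plus
    background partition the DC image.
    """
    if names is None:
        names = list(clustering.component_map.values())
    out: dict[str, np.ndarray] = {}
    for name in names:
        cid = clustering.cluster_of(name)  # KeyError for unknown names
        img = np.where(clustering.assignments == cid, field.dc, 0.0)
        out[name] = img
    return out


@dataclass
class UnmixResult:
    """Per-pixel non-negative abundances and the residual image (QC)."""

    abundances: dict[str, np.ndarray]
    residual: np.ndarray


def unmix_dual_probe(
    stack: HyperspectralStack,
    references: Mapping[str, np.ndarray],
    background: np.ndarray | None = None,
) -> UnmixResult:
    """Least-squares two-component unmixing with non-negativity.

    Solves, per pixel, ``min ||y - A x||, x >= 0`` where the columns of A are
    the two reference spectra (e.g. the C#C and C-D components).  With two
    components the NNLS solution is closed-form: take the unconstrained
    solution, and where a coefficient goes negative fall back to the better
    of the two single-component fits.  ``background`` (a spectrum) is
    subtracted from every pixel first.
    """
    names = list(references)
    if len(names) != 2:
        raise ValueError("unmix_dual_probe expects exactly two references")
    A = np.column_stack([np.asarray(references[n], dtype=float) for n in names])
    if A.shape[0] != stack.n_channels:
        raise IncompatibilityError(
            "reference spectra length does not match stack channels"
        )
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] <= 1e-8 * sv[0]:
        raise ConditioningError("reference spectra are (nearly) collinear")

    n_ch, h, w = stack.data.shape
    Y = np.asarray(stack.data, dtype=np.float64).reshape(n_ch, -1)
    if background is not None:
        Y = Y - np.asarray(background, dtype=float)[:, None]

    # unconstrained LS via normal equations (2x2, well conditioned by check)
    AtA = A.T @ A
    AtY = A.T @ Y
    X = np.linalg.solve(AtA, AtY)  # (2, n_pix)

    neg = (X < 0).any(axis=0)
    if neg.any():
        Yn = Y[:, neg]
        norms = (A**2).sum(axis=0)
        # best single-component fits, clipped at zero
        c0 = np.clip(A[:, 0] @ Yn / norms[0], 0.0, None)
        c1 = np.clip(A[:, 1] @ Yn / norms[1], 0.0, None)
        r0 = ((Yn - A[:, [0]] * c0) ** 2).sum(axis=0)
        r1 = ((Yn - A[:, [1]] * c1) ** 2).sum(axis=0)
        pick0 = r0 <= r1
        Xn = np.zeros((2, Yn.shape[1]))
        Xn[0, pick0] = c0[pick0]
        Xn[1, ~pick0] = c1[~pick0]
        X[:, neg] = Xn

    resid = np.sqrt(((Y - A @ X) ** 2).sum(axis=0)).reshape(h, w)
    abundances = {
        names[0]: X[0].reshape(h, w),
        names[1]: X[1].reshape(h, w),
    }
    return UnmixResult(abundances=abundances, residual=resid)
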