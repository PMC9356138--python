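"""Synthetic ground-truth generators for every pipeline stage.

This module fabricates the four kinds of data the analysis consumes, each
with known truth so recovery can be asserted:

* hyperspectral *cell phantoms* — fields of non-overlapping disc cells with
  nucleus, cytoplasm and lipid-droplet compartments, each compartment a
  linear mixture of Gaussian-peak component spectra, with a lipid-poor /
  lipid-rich class structure and shot-like noise;
* *per-cell intensity populations* — log-normal mixtures emulating the
  bimodal integrated-lipid histograms seen in single-cell SRS data;
* *dose–response tables* — 4-parameter logistic viability curves with
  replicate structure;
* *resistance cohorts* — per-sample sets of per-cell metabolic indices for
  sensitive and resistant groups.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PackingError
from .io import HyperspectralStack

__all__ = [
    "SpectralComponent",
    "PhantomSpec",
    "GroundTruth",
    "Cohort",
    "make_component_spectrum",
    "generate_cell_phantom",
    "generate_population_intensities",
    "generate_dose_response",
    "generate_cohort",
    "save_phantom",
    "ch_window_components",
    "dual_probe_components",
]


@dataclass(frozen=True)
class SpectralComponent:
    """A pure chemical component spectrum: Gaussian peaks over a baseline.

    ``peaks`` is a sequence of ``(center_cm1, width_cm1, amplitude)``.
    Gaussian lineshapes are an analytically simple stand-in adequate for
    segmentation tests; no Raman lineshape physics is claimed.
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        for center, width, amplitude in self.peaks:
            if width <= 0:
                raise ValueError(f"{self.name}: peak width must be > 0, got {width}")
            if amplitude < 0:
                raise ValueError(f"{self.name}: amplitude must be >= 0")
        if self.baseline < 0:
            raise ValueError(f"{self.name}: baseline must be >= 0")


def make_component_spectrum(
    component: SpectralComponent, axis: np.ndarray
) -> np.ndarray:
    """Evaluate a component on a strictly increasing wavenumber axis.

    value(nu) = baseline + sum_peaks amplitude * exp(-(nu - center)^2 / (2 width^2))
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 1 or (axis.size > 1 and not np.all(np.diff(axis) > 0)):
        raise ValueError("wavenumber axis must be 1-D and strictly increasing")
    spectrum = np.full(axis.shape, float(component.baseline))
    for center, width, amplitude in component.peaks:
        spectrum += amplitude * np.exp(-((axis - center) ** 2) / (2.0 * width**2))
    return spectrum


def ch_window_components() -> tuple[SpectralComponent, SpectralComponent]:
    """Default C-H window (2800-3050 cm^-1) components.

    Protein/nucleic-acid CH3 stretch near 2930 dominates nuclei and
    cytoplasm; lipid CH2 stretch near 2850 dominates droplets.
    """
    protein = SpectralComponent("CH_protein", ((2930.0, 35.0, 1.0),))
    lipid = SpectralComponent("CH_lipid", ((2850.0, 25.0, 1.0),))
    return protein, lipid


def dual_probe_components() -> tuple[SpectralComponent, SpectralComponent]:
    """Default cell-silent window components for the two-probe experiment.

    The alkyne C#C stretch of ODYA is a sharp peak near 2100 cm^-1; the C-D
    band from deuterated-glucose-derived macromolecules is broad and centred
    near 2150 cm^-1.
    """
    cc = SpectralComponent("CC_odya", ((2100.0, 15.0, 1.0),))
    cd = SpectralComponent("CD_glucose", ((2150.0, 45.0, 1.0),))
    return cc, cd


def _default_abundances() -> dict[str, dict[str, float]]:
    return {
        "nucleus": {"CH_protein": 1.0},
        "cytoplasm": {"CH_protein": 0.35, "CH_lipid": 0.05},
        "droplet": {"CH_lipid": 1.0},
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, chemistry and noise of a hyperspectral cell phantom.

    Defaults emulate the acquisition this pipeline targets: ~50 spectral
    channels over the C-H window, fields of tens to hundreds of cells, and
    a lipid-poor/lipid-rich split where rich cells carry 10x the droplet
    component (the class contrast that renders integrated-lipid histograms
    bimodal).
    """

    image_shape: tuple[int, int] = (256, 256)
    n_channels: int = 50
    wavenumber_range: tuple[float, float] = (2800.0, 3050.0)
    n_cells: int = 30
    cell_radius_range: tuple[float, float] = (12.0, 18.0)
    nucleus_radius_fraction: float = 0.45
    droplets_per_cell: tuple[int, int] = (3, 6)
    droplet_radius_range: tuple[float, float] = (2.0, 3.5)
    components: tuple[SpectralComponent, ...] = field(
        default_factory=ch_window_components
    )
    component_abundances: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_abundances
    )
    population_mixture: tuple[float, float] = (0.5, 0.5)  # (lipid-poor, lipid-rich)
    class_droplet_scale: tuple[float, float] = (1.0, 10.0)
    noise: tuple[float, float] = (0.05, 0.02)  # (shot_scale, gaussian_sd)
    pixel_size: float = 0.5  # um / pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0.0 < self.nucleus_radius_fraction < 1.0:
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")
        if abs(sum(self.population_mixture) - 1.0) > 1e-9:
            raise ValueError("population_mixture fractions must sum to 1")
        if self.noise[0] < 0 or self.noise[1] < 0:
            raise ValueError("noise levels must be >= 0")
        if self.droplets_per_cell[0] < 0 or self.droplets_per_cell[1] < self.droplets_per_cell[0]:
            raise ValueError("droplets_per_cell must be a non-negative (lo, hi) range")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(*self.wavenumber_range, self.n_channels)


@dataclass
class GroundTruth:
    """Label maps and per-cell truth table for a rendered phantom.

    ``cell_truth`` columns: cell_id, cell_class ("lipid-poor"/"lipid-rich"),
    droplet_count, droplet_area_px, integrated_droplet_signal (noise-free DC
    summed over droplet pixels), droplet_scale, plus true droplet component
    abundances as ``abundance_<component>``.
    """

    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    droplet_labels: np.ndarray
    droplet_to_cell: dict[int, int]
    cell_truth: pd.DataFrame


def generate_cell_phantom(spec: PhantomSpec) -> tuple[HyperspectralStack, GroundTruth]:
    """Render a hyperspectral phantom and its ground truth.

    Cells are non-overlapping discs; each nucleus is a concentric disc and
    droplets are small discs confined to the cytoplasmic annulus.  Droplet
    abundances are scaled per cell class before noise is applied, so the
    truth table's integrated droplet signal refers to the noise-free image.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    rows, cols = np.mgrid[0:h, 0:w]

    centers, radii = _place_cells(spec, rng)
    n_cells = len(centers)
    classes = rng.choice(2, size=n_cells, p=list(spec.population_mixture))

    nuclei = np.zeros((h, w), dtype=np.int32)
    cells = np.zeros((h, w), dtype=np.int32)
    droplets = np.zeros((h, w), dtype=np.int32)
    droplet_to_cell: dict[int, int] = {}
    droplet_id = 0

    spectra = {
        c.name: make_component_spectrum(c, spec.wavenumbers) for c in spec.components
    }
    comp_names = list(spectra)
    # per-component abundance maps
    weight_maps = {name: np.zeros((h, w), dtype=np.float64) for name in comp_names}

    records = []
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        dist2 = (rows - cy) ** 2 + (cols - cx) ** 2
        cell_mask = dist2 <= r**2
        r_nuc = spec.nucleus_radius_fraction * r
        nuc_mask = dist2 <= r_nuc**2
        cells[cell_mask] = i
        nuclei[nuc_mask] = i

        scale = spec.class_droplet_scale[classes[i - 1]]
        n_drop = int(rng.integers(spec.droplets_per_cell[0], spec.droplets_per_cell[1] + 1))
        drop_mask_cell = np.zeros((h, w), dtype=bool)
        placed = 0
        for _ in range(200):
            if placed >= n_drop:
                break
            rd = rng.uniform(*spec.droplet_radius_range)
            lo, hi = r_nuc + rd + 1.0, r - rd - 1.0
            if hi <= lo:
                continue
            rad = rng.uniform(lo, hi)
            ang = rng.uniform(0, 2 * np.pi)
            dy, dx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            d2 = (rows - dy) ** 2 + (cols - dx) ** 2
            m = d2 <= rd**2
            if not m.any() or (droplets[m] != 0).any() or drop_mask_cell[m].any():
                continue
            droplet_id += 1
            droplets[m] = droplet_id
            drop_mask_cell |= m
            droplet_to_cell[droplet_id] = i
            placed += 1

        cyto_mask = cell_mask & ~nuc_mask & ~drop_mask_cell
        nuc_only = nuc_mask & ~drop_mask_cell
        for compartment, mask in (
            ("nucleus", nuc_only),
            ("cytoplasm", cyto_mask),
            ("droplet", drop_mask_cell),
        ):
            weights = spec.component_abundances.get(compartment, {})
            mult = scale if compartment == "droplet" else 1.0
            for name, wgt in weights.items():
                weight_maps[name][mask] += wgt * mult

        drop_weights = {
            name: spec.component_abundances.get("droplet", {}).get(name, 0.0) * scale
            for name in comp_names
        }
        drop_dc = sum(
            drop_weights[name] * spectra[name].sum() for name in comp_names
        ) * int(drop_mask_cell.sum())
        rec = {
            "cell_id": i,
            "cell_class": "lipid-rich" if classes[i - 1] == 1 else "lipid-poor",
            "droplet_count": placed,
            "droplet_area_px": int(drop_mask_cell.sum()),
            "integrated_droplet_signal": float(drop_dc),
            "droplet_scale": float(scale),
        }
        for name in comp_names:
            rec[f"abundance_{name}"] = drop_weights[name]
        records.append(rec)

    stack = np.zeros((spec.n_channels, h, w), dtype=np.float64)
    for name in comp_names:
        stack += spectra[name][:, None, None] * weight_maps[name][None, :, :]

    shot_scale, gaussian_sd = spec.noise
    if shot_scale > 0:
        stack = stack + rng.standard_normal(stack.shape) * (
            shot_scale * np.sqrt(np.clip(stack, 0, None))
        )
    if gaussian_sd > 0:
        stack = stack + rng.standard_normal(stack.shape) * gaussian_sd
    np.clip(stack, 0, None, out=stack)

    truth = GroundTruth(
        nuclei_labels=nuclei,
        cell_labels=cells,
        droplet_labels=droplets,
        droplet_to_cell=droplet_to_cell,
        cell_truth=pd.DataFrame.from_records(records)
        if records
        else pd.DataFrame(
            columns=[
                "cell_id",
                "cell_class",
                "droplet_count",
                "droplet_area_px",
                "integrated_droplet_signal",
                "droplet_scale",
            ]
        ),
    )
    hs = HyperspectralStack(
        data=stack,
        wavenumbers=spec.wavenumbers,
        pixel_size=spec.pixel_size,
        metadata={"seed": spec.seed, "phantom": True},
    )
    return hs, truth


def _place_cells(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[list[tuple[float, float]], list[float]]:
    """Rejection-sample non-overlapping disc centres; bounded retries."""
    h, w = spec.image_shape
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_tries = 400 * max(spec.n_cells, 1)
    tries = 0
    while len(centers) < spec.n_cells:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {spec.n_cells} cells of radius "
                f"{spec.cell_radius_range} in a {spec.image_shape} image "
                f"after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(*spec.cell_radius_range)
        if 2 * r + 2 > min(h, w):
            raise PackingError(
                f"cell_radius_range {spec.cell_radius_range} does not fit in "
                f"image_shape {spec.image_shape}"
            )
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if all(
            (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + 1.0) ** 2
            for (oy, ox), orad in zip(centers, radii)
        ):
            centers.append((cy, cx))
            radii.append(r)
    return centers, radii


def generate_population_intensities(
    weights: Sequence[float],
    log_means: Sequence[float],
    log_sd: float,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cell intensities from a log-normal mixture.

    Returns ``(values, labels)`` where ``labels[i]`` is the mixture component
    each cell was drawn from — the recovery oracle for subpopulation
    classification tests.
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {weights.sum()})")
    if len(weights) != len(log_means):
        raise ValueError("weights and log_means must have equal length")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0), np.empty(0, dtype=int)
    if n < 0:
        raise ValueError("n must be >= 0")
    labels = rng.choice(len(weights), size=n, p=weights)
    values = np.exp(rng.normal(np.asarray(log_means, dtype=float)[labels], log_sd))
    return values, labels


def generate_dose_response(
    ic50: float,
    hill: float,
    top: float,
    bottom: float,
    doses: Sequence[float],
    noise_sd: float = 0.0,
    replicates: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a 4-parameter-logistic viability table.

    viability = bottom + (top - bottom) / (1 + (dose / ic50)^hill) + noise

    Six replicates per dose is the default, matching standard 96-well
    viability assay design.  Returns columns ``dose_uM, viability_pct,
    replicate``.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    if top <= bottom:
        raise ValueError("top must exceed bottom")
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        clean = bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)
        for rep in range(replicates):
            v = clean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"dose_uM": dose, "viability_pct": v, "replicate": rep})
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """Per-cell index draws plus per-sample summaries with resistance labels.

    ``cells`` columns: sample_id, label, cell_index.
    ``samples`` columns: sample_id, label, mean_index, sem, n_cells.
    """

    cells: pd.DataFrame
    samples: pd.DataFrame


def generate_cohort(
    n_sensitive: int,
    n_resistant: int,
    mean_s: float,
    mean_r: float,
    sd: float,
    cells_per_sample: int = 30,
    seed: int = 0,
) -> Cohort:
    """Simulate a sensitive/resistant cohort of per-sample metabolic indices.

    Per-cell indices are normal draws truncated to [0, 1] by resampling
    (the index's domain).  Each sample reports the mean of its cells and the
    SEM, mirroring per-patient averaging of single-cell indices.
    """
    for m in (mean_s, mean_r):
        if not 0.0 < m < 1.0:
            raise ValueError(f"group means must lie in (0, 1), got {m}")
    if n_sensitive < 1 or n_resistant < 1 or cells_per_sample < 1:
        raise ValueError("counts must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    cell_rows = []
    sample_rows = []
    groups = [("sensitive", "S", n_sensitive, mean_s), ("resistant", "R", n_resistant, mean_r)]
    for label, prefix, count, mean in groups:
        for j in range(1, count + 1):
            sid = f"{prefix}{j}"
            vals = _truncated_normal(rng, mean, sd, cells_per_sample)
            for v in vals:
                cell_rows.append({"sample_id": sid, "label": label, "cell_index": v})
            n = len(vals)
            sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            sample_rows.append(
                {
                    "sample_id": sid,
                    "label": label,
                    "mean_index": float(np.mean(vals)),
                    "sem": sem,
                    "n_cells": n,
                }
            )
    return Cohort(cells=pd.DataFrame(cell_rows), samples=pd.DataFrame(sample_rows))


def save_phantom(
    stack: HyperspectralStack, truth: GroundTruth, out_dir
) -> dict[str, str]:
    """Write a phantom to disk: multi-page TIFF + sidecar, 16-bit label maps,
    truth tables as CSV.  Returns the paths written, keyed by artifact."""
    import tifffile
    from pathlib import Path

    from .io import write_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    tif, sidecar = write_stack(stack, out / "stack.tif")
    paths["stack"], paths["sidecar"] = str(tif), str(sidecar)
    for name, labels in (
        ("nuclei_labels", truth.nuclei_labels),
        ("cell_labels", truth.cell_labels),
        ("droplet_labels", truth.droplet_labels),
    ):
        p = out / f"{name}.tif"
        tifffile.imwrite(p, labels.astype(np.uint16), photometric="minisblack")
        paths[name] = str(p)
    truth_csv = out / "cell_truth.csv"
    truth.cell_truth.to_csv(truth_csv, index=False)
    paths["cell_truth"] = str(truth_csv)
    mapping_csv = out / "droplet_to_cell.csv"
    pd.DataFrame(
        [{"droplet_id": d, "cell_id": c} for d, c in truth.droplet_to_cell.items()]
    ).to_csv(mapping_csv, index=False)
    paths["droplet_to_cell"] = str(mapping_csv)
    return paths


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[(draw >= 0.0) & (draw <= 1.0)][: n - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out
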