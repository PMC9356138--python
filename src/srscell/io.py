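"""Hyperspectral stack I/O and large-area montage assembly.

A hyperspectral SRS acquisition is stored as a multi-page TIFF (one page per
Raman shift) plus a JSON sidecar carrying the wavenumber calibration, pixel
size and free-form metadata (schema ``srsmi-stack/1``).  Large fields of view
are acquired as a grid of overlapping tiles driven by stage positions and
stitched into a single stack.

Conventions: arrays are ``(channel, row, col)``, row-major, 0-based, origin
top-left.  Non-integer overlap widths are floored so output sizes are
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import CalibrationError, IncompatibilityError

SIDECAR_FORMAT = "srsmi-stack/1"

__all__ = [
    "HyperspectralStack",
    "MontageLayout",
    "read_stack",
    "write_stack",
    "stitch_montage",
    "sidecar_path_for",
]


@dataclass
class HyperspectralStack:
    """A calibrated 3-D intensity cube ``(channel, row, col)``.

    Parameters
    ----------
    data
        Non-negative intensities, arbitrary units.
    wavenumbers
        One Raman shift (cm^-1) per channel, strictly monotonic.
    pixel_size
        Lateral pixel size in micrometres.
    metadata
        Free-form key/value pairs carried through I/O.
    """

    data: np.ndarray
    wavenumbers: np.ndarray
    pixel_size: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (channel, row, col)")
        if self.wavenumbers.ndim != 1 or len(self.wavenumbers) != self.data.shape[0]:
            raise CalibrationError(
                f"wavenumber axis length {self.wavenumbers.size} does not match "
                f"{self.data.shape[0]} channels"
            )
        diffs = np.diff(self.wavenumbers)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise CalibrationError("wavenumber axis must be strictly monotonic")
        if self.data.shape[1] < 1 or self.data.shape[2] < 1:
            raise ValueError("spatial dimensions must be >= 1")
        if np.isnan(self.data).any():
            raise ValueError("stack contains NaN; sanitize on load (see read_stack)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def dc(self) -> np.ndarray:
        """Total (channel-summed) intensity image."""
        return self.data.sum(axis=0)


@dataclass(frozen=True)
class MontageLayout:
    """Tile arrangement for a large-area acquisition.

    ``grid`` is ``(tiles_y, tiles_x)``; tiles are supplied in row-major scan
    order.  ``overlap_fraction`` is the fraction of each tile shared with its
    neighbour along both axes.  ``blend`` is ``"feather"`` (linear ramp across
    the overlap) or ``"first"`` (first tile wins, exact).
    """

    grid: tuple[int, int]
    tile_shape: tuple[int, int]
    overlap_fraction: float = 0.0
    blend: str = "feather"

    def __post_init__(self) -> None:
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValueError("grid counts must be >= 1")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.blend not in ("feather", "first"):
            raise ValueError(f"unknown blend policy {self.blend!r}")

    @property
    def overlap_px(self) -> tuple[int, int]:
        # floored: deterministic integer geometry
        return (
            int(np.floor(self.overlap_fraction * self.tile_shape[0])),
            int(np.floor(self.overlap_fraction * self.tile_shape[1])),
        )


def sidecar_path_for(path: str | Path) -> Path:
    """Default JSON sidecar location for a TIFF path (same stem, ``.json``)."""
    return Path(path).with_suffix(".json")


def write_stack(stack: HyperspectralStack, path: str | Path) -> tuple[Path, Path]:
    """Write a stack as multi-page float32 TIFF plus JSON sidecar.

    Returns the (tiff_path, sidecar_path) written.  Round-trips are lossless
    for 32-bit data.
    """
    path = Path(path)
    tifffile.imwrite(
        path,
        np.ascontiguousarray(stack.data, dtype=np.float32),
        photometric="minisblack",  # pages are spectral channels, never RGB
    )
    sidecar = sidecar_path_for(path)
    payload = {
        "format": SIDECAR_FORMAT,
        "wavenumbers": [float(w) for w in stack.wavenumbers],
        "pixel_size_um": float(stack.pixel_size),
        "metadata": _jsonable(stack.metadata),
    }
    sidecar.write_text(json.dumps(payload))
    return path, sidecar


def read_stack(path: str | Path, sidecar_path: str | Path | None = None) -> HyperspectralStack:
    """Read a multi-page TIFF stack with its wavenumber calibration sidecar.

    Raises :class:`CalibrationError` when the sidecar is missing or its
    wavenumber count disagrees with the TIFF page count — the reader never
    guesses a calibration.  NaN pixels are replaced by 0 and counted in
    ``metadata["nan_pixels"]``.
    """
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path is not None else sidecar_path_for(path)
    if not sidecar.exists():
        raise CalibrationError(f"no calibration sidecar at {sidecar}")
    payload = json.loads(sidecar.read_text())
    wavenumbers = np.asarray(payload["wavenumbers"], dtype=float)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.shape[0] != len(wavenumbers):
        raise CalibrationError(
            f"TIFF has {data.shape[0]} pages but sidecar lists "
            f"{len(wavenumbers)} wavenumbers"
        )
    metadata = dict(payload.get("metadata", {}))
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        data = np.nan_to_num(data, nan=0.0)
        metadata["nan_pixels"] = n_nan
    return HyperspectralStack(
        data=data,
        wavenumbers=wavenumbers,
        pixel_size=float(payload.get("pixel_size_um", 1.0)),
        metadata=metadata,
    )


def stitch_montage(
    tiles: Sequence[HyperspectralStack],
    layout: MontageLayout,
    refine: bool = False,
) -> HyperspectralStack:
    """Assemble row-major tiles into one stack using stage-position offsets.

    Output spatial size per axis is ``tile - overlap_px`` steps:
    ``tile + (n_tiles - 1) * (tile - overlap_px)``.  Overlap regions are
    blended per ``layout.blend``.  With ``refine=True`` the nominal offsets
    are corrected by cross-correlating channel-summed overlap strips against
    the already-composited canvas (stage positions are normally trusted, so
    refinement defaults off).
    """
    ty, tx = layout.grid
    if len(tiles) != ty * tx:
        raise IncompatibilityError(f"expected {ty * tx} tiles, got {len(tiles)}")
    ref = tiles[0]
    for t in tiles[1:]:
        if t.data.shape != ref.data.shape:
            raise IncompatibilityError("all tiles must share the same shape")
        if not np.allclose(t.wavenumbers, ref.wavenumbers):
            raise IncompatibilityError("all tiles must share the wavenumber axis")
    th, tw = ref.spatial_shape
    if (th, tw) != tuple(layout.tile_shape):
        raise IncompatibilityError(
            f"tiles are {(th, tw)} but layout.tile_shape is {layout.tile_shape}"
        )
    ov_y, ov_x = layout.overlap_px
    step_y, step_x = th - ov_y, tw - ov_x
    offsets = [(iy * step_y, ix * step_x) for iy in range(ty) for ix in range(tx)]
    if refine:
        offsets = _refine_offsets(tiles, offsets, (ty, tx), (th, tw), (ov_y, ov_x))
    out_h = max(oy for oy, _ in offsets) + th
    out_w = max(ox for _, ox in offsets) + tw
    n_ch = ref.n_channels

    if layout.blend == "first":
        out = np.zeros((n_ch, out_h, out_w), dtype=np.float64)
        filled = np.zeros((out_h, out_w), dtype=bool)
        for tile, (oy, ox) in zip(tiles, offsets):
            region = ~filled[oy : oy + th, ox : ox + tw]
            out[:, oy : oy + th, ox : ox + tw][:, region] = tile.data[:, region]
            filled[oy : oy + th, ox : ox + tw] |= True
    else:
        acc = np.zeros((n_ch, out_h, out_w), dtype=np.float64)
        wacc = np.zeros((out_h, out_w), dtype=np.float64)
        w2d = np.outer(_feather_profile(th, ov_y), _feather_profile(tw, ov_x))
        for tile, (oy, ox) in zip(tiles, offsets):
            acc[:, oy : oy + th, ox : ox + tw] += tile.data * w2d
            wacc[oy : oy + th, ox : ox + tw] += w2d
        out = acc / np.where(wacc > 0, wacc, 1.0)

    return HyperspectralStack(
        data=out.astype(ref.data.dtype, copy=False),
        wavenumbers=ref.wavenumbers.copy(),
        pixel_size=ref.pixel_size,
        metadata={"montage_grid": [ty, tx], "overlap_px": [ov_y, ov_x]},
    )


def _feather_profile(length: int, overlap: int) -> np.ndarray:
    """1-D blend weight: linear ramp over the overlap width at both ends.

    Weights never reach zero so normalized accumulation reproduces a lone
    tile exactly, including at the canvas border.
    """
    w = np.ones(length, dtype=np.float64)
    if overlap > 0:
        ramp = np.arange(1, overlap + 1, dtype=np.float64) / (overlap + 1)
        w[:overlap] = ramp
        w[-overlap:] = ramp[::-1]
    return w


def _refine_offsets(tiles, offsets, grid, tile_shape, overlap_px):
    from skimage.registration import phase_cross_correlation

    ty, tx = grid
    th, tw = tile_shape
    ov_y, ov_x = overlap_px
    refined = list(offsets)
    dcs = [t.dc() for t in tiles]
    for iy in range(ty):
        for ix in range(tx):
            i = iy * tx + ix
            if ix > 0 and ov_x > 1:
                # left-neighbour overlap strips
                left = dcs[i - 1][:, tw - ov_x :]
                here = dcs[i][:, :ov_x]
                shift, _, _ = phase_cross_correlation(left, here, normalization=None)
                dy, dx = int(round(shift[0])), int(round(shift[1]))
                oy, ox = refined[i]
                refined[i] = (max(0, oy + dy), max(0, ox + dx))
            elif iy > 0 and ov_y > 1:
                up = dcs[i - tx][th - ov_y :, :]
                here = dcs[i][:ov_y, :]
                shift, _, _ = phase_cross_correlation(up, here, normalization=None)
                dy, dx = int(round(shift[0])), int(round(shift[1]))
                oy, ox = refined[i]
                refined[i] = (max(0, oy + dy), max(0, ox + dx))
    return refined


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
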