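"""Image stack I/O and preprocessing.

Covers the standard steps applied before any index is computed:
flat-field/dark-field illumination correction, summed z-projections,
central-slice window selection around a focus plane, and median background
subtraction outside a cell mask.

Axis convention (shared package-wide): arrays are ordered ``(z, y, x)``;
ventral is increasing ``y``, anterior is decreasing ``x``.  All coordinates
are 0-based voxel indices and all ranges are half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from vulquant.errors import CalibrationError, FormatError, VulquantError

log = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "Projection",
    "read_stack",
    "write_stack",
    "correct_illumination",
    "sum_projection",
    "central_slices",
    "subtract_background",
]


@dataclass
class ImageStack:
    """One channel's 3-D intensity volume with physical calibration.

    Parameters
    ----------
    voxels
        3-D array ordered ``(z, y, x)``; intensities must be finite and
        non-negative.
    voxel_size
        Physical voxel extent ``(z, y, x)`` in micrometres; strictly
        positive on every axis.
    channel_label
        Free-text channel name, e.g. ``"mNGr::LIN-3"`` or ``"mCherry::H2B"``.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VulquantError(
                f"stack must be 3-D (z, y, x); got ndim={self.voxels.ndim}"
            )
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise CalibrationError(
                f"voxel_size must be three strictly positive extents (µm); "
                f"got {self.voxel_size!r}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise VulquantError("stack contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class Projection:
    """A 2-D (y, x) projection of a stack, with provenance.

    ``provenance`` records the source stack identity and the half-open
    z-range that was projected, plus any processing steps applied since.
    """

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise VulquantError(
                f"projection must be 2-D (y, x); got ndim={self.pixels.ndim}"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF plus a JSON sidecar.

    The sidecar (``<path>.json``) carries the voxel size and channel label;
    integer data round-trips bit-identically through :func:`read_stack`.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.voxels)
    meta = {
        "voxel_size_um": list(stack.voxel_size),
        "channel_label": stack.channel_label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel_label: str | None = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Calibration is taken from the JSON sidecar written by
    :func:`write_stack` if present, otherwise from ``voxel_size``.

    Raises
    ------
    FormatError
        If any page is RGB/multi-sample or the pages disagree in shape.
    CalibrationError
        If no voxel size is available from sidecar or argument.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        shapes = {p.shape for p in pages}
        for p in pages:
            if p.samplesperpixel != 1 or len(p.shape) != 2:
                raise FormatError(
                    f"{path}: unsupported format — expected single-sample "
                    f"grayscale pages, got shape {p.shape} with "
                    f"{p.samplesperpixel} samples/pixel"
                )
        if len(shapes) != 1:
            raise FormatError(
                f"{path}: pages have mismatched shapes {sorted(shapes)}"
            )
        data = tif.asarray()
    if data.ndim == 2:  # single-slice TIFF -> z-extent 1
        data = data[np.newaxis]

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size = tuple(meta["voxel_size_um"])  # type: ignore[assignment]
        if channel_label is None:
            channel_label = meta.get("channel_label", "")
    if voxel_size is None:
        raise CalibrationError(
            f"{path}: no calibration found. Supply voxel_size=(z, y, x) in "
            f"µm, or provide a sidecar file {sidecar.name} with key "
            f"'voxel_size_um'."
        )
    return ImageStack(data, tuple(voxel_size), channel_label or "")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def correct_illumination(
    stack: ImageStack, flatfield: Projection, darkfield: Projection
) -> ImageStack:
    """Flat-field / dark-field correction of every slice.

    Each slice becomes ``(raw - dark) / (flat - dark) * mean(flat - dark)``,
    clamped at zero, so a spatially uniform specimen maps to a spatially
    uniform image while the global intensity scale is preserved.
    """
    flat = np.asarray(flatfield.pixels, dtype=float)
    dark = np.asarray(darkfield.pixels, dtype=float)
    if flat.shape != stack.voxels.shape[1:] or dark.shape != flat.shape:
        raise VulquantError(
            f"calibration image shape {flat.shape}/{dark.shape} does not "
            f"match slice shape {stack.voxels.shape[1:]}"
        )
    gain = flat - dark
    n_bad = int(np.count_nonzero(gain <= 0))
    if n_bad:
        raise VulquantError(
            f"flat - dark is non-positive at {n_bad} pixel(s); "
            "check the calibration images"
        )
    corrected = (stack.voxels.astype(float) - dark) / gain * gain.mean()
    corrected = np.clip(corrected, 0.0, None)
    return ImageStack(corrected, stack.voxel_size, stack.channel_label)


def sum_projection(stack: ImageStack, z_range: tuple[int, int] | None = None) -> Projection:
    """Pixelwise sum over the half-open slice range ``z_range``.

    ``z_range=None`` projects the full stack.  The sum of the projection
    equals the sum of the projected slab exactly (linearity of the sum).
    """
    if z_range is None:
        z_range = (0, stack.n_slices)
    z0, z1 = z_range
    if not (0 <= z0 < z1 <= stack.n_slices):
        raise VulquantError(
            f"empty or out-of-bounds z-range [{z0}, {z1}) for a stack of "
            f"{stack.n_slices} slices"
        )
    pixels = stack.voxels[z0:z1].astype(float).sum(axis=0)
    return Projection(
        pixels,
        provenance={
            "channel": stack.channel_label,
            "z_range": [int(z0), int(z1)],
            "operation": "sum_projection",
        },
    )


def central_slices(stack: ImageStack, focus_z: int, k: int = 5) -> tuple[int, int]:
    """The ``k``-slice half-open window centred on ``focus_z``.

    Used to project the central slices around the focus of the nuclear
    H2B signal before ratiometric measurement.  The window is truncated at
    the stack boundaries (a warning is logged); for even ``k`` the extra
    slice lies below the focus.
    """
    if k < 1:
        raise VulquantError(f"window size k must be >= 1, got {k}")
    if not 0 <= focus_z < stack.n_slices:
        raise VulquantError(
            f"focus_z={focus_z} outside stack of {stack.n_slices} slices"
        )
    lo = focus_z - k // 2
    hi = lo + k
    clipped_lo, clipped_hi = max(lo, 0), min(hi, stack.n_slices)
    if (clipped_lo, clipped_hi) != (lo, hi):
        log.warning(
            "central_slices window [%d, %d) truncated to [%d, %d) at stack "
            "boundary", lo, hi, clipped_lo, clipped_hi,
        )
    return clipped_lo, clipped_hi


def subtract_background(projection: Projection, mask: np.ndarray) -> Projection:
    """Subtract the median intensity outside ``mask``; clamp at zero.

    The median is robust to the bright tail contributed by the cell itself
    when the mask underestimates its true footprint.  Idempotent on its own
    output for a strictly positive background.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != projection.pixels.shape:
        raise VulquantError(
            f"mask shape {mask.shape} does not match projection "
            f"{projection.pixels.shape}"
        )
    if mask.all() or not mask.any():
        raise VulquantError(
            "background mask must be non-empty and not cover the whole image"
        )
    background = float(np.median(projection.pixels[~mask]))
    pixels = np.clip(projection.pixels.astype(float) - background, 0.0, None)
    provenance = dict(projection.provenance)
    provenance["background_subtracted"] = background
    provenance["background_estimator"] = "median outside mask, after projection"
    return Projection(pixels, provenance)
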