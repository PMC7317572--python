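"""Volume I/O, intensity standardization and cropping.

Volumes are scalar grids indexed ``(z, y, x)`` with ``z`` increasing
upward (toward the panicle apex) and a physical voxel edge length in µm.
CT scanners print intensities on arbitrary, scan-dependent scales;
:func:`standardize_intensity` maps every scan onto a common scale where
the air (background) mode sits at 0 and a reference anchor — the mode of
a marker material imaged alongside every sample, or, without a marker,
the 99.5th intensity percentile — sits at 1000.  All downstream
segmentation thresholds are expressed on this standardized scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import CropError, DimensionError, FormatError, StandardizationError

#: Standardized intensity of the reference anchor (air mode maps to 0).
ANCHOR_VALUE = 1000.0

#: Percentile substituting for the marker mode when no marker box is given.
FALLBACK_PERCENTILE = 99.5


@dataclass
class VoxelVolume:
    """A 3D scalar intensity grid with physical voxel size.

    Parameters
    ----------
    intensities
        3D array indexed ``(z, y, x)``; ``z`` increases upward.
    voxel_edge
        Edge length of the cubic voxel, in µm.
    name
        Sample identifier.
    """

    intensities: np.ndarray
    voxel_edge: float
    name: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise DimensionError(
                f"expected a 3D grid, got shape {self.intensities.shape}"
            )
        if not self.voxel_edge > 0:
            raise ValueError(f"voxel_edge must be positive, got {self.voxel_edge}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_mm(self) -> float:
        """Voxel edge in mm."""
        return self.voxel_edge / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_mm**3


_TIFF_SUFFIXES = {".tif", ".tiff"}
_ITK_SUFFIXES = {".nrrd", ".mha", ".mhd"}


def read_volume(path: str | os.PathLike, voxel_edge: float | None = None,
                name: str | None = None) -> VoxelVolume:
    """Read a volume from a TIFF slice directory, multipage TIFF, NRRD or MetaImage.

    ``voxel_edge`` (µm) overrides any spacing embedded in the file; for
    TIFF input, where no physical spacing is stored, it is required.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    if path.is_dir():
        arr = _read_slice_directory(path)
        if voxel_edge is None:
            raise FormatError("TIFF slice stacks carry no spacing; pass voxel_edge")
        return VoxelVolume(arr, voxel_edge, name)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        import tifffile

        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - wrap any reader failure
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise DimensionError(f"TIFF {path} has shape {arr.shape}, expected 3D")
        if voxel_edge is None:
            raise FormatError("TIFF files carry no spacing; pass voxel_edge")
        return VoxelVolume(arr, voxel_edge, name)
    if suffix in _ITK_SUFFIXES:
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot read {path}: {exc}") from exc
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        if arr.ndim != 3:
            raise DimensionError(f"{path} has shape {arr.shape}, expected 3D")
        if voxel_edge is None:
            # ITK spacing is stored in mm
            voxel_edge = float(img.GetSpacing()[0]) * 1000.0
        return VoxelVolume(arr, voxel_edge, name)
    raise FormatError(f"unsupported volume format: {path}")


def _read_slice_directory(path: Path) -> np.ndarray:
    import tifffile

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES
    )
    if not files:
        raise FormatError(f"no TIFF slices found in {path}")
    slices = []
    for f in files:
        sl = tifffile.imread(f)
        if sl.ndim != 2:
            raise DimensionError(f"slice {f} has shape {sl.shape}, expected 2D")
        if slices and sl.shape != slices[0].shape:
            raise DimensionError(
                f"slice {f} shape {sl.shape} differs from first slice {slices[0].shape}"
            )
        slices.append(sl)
    return np.stack(slices)


def write_volume(vol: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a volume to NRRD/MetaImage (with spacing) or multipage TIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _ITK_SUFFIXES:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.intensities)
        mm = vol.voxel_mm
        img.SetSpacing((mm, mm, mm))
        sitk.WriteImage(img, str(path))
    elif suffix in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, vol.intensities)
    else:
        raise FormatError(f"unsupported output format: {path}")


def _histogram_mode(values: np.ndarray, below: float | None = None,
                    bins: int = 512) -> float:
    """Modal value estimated from a histogram peak, refined to the bin median.

    ``below`` restricts the search to bins whose center is below that
    value (used to find the air peak below the overall median).  The bin
    grid spans [min, max] of ``values`` so the estimate is equivariant
    under affine transforms of the input.
    """
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        return vmin  # constant region: it is its own mode
    counts, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if below is not None:
        eligible = centers < below
        if not eligible.any():
            raise StandardizationError("no histogram mass below the requested bound")
        counts = np.where(eligible, counts, -1)
    peak = int(np.argmax(counts))
    lo, hi = edges[peak], edges[peak + 1]
    in_bin = values[(values >= lo) & (values <= hi)]
    if in_bin.size == 0:
        return float(centers[peak])
    return float(np.median(in_bin))


def standardize_intensity(
    vol: VoxelVolume,
    marker_box: tuple[int, int, int, int, int, int] | None = None,
) -> VoxelVolume:
    """Map intensities affinely so that air mode → 0 and the anchor → 1000.

    The air mode is the largest histogram peak below the overall median
    (air dominates the scan volume).  The anchor is the modal intensity
    inside ``marker_box`` (``(z0, z1, y0, y1, x0, x1)``, half-open) when
    a reference marker was scanned, otherwise the 99.5th percentile of
    the whole volume.  The map is monotone and idempotent, and the
    result is invariant under affine transforms of the raw intensities.
    """
    data = vol.intensities.astype(np.float64)
    flat = data.ravel()
    air = _histogram_mode(flat, below=float(np.median(flat)))
    if marker_box is not None:
        z0, z1, y0, y1, x0, x1 = marker_box
        box = data[z0:z1, y0:y1, x0:x1]
        if box.size == 0:
            raise StandardizationError("marker_box selects no voxels")
        anchor = _histogram_mode(box.ravel())
    else:
        anchor = float(np.percentile(flat, FALLBACK_PERCENTILE))
    span = anchor - air
    if span <= 1e-9 * max(1.0, abs(float(flat.max()) - float(flat.min()))):
        raise StandardizationError(
            "anchor and air modes coincide; cannot standardize"
        )
    out = (data - air) * (ANCHOR_VALUE / span)
    return replace(vol, intensities=out.astype(np.float32))


def crop_volume(vol: VoxelVolume, lowest_node_z: int,
                threshold: float = 300.0, margin_mm: float = 10.0) -> VoxelVolume:
    """Crop margin space and the stem below the lowermost node.

    Retains ``z ≥ lowest_node_z − round(margin_mm / voxel_edge)`` (about
    1 cm of stem below the first node by default) and the tight x/y
    bounding box of the foreground (``intensity > threshold``) plus a
    2-voxel margin.
    """
    nz, ny, nx = vol.shape
    if not 0 <= lowest_node_z < nz:
        raise CropError(f"lowest_node_z {lowest_node_z} outside grid of depth {nz}")
    below = int(round(margin_mm * 1000.0 / vol.voxel_edge))
    z0 = max(0, lowest_node_z - below)
    sub = vol.intensities[z0:]
    fg = sub > threshold
    if not fg.any():
        raise CropError("crop would leave no foreground voxels")
    zs, ys, xs = np.nonzero(fg)
    y0, y1 = max(0, ys.min() - 2), min(ny, ys.max() + 3)
    x0, x1 = max(0, xs.min() - 2), min(nx, xs.max() + 3)
    return replace(vol, intensities=sub[:, y0:y1, x0:x1])
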