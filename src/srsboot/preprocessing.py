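"""Image-side preprocessing contracts: Z-score normalization over a brain
mask with +/-3 SD clipping, trilinear resampling to an isotropic grid,
and fixed-bin-count intensity discretization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ConfigurationError, DegenerateInputError


@dataclass
class ImageVolume:
    """A 3-D scalar grid with per-axis voxel spacing (mm) and optional mask."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("volume data must be 3-D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be three positive values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ConfigurationError("mask shape must equal data shape")


def zscore_normalize(vol: ImageVolume, clip_sd: float | None = 3.0) -> ImageVolume:
    """Standardize the whole scan by in-mask mean/SD, clipping at ``clip_sd``.

    Pass ``clip_sd=None`` for the unclipped variant.
    """
    if vol.mask is None or not vol.mask.any():
        raise DegenerateInputError("a non-empty mask is required for normalization")
    inside = vol.data[vol.mask]
    mu = inside.mean()
    sigma = inside.std()
    if sigma == 0:
        raise DegenerateInputError("zero in-mask intensity variance")
    out = (vol.data - mu) / sigma
    if clip_sd is not None:
        out = np.clip(out, -clip_sd, clip_sd)
    return ImageVolume(out, vol.spacing, vol.mask)


def resample_isotropic(vol: ImageVolume, target_spacing_mm: float = 0.5) -> ImageVolume:
    """Trilinear resampling onto a corner-aligned isotropic grid.

    The output grid covers the original physical extent (half-open,
    origin at the input corner); the number of voxels per axis is
    ``ceil(extent / target)``.  Values are interpolated at voxel centres
    with edge clamping, so no extrapolation occurs.
    """
    if target_spacing_mm <= 0:
        raise ConfigurationError("target spacing must be positive")
    shape = vol.data.shape
    extents = [n * s for n, s in zip(shape, vol.spacing)]
    out_shape = tuple(int(np.ceil(e / target_spacing_mm)) for e in extents)
    coords = np.meshgrid(
        *[
            ((np.arange(n) + 0.5) * target_spacing_mm) / s - 0.5
            for n, s in zip(out_shape, vol.spacing)
        ],
        indexing="ij",
    )
    data = map_coordinates(vol.data, coords, order=1, mode="nearest")
    out = ImageVolume(data, (target_spacing_mm,) * 3)
    if vol.mask is not None:
        m = map_coordinates(vol.mask.astype(float), coords, order=1, mode="nearest")
        out.mask = m >= 0.5
    return out


def discretize_fixed_bins(values, n_bins: int = 64) -> np.ndarray:
    """Equal-width bins over [min, max]; returns indices in 1..n_bins.

    The maximum value lands in the top bin.  All-identical input yields
    a single-bin degenerate output with a warning.
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise DegenerateInputError("no finite values to discretize")
    lo, hi = x[finite].min(), x[finite].max()
    if hi == lo:
        warnings.warn("all values identical: single-bin degenerate output", stacklevel=2)
        return np.ones_like(x, dtype=int)
    width = (hi - lo) / n_bins
    idx = np.floor((x - lo) / width).astype(int) + 1
    return np.clip(idx, 1, n_bins)


# ---------------------------------------------------------------------------
# NIfTI round trip (CLI support)


def load_nifti(path, mask_path=None) -> ImageVolume:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing, mask)


def save_nifti(vol: ImageVolume, path) -> None:
    import nibabel as nib

    affine = np.diag([*vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))
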