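"""Volume I/O, Gaussian smoothing, lateral flipping and SUVR normalization.

The preprocessing chain mirrors standard small-animal PET practice: volumes
are stored as NIfTI-1, smoothed with a Gaussian kernel specified by its
full width at half maximum (FWHM) in mm, flipped so the lesioned hemisphere
is always displayed on the same side, and intensity-normalised to a
reference region (cerebellum for FDOPA, whole brain for FDG), yielding a
standardized uptake value ratio (SUVR) image whose in-reference mean is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import Image3D, LabelAtlas

__all__ = [
    "SUVRImage",
    "fwhm_to_sigma",
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "gaussian_smooth",
    "flip_lateral",
    "normalize_suvr",
]

# FWHM = sigma * 2*sqrt(2*ln 2)
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SUVRImage:
    """A reference-normalised image; mean over the reference mask is 1."""

    image: Image3D
    reference_name: str
    reference_mean: float

    @property
    def values(self) -> np.ndarray:
        return self.image.values


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Per-axis Gaussian sigma in voxel units for a kernel FWHM in mm."""
    return (fwhm_mm / voxel_size_mm) / _FWHM_PER_SIGMA


def read_volume(path: str | Path, lateral_axis: int = 0) -> Image3D:
    """Read a 3D NIfTI-1 volume; voxel sizes come from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a spatial-3D volume, got {data.ndim}D data"
        )
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        idx = np.argwhere(~np.isfinite(data))[0]
        raise ValueError(
            f"{path.name}: non-finite voxel at index {tuple(int(i) for i in idx)}"
        )
    zooms = img.header.get_zooms()[:3]
    return Image3D(data, tuple(float(z) for z in zooms), lateral_axis=lateral_axis)


def write_volume(image: Image3D, path: str | Path) -> None:
    """Write as float32 NIfTI-1 with a diagonal voxel-size affine."""
    affine = np.diag(list(image.voxel_size) + [1.0])
    nib.save(
        nib.Nifti1Image(np.asarray(image.values, dtype=np.float32), affine),
        str(path),
    )


def write_atlas(atlas: LabelAtlas, path: str | Path) -> None:
    """Write labels as int16 NIfTI plus a ``<stem>_labels.tsv`` name table."""
    path = Path(path)
    affine = np.diag(list(atlas.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(path))
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    table = path.with_name(stem + "_labels.tsv")
    with open(table, "w") as fh:
        fh.write("label\tname\tpartner\n")
        for lab in sorted(atlas.names):
            name = atlas.names[lab]
            fh.write(f"{lab}\t{name}\t{atlas.pairs.get(name, '')}\n")


def read_atlas(path: str | Path, lateral_axis: int = 0) -> LabelAtlas:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj).astype(np.int32)
    stem = path.name.removesuffix(".gz").removesuffix(".nii")
    table = path.with_name(stem + "_labels.tsv")
    names: dict[int, str] = {}
    pairs: dict[str, str] = {}
    with open(table) as fh:
        next(fh)
        for line in fh:
            lab, name, partner = line.rstrip("\n").split("\t")
            names[int(lab)] = name
            if partner:
                pairs[name] = partner
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelAtlas(labels, names, zooms, lateral_axis=lateral_axis, pairs=pairs)


def gaussian_smooth(
    image: Image3D, fwhm_mm: float, mask: np.ndarray | None = None
) -> Image3D:
    """Gaussian smoothing with FWHM given in mm.

    Without a mask the filter uses reflective boundaries, which conserves
    total intensity exactly for the symmetric kernel.  With a mask the
    kernel is renormalised over in-mask support (normalized convolution),
    so no intensity leaks across the mask edge and constants are preserved;
    out-of-mask voxels are returned unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return image.with_values(image.values.copy())
    sigma = [fwhm_to_sigma(fwhm_mm, v) for v in image.voxel_size]
    vals = np.asarray(image.values, dtype=np.float64)
    if mask is None:
        out = ndimage.gaussian_filter(vals, sigma=sigma, mode="reflect")
        return image.with_values(out)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vals.shape:
        raise ValueError("mask shape does not match image")
    m = mask.astype(np.float64)
    num = ndimage.gaussian_filter(vals * m, sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(m, sigma=sigma, mode="constant")
    out = vals.copy()
    inm = mask & (den > 0)
    out[inm] = num[inm] / den[inm]
    return image.with_values(out)


def flip_lateral(obj: Image3D | LabelAtlas) -> Image3D | LabelAtlas:
    """Mirror a volume across the midline (index i -> n-1-i on the lateral axis).

    Applied to every subject with a right-hemispheric injection before any
    group statistic, so the intervention is always displayed on the left.
    """
    if isinstance(obj, LabelAtlas):
        return LabelAtlas(
            np.flip(obj.labels, axis=obj.lateral_axis).copy(),
            dict(obj.names),
            obj.voxel_size,
            lateral_axis=obj.lateral_axis,
            pairs=dict(obj.pairs),
        )
    return obj.with_values(np.flip(obj.values, axis=obj.lateral_axis).copy())


def normalize_suvr(
    image: Image3D, reference_mask: np.ndarray, reference_name: str = "reference"
) -> SUVRImage:
    """Divide every voxel by the mean over the reference mask.

    Scale-invariant: scaling the input by any c > 0 leaves the output
    unchanged, which makes downstream ratio statistics independent of
    injected dose and scanner calibration.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != image.shape:
        raise ValueError("reference mask shape does not match image")
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(np.asarray(image.values, dtype=np.float64)[reference_mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be positive, got {ref_mean}")
    out = image.with_values(np.asarray(image.values, dtype=np.float64) / ref_mean)
    return SUVRImage(out, reference_name, ref_mean)
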