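"""VOI statistics, paired ipsi/contra testing and the depletion-severity score.

Dopamine depletion severity is defined on cerebellum-normalised FDOPA
images as ``1 - (ipsilesional mean / contralesional mean)`` over a combined
striatum + nucleus accumbens VOI: 0 for an intact, laterally symmetric
brain, 1 for complete ipsilesional signal loss.  The SUVR normalisation
cancels algebraically in the ratio but is kept in the procedure, both for
fidelity and because reference masks may differ between subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Image3D, LabelAtlas
from .image_prep import SUVRImage
from .synthetic import SEVERITY_VOI

__all__ = [
    "DepletionScore",
    "PairedTestResult",
    "voi_mean",
    "depletion_severity",
    "paired_ttest",
]


@dataclass
class DepletionScore:
    subject_id: str
    severity: float
    mean_ipsi: float
    mean_contra: float


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    n: int


def _image_values(image: Image3D | SUVRImage) -> np.ndarray:
    if isinstance(image, SUVRImage):
        image = image.image
    return np.asarray(image.values, dtype=np.float64)


def voi_mean(
    image: Image3D | SUVRImage, atlas: LabelAtlas, region: str | list[str]
) -> float:
    """Arithmetic mean over the voxels of a named region (or union)."""
    vals = _image_values(image)
    if vals.shape != atlas.shape:
        raise ValueError("image and atlas are on different grids")
    mask = atlas.mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} is empty")
    return float(vals[mask].mean())


def depletion_severity(
    suvr_image: Image3D | SUVRImage,
    atlas: LabelAtlas,
    ipsi_side: str = "left",
    regions: tuple[str, ...] = SEVERITY_VOI,
    subject_id: str = "",
) -> DepletionScore:
    """Severity = 1 - (ipsi mean / contra mean) over the combined VOI.

    Voxels of all sub-VOIs are pooled (count-weighted) per hemisphere.
    ``ipsi_side`` is the lesioned hemisphere; after lateral flipping the
    convention is ipsi = left.
    """
    if ipsi_side not in ("left", "right"):
        raise ValueError("ipsi_side must be 'left' or 'right'")
    ipsi_sfx, contra_sfx = ("L", "R") if ipsi_side == "left" else ("R", "L")
    mean_ipsi = voi_mean(suvr_image, atlas, [f"{r}_{ipsi_sfx}" for r in regions])
    mean_contra = voi_mean(suvr_image, atlas, [f"{r}_{contra_sfx}" for r in regions])
    if mean_contra <= 0:
        raise ValueError(f"contralesional mean must be positive, got {mean_contra}")
    return DepletionScore(
        subject_id=subject_id,
        severity=1.0 - mean_ipsi / mean_contra,
        mean_ipsi=mean_ipsi,
        mean_contra=mean_contra,
    )


def paired_ttest(values_a, values_b) -> PairedTestResult:
    """Two-sided paired t test on matched samples (e.g. ipsi vs contra VOI means)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t test requires two equal-length 1D samples")
    n = a.size
    if n < 3:
        raise ValueError("paired t test requires n >= 3")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            # identical vectors: no effect, maximally non-significant
            return PairedTestResult(0.0, n - 1, 1.0, float(a.mean()), float(b.mean()), n)
        raise ValueError("zero-variance differences: paired t statistic undefined")
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(
        float(t), n - 1, float(p), float(a.mean()), float(b.mean()), n
    )
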