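"""Core in-memory containers: scalar volumes and label atlases.

All volumes in one analysis share a single grid (shape + voxel size); no
resampling is implemented anywhere in the package, so grid mismatches are
hard errors.  Values are stored as float32 on disk but all statistics are
computed in float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Image3D", "LabelAtlas", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class Image3D:
    """A scalar 3D volume on a regular grid.

    Parameters
    ----------
    values
        3D array of voxel values (any float dtype; converted lazily).
    voxel_size
        Edge length of a voxel in mm along each axis.
    lateral_axis
        The array axis that crosses the midline (left-right axis).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    lateral_axis: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"Image3D requires a 3D array, got {self.values.ndim} dimensions"
            )
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"invalid voxel size {self.voxel_size!r}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if not (0 <= self.lateral_axis <= 2):
            raise ValueError("lateral_axis must be 0, 1 or 2")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            idx = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite voxel at index {tuple(int(i) for i in idx)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "Image3D":
        """New image on the same grid with different voxel values."""
        return replace(self, values=values)

    def same_grid(self, other: "Image3D | LabelAtlas") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
        )

    def require_same_grid(self, other: "Image3D | LabelAtlas") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}@{self.voxel_size} vs "
                f"{other.shape}@{other.voxel_size}"
            )


@dataclass
class LabelAtlas:
    """Integer-labelled volume with named regions and left/right pairing.

    ``labels`` holds one integer per voxel (0 = outside brain).  ``names``
    maps label -> region name; ``pairs`` maps a region name to its mirror
    partner on the other hemisphere (symmetric; midline regions absent).
    """

    labels: np.ndarray
    names: dict[int, str]
    voxel_size: tuple[float, float, float]
    lateral_axis: int = 0
    pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelAtlas requires a 3D label array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self._by_name = {v: k for k, v in self.names.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def region_names(self) -> list[str]:
        return sorted(self._by_name)

    def label_of(self, name: str) -> int:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; available: {', '.join(self.region_names)}"
            ) from None

    def mask(self, region: str | list[str] | tuple[str, ...]) -> np.ndarray:
        """Boolean mask of one region or the union of several."""
        if isinstance(region, str):
            region = [region]
        out = np.zeros(self.shape, dtype=bool)
        for name in region:
            out |= self.labels == self.label_of(name)
        return out

    def brain_mask(self) -> np.ndarray:
        """Union of all labelled regions (whole-brain mask)."""
        return self.labels > 0

    def partner(self, name: str) -> str:
        """Mirror region on the opposite hemisphere (raises for midline)."""
        self.label_of(name)  # validate
        if name not in self.pairs:
            raise KeyError(f"region {name!r} has no lateral partner")
        return self.pairs[name]

    def same_grid(self, other: "Image3D | LabelAtlas") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size
        )
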