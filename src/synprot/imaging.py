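"""Array-tomography puncta segmentation, density and colocalization.

Array tomography images ribbons of ultrathin (typically 70 nm) serial
sections; after alignment, synaptic markers appear as small punctate
objects spanning one or a few sections.  This module thresholds each
slice at mean + k*SD of that slice (per-slice, to tolerate
section-to-section staining variation), labels 3D connected components
(26-connectivity across sections), filters them by voxel count and slice
span, and measures puncta densities per unit volume.  Two channels are
compared by opposed-puncta colocalization: a punctum in channel B counts
as colocalized when its centroid lies within a physical distance cutoff
of any channel-A centroid, with anisotropic voxel size respected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import cKDTree
from skimage.measure import label, regionprops

from .errors import ConfigError, SchemaError

__all__ = [
    "ImageStack",
    "Punctum",
    "segment_puncta",
    "puncta_density",
    "colocalize",
    "group_percent_change",
    "puncta_table",
]


@dataclass(frozen=True)
class ImageStack:
    """A single-channel aligned serial-section stack.

    Parameters
    ----------
    data
        Array of shape (slices, rows, cols), any numeric dtype.
    voxel_size_nm
        Physical voxel size (dz, dy, dx) in nanometres; dz is the
        section thickness (70 nm in typical preparations).
    """

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (70.0, 100.0, 100.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise SchemaError(f"stack must be 3D (slices, rows, cols), got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise SchemaError("stack contains non-finite intensities")
        if len(self.voxel_size_nm) != 3 or any(v <= 0 for v in self.voxel_size_nm):
            raise ConfigError(f"voxel size must be three positive values, got {self.voxel_size_nm}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_size_nm", tuple(float(v) for v in self.voxel_size_nm))

    @property
    def volume_um3(self) -> float:
        """Total stack volume in cubic micrometres."""
        dz, dy, dx = self.voxel_size_nm
        return self.data.size * dz * dy * dx * 1e-9

    @classmethod
    def from_tiff(
        cls, path: str, voxel_size_nm: tuple[float, float, float]
    ) -> "ImageStack":
        """Read a multi-page TIFF as one channel's stack."""
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None, :, :]
        return cls(data=data, voxel_size_nm=voxel_size_nm)

    def to_tiff(self, path: str) -> None:
        tifffile.imwrite(path, self.data.astype(np.float32))


@dataclass(frozen=True)
class Punctum:
    """A segmented punctate object in one channel."""

    channel: str
    centroid_nm: tuple[float, float, float]  # (z, y, x)
    n_voxels: int
    volume_um3: float
    slice_span: int


def segment_puncta(
    stack: ImageStack,
    channel: str = "A",
    threshold_k: float = 2.0,
    min_voxels: int = 2,
    max_voxels: int | None = None,
    min_slices: int = 1,
) -> list[Punctum]:
    """Threshold, label and size-filter punctate objects.

    Each slice is binarized at (slice mean) + ``threshold_k`` * (slice
    SD), strictly above; 3D connected components are taken with
    26-connectivity, then components outside the voxel-count or
    slice-span bounds are discarded.  The result is invariant to
    multiplying the stack by any positive constant.
    """
    if min_voxels < 1:
        raise ConfigError(f"min_voxels must be >= 1, got {min_voxels}")
    arr = stack.data
    mean = arr.mean(axis=(1, 2), keepdims=True)
    sd = arr.std(axis=(1, 2), keepdims=True)
    mask = arr > mean + threshold_k * sd
    labels = label(mask, connectivity=3)
    dz, dy, dx = stack.voxel_size_nm
    voxel_um3 = dz * dy * dx * 1e-9
    puncta = []
    for region in regionprops(labels):
        n_vox = int(region.area)
        if n_vox < min_voxels:
            continue
        if max_voxels is not None and n_vox > max_voxels:
            continue
        z0, _, _, z1, _, _ = region.bbox
        span = z1 - z0
        if span < min_slices:
            continue
        cz, cy, cx = region.centroid
        puncta.append(
            Punctum(
                channel=channel,
                centroid_nm=(cz * dz, cy * dy, cx * dx),
                n_voxels=n_vox,
                volume_um3=n_vox * voxel_um3,
                slice_span=span,
            )
        )
    return puncta


def puncta_density(puncta: Sequence[Punctum], stack: ImageStack) -> float:
    """Puncta per cubic micrometre of analyzed stack volume."""
    vol = stack.volume_um3
    if vol <= 0:
        raise ConfigError("stack volume is zero")
    return len(puncta) / vol


def colocalize(
    puncta_a: Sequence[Punctum],
    puncta_b: Sequence[Punctum],
    max_distance_nm: float = 500.0,
) -> float:
    """Fraction of channel-B puncta with a channel-A partner.

    A B punctum is colocalized when its nearest A centroid (Euclidean
    distance in physical nm) is within ``max_distance_nm``.  A single A
    punctum may partner any number of B puncta.  Returns 0.0 when either
    list is empty.
    """
    if max_distance_nm < 0:
        raise ConfigError(f"max_distance_nm must be >= 0, got {max_distance_nm}")
    if not puncta_b or not puncta_a:
        return 0.0
    tree = cKDTree([p.centroid_nm for p in puncta_a])
    dists, _ = tree.query([p.centroid_nm for p in puncta_b])
    return float(np.mean(dists <= max_distance_nm))


def group_percent_change(
    densities_a: Sequence[float], densities_b: Sequence[float]
) -> float:
    """Percent difference of group-B mean density relative to group A:
    ``100 * (mean_b - mean_a) / mean_a``.
    """
    if len(densities_a) == 0 or len(densities_b) == 0:
        raise ConfigError("both density groups must be non-empty")
    mean_a = float(np.mean(densities_a))
    mean_b = float(np.mean(densities_b))
    if mean_a == 0:
        raise ConfigError("reference group mean density is zero")
    return 100.0 * (mean_b - mean_a) / mean_a


def puncta_table(puncta: Sequence[Punctum]) -> pd.DataFrame:
    """Tabulate puncta: channel, centroid (nm), voxel count, slice span."""
    return pd.DataFrame(
        {
            "channel": [p.channel for p in puncta],
            "z_nm": [p.centroid_nm[0] for p in puncta],
            "y_nm": [p.centroid_nm[1] for p in puncta],
            "x_nm": [p.centroid_nm[2] for p in puncta],
            "n_voxels": [p.n_voxels for p in puncta],
            "volume_um3": [p.volume_um3 for p in puncta],
            "slice_span": [p.slice_span for p in puncta],
        }
    )
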