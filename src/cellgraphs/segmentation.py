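"""Nuclei segmentation for 3D fluorescence z-stacks.

The pipeline is deliberately simple, matching common practice for
high-throughput hydrogel imaging: a single global Otsu threshold over the
whole stack's intensity histogram, 3D connected-component labelling, and
centroid extraction in physical micrometres.  No watershed splitting or
deconvolution is attempted; touching nuclei merge into one component.

Conventions
-----------
* Foreground is strictly greater than the threshold.
* Voxel (k, j, i) (0-based z, y, x index) has its centre at
  ``((i + 0.5) * sx, (j + 0.5) * sy, (k + 0.5) * sz)`` micrometres.
* Otsu thresholding and labelling are metric-free; anisotropic voxel
  spacing enters only at centroid extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import PointCloud

__all__ = [
    "ImageStack",
    "SegmentationResult",
    "otsu_threshold",
    "binarize",
    "label_components",
    "extract_centroids",
    "segment_stack",
]


@dataclass
class ImageStack:
    """A 3D intensity volume indexed (z, y, x) with voxel size in um."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]  # (z, y, x) um per voxel

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be 3 strictly positive components")

    def write_tiff(self, path) -> None:
        """Write as multi-page TIFF with a JSON sidecar recording voxel size."""
        path = Path(path)
        tifffile.imwrite(path, self.voxels, photometric="minisblack")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"voxel_size_um_zyx": list(self.voxel_size)}))

    @classmethod
    def read_tiff(cls, path, voxel_size=None) -> "ImageStack":
        """Read a multi-page TIFF; voxel size from argument or sidecar JSON."""
        path = Path(path)
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
        if voxel_size is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            if not sidecar.exists():
                raise ValueError(
                    f"no voxel size given and no sidecar {sidecar.name} found"
                )
            voxel_size = tuple(json.loads(sidecar.read_text())["voxel_size_um_zyx"])
        return cls(voxels=voxels, voxel_size=tuple(voxel_size))


@dataclass
class SegmentationResult:
    threshold: float
    mask: np.ndarray
    labels: np.ndarray
    centroids: PointCloud


class DegenerateHistogramError(ValueError):
    """Raised when an image has no intensity variation to threshold."""


def otsu_threshold(stack: ImageStack, n_bins: int = 256) -> float:
    """Global Otsu threshold over the stack's full intensity histogram.

    Maximizes between-class variance of the foreground/background split.
    Raises :class:`DegenerateHistogramError` for constant stacks, where no
    foreground/background separation exists.
    """
    voxels = stack.voxels
    if voxels.min() == voxels.max():
        raise DegenerateHistogramError(
            "constant-intensity stack: histogram has a single bin occupied"
        )
    return float(threshold_otsu(voxels.ravel(), nbins=n_bins))


def binarize(stack: ImageStack, threshold: float) -> np.ndarray:
    """Foreground mask: voxels strictly greater than the threshold."""
    return stack.voxels > threshold


# scipy structuring elements for the three standard 3D connectivities:
# 6 = faces only, 18 = faces+edges, 26 = faces+edges+corners.
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def label_components(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label 3D connected components; labels 1..n, 0 is background."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, _ = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    return labels


def extract_centroids(
    labels: np.ndarray,
    voxel_size: tuple[float, float, float],
    min_voxels: int = 4,
) -> PointCloud:
    """Unweighted component centroids in um under the voxel-centre convention.

    Components with fewer than ``min_voxels`` voxels are discarded as
    speckle noise (set ``min_voxels=1`` to keep everything).
    """
    labels = np.asarray(labels)
    n = int(labels.max())
    if n == 0:
        return PointCloud(np.empty((0, 3)))
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.flatnonzero(counts[1:] >= max(int(min_voxels), 1)) + 1
    if keep.size == 0:
        return PointCloud(np.empty((0, 3)))
    # mean voxel index per component, then voxel-centre shift and um scaling
    centers = ndimage.center_of_mass(np.ones_like(labels), labels, keep)
    centers = np.asarray(centers, dtype=float) + 0.5  # (z, y, x) index space
    sz, sy, sx = voxel_size
    coords = np.column_stack(
        [centers[:, 2] * sx, centers[:, 1] * sy, centers[:, 0] * sz]
    )
    return PointCloud(coords)


def segment_stack(
    stack: ImageStack,
    n_bins: int = 256,
    connectivity: int = 26,
    min_voxels: int = 4,
) -> SegmentationResult:
    """Full segmentation: Otsu threshold, binarize, label, extract centroids."""
    threshold = otsu_threshold(stack, n_bins=n_bins)
    mask = binarize(stack, threshold)
    labels = label_components(mask, connectivity=connectivity)
    centroids = extract_centroids(labels, stack.voxel_size, min_voxels=min_voxels)
    return SegmentationResult(
        threshold=threshold, mask=mask, labels=labels, centroids=centroids
    )
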