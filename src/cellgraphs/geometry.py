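"""Core spatial containers: imaging volumes and labelled nuclei point clouds.

A :class:`PointCloud` is the central exchange object of the package: it is
what the synthetic generators produce, what segmentation extracts from a
z-stack, and what cell-graph construction consumes.  Coordinates are always
physical micrometres, never voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["VolumeSpec", "PointCloud"]

#: Column order of the on-disk CSV schema for point clouds.
POINT_CLOUD_COLUMNS = [
    "sample_id",
    "cell_line",
    "time_h",
    "replicate",
    "x_um",
    "y_um",
    "z_um",
]


@dataclass(frozen=True)
class VolumeSpec:
    """Physical extent of an imaged hydrogel volume and its voxel grid.

    Defaults correspond to a 900 x 900 um cross-section imaged through
    100 um of depth, the standard acquisition geometry for the hydrogel
    cultures this package models.  ``voxel_size`` is (z, y, x) in um/voxel.
    """

    extent_x: float = 900.0
    extent_y: float = 900.0
    extent_z: float = 100.0
    voxel_size: tuple[float, float, float] = (2.0, 1.76, 1.76)

    def __post_init__(self) -> None:
        if not (self.extent_x > 0 and self.extent_y > 0 and self.extent_z > 0):
            raise ValueError("volume extents must be strictly positive")
        if len(self.voxel_size) != 3:
            raise ValueError("voxel_size must have exactly 3 components (z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be strictly positive")

    @property
    def volume_um3(self) -> float:
        return self.extent_x * self.extent_y * self.extent_z

    @property
    def shape(self) -> tuple[int, int, int]:
        """Voxel grid shape (z, y, x) covering the full extent."""
        sz, sy, sx = self.voxel_size
        return (
            int(np.ceil(self.extent_z / sz)),
            int(np.ceil(self.extent_y / sy)),
            int(np.ceil(self.extent_x / sx)),
        )


@dataclass
class PointCloud:
    """Nuclei centroids in micrometres with sample provenance labels."""

    coords: np.ndarray  # (n, 3) float array, columns x, y, z in um
    sample_id: str = ""
    cell_line: str = ""
    time_h: float = float("nan")
    replicate: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.size and not np.isfinite(self.coords).all():
            raise ValueError("point cloud coordinates must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def with_labels(self, **labels) -> "PointCloud":
        return replace(self, **labels)

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame(
            {
                "sample_id": [self.sample_id] * n,
                "cell_line": [self.cell_line] * n,
                "time_h": [self.time_h] * n,
                "replicate": [self.replicate] * n,
                "x_um": self.coords[:, 0],
                "y_um": self.coords[:, 1],
                "z_um": self.coords[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PointCloud":
        """Build a single cloud from a CSV-schema frame (one sample only)."""
        if df.empty:
            return cls(np.empty((0, 3)))
        ids = df["sample_id"].unique()
        if len(ids) > 1:
            raise ValueError(f"frame contains {len(ids)} samples; expected one")
        row = df.iloc[0]
        return cls(
            coords=df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            sample_id=str(row["sample_id"]),
            cell_line=str(row["cell_line"]),
            time_h=float(row["time_h"]),
            replicate=int(row["replicate"]),
        )


def clouds_to_frame(clouds: list[PointCloud]) -> pd.DataFrame:
    """Concatenate clouds into one long frame in the CSV schema."""
    if not clouds:
        return pd.DataFrame(columns=POINT_CLOUD_COLUMNS)
    return pd.concat([c.to_frame() for c in clouds], ignore_index=True)


def frame_to_clouds(df: pd.DataFrame) -> list[PointCloud]:
    """Split a long frame back into one PointCloud per sample_id."""
    out = []
    for _, sub in df.groupby("sample_id", sort=True):
        out.append(PointCloud.from_frame(sub))
    return out


def write_clouds_csv(clouds: list[PointCloud], path) -> None:
    clouds_to_frame(clouds).to_csv(path, index=False)


def read_clouds_csv(path) -> list[PointCloud]:
    return frame_to_clouds(pd.read_csv(path))
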