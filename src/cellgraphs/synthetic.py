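"""Synthetic hydrogel cultures: spatial point processes, image rendering,
and planted-influence tensors.

The generators emulate the study design this package targets: 900 x 900 x
100 um collagen-hydrogel volumes imaged at six time points (hours 10, 16,
24, 72, 120, 168) with five replicate samples each, across a panel of
cell-line archetypes whose nuclear organisation ranges from spatially
uniform to strongly clustered.

Two point-process regimes are provided:

* ``uniform`` — homogeneous Poisson: a Poisson-distributed number of nuclei
  placed independently and uniformly in the box.
* ``clustered`` — Thomas process: Poisson-distributed cluster parents,
  Poisson-distributed offspring counts per parent, isotropic Gaussian
  displacements; offspring falling outside the box are discarded (the box
  is an imaging window, not a torus).

Archetype parameters may drift over the time course through per-time-point
multipliers, emulating proliferation (rates increasing) and cluster
compaction (``cluster_sigma`` shrinking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PointCloud, VolumeSpec
from .segmentation import ImageStack

__all__ = [
    "ArchetypeParams",
    "DEFAULT_TIME_POINTS_H",
    "default_archetypes",
    "sample_point_cloud",
    "generate_time_course",
    "render_image_stack",
    "plant_influence_tensor",
]

#: Fixation time points (hours) of the emulated study design.
DEFAULT_TIME_POINTS_H = (10.0, 16.0, 24.0, 72.0, 120.0, 168.0)

#: Parameter names that time_interpolation multipliers may address.
_INTERPOLATABLE = ("intensity_per_volume", "parent_rate", "offspring_mean", "cluster_sigma")


@dataclass(frozen=True)
class ArchetypeParams:
    """One cell-line archetype of a spatial point process in a volume.

    Rates are intensities per um^3.  For the uniform regime only
    ``intensity_per_volume`` is used; for the clustered (Thomas) regime
    ``parent_rate``, ``offspring_mean`` and ``cluster_sigma`` define the
    process and the expected total is parent_rate * volume * offspring_mean.

    ``time_interpolation`` maps a parameter name to one multiplier per
    configured time point, e.g. ``{"parent_rate": (1, 1.1, 1.3, 1.9, 2.4,
    2.8)}`` for a proliferating line.
    """

    name: str
    regime: str  # "uniform" | "clustered"
    intensity_per_volume: float | None = None  # nuclei per um^3 (uniform regime)
    parent_rate: float | None = None  # cluster parents per um^3 (clustered)
    offspring_mean: float | None = None  # expected nuclei per cluster
    cluster_sigma: float | None = None  # Gaussian displacement scale, um
    time_interpolation: dict[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.regime not in ("uniform", "clustered"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "uniform":
            if self.intensity_per_volume is None or not (self.intensity_per_volume >= 0):
                raise ValueError("uniform regime requires intensity_per_volume >= 0")
        else:
            for fname in ("parent_rate", "offspring_mean", "cluster_sigma"):
                v = getattr(self, fname)
                if v is None or not (v > 0):
                    raise ValueError(f"clustered regime requires {fname} > 0")
        if self.time_interpolation is not None:
            for key in self.time_interpolation:
                if key not in _INTERPOLATABLE:
                    raise ValueError(f"cannot interpolate unknown parameter {key!r}")

    def at_time(self, j: int, n_time: int) -> "ArchetypeParams":
        """Parameters at time index ``j`` after applying the multipliers."""
        if self.time_interpolation is None:
            return self
        updates: dict = {}
        for key, mults in self.time_interpolation.items():
            if len(mults) != n_time:
                raise ValueError(
                    f"time_interpolation[{key!r}] has {len(mults)} entries "
                    f"for {n_time} time points"
                )
            base = getattr(self, key)
            if base is not None:
                updates[key] = base * float(mults[j])
        return ArchetypeParams(
            name=self.name,
            regime=self.regime,
            intensity_per_volume=updates.get("intensity_per_volume", self.intensity_per_volume),
            parent_rate=updates.get("parent_rate", self.parent_rate),
            offspring_mean=updates.get("offspring_mean", self.offspring_mean),
            cluster_sigma=updates.get("cluster_sigma", self.cluster_sigma),
            time_interpolation=None,
        )

    @staticmethod
    def uniform_from_count(
        name: str,
        expected_count: float,
        volume: VolumeSpec,
        time_interpolation: dict[str, tuple[float, ...]] | None = None,
    ) -> "ArchetypeParams":
        return ArchetypeParams(
            name=name,
            regime="uniform",
            intensity_per_volume=expected_count / volume.volume_um3,
            time_interpolation=time_interpolation,
        )

    @staticmethod
    def clustered_from_counts(
        name: str,
        expected_parents: float,
        offspring_mean: float,
        cluster_sigma: float,
        volume: VolumeSpec,
        time_interpolation: dict[str, tuple[float, ...]] | None = None,
    ) -> "ArchetypeParams":
        return ArchetypeParams(
            name=name,
            regime="clustered",
            parent_rate=expected_parents / volume.volume_um3,
            offspring_mean=offspring_mean,
            cluster_sigma=cluster_sigma,
            time_interpolation=time_interpolation,
        )


def default_archetypes(volume: VolumeSpec | None = None) -> list[ArchetypeParams]:
    """The default 11-archetype panel spanning uniform and clustered regimes.

    Archetypes are named after the cell-line panel they emulate; two breast
    cancer archetypes (AU565 and MDA-MB231) deliberately share identical
    parameters, providing the one pair a downstream discrimination analysis
    should *fail* to separate.  Expected nuclei counts are per full volume
    at the first time point; multipliers model proliferation and cluster
    compaction over the 10 h - 168 h course.
    """
    vol = volume or VolumeSpec()
    growth_fast = (1.0, 1.08, 1.2, 1.8, 2.2, 2.4)
    growth_moderate = (1.0, 1.05, 1.15, 1.5, 1.8, 2.0)
    flat = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    U = ArchetypeParams.uniform_from_count
    C = ArchetypeParams.clustered_from_counts
    breast_cluster = dict(
        expected_parents=40,
        offspring_mean=4.5,
        cluster_sigma=22.0,
        time_interpolation={"parent_rate": growth_moderate},
    )
    return [
        U("MCF10A", 180, vol, {"intensity_per_volume": growth_fast}),
        C("AU565", volume=vol, **breast_cluster),
        C("MCF7", 25, 9.0, 15.0, vol, {
            "parent_rate": (1.0, 1.1, 1.2, 1.6, 2.0, 2.3),
            "cluster_sigma": (1.0, 1.0, 0.95, 0.85, 0.8, 0.75),
        }),
        C("MDA-MB231", volume=vol, **breast_cluster),  # identical twin of AU565
        U("hDFB", 110, vol, {"intensity_per_volume": (1.0, 1.0, 1.05, 1.2, 1.3, 1.35)}),
        U("NHA", 70, vol, {"intensity_per_volume": flat}),
        C("U118MG", 18, 14.0, 32.0, vol, {"parent_rate": (1.0, 1.1, 1.3, 1.9, 2.4, 2.8)}),
        U("NHOst", 140, vol, {"intensity_per_volume": (1.0, 1.0, 1.1, 1.4, 1.55, 1.6)}),
        C("MG63", 55, 5.0, 10.0, vol, {
            "parent_rate": (1.0, 1.05, 1.2, 1.7, 2.1, 2.3),
            "cluster_sigma": (1.0, 0.95, 0.9, 0.8, 0.7, 0.65),
        }),
        U("RWPE-1", 260, vol, {"intensity_per_volume": (1.0, 1.0, 1.02, 1.08, 1.12, 1.15)}),
        C("DU145", 12, 13.0, 45.0, vol, {"parent_rate": (1.0, 1.05, 1.15, 1.45, 1.7, 1.85)}),
    ]


def sample_point_cloud(
    params: ArchetypeParams,
    volume: VolumeSpec,
    seed,
    parents: np.ndarray | None = None,
) -> PointCloud:
    """Draw one realisation of the archetype's point process in the volume.

    ``seed`` may be an int or a numpy Generator/SeedSequence; a fixed seed
    gives a bit-identical cloud.  For the clustered regime, ``parents``
    optionally fixes the cluster-parent locations (an (n, 3) array in um)
    instead of drawing them, for controlled simulations.
    """
    rng = np.random.default_rng(seed)
    lo = np.zeros(3)
    hi = np.array([volume.extent_x, volume.extent_y, volume.extent_z])
    if params.regime == "uniform":
        n = rng.poisson(params.intensity_per_volume * volume.volume_um3)
        pts = rng.uniform(lo, hi, size=(n, 3))
    else:
        if parents is not None:
            parents = np.asarray(parents, dtype=float).reshape(-1, 3)
            n_parents = parents.shape[0]
        else:
            n_parents = rng.poisson(params.parent_rate * volume.volume_um3)
            parents = rng.uniform(lo, hi, size=(n_parents, 3))
        counts = rng.poisson(params.offspring_mean, size=n_parents)
        pts = np.repeat(parents, counts, axis=0)
        pts = pts + rng.normal(0.0, params.cluster_sigma, size=pts.shape)
        inside = np.all((pts >= lo) & (pts <= hi), axis=1)
        pts = pts[inside]
    return PointCloud(pts, cell_line=params.name)


def generate_time_course(
    archetypes: list[ArchetypeParams],
    time_points_h=DEFAULT_TIME_POINTS_H,
    replicates: int = 5,
    volume: VolumeSpec | None = None,
    seed=0,
) -> list[PointCloud]:
    """One cloud per (archetype, time point, replicate), fully labelled.

    Defaults reproduce the emulated design: 6 time points x 5 replicates.
    Sub-seeds are spawned deterministically per sample, so the whole course
    is reproducible from one seed.
    """
    if not archetypes:
        raise ValueError("archetype list must not be empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    vol = volume or VolumeSpec()
    time_points_h = [float(t) for t in time_points_h]
    n_time = len(time_points_h)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(archetypes) * n_time * replicates)
    clouds = []
    idx = 0
    for arch in archetypes:
        for j, t in enumerate(time_points_h):
            params_t = arch.at_time(j, n_time)
            for r in range(1, replicates + 1):
                cloud = sample_point_cloud(params_t, vol, children[idx])
                idx += 1
                clouds.append(
                    cloud.with_labels(
                        sample_id=f"{arch.name}_t{t:g}_r{r}",
                        cell_line=arch.name,
                        time_h=t,
                        replicate=r,
                    )
                )
    return clouds


def render_image_stack(
    cloud: PointCloud,
    volume: VolumeSpec,
    blob_sigma_um: float = 3.0,
    noise_sd: float = 0.0,
    seed=0,
    peak_intensity: float = 255.0,
) -> ImageStack:
    """Render nuclei as isotropic Gaussian blobs on the volume's voxel grid.

    Each nucleus contributes a Gaussian of physical scale ``blob_sigma_um``
    (isotropic in um, hence anisotropic in voxels), on top of additive
    Gaussian background noise; intensities are clipped at zero.
    """
    if not (blob_sigma_um > 0):
        raise ValueError("blob_sigma_um must be strictly positive")
    if any(v <= 0 for v in volume.voxel_size):
        raise ValueError("voxel_size components must be strictly positive")
    rng = np.random.default_rng(seed)
    shape = volume.shape
    sz, sy, sx = volume.voxel_size
    img = np.zeros(shape, dtype=float)
    # voxel-centre coordinate axes in um
    zs = (np.arange(shape[0]) + 0.5) * sz
    ys = (np.arange(shape[1]) + 0.5) * sy
    xs = (np.arange(shape[2]) + 0.5) * sx
    half = 4.0 * blob_sigma_um  # truncation window per blob
    for x, y, z in cloud.coords:
        k0, k1 = np.searchsorted(zs, [z - half, z + half])
        j0, j1 = np.searchsorted(ys, [y - half, y + half])
        i0, i1 = np.searchsorted(xs, [x - half, x + half])
        if k0 == k1 or j0 == j1 or i0 == i1:
            continue
        gz = np.exp(-0.5 * ((zs[k0:k1] - z) / blob_sigma_um) ** 2)
        gy = np.exp(-0.5 * ((ys[j0:j1] - y) / blob_sigma_um) ** 2)
        gx = np.exp(-0.5 * ((xs[i0:i1] - x) / blob_sigma_um) ** 2)
        img[k0:k1, j0:j1, i0:i1] += peak_intensity * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    np.clip(img, 0.0, None, out=img)
    return ImageStack(voxels=img, voxel_size=volume.voxel_size)


def plant_influence_tensor(
    n_features: int = 20,
    n_time: int = 6,
    n_lines: int = 11,
    influential: set | frozenset | tuple = (0, 1, 2, 3, 4),
    signal_sd: float = 5.0,
    noise_sd: float = 1.0,
    seed=0,
):
    """Feature x time x line tensor with known influential features.

    Non-influential features are pure i.i.d. Gaussian noise of scale
    ``noise_sd``.  Influential features carry a structured time-and-line
    dependent signal: each signal slice is a random mixture of two shared
    smooth time factors and two shared line factors, rescaled so its
    root-mean-square amplitude equals ``signal_sd``, plus the same noise
    floor.  The planted index set is recorded in the returned tensor's
    ``meta["planted_influential"]``.

    Returns a :class:`cellgraphs.multiway.FeatureTensor`.
    """
    from .multiway import FeatureTensor  # local import avoids a cycle

    influential = sorted(int(i) for i in influential)
    if not influential:
        raise ValueError("influential set must not be empty")
    if influential[0] < 0 or influential[-1] >= n_features:
        raise ValueError("influential indices out of range")
    if not (signal_sd > noise_sd):
        raise ValueError("signal_sd must exceed noise_sd")
    rng = np.random.default_rng(seed)
    entries = rng.normal(0.0, noise_sd, size=(n_features, n_time, n_lines))
    # shared low-rank structure: 2 time factors x 2 line factors
    u = rng.normal(size=(2, n_time))
    v = rng.normal(size=(2, n_lines))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    for i in influential:
        coeff = rng.normal(size=(2, 2))
        slab = np.einsum("ab,aj,bk->jk", coeff, u, v)
        rms = np.sqrt(np.mean(slab**2))
        entries[i] += signal_sd * slab / rms
    return FeatureTensor(
        entries=entries,
        feature_names=[f"feature_{i+1:02d}" for i in range(n_features)],
        time_points=[float(j) for j in range(n_time)],
        cell_lines=[f"line_{k+1:02d}" for k in range(n_lines)],
        meta={"planted_influential": influential},
    )
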