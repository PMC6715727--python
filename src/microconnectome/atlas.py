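"""Voxel atlas, flat map, and synthetic fixtures with planted ground truth.

The pipeline consumes (a) a 3-D label volume with region, layer, and
hemisphere annotations, (b) a flat map projecting labeled voxels to a 2-D
plane, (c) voxelized projection tensors, and (d) neuron and dendritic
segment tables.  The generators in this module emulate all of these at desk
scale: a slab-shaped cortex of mirror-symmetric hemispheres, regions tiling
the flattened sheet, layers stacked along depth, projections generated from
a *planted* topographic mapping, and Poisson-placed neurons with positive
length segments.  Every generator is deterministic for a fixed seed, and the
planted parameters are returned so downstream fits can be validated against
known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import keyed_rng
from .mapping import BarycentricSystem, TopographicMapping, fit_source_anchors

__all__ = [
    "AtlasSpec",
    "VoxelAtlas",
    "FlatMap",
    "VoxelProjectionTensor",
    "build_synthetic_atlas",
    "make_planted_mapping",
    "synth_projection_tensor",
    "synth_neurons_and_segments",
    "synth_axon_table",
    "save_atlas",
    "load_atlas",
]

NEURON_COLUMNS = ["neuron_id", "region", "layer", "mtype",
                  "x", "y", "z", "flat_x", "flat_y"]
SEGMENT_COLUMNS = ["segment_id", "neuron_id", "region", "layer",
                   "x", "y", "z", "flat_x", "flat_y", "length"]


@dataclass
class AtlasSpec:
    """Description of a synthetic slab cortex.

    ``shape`` is (nx, ny, nz) voxels with x the medio-lateral axis (split
    into hemispheres), y anterior-posterior and z depth (layer 1 at z=0).
    Regions tile each hemisphere footprint on a ``region_grid`` of
    (gx, gy) patches; with the default grid regions form bands along y.
    """

    n_regions: int = 2            # per hemisphere
    n_layers: int = 6
    shape: tuple = (10, 10, 12)
    voxel_size: float = 100.0     # micrometers
    region_grid: tuple | None = None
    n_modules: int = 2

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions per hemisphere")
        if self.n_layers < 2:
            raise ValueError("need at least 2 layers")
        if any(s <= 0 for s in self.shape):
            raise ValueError("extents must be positive")
        if self.region_grid is None:
            self.region_grid = (1, self.n_regions)


@dataclass
class FlatMap:
    """Orthographic flat map collapsing the depth (z) axis.

    Defined for every labeled voxel; pixel (i, j) covers the square
    [i*s, (i+1)*s) x [j*s, (j+1)*s) and flat coordinates are micrometers at
    voxel centers.
    """

    pixel_size: float

    def flat_xy(self, voxels: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(voxels))
        return (v[:, :2] + 0.5) * self.pixel_size

    def pixels(self, voxels: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(voxels))
        return v[:, :2].astype(int)

    def pixel_of_point(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor(p / self.pixel_size).astype(int)


@dataclass
class VoxelAtlas:
    labels: np.ndarray          # 3-D int, region id per voxel, 0 = outside
    layer_labels: np.ndarray    # 3-D int, 1..n_layers inside, 0 outside
    hemisphere: np.ndarray      # 3-D int, 1 left / 2 right, 0 outside
    voxel_size: float
    region_volumes: dict        # region id -> um^3
    modules: dict               # region id -> module id
    hierarchy_score: dict       # region id -> float
    n_regions_per_hemisphere: int

    @property
    def regions(self) -> list:
        return sorted(self.region_volumes)

    def mirror_region(self, region: int) -> int:
        n = self.n_regions_per_hemisphere
        return region + n if region <= n else region - n

    def base_region(self, region: int) -> int:
        """Hemisphere-independent region index (1..n per hemisphere)."""
        n = self.n_regions_per_hemisphere
        return region if region <= n else region - n

    def region_voxels(self, region: int) -> np.ndarray:
        return np.argwhere(self.labels == region)

    def region_footprint(self, region: int) -> np.ndarray:
        """Unique flat-map pixels covered by the region."""
        vox = self.region_voxels(region)
        return np.unique(vox[:, :2], axis=0)

    def layer_voxels(self, region: int, layer: int) -> np.ndarray:
        return np.argwhere((self.labels == region) & (self.layer_labels == layer))

    def layer_thicknesses(self) -> dict:
        """Layer id -> thickness in micrometers (slab geometry)."""
        out = {}
        for lay in range(1, int(self.layer_labels.max()) + 1):
            zs = np.unique(np.argwhere(self.layer_labels == lay)[:, 2])
            out[lay] = len(zs) * self.voxel_size
        return out


@dataclass
class VoxelProjectionTensor:
    """Voxelized projection strengths from one source region to the flat-map
    pixels of one target region."""

    source_region: int
    target_region: int
    class_label: str
    source_voxels: np.ndarray   # (n, 3) int
    target_pixels: np.ndarray   # (m, 2) int
    strengths: np.ndarray       # (n, m) float, >= 0

    def __post_init__(self) -> None:
        if (np.asarray(self.strengths) < 0).any():
            raise ValueError("strengths must be non-negative")


# --------------------------------------------------------------------------
# atlas construction
# --------------------------------------------------------------------------

def build_synthetic_atlas(spec: AtlasSpec, seed: int = 0) -> tuple[VoxelAtlas, FlatMap]:
    """Build a mirror-symmetric two-hemisphere slab atlas.

    Region ids are 1..n in the left hemisphere and n+1..2n in the right, the
    right hemisphere being the mirror image (about the mid-sagittal plane) of
    the left.  Raises if any region or layer would receive zero voxels.
    """
    nx, ny, nz = spec.shape
    half = nx // 2
    if half < 1:
        raise ValueError("x extent too small for two hemispheres")
    gx, gy = spec.region_grid
    if gx * gy < spec.n_regions:
        raise ValueError("region grid too small for the number of regions")
    x_edges = np.linspace(0, half, gx + 1).astype(int)
    y_edges = np.linspace(0, ny, gy + 1).astype(int)
    z_edges = np.linspace(0, nz, spec.n_layers + 1).astype(int)
    if np.any(np.diff(z_edges) == 0):
        raise ValueError("a layer would have zero extent")

    labels = np.zeros(spec.shape, dtype=np.int32)
    layer_labels = np.zeros(spec.shape, dtype=np.int32)
    hemisphere = np.zeros(spec.shape, dtype=np.int32)

    region = 0
    for jy in range(gy):
        for jx in range(gx):
            region += 1
            if region > spec.n_regions:
                break
            xs = slice(x_edges[jx], x_edges[jx + 1])
            ys = slice(y_edges[jy], y_edges[jy + 1])
            if x_edges[jx + 1] == x_edges[jx] or y_edges[jy + 1] == y_edges[jy]:
                raise ValueError(f"region {region} would have zero extent")
            labels[xs, ys, :] = region
    if region < spec.n_regions:
        raise ValueError("region grid left regions without voxels")

    # mirror into the right hemisphere
    left = labels[:half]
    labels[nx - half:] = np.where(left[::-1] > 0, left[::-1] + spec.n_regions, 0)
    hemisphere[:half][left > 0] = 1
    hemisphere[nx - half:][labels[nx - half:] > 0] = 2

    for lay in range(spec.n_layers):
        zs = slice(z_edges[lay], z_edges[lay + 1])
        layer_labels[:, :, zs] = lay + 1
    layer_labels[labels == 0] = 0

    vs3 = spec.voxel_size ** 3
    region_volumes = {
        int(r): int((labels == r).sum()) * vs3
        for r in np.unique(labels) if r > 0
    }
    modules = {}
    scores = {}
    for r in region_volumes:
        base = r if r <= spec.n_regions else r - spec.n_regions
        modules[r] = (base - 1) * spec.n_modules // spec.n_regions + 1
        scores[r] = float(base)
    atlas = VoxelAtlas(
        labels=labels, layer_labels=layer_labels, hemisphere=hemisphere,
        voxel_size=spec.voxel_size, region_volumes=region_volumes,
        modules=modules, hierarchy_score=scores,
        n_regions_per_hemisphere=spec.n_regions,
    )
    return atlas, FlatMap(pixel_size=spec.voxel_size)


# --------------------------------------------------------------------------
# planted mappings and projection tensors
# --------------------------------------------------------------------------

def make_planted_mapping(
    atlas: VoxelAtlas,
    flatmap: FlatMap,
    source: int,
    target: int,
    rotation_deg: int = 0,
    reflection: bool = False,
    kernel_width: float = 0.0,
) -> TopographicMapping:
    """A ground-truth mapping between two regions.

    Source anchors are the geometric anchors of the source footprint; target
    anchors are their images under the similarity transform that translates
    the source centroid onto the target centroid and applies
    Rot(rotation_deg) . diag(1,-1)^reflection about it.  For congruent
    (same-shape) region patches under multiples of 90 degrees this keeps the
    anchors inside the target region.
    """
    s = flatmap.pixel_size
    src_mask = atlas.region_footprint(source)
    tgt_mask = atlas.region_footprint(target)
    src_sys = fit_source_anchors(src_mask, pixel_size=s)
    c_src = (src_mask.mean(axis=0) + 0.5) * s
    c_tgt = (tgt_mask.mean(axis=0) + 0.5) * s
    theta = np.radians(rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    lin = rot @ np.diag([1.0, -1.0]) if reflection else rot
    tgt_anchors = (src_sys.anchors - c_src) @ lin.T + c_tgt
    return TopographicMapping(
        source=src_sys, target=BarycentricSystem(tgt_anchors),
        kernel_width=kernel_width,
    )


def synth_projection_tensor(
    atlas: VoxelAtlas,
    flatmap: FlatMap,
    planted: dict,
    base_strengths: pd.DataFrame,
    kernel_width: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    class_label: str = "wild_type",
) -> list[VoxelProjectionTensor]:
    """Generate voxelized projection tensors from planted mappings.

    For each (source, target) pair with positive base strength, the expected
    strength from source voxel v to target pixel q is
    ``base * exp(-|q - map(v)|^2 / (2 w^2))`` with ``w = kernel_width``
    (for w = 0 all mass falls on the pixel containing the mapped point),
    plus half-normal noise of scale ``noise_sd``.  Pairs with zero base
    strength produce no tensor.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    tensors = []
    s = flatmap.pixel_size
    for src in base_strengths.index:
        for tgt in base_strengths.columns:
            base = float(base_strengths.loc[src, tgt])
            if base <= 0 or (src, tgt) not in planted:
                continue
            m = planted[(src, tgt)]
            _check_anchors_inside(m.source.anchors, atlas.region_footprint(src), s)
            src_vox = atlas.region_voxels(src)
            tgt_px = atlas.region_footprint(tgt)
            flat_src = flatmap.flat_xy(src_vox)
            centers, _ = _map_points(flat_src, m)
            tgt_pts = (tgt_px + 0.5) * s
            d2 = ((centers[:, None, :] - tgt_pts[None, :, :]) ** 2).sum(axis=2)
            if kernel_width > 0:
                strengths = base * np.exp(-d2 / (2.0 * kernel_width ** 2))
            else:
                strengths = np.zeros_like(d2)
                nearest = d2.argmin(axis=1)
                hit = d2[np.arange(len(nearest)), nearest] <= 2 * (s / 2) ** 2 + 1e-9
                strengths[np.arange(len(nearest))[hit], nearest[hit]] = base
            if noise_sd > 0:
                rng = keyed_rng(seed, "tensor", src, tgt)
                strengths = strengths + np.abs(
                    rng.normal(0.0, noise_sd, size=strengths.shape))
            tensors.append(VoxelProjectionTensor(
                source_region=int(src), target_region=int(tgt),
                class_label=class_label, source_voxels=src_vox,
                target_pixels=tgt_px, strengths=strengths,
            ))
    return tensors


def _map_points(points: np.ndarray, m: TopographicMapping):
    bary = m.source.to_bary(points)
    return m.target.from_bary(bary), m.kernel_width


def _check_anchors_inside(anchors: np.ndarray, mask: np.ndarray, s: float) -> None:
    pts = (mask + 0.5) * s
    for a in anchors:
        if np.linalg.norm(pts - a, axis=1).min() > 1.5 * s:
            raise ValueError("planted anchor lies outside its region")


# --------------------------------------------------------------------------
# neurons and segments
# --------------------------------------------------------------------------

DEFAULT_MTYPE_FRACTIONS = {
    1: {"INT": 1.0},
    2: {"PC": 0.9, "INT": 0.1},
    3: {"PC": 0.9, "INT": 0.1},
    4: {"PC": 0.9, "INT": 0.1},
    5: {"L5_TPC": 0.45, "L5_STPC": 0.3, "L5_UPC": 0.15, "INT": 0.1},
    6: {"PC": 0.9, "INT": 0.1},
}


def synth_neurons_and_segments(
    atlas: VoxelAtlas,
    flatmap: FlatMap,
    neuron_density,
    seed: int = 0,
    segments_per_neuron: float = 3.0,
    segment_length_mean: float = 20.0,
    mtype_fractions: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place neurons and dendritic segments in the atlas.

    ``neuron_density`` is either a scalar or a map layer -> density in
    um^-3.  Counts per (region, layer) are Poisson with mean density times
    the compartment volume; soma positions are uniform within the
    compartment's voxels.  Each neuron receives 1 + Poisson(extra) segments
    co-located with its soma voxel, with positive lengths; segment flat
    positions use the segment midpoint's voxel.
    """
    if np.isscalar(neuron_density):
        density = {lay: float(neuron_density)
                   for lay in range(1, int(atlas.layer_labels.max()) + 1)}
    else:
        density = {int(k): float(v) for k, v in neuron_density.items()}
    if any(v < 0 for v in density.values()):
        raise ValueError("densities must be >= 0")
    fractions = mtype_fractions or DEFAULT_MTYPE_FRACTIONS
    rng = keyed_rng(seed, "neurons")
    vs3 = atlas.voxel_size ** 3
    neuron_rows, seg_rows = [], []
    nid = 0
    sid = 0
    for region in atlas.regions:
        for layer in sorted(density):
            vox = atlas.layer_voxels(region, layer)
            if len(vox) == 0:
                continue
            n = rng.poisson(density[layer] * len(vox) * vs3)
            if n == 0:
                continue
            choice = rng.integers(0, len(vox), size=n)
            offs = rng.random((n, 3))
            pos = (vox[choice] + offs) * atlas.voxel_size
            flat = flatmap.flat_xy(vox[choice])
            fr = fractions.get(layer, {"PC": 1.0})
            mtypes = rng.choice(list(fr), size=n, p=np.asarray(list(fr.values())))
            n_seg = 1 + rng.poisson(max(segments_per_neuron - 1, 0), size=n)
            for i in range(n):
                nid += 1
                neuron_rows.append((nid, region, layer, mtypes[i],
                                    pos[i, 0], pos[i, 1], pos[i, 2],
                                    flat[i, 0], flat[i, 1]))
                for _ in range(n_seg[i]):
                    sid += 1
                    so = (vox[choice[i]] + rng.random(3)) * atlas.voxel_size
                    length = rng.exponential(segment_length_mean) + 0.1
                    sfl = flatmap.flat_xy(vox[choice[i]])[0]
                    seg_rows.append((sid, nid, region, layer,
                                     so[0], so[1], so[2], sfl[0], sfl[1], length))
    neurons = pd.DataFrame(neuron_rows, columns=NEURON_COLUMNS)
    segments = pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS)
    return neurons, segments


def synth_axon_table(tree, source_region, n_axons: int, seed: int = 0) -> pd.DataFrame:
    """Binary axon-by-region innervation matrix sampled from a p-type tree."""
    from . import ptypes

    if source_region not in tree.leaves:
        raise ValueError(f"unknown source region {source_region!r}")
    mat = ptypes.sample_innervation_profiles(tree, source_region, n_axons, seed=seed)
    return mat


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def save_atlas(atlas: VoxelAtlas, prefix: str) -> None:
    """Write the label volumes as a compressed npz plus a JSON sidecar."""
    np.savez_compressed(prefix + ".npz", labels=atlas.labels,
                        layer_labels=atlas.layer_labels,
                        hemisphere=atlas.hemisphere)
    sidecar = {
        "voxel_size": atlas.voxel_size,
        "region_volumes": {str(k): v for k, v in atlas.region_volumes.items()},
        "modules": {str(k): v for k, v in atlas.modules.items()},
        "hierarchy_score": {str(k): v for k, v in atlas.hierarchy_score.items()},
        "n_regions_per_hemisphere": atlas.n_regions_per_hemisphere,
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_atlas(prefix: str) -> tuple[VoxelAtlas, FlatMap]:
    arrays = np.load(prefix + ".npz")
    with open(prefix + ".json") as fh:
        sidecar = json.load(fh)
    atlas = VoxelAtlas(
        labels=arrays["labels"], layer_labels=arrays["layer_labels"],
        hemisphere=arrays["hemisphere"], voxel_size=sidecar["voxel_size"],
        region_volumes={int(k): v for k, v in sidecar["region_volumes"].items()},
        modules={int(k): v for k, v in sidecar["modules"].items()},
        hierarchy_score={int(k): v for k, v in sidecar["hierarchy_score"].items()},
        n_regions_per_hemisphere=sidecar["n_regions_per_hemisphere"],
    )
    return atlas, FlatMap(pixel_size=atlas.voxel_size)
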