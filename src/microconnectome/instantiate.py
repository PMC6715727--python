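"""Stochastic instantiation of a connectome from the projection recipe.

Four steps per projection: allocate which source neurons participate
(matching first-order fractions and pairwise overlap interactions),
translate the synapse density into per-voxel counts shaped by the laminar
profile, place the synapses on dendritic segments (length-weighted, with
random offsets), and assign each synapse a presynaptic neuron with a
Gaussian weighting of the distance between the synapse and the source
neuron's mapped location in flat space.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite
from scipy.spatial import cKDTree

from ._rng import keyed_rng
from .mapping import TopographicMapping, map_source_to_target

__all__ = [
    "AllocationSpec",
    "allocate_source_neurons",
    "projection_synapse_counts",
    "sample_synapse_positions",
    "assign_presynaptic_neurons",
    "assign_projection_classes",
    "write_edge_output",
    "read_edge_output",
]

log = logging.getLogger(__name__)

SYNAPSE_COLUMNS = ["synapse_id", "source_neuron", "target_neuron",
                   "segment_id", "offset", "x", "y", "z", "projection"]


@dataclass
class AllocationSpec:
    """Participation fractions and pairwise interaction factors.

    ``fractions``: projection id -> fraction of the source population
    participating (the first-order innervation probability).
    ``interactions``: (projection a, projection b) -> conditional increase
    (>= 1); unspecified pairs default to independence.
    """

    fractions: dict
    interactions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, f in self.fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(f"fraction for {k!r} outside [0, 1]")
        for k, v in self.interactions.items():
            if v < 1:
                raise ValueError(f"interaction factor for {k!r} below 1")


def allocate_source_neurons(population: np.ndarray, spec: AllocationSpec,
                            seed: int = 0) -> dict:
    """Greedy neuron allocation with enforced pairwise overlaps.

    Each projection receives round(fraction x N) neurons sampled without
    replacement.  For every specified pair the overlap is raised to
    round(f_a x f_b x interaction x N) — when too small, neurons are
    sampled from each group and replace non-overlap members of the other
    group.  Later pairs can perturb earlier ones; the pass is a single
    greedy sweep in sorted pair order, as exact joint allocation does not
    scale.
    """
    pop = np.asarray(population)
    n = len(pop)
    if n == 0:
        raise ValueError("population is empty")
    rng = keyed_rng(seed, "allocation")
    groups = {}
    for proj in sorted(spec.fractions, key=str):
        size = int(round(spec.fractions[proj] * n))
        groups[proj] = set(pop[rng.choice(n, size=size, replace=False)])

    for (pa, pb) in sorted(spec.interactions, key=str):
        factor = spec.interactions[(pa, pb)]
        required = int(round(spec.fractions[pa] * spec.fractions[pb]
                             * factor * n))
        ga, gb = groups[pa], groups[pb]
        if required > min(len(ga), len(gb)):
            raise ValueError(
                f"infeasible overlap for pair ({pa!r}, {pb!r}): "
                f"required {required} > min group size {min(len(ga), len(gb))}")
        toggle = True
        while len(ga & gb) < required:
            # move one not-yet-shared neuron from one group into the other,
            # evicting a non-shared member to keep sizes fixed
            src, dst = (ga, gb) if toggle else (gb, ga)
            toggle = not toggle
            cand = sorted(src - dst)
            evict = sorted(dst - src)
            if not cand or not evict:
                continue
            chosen = cand[rng.integers(len(cand))]
            victim = evict[rng.integers(len(evict))]
            dst.remove(victim)
            dst.add(chosen)
    return {k: np.array(sorted(v)) for k, v in groups.items()}


def projection_synapse_counts(
    atlas,
    target_region: int,
    density: float,
    profile: np.ndarray,
    seed: int = 0,
    target_voxels: np.ndarray | None = None,
) -> dict:
    """Per-voxel expected synapse counts for one projection.

    The expected total is density x targeted volume; it is distributed
    across layers proportionally to profile value x layer thickness and
    uniformly across the voxels of each layer.  Fractional per-voxel counts
    are resolved by stochastic rounding, which preserves the expectation.
    Returns a map voxel (i, j, k) -> integer count.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    profile = np.asarray(profile, dtype=float)
    thick = atlas.layer_thicknesses()
    layers = sorted(thick)
    rng = keyed_rng(seed, "synapse-counts", target_region)
    vs3 = atlas.voxel_size ** 3

    if target_voxels is not None:
        allowed = {tuple(v) for v in np.asarray(target_voxels)}
    else:
        allowed = None

    voxels_by_layer = {}
    for lay in layers:
        vox = atlas.layer_voxels(target_region, lay)
        if allowed is not None:
            vox = np.array([v for v in vox if tuple(v) in allowed]).reshape(-1, 3)
        voxels_by_layer[lay] = vox
    n_total = sum(len(v) for v in voxels_by_layer.values())
    if n_total == 0:
        log.warning("projection into region %s targets an empty volume",
                    target_region)
        return {}

    total_expected = density * n_total * vs3
    weights = np.array([
        profile[lay - 1] * thick[lay] if len(voxels_by_layer[lay]) else 0.0
        for lay in layers
    ])
    if weights.sum() <= 0:
        return {}
    weights = weights / weights.sum()

    counts = {}
    for lay, w in zip(layers, weights):
        vox = voxels_by_layer[lay]
        if len(vox) == 0 or w == 0:
            continue
        per_voxel = total_expected * w / len(vox)
        base = int(np.floor(per_voxel))
        frac = per_voxel - base
        extra = rng.random(len(vox)) < frac
        for v, e in zip(vox, extra):
            c = base + int(e)
            if c > 0:
                counts[tuple(int(i) for i in v)] = c
    return counts


def sample_synapse_positions(counts: dict, segments: pd.DataFrame,
                             voxel_size: float, seed: int = 0) -> pd.DataFrame:
    """Place synapses on segments, length-weighted, offsets uniform in [0,1].

    Within each voxel, segments are sampled with replacement with weights
    proportional to their length.  A voxel with a positive count but no
    segments hands its count to the nearest voxel that has segments
    (logged).  Deterministic per seed.
    """
    rng = keyed_rng(seed, "synapse-positions")
    if not counts:
        return pd.DataFrame(columns=["synapse_id", "target_neuron",
                                     "segment_id", "offset", "x", "y", "z"])
    seg_voxels = (segments[["x", "y", "z"]].values // voxel_size).astype(int)
    seg_by_voxel: dict = {}
    for idx, v in enumerate(map(tuple, seg_voxels)):
        seg_by_voxel.setdefault(v, []).append(idx)
    occupied = np.array(sorted(seg_by_voxel))
    if len(occupied) == 0:
        raise ValueError("segment table is empty")

    rows = []
    sid = 0
    for voxel in sorted(counts):
        c = counts[voxel]
        if c <= 0:
            continue
        if voxel not in seg_by_voxel:
            d2 = ((occupied - np.asarray(voxel)) ** 2).sum(axis=1)
            voxel = tuple(occupied[d2.argmin()])
            log.debug("count reassigned to nearest voxel with segments: %s",
                      voxel)
        idxs = seg_by_voxel[voxel]
        lengths = segments["length"].values[idxs]
        picks = rng.choice(len(idxs), size=c, p=lengths / lengths.sum())
        offs = rng.random(c)
        for p, off in zip(picks, offs):
            row = segments.iloc[idxs[p]]
            sid += 1
            rows.append((sid, int(row["neuron_id"]), int(row["segment_id"]),
                         float(off), float(row["x"]), float(row["y"]),
                         float(row["z"])))
    return pd.DataFrame(rows, columns=["synapse_id", "target_neuron",
                                       "segment_id", "offset", "x", "y", "z"])


def assign_presynaptic_neurons(
    placed: pd.DataFrame,
    sources: pd.DataFrame,
    mapping: TopographicMapping,
    seed: int = 0,
    projection: str = "proj",
    k_nearest: int = 100,
) -> pd.DataFrame:
    """Assign each placed synapse to an allocated source neuron.

    Source neurons' flat positions are mapped through the barycentric pair
    into target flat space; per synapse the ``k_nearest`` mapped source
    locations are candidates, weighted by an isotropic Gaussian of the
    mapping's kernel width evaluated at the synapse-candidate distance.
    Zero kernel width degenerates to a uniform choice among the tied
    nearest candidates.
    """
    if len(sources) == 0:
        raise ValueError("no allocated source neurons")
    rng = keyed_rng(seed, "presyn-assignment", projection)
    src_flat = sources[["flat_x", "flat_y"]].values
    mapped, width = map_source_to_target(src_flat, mapping)
    tree = cKDTree(mapped)
    syn_flat = placed[["x", "y"]].values  # orthographic flat map: (x, y)
    k = min(k_nearest, len(sources))
    dist, idx = tree.query(syn_flat, k=k)
    dist = np.atleast_2d(dist.T).T.reshape(len(placed), k)
    idx = np.atleast_2d(idx.T).T.reshape(len(placed), k)
    src_ids = sources["neuron_id"].values

    chosen = np.empty(len(placed), dtype=src_ids.dtype)
    for i in range(len(placed)):
        d = dist[i]
        if width > 0:
            w = np.exp(-(d ** 2) / (2.0 * width ** 2))
        else:
            w = (d <= d.min() + 1e-9).astype(float)
        if w.sum() <= 0:
            w = (d <= d.min() + 1e-9).astype(float)
        w = w / w.sum()
        chosen[i] = src_ids[idx[i][rng.choice(k, p=w)]]

    out = placed.copy()
    out.insert(1, "source_neuron", chosen)
    out["projection"] = projection
    return out[SYNAPSE_COLUMNS]


def assign_projection_classes(neurons: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Map each neuron to a projection class (or None).

    Pyramidal neurons in layers 2/3, 4, 6 join their layer's class; slender
    tufted and untufted layer 5 cells join L5IT; thick tufted layer 5 cells
    join L5PT with probability one half (the rest are corticothalamic,
    outside this purely cortical model); interneurons and unknown types get
    no class.
    """
    rng = keyed_rng(seed, "projection-classes")
    out = []
    for _, row in neurons.iterrows():
        mtype, layer = row["mtype"], int(row["layer"])
        if mtype == "INT":
            out.append(None)
        elif mtype == "PC":
            if layer in (2, 3):
                out.append("L23")
            elif layer == 4:
                out.append("L4")
            elif layer == 6:
                out.append("L6")
            else:
                out.append(None)
        elif mtype in ("L5_STPC", "L5_UPC"):
            out.append("L5IT")
        elif mtype == "L5_TPC":
            out.append("L5PT" if rng.random() < 0.5 else None)
        else:
            log.warning("unknown morphological type %r", mtype)
            out.append(None)
    return pd.Series(out, index=neurons.index, name="projection_class")


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------

def write_edge_output(table: pd.DataFrame, out_dir: str,
                      target_regions: pd.Series | None = None) -> list:
    """Write the synapse table as an HDF5 edge file in the layout of the
    SONATA population format, plus one MatrixMarket neuron-by-neuron
    connection-count matrix per target region.  Returns written paths."""
    import h5py

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    edge_path = os.path.join(out_dir, "edges.h5")
    with h5py.File(edge_path, "w") as fh:
        grp = fh.create_group("edges/default")
        grp.create_dataset("source_node_id",
                           data=table["source_neuron"].values.astype(np.int64))
        grp.create_dataset("target_node_id",
                           data=table["target_neuron"].values.astype(np.int64))
        g0 = grp.create_group("0")
        g0.create_dataset("segment_id",
                          data=table["segment_id"].values.astype(np.int64))
        g0.create_dataset("offset", data=table["offset"].values.astype(float))
        for col in ("x", "y", "z"):
            g0.create_dataset(f"afferent_center_{col}",
                              data=table[col].values.astype(float))
        g0.create_dataset(
            "projection",
            data=np.array(table["projection"].astype(str).values, dtype="S"))
        g0.create_dataset("synapse_id",
                          data=table["synapse_id"].values.astype(np.int64))
    paths.append(edge_path)

    if target_regions is not None and len(table):
        n_dim = int(max(table["source_neuron"].max(),
                        table["target_neuron"].max())) + 1
        for region, group in table.groupby(
                table["target_neuron"].map(target_regions)):
            mat = sparse.coo_matrix(
                (np.ones(len(group)),
                 (group["source_neuron"].values, group["target_neuron"].values)),
                shape=(n_dim, n_dim))
            path = os.path.join(out_dir, f"conn_region_{region}.mtx")
            mmwrite(path, mat.tocsc())
            paths.append(path)
    return paths


def read_edge_output(out_dir: str) -> pd.DataFrame:
    """Round-trip reader for :func:`write_edge_output`."""
    import h5py

    with h5py.File(os.path.join(out_dir, "edges.h5"), "r") as fh:
        grp = fh["edges/default"]
        g0 = grp["0"]
        table = pd.DataFrame({
            "synapse_id": g0["synapse_id"][:],
            "source_neuron": grp["source_node_id"][:],
            "target_neuron": grp["target_node_id"][:],
            "segment_id": g0["segment_id"][:],
            "offset": g0["offset"][:],
            "x": g0["afferent_center_x"][:],
            "y": g0["afferent_center_y"][:],
            "z": g0["afferent_center_z"][:],
            "projection": [s.decode() for s in g0["projection"][:]],
        })
    return table[SYNAPSE_COLUMNS]
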