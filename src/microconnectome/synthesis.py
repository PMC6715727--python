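"""End-to-end composition helpers.

``default_fixture_inputs`` bundles a complete, seeded set of synthetic
pipeline inputs (wild-type matrices, class/module weights, frequency
tables, profile library, projection tensors with planted mappings) for a
given synthetic atlas.  ``instantiate_from_recipe`` turns a recipe plus
neuron/segment tables into one synapse-table instance, applying the
hemisphere symmetry of the fitted constraints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import keyed_rng, keyed_seed
from . import atlas as at
from . import densities as dens
from . import layer_profiles as lp
from . import mapping as mp
from .instantiate import (AllocationSpec, allocate_source_neurons,
                          assign_presynaptic_neurons,
                          assign_projection_classes,
                          projection_synapse_counts, sample_synapse_positions,
                          SYNAPSE_COLUMNS)
from .recipe import Recipe

__all__ = ["default_fixture_inputs", "instantiate_from_recipe"]


def default_fixture_inputs(atlas: at.VoxelAtlas, flatmap: at.FlatMap,
                           seed: int = 0, noise_sd: float = 0.0,
                           kernel_width: float = 0.0) -> dict:
    """Seeded synthetic inputs for every fitting stage.

    Wild-type strengths are log-normal (the heavy-tailed distribution of
    projection strengths seen in tracer data); class/module weights and
    frequency tables are random but valid; projection tensors are generated
    from planted identity mappings between hemisphere-1 region pairs.
    """
    rng = keyed_rng(seed, "fixture-inputs")
    base = sorted({atlas.base_region(r) for r in atlas.regions})
    n = len(base)

    strengths = np.exp(rng.normal(0.0, 1.0, size=(n, n)))
    ipsi = pd.DataFrame(strengths, index=base, columns=base)
    contra = pd.DataFrame(
        np.exp(rng.normal(-1.0, 1.0, size=(n, n))), index=base, columns=base)
    wild_type = dens.ProjectionMatrix(ipsi, contra)

    mods = sorted(set(atlas.modules.values()))
    classes = dens.PROJECTION_CLASSES
    class_module_weights = {
        c: pd.DataFrame(rng.random((len(mods), len(mods))) + 0.1,
                        index=mods, columns=mods)
        for c in classes
    }

    def simplex(k):
        v = rng.random(k) + 0.05
        return v / v.sum()

    class_freq = {c: simplex(6) for c in classes}
    module_freq = {(m, kind): simplex(6)
                   for m in mods for kind in ("intra", "inter")}
    counts = {(m, c, kind): int(rng.integers(1, 10))
              for m in mods for c in classes for kind in ("intra", "inter")}
    freq_tables = lp.FrequencyTables(class_freq=class_freq,
                                     module_freq=module_freq,
                                     projection_counts=counts)

    library = lp.ProfileLibrary.synthetic(atlas.layer_thicknesses())

    planted = {}
    for src in base:
        for tgt in base:
            if src != tgt:
                planted[(src, tgt)] = at.make_planted_mapping(
                    atlas, flatmap, src, tgt, kernel_width=kernel_width)
    tensors = at.synth_projection_tensor(
        atlas, flatmap, planted, ipsi, kernel_width=kernel_width,
        noise_sd=noise_sd, seed=seed)

    return {
        "wild_type": wild_type,
        "class_module_weights": class_module_weights,
        "freq_tables": freq_tables,
        "profile_library": library,
        "tensors": tensors,
        "planted_mappings": planted,
    }


def _mirror_anchors(anchors: np.ndarray, atlas: at.VoxelAtlas) -> np.ndarray:
    """Reflect flat-space anchors about the mid-sagittal plane."""
    width = atlas.labels.shape[0] * atlas.voxel_size
    out = np.asarray(anchors, dtype=float).copy()
    out[:, 0] = width - out[:, 0]
    return out


def _resolve_mapping(entry: dict, atlas: at.VoxelAtlas, flatmap: at.FlatMap,
                     src_full: int, tgt_full: int) -> mp.TopographicMapping:
    """Mapping for a concrete (hemisphere-resolved) projection instance.

    Recipe anchors are fitted on hemisphere-1 geometry; instances in the
    mirrored hemisphere reuse them reflected about the mid-sagittal plane.
    Entries without fitted anchors fall back to geometric systems.
    """
    if "source_anchors" in entry:
        src_anchors = np.asarray(entry["source_anchors"], dtype=float)
        tgt_anchors = np.asarray(entry["target_anchors"], dtype=float)
        n = atlas.n_regions_per_hemisphere
        if src_full > n:
            src_anchors = _mirror_anchors(src_anchors, atlas)
        if tgt_full > n:
            tgt_anchors = _mirror_anchors(tgt_anchors, atlas)
        return mp.TopographicMapping(
            source=mp.BarycentricSystem(src_anchors),
            target=mp.BarycentricSystem(tgt_anchors),
            kernel_width=float(entry.get("kernel_width", 0.0)))
    src_sys = mp.fit_source_anchors(atlas.region_footprint(src_full),
                                    pixel_size=flatmap.pixel_size)
    tgt_sys = mp.fit_source_anchors(atlas.region_footprint(tgt_full),
                                    pixel_size=flatmap.pixel_size)
    return mp.TopographicMapping(source=src_sys, target=tgt_sys,
                                 kernel_width=flatmap.pixel_size)


def instantiate_from_recipe(
    recipe: Recipe,
    atlas: at.VoxelAtlas,
    flatmap: at.FlatMap,
    neurons: pd.DataFrame,
    segments: pd.DataFrame,
    seed: int = 0,
    profile_library: lp.ProfileLibrary | None = None,
) -> pd.DataFrame:
    """Instantiate one synapse table from a recipe.

    Per projection class and source region: participating neurons are
    allocated according to the p-type fractions and pairwise interactions;
    per projection, densities become per-voxel counts shaped by the layer
    profile, synapses are placed on length-weighted segments, and source
    neurons are assigned by Gaussian-weighted distance in mapped flat
    space.  Deterministic per seed.
    """
    library = profile_library or lp.ProfileLibrary.synthetic(
        atlas.layer_thicknesses())
    classes = assign_projection_classes(neurons, seed=keyed_seed(seed, "cls"))
    neurons = neurons.assign(projection_class=classes.values)
    n_half = atlas.n_regions_per_hemisphere

    # neuron allocation per (class, full source region)
    allocations: dict = {}
    for cls, block in recipe.ptype_blocks.items():
        for src, spec in block.items():
            src = int(src)
            pop = neurons.query(
                "region == @src and projection_class == @cls")["neuron_id"].values
            if len(pop) == 0 or not spec["fractions"]:
                continue
            fractions = {str(t): float(f) for t, f in spec["fractions"].items()}
            interactions = {}
            for pair, inc in spec.get("interactions", {}).items():
                t1, t2 = pair.split("|")
                if t1 in fractions and t2 in fractions:
                    interactions[(t1, t2)] = float(inc)
            aspec = AllocationSpec(fractions=fractions,
                                   interactions=interactions)
            try:
                alloc = allocate_source_neurons(
                    pop, aspec, seed=keyed_seed(seed, "alloc", cls, src))
            except ValueError:
                # infeasible overlap demands at small population sizes:
                # fall back to independent allocation
                aspec = AllocationSpec(fractions=fractions)
                alloc = allocate_source_neurons(
                    pop, aspec, seed=keyed_seed(seed, "alloc", cls, src))
            for tgt, ids in alloc.items():
                allocations[(cls, src, int(tgt))] = ids

    tables = []
    for entry in recipe.projections:
        cls, side = entry["class"], entry["side"]
        bs, bt = int(entry["source"]), int(entry["target"])
        for hemi in (1, 2):
            src_full = bs if hemi == 1 else bs + n_half
            if side == "ipsi":
                tgt_full = bt if hemi == 1 else bt + n_half
            else:
                tgt_full = bt + n_half if hemi == 1 else bt
            ids = allocations.get((cls, src_full, tgt_full))
            if ids is None or len(ids) == 0:
                continue
            counts = projection_synapse_counts(
                atlas, tgt_full, entry["density"],
                library.vector(entry["layer_profile"]),
                seed=keyed_seed(seed, "counts", cls, src_full, tgt_full))
            if not counts:
                continue
            tgt_segments = segments[segments["region"] == tgt_full]
            if len(tgt_segments) == 0:
                continue
            placed = sample_synapse_positions(
                counts, tgt_segments, atlas.voxel_size,
                seed=keyed_seed(seed, "placement", cls, src_full, tgt_full))
            if len(placed) == 0:
                continue
            sources = neurons[neurons["neuron_id"].isin(ids)]
            m = _resolve_mapping(entry, atlas, flatmap, src_full, tgt_full)
            table = assign_presynaptic_neurons(
                placed, sources, m,
                seed=keyed_seed(seed, "assign", cls, src_full, tgt_full),
                projection=f"{cls}:{src_full}->{tgt_full}")
            tables.append(table)
    if not tables:
        return pd.DataFrame(columns=SYNAPSE_COLUMNS)
    out = pd.concat(tables, ignore_index=True)
    out["synapse_id"] = np.arange(1, len(out) + 1)
    return out
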