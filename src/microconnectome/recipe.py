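"""Projection recipe: composition and serialization of all fitted constraints.

The recipe is the single YAML artifact consumed by the instantiation step.
It has three sections: ``populations`` (which neurons belong to which
source/target population), ``projections`` (per projection: synapse
density, layer profile id, source and target anchor triangles, kernel
width) and ``ptypes`` (per source population: first-order innervation
fractions per target and pairwise conditional increases).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import densities as dens
from . import layer_profiles as lp
from . import mapping as mp
from . import ptypes as pt

__all__ = ["PipelineConfig", "Recipe", "build_recipe", "validate_recipe",
           "expand_to_hemispheres"]


@dataclass
class PipelineConfig:
    """Named defaults for every constant of the pipeline."""

    mean_density: float = dens.DEFAULT_MEAN_DENSITY          # um^-3
    cortex_volume_mm3: float = dens.DEFAULT_CORTEX_VOLUME_MM3
    long_range_budget: float = dens.DEFAULT_LONG_RANGE_BUDGET
    max_loss_fraction: float = 0.05
    gamma_start: float = 6.0
    gamma_step: float = 0.05
    k_nearest_sources: int = 100
    saturation_threshold: float = 0.5
    anchor_shrink: float = 0.25
    out_of_region_penalty: float = 1.0
    epsilon: float = 1e-6

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class Recipe:
    populations: list
    projections: list
    ptype_blocks: dict
    cutoff: float = 0.0
    meta: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "populations": self.populations,
            "projections": self.projections,
            "p-types": self.ptype_blocks,
            "cutoff": self.cutoff,
            "meta": self.meta,
        }, sort_keys=True)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path: str) -> "Recipe":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(populations=d["populations"], projections=d["projections"],
                   ptype_blocks=d["p-types"], cutoff=d.get("cutoff", 0.0),
                   meta=d.get("meta", {}))


def expand_to_hemispheres(split: dens.ClassSplit, atlas) -> dict:
    """Expand base-region ipsi/contra class matrices to one full
    (2R x 2R) density matrix per class covering both hemispheres.

    Connectivity is assumed symmetric between hemispheres: a full-matrix
    entry looks up the base-region ipsi entry when source and target share a
    hemisphere and the contra entry otherwise.
    """
    regions = atlas.regions
    out = {}
    for cls, pm in split.class_matrices.items():
        full = pd.DataFrame(0.0, index=regions, columns=regions)
        hemi = {r: 1 if r <= atlas.n_regions_per_hemisphere else 2
                for r in regions}
        for src in regions:
            for tgt in regions:
                bs, bt = atlas.base_region(src), atlas.base_region(tgt)
                if hemi[src] == hemi[tgt]:
                    if src != tgt:
                        full.loc[src, tgt] = pm.ipsi.loc[bs, bt]
                else:
                    full.loc[src, tgt] = pm.contra.loc[bs, bt]
        out[cls] = full
    return out


def build_recipe(
    atlas,
    flatmap,
    wild_type: dens.ProjectionMatrix,
    class_module_weights: dict,
    freq_tables: lp.FrequencyTables,
    profile_library: lp.ProfileLibrary,
    tensors: list,
    config: PipelineConfig | None = None,
    seed: int = 0,
    fit_mappings: bool = True,
) -> Recipe:
    """Run all fitting stages and assemble the recipe.

    Stages: density scaling and class splitting -> strength cutoff ->
    layer-profile assignment -> topographic-mapping fits (from the supplied
    voxelized projection tensors) -> p-type tree fit per projection class.
    Deterministic for a fixed seed.  ``fit_mappings=False`` falls back to
    geometric (source-anchor) systems in both regions, for quick runs.
    """
    config = config or PipelineConfig()
    base_regions = sorted({atlas.base_region(r) for r in atlas.regions})
    volumes = pd.Series({r: atlas.region_volumes[r] for r in base_regions})
    geom = dens.RegionGeometry(volumes=volumes)

    sigma, scaled = dens.compute_scaling_factor(
        wild_type, geom, config.long_range_budget)
    base_modules = {r: atlas.modules[r] for r in base_regions}
    split = dens.split_by_class(scaled, class_module_weights, base_modules)
    cutoff, split, loss = dens.apply_strength_cutoff(
        split, geom, config.max_loss_fraction)

    assignment = lp.assign_profiles(
        split, freq_tables, profile_library,
        {r: atlas.hierarchy_score[r] for r in base_regions}, base_modules)

    # mapping fits, per available tensor
    tensor_by_pair = {(t.source_region, t.target_region): t for t in tensors}
    mappings = {}
    for (src, tgt), tensor in sorted(tensor_by_pair.items()):
        src_mask = atlas.region_footprint(src)
        tgt_mask = atlas.region_footprint(tgt)
        src_sys = mp.fit_source_anchors(src_mask, pixel_size=flatmap.pixel_size,
                                        shrink=config.anchor_shrink)
        if fit_mappings:
            img = mp.render_projection_image(
                tensor, src_sys, flatmap.pixel_size,
                saturation_threshold=config.saturation_threshold)
            norm = mp.normalize_image(img)
            tgt_sys, err = mp.fit_target_anchors(
                norm, tgt_mask, src_sys, src_mask, flatmap.pixel_size,
                lam=config.out_of_region_penalty, seed=seed)
            width = mp.fit_kernel_width(norm, tgt_sys, flatmap.pixel_size)
        else:
            tgt_sys = mp.fit_source_anchors(
                tgt_mask, pixel_size=flatmap.pixel_size,
                shrink=config.anchor_shrink)
            err, width = 0.0, 0.0
        mappings[(src, tgt)] = mp.TopographicMapping(
            source=src_sys, target=tgt_sys, kernel_width=width, fit_error=err)

    # p-type trees per class from the expanded full matrices
    full = expand_to_hemispheres(split, atlas)
    vol_full = pd.Series(atlas.region_volumes)
    ptype_blocks = {}
    for cls, mat in full.items():
        ncd = mat / np.outer(vol_full[mat.index], vol_full[mat.columns])
        ncd = pd.DataFrame(ncd, index=mat.index, columns=mat.columns)
        # axon amount proxied by synapse count (density x target volume),
        # normalized by source volume; rescaled to median 1 over present
        # projections so the innervation-probability scale is set by the
        # class constants, not by the overall budget
        nps = mat.multiply(vol_full[mat.columns], axis=1).divide(
            vol_full[mat.index], axis=0)
        if (mat.values > 0).sum() == 0:
            continue
        med = np.median(nps.values[mat.values > 0])
        if med > 0:
            nps = nps / med
        skeleton = pt.build_tree_topology(
            ncd, gamma_start=config.gamma_start,
            gamma_step=config.gamma_step, seed=seed)
        probs = np.minimum(1.0, pt.K_CLASS[cls] * np.sqrt(nps.values))
        probs = np.clip(probs, config.epsilon, 1.0)
        m_matrix = pd.DataFrame(-np.log10(probs), index=mat.index,
                                columns=mat.columns)
        tree = pt.fit_edge_probabilities(skeleton, m_matrix,
                                         epsilon=config.epsilon)
        block = {}
        for src in mat.index:
            fractions = {
                int(tgt): float(10 ** -tree.path_length(src, tgt))
                for tgt in mat.columns if tgt != src and mat.loc[src, tgt] > 0
            }
            targets = sorted(fractions)
            interactions = {}
            for i, t1 in enumerate(targets):
                for t2 in targets[i + 1:]:
                    inc = pt.conditional_increase(tree, src, t1, t2)
                    if inc > 1.0 + 1e-9:
                        interactions[f"{t1}|{t2}"] = float(inc)
            block[int(src)] = {"fractions": fractions,
                               "interactions": interactions}
        ptype_blocks[cls] = block

    populations = [
        {"name": f"{cls}_region_{r}", "region": int(r), "class": cls}
        for cls in split.class_matrices for r in atlas.regions
    ]
    projections = []
    for (cls, side, src, tgt), pid in sorted(assignment.items()):
        d = float(split.class_matrices[cls].ipsi.loc[src, tgt] if side == "ipsi"
                  else split.class_matrices[cls].contra.loc[src, tgt])
        entry = {
            "class": cls, "side": side, "source": int(src), "target": int(tgt),
            "density": d, "layer_profile": int(pid),
        }
        m = mappings.get((src, tgt))
        if m is not None:
            entry["source_anchors"] = np.round(m.source.anchors, 6).tolist()
            entry["target_anchors"] = np.round(m.target.anchors, 6).tolist()
            entry["kernel_width"] = float(m.kernel_width)
            entry["mapping_error"] = float(m.fit_error)
        projections.append(entry)

    return Recipe(
        populations=populations, projections=projections,
        ptype_blocks=ptype_blocks, cutoff=float(cutoff),
        meta={"sigma": float(sigma), "loss_fraction": float(loss),
              "seed": int(seed)},
    )


def validate_recipe(recipe: Recipe, atlas=None) -> list:
    """Check recipe invariants; returns a machine-readable violation list
    (empty when valid).  Never raises on content problems."""
    violations = []
    region_ids = set(atlas.regions) if atlas is not None else None
    for i, proj in enumerate(recipe.projections):
        where = f"projections[{i}]"
        if proj["density"] < recipe.cutoff:
            violations.append({"where": where, "problem": "density below cutoff",
                               "value": proj["density"]})
        if not 1 <= proj.get("layer_profile", 0) <= 6:
            violations.append({"where": where, "problem": "invalid profile id",
                               "value": proj.get("layer_profile")})
        if region_ids is not None and (
                atlas.base_region(proj["source"]) not in
                {atlas.base_region(r) for r in region_ids}):
            violations.append({"where": where, "problem": "unknown region",
                               "value": proj["source"]})
    for cls, block in recipe.ptype_blocks.items():
        for src, spec in block.items():
            where = f"p-types[{cls}][{src}]"
            for tgt, f in spec.get("fractions", {}).items():
                if not 0 <= f <= 1:
                    violations.append({"where": where,
                                       "problem": "fraction outside [0, 1]",
                                       "value": f})
            for pair, inc in spec.get("interactions", {}).items():
                if inc < 1:
                    violations.append({"where": f"{where}[{pair}]",
                                       "problem": "conditional increase below 1",
                                       "value": inc})
    return violations
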