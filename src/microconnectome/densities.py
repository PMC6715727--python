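"""Volumetric synapse densities of long-range projections.

The mesoscale data provide region-to-region projection strengths that are
proportional to the mean volumetric density of projection axons in the
target region.  This module converts them into synapse densities (um^-3):
a global scaling factor matches the summed synapse count to a prescribed
long-range budget; the scaled wild-type matrix is split into five
projection-class matrices by scaling module-to-module submatrices (the
class matrices sum exactly to the wild type); projections weaker than a
loss-bounded cutoff are removed; and densities are mirrored so connectivity
is symmetric between hemispheres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PROJECTION_CLASSES",
    "DEFAULT_MEAN_DENSITY",
    "DEFAULT_CORTEX_VOLUME_MM3",
    "DEFAULT_LONG_RANGE_BUDGET",
    "ProjectionMatrix",
    "RegionGeometry",
    "ClassSplit",
    "total_synapse_budget",
    "compute_scaling_factor",
    "split_by_class",
    "apply_strength_cutoff",
    "mirror_contralateral",
]

PROJECTION_CLASSES = ("L23", "L4", "L5IT", "L5PT", "L6")

#: mean cortical synapse density, um^-3
DEFAULT_MEAN_DENSITY = 0.72
#: isocortex volume, mm^3
DEFAULT_CORTEX_VOLUME_MM3 = 123.2
#: synapse budget attributed to long-range projections
DEFAULT_LONG_RANGE_BUDGET = 68.74e9


@dataclass
class ProjectionMatrix:
    """Ipsi- and contralateral region-by-region projection matrices.

    The main diagonal of the ipsilateral matrix is forced to 0: same-region
    connectivity is local connectivity, outside this model.
    """

    ipsi: pd.DataFrame
    contra: pd.DataFrame
    units: str = "raw"  # "raw" or "um^-3"

    def __post_init__(self) -> None:
        if (self.ipsi.values < 0).any() or (self.contra.values < 0).any():
            raise ValueError("projection strengths must be non-negative")
        ipsi = self.ipsi.copy()
        np.fill_diagonal(ipsi.values, 0.0)
        self.ipsi = ipsi

    def scaled(self, factor: float, units: str) -> "ProjectionMatrix":
        return ProjectionMatrix(self.ipsi * factor, self.contra * factor,
                                units=units)


@dataclass
class RegionGeometry:
    """Region volumes (um^3) and target coverage fractions in [0, 1]."""

    volumes: pd.Series
    coverage: pd.DataFrame | None = None  # source x target; default all ones

    def __post_init__(self) -> None:
        if (self.volumes <= 0).any():
            raise ValueError("region volumes must be positive")
        if self.coverage is None:
            regs = self.volumes.index
            self.coverage = pd.DataFrame(1.0, index=regs, columns=regs)
        if ((self.coverage.values < 0) | (self.coverage.values > 1)).any():
            raise ValueError("coverage fractions must lie in [0, 1]")


@dataclass
class ClassSplit:
    """Per-class synapse-density matrices summing exactly to the wild type."""

    class_matrices: dict          # class -> ProjectionMatrix (um^-3)
    module_weights: dict          # class -> module x module DataFrame
    classes: tuple = PROJECTION_CLASSES


def total_synapse_budget(mean_density: float = DEFAULT_MEAN_DENSITY,
                         cortex_volume_mm3: float = DEFAULT_CORTEX_VOLUME_MM3
                         ) -> float:
    """Total cortical synapse count: density (um^-3) x volume (mm^3).

    1 mm^3 = 1e9 um^3; the defaults give 8.874e10 synapses.
    """
    if mean_density < 0 or cortex_volume_mm3 < 0:
        raise ValueError("inputs must be >= 0")
    return float(mean_density) * float(cortex_volume_mm3) * 1e9


def _budget_sum(pm: ProjectionMatrix, geom: RegionGeometry) -> float:
    v = geom.volumes.reindex(pm.ipsi.columns).values
    ct = geom.coverage.reindex(index=pm.ipsi.index,
                               columns=pm.ipsi.columns).values
    total = ((pm.ipsi.values + pm.contra.values) * v[None, :] * ct).sum()
    return float(total)


def compute_scaling_factor(wild_type: ProjectionMatrix,
                           geom: RegionGeometry,
                           long_range_budget: float = DEFAULT_LONG_RANGE_BUDGET
                           ) -> tuple[float, ProjectionMatrix]:
    """Scaling factor sigma such that the summed synapse count of the scaled
    matrices equals ``long_range_budget`` exactly.

    sigma * sum_{a,b} (M_i + M_c)[a,b] * V[b] * C_t[a,b] = budget.
    Returns sigma and the matrices scaled to um^-3.
    """
    denom = _budget_sum(wild_type, geom)
    if denom <= 0:
        raise ValueError("projection matrices sum to zero; cannot scale")
    sigma = float(long_range_budget) / denom
    return sigma, wild_type.scaled(sigma, units="um^-3")


def split_by_class(wild_type: ProjectionMatrix,
                   class_module_weights: dict,
                   modules: dict,
                   layer4_missing: set | None = None) -> ClassSplit:
    """Split the scaled wild-type matrix into per-class matrices.

    ``class_module_weights`` maps class -> module-by-module non-negative
    weights; weights are normalized per (source module, target module) cell
    so the five class matrices sum to the wild type exactly.  Source regions
    that lack layer 4 get a zero L4 row.
    """
    classes = tuple(class_module_weights)
    regions = list(wild_type.ipsi.index)
    mods = sorted({modules[r] for r in regions})
    layer4_missing = layer4_missing or set()

    # normalize per module-block cell
    stacked = {}
    for ms in mods:
        for mt in mods:
            tot = sum(float(class_module_weights[c].loc[ms, mt]) for c in classes)
            if tot <= 0:
                raise ValueError(
                    f"all-zero class weights for module block ({ms}, {mt})")
            stacked[(ms, mt)] = {
                c: float(class_module_weights[c].loc[ms, mt]) / tot
                for c in classes
            }

    norm_weights = {
        c: pd.DataFrame(
            [[stacked[(ms, mt)][c] for mt in mods] for ms in mods],
            index=mods, columns=mods)
        for c in classes
    }

    mod_of = np.array([modules[r] for r in regions])
    out = {}
    for c in classes:
        w = np.zeros((len(regions), len(regions)))
        for i, ms in enumerate(mod_of):
            for j, mt in enumerate(mod_of):
                w[i, j] = stacked[(ms, mt)][c]
        ipsi = wild_type.ipsi * w
        contra = wild_type.contra * w
        if c == "L4":
            for r in layer4_missing:
                if r in ipsi.index:
                    ipsi.loc[r] = 0.0
                    contra.loc[r] = 0.0
        out[c] = ProjectionMatrix(ipsi, contra, units=wild_type.units)

    # fold float rounding into the last class so the sequential class-order
    # sum reproduces the wild type bit-exactly (entries nudged by ulps where
    # a single residual correction still rounds away)
    last = classes[-1]
    for attr, wt_mat in (("ipsi", wild_type.ipsi), ("contra", wild_type.contra)):
        partial = np.zeros_like(wt_mat.values)
        for c in classes[:-1]:
            partial = partial + getattr(out[c], attr).values
        x = wt_mat.values - partial
        for _ in range(60):
            err = (partial + x) - wt_mat.values
            mask = err != 0
            if not mask.any():
                break
            target = np.where(err > 0, -np.inf, np.inf)
            x[mask] = np.nextafter(x, target)[mask]
        getattr(out[last], attr).values[:] = x
    return ClassSplit(class_matrices=out, module_weights=norm_weights,
                      classes=classes)


def _iter_projections(split: ClassSplit):
    for c, pm in split.class_matrices.items():
        for side, mat in (("ipsi", pm.ipsi), ("contra", pm.contra)):
            for src in mat.index:
                for tgt in mat.columns:
                    d = float(mat.loc[src, tgt])
                    if d > 0:
                        yield (c, side, src, tgt, d)


def apply_strength_cutoff(split: ClassSplit, geom: RegionGeometry,
                          max_loss_fraction: float = 0.05
                          ) -> tuple[float, ClassSplit, float]:
    """Remove projections weaker than a loss-bounded density cutoff.

    The cutoff is the largest value in the multiset of projection densities
    such that the synapse count removed (density x target volume x
    coverage, over all projections with density strictly below the cutoff)
    stays strictly below ``max_loss_fraction`` of the total.  Returns
    (cutoff, filtered split, realized loss fraction).
    """
    if not 0 <= max_loss_fraction < 1:
        raise ValueError("max_loss_fraction must be in [0, 1)")
    projections = list(_iter_projections(split))
    if not projections or max_loss_fraction == 0:
        return 0.0, split, 0.0

    def syn_count(c, side, src, tgt, d):
        v = float(geom.volumes[tgt])
        ct = float(geom.coverage.loc[src, tgt])
        return d * v * ct

    counts = np.array([syn_count(*p) for p in projections])
    dens = np.array([p[4] for p in projections])
    total = counts.sum()
    order = np.argsort(dens, kind="stable")
    cum = np.cumsum(counts[order])
    sorted_d = dens[order]
    cutoff = 0.0
    # candidate cutoffs are the distinct density values; removing all
    # projections with density < c removes the prefix below c
    for k, c in enumerate(sorted_d):
        removed = cum[k - 1] if k > 0 else 0.0
        # skip duplicates: only evaluate at the first index of each value
        if k > 0 and sorted_d[k - 1] == c:
            continue
        if removed < max_loss_fraction * total:
            cutoff = float(c)
    removed_total = counts[dens < cutoff].sum()
    loss = float(removed_total / total) if total > 0 else 0.0

    filtered = {}
    for cls, pm in split.class_matrices.items():
        ipsi = pm.ipsi.where(~((pm.ipsi > 0) & (pm.ipsi < cutoff)), 0.0)
        contra = pm.contra.where(~((pm.contra > 0) & (pm.contra < cutoff)), 0.0)
        filtered[cls] = ProjectionMatrix(ipsi, contra, units=pm.units)
    return cutoff, ClassSplit(class_matrices=filtered,
                              module_weights=split.module_weights,
                              classes=split.classes), loss


def mirror_contralateral(split: ClassSplit, mirror: dict) -> ClassSplit:
    """Enforce hemisphere symmetry: D[r -> t] = D[mirror(r) -> mirror(t)].

    ``mirror`` maps each region to its contralateral homologue.  Each
    mirror-pair orbit is combined by averaging its nonzero members, so data
    present on one hemisphere only is copied to the other at equal density,
    and already-symmetric input is unchanged.  Ipsilateral within-region
    entries stay 0.
    """
    for r in split.class_matrices[next(iter(split.class_matrices))].ipsi.index:
        if r not in mirror:
            raise ValueError(f"region {r!r} has no mirror partner")

    def symmetrize(mat: pd.DataFrame) -> pd.DataFrame:
        out = mat.copy()
        for src in mat.index:
            for tgt in mat.columns:
                ms, mt = mirror[src], mirror[tgt]
                if ms not in mat.index or mt not in mat.columns:
                    raise ValueError(f"mirror of ({src}, {tgt}) not in matrix")
                a, b = float(mat.loc[src, tgt]), float(mat.loc[ms, mt])
                nz = [v for v in (a, b) if v != 0]
                val = float(np.mean(nz)) if nz else 0.0
                out.loc[src, tgt] = val
                out.loc[ms, mt] = val
        np.fill_diagonal(out.values, out.values.diagonal())
        return out

    mirrored = {}
    for cls, pm in split.class_matrices.items():
        ipsi = symmetrize(pm.ipsi)
        np.fill_diagonal(ipsi.values, 0.0)
        mirrored[cls] = ProjectionMatrix(ipsi, symmetrize(pm.contra),
                                         units=pm.units)
    return ClassSplit(class_matrices=mirrored,
                      module_weights=split.module_weights,
                      classes=split.classes)
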