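"""Laminar synapse-density profiles of projections.

Every projection (projection class, source region, target region) is
assigned one of six prototype layer profiles — relative synapse density per
layer, normalized to a thickness-weighted mean of 1 over the cortical
depth.  The assignment combines three frequency constraints: base profile
frequencies per projection class, observed frequencies per source module
(intra- vs inter-module), and the feedforward/feedback character of the
projection derived from the regions' positions in the cortical hierarchy.
Profiles 1, 3, 5 are feedforward-type, 2, 4, 6 feedback-type; the
adjustment factors of the opposite type are halved before the most likely
profile is picked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FF_PROFILES",
    "FB_PROFILES",
    "ProfileLibrary",
    "FrequencyTables",
    "expected_frequencies",
    "adjustment_factors",
    "classify_ff_fb",
    "assign_profiles",
    "profile_zscores",
]

FF_PROFILES = (1, 3, 5)
FB_PROFILES = (2, 4, 6)


@dataclass
class ProfileLibrary:
    """Six prototype laminar profiles.

    ``profiles`` maps profile id (1..6) to a vector of relative density per
    layer; each must have thickness-weighted mean 1 over the depth.
    ``layer_thicknesses`` maps layer id to thickness in micrometers.
    """

    profiles: dict
    layer_thicknesses: dict

    def __post_init__(self) -> None:
        th = np.array([self.layer_thicknesses[k]
                       for k in sorted(self.layer_thicknesses)], dtype=float)
        wsum = th.sum()
        for pid, vec in self.profiles.items():
            v = np.asarray(vec, dtype=float)
            if (v < 0).any():
                raise ValueError(f"profile {pid} has negative entries")
            mean = float((v * th).sum() / wsum)
            if abs(mean - 1.0) > 1e-9:
                raise ValueError(
                    f"profile {pid} thickness-weighted mean is {mean}, not 1")

    def vector(self, pid: int) -> np.ndarray:
        return np.asarray(self.profiles[pid], dtype=float)

    @classmethod
    def synthetic(cls, layer_thicknesses: dict) -> "ProfileLibrary":
        """Six distinguishable synthetic prototypes (peaked at different
        depths), thickness-normalized."""
        n = len(layer_thicknesses)
        th = np.array([layer_thicknesses[k]
                       for k in sorted(layer_thicknesses)], dtype=float)
        profiles = {}
        for pid in range(1, 7):
            peak = (pid - 1) % n
            v = 0.2 + np.exp(-0.5 * ((np.arange(n) - peak) / 0.8) ** 2)
            v = v / ((v * th).sum() / th.sum())
            profiles[pid] = v
        return cls(profiles=profiles, layer_thicknesses=dict(layer_thicknesses))


@dataclass
class FrequencyTables:
    """Relative profile frequencies and projection counts.

    ``class_freq``: projection class -> 6-vector (sums to 1).
    ``module_freq``: (source module, "intra"|"inter") -> observed 6-vector.
    ``projection_counts``: (source module, class, "intra"|"inter") -> count.
    """

    class_freq: dict
    module_freq: dict
    projection_counts: dict

    def __post_init__(self) -> None:
        for key, vec in list(self.class_freq.items()) + list(self.module_freq.items()):
            v = np.asarray(vec, dtype=float)
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"frequency vector {key} does not sum to 1")


def expected_frequencies(module, intra_or_inter: str,
                         tables: FrequencyTables) -> np.ndarray:
    """Expected profile frequencies for projections from a module: the
    count-weighted average of the per-class frequency vectors."""
    counts = {
        c: tables.projection_counts.get((module, c, intra_or_inter), 0)
        for c in tables.class_freq
    }
    total = sum(counts.values())
    if total <= 0:
        raise ValueError(
            f"no projections counted for module {module!r} ({intra_or_inter})")
    out = np.zeros(6)
    for c, n in counts.items():
        out += n * np.asarray(tables.class_freq[c], dtype=float)
    return out / total


def adjustment_factors(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Elementwise observed / expected frequency ratios.

    Where both are 0 the factor is 1 (no evidence either way); an observed
    frequency with zero expectation is contradictory input.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if abs(obs.sum() - 1.0) > 1e-6 or abs(exp.sum() - 1.0) > 1e-6:
        raise ValueError("frequency vectors must sum to 1")
    out = np.ones_like(obs)
    nz = exp > 0
    out[nz] = obs[nz] / exp[nz]
    if ((exp == 0) & (obs > 0)).any():
        raise ValueError("observed frequency positive where expected is zero")
    return out


def classify_ff_fb(source_region, target_region, hierarchy_score: dict) -> str:
    """Feedforward iff the source sits lower in the hierarchy than the
    target; ties count as feedforward."""
    try:
        s = hierarchy_score[source_region]
        t = hierarchy_score[target_region]
    except KeyError as exc:
        raise ValueError(f"missing hierarchy score: {exc}") from None
    return "feedforward" if s <= t else "feedback"


def assign_profiles(split, tables: FrequencyTables, library: ProfileLibrary,
                    hierarchy_score: dict, modules: dict,
                    base_regions=None) -> dict:
    """Assign one profile id to every surviving projection.

    For each (class, source, target) with positive density: adjusted
    frequency = class frequency x adjustment factor (observed over expected
    per source module and intra/inter), with the factors of the
    opposite-type profiles halved; the argmax wins, ties broken toward the
    lowest profile id.  Pure function of its inputs.

    ``base_regions`` optionally maps a region label to the label used in
    the hierarchy/modules tables (e.g. collapsing hemispheres).
    """
    base = base_regions or {}

    def look(r):
        return base.get(r, r)

    out = {}
    for cls, pm in split.class_matrices.items():
        for side, mat in (("ipsi", pm.ipsi), ("contra", pm.contra)):
            for src in mat.index:
                for tgt in mat.columns:
                    if float(mat.loc[src, tgt]) <= 0:
                        continue
                    ms = modules[look(src)]
                    mt = modules[look(tgt)]
                    kind = "intra" if ms == mt else "inter"
                    expected = expected_frequencies(ms, kind, tables)
                    observed = np.asarray(tables.module_freq[(ms, kind)], float)
                    factors = adjustment_factors(observed, expected)
                    direction = classify_ff_fb(look(src), look(tgt),
                                               hierarchy_score)
                    halved = FB_PROFILES if direction == "feedforward" else FF_PROFILES
                    for pid in halved:
                        factors[pid - 1] *= 0.5
                    adjusted = np.asarray(tables.class_freq[cls], float) * factors
                    pid = int(np.argmax(adjusted)) + 1  # argmax -> lowest id
                    out[(cls, side, src, tgt)] = pid
    return out


def profile_zscores(prediction: np.ndarray, raw_profiles: np.ndarray,
                    min_experiments: int = 5) -> dict | None:
    """Per-layer z-scores of a predicted profile against raw experiments.

    z = (prediction - mean(raw)) / SD(raw) per layer; also reports the
    fraction of layers with \\|z\\| < 2.  Projections with fewer than
    ``min_experiments`` raw profiles are skipped with a warning (biological
    variability cannot be estimated).
    """
    raw = np.atleast_2d(np.asarray(raw_profiles, dtype=float))
    if raw.shape[0] < min_experiments:
        warnings.warn(f"only {raw.shape[0]} raw profiles (<{min_experiments}); "
                      "projection skipped")
        return None
    pred = np.asarray(prediction, dtype=float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (pred - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return {"z": z, "fraction_within_2sd": float((np.abs(z) < 2).mean())}
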