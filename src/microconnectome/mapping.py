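"""Topographic mapping of projections between flattened cortical regions.

Each projection is assigned a pair of barycentric coordinate systems, one in
the 2-D (flat-mapped) source region and one in the target region.  A point in
the source region is mapped to the point with identical barycentric
coordinates in the target system; because single projection axons arborize
over an extended area rather than a point, the mapped location is interpreted
as the center of an isotropic 2-D Gaussian kernel whose width is fitted per
projection.

The source system is constructed geometrically from the region outline; the
target system is fitted so that an RGB rendering of the voxelized projection
data (each color channel carrying one barycentric coordinate of the source
voxels) is best reproduced by coloring the target region according to the
candidate target system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "BarycentricSystem",
    "ProjectionImage",
    "NormalizedImage",
    "TopographicMapping",
    "fit_source_anchors",
    "render_projection_image",
    "normalize_image",
    "anchor_coloring",
    "fit_target_anchors",
    "fit_kernel_width",
    "mapping_relative_error",
    "characterize_transform",
    "map_source_to_target",
    "rgb_saturation",
]


# --------------------------------------------------------------------------
# coordinate systems
# --------------------------------------------------------------------------

@dataclass
class BarycentricSystem:
    """Three non-collinear anchor points defining affine coordinates.

    Coordinate ``i`` of a point doubles as color channel ``(R, G, B)[i]``
    when regions are rendered as images.
    """

    anchors: np.ndarray  # (3, 2) float, flat-space micrometers

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=float).reshape(3, 2)
        if abs(_signed_area(self.anchors)) < 1e-12:
            raise ValueError("anchor triangle is degenerate (collinear points)")

    def to_bary(self, points: np.ndarray) -> np.ndarray:
        """Barycentric coordinates (summing to 1) of ``points`` (n, 2)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        a, b, c = self.anchors
        T = np.column_stack([a - c, b - c])  # 2x2
        lam = np.linalg.solve(T, (p - c).T).T  # (n, 2)
        out = np.column_stack([lam, 1.0 - lam.sum(axis=1)])
        return out

    def from_bary(self, coords: np.ndarray) -> np.ndarray:
        """Cartesian points for barycentric ``coords`` (n, 3)."""
        c = np.atleast_2d(np.asarray(coords, dtype=float))
        return c @ self.anchors


@dataclass
class ProjectionImage:
    """Raw RGB rendering of a projection onto the target region's pixels."""

    pixels: np.ndarray          # (m, 2) int pixel coordinates
    raw: np.ndarray             # (m, 3) non-negative RGB
    lightness_scale: float = 1.0
    saturation_threshold: float = 0.5


@dataclass
class NormalizedImage:
    """Per-pixel normalized colors; channel sums fade to 0 where the
    projection is weak (raw sum below ``sigma_tgt``)."""

    pixels: np.ndarray          # (m, 2) int
    colors: np.ndarray          # (m, 3)
    sigma_tgt: float


@dataclass
class TopographicMapping:
    source: BarycentricSystem
    target: BarycentricSystem
    kernel_width: float = 0.0   # micrometers
    fit_error: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel_width < 0:
            raise ValueError("kernel_width must be >= 0")


def _signed_area(tri: np.ndarray) -> float:
    a, b, c = np.asarray(tri, dtype=float)
    u, v = b - a, c - a
    return 0.5 * float(u[0] * v[1] - u[1] * v[0])


def rgb_saturation(colors: np.ndarray) -> np.ndarray:
    """HSV-style saturation, (max-min)/max per RGB triple; 0 for black."""
    c = np.atleast_2d(colors)
    mx = c.max(axis=1)
    mn = c.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return sat


# --------------------------------------------------------------------------
# source system
# --------------------------------------------------------------------------

def fit_source_anchors(
    mask_pixels: np.ndarray,
    pixel_size: float = 1.0,
    shrink: float = 0.25,
) -> BarycentricSystem:
    """Anchor triangle of a region: the three pixels maximizing the sum of
    pairwise distances, each then moved ``shrink`` of the way toward the
    region centroid.

    The search is restricted to convex-hull vertices, which provably contains
    the maximizer (the objective is a sum of convex functions of each point).
    Ties are broken by lexicographic pixel order.
    """
    px = np.asarray(mask_pixels, dtype=float).reshape(-1, 2)
    if px.shape[0] < 3:
        raise ValueError("need at least 3 pixels to define anchors")
    pts = (px + 0.5) * pixel_size
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("mask is degenerate (collinear pixels)") from exc
    verts = pts[hull.vertices]
    # lexicographic ordering for deterministic tie-breaks
    order = np.lexsort((verts[:, 1], verts[:, 0]))
    verts = verts[order]
    best, best_val = None, -np.inf
    for i, j, k in combinations(range(len(verts)), 3):
        tri = verts[[i, j, k]]
        val = (
            np.linalg.norm(tri[0] - tri[1])
            + np.linalg.norm(tri[0] - tri[2])
            + np.linalg.norm(tri[1] - tri[2])
        )
        if val > best_val + 1e-9:
            best_val, best = val, tri
    centroid = pts.mean(axis=0)
    anchors = best + shrink * (centroid - best)
    return BarycentricSystem(anchors)


# --------------------------------------------------------------------------
# projection images
# --------------------------------------------------------------------------

def render_projection_image(
    tensor,
    src_system: BarycentricSystem,
    pixel_size: float,
    saturation_threshold: float = 0.5,
    lightness_scale: float | None = None,
) -> ProjectionImage:
    """Render the voxelized projection of ``tensor`` as an RGB image.

    Each source voxel contributes its 2-D projected strength times its color,
    where the color encodes the voxel's barycentric coordinates in the source
    system.  Source voxels whose color saturation falls below the threshold
    are ignored, as near-centroid colors carry no directional information.
    If ``lightness_scale`` is None it is chosen such that the brightest pixel
    has channel sum 1.
    """
    src_vox = np.asarray(tensor.source_voxels)
    flat = (src_vox[:, :2] + 0.5) * pixel_size
    colors = np.clip(src_system.to_bary(flat), 0.0, None)
    sat = rgb_saturation(colors)
    keep = sat >= saturation_threshold
    strengths = np.asarray(tensor.strengths, dtype=float)
    raw = colors[keep].T @ strengths[keep]  # (3, m)
    raw = raw.T
    if lightness_scale is None:
        mx = raw.sum(axis=1).max() if raw.size else 0.0
        lightness_scale = 1.0 / mx if mx > 0 else 1.0
    return ProjectionImage(
        pixels=np.asarray(tensor.target_pixels),
        raw=raw * lightness_scale,
        lightness_scale=float(lightness_scale),
        saturation_threshold=saturation_threshold,
    )


def normalize_image(img: ProjectionImage) -> NormalizedImage:
    """Divide each pixel by max(channel sum, sigma_tgt).

    ``sigma_tgt`` is 25% of the maximum channel sum over the image, so that
    weakly innervated pixels fade to black instead of being amplified.
    """
    sums = img.raw.sum(axis=1)
    peak = sums.max() if sums.size else 0.0
    if peak <= 0:
        warnings.warn("all-black projection image; normalization is identity")
        return NormalizedImage(pixels=img.pixels, colors=np.zeros_like(img.raw),
                               sigma_tgt=0.0)
    sigma = 0.25 * peak
    denom = np.maximum(sums, sigma)
    return NormalizedImage(pixels=img.pixels, colors=img.raw / denom[:, None],
                           sigma_tgt=float(sigma))


def anchor_coloring(system: BarycentricSystem, pixels: np.ndarray,
                    pixel_size: float) -> np.ndarray:
    """Color target pixels by their barycentric coordinates.

    Negative coordinates (outside the anchor triangle) are clipped to 0 and
    the triple renormalized to unit channel sum, matching the normalization
    of projection images so model and data colors are directly comparable.
    """
    pts = (np.asarray(pixels, dtype=float) + 0.5) * pixel_size
    return _bary_colors(system.to_bary(pts))


def _bary_colors(bary: np.ndarray) -> np.ndarray:
    c = np.clip(bary, 0.0, None)
    sums = c.sum(axis=1, keepdims=True)
    return np.divide(c, sums, out=np.zeros_like(c), where=sums > 0)


# --------------------------------------------------------------------------
# target system fit
# --------------------------------------------------------------------------

def fit_target_anchors(
    norm: NormalizedImage,
    target_mask: np.ndarray,
    source_system: BarycentricSystem,
    source_mask: np.ndarray,
    pixel_size: float,
    lam: float = 1.0,
    n_restarts: int = 8,
    seed: int = 0,
    bright_threshold: float = 0.5,
) -> tuple[BarycentricSystem, float]:
    """Optimize target anchors to reproduce the normalized projection colors.

    The objective is the mean per-pixel L1 color difference between the
    anchor-induced coloring and ``norm`` over bright pixels (channel sum >=
    ``bright_threshold``; dark pixels carry no mapping signal by
    construction of the normalization), plus ``lam`` times the fraction of
    the source region whose mapped image falls outside the target mask.

    Derivative-free simplex search with multiple restarts: the six label
    permutations of the target region's own geometric anchor triangle (these
    cover all rotation/reflection hypotheses of the color scheme), plus
    seeded perturbations.  Returns the best system and its relative error
    against the fitted coloring (``mapping_relative_error``).
    """
    target_mask = np.asarray(target_mask).reshape(-1, 2)
    if target_mask.shape[0] == 0:
        raise ValueError("empty target mask")
    source_mask = np.asarray(source_mask).reshape(-1, 2)
    rng = np.random.default_rng(seed)

    bright = norm.colors.sum(axis=1) >= bright_threshold
    if not bright.any():
        bright = np.ones(len(norm.colors), dtype=bool)
    data_px = norm.pixels[bright]
    data_colors = norm.colors[bright]
    data_pts = (data_px + 0.5) * pixel_size

    tgt_pixel_set = {(int(a), int(b)) for a, b in target_mask}
    src_pts = (source_mask + 0.5) * pixel_size
    src_bary = source_system.to_bary(src_pts)

    def objective(x: np.ndarray) -> float:
        tri = x.reshape(3, 2)
        if abs(_signed_area(tri)) < 1e-6:
            return 1e6
        sys_ = BarycentricSystem(tri.copy())
        model = _bary_colors(sys_.to_bary(data_pts))
        j_color = np.abs(model - data_colors).sum(axis=1).mean()
        mapped = src_bary @ tri
        mapped_px = np.floor(mapped / pixel_size).astype(int)
        outside = sum(
            (int(a), int(b)) not in tgt_pixel_set for a, b in mapped_px
        )
        return j_color + lam * outside / len(mapped_px)

    base = fit_source_anchors(target_mask, pixel_size=pixel_size)
    # orientation hypotheses: the source triangle carried to the target
    # centroid under each of the 8 axis-aligned rotation/reflection
    # transforms, plus all label permutations of the target's own triangle
    c_src = src_pts.mean(axis=0)
    c_tgt = ((target_mask + 0.5) * pixel_size).mean(axis=0)
    starts = []
    for k in range(4):
        th = np.pi / 2 * k
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        for refl in (False, True):
            lin = rot @ np.diag([1.0, -1.0]) if refl else rot
            starts.append((source_system.anchors - c_src) @ lin.T + c_tgt)
    starts += [base.anchors[list(p)] for p in permutations(range(3))]
    scale = np.ptp(target_mask, axis=0).max() * pixel_size * 0.1 + pixel_size
    while len(starts) < max(n_restarts, 14):
        starts.append(base.anchors + rng.normal(0, scale, size=(3, 2)))

    best_x, best_j = None, np.inf
    converged = False
    for s in starts:
        res = minimize(
            objective, np.asarray(s, dtype=float).ravel(),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 4000},
        )
        if res.fun < best_j:
            best_j, best_x = res.fun, res.x
            converged = converged or res.success
    if not converged:
        warnings.warn("target-anchor optimization did not fully converge; "
                      "returning best solution found")
    fitted = BarycentricSystem(best_x.reshape(3, 2))
    model_full = anchor_coloring(fitted, data_px, pixel_size)
    fit_error = mapping_relative_error(model_full, data_colors)
    return fitted, float(fit_error)


def fit_kernel_width(
    norm: NormalizedImage,
    fitted: BarycentricSystem,
    pixel_size: float,
    widths: np.ndarray | None = None,
) -> float:
    """Fit the Gaussian kernel width of the point-to-area mapping.

    Chooses, on a logarithmic grid, the width for which blurring the
    anchor-induced coloring with an isotropic Gaussian best reproduces the
    distribution of color saturation values observed in ``norm``
    (Kolmogorov-Smirnov distance between the two saturation samples).
    """
    if widths is None:
        widths = np.concatenate([[0.0], np.geomspace(0.25, 32.0, 15) * pixel_size])
    px = norm.pixels
    lo = px.min(axis=0)
    shape = px.max(axis=0) - lo + 1
    grid = np.zeros((shape[0], shape[1], 3))
    mask = np.zeros(tuple(shape), dtype=bool)
    idx = (px - lo).astype(int)
    grid[idx[:, 0], idx[:, 1]] = anchor_coloring(fitted, px, pixel_size)
    mask[idx[:, 0], idx[:, 1]] = True

    data_sat = np.sort(rgb_saturation(norm.colors))
    best_w, best_ks = float(widths[0]), np.inf
    for w in widths:
        if w > 0:
            blurred = np.stack(
                [ndimage.gaussian_filter(grid[:, :, c], sigma=w / pixel_size)
                 for c in range(3)], axis=-1)
        else:
            blurred = grid
        model_sat = np.sort(rgb_saturation(blurred[mask]))
        ks = _ks_statistic(model_sat, data_sat)
        if ks < best_ks - 1e-12:
            best_ks, best_w = ks, float(w)
    return best_w


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic for pre-sorted samples."""
    all_vals = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, all_vals, side="right") / len(a)
    cdf_b = np.searchsorted(b, all_vals, side="right") / len(b)
    return float(np.abs(cdf_a - cdf_b).max())


# --------------------------------------------------------------------------
# error metric and transform characterization
# --------------------------------------------------------------------------

def mapping_relative_error(m_img: np.ndarray, n_img: np.ndarray) -> float:
    """Sum of absolute differences of two images, divided by their average
    value and by the number of pixels.  0 iff identical; symmetric."""
    m = np.asarray(m_img, dtype=float)
    n = np.asarray(n_img, dtype=float)
    if m.shape != n.shape:
        raise ValueError("images must have the same shape")
    avg = np.mean((m + n) / 2.0)
    if avg == 0:
        return 0.0
    return float(np.abs(m - n).sum() / avg / m.shape[0])


def characterize_transform(mapping: TopographicMapping) -> dict:
    """Reflection / rotation class of the source-to-target affine map.

    The linear part is decomposed as Rot(theta) . diag(1, -1)^k: reflection
    iff the signed area of the anchor triangle flips sign, rotation is the
    polar-decomposition angle (after factoring out the reflection) snapped to
    the nearest multiple of 90 degrees.
    """
    src, tgt = mapping.source.anchors, mapping.target.anchors
    a_src, a_tgt = _signed_area(src), _signed_area(tgt)
    if abs(a_src) < 1e-12 or abs(a_tgt) < 1e-12:
        raise ValueError("degenerate anchor triangle")
    # linear part of the affine map taking source anchors to target anchors
    ds = (src[1:] - src[0]).T  # 2x2
    dt = (tgt[1:] - tgt[0]).T
    lin = dt @ np.linalg.inv(ds)
    reflection = bool(np.linalg.det(lin) < 0)
    if reflection:
        lin = lin @ np.diag([1.0, -1.0])
    u, _, vt = np.linalg.svd(lin)
    rot = u @ vt
    if np.linalg.det(rot) < 0:  # numerical guard
        rot = u @ np.diag([1.0, -1.0]) @ vt
    theta = np.degrees(np.arctan2(rot[1, 0], rot[0, 0])) % 360.0
    snapped = int(round(theta / 90.0)) % 4 * 90
    return {"reflection": reflection, "rotation_deg": snapped}


def map_source_to_target(points: np.ndarray,
                         mapping: TopographicMapping) -> tuple[np.ndarray, float]:
    """Map flat-space points through the barycentric pair; returns the kernel
    centers in target flat space plus the kernel width.  Extrapolation
    outside the source triangle is allowed."""
    bary = mapping.source.to_bary(points)
    return mapping.target.from_bary(bary), mapping.kernel_width
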