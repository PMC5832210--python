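"""118-feature PET radiomics extraction from an SUV image and ROI mask.

The feature vector is partitioned into four families:

* 16 first-order statistics of the masked SUV distribution (``stats_*``),
* 13 shape/size descriptors of the binary mask (``shape_*``),
* 45 intensity-volume-histogram descriptors (``ivh_*``),
* 44 texture descriptors from grey-level co-occurrence (22, ``glcm_*``),
  run-length (11, ``glrlm_*``) and size-zone (11, ``glszm_*``) matrices.

Texture matrices are computed on SUV values discretized with a fixed bin
width (default 0.5 SUV):

    I_D(x) = ceil(I(x) / W) - min_ROI ceil(I(x) / W) + 1

so grey levels start at 1.  Voxels are neighbors under 26-connectivity;
GLCM and GLRLM are averaged over the 13 unique directions (offset pairs
modulo sign) at a distance of one voxel, while the GLSZM is a single
directionless matrix of 26-connected equal-level zones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import marching_cubes, mesh_surface_area

from .images import ROIMask, SUVImage

__all__ = [
    "DiscretizedROI",
    "discretize",
    "direction_set",
    "compute_glcm",
    "compute_glrlm",
    "compute_glszm",
    "first_order_features",
    "shape_features",
    "ivh_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "extract_all",
    "FAMILY_SIZES",
    "feature_names",
]

FAMILY_SIZES = {"stats": 16, "shape": 13, "ivh": 45, "glcm": 22, "glrlm": 11, "glszm": 11}


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer grey levels per ROI voxel, labels contiguous-start from 1.

    ``volume`` holds the labels on the full grid (0 outside the ROI) so
    texture matrices can address spatial neighbors; ``n_levels`` is the
    maximum label Ng.
    """

    volume: np.ndarray
    mask: np.ndarray
    bin_width: float
    n_levels: int

    @property
    def labels(self) -> np.ndarray:
        """Grey levels of the ROI voxels only (1..Ng)."""
        return self.volume[self.mask]


def discretize(image: SUVImage, mask: ROIMask, bin_width: float = 0.5) -> DiscretizedROI:
    """Fixed-bin-width discretization of the masked SUV values."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask.check_congruent(image)
    ind = mask.indicator
    if not ind.any():
        raise ValueError("empty mask")
    vals = image.values[ind]
    if np.any(vals < 0):
        raise ValueError("masked SUV values must be non-negative")
    ceiled = np.ceil(vals / bin_width).astype(np.int64)
    labels = ceiled - ceiled.min() + 1
    volume = np.zeros(image.values.shape, dtype=np.int64)
    volume[ind] = labels
    return DiscretizedROI(volume=volume, mask=ind, bin_width=float(bin_width),
                          n_levels=int(labels.max()))


def direction_set() -> list[tuple[int, int, int]]:
    """The 13 unique 26-connectivity offsets modulo sign.

    Exactly one representative of each {d, -d} pair of the 26 neighbor
    offsets in {-1,0,1}^3 \\ {0}; the first nonzero component is positive.
    """
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                first = next(c for c in d if c != 0)
                if first > 0:
                    dirs.append(d)
    assert len(dirs) == 13
    return dirs


def _bbox(mask: np.ndarray, pad: int = 1) -> tuple[slice, slice, slice]:
    """Bounding-box slices (padded, clipped) around the set voxels."""
    slices = []
    for ax in range(3):
        proj = np.any(mask, axis=tuple(a for a in range(3) if a != ax))
        idx = np.where(proj)[0]
        lo = max(int(idx[0]) - pad, 0)
        hi = min(int(idx[-1]) + 1 + pad, mask.shape[ax])
        slices.append(slice(lo, hi))
    return tuple(slices)


def _shift_pair(vol: np.ndarray, roi: np.ndarray, d: tuple[int, int, int]):
    """Grey levels of (voxel, neighbor at +d) pairs where both lie in the ROI."""
    sl_a, sl_b = [], []
    for c, n in zip(d, vol.shape):
        if c == 0:
            sl_a.append(slice(None)); sl_b.append(slice(None))
        elif c > 0:
            sl_a.append(slice(0, n - c)); sl_b.append(slice(c, n))
        else:
            sl_a.append(slice(-c, n)); sl_b.append(slice(0, n + c))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    both = roi[sl_a] & roi[sl_b]
    return vol[sl_a][both], vol[sl_b][both]


def compute_glcm(disc: DiscretizedROI) -> np.ndarray:
    """Symmetric GLCM averaged over the 13 directions at distance 1.

    Each directional matrix is symmetrized and normalized to sum 1 before
    averaging; directions with no in-ROI voxel pair are excluded.
    """
    ng = disc.n_levels
    sub = _bbox(disc.mask)
    vol, roi = disc.volume[sub], disc.mask[sub]
    acc = np.zeros((ng, ng))
    contributing = 0
    for d in direction_set():
        a, b = _shift_pair(vol, roi, d)
        if a.size == 0:
            continue
        counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
        counts = counts + counts.T  # symmetrize
        acc += counts / counts.sum()
        contributing += 1
    if contributing == 0:
        raise ValueError("ROI has no neighboring voxel pair in any direction")
    return acc / contributing


def compute_glrlm(disc: DiscretizedROI) -> np.ndarray:
    """Run-length matrix averaged over the 13 directions.

    Entry (g-1, r-1) is the number of maximal collinear runs of grey level
    g and length r; runs are confined to the ROI.
    """
    ng = disc.n_levels
    sub = _bbox(disc.mask)
    vol, roi = disc.volume[sub], disc.mask[sub]
    rmax = max(vol.shape)
    acc = np.zeros((ng, rmax))
    for d in direction_set():
        # a voxel starts a run if its predecessor along -d is outside the
        # ROI or has a different grey level
        prev_same = np.zeros(vol.shape, dtype=bool)
        sl_a, sl_b = _pair_slices(vol.shape, d)
        same = roi[sl_a] & roi[sl_b] & (vol[sl_a] == vol[sl_b])
        prev_same[sl_b] = same
        starts = roi & ~prev_same
        # walk along +d from each run start, counting equal-level voxels
        next_same = np.zeros(vol.shape, dtype=bool)
        next_same[sl_a] = same
        coords = np.array(np.nonzero(starts)).T
        lengths = np.ones(len(coords), dtype=np.int64)
        cur = coords
        alive = np.arange(len(coords))
        step = np.array(d)
        while alive.size:
            cont = next_same[tuple(cur.T)]
            alive = alive[cont]
            if alive.size == 0:
                break
            cur = cur[cont] + step
            lengths[alive] += 1
        g = vol[tuple(coords.T)]
        mat = np.zeros((ng, rmax))
        np.add.at(mat, (g - 1, lengths - 1), 1.0)
        acc += mat
    return acc / 13.0


def _pair_slices(shape, d):
    sl_a, sl_b = [], []
    for c, n in zip(d, shape):
        if c == 0:
            sl_a.append(slice(None)); sl_b.append(slice(None))
        elif c > 0:
            sl_a.append(slice(0, n - c)); sl_b.append(slice(c, n))
        else:
            sl_a.append(slice(-c, n)); sl_b.append(slice(0, n + c))
    return tuple(sl_a), tuple(sl_b)


def compute_glszm(disc: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix: 26-connected zones of equal grey level (directionless)."""
    ng = disc.n_levels
    sub = _bbox(disc.mask)
    vol, roi = disc.volume[sub], disc.mask[sub]
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    smax = 1
    for g in range(1, ng + 1):
        level = (vol == g) & roi
        if not level.any():
            continue
        lab, n = ndimage.label(level, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((g, int(s)))
            smax = max(smax, int(s))
    mat = np.zeros((ng, smax))
    for g, s in zones:
        mat[g - 1, s - 1] += 1.0
    return mat


# --- first-order ------------------------------------------------------------

def first_order_features(image: SUVImage, mask: ROIMask,
                         bin_width: float = 0.5) -> dict[str, float]:
    """16 first-order statistics of the masked SUV distribution.

    Entropy and uniformity use the same fixed-bin-width histogram as the
    texture matrices; SUV-peak is the ROI-restricted mean over the 3x3x3
    voxel neighborhood centered on the hottest voxel (~1.5 cc at the
    development spacing).
    """
    mask.check_congruent(image)
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    x = image.values[mask.indicator].astype(float)
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    var = float(x.var(ddof=0))
    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))
    else:
        skew = 0.0
        kurt = 0.0
    disc = discretize(image, mask, bin_width)
    p = np.bincount(disc.labels)[1:].astype(float)
    p = p[p > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    # SUV-peak
    hot = np.unravel_index(np.argmax(np.where(mask.indicator, image.values, -np.inf)),
                           image.values.shape)
    lo = [max(c - 1, 0) for c in hot]
    hi = [min(c + 2, s) for c, s in zip(hot, image.values.shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    nb = mask.indicator[box]
    peak = float(image.values[box][nb].mean())

    return {
        "stats_min": float(x.min()),
        "stats_max": float(x.max()),
        "stats_range": float(x.max() - x.min()),
        "stats_mean": mean,
        "stats_median": float(np.median(x)),
        "stats_sd": sd,
        "stats_variance": var,
        "stats_skewness": skew,
        "stats_kurtosis": kurt,
        "stats_energy": float((x ** 2).sum()),
        "stats_entropy": entropy,
        "stats_uniformity": uniformity,
        "stats_mad": float(np.mean(np.abs(x - mean))),
        "stats_rms": float(np.sqrt(np.mean(x ** 2))),
        "stats_suv_peak": peak,
        "stats_cov": sd / mean if mean != 0 else 0.0,
    }


# --- shape ------------------------------------------------------------------

def _max_pairwise_distance(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; convex hull prunes candidates."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 10 and points.shape[1] >= 2:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (flat) point sets: brute force below
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: ROIMask, spacing=None) -> dict[str, float]:
    """13 shape/size descriptors of the binary mask.

    Volume is reported in cc; surface area from marching-cubes
    triangulation at iso-level 0.5 with physical spacing; diameters are
    largest pairwise distances between voxel corners in mm (the full
    physical extent of the mask).  Surface-to-volume ratio is reported
    in 1/cm.  Elongation and flatness derive from the principal-axis
    eigenvalues of the voxel-center cloud (both 1 for a single voxel).
    """
    if spacing is None:
        spacing = mask.spacing
    ind = mask.indicator
    if not ind.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    n = int(ind.sum())
    volume_mm3 = n * float(spacing.prod())

    padded = np.pad(ind.astype(float), 1)
    verts, faces, *_ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area_mm2 = float(mesh_surface_area(verts, faces))

    idx = np.array(np.nonzero(ind)).T
    coords = idx * spacing  # voxel centers, mm
    # diameters measured between voxel corners (full physical extent): a
    # cube of side a measures a*sqrt(3), a ball of radius r measures 2r
    corner_offsets = np.array([[sx, sy, sz] for sx in (-0.5, 0.5)
                               for sy in (-0.5, 0.5) for sz in (-0.5, 0.5)])
    corners = (idx[:, None, :] + corner_offsets[None, :, :]).reshape(-1, 3) * spacing
    max3d = _max_pairwise_distance(np.unique(corners, axis=0))
    # maximum in-plane diameter per orthogonal plane, maximized over slices
    plane_names = {0: "shape_max_2d_diameter_x", 1: "shape_max_2d_diameter_y",
                   2: "shape_max_2d_diameter_z"}
    corner2d = np.array([[sa, sb] for sa in (-0.5, 0.5) for sb in (-0.5, 0.5)])
    diam2d = {}
    for ax, name in plane_names.items():
        keep = [a for a in range(3) if a != ax]
        best = 0.0
        for s in np.unique(idx[:, ax]):
            pts = idx[idx[:, ax] == s][:, keep].astype(float)
            pts = (pts[:, None, :] + corner2d[None, :, :]).reshape(-1, 2)
            best = max(best, _max_pairwise_distance(np.unique(pts, axis=0) * spacing[keep]))
        diam2d[name] = best

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    if eig[0] > 0:
        elongation = float(np.sqrt(eig[1] / eig[0]))
        flatness = float(np.sqrt(eig[2] / eig[0]))
    else:
        elongation = 1.0
        flatness = 1.0

    r_equiv = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume_mm3) ** (2.0 / 3.0) / area_mm2
    return {
        "shape_volume_cc": volume_mm3 / 1000.0,
        "shape_surface_area_mm2": area_mm2,
        "shape_surface_to_volume_ratio": area_mm2 / volume_mm3 * 10.0,  # 1/cm
        "shape_sphericity": float(sphericity),
        "shape_compactness1": float(volume_mm3 / (np.sqrt(np.pi) * area_mm2 ** 1.5)),
        "shape_compactness2": float(36.0 * np.pi * volume_mm3 ** 2 / area_mm2 ** 3),
        "shape_spherical_disproportion": float(area_mm2 / (4.0 * np.pi * r_equiv ** 2)),
        "shape_max_3d_diameter": max3d,
        **diam2d,
        "shape_elongation": elongation,
        "shape_flatness": flatness,
    }


# --- intensity-volume histogram ---------------------------------------------

def ivh_features(image: SUVImage, mask: ROIMask) -> dict[str, float]:
    """45 intensity-volume-histogram descriptors.

    The IVH gives the fraction of ROI volume with SUV at or above a
    threshold.  Descriptors: relative-threshold volume fractions Vx at
    x = 10..90% of the ROI intensity range (9); intensity thresholds Ix of
    the hottest x% of the volume, x = 10..90 (9); the differences
    Vx - V(100-x) and Ix - I(100-x) for x = 10..40 (8); absolute-threshold
    volume fractions and residual volumes in cc at SUV 1..9 (18); and the
    area under the range-normalized IVH curve (1).
    """
    mask.check_congruent(image)
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    x = image.values[mask.indicator].astype(float)
    n = x.size
    lo, hi = float(x.min()), float(x.max())
    rng = hi - lo
    voxel_cc = float(np.prod(mask.spacing)) / 1000.0

    def frac_at_or_above(th: float) -> float:
        return float((x >= th).sum()) / n

    feats: dict[str, float] = {}
    vx = {}
    for pct in range(10, 100, 10):
        th = lo + pct / 100.0 * rng
        vx[pct] = frac_at_or_above(th) if rng > 0 else 1.0
        feats[f"ivh_v{pct}"] = vx[pct]
    xs = np.sort(x)[::-1]
    ix = {}
    for pct in range(10, 100, 10):
        k = int(np.ceil(pct / 100.0 * n))
        ix[pct] = float(xs[k - 1])
        feats[f"ivh_i{pct}"] = ix[pct]
    for pct in (10, 20, 30, 40):
        feats[f"ivh_v{pct}_minus_v{100 - pct}"] = vx[pct] - vx[100 - pct]
    for pct in (10, 20, 30, 40):
        feats[f"ivh_i{pct}_minus_i{100 - pct}"] = ix[pct] - ix[100 - pct]
    for suv in range(1, 10):
        feats[f"ivh_vf_suv{suv}"] = frac_at_or_above(float(suv))
    for suv in range(1, 10):
        feats[f"ivh_vol_cc_suv{suv}"] = float((x >= suv).sum()) * voxel_cc
    # AUC of the IVH over the normalized intensity range; the step-function
    # integral collapses to (mean - min) / range, and is 1 for a constant ROI
    feats["ivh_auc"] = float((x.mean() - lo) / rng) if rng > 0 else 1.0
    assert len(feats) == 45
    return feats


# --- texture features -------------------------------------------------------

def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(mat: np.ndarray) -> dict[str, float]:
    """22 grey-level co-occurrence features from a normalized symmetric GLCM.

    Correlation-type features fall back to 0 on a degenerate single-level
    matrix (IMC1 = 0, IMC2 = 0, correlation = 0).
    """
    p = np.asarray(mat, dtype=float)
    p = p / p.sum()
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    pxy_sum = np.zeros(2 * ng + 1)
    np.add.at(pxy_sum, (ii + jj).ravel(), p.ravel())
    pxy_diff = np.zeros(ng)
    np.add.at(pxy_diff, np.abs(ii - jj).ravel(), p.ravel())
    ks = np.arange(2 * ng + 1)
    sum_avg = float((ks * pxy_sum).sum())

    hxy = _entropy2(p.ravel())
    pxpy = np.outer(px, py)
    nz = pxpy > 0
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = _entropy2(pxpy.ravel())
    hx = _entropy2(px)
    hy = _entropy2(py)

    if sigx > 0 and sigy > 0:
        correlation = float(((ii * jj * p).sum() - mux * muy) / (sigx * sigy))
    else:
        correlation = 0.0
    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(max(imc2_arg, 0.0)))

    off = ii != jj
    inv_var = float((p[off] / (ii - jj)[off] ** 2).sum()) if off.any() else 0.0

    return {
        "glcm_autocorrelation": float((ii * jj * p).sum()),
        "glcm_cluster_prominence": float((((ii + jj) - mux - muy) ** 4 * p).sum()),
        "glcm_cluster_shade": float((((ii + jj) - mux - muy) ** 3 * p).sum()),
        "glcm_cluster_tendency": float((((ii + jj) - mux - muy) ** 2 * p).sum()),
        "glcm_contrast": float(((ii - jj) ** 2 * p).sum()),
        "glcm_correlation": correlation,
        "glcm_difference_entropy": _entropy2(pxy_diff),
        "glcm_dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "glcm_energy": float((p ** 2).sum()),
        "glcm_entropy": hxy,
        "glcm_homogeneity1": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "glcm_homogeneity2": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "glcm_idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "glcm_inverse_variance": inv_var,
        "glcm_max_probability": float(p.max()),
        "glcm_sum_average": sum_avg,
        "glcm_sum_entropy": _entropy2(pxy_sum),
        "glcm_sum_variance": float(((ks - sum_avg) ** 2 * pxy_sum).sum()),
        "glcm_variance": float(((ii - mux) ** 2 * p).sum()),
    }


def _rl_features(mat: np.ndarray, n_voxels: int, prefix: str,
                 names: tuple[str, ...]) -> dict[str, float]:
    """Shared run-length / size-zone feature arithmetic.

    ``mat[g-1, r-1]`` counts runs (zones) of grey level g and length
    (size) r; ``n_voxels`` is the ROI voxel count.
    """
    m = np.asarray(mat, dtype=float)
    ng, rmax = m.shape
    g = np.arange(1, ng + 1)[:, None].astype(float)
    r = np.arange(1, rmax + 1)[None, :].astype(float)
    total = m.sum()
    if total == 0:
        raise ValueError("empty run/zone matrix")
    sre = (m / r ** 2).sum() / total
    lre = (m * r ** 2).sum() / total
    gln = (m.sum(axis=1) ** 2).sum() / total
    rln = (m.sum(axis=0) ** 2).sum() / total
    rp = total / n_voxels
    lgre = (m / g ** 2).sum() / total
    hgre = (m * g ** 2).sum() / total
    srlge = (m / (g ** 2 * r ** 2)).sum() / total
    srhge = (m * g ** 2 / r ** 2).sum() / total
    lrlge = (m * r ** 2 / g ** 2).sum() / total
    lrhge = (m * g ** 2 * r ** 2).sum() / total
    vals = (sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge)
    return {f"{prefix}_{n}": float(v) for n, v in zip(names, vals)}


_GLRLM_NAMES = ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
                "srlge", "srhge", "lrlge", "lrhge")
_GLSZM_NAMES = ("sae", "lae", "gln", "zsn", "zp", "lgze", "hgze",
                "salge", "sahge", "lalge", "lahge")


def glrlm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """11 run-length features (SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE,
    SRHGE, LRLGE, LRHGE)."""
    return _rl_features(mat, n_voxels, "glrlm", _GLRLM_NAMES)


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """11 size-zone features, the zone-based analogues of the run-length set."""
    return _rl_features(mat, n_voxels, "glszm", _GLSZM_NAMES)


def extract_all(image: SUVImage, mask: ROIMask, bin_width: float = 0.5) -> dict[str, float]:
    """The full 118-feature vector for one ROI, family-prefixed names.

    Families: 16 first-order, 13 shape, 45 IVH, 22 GLCM, 11 GLRLM,
    11 GLSZM.  Deterministic in (image, mask, bin_width).
    """
    disc = discretize(image, mask, bin_width)
    n_vox = mask.n_voxels
    feats: dict[str, float] = {}
    feats.update(first_order_features(image, mask, bin_width))
    feats.update(shape_features(mask))
    feats.update(ivh_features(image, mask))
    feats.update(glcm_features(compute_glcm(disc)))
    feats.update(glrlm_features(compute_glrlm(disc), n_vox))
    feats.update(glszm_features(compute_glszm(disc), n_vox))
    assert len(feats) == 118
    bad = {k: v for k, v in feats.items() if not np.isfinite(v)}
    if bad:
        raise ValueError(f"non-finite features: {sorted(bad)}")
    return feats


def feature_names() -> list[str]:
    """Canonical ordering of the 118 feature names (tiny probe extraction)."""
    rng = np.random.default_rng(0)
    img = SUVImage(rng.uniform(1.0, 5.0, size=(4, 4, 4)))
    msk = ROIMask(np.ones((4, 4, 4), dtype=bool))
    return list(extract_all(img, msk))
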