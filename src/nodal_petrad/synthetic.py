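"""Synthetic PET phantoms, replicate segmentations, and survival outcomes.

The generator emulates the data layout of a node-positive NSCLC
FDG-PET cohort so the extraction / pre-selection / modeling stages can
be exercised with known ground truth:

* one heterogeneous primary-tumor blob plus 1-5 metastatic lymph-node
  blobs on a PET grid at the development voxel spacing
  (4.0728 x 4.0728 x 3 mm),
* replicate segmentations (controlled boundary perturbations) standing
  in for test-retest and inter-observer delineations,
* right-censored Weibull overall-survival times whose log-hazard is
  linear in chosen ground-truth features.

Blobs are random ellipsoids (axis ratio <= 2) so shape features vary;
uptake inside a blob is the blob mean times a correlated lognormal
texture field (Gaussian-filtered white noise, exponentiated), keeping
SUV strictly positive with tunable heterogeneity.  Each patient draws
from an RNG stream keyed by (master seed, patient index), so cohorts
are reproducible independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import ROIMask, SUVImage, DEFAULT_SPACING

__all__ = [
    "PhantomSpec",
    "SurvivalSpec",
    "PlacementError",
    "simulate_patient_images",
    "perturb_segmentation",
    "simulate_survival",
]


class PlacementError(RuntimeError):
    """Raised when blobs cannot be placed disjointly within the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic patient phantom.

    ``texture_scale`` is the correlation length (in voxels) of the
    multiplicative noise field; ``noise_cv`` its coefficient of
    variation (0 gives uniform uptake inside each blob).
    """

    grid_shape: tuple[int, int, int] = (44, 44, 36)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    n_nodes: int = 2
    tumor_suv_mean: float = 8.0
    node_suv_mean: float = 5.0
    tumor_radius_vox: float = 5.0
    node_radius_vox: float = 3.5
    node_size_sigma: float = 0.7
    texture_scale: float = 1.0
    noise_cv: float = 0.2
    background_suv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("cohort is node-positive: n_nodes must be >= 1")
        for name in ("tumor_suv_mean", "node_suv_mean", "background_suv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_cv < 0 or self.texture_scale < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SurvivalSpec:
    """Weibull proportional-hazards outcome model with administrative censoring.

    ``betas`` maps ground-truth feature names to log-hazard coefficients
    per standard deviation of the feature across the cohort.
    """

    n_patients: int
    betas: dict[str, float] = field(default_factory=dict)
    baseline_shape: float = 1.2
    baseline_scale: float = 24.0  # months; median OS ~ 18 months at lp = 0
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least two patients")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull parameters must be positive")


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    """Axis-aligned ellipsoid (random per-axis semi-axes) on the voxel grid."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _texture_field(shape, scale, cv, rng) -> np.ndarray:
    """Correlated lognormal field with mean ~1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=max(scale, 1e-6))
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    sigma_ln = np.sqrt(np.log(1.0 + cv ** 2))
    return np.exp(sigma_ln * smooth - 0.5 * sigma_ln ** 2)


def simulate_patient_images(spec: PhantomSpec):
    """One patient's phantom: (SUVImage, tumor ROIMask, list of node ROIMasks).

    Tumor and node masks are non-empty, pairwise disjoint (with a 1-voxel
    moat so they stay separate structures), 26-connected, and do not touch
    the grid boundary.  Raises :class:`PlacementError` after bounded
    retries if the grid cannot hold all blobs.
    """
    rng = np.random.default_rng((spec.seed, 0xB10B))
    shape = tuple(int(s) for s in spec.grid_shape)
    occupied = np.zeros(shape, dtype=bool)

    def place(radius_vox, jitter=0.3):
        # random semi-axes with ratio <= 2, random center away from edges
        for _ in range(200):
            axes = radius_vox * rng.uniform(1.0, 2.0, size=3)
            axes = axes / axes.max() * radius_vox * rng.uniform(1.0, 1.4)
            axes = np.clip(axes, 1.2, None)
            margin = axes + 2
            if any(2 * m >= s for m, s in zip(margin, shape)):
                raise PlacementError(
                    f"blob of radius {radius_vox} cannot fit grid {shape}")
            center = [rng.uniform(m, s - m) for m, s in zip(margin, shape)]
            blob = _ellipsoid_mask(shape, center, axes)
            if not blob.any():
                continue
            # 1-voxel moat keeps structures disjoint and non-touching
            halo = ndimage.binary_dilation(blob, np.ones((3, 3, 3), dtype=bool))
            if not (halo & occupied).any():
                occupied[blob] = True
                return blob
        raise PlacementError("could not place blob after 200 attempts")

    tumor = place(spec.tumor_radius_vox)
    # node volumes span orders of magnitude in real cohorts: lognormal radii
    max_r = min(spec.grid_shape) / 5.0
    node_radii = np.clip(
        spec.node_radius_vox * rng.lognormal(0.0, spec.node_size_sigma, spec.n_nodes),
        1.3, max_r)
    nodes = [place(r) for r in np.sort(node_radii)[::-1]]

    values = np.full(shape, spec.background_suv, dtype=float)
    values *= _texture_field(shape, spec.texture_scale, min(spec.noise_cv, 0.1), rng)
    field_ = _texture_field(shape, spec.texture_scale, spec.noise_cv, rng)
    values[tumor] = spec.tumor_suv_mean * field_[tumor]
    for node in nodes:
        node_field = _texture_field(shape, spec.texture_scale, spec.noise_cv, rng)
        values[node] = spec.node_suv_mean * node_field[node]

    image = SUVImage(values, spec.spacing)
    tumor_mask = ROIMask(tumor, label="tumor", spacing=spec.spacing)
    node_masks = [ROIMask(n, label=f"node_{i}", spacing=spec.spacing)
                  for i, n in enumerate(nodes)]
    return image, tumor_mask, node_masks


def perturb_segmentation(mask: ROIMask, magnitude: float, seed: int) -> ROIMask:
    """Replicate segmentation: random boundary shift of ~``magnitude`` voxels.

    The signed Euclidean distance to the contour (positive inside) is
    perturbed by a smooth unit-variance noise field scaled by
    ``magnitude``, and re-thresholded at zero; ``magnitude=0`` returns
    the input unchanged.  Raises if the perturbed mask would be empty.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask cannot be perturbed")
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return mask
    ind = mask.indicator
    inside = ndimage.distance_transform_edt(ind)
    outside = ndimage.distance_transform_edt(~ind)
    signed = inside - outside  # > 0 exactly on mask voxels
    rng = np.random.default_rng((seed, 0x5E6))
    noise = ndimage.gaussian_filter(rng.standard_normal(ind.shape), sigma=2.0)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    new = (signed + magnitude * noise) > 0
    if not new.any():
        raise ValueError("perturbation emptied the mask")
    return ROIMask(new, label=mask.label, spacing=mask.spacing)


def simulate_survival(features, spec: SurvivalSpec):
    """Right-censored Weibull survival times from a linear log-hazard.

    ``features`` is a mapping (or DataFrame) of per-patient ground-truth
    feature arrays; the linear predictor is the beta-weighted sum of the
    z-scored features named in ``spec.betas``.  Censoring is
    administrative: a single cutoff at the empirical (1 - rate) quantile
    of the drawn event times, independent of covariates.

    Returns ``(time, event)`` arrays; ``event`` is 1 when death is
    observed and 0 when right-censored.
    """
    n = spec.n_patients
    lp = np.zeros(n)
    for name, beta in spec.betas.items():
        try:
            x = np.asarray(features[name], dtype=float)
        except (KeyError, IndexError) as exc:
            raise KeyError(f"feature {name!r} missing from features") from exc
        if x.shape != (n,):
            raise ValueError(f"feature {name!r} has shape {x.shape}, expected ({n},)")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"feature {name!r} contains non-finite values")
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"feature {name!r} has zero variance")
        lp += beta * (x - x.mean()) / sd

    rng = np.random.default_rng((spec.seed, 0x50F7))
    u = rng.uniform(size=n)
    # Weibull PH: S(t|x) = exp(-(t/scale)^shape * e^lp)
    t_event = spec.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / spec.baseline_shape)
    if spec.censoring_rate == 0:
        return t_event, np.ones(n, dtype=int)
    cutoff = np.quantile(t_event, 1.0 - spec.censoring_rate)
    event = (t_event <= cutoff).astype(int)
    time = np.minimum(t_event, cutoff)
    return time, event
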