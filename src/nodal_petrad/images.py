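"""SUV images, ROI masks, and lymph-node structure constructions.

An :class:`SUVImage` is a 3D scalar field of standardized uptake values
(SUV) on a regular grid with physical voxel spacing in mm.  An
:class:`ROIMask` is a binary indicator volume congruent with its image,
labeled by the anatomical structure it delineates (primary tumor, an
individual metastatic lymph node, or one of the derived nodal
structures: the union of all nodes ``LN_merged``, the largest node
``LN_volume``, and the most FDG-avid node ``LN_max``).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "SUVImage",
    "ROIMask",
    "merge_nodes",
    "select_largest_node",
    "select_most_active_node",
    "tumor_load",
    "read_nifti_image",
    "read_nifti_mask",
    "write_nifti",
]

#: development-cohort PET voxel spacing in mm (x, y, z)
DEFAULT_SPACING = (4.0728, 4.0728, 3.0)


@dataclass(frozen=True)
class SUVImage:
    """3D SUV volume with physical voxel spacing (mm) and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"SUV volume must be 3D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("SUV volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ROIMask:
    """Binary mask congruent with its SUVImage grid.

    ``label`` identifies the structure: ``"tumor"``, ``"node_<i>"``,
    ``"LN_merged"``, ``"LN_volume"`` or ``"LN_max"``.
    """

    indicator: np.ndarray
    label: str = "roi"
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator).astype(bool)
        if ind.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {ind.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "indicator", ind)
        object.__setattr__(self, "spacing", spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))

    @property
    def volume_cc(self) -> float:
        """Physical volume in cc (mm^3 / 1000), the unit used for reporting."""
        return self.volume_mm3 / 1000.0

    def check_congruent(self, image: SUVImage) -> None:
        if self.indicator.shape != image.values.shape:
            raise ValueError(
                f"mask shape {self.indicator.shape} does not match image shape "
                f"{image.values.shape}"
            )


def _check_grids(nodes: list[ROIMask]) -> None:
    if not nodes:
        raise ValueError("need at least one node mask")
    shape = nodes[0].indicator.shape
    for k, node in enumerate(nodes):
        if node.indicator.shape != shape:
            raise ValueError(
                f"node {k} grid {node.indicator.shape} differs from {shape}"
            )


def merge_nodes(nodes: list[ROIMask]) -> ROIMask:
    """Voxelwise union of all metastatic lymph-node masks (``LN_merged``).

    A single structure representing every node regardless of their number;
    the nodal feature vector of a patient is extracted from this union.
    """
    _check_grids(nodes)
    union = np.zeros_like(nodes[0].indicator, dtype=bool)
    for node in nodes:
        union |= node.indicator
    return ROIMask(union, label="LN_merged", spacing=nodes[0].spacing)


def select_largest_node(nodes: list[ROIMask]) -> ROIMask:
    """Node with the largest physical volume (``LN_volume``).

    Exact ties are broken by input order: the first of the tied nodes wins.
    """
    _check_grids(nodes)
    volumes = [n.volume_mm3 for n in nodes]
    best = int(np.argmax(volumes))  # argmax returns the first maximum
    winner = nodes[best]
    return ROIMask(winner.indicator, label="LN_volume", spacing=winner.spacing)


def select_most_active_node(nodes: list[ROIMask], image: SUVImage) -> ROIMask:
    """Node with the highest maximum SUV (``LN_max``); ties go to the first."""
    _check_grids(nodes)
    for node in nodes:
        node.check_congruent(image)
        if node.n_voxels == 0:
            raise ValueError("empty node mask")
    peaks = [float(image.values[n.indicator].max()) for n in nodes]
    best = int(np.argmax(peaks))
    winner = nodes[best]
    return ROIMask(winner.indicator, label="LN_max", spacing=winner.spacing)


def tumor_load(volume_tumor_cc: float, volume_ln_cc: float) -> float:
    """Tumor load: sum of primary-tumor and lymph-node volumes, in cc."""
    if volume_tumor_cc < 0 or volume_ln_cc < 0:
        raise ValueError("volumes must be non-negative")
    return float(volume_tumor_cc) + float(volume_ln_cc)


# --- NIfTI I/O --------------------------------------------------------------
# Images and masks are stored as standard NIfTI volumes whose affine encodes
# the voxel spacing; masks are 0/1 integer volumes, with the structure label
# carried by the `<patient>_<label>.nii.gz` filename convention.


def _affine(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_nifti(obj: SUVImage | ROIMask, path) -> None:
    if isinstance(obj, SUVImage):
        data = obj.values.astype(np.float32)
        aff = _affine(obj.spacing, obj.origin)
    else:
        data = obj.indicator.astype(np.uint8)
        aff = _affine(obj.spacing)
    nib.save(nib.Nifti1Image(data, aff), str(path))


def read_nifti_image(path) -> SUVImage:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in np.asarray(img.affine)[:3, 3])
    return SUVImage(np.asarray(img.dataobj, dtype=float), spacing, origin)


def read_nifti_mask(path, label: str = "roi") -> ROIMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ROIMask(np.asarray(img.dataobj) > 0.5, label=label, spacing=spacing)
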