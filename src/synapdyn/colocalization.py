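"""Mask-based two-channel overlap and compartment intensity statistics.

The overlap between two channels is computed by the mask-arithmetic
construction used in FIJI workflows — the inverted second mask subtracted
from the first, clamped at zero — which is identical to the pixelwise
logical AND; the implementation asserts that equivalence on every call.
Object-level colocalization is then the percentage of structures in one
channel whose footprint shares at least ``min_overlap_px`` pixels with
the other channel's mask.

Compartment statistics split a cell into a "cluster" mask (thresholded
cluster channel) and the remaining cytosol, and report the mean-intensity
fold change of a second channel between the two, or — for translocation
readouts — the ratio of integrated nuclear to whole-cell intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_detection import StructureSet


class ColocalizationError(ValueError):
    pass


@dataclass
class MaskPair:
    """Two same-shape boolean masks, one per channel."""

    mask_a: np.ndarray
    mask_b: np.ndarray
    name_a: str = "A"
    name_b: str = "B"

    def __post_init__(self) -> None:
        self.mask_a = np.asarray(self.mask_a)
        self.mask_b = np.asarray(self.mask_b)
        if self.mask_a.shape != self.mask_b.shape:
            raise ColocalizationError(
                f"mask shapes differ: {self.mask_a.shape} vs {self.mask_b.shape}"
            )
        for m, name in ((self.mask_a, self.name_a), (self.mask_b, self.name_b)):
            if m.dtype != bool and not np.isin(m, (0, 1)).all():
                raise ColocalizationError(f"mask {name} is not boolean-valued")
        self.mask_a = self.mask_a.astype(bool)
        self.mask_b = self.mask_b.astype(bool)


@dataclass
class CompartmentMasks:
    """Cluster/cytosol split of a cell, optionally with cell and nucleus."""

    cluster: np.ndarray
    cytosol: np.ndarray
    cell: np.ndarray | None = None
    nucleus: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cluster = np.asarray(self.cluster, dtype=bool)
        self.cytosol = np.asarray(self.cytosol, dtype=bool)
        if self.cluster.shape != self.cytosol.shape:
            raise ColocalizationError("cluster and cytosol shapes differ")
        if np.any(self.cluster & self.cytosol):
            raise ColocalizationError("cluster and cytosol masks overlap")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=bool)
        if self.nucleus is not None:
            self.nucleus = np.asarray(self.nucleus, dtype=bool)
            if self.cell is not None and np.any(self.nucleus & ~self.cell):
                raise ColocalizationError("nucleus mask extends outside cell mask")


def overlap_mask(pair: MaskPair) -> np.ndarray:
    """Pixels present in both masks, via inverted-mask subtraction.

    Computes ``clip(A - invert(B), 0)`` in integer arithmetic and asserts
    it equals ``A AND B`` before returning the boolean result.
    """
    a = pair.mask_a.astype(np.int8)
    inv_b = (~pair.mask_b).astype(np.int8)
    subtracted = np.clip(a - inv_b, 0, None).astype(bool)
    assert np.array_equal(
        subtracted, pair.mask_a & pair.mask_b
    ), "mask-subtraction overlap disagrees with logical AND"
    return subtracted


def percent_structures_overlapping(
    structures_a: StructureSet,
    mask_b: np.ndarray,
    min_overlap_px: int = 1,
) -> float:
    """Percentage of channel-A structures overlapping the channel-B mask.

    A structure overlaps iff at least ``min_overlap_px`` of its pixels lie
    in ``mask_b``.  The default of a single shared pixel is the most
    permissive criterion; raise it to demand more substantial overlap.
    """
    if len(structures_a) == 0:
        raise ColocalizationError(
            "no structures in channel A: overlap percentage undefined"
        )
    if min_overlap_px < 1:
        raise ColocalizationError("min_overlap_px must be >= 1")
    mask_b = np.asarray(mask_b, dtype=bool)
    mb = mask_b
    while mb.ndim < 4:
        mb = mb[None]
    if mb.shape != structures_a.mask.shape:
        raise ColocalizationError(
            f"mask_b shape {mask_b.shape} incompatible with structures mask "
            f"{structures_a.mask.shape}"
        )
    n_overlap = 0
    for rec in structures_a.records.itertuples():
        box = np.s_[
            rec.bbox_min_y : rec.bbox_max_y, rec.bbox_min_x : rec.bbox_max_x
        ]
        own = structures_a.labels[rec.frame, rec.z][box] == rec.label
        shared = int(np.sum(own & mb[rec.frame, rec.z][box]))
        if shared >= min_overlap_px:
            n_overlap += 1
    return 100.0 * n_overlap / len(structures_a)


def build_compartments(
    cluster_image: np.ndarray,
    cluster_threshold: float,
    cell_mask: np.ndarray | None = None,
) -> CompartmentMasks:
    """Split a field into cluster pixels and the surrounding cytosol.

    Cluster = pixels of ``cluster_image`` strictly above
    ``cluster_threshold``; cytosol = the cell mask (whole field if none)
    minus the cluster.  Either compartment ending up empty is an error.
    """
    img = np.asarray(cluster_image, dtype=float)
    cluster = img > cluster_threshold
    domain = (
        np.asarray(cell_mask, dtype=bool)
        if cell_mask is not None
        else np.ones_like(cluster)
    )
    if domain.shape != cluster.shape:
        raise ColocalizationError("cell_mask shape differs from image")
    cluster = cluster & domain
    cytosol = domain & ~cluster
    if not cluster.any():
        raise ColocalizationError(
            f"threshold {cluster_threshold} leaves an empty cluster compartment"
        )
    if not cytosol.any():
        raise ColocalizationError(
            f"threshold {cluster_threshold} leaves an empty cytosol compartment"
        )
    return CompartmentMasks(cluster=cluster, cytosol=cytosol, cell=domain)


def intensity_fold_change(
    measure_image: np.ndarray, compartments: CompartmentMasks
) -> float:
    """Mean intensity in the cluster mask over mean intensity in cytosol."""
    img = np.asarray(measure_image, dtype=float)
    if img.shape != compartments.cluster.shape:
        raise ColocalizationError("measure_image shape differs from compartments")
    cyt = img[compartments.cytosol].mean()
    if cyt <= 0:
        raise ColocalizationError("cytosol mean intensity is zero; fold undefined")
    return float(img[compartments.cluster].mean() / cyt)


def nuclear_intensity_ratio(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    denominator: str = "cell",
) -> float:
    """Integrated nuclear intensity over integrated cell (or cytoplasm).

    ``denominator="cell"`` is the headline translocation metric
    (nucleus/whole-cell); ``"cytoplasm"`` reproduces the
    nucleus/cytoplasm variant of the classic intensity-ratio plugin.
    """
    img = np.asarray(image, dtype=float)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if not nuc.any():
        raise ColocalizationError("empty nucleus mask")
    if not cell.any():
        raise ColocalizationError("empty cell mask")
    if np.any(nuc & ~cell):
        raise ColocalizationError("nucleus mask extends outside cell mask")
    nuc_sum = img[nuc].sum()
    if denominator == "cell":
        denom = img[cell].sum()
    elif denominator == "cytoplasm":
        denom = img[cell & ~nuc].sum()
    else:
        raise ColocalizationError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ColocalizationError("zero integrated intensity in denominator")
    return float(nuc_sum / denom)
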