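"""Threshold-based detection and counting of fluorescent structures.

The procedure mirrors the classic manual FIJI workflow for counting
endosomes/microclusters: one global intensity threshold — chosen on the
z-plane with the most identifiable structures — is applied to the whole
stack, the resulting binary mask is labelled per slice, and components
outside a size window (default 5–1000 px at 65 nm/pixel) are discarded.
Components are never merged across z: a z-stack's total count is the sum
of per-slice counts, and the per-slice counts positioned by the z-step
give the axial profile of structures relative to a chosen reference
plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from .image_io import ImageStack


class DetectionError(ValueError):
    pass


@dataclass
class DetectionParams:
    """Threshold and size-filter settings.

    ``threshold_mode`` is ``"manual"`` (value required) or ``"otsu"``
    (computed on the reference plane, then applied globally).  The size
    window defaults to the 5–1000 px cut-off used for endosome counting.
    Thresholding is strict (``intensity > threshold``).
    """

    threshold_mode: str = "otsu"
    threshold_value: float | None = None
    min_size_px: int = 5
    max_size_px: int = 1000
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.threshold_mode not in {"manual", "otsu"}:
            raise DetectionError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "manual":
            if self.threshold_value is None or self.threshold_value <= 0:
                raise DetectionError("manual threshold requires threshold_value > 0")
        if not 1 <= self.min_size_px <= self.max_size_px:
            raise DetectionError(
                f"need 1 <= min_size_px <= max_size_px "
                f"(got {self.min_size_px}, {self.max_size_px})"
            )
        if self.connectivity not in (4, 8):
            raise DetectionError("connectivity must be 4 or 8")

    @property
    def skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


@dataclass
class StructureSet:
    """Detected structures: per-structure records plus the filtered mask.

    ``records`` columns: frame, z, label, area_px, centroid_y, centroid_x,
    mean_intensity (NaN without a source image), bbox_{min,max}_{y,x}.
    ``labels`` has shape (T, Z, Y, X); size-passing components keep their
    per-plane label, everything else is 0.  ``mask`` is the boolean view.
    """

    records: pd.DataFrame
    labels: np.ndarray
    params: DetectionParams = field(default_factory=DetectionParams)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def __len__(self) -> int:
        return len(self.records)

    def counts_per_slice(self) -> pd.DataFrame:
        n_t, n_z = self.mask.shape[:2]
        idx = pd.MultiIndex.from_product([range(n_t), range(n_z)], names=["frame", "z"])
        counts = (
            self.records.groupby(["frame", "z"]).size()
            if len(self.records)
            else pd.Series(dtype=int)
        )
        return counts.reindex(idx, fill_value=0).rename("count").reset_index()


def _channel_planes(stack: ImageStack, channel: int | str) -> np.ndarray:
    return np.asarray(stack.channel(channel), dtype=float)  # (T, Z, Y, X)


def _count_components(plane_mask: np.ndarray, params: DetectionParams) -> int:
    labels = measure.label(plane_mask, connectivity=params.skimage_connectivity)
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(np.sum((areas >= params.min_size_px) & (areas <= params.max_size_px)))


def select_reference_plane(
    stack: ImageStack,
    channel: int | str = 0,
    params: DetectionParams | None = None,
) -> int:
    """Index of the z-plane with the most identifiable structures.

    A provisional automatic (Otsu) threshold over the whole channel
    volume is applied to each slice and the slice maximizing the number
    of size-passing connected components is returned; ties go to the
    lowest z.
    """
    params = params or DetectionParams()
    planes = _channel_planes(stack, channel)
    if stack.n_slices < 2:
        raise DetectionError("reference-plane selection needs Z > 1")
    vol = planes[0]  # (Z, Y, X); reference plane is a z-stack concept
    if np.ptp(vol) == 0:
        raise DetectionError("no structures at any plane (constant stack)")
    thr = threshold_otsu(vol)
    counts = [_count_components(vol[z] > thr, params) for z in range(vol.shape[0])]
    if max(counts) == 0:
        raise DetectionError("no structures at any plane")
    return int(np.argmax(counts))  # argmax returns the first (lowest z) maximum


def resolve_threshold(
    stack: ImageStack, channel: int | str, params: DetectionParams
) -> float:
    """The single global threshold the given params imply for this stack."""
    if params.threshold_mode == "manual":
        return float(params.threshold_value)
    planes = _channel_planes(stack, channel)
    if stack.n_slices > 1:
        ref = select_reference_plane(stack, channel, params)
        img = planes[0, ref]
    else:
        img = planes
    if np.ptp(img) == 0:
        raise DetectionError("Otsu threshold undefined on a constant image")
    return float(threshold_otsu(img))


def binarize(
    stack: ImageStack, channel: int | str, params: DetectionParams
) -> np.ndarray:
    """Apply one global threshold to every slice and frame of a channel.

    Returns a boolean (T, Z, Y, X) mask; a pixel is set iff its intensity
    strictly exceeds the threshold.
    """
    thr = resolve_threshold(stack, channel, params)
    return _channel_planes(stack, channel) > thr


def detect_structures(
    mask: np.ndarray,
    params: DetectionParams | None = None,
    image: np.ndarray | None = None,
) -> StructureSet:
    """Label per-plane connected components and apply the size filter.

    ``mask`` is boolean (T, Z, Y, X) (2-D/3-D inputs are promoted).  With
    ``image`` supplied (same shape), centroids are intensity-weighted and
    mean intensities reported; otherwise centroids are geometric.
    """
    params = params or DetectionParams()
    mask = np.asarray(mask, dtype=bool)
    while mask.ndim < 4:
        mask = mask[None]
    if image is not None:
        image = np.asarray(image, dtype=float)
        while image.ndim < 4:
            image = image[None]
        if image.shape != mask.shape:
            raise DetectionError("image and mask shapes differ")

    rows = []
    out_labels = np.zeros(mask.shape, dtype=np.int32)
    for t in range(mask.shape[0]):
        for z in range(mask.shape[1]):
            labels = measure.label(
                mask[t, z], connectivity=params.skimage_connectivity
            )
            img = image[t, z] if image is not None else None
            for prop in measure.regionprops(labels, intensity_image=img):
                if not params.min_size_px <= prop.area <= params.max_size_px:
                    continue
                out_labels[t, z][labels == prop.label] = prop.label
                cy, cx = (
                    prop.centroid_weighted if img is not None else prop.centroid
                )
                rows.append(
                    {
                        "frame": t,
                        "z": z,
                        "label": prop.label,
                        "area_px": int(prop.area),
                        "centroid_y": float(cy),
                        "centroid_x": float(cx),
                        "mean_intensity": float(prop.intensity_mean)
                        if img is not None
                        else np.nan,
                        "bbox_min_y": prop.bbox[0],
                        "bbox_min_x": prop.bbox[1],
                        "bbox_max_y": prop.bbox[2],
                        "bbox_max_x": prop.bbox[3],
                    }
                )
    columns = [
        "frame", "z", "label", "area_px", "centroid_y", "centroid_x",
        "mean_intensity", "bbox_min_y", "bbox_min_x", "bbox_max_y", "bbox_max_x",
    ]
    records = pd.DataFrame(rows, columns=columns)
    return StructureSet(records=records, labels=out_labels, params=params)


def count_total(structures: StructureSet) -> int:
    """Total structure count: per-slice counts summed over the stack."""
    return len(structures)


def axial_profile(
    structures: StructureSet, z_step_um: float, z0_index: int = 0
) -> pd.DataFrame:
    """Structure count per slice, positioned in µm relative to slice z0.

    The reference slice ``z0_index`` (by convention the first plane where
    the cell came into focus) sits at axial position 0 µm; slice z lies at
    ``(z - z0_index) * z_step_um``.  All slices are reported, including
    zero counts, so the profile sums to the total count.
    """
    n_z = structures.mask.shape[1]
    if not 0 <= z0_index < n_z:
        raise DetectionError(f"z0_index {z0_index} out of range for {n_z} slices")
    if z_step_um <= 0:
        raise DetectionError("z_step_um must be positive")
    counts = (
        structures.counts_per_slice().groupby("z")["count"].sum().reindex(
            range(n_z), fill_value=0
        )
    )
    return pd.DataFrame(
        {
            "z": np.arange(n_z),
            "position_um": (np.arange(n_z) - z0_index) * z_step_um,
            "count": counts.to_numpy(),
        }
    )


def peak_axial_position(profile: pd.DataFrame) -> float:
    """Axial position (µm) of the maximal structure count; ties -> smallest."""
    counts = np.asarray(profile["count"])
    if counts.sum() == 0:
        raise DetectionError("all-zero axial profile has no peak")
    pos = np.asarray(profile["position_um"], dtype=float)
    best = counts.max()
    return float(pos[counts == best].min())
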