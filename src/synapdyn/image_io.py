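"""Image-stack and ROI input/output with physical calibration.

All pixel data are carried as 5-D arrays with fixed axis order
``(T, Z, C, Y, X)``; axes absent from an acquisition have length 1.
Coordinates are 0-based ``(row, col) = (Y, X)``; z index 0 is the first
acquired slice.  Images travel as TIFF/OME-style TIFF written through
:mod:`tifffile`; regions of interest are a documented JSON schema; results
are CSV with a JSON sidecar recording the run configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

AXES = "TZCYX"

ROI_ROLES = frozenset(
    {"bleach", "control", "cytosol", "nucleus", "cell", "photoactivation"}
)

RESULT_KEY = ["experiment_id", "cell_id", "condition", "metric"]
RESULT_COLUMNS = RESULT_KEY + ["value", "units"]


class ImageIOError(ValueError):
    """Raised for unreadable files, axis ambiguity or invalid calibration."""


class ROIError(ValueError):
    """Raised for ROI schema violations, unknown roles or geometry errors."""


def _expand_to_5d(pixels: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with axis labels drawn from TZCYX to 5-D."""
    axes = axes.upper()
    if len(axes) != pixels.ndim:
        raise ImageIOError(
            f"axes string {axes!r} does not match array of ndim {pixels.ndim}"
        )
    if len(set(axes)) != len(axes) or not set(axes) <= set(AXES):
        raise ImageIOError(f"invalid axes string {axes!r}; use letters from {AXES}")
    if "Y" not in axes or "X" not in axes:
        raise ImageIOError("axes must include Y and X")
    full = pixels
    for ax in AXES:
        if ax not in axes:
            pos = sum(1 for a in AXES[: AXES.index(ax)] if a in axes)
            full = np.expand_dims(full, axis=pos)
            axes = axes[:pos] + ax + axes[pos:]
    order = [axes.index(a) for a in AXES]
    return np.transpose(full, order)


@dataclass
class ImageStack:
    """Pixel data plus the physical calibration every analysis stage needs.

    Parameters
    ----------
    pixels:
        Non-negative intensity array of shape ``(T, Z, C, Y, X)``.
    pixel_size_nm:
        Lateral calibration in nm per pixel (the study images at 65 nm/px).
    z_step_um:
        Axial step in µm per slice; required when ``Z > 1`` (0.19 µm in the
        study's stacks).
    frame_interval_s:
        Seconds per frame; required when ``T > 1``.
    channel_names:
        One name per channel.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    z_step_um: float | None = None
    frame_interval_s: float | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ImageIOError(
                f"pixels must be 5-D (T,Z,C,Y,X); got ndim {self.pixels.ndim} "
                "(use ImageStack.from_array to expand labelled axes)"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ImageIOError("pixels contain non-finite values")
        if np.any(self.pixels < 0):
            raise ImageIOError("pixels contain negative intensities")
        if not self.pixel_size_nm or self.pixel_size_nm <= 0:
            raise ImageIOError("pixel_size_nm must be positive")
        if self.n_slices > 1 and (self.z_step_um is None or self.z_step_um <= 0):
            raise ImageIOError("z_step_um must be positive when Z > 1")
        if self.n_frames > 1 and (
            self.frame_interval_s is None or self.frame_interval_s <= 0
        ):
            raise ImageIOError("frame_interval_s must be positive when T > 1")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ImageIOError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )

    @classmethod
    def from_array(
        cls,
        pixels: np.ndarray,
        axes: str,
        *,
        pixel_size_nm: float,
        z_step_um: float | None = None,
        frame_interval_s: float | None = None,
        channel_names: Sequence[str] | None = None,
    ) -> "ImageStack":
        return cls(
            _expand_to_5d(np.asarray(pixels), axes),
            pixel_size_nm=pixel_size_nm,
            z_step_um=z_step_um,
            frame_interval_s=frame_interval_s,
            channel_names=list(channel_names) if channel_names else [],
        )

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[3], self.pixels.shape[4]

    def channel(self, channel: int | str) -> np.ndarray:
        """Return one channel as a ``(T, Z, Y, X)`` view."""
        if isinstance(channel, str):
            try:
                channel = self.channel_names.index(channel)
            except ValueError:
                raise ImageIOError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        return self.pixels[:, :, channel]


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as TIFF with calibration metadata."""
    meta = {
        "axes": AXES,
        "pixel_size_nm": stack.pixel_size_nm,
        "z_step_um": stack.z_step_um,
        "frame_interval_s": stack.frame_interval_s,
        "channel_names": stack.channel_names,
    }
    tifffile.imwrite(str(path), stack.pixels, metadata=meta)


def read_stack(
    path: str | Path,
    *,
    axes: str | None = None,
    pixel_size_nm: float | None = None,
    z_step_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF stack, resolving axes and calibration.

    Metadata stored by :func:`write_stack` is honoured; explicit keyword
    overrides win over metadata.  Ambiguity (axes unresolvable, missing
    pixel size) is an error, never a guess.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            meta: dict = {}
            if tif.shaped_metadata:
                meta = dict(tif.shaped_metadata[0])
    except (FileNotFoundError, tifffile.TiffFileError) as exc:
        raise ImageIOError(f"cannot read TIFF {path}: {exc}") from exc

    eff_axes = axes or meta.get("axes")
    if eff_axes is None:
        if arr.ndim == 2:
            eff_axes = "YX"
        else:
            raise ImageIOError(
                f"axis order of {arr.ndim}-D array in {path} is ambiguous; "
                "pass axes= explicitly"
            )
    pixels = _expand_to_5d(arr, eff_axes)

    def pick(override, key):
        return override if override is not None else meta.get(key)

    psz = pick(pixel_size_nm, "pixel_size_nm")
    if psz is None:
        raise ImageIOError(
            f"{path}: missing field 'pixel_size_nm' (not in metadata and no "
            "override given)"
        )
    return ImageStack(
        pixels,
        pixel_size_nm=psz,
        z_step_um=pick(z_step_um, "z_step_um"),
        frame_interval_s=pick(frame_interval_s, "frame_interval_s"),
        channel_names=list(channel_names)
        if channel_names
        else list(meta.get("channel_names") or []),
    )


# --------------------------------------------------------------------------
# Regions of interest
# --------------------------------------------------------------------------


@dataclass
class ROI:
    """A named region with a role, rasterizable to a boolean mask.

    Shapes: ``circle`` (center ``(y, x)``, radius, all in pixels),
    ``rectangle`` (top-left ``(y, x)``, ``height``, ``width``) and
    ``polygon`` (vertex list ``[(y, x), ...]``).  A pixel belongs to a
    circle iff its center lies at distance <= radius from the circle
    center; polygon membership tests the pixel center against the vertex
    path.
    """

    name: str
    role: str
    shape_type: str
    params: dict
    channel: str | None = None
    frames: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise ROIError(
                f"ROI {self.name!r}: unknown role {self.role!r}; "
                f"allowed roles: {sorted(ROI_ROLES)}"
            )
        if self.shape_type not in {"circle", "rectangle", "polygon"}:
            raise ROIError(
                f"ROI {self.name!r}: unknown shape {self.shape_type!r}"
            )
        required = {
            "circle": {"center", "radius"},
            "rectangle": {"origin", "height", "width"},
            "polygon": {"vertices"},
        }[self.shape_type]
        missing = required - set(self.params)
        if missing:
            raise ROIError(
                f"ROI {self.name!r}: shape {self.shape_type} missing "
                f"parameters {sorted(missing)}"
            )
        if self.shape_type == "circle" and self.params["radius"] <= 0:
            raise ROIError(f"ROI {self.name!r}: radius must be positive")

    def bounds(self) -> tuple[float, float, float, float]:
        """(ymin, xmin, ymax, xmax) of the region's extent."""
        if self.shape_type == "circle":
            cy, cx = self.params["center"]
            r = self.params["radius"]
            return cy - r, cx - r, cy + r, cx + r
        if self.shape_type == "rectangle":
            y0, x0 = self.params["origin"]
            return y0, x0, y0 + self.params["height"] - 1, x0 + self.params["width"] - 1
        verts = np.asarray(self.params["vertices"], dtype=float)
        return (
            verts[:, 0].min(),
            verts[:, 1].min(),
            verts[:, 0].max(),
            verts[:, 1].max(),
        )

    def mask(self, shape_yx: tuple[int, int]) -> np.ndarray:
        ny, nx = shape_yx
        if self.shape_type == "circle":
            cy, cx = self.params["center"]
            r = self.params["radius"]
            yy, xx = np.ogrid[:ny, :nx]
            return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if self.shape_type == "rectangle":
            y0, x0 = self.params["origin"]
            m = np.zeros(shape_yx, dtype=bool)
            m[
                max(int(y0), 0) : int(y0) + int(self.params["height"]),
                max(int(x0), 0) : int(x0) + int(self.params["width"]),
            ] = True
            return m
        from matplotlib.path import Path as MplPath

        verts = np.asarray(self.params["vertices"], dtype=float)
        yy, xx = np.mgrid[:ny, :nx]
        pts = np.column_stack([yy.ravel(), xx.ravel()])
        # tiny positive radius makes boundary pixels inclusive
        inside = MplPath(verts).contains_points(pts, radius=1e-9)
        return inside.reshape(shape_yx)


@dataclass
class ROISet:
    """A validated collection of ROIs for one acquisition."""

    rois: list[ROI]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ROIError("duplicate ROI names")
        self._check_bleach_control_disjoint()

    def _check_bleach_control_disjoint(self) -> None:
        bleach = [r for r in self.rois if r.role == "bleach"]
        controls = [r for r in self.rois if r.role == "control"]
        if not bleach or not controls:
            return
        extent = 0.0
        for r in bleach + controls:
            _, _, ymax, xmax = r.bounds()
            extent = max(extent, ymax, xmax)
        shape = (int(np.ceil(extent)) + 2, int(np.ceil(extent)) + 2)
        for b in bleach:
            mb = b.mask(shape)
            for c in controls:
                if np.any(mb & c.mask(shape)):
                    raise ROIError(
                        f"bleach ROI {b.name!r} overlaps control ROI {c.name!r}"
                    )

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def by_role(self, role: str) -> list[ROI]:
        if role not in ROI_ROLES:
            raise ROIError(f"unknown role {role!r}")
        return [r for r in self.rois if r.role == role]

    def get(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise ROIError(f"no ROI named {name!r}")

    def validate_bounds(self, shape_yx: tuple[int, int]) -> None:
        ny, nx = shape_yx
        for r in self.rois:
            ymin, xmin, ymax, xmax = r.bounds()
            if ymin < 0 or xmin < 0 or ymax > ny - 1 or xmax > nx - 1:
                raise ROIError(
                    f"ROI {r.name!r} extends outside image bounds {shape_yx}"
                )


def read_rois(
    path: str | Path, image_shape: tuple[int, int] | None = None
) -> ROISet:
    """Read an ROI set from the documented JSON schema.

    The document is ``{"rois": [{"name", "role", "shape": {"type", ...},
    "channel"?, "frames"?}, ...]}``.  With ``image_shape`` given, every
    region is additionally checked to lie within bounds.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ROIError(f"cannot read ROI file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "rois" not in doc:
        raise ROIError(f"{path}: ROI document must be an object with key 'rois'")
    rois = []
    for entry in doc["rois"]:
        shape = dict(entry.get("shape", {}))
        stype = shape.pop("type", None)
        if stype is None:
            raise ROIError(f"ROI {entry.get('name')!r}: shape has no 'type'")
        frames = entry.get("frames")
        rois.append(
            ROI(
                name=entry["name"],
                role=entry["role"],
                shape_type=stype,
                params=shape,
                channel=entry.get("channel"),
                frames=tuple(frames) if frames else None,
            )
        )
    roiset = ROISet(rois)
    if image_shape is not None:
        roiset.validate_bounds(image_shape)
    return roiset


def write_rois(roiset: ROISet, path: str | Path) -> None:
    doc = {
        "rois": [
            {
                "name": r.name,
                "role": r.role,
                "shape": {"type": r.shape_type, **r.params},
                "channel": r.channel,
                "frames": list(r.frames) if r.frames else None,
            }
            for r in roiset
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# --------------------------------------------------------------------------
# Result tables
# --------------------------------------------------------------------------


@dataclass
class ResultTable:
    """Tidy per-cell results keyed by (experiment, cell, condition, metric)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in RESULT_COLUMNS if c not in df.columns]
        if missing:
            raise ImageIOError(f"ResultTable missing columns {missing}")
        df = df[RESULT_COLUMNS].reset_index(drop=True)
        if df.duplicated(RESULT_KEY).any():
            dup = df[df.duplicated(RESULT_KEY)].iloc[0]
            raise ImageIOError(
                "duplicate result key "
                f"{tuple(dup[k] for k in RESULT_KEY)}"
            )
        units = df["units"].astype(str)
        if (units.str.strip() == "").any() or df["units"].isna().any():
            bad = df.loc[df["units"].isna() | (units.str.strip() == ""), "metric"]
            raise ImageIOError(
                f"missing units for metric(s): {sorted(set(bad))}"
            )
        self.records = df

    def __len__(self) -> int:
        return len(self.records)


def write_results(
    table: ResultTable,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write results as CSV plus a JSON sidecar with run config and seed."""
    path = Path(path)
    table.records.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"config": config or {}, "seed": seed}, indent=2, default=_jsonify)
    )


def read_results(path: str | Path) -> ResultTable:
    df = pd.read_csv(path)
    return ResultTable(df)
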