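"""Synthetic fluorescence-microscopy scenes with planted ground truth.

Every generator returns the simulated data together with a
:class:`SyntheticTruth` that records all planted parameters, so the
expected output of each analysis stage can be computed in closed form or
by brute force.  Scenes are rendered as isotropic 2-D Gaussian spots
(diffraction-limited cluster appearance) on a constant background; the
noise model is Poisson shot noise plus Gaussian read noise, both optional
so that the noise-free state gives exact oracles.

Default calibration mirrors the study's acquisitions: 65 nm/pixel in XY
and 0.19 µm z-steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .curves import CurveEnsemble, RecoveryCurve
from .image_io import ImageStack

PIXEL_SIZE_NM = 65.0
Z_STEP_UM = 0.19


class SyntheticDataError(ValueError):
    pass


@dataclass
class NoiseParams:
    """Poisson shot noise on the signal plus Gaussian read noise."""

    poisson: bool = False
    read_sd: float = 0.0

    @property
    def enabled(self) -> bool:
        return self.poisson or self.read_sd > 0


#: Default noise used by acceptance-style recovery checks: shot noise on
#: the full signal plus a 3-count read-noise floor.
DEFAULT_NOISE = NoiseParams(poisson=True, read_sd=3.0)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated scene.

    ``spots`` is a tidy table (channel, frame, z, y, x, sigma_px,
    amplitude, paired) of every planted structure; ``params`` carries the
    scene-kind-specific planted parameters (kinetic constants, divergence
    time, thresholds...).
    """

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    spots: pd.DataFrame | None = None

    @property
    def n_spots(self) -> int:
        return 0 if self.spots is None else len(self.spots)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _render_spots(
    shape_yx: tuple[int, int],
    spots: Sequence[tuple[float, float, float, float]],
    background: float,
) -> np.ndarray:
    """Render (y, x, sigma, amplitude) Gaussian spots on a flat background."""
    img = np.full(shape_yx, float(background))
    ny, nx = shape_yx
    for y, x, sigma, amp in spots:
        r = int(math.ceil(4 * sigma))
        y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, ny)
        x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, nx)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amp * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
        )
    return img


def _apply_noise(
    img: np.ndarray, noise: NoiseParams | None, rng: np.random.Generator
) -> np.ndarray:
    if noise is None or not noise.enabled:
        return img
    out = img.astype(float)
    if noise.poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if noise.read_sd > 0:
        out = out + rng.normal(0.0, noise.read_sd, size=out.shape)
    return np.clip(out, 0, None)


def _place_points(
    n: int,
    shape_yx: tuple[int, int],
    min_separation: float,
    margin: float,
    rng: np.random.Generator,
    existing: list[tuple[float, float]] | None = None,
    max_attempts: int = 20_000,
) -> list[tuple[float, float]]:
    """Rejection-sample n points with a minimum pairwise separation."""
    ny, nx = shape_yx
    usable = (ny - 2 * margin) * (nx - 2 * margin)
    if usable <= 0 or n * min_separation**2 > usable:
        raise SyntheticDataError(
            f"field {shape_yx} too small for {n} structures at separation "
            f"{min_separation} px"
        )
    pts: list[tuple[float, float]] = list(existing or [])
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise SyntheticDataError(
                f"field {shape_yx} too small: could not place {n} structures "
                f"at separation {min_separation} px"
            )
        y = rng.uniform(margin, ny - 1 - margin)
        x = rng.uniform(margin, nx - 1 - margin)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_separation**2 for py, px in pts):
            pts.append((y, x))
            placed.append((y, x))
    return placed


# --------------------------------------------------------------------------
# Two-channel cluster scenes (overlap / colocalization ground truth)
# --------------------------------------------------------------------------


def make_cluster_scene(
    n_clusters_a: int,
    n_clusters_b: int,
    overlap_fraction: float,
    *,
    sigma_px: float = 2.0,
    amplitude: float = 200.0,
    background: float = 10.0,
    shape: tuple[int, int] = (128, 128),
    min_separation_px: float = 14.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[ImageStack, SyntheticTruth]:
    """Two-channel frame with a controlled fraction of co-centered spots.

    Channel 0 ("A") holds ``n_clusters_a`` Gaussian spots.  A fraction
    ``overlap_fraction`` of channel-1 ("B") spots is co-centered with A
    spots; the rest are placed at least ``min_separation_px`` from every
    other spot, so their thresholded masks cannot touch.
    """
    if not 0 <= overlap_fraction <= 1:
        raise SyntheticDataError("overlap_fraction must be in [0, 1]")
    rng = _rng(seed)
    n_pair = int(round(overlap_fraction * n_clusters_b))
    if n_pair > n_clusters_a:
        raise SyntheticDataError(
            f"cannot co-center {n_pair} B spots with only {n_clusters_a} A spots"
        )
    margin = 4 * sigma_px + 1
    pts_a = _place_points(n_clusters_a, shape, min_separation_px, margin, rng)
    pts_b_pair = pts_a[:n_pair]
    pts_b_free = _place_points(
        n_clusters_b - n_pair, shape, min_separation_px, margin, rng, existing=pts_a
    )

    rows = []
    for y, x in pts_a:
        rows.append(("A", 0, 0, y, x, sigma_px, amplitude, (y, x) in pts_b_pair))
    for y, x in pts_b_pair:
        rows.append(("B", 0, 0, y, x, sigma_px, amplitude, True))
    for y, x in pts_b_free:
        rows.append(("B", 0, 0, y, x, sigma_px, amplitude, False))
    spots = pd.DataFrame(
        rows,
        columns=["channel", "frame", "z", "y", "x", "sigma_px", "amplitude", "paired"],
    )

    img_a = _render_spots(shape, [(y, x, sigma_px, amplitude) for y, x in pts_a], background)
    img_b = _render_spots(
        shape,
        [(y, x, sigma_px, amplitude) for y, x in pts_b_pair + pts_b_free],
        background,
    )
    img_a = _apply_noise(img_a, noise, rng)
    img_b = _apply_noise(img_b, noise, rng)

    pixels = np.stack([img_a, img_b])[None, None]  # (1, 1, 2, Y, X)
    stack = ImageStack(
        pixels, pixel_size_nm=PIXEL_SIZE_NM, channel_names=["A", "B"]
    )
    truth = SyntheticTruth(
        kind="cluster_scene",
        seed=seed,
        params={
            "n_clusters_a": n_clusters_a,
            "n_clusters_b": n_clusters_b,
            "overlap_fraction": overlap_fraction,
            "n_paired": n_pair,
            "sigma_px": sigma_px,
            "amplitude": amplitude,
            "background": background,
            "suggested_threshold": background + amplitude / 2,
            "noise": noise is not None and noise.enabled,
        },
        spots=spots,
    )
    return stack, truth


# --------------------------------------------------------------------------
# Z-stacks with a planted axial distribution
# --------------------------------------------------------------------------


def make_zstack_scene(
    axial_counts: Sequence[int],
    *,
    sigma_px: float = 2.0,
    amplitude: float = 200.0,
    background: float = 10.0,
    shape: tuple[int, int] = (128, 128),
    min_separation_px: float = 14.0,
    z_step_um: float = Z_STEP_UM,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[ImageStack, SyntheticTruth]:
    """Z-stack whose slice z contains exactly ``axial_counts[z]`` spots."""
    counts = [int(c) for c in axial_counts]
    if any(c < 0 for c in counts):
        raise SyntheticDataError("axial_counts must be non-negative")
    rng = _rng(seed)
    margin = 4 * sigma_px + 1
    planes = []
    rows = []
    for z, c in enumerate(counts):
        pts = _place_points(c, shape, min_separation_px, margin, rng) if c else []
        for y, x in pts:
            rows.append(("A", 0, z, y, x, sigma_px, amplitude, False))
        img = _render_spots(shape, [(y, x, sigma_px, amplitude) for y, x in pts], background)
        planes.append(_apply_noise(img, noise, rng))
    spots = pd.DataFrame(
        rows,
        columns=["channel", "frame", "z", "y", "x", "sigma_px", "amplitude", "paired"],
    )
    pixels = np.stack(planes)[None, :, None]  # (1, Z, 1, Y, X)
    stack = ImageStack(
        pixels,
        pixel_size_nm=PIXEL_SIZE_NM,
        z_step_um=z_step_um,
        channel_names=["A"],
    )
    truth = SyntheticTruth(
        kind="zstack_scene",
        seed=seed,
        params={
            "axial_counts": counts,
            "z_step_um": z_step_um,
            "sigma_px": sigma_px,
            "amplitude": amplitude,
            "background": background,
            "suggested_threshold": background + amplitude / 2,
        },
        spots=spots,
    )
    return stack, truth


# --------------------------------------------------------------------------
# FRAP recovery traces
# --------------------------------------------------------------------------


def frap_model(
    t: np.ndarray, w: Sequence[float], tau: Sequence[float], f_inf: float
) -> np.ndarray:
    """Multi-exponential recovery F_inf * (1 - sum_i w_i exp(-t/tau_i))."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for wi, ti in zip(w, tau):
        out += wi * np.exp(-t / ti)
    return f_inf * (1.0 - out)


def make_frap_series(
    *,
    prebleach_frames: int = 10,
    postbleach_frames: int = 191,
    dt: float = 2.0,
    w: Sequence[float] = (0.6, 0.4),
    tau: Sequence[float] = (20.0, 200.0),
    f_inf: float = 0.7,
    k_b: float = 0.0,
    noise_sd: float = 0.0,
    plateau: float = 1.0,
    n_replicates: int = 1,
    n_controls: int = 2,
    seed: int = 0,
) -> tuple[list[RecoveryCurve], list[RecoveryCurve], SyntheticTruth]:
    """Raw bleach-ROI traces plus unbleached control-ROI traces.

    The bleach-ROI trace follows ``plateau * F_inf*(1 - sum w_i e^{-t/tau_i})
    * e^{-k_b (t + t_pre)}`` after the bleach (t >= 0) and the pre-bleach
    plateau (times < 0) decays with the imaging-bleach rate ``k_b`` alone.
    Control traces decay as ``e^{-k_b s}`` with s the time since
    acquisition start.  Gaussian noise of sd ``noise_sd`` (same scale as
    ``plateau``) is added to every trace.
    """
    w = tuple(float(x) for x in w)
    tau = tuple(float(x) for x in tau)
    if len(w) != len(tau):
        raise SyntheticDataError("w and tau must have equal length")
    if abs(sum(w) - 1.0) > 1e-9:
        raise SyntheticDataError(f"component weights must sum to 1 (got {sum(w)})")
    if any(t <= 0 for t in tau):
        raise SyntheticDataError("time constants must be positive")
    if not 0 < f_inf <= 1:
        raise SyntheticDataError("F_inf must be in (0, 1]")
    if prebleach_frames < 1 or postbleach_frames < 2:
        raise SyntheticDataError("need >= 1 pre-bleach and >= 2 post-bleach frames")
    rng = _rng(seed)

    t_pre = prebleach_frames * dt
    time = np.arange(-prebleach_frames, postbleach_frames) * dt
    s = time + t_pre  # time since acquisition start, >= 0
    bleach_decay = np.exp(-k_b * s)

    clean = np.where(
        time < 0,
        plateau * bleach_decay,
        plateau * frap_model(np.clip(time, 0, None), w, tau, f_inf) * bleach_decay,
    )

    # traces are ROI means; with read noise they may dip slightly below
    # zero right after a full bleach, as background-subtracted data do
    bleach_curves = [
        RecoveryCurve(
            time,
            clean + rng.normal(0, noise_sd, clean.shape)
            if noise_sd > 0
            else clean.copy(),
            stage="raw",
            cell_id=f"cell{i}",
        )
        for i in range(n_replicates)
    ]
    control_clean = plateau * np.exp(-k_b * s)
    control_curves = [
        RecoveryCurve(
            time,
            control_clean + rng.normal(0, noise_sd, s.shape)
            if noise_sd > 0
            else control_clean.copy(),
            stage="raw",
            cell_id=f"control{i}",
        )
        for i in range(n_controls)
    ]
    truth = SyntheticTruth(
        kind="frap_series",
        seed=seed,
        params={
            "w": w,
            "tau": tau,
            "f_inf": f_inf,
            "k_b": k_b,
            "dt": dt,
            "prebleach_frames": prebleach_frames,
            "postbleach_frames": postbleach_frames,
            "noise_sd": noise_sd,
            "plateau": plateau,
        },
    )
    return bleach_curves, control_curves, truth


# --------------------------------------------------------------------------
# Photoactivation pulse-chase series
# --------------------------------------------------------------------------


def default_cluster_mask(
    shape: tuple[int, int] = (96, 96),
    n_clusters: int = 8,
    radius_px: float = 4.0,
    min_separation_px: float = 16.0,
    seed: int = 0,
) -> np.ndarray:
    """A boolean cluster mask of disjoint disks, for convenience."""
    rng = _rng(seed)
    pts = _place_points(n_clusters, shape, min_separation_px, radius_px + 1, rng)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for y, x in pts:
        mask |= (yy - y) ** 2 + (xx - x) ** 2 <= radius_px**2
    return mask


def make_photoactivation_series(
    *,
    frames: int = 60,
    dt: float = 2.0,
    activation_frame: int = 10,
    cluster_mask: np.ndarray | None = None,
    incorporation_rate: float = 0.05,
    cluster_amplitude: float = 100.0,
    cytosol_amplitude: float = 25.0,
    cytosol_level_fn: Callable[[float], float] | None = None,
    cluster_channel_amplitude: float = 150.0,
    background: float = 5.0,
    vesicle_events: Sequence[dict] | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[ImageStack, SyntheticTruth]:
    """Two-channel time series of photoactivated-signal incorporation.

    Channel 0 is the static cluster channel (``background`` plus
    ``cluster_channel_amplitude`` inside ``cluster_mask``).  Channel 1 is
    the photoactivated channel: zero before ``activation_frame``, then
    inside the mask ``cluster_amplitude * (1 - e^{-rate (t - t_act)})``
    and outside it the cytosol level (default: the same saturation shape
    scaled to ``cytosol_amplitude``).  Optional ``vesicle_events`` — dicts
    with keys frame, y, x and optional amplitude/sigma — plant transient
    single-frame puncta in the photoactivated channel.
    """
    if not 0 <= activation_frame < frames:
        raise SyntheticDataError(
            f"activation_frame {activation_frame} outside series of {frames} frames"
        )
    if cluster_mask is None:
        cluster_mask = default_cluster_mask(seed=seed)
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    shape = cluster_mask.shape
    rng = _rng(seed)

    if cytosol_level_fn is None:
        def cytosol_level_fn(t: float) -> float:  # noqa: E731-like default
            return cytosol_amplitude * (1.0 - math.exp(-incorporation_rate * t))

    events = [dict(e) for e in (vesicle_events or [])]
    for e in events:
        e.setdefault("amplitude", 400.0)
        e.setdefault("sigma", 1.5)
        if not activation_frame <= e["frame"] < frames:
            raise SyntheticDataError(
                f"vesicle event at frame {e['frame']} outside post-activation range"
            )

    ch0 = np.full(shape, background) + cluster_channel_amplitude * cluster_mask
    t_frames = []
    for f in range(frames):
        t = (f - activation_frame) * dt
        pa = np.zeros(shape)
        if f >= activation_frame:
            in_level = cluster_amplitude * (1.0 - math.exp(-incorporation_rate * t))
            pa[cluster_mask] = in_level
            pa[~cluster_mask] = cytosol_level_fn(t)
            for e in events:
                if e["frame"] == f:
                    pa += _render_spots(
                        shape, [(e["y"], e["x"], e["sigma"], e["amplitude"])], 0.0
                    )
        t_frames.append(
            np.stack([_apply_noise(ch0.copy(), noise, rng), _apply_noise(pa, noise, rng)])
        )
    pixels = np.stack(t_frames)[:, None]  # (T, 1, 2, Y, X)
    stack = ImageStack(
        pixels,
        pixel_size_nm=PIXEL_SIZE_NM,
        frame_interval_s=dt,
        channel_names=["cluster", "photoactivated"],
    )
    spot_rows = [
        ("photoactivated", e["frame"], 0, e["y"], e["x"], e["sigma"], e["amplitude"], False)
        for e in events
    ]
    truth = SyntheticTruth(
        kind="photoactivation_series",
        seed=seed,
        params={
            "frames": frames,
            "dt": dt,
            "activation_frame": activation_frame,
            "incorporation_rate": incorporation_rate,
            "cluster_amplitude": cluster_amplitude,
            "cytosol_amplitude": cytosol_amplitude,
            "cluster_channel_amplitude": cluster_channel_amplitude,
            "background": background,
            "cluster_mask": cluster_mask,
            "vesicle_events": events,
            "cluster_threshold": background + cluster_channel_amplitude / 2,
        },
        spots=pd.DataFrame(
            spot_rows,
            columns=["channel", "frame", "z", "y", "x", "sigma_px", "amplitude", "paired"],
        ),
    )
    return stack, truth


# --------------------------------------------------------------------------
# Two-condition curve ensembles with a planted divergence time
# --------------------------------------------------------------------------


def make_two_condition_ensembles(
    *,
    n_per_group: int = 10,
    timepoints: Sequence[float] | None = None,
    n_timepoints: int = 150,
    dt: float = 2.0,
    t_star: float = 94.0,
    effect_size: float = 0.2,
    noise_sd: float = 0.02,
    baseline_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[CurveEnsemble, CurveEnsemble, SyntheticTruth]:
    """Two replicate ensembles sharing a mean trajectory until ``t_star``.

    After ``t_star`` group B's mean is offset by ``effect_size``;
    replicate noise is i.i.d. Gaussian with sd ``noise_sd``.  With
    ``effect_size = 0`` the groups are exchangeable and a divergence
    statistic should report no divergence.
    """
    if n_per_group < 2:
        raise SyntheticDataError("n_per_group must be >= 2 (test undefined)")
    t = (
        np.asarray(timepoints, dtype=float)
        if timepoints is not None
        else np.arange(n_timepoints) * dt
    )
    if not t[0] <= t_star <= t[-1]:
        raise SyntheticDataError(
            f"t_star={t_star} outside time range [{t[0]}, {t[-1]}]"
        )
    rng = _rng(seed)
    base = baseline_fn(t) if baseline_fn is not None else 0.7 * (1 - np.exp(-t / 60.0))
    mean_a = base
    mean_b = base + effect_size * (t >= t_star)
    vals_a = mean_a + rng.normal(0, noise_sd, (n_per_group, len(t)))
    vals_b = mean_b + rng.normal(0, noise_sd, (n_per_group, len(t)))
    ens_a = CurveEnsemble(t, vals_a, condition="A")
    ens_b = CurveEnsemble(t, vals_b, condition="B")
    truth = SyntheticTruth(
        kind="two_condition_ensembles",
        seed=seed,
        params={
            "t_star": t_star,
            "effect_size": effect_size,
            "noise_sd": noise_sd,
            "n_per_group": n_per_group,
            "dt": float(np.median(np.diff(t))),
        },
    )
    return ens_a, ens_b, truth
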