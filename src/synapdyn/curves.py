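"""Intensity-trace containers shared by the FRAP and statistics modules.

A :class:`RecoveryCurve` is a single ROI intensity trace; time 0 is the
first post-bleach (or post-activation) frame and pre-bleach frames carry
negative times.  A :class:`CurveEnsemble` is a replicate set on a common
time grid with per-timepoint mean and SEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

STAGES = ("raw", "bleach_corrected", "normalized")


class CurveError(ValueError):
    pass


@dataclass
class RecoveryCurve:
    """One ROI intensity trace through its correction/normalization stages."""

    time: np.ndarray
    intensity: np.ndarray
    stage: str = "raw"
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape or self.time.ndim != 1:
            raise CurveError("time and intensity must be equal-length 1-D arrays")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise CurveError("times must be strictly increasing")
        if self.stage not in STAGES:
            raise CurveError(f"unknown stage {self.stage!r}")

    # -- views ------------------------------------------------------------
    @property
    def prebleach_mask(self) -> np.ndarray:
        return self.time < 0

    @property
    def postbleach_mask(self) -> np.ndarray:
        return self.time >= 0

    @property
    def prebleach_mean(self) -> float:
        pre = self.intensity[self.prebleach_mask]
        if pre.size == 0:
            raise CurveError("curve has no pre-bleach frames")
        return float(pre.mean())

    @property
    def postbleach_value(self) -> float:
        post = self.intensity[self.postbleach_mask]
        if post.size == 0:
            raise CurveError("curve has no post-bleach frames")
        return float(post[0])

    @property
    def dt(self) -> float:
        if len(self.time) < 2:
            raise CurveError("single-point curve has no sampling interval")
        return float(np.median(np.diff(self.time)))

    def with_intensity(self, intensity: np.ndarray, stage: str) -> "RecoveryCurve":
        return replace(self, intensity=np.asarray(intensity, float), stage=stage)

    def value_at(self, t: float, tol: float | None = None) -> float:
        """Nearest-frame lookup; `tol` defaults to half the sampling interval."""
        if tol is None:
            tol = self.dt / 2
        i = int(np.argmin(np.abs(self.time - t)))
        if abs(self.time[i] - t) > tol + 1e-12:
            raise CurveError(
                f"no frame within {tol} s of t={t} s "
                f"(range {self.time[0]}..{self.time[-1]} s)"
            )
        return float(self.intensity[i])


@dataclass
class CurveEnsemble:
    """Replicate curves on a common time grid, with mean and SEM."""

    time: np.ndarray
    values: np.ndarray  # (n_members, n_timepoints)
    condition: str = ""
    experiment_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.time.shape[0]:
            raise CurveError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.time)} timepoints"
            )
        if self.n_members < 2:
            raise CurveError("an ensemble needs >= 2 members (SEM undefined)")
        if self.experiment_ids and len(self.experiment_ids) != self.n_members:
            raise CurveError("experiment_ids length mismatch")

    @classmethod
    def from_curves(
        cls, curves: Sequence[RecoveryCurve], condition: str = ""
    ) -> "CurveEnsemble":
        if len(curves) < 2:
            raise CurveError("an ensemble needs >= 2 members (SEM undefined)")
        t0 = curves[0].time
        for c in curves[1:]:
            if c.time.shape != t0.shape or not np.allclose(c.time, t0):
                raise CurveError("curves are not on a common time grid")
        return cls(
            time=t0,
            values=np.stack([c.intensity for c in curves]),
            condition=condition or curves[0].condition,
            experiment_ids=[c.cell_id for c in curves],
        )

    @property
    def n_members(self) -> int:
        return self.values.shape[0]

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def sem(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=1) / np.sqrt(self.n_members)

    def mean_curve(self, stage: str = "normalized") -> RecoveryCurve:
        return RecoveryCurve(
            self.time, self.mean(), stage=stage, condition=self.condition
        )
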