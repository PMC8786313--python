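"""FRAP curve correction, normalization and multi-exponential fitting.

The processing chain follows the standard confocal FRAP workflow:

1. *Bleach correction* — the bleached-ROI trace is divided by the mean
   relative decay of unbleached control ROIs, removing the multiplicative
   photobleaching caused by the imaging laser itself.
2. *Normalization* — the intensity right after the bleach is subtracted
   and the result divided by the pre-bleach steady state, mapping the
   curve to [0, 1] with value 0 at t = 0 by construction.
3. *Fitting* — the normalized recovery is fitted with
   ``F(t) = F_inf * (1 - sum_i w_i exp(-t / tau_i))`` for 1–3 components
   (the unrecovered fraction decays multi-exponentially; mobile fraction
   ``F_inf``, weights summing to 1, time constants tau sorted ascending).
   Fits are weighted least squares (1/SEM^2 when an SEM is supplied),
   multi-start over log-spaced time constants, and model order is chosen
   by parsimony: the smallest component count whose weighted SSR the next
   model does not improve by more than a configurable fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curves import CurveEnsemble, CurveError, RecoveryCurve

F_INF_MAX = 1.2  # plateau bound; slightly above 1 to tolerate noise


class FRAPFitError(RuntimeError):
    pass


@dataclass
class ExpFit:
    """Multi-exponential recovery fit with weighted SSR for model choice."""

    n_components: int
    weights: tuple[float, ...]
    tau: tuple[float, ...]
    f_inf: float
    ssr: float
    converged: bool

    def __post_init__(self) -> None:
        if self.n_components not in (1, 2, 3):
            raise FRAPFitError("n_components must be 1, 2 or 3")
        if any(t <= 0 for t in self.tau):
            raise FRAPFitError("fitted time constants must be positive")
        if not 0 < self.f_inf <= F_INF_MAX:
            raise FRAPFitError(f"fitted plateau {self.f_inf} outside (0, {F_INF_MAX}]")
        if self.ssr < 0:
            raise FRAPFitError("SSR must be non-negative")

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        decay = sum(w * np.exp(-t / tau) for w, tau in zip(self.weights, self.tau))
        return self.f_inf * (1.0 - decay)


def bleach_correct(
    target: RecoveryCurve, controls: list[RecoveryCurve]
) -> RecoveryCurve:
    """Divide out imaging-laser photobleaching using unbleached ROIs.

    The correction factor at time t is the mean over controls of
    ``control(t) / control_initial``, each control referenced to its first
    acquired frame — its level before any imaging bleach; the corrected
    trace is ``target(t) / factor(t)``.  Constant controls therefore leave
    the target unchanged, and a pure multiplicative decay shared by target
    and controls is removed exactly.
    """
    if not controls:
        raise CurveError("bleach correction needs at least one control ROI")
    for c in controls:
        if c.time.shape != target.time.shape or not np.allclose(c.time, target.time):
            raise CurveError("control curve not on the target's time grid")
        if np.any(c.intensity <= 0):
            raise CurveError(
                f"control {c.cell_id or '?'} has non-positive intensities; "
                "cannot form a bleach-correction factor"
            )
    rel = np.stack([c.intensity / c.intensity[0] for c in controls])
    factor = rel.mean(axis=0)
    return target.with_intensity(target.intensity / factor, stage="bleach_corrected")


def normalize_recovery(curve: RecoveryCurve, prebleach_frames: int) -> RecoveryCurve:
    """Map a recovery trace to [0, 1]: 0 right after the bleach, 1 at the
    pre-bleach steady state.

    ``out(t) = (in(t) - F_post) / (F_pre - F_post)`` with ``F_pre`` the
    mean of the last ``prebleach_frames`` pre-bleach values and ``F_post``
    the value at t = 0.
    """
    pre = curve.intensity[curve.prebleach_mask]
    if pre.size < 1:
        raise CurveError("need at least one pre-bleach frame")
    if prebleach_frames < 1 or prebleach_frames > pre.size:
        raise CurveError(
            f"prebleach_frames={prebleach_frames} but curve has {pre.size} "
            "pre-bleach frames"
        )
    post = curve.intensity[curve.postbleach_mask]
    if post.size < 2:
        raise CurveError("need at least two post-bleach frames")
    f_pre = float(pre[-prebleach_frames:].mean())
    f_post = float(post[0])
    if f_pre <= f_post:
        raise CurveError(
            f"pre-bleach level {f_pre} not above post-bleach level {f_post}: "
            "no bleach occurred"
        )
    out = (curve.intensity - f_post) / (f_pre - f_post)
    return curve.with_intensity(out, stage="normalized")


def mean_curve(ensemble: CurveEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean and SEM per timepoint over ensemble members."""
    return ensemble.mean(), ensemble.sem()


# --------------------------------------------------------------------------
# Multi-exponential fitting
# --------------------------------------------------------------------------


def _model_amplitudes(t: np.ndarray, amps: np.ndarray, taus: np.ndarray) -> np.ndarray:
    # F(t) = sum_i A_i (1 - e^{-t/tau_i}); A_i = F_inf * w_i
    return np.sum(amps[:, None] * (1.0 - np.exp(-t[None, :] / taus[:, None])), axis=0)


def fit_recovery(
    curve: RecoveryCurve,
    n_components: int,
    sem: np.ndarray | None = None,
    n_starts: int = 16,
    seed: int = 0,
    _warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> ExpFit:
    """Weighted least-squares fit of an n-component recovery model.

    Residuals are weighted by 1/SEM when per-timepoint SEMs are supplied
    (heteroscedastic weighting for ensemble means), uniformly otherwise.
    Initial time constants are log-spaced over [dt, 10 t_max] across
    ``n_starts`` seeded starts and the best weighted SSR is kept.
    """
    if curve.stage != "normalized":
        raise FRAPFitError("fit_recovery expects a normalized curve")
    if n_components not in (1, 2, 3):
        raise FRAPFitError("n_components must be 1, 2 or 3")
    t = curve.time[curve.postbleach_mask]
    y = curve.intensity[curve.postbleach_mask]
    if len(t) < 3 * (2 * n_components + 1):
        raise FRAPFitError(
            f"{len(t)} post-bleach points are too few for {n_components} "
            f"components (need >= {3 * (2 * n_components + 1)})"
        )
    if np.allclose(y, 0):
        raise FRAPFitError("flat zero curve: no recovery signal to fit")
    if sem is not None:
        sem = np.asarray(sem, dtype=float)
        if sem.shape == curve.time.shape:
            sem = sem[curve.postbleach_mask]
        if sem.shape != t.shape:
            raise FRAPFitError("sem length does not match the curve")
        w_res = 1.0 / np.where(sem > 0, sem, np.nanmin(sem[sem > 0]))
    else:
        w_res = np.ones_like(t)

    dt = curve.dt
    t_max = float(t[-1])
    rng = np.random.default_rng(seed)
    plateau_guess = float(np.clip(np.mean(y[-max(3, len(y) // 10):]), 0.05, F_INF_MAX))

    def residuals(theta):
        amps, taus = theta[:n_components], theta[n_components:]
        return (_model_amplitudes(t, amps, taus) - y) * w_res

    lo = np.concatenate([np.zeros(n_components), np.full(n_components, dt / 10)])
    hi = np.concatenate(
        [np.full(n_components, F_INF_MAX), np.full(n_components, 100 * t_max)]
    )

    starts = []
    # deterministic spread: taus log-spaced over [dt, 10 t_max]
    grid = np.geomspace(dt, 10 * t_max, num=max(n_components, 4))
    for i in range(min(len(grid) - n_components + 1, max(n_starts // 4, 1))):
        starts.append(
            (
                np.full(n_components, plateau_guess / n_components),
                grid[i : i + n_components].copy(),
            )
        )
    while len(starts) < n_starts:
        taus0 = np.sort(np.exp(rng.uniform(np.log(dt), np.log(10 * t_max), n_components)))
        a0 = rng.dirichlet(np.ones(n_components)) * plateau_guess
        starts.append((a0, taus0))
    if _warm_start is not None:
        starts.insert(0, _warm_start)

    best = None
    for a0, taus0 in starts:
        theta0 = np.clip(np.concatenate([a0, taus0]), lo, hi)
        try:
            res = least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf", max_nfev=2000
            )
        except Exception:
            continue
        ssr = float(np.sum(res.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        raise FRAPFitError(
            f"no {n_components}-component start converged on curve "
            f"{curve.cell_id or '?'}"
        )
    ssr, res = best
    amps = np.clip(res.x[:n_components], 1e-12, None)
    taus = res.x[n_components:]
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    f_inf = float(np.clip(amps.sum(), 1e-12, F_INF_MAX))
    weights = tuple(float(a / amps.sum()) for a in amps)
    return ExpFit(
        n_components=n_components,
        weights=weights,
        tau=tuple(float(x) for x in taus),
        f_inf=f_inf,
        ssr=ssr,
        converged=bool(res.success),
    )


def select_model(
    curve: RecoveryCurve,
    candidates: tuple[int, ...] = (1, 2, 3),
    sem: np.ndarray | None = None,
    rel_improvement: float = 0.05,
    n_starts: int = 16,
    seed: int = 0,
) -> tuple[ExpFit, dict[int, ExpFit]]:
    """Fit all candidate component counts and pick by parsimony.

    Walks candidates in increasing order and accepts the first count whose
    weighted SSR the next candidate fails to improve by more than
    ``rel_improvement`` (relative).  Returns the chosen fit and every fit
    by component count (all SSRs reported).  Each higher-order fit is
    warm-started from the previous solution padded with a zero-amplitude
    component, so SSR cannot increase with model order.
    """
    candidates = tuple(sorted(candidates))
    fits: dict[int, ExpFit] = {}
    warm = None
    for n in candidates:
        fits[n] = fit_recovery(
            curve, n, sem=sem, n_starts=n_starts, seed=seed, _warm_start=warm
        )
        amps = np.array(fits[n].weights) * fits[n].f_inf
        warm = (
            np.concatenate([amps, [0.0]]),
            np.concatenate([fits[n].tau, [np.median(fits[n].tau)]]),
        )
    chosen = fits[candidates[-1]]
    for i, n in enumerate(candidates[:-1]):
        nxt = candidates[i + 1]
        if fits[nxt].ssr >= (1.0 - rel_improvement) * fits[n].ssr:
            chosen = fits[n]
            break
    return chosen, fits


def recovery_at_time(curve: RecoveryCurve, t: float = 380.0) -> float:
    """Normalized recovery at time t, as a percentage (nearest frame)."""
    if curve.stage != "normalized":
        raise FRAPFitError("recovery_at_time expects a normalized curve")
    return 100.0 * curve.value_at(t)


def process_frap(
    target: RecoveryCurve,
    controls: list[RecoveryCurve],
    prebleach_frames: int,
) -> RecoveryCurve:
    """Convenience chain: bleach-correct then normalize one trace."""
    return normalize_recovery(bleach_correct(target, controls), prebleach_frames)
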