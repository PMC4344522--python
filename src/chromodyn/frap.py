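"""FRAP (fluorescence recovery after photobleaching) quantification.

A bleached nuclear region recovers fluorescence as unbleached molecules
exchange in; the recovery curve reports chromatin-binding kinetics.  This
module implements the full quantification chain used for linker-histone-like
proteins:

1. translational registration of the time-lapse stack,
2. extraction of bleach-region and whole-nucleus mean-intensity traces,
3. double normalization -- each channel referenced to the mean of its last
   five pre-bleach frames, then the region divided by the whole-nucleus
   channel to correct for acquisition photobleaching and the bleach-event
   signal loss,
4. ensemble averaging (mean +/- SEM over nuclei),
5. kinetic summary: half-time of recovery (tau-half), mobile/immobile
   fractions and plateau, either by direct interpolation of the curve or by
   a single-exponential fit,
6. bootstrap comparison of kinetic summaries between conditions.

The half-time is measured relative to the span from the first post-bleach
level ``f0`` to the plateau, the only definition consistent with a non-zero
immobile fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

__all__ = [
    "IntensityTrace",
    "NormalizedCurve",
    "CurveEnsemble",
    "KineticSummary",
    "register_stack",
    "extract_trace",
    "normalize_trace",
    "aggregate_curves",
    "fit_recovery",
    "compare_kinetics",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityTrace:
    """Per-frame mean intensities of the bleached region and whole nucleus.

    Times are in seconds with t = 0 at the first post-bleach frame; the
    bleach frame itself belongs to neither phase and is never stored.
    """

    times: np.ndarray
    roi_mean: np.ndarray
    nucleus_mean: np.ndarray
    phase: np.ndarray  # array of "pre" / "post" strings
    nucleus_id: str = "0"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "roi_mean", np.asarray(self.roi_mean, dtype=float))
        object.__setattr__(self, "nucleus_mean", np.asarray(self.nucleus_mean, dtype=float))
        phase = np.asarray(self.phase, dtype=object)
        object.__setattr__(self, "phase", phase)
        n = len(times)
        if not (len(self.roi_mean) == len(self.nucleus_mean) == len(phase) == n):
            raise ValueError("trace arrays must share one length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        is_pre = phase == "pre"
        if is_pre.sum() < 5:
            raise ValueError(
                f"nucleus {self.nucleus_id}: needs >=5 pre-bleach frames, got {is_pre.sum()}"
            )
        # phases must be contiguous: all pre before all post
        if np.any(np.diff(is_pre.astype(int)) > 0):
            raise ValueError("phases must be contiguous (all pre before all post)")

    @property
    def n_prebleach(self) -> int:
        return int((self.phase == "pre").sum())

    @property
    def n_postbleach(self) -> int:
        return int((self.phase == "post").sum())


@dataclass(frozen=True)
class NormalizedCurve:
    """Double-normalized recovery curve; pre-bleach level is 1 by construction."""

    times: np.ndarray          # post-bleach times, t=0 at first post frame
    values: np.ndarray         # normalized post-bleach intensities
    prebleach_values: np.ndarray
    nucleus_id: str = "0"


@dataclass(frozen=True)
class CurveEnsemble:
    """Pointwise mean +/- SEM of normalized curves sharing one time grid."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_nuclei: int


@dataclass(frozen=True)
class KineticSummary:
    """Headline FRAP quantities for one curve (single nucleus or ensemble mean)."""

    tau_half: float | None     # seconds; None when there is no recovery
    mobile_fraction: float
    immobile_fraction: float
    plateau: float
    f0: float
    method: Literal["interpolated", "exponential_fit"]
    no_recovery: bool = False
    fit_fallback: bool = False


# ---------------------------------------------------------------------------
# registration and trace extraction
# ---------------------------------------------------------------------------

def register_stack(
    stack: np.ndarray, upsample_factor: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Translation-only registration of a time-lapse stack.

    Each frame is aligned to the first frame by maximizing the
    cross-correlation (phase correlation, with parabolic-equivalent
    sub-pixel refinement through Fourier upsampling).  Frames are resampled
    by nearest neighbor so that pixel intensities are moved, never blended.

    Returns ``(registered_stack, shifts)`` with ``shifts[t]`` the (row, col)
    translation applied to frame ``t``.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (n_frames, H, W) with >=2 frames")
    reference = stack[0]
    if not np.any(reference):
        raise ValueError("all-zero reference frame: no registration signal")
    registered = np.empty_like(stack)
    registered[0] = reference
    shifts = np.zeros((stack.shape[0], 2), dtype=float)
    for t in range(1, stack.shape[0]):
        if not np.any(stack[t]):
            raise ValueError(f"all-zero frame {t}: no registration signal")
        shift, _, _ = phase_cross_correlation(
            reference, stack[t], upsample_factor=upsample_factor, normalization=None
        )
        shifts[t] = shift
        registered[t] = ndimage.shift(stack[t], shift, order=0, mode="constant", cval=0.0)
    return registered, shifts


def extract_trace(
    stack: np.ndarray,
    roi_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    bleach_frame_index: int,
    frame_interval: float = 1.0,
    nucleus_id: str = "0",
) -> IntensityTrace:
    """Mean-intensity traces over the bleach region and whole nucleus.

    Frames before ``bleach_frame_index`` are labeled pre-bleach, the bleach
    frame is dropped, the remainder are post-bleach with t=0 at the first
    post frame.
    """
    stack = np.asarray(stack, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    if np.any(roi_mask & ~nucleus_mask):
        raise ValueError("ROI must lie inside the nucleus mask")
    n_frames = stack.shape[0]
    if not 0 < bleach_frame_index < n_frames - 1:
        raise ValueError("bleach frame must be interior to the stack")
    roi = stack[:, roi_mask].mean(axis=1)
    nuc = stack[:, nucleus_mask].mean(axis=1)
    keep = np.arange(n_frames) != bleach_frame_index
    frames = np.arange(n_frames)[keep]
    phase = np.where(frames < bleach_frame_index, "pre", "post").astype(object)
    # t=0 at first post frame; earlier frames get negative times
    times = (frames - (bleach_frame_index + 1)) * float(frame_interval)
    return IntensityTrace(
        times=times, roi_mean=roi[keep], nucleus_mean=nuc[keep],
        phase=phase, nucleus_id=nucleus_id,
    )


# ---------------------------------------------------------------------------
# normalization and aggregation
# ---------------------------------------------------------------------------

def normalize_trace(trace: IntensityTrace) -> NormalizedCurve:
    """Double normalization of a raw trace.

    value(t) = [roi(t) / <roi>_pre5] / [nuc(t) / <nuc>_pre5]

    where <.>_pre5 is the mean of the last five pre-bleach frames of the
    respective channel.  Referencing each channel to its own pre-bleach mean
    makes the pre-bleach level 1; dividing by the whole-nucleus channel
    corrects for both acquisition photobleaching and the total signal lost
    at the bleach event.
    """
    is_pre = trace.phase == "pre"
    pre_idx = np.flatnonzero(is_pre)
    roi_ref = trace.roi_mean[pre_idx[-5:]].mean()
    nuc_ref = trace.nucleus_mean[pre_idx[-5:]].mean()
    if roi_ref == 0 or nuc_ref == 0:
        raise ValueError("zero pre-bleach mean; cannot normalize")
    values = (trace.roi_mean / roi_ref) / (trace.nucleus_mean / nuc_ref)
    post = ~is_pre
    return NormalizedCurve(
        times=trace.times[post],
        values=values[post],
        prebleach_values=values[is_pre],
        nucleus_id=trace.nucleus_id,
    )


def aggregate_curves(curves: Sequence[NormalizedCurve]) -> CurveEnsemble:
    """Pointwise mean and SEM (= sd / sqrt(n)) over nuclei on one time grid."""
    if len(curves) < 1:
        raise ValueError("need at least one curve")
    times = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(times) or not np.allclose(c.times, times):
            raise ValueError("curves must share one time grid")
    mat = np.vstack([c.values for c in curves])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return CurveEnsemble(times=times.copy(), mean=mean, sem=sem, n_nuclei=n)


# ---------------------------------------------------------------------------
# kinetic summary
# ---------------------------------------------------------------------------

def _recovery_model(t, f0, plateau, k):
    return f0 + (plateau - f0) * (1.0 - np.exp(-k * t))


def fit_recovery(
    curve: CurveEnsemble | NormalizedCurve,
    method: Literal["interpolated", "exponential_fit"] = "interpolated",
    plateau_tail_fraction: float = 0.10,
) -> KineticSummary:
    """Kinetic summary of a normalized recovery curve.

    interpolated (default)
        ``f0`` is the first post-bleach sample; the plateau is the mean of
        the final ``plateau_tail_fraction`` of post-bleach frames (the
        curve is taken as flattened there); tau-half is the first time the
        curve crosses (f0 + plateau)/2, linearly interpolated between
        frames.

    exponential_fit
        least-squares fit of F(t) = f0 + (plateau - f0)(1 - exp(-k t)) with
        f0, plateau and k free; tau-half = ln 2 / k.  A non-convergent fit
        falls back to the interpolated method with a warning.

    mobile fraction = (plateau - f0) / (1 - f0), clipped to [0, 1]; the
    immobile fraction is its complement.  A curve with plateau <= f0 is
    flagged as no-recovery (mobile 0, tau-half undefined), not an error.
    """
    times = curve.times
    values = curve.mean if isinstance(curve, CurveEnsemble) else curve.values
    if len(times) < 10:
        raise ValueError("need >=10 post-bleach points")

    if method == "exponential_fit":
        f0_guess = values[0]
        plat_guess = values[-max(3, len(values) // 10):].mean()
        span = max(plat_guess - f0_guess, 1e-6)
        # crude rate guess from the time to reach half span
        above = values >= f0_guess + 0.5 * span
        k_guess = np.log(2) / max(times[np.argmax(above)], times[1] - times[0]) if above.any() else 1.0
        try:
            popt, _ = optimize.curve_fit(
                _recovery_model, times, values,
                p0=(f0_guess, plat_guess, k_guess),
                bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        except RuntimeError:
            warnings.warn("exponential fit did not converge; falling back to interpolation")
            summary = fit_recovery(curve, method="interpolated",
                                   plateau_tail_fraction=plateau_tail_fraction)
            return KineticSummary(
                tau_half=summary.tau_half,
                mobile_fraction=summary.mobile_fraction,
                immobile_fraction=summary.immobile_fraction,
                plateau=summary.plateau, f0=summary.f0,
                method="exponential_fit", no_recovery=summary.no_recovery,
                fit_fallback=True,
            )
        f0, plateau, k = popt
        if plateau <= f0:
            return KineticSummary(tau_half=None, mobile_fraction=0.0,
                                  immobile_fraction=1.0, plateau=float(plateau),
                                  f0=float(f0), method=method, no_recovery=True)
        mobile = float(np.clip((plateau - f0) / (1.0 - f0), 0.0, 1.0))
        return KineticSummary(tau_half=float(np.log(2) / k), mobile_fraction=mobile,
                              immobile_fraction=1.0 - mobile, plateau=float(plateau),
                              f0=float(f0), method=method)

    if method != "interpolated":
        raise ValueError(f"unknown method {method!r}")

    f0 = float(values[0])
    n_tail = max(1, int(np.ceil(plateau_tail_fraction * len(values))))
    plateau = float(values[-n_tail:].mean())
    if plateau <= f0:
        return KineticSummary(tau_half=None, mobile_fraction=0.0, immobile_fraction=1.0,
                              plateau=plateau, f0=f0, method=method, no_recovery=True)
    half = 0.5 * (f0 + plateau)
    above = values >= half
    above[0] = False  # f0 itself is below half by construction (plateau > f0)
    if not above.any():
        # never reaches half-recovery within the record; flag as no recovery
        return KineticSummary(tau_half=None, mobile_fraction=0.0, immobile_fraction=1.0,
                              plateau=plateau, f0=f0, method=method, no_recovery=True)
    j = int(np.argmax(above))
    t0, t1 = times[j - 1], times[j]
    v0, v1 = values[j - 1], values[j]
    tau = t0 + (half - v0) / (v1 - v0) * (t1 - t0) if v1 != v0 else t1
    mobile = float(np.clip((plateau - f0) / (1.0 - f0), 0.0, 1.0))
    return KineticSummary(tau_half=float(tau), mobile_fraction=mobile,
                          immobile_fraction=1.0 - mobile, plateau=plateau, f0=f0,
                          method=method)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

def compare_kinetics(
    group_a: Sequence[KineticSummary],
    group_b: Sequence[KineticSummary],
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """Bootstrap comparison of per-nucleus kinetic summaries between groups.

    Reports the fold-change of group-mean tau-half (a / b) and the
    difference of mean immobile fractions (a - b), each with a two-sided
    bootstrap p-value (fraction of nucleus-resampled replicates on the
    other side of the null value, doubled and capped at 1).  Groups whose
    tau-half values are all undefined skip the tau comparison; the immobile
    comparison always runs.  The test method is recorded in the output
    since different labs report different tests for these contrasts.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs >=3 per-nucleus summaries")
    rng = np.random.default_rng(seed)
    out: dict = {"test": "bootstrap", "n_boot": int(n_boot)}

    tau_a = np.array([s.tau_half for s in group_a if s.tau_half is not None], dtype=float)
    tau_b = np.array([s.tau_half for s in group_b if s.tau_half is not None], dtype=float)
    if len(tau_a) >= 3 and len(tau_b) >= 3:
        out["tau_fold"] = float(tau_a.mean() / tau_b.mean())
        out["tau_p"] = _boot_p(tau_a, tau_b, rng, n_boot, statistic="log_ratio")
    else:
        out["tau_fold"] = None
        out["tau_p"] = None

    imm_a = np.array([s.immobile_fraction for s in group_a], dtype=float)
    imm_b = np.array([s.immobile_fraction for s in group_b], dtype=float)
    out["immobile_diff"] = float(imm_a.mean() - imm_b.mean())
    out["immobile_p"] = _boot_p(imm_a, imm_b, rng, n_boot, statistic="diff")
    return out


def _boot_p(a: np.ndarray, b: np.ndarray, rng: np.random.Generator,
            n_boot: int, statistic: str) -> float:
    """Two-sided percentile bootstrap p from the zero-crossing rate."""
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    ma, mb = a[ia].mean(axis=1), b[ib].mean(axis=1)
    if statistic == "log_ratio":
        stat = np.log(ma) - np.log(mb)
        observed = np.log(a.mean()) - np.log(b.mean())
    else:
        stat = ma - mb
        observed = a.mean() - b.mean()
    if observed == 0:
        return 1.0
    crossings = np.mean(stat <= 0) if observed > 0 else np.mean(stat >= 0)
    return float(min(1.0, 2.0 * crossings + 2.0 / n_boot))
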