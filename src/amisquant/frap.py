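"""FRAP trace normalization and one-phase-association fitting.

A fluorescence-recovery-after-photobleaching experiment yields a mean
ROI intensity series F(t): a few pre-bleach frames, a bleach event, and
a recovery tail.  The normalized recovery is

    FRAP(t) = (F(t) - F(0)) / (F(i) - F(0)),

where F(i) is the mean of the pre-bleach frames and F(0) the first
post-bleach frame, so FRAP(0) = 0 by construction and full recovery to
the pre-bleach level maps to 1.  The normalized curve is fitted by
unweighted non-linear least squares to the exponential one-phase
association model with the intercept fixed at zero,

    Y(t) = plateau * (1 - exp(-k t)),

and the plateau is reported as the mobile fraction: the share of the
bleached protein pool that exchanges on the measured timescale.  The
bleach depth 1 - F(0)/F(i) serves as a quality-control statistic for
accepting a bleach event (deep bleaches, > 0.8, are typical at cell–cell
interfaces).

Traces may be fitted per trace and pooled afterwards (the default) or a
single fit may be run on the pointwise mean of several normalized
traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateTraceError, FitError

DEFAULT_PRE_FRAMES = 3


@dataclass
class FRAPTrace:
    """Raw intensity series of one bleach event.

    ``times_s`` are acquisition times (strictly increasing, any origin);
    the first ``n_pre`` frames are pre-bleach.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    n_pre: int = DEFAULT_PRE_FRAMES
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.times_s.shape != self.intensities.shape:
            raise ValueError("times and intensities must have the same length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_pre < 1:
            raise ValueError("need at least one pre-bleach frame")
        if len(self.times_s) <= self.n_pre:
            raise ValueError("trace has no post-bleach frames")


@dataclass
class NormalizedFRAP:
    """Normalized recovery curve; t = 0 at the first post-bleach frame."""

    times_s: np.ndarray
    values: np.ndarray
    f_pre: float  # F(i), mean pre-bleach intensity
    f_bleach: float  # F(0), first post-bleach intensity
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.values = np.asarray(self.values, float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times_s[0] != 0:
            raise ValueError("normalized times must start at 0")


@dataclass
class FRAPFitResult:
    """One-phase-association fit of a normalized recovery curve."""

    plateau: float  # mobile fraction
    rate_k: float  # 1/s
    rss: float
    converged: bool
    n_points: int
    plateau_stderr: float = float("nan")
    rate_k_stderr: float = float("nan")
    trace_id: str = "trace"

    def predict(self, times_s: np.ndarray) -> np.ndarray:
        return one_phase_association(np.asarray(times_s, float), self.plateau, self.rate_k)


def one_phase_association(t: np.ndarray, plateau: float, k: float) -> np.ndarray:
    """Y(t) = plateau * (1 - exp(-k t)), the recovery model with Y(0) = 0."""
    return plateau * -np.expm1(-k * t)


def normalize_frap(trace: FRAPTrace) -> NormalizedFRAP:
    """Normalize a raw trace to FRAP(t) = (F(t) - F(0)) / (F(i) - F(0)).

    F(i) is the mean of the ``n_pre`` pre-bleach intensities and F(0) the
    first post-bleach intensity; times are rebased so the F(0) frame is
    t = 0.  The formula is invariant under affine intensity transforms
    aF + b with a > 0.
    """
    f_pre = float(trace.intensities[: trace.n_pre].mean())
    post = trace.intensities[trace.n_pre :]
    f0 = float(post[0])
    if f_pre == f0:
        raise DegenerateTraceError(
            "pre-bleach mean equals the first post-bleach frame (no bleach)"
        )
    t = trace.times_s[trace.n_pre :] - trace.times_s[trace.n_pre]
    values = (post - f0) / (f_pre - f0)
    return NormalizedFRAP(t, values, f_pre=f_pre, f_bleach=f0, trace_id=trace.trace_id)


def bleach_depth(trace: FRAPTrace) -> float:
    """Bleach-event QC statistic 1 - F(0)/F(i)."""
    f_pre = float(trace.intensities[: trace.n_pre].mean())
    if f_pre <= 0:
        raise DegenerateTraceError("non-positive pre-bleach intensity")
    f0 = float(trace.intensities[trace.n_pre])
    return 1.0 - f0 / f_pre


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """plateau0 = mean of the last 5 points; k0 = ln 2 / half-rise time."""
    p0 = float(y[-5:].mean())
    p0 = min(max(p0, 1e-3), 2.0)
    half = p0 / 2.0
    above = np.nonzero(y >= half)[0]
    k0 = 0.1
    if len(above) and t[above[0]] > 0:
        k0 = float(np.log(2.0) / t[above[0]])
    k0 = min(max(k0, 1e-4), 10.0)
    return p0, k0


def fit_one_phase_association(
    norm: NormalizedFRAP, max_restarts: int = 3
) -> FRAPFitResult:
    """Fit Y(t) = plateau * (1 - exp(-k t)) to a normalized trace.

    Unweighted least squares with bounds plateau ∈ [0, 2], k ∈ [0, 10] /s.
    Initialization uses the tail mean for the plateau and the half-rise
    time for k; on non-convergence a fixed, seeded schedule of up to
    ``max_restarts`` perturbed starts is tried before raising
    :class:`~amisquant.errors.FitError`.
    """
    t, y = norm.times_s, norm.values
    if len(t) < 5:
        raise ValueError("need at least 5 post-bleach points to fit")
    if np.allclose(y, 0.0, atol=1e-12):
        return FRAPFitResult(
            plateau=0.0, rate_k=0.0, rss=0.0, converged=True,
            n_points=len(t), trace_id=norm.trace_id,
        )
    starts = [_initial_guess(t, y)]
    rng = np.random.default_rng(0)
    for _ in range(max_restarts):
        p0, k0 = starts[0]
        starts.append(
            (
                float(np.clip(p0 * rng.uniform(0.5, 1.5), 1e-3, 2.0)),
                float(np.clip(k0 * rng.uniform(0.3, 3.0), 1e-4, 10.0)),
            )
        )
    last_err: Exception | None = None
    for p0, k0 in starts:
        try:
            popt, pcov = curve_fit(
                one_phase_association,
                t,
                y,
                p0=(p0, k0),
                bounds=([0.0, 0.0], [2.0, 10.0]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover - restarts
            last_err = err
            continue
        resid = y - one_phase_association(t, *popt)
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
        return FRAPFitResult(
            plateau=float(popt[0]),
            rate_k=float(popt[1]),
            rss=float(resid @ resid),
            converged=True,
            n_points=len(t),
            plateau_stderr=float(perr[0]),
            rate_k_stderr=float(perr[1]),
            trace_id=norm.trace_id,
        )
    raise FitError(f"one-phase association fit failed to converge: {last_err}")


def fit_frap_traces(
    norms: list[NormalizedFRAP], mode: str = "per-trace"
) -> list[FRAPFitResult]:
    """Fit several normalized traces.

    ``mode="per-trace"`` (default) fits each trace independently so the
    per-trace mobile fractions can be pooled downstream;
    ``mode="pooled"`` fits a single curve to the pointwise mean of the
    traces (all traces must share their time base) and returns a
    one-element list.
    """
    if not norms:
        raise ValueError("no traces to fit")
    if mode == "per-trace":
        return [fit_one_phase_association(n) for n in norms]
    if mode == "pooled":
        t0 = norms[0].times_s
        if any(not np.array_equal(n.times_s, t0) for n in norms):
            raise ValueError("pooled fitting requires a common time base")
        mean_vals = np.stack([n.values for n in norms]).mean(axis=0)
        pooled = NormalizedFRAP(
            t0, mean_vals,
            f_pre=float(np.mean([n.f_pre for n in norms])),
            f_bleach=float(np.mean([n.f_bleach for n in norms])),
            trace_id="pooled",
        )
        return [fit_one_phase_association(pooled)]
    raise ValueError("mode must be 'per-trace' or 'pooled'")
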