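"""Transient-absorbance kinetics: pseudo-first-order formation and
second-order decay fits.

The radical formation croc + OH• -> croc(-H)• + H2O is followed at a fixed
wavelength; with crocin in excess the approach to the plateau is exponential
and the pseudo-first-order test (linearity of ln|A_inf - A(t)| vs t) yields
k_obs = k2 [croc].  The radical self-reaction 2 R• -> R2 is second order in
the radical, so 1/A(t) vs t is a straight line whose slope converts to
2k = slope * eps * l.

Both fits are ordinary unweighted linear regressions on the linearized data
(the classical "tests"); a nonlinear least-squares option is available for
the formation fit when noise makes the log-linearization fragile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KineticTrace",
    "FirstOrderFit",
    "SecondOrderFit",
    "OrderReport",
    "fit_pseudo_first_order",
    "fit_second_order",
    "order_discrimination",
]

#: Default start of the fit window (s): excludes the hydrated-electron bump,
#: which is over by ~50 ns after the pulse.
BUMP_EXCLUSION_S = 50e-9


@dataclass
class KineticTrace:
    """Time-resolved absorbance at one wavelength.

    ``times_s`` must be strictly increasing and the same length as
    ``absorbance``; ``path_cm`` is the optical path of the cell.
    """

    times_s: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float
    path_cm: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times_s.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("times and absorbance must be 1-D")
        if self.times_s.shape != self.absorbance.shape:
            raise ValueError("times and absorbance must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.path_cm <= 0:
            raise ValueError("path_cm must be > 0")

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask selecting t0 <= t <= t1."""
        return (self.times_s >= t0) & (self.times_s <= t1)


@dataclass
class FirstOrderFit:
    """Result of the pseudo-first-order formation test."""

    k_obs: float  # s^-1
    k2: float  # M^-1 s^-1, k_obs / [scavenger]
    plateau: float  # A_inf used in the linearization
    r_squared: float
    window_s: tuple[float, float]
    n_points: int
    ok: bool
    message: str = ""


@dataclass
class SecondOrderFit:
    """Result of the second-order (1/A vs t) decay test."""

    slope: float  # s^-1, the paper-convention k_obs
    intercept: float  # reciprocal absorbance at t=0
    rate_2k: float  # M^-1 s^-1, slope * eps * conversion path
    conversion_path_cm: float
    r_squared: float
    window_s: tuple[float, float]
    n_points: int
    ok: bool
    message: str = ""


@dataclass
class OrderReport:
    """Which linearization (first vs second order) is more linear."""

    first_order_r2: float
    second_order_r2: float
    verdict: str  # "first" | "second" | "neither"
    notes: list[str] = field(default_factory=list)


def _estimate_plateau(trace: KineticTrace, fraction: float = 0.05) -> float:
    """Plateau absorbance as the mean of the final ``fraction`` of samples."""
    n = max(3, int(round(fraction * trace.times_s.size)))
    return float(np.mean(trace.absorbance[-n:]))


def fit_pseudo_first_order(
    trace: KineticTrace,
    scavenger_conc: float,
    window: tuple[float, float | None] = (BUMP_EXCLUSION_S, None),
    plateau: float | None = None,
    min_r2: float = 0.9,
    conversion_cutoff: float = 0.9,
    method: str = "linearized",
) -> FirstOrderFit:
    """Fit an exponential approach to plateau; k_obs = k2 [scavenger].

    Linearized method: ordinary least squares of ln(A_inf - A) vs t inside
    the window, restricted to points before ``conversion_cutoff`` of the
    total rise (beyond ~90% conversion the plateau distance is comparable to
    the absorbance noise and the log would be dominated by it).  ``plateau``
    defaults to the mean of the last 5% of samples.  A fit with R^2 below
    ``min_r2``, a non-positive rate, or an unreached plateau is returned
    with ``ok=False`` rather than raising.
    """
    if scavenger_conc <= 0:
        raise ValueError("scavenger_conc must be > 0")
    if not 0 < conversion_cutoff < 1:
        raise ValueError("conversion_cutoff must be in (0, 1)")
    t0, t1 = window
    if t1 is None:
        t1 = float(trace.times_s[-1])
    a_inf = _estimate_plateau(trace) if plateau is None else float(plateau)

    mask = trace.window(t0, t1)
    t_raw = t = trace.times_s[mask]
    a_raw = a = trace.absorbance[mask]
    failed = FirstOrderFit(
        k_obs=math.nan, k2=math.nan, plateau=a_inf, r_squared=math.nan,
        window_s=(t0, t1), n_points=0, ok=False,
    )
    if t.size < 10:
        failed.message = "fewer than 10 points in the fit window"
        return failed

    depth = a_inf - a
    # Moving-average smoothing of the plateau distance: for an exponential
    # approach this multiplies the depth by a constant (slope unchanged)
    # while shrinking the log-transform noise and its concavity bias by
    # sqrt(k).  Edge points of the convolution are discarded.
    k_smooth = max(1, min(15, depth.size // 10))
    kernel = np.ones(k_smooth) / k_smooth
    depth_s = np.convolve(depth, kernel, mode="same")
    edge = k_smooth // 2
    if edge:
        t, depth_s = t[edge:-edge], depth_s[edge:-edge]
    d0 = float(np.max(depth_s)) if depth_s.size else 0.0
    if d0 <= 0:
        failed.message = "no rise toward the plateau (constant or decaying trace)"
        return failed
    # fit only the contiguous stretch before the conversion cutoff, so
    # noise-dominated plateau points cannot re-enter the regression
    below = np.nonzero(depth_s < (1.0 - conversion_cutoff) * d0)[0]
    start = int(np.argmax(depth_s))
    cut = depth_s.size
    for i in below:
        if i > start:
            cut = int(i)
            break
    valid = np.zeros(depth_s.size, dtype=bool)
    valid[:cut] = depth_s[:cut] > 0
    t_fit, depth_fit = t[valid], depth_s[valid]
    if t_fit.size < 10:
        failed.message = "fewer than 10 points before the conversion cutoff"
        failed.n_points = int(t_fit.size)
        return failed

    if method == "linearized":
        res = stats.linregress(t_fit, np.log(depth_fit))
        k_obs = -float(res.slope)
        r2 = float(res.rvalue**2)
    elif method == "nonlinear":
        res0 = stats.linregress(t_fit, np.log(depth_fit))
        k0 = max(-float(res0.slope), 1.0 / (t_fit[-1] - t_fit[0]))
        popt, _ = optimize.curve_fit(
            lambda tt, a_end, amp, k: a_end - amp * np.exp(-k * tt),
            t_raw, a_raw, p0=(a_inf, d0, k0), maxfev=10_000,
        )
        a_inf, _, k_obs = (float(v) for v in popt)
        pred = popt[0] - popt[1] * np.exp(-popt[2] * t_raw)
        ss_res = float(np.sum((a_raw - pred) ** 2))
        ss_tot = float(np.sum((a_raw - a_raw.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    else:
        raise ValueError(f"unknown method {method!r}")

    message = ""
    ok = True
    if not np.isfinite(k_obs) or k_obs <= 0:
        ok, message = False, "non-positive rate: trace is not a first-order rise"
    elif r2 < min_r2:
        ok, message = False, f"poor linearity (R^2 = {r2:.3f} < {min_r2})"
    # plateau-reached check: the rise rate at the trace end should be a
    # small fraction of the initial rise rate
    n_seg = max(5, t_raw.size // 7)
    if ok and t_raw.size >= 2 * n_seg:
        slope_start = stats.linregress(t_raw[:n_seg], a_raw[:n_seg]).slope
        slope_end = stats.linregress(t_raw[-n_seg:], a_raw[-n_seg:]).slope
        if slope_start > 0 and slope_end > 0.1 * slope_start:
            ok, message = False, "plateau not reached within the trace"

    return FirstOrderFit(
        k_obs=k_obs,
        k2=k_obs / scavenger_conc,
        plateau=a_inf,
        r_squared=r2,
        window_s=(t0, t1),
        n_points=int(t_fit.size),
        ok=ok,
        message=message,
    )


def fit_second_order(
    trace: KineticTrace,
    epsilon: float,
    conversion_path_cm: float = 1.0,
    window: tuple[float, float | None] | None = None,
    min_r2: float = 0.9,
) -> SecondOrderFit:
    """Second-order test: 1/A vs t regression; 2k = slope * eps * l_conv.

    ``conversion_path_cm`` is the optical path folded into the conversion of
    the reciprocal-absorbance slope to concentration units.  It defaults to
    1 cm, the convention under which the reported slope (s^-1) and the
    radical molar absorptivity reproduce 2k directly; pass the actual cell
    path to use the strict Beer-Lambert conversion.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if conversion_path_cm <= 0:
        raise ValueError("conversion_path_cm must be > 0")
    if window is None:
        t0, t1 = float(trace.times_s[0]), float(trace.times_s[-1])
    else:
        t0, t1 = window
        t1 = float(trace.times_s[-1]) if t1 is None else t1
    mask = trace.window(t0, t1)
    t = trace.times_s[mask]
    a = trace.absorbance[mask]
    if np.any(a <= 0):
        raise ValueError("nonpositive absorbance inside the fit window")
    if t.size < 3:
        return SecondOrderFit(
            slope=math.nan, intercept=math.nan, rate_2k=math.nan,
            conversion_path_cm=conversion_path_cm, r_squared=math.nan,
            window_s=(t0, t1), n_points=int(t.size), ok=False,
            message="too few points",
        )
    res = stats.linregress(t, 1.0 / a)
    slope = float(res.slope)
    r2 = float(res.rvalue**2)
    ok, message = True, ""
    if slope <= 0:
        ok, message = False, "non-positive slope: no second-order decay"
    elif r2 < min_r2:
        ok, message = False, f"poor linearity (R^2 = {r2:.3f} < {min_r2})"
    return SecondOrderFit(
        slope=slope,
        intercept=float(res.intercept),
        rate_2k=slope * epsilon * conversion_path_cm,
        conversion_path_cm=conversion_path_cm,
        r_squared=r2,
        window_s=(t0, t1),
        n_points=int(t.size),
        ok=ok,
        message=message,
    )


def order_discrimination(
    trace: KineticTrace,
    window: tuple[float, float | None] | None = None,
) -> OrderReport:
    """Compare first- and second-order linearizations of a decay trace.

    The first-order test regresses ln A vs t (decay to zero baseline), the
    second-order test 1/A vs t; the verdict is the more linear of the two,
    or "neither" when both are degenerate (e.g. a constant trace).
    """
    if window is None:
        t0, t1 = float(trace.times_s[0]), float(trace.times_s[-1])
    else:
        t0, t1 = window
        t1 = float(trace.times_s[-1]) if t1 is None else t1
    mask = trace.window(t0, t1)
    t = trace.times_s[mask]
    a = trace.absorbance[mask]
    notes: list[str] = []
    if t.size < 10:
        return OrderReport(math.nan, math.nan, "neither", ["fewer than 10 points"])
    if np.any(a <= 0):
        return OrderReport(math.nan, math.nan, "neither", ["nonpositive absorbance"])
    if np.ptp(a) <= 1e-12 * np.max(np.abs(a)):
        return OrderReport(math.nan, math.nan, "neither", ["constant trace: no kinetics"])

    res1 = stats.linregress(t, np.log(a))
    res2 = stats.linregress(t, 1.0 / a)
    r1, r2_ = float(res1.rvalue**2), float(res2.rvalue**2)
    if res1.slope >= 0:
        notes.append("first-order test: non-decaying slope")
    if res2.slope <= 0:
        notes.append("second-order test: non-decaying slope")
    verdict = "second" if r2_ > r1 else "first"
    return OrderReport(r1, r2_, verdict, notes)
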