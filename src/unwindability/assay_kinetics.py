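"""Analysis of fluorescence unwinding time courses.

Helicase unwinding assays read out strand separation as a saturating
rise in fluorescence (a quenched dye lights up as the duplex opens).
The summaries computed here are the plateau amplitude, the observed
rate and the initial unwinding velocity, plus the amplitude and
velocity of a test substrate relative to a reference substrate - the
quantities used to compare homopurine- versus homopyrimidine-displaced
duplexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .surrogate_data import KineticTrace

__all__ = [
    "UnwindingSummary",
    "RelativeEfficiency",
    "normalize_trace",
    "fit_exponential",
    "relative_efficiency",
]


@dataclass
class UnwindingSummary:
    """Single-exponential description of one unwinding trace."""

    amplitude: float
    amplitude_se: float
    rate: float  # 1/min
    baseline: float
    velocity_fit: float  # amplitude * rate, per min
    velocity_early: float  # slope of the early-rise linear fit, per min
    resid_rms: float
    no_unwinding: bool = False


@dataclass
class RelativeEfficiency:
    """Test-vs-reference unwinding ratios (reference = 100%)."""

    amplitude_pct: float
    velocity_pct: float
    reference: str = "reference"
    estimator: str = "exponential-fit"

    def __post_init__(self) -> None:
        if self.amplitude_pct < 0 or self.velocity_pct < 0:
            raise ValueError("ratios must be nonnegative")


def normalize_trace(
    trace: KineticTrace,
    k_baseline: int = 5,
    mode: str = "fold",
    reference: Optional[KineticTrace] = None,
) -> KineticTrace:
    """Baseline-subtract and rescale a trace.

    'fold' mode divides the baseline-subtracted signal by the raw
    baseline (fold change over background); 'relative' divides by the
    plateau of a reference trace (its mean over the last 10% of points),
    making the reference plateau 1 by construction.
    """
    if len(trace.time_min) < 5:
        raise ValueError("need at least 5 points")
    base = float(np.mean(trace.fluorescence[:k_baseline]))
    y = trace.fluorescence - base
    if mode == "fold":
        if base <= 0:
            raise ValueError("nonpositive baseline; fold-change undefined")
        y = y / base
    elif mode == "relative":
        ref = trace if reference is None else reference
        tail = max(1, len(ref.fluorescence) // 10)
        ref_base = float(np.mean(ref.fluorescence[:k_baseline]))
        plateau = float(np.mean(ref.fluorescence[-tail:])) - ref_base
        if plateau <= 0:
            raise ValueError("nonpositive reference plateau")
        y = y / plateau
    else:
        raise ValueError(f"unknown mode {mode!r}")
    params = dict(trace.params)
    params.update({"normalized": mode, "k_baseline": k_baseline})
    return KineticTrace(trace.time_min.copy(), y, params)


def _exp_model(t, base, amp, k):
    return base + amp * (1.0 - np.exp(-k * t))


def fit_exponential(trace: KineticTrace) -> UnwindingSummary:
    """Least-squares fit of baseline + A (1 - exp(-k t)).

    The initial velocity is reported both as A*k and as the slope of a
    linear fit to the first 10% of the rise.  Traces whose fitted
    amplitude is indistinguishable from the residual noise are flagged
    as 'no unwinding' instead of reporting a spurious rate.
    """
    t, y = trace.time_min, trace.fluorescence
    if len(t) < 8:
        raise ValueError("need at least 8 points to fit")
    y0 = float(np.mean(y[:3]))
    amp0 = float(np.mean(y[-max(3, len(y) // 10):]) - y0)
    span = t[-1] - t[0]
    k0 = 2.0 / span if span > 0 else 1.0
    try:
        popt, pcov = curve_fit(
            _exp_model, t, y, p0=[y0, max(amp0, 1e-6), k0],
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"exponential fit did not converge: {err}; "
            f"n={len(t)}, span={span:.3g} min, crude amplitude={amp0:.3g}"
        ) from None
    base, amp, k = popt
    resid = y - _exp_model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    amp_se = float(np.sqrt(max(pcov[1, 1], 0.0))) if np.all(np.isfinite(pcov)) else float("inf")

    no_unwinding = amp <= max(3.0 * rms, 0.0) and abs(amp) < 0.05 * max(abs(y).max(), 1e-12) + 3 * rms

    # early-rise slope: linear fit over points before 10% of the rise
    target = base + 0.1 * amp
    rising = np.nonzero(y >= target)[0]
    i_end = max(int(rising[0]) + 1, 3) if len(rising) else len(t)
    i_end = min(i_end, len(t))
    sl = np.polyfit(t[:i_end], y[:i_end], 1)[0] if i_end >= 2 else 0.0
    return UnwindingSummary(
        amplitude=float(amp),
        amplitude_se=amp_se,
        rate=float(k),
        baseline=float(base),
        velocity_fit=float(amp * k),
        velocity_early=float(sl),
        resid_rms=rms,
        no_unwinding=bool(no_unwinding),
    )


def relative_efficiency(
    test: UnwindingSummary,
    reference: UnwindingSummary,
    use_early_velocity: bool = False,
) -> RelativeEfficiency:
    """Amplitude and initial-velocity percentages of test vs reference."""
    if reference.amplitude <= 0:
        raise ValueError("reference amplitude must be positive")
    v_test = test.velocity_early if use_early_velocity else test.velocity_fit
    v_ref = reference.velocity_early if use_early_velocity else reference.velocity_fit
    if v_ref <= 0:
        raise ValueError("reference velocity must be positive")
    amp_pct = 100.0 * max(test.amplitude, 0.0) / reference.amplitude
    vel_pct = 100.0 * max(v_test, 0.0) / v_ref
    return RelativeEfficiency(
        amplitude_pct=amp_pct,
        velocity_pct=vel_pct,
        estimator="early-slope" if use_early_velocity else "exponential-fit",
    )
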