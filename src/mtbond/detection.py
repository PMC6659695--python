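"""Rupture-event detection and classification on sampled force traces.

A rupture appears in a trace as a ramp that ends in an abrupt force drop
(the bead snapping back toward the trap centre within a few bead
relaxation times).  Detection is therefore a force-drop criterion: a
sample is a rupture candidate when the smoothed force magnitude falls by
at least ``drop_fraction`` of its peak value within ``drop_window``
seconds.  Events whose peak never exceeds the instrument's force
detection limit (~0.3 pN in the emulated setup) are suppressed.

Events are classified *primary* when the bond formed at (near-)zero
force — the smoothed force magnitude between the previous rupture and
the new ramp dipped below ``primary_threshold`` — and *secondary* when
the head rebound before the bead finished relaxing (F_start > 0).  Only
primary events enter downstream statistics, since the force history of a
secondary event depends on its starting force.

The per-event loading rate is the least-squares slope of the 200 ms of
force preceding detachment, mirroring how compliance-corrected loading
rates are measured experimentally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import EventSet, ForceTrace, RuptureEvent

__all__ = [
    "DetectionParams",
    "DetectionError",
    "detect_events",
    "classify_primary",
    "fit_loading_rate",
]


class DetectionError(ValueError):
    """Invalid trace or detection configuration."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds for rupture detection.

    ``smooth_window`` is in samples; ``None`` selects 5 ms worth of
    samples (below the bead relaxation time, above single-sample noise).
    """

    F_min_event: float = 0.3  # pN, instrument detection limit
    drop_fraction: float = 0.8  # fraction of peak lost within drop_window
    drop_window: float = 0.02  # s
    primary_threshold: float = 0.3  # pN, max F_start for a primary call
    smooth_window: int | None = None  # samples; None -> 5 ms of samples

    def __post_init__(self) -> None:
        if not self.F_min_event > 0:
            raise DetectionError("F_min_event must be positive")
        if not 0 < self.drop_fraction <= 1:
            raise DetectionError("drop_fraction must be in (0, 1]")
        if self.primary_threshold < 0:
            raise DetectionError("primary_threshold must be >= 0")
        if self.smooth_window is not None and self.smooth_window < 1:
            raise DetectionError("smooth_window must be >= 1")

    def window_samples(self, f_sample: float) -> int:
        if self.smooth_window is not None:
            return self.smooth_window
        return max(1, int(round(0.005 * f_sample)))


def _boxcar(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w) / w
    # edge-padded moving average keeps length and avoids edge bias
    xp = np.pad(x.astype(float), (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def detect_events(trace: ForceTrace, params: DetectionParams | None = None) -> EventSet:
    """Recover rupture events from a force trace.

    Returns events ordered in time with F_unbind read from the smoothed
    trace at the pre-drop peak, F_start from the minimum force magnitude
    between consecutive ramps, and r_local from the pre-detachment line
    fit.  When two samples inside one drop window both qualify, the
    earlier one is kept.
    """
    params = params or DetectionParams()
    if len(trace.F) == 0:
        raise DetectionError(f"trace {trace.trace_id!r} is empty")
    if not np.all(np.isfinite(trace.F)):
        raise DetectionError(f"trace {trace.trace_id!r} contains non-finite samples")

    f_sample = trace.trap.f_sample
    w_smooth = params.window_samples(f_sample)
    w_drop = max(1, int(round(params.drop_window * f_sample)))
    Fs = _boxcar(trace.F, w_smooth)
    A = np.abs(Fs)
    n = len(A)

    # forward rolling minimum of A over (i, i + w_drop]
    fwd_min = np.full(n, np.inf)
    for j in range(1, w_drop + 1):
        fwd_min[: n - j] = np.minimum(fwd_min[: n - j], A[j:])
    local_peak = np.zeros(n, dtype=bool)
    local_peak[:-1] = A[:-1] >= A[1:]
    cand = (
        (A >= params.F_min_event)
        & (fwd_min <= (1.0 - params.drop_fraction) * A)
        & local_peak
    )
    cand_idx = np.flatnonzero(cand)

    events: list[RuptureEvent] = []
    prev_end = 0
    last_accept = -10 * w_drop
    for i in cand_idx:
        if i - last_accept <= w_drop:
            continue
        seg = A[prev_end:i]
        if len(seg):
            j_min = prev_end + int(np.argmin(seg))
            F_start = float(A[j_min])
        else:
            j_min = i
            F_start = 0.0
        ev = RuptureEvent(
            F_unbind=float(Fs[i]),
            F_start=F_start,
            direction="forward" if Fs[i] < 0 else "backward",
            r_local=float("nan"),
            primary=F_start <= params.primary_threshold,
            t_bind=float(trace.t[j_min]),
            t_unbind=float(trace.t[i]),
            trace_id=trace.trace_id,
        )
        events.append(ev)
        last_accept = i
        prev_end = min(i + w_drop + 1, n)

    # fill per-event loading rates from the pre-detachment segment
    filled: list[RuptureEvent] = []
    for ev in events:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # window-shrink flags, one per short event
                r_loc = fit_loading_rate(trace, ev)
        except DetectionError:
            r_loc = float("nan")
        filled.append(
            RuptureEvent(
                F_unbind=ev.F_unbind,
                F_start=ev.F_start,
                direction=ev.direction,
                r_local=r_loc,
                primary=ev.primary,
                t_bind=ev.t_bind,
                t_unbind=ev.t_unbind,
                trace_id=ev.trace_id,
            )
        )
    return EventSet(events=filled, label=trace.trace_id)


def classify_primary(event: RuptureEvent, params: DetectionParams | None = None) -> bool:
    """True iff the event's starting force is at or below the primary threshold."""
    params = params or DetectionParams()
    return event.F_start <= params.primary_threshold


def fit_loading_rate(trace: ForceTrace, event: RuptureEvent, window: float = 0.2) -> float:
    """Least-squares loading rate (pN/s) from the segment before detachment.

    Fits a line to force vs. time on [t_unbind - window, t_unbind) and
    returns the slope magnitude.  If the window would reach before the
    bond formed it is shrunk to [t_bind, t_unbind) with a warning.
    """
    t0 = event.t_unbind - window
    if t0 < event.t_bind:
        warnings.warn(
            f"loading-rate window shrunk to bond lifetime for event at "
            f"t={event.t_unbind:.3f}s on {trace.trace_id!r}",
            stacklevel=2,
        )
        t0 = event.t_bind
    mask = (trace.t >= t0) & (trace.t <= event.t_unbind)
    if int(mask.sum()) < 10:
        raise DetectionError(
            f"fewer than 10 samples in loading-rate window for event at "
            f"t={event.t_unbind:.3f}s on {trace.trace_id!r}"
        )
    slope = np.polyfit(trace.t[mask], trace.F[mask], 1)[0]
    return float(abs(slope))
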