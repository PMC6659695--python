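"""Synthetic optical-trap, dwell-time, and motility data with known truth.

Emulates the three single-molecule assays that produce the data this
package analyses:

* **Constant-pulling trap assay** — a bead-bound motor head is held in an
  optical trap while the stage sweeps the microtubule past it at constant
  speed, ramping the load on the bond at a nominal r = k_trap * v_stage
  (5.6 pN/s in the experiments this emulates) until the bond ruptures.
  Two simulators are provided: an event-level fast path
  (:func:`simulate_events`) that samples rupture forces exactly from the
  inhomogeneous-Poisson survival along the deterministic ramp, and a
  trace-level path (:func:`simulate_trace`) that emits a sampled force
  trace with noise, bead relaxation and rebinding, plus an embedded
  ground-truth event log for validating detection.
* **TIRF dwell assay** — exponential zero-load bound times observed at a
  finite frame interval (100 ms in the experiments), so recorded dwells
  are frame-quantized and sub-frame events are unobservable.
* **Motility assay** — processive runs with Gaussian velocities and
  exponential run lengths.

All randomness flows through an explicit integer seed; equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bond_models import AnisotropicBond, BondModelError, RateLaw

__all__ = [
    "TrapConfig",
    "MotorLinkage",
    "PullingProtocol",
    "ForceTrace",
    "RuptureEvent",
    "EventSet",
    "DwellSet",
    "RunSet",
    "effective_loading_rate",
    "peak_loading_rate",
    "simulate_events",
    "simulate_trace",
    "simulate_dwells",
    "simulate_runs",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = (
    "trace_id",
    "t_bind",
    "t_unbind",
    "F_start",
    "F_unbind",
    "direction",
    "r_local",
    "primary",
)

#: force step (pN) for hazard-inversion grids in the event-level sampler
_SAMPLER_DF = 1e-4


class ConfigError(ValueError):
    """Invalid assay configuration."""


@dataclass(frozen=True)
class TrapConfig:
    """Optical-trap settings for a pulling assay.

    Defaults follow the weak-binding operating point of the emulated
    experiments: 0.025 pN/nm stiffness and a 225 nm/s stage speed give
    the nominal 5.6 pN/s loading rate.
    """

    k_trap: float = 0.025  # pN/nm
    v_stage: float = 225.0  # nm/s
    f_sample: float = 2000.0  # Hz
    sigma_noise: float = 0.08  # pN, white Gaussian on sampled force
    tau_bead: float = 0.005  # s, bead relaxation after release

    def __post_init__(self) -> None:
        if self.k_trap < 0.001:
            raise ConfigError(f"k_trap must be >= 0.001 pN/nm, got {self.k_trap}")
        if not self.v_stage > 0:
            raise ConfigError(f"v_stage must be positive, got {self.v_stage}")
        if not self.f_sample > 0:
            raise ConfigError(f"f_sample must be positive, got {self.f_sample}")
        if self.sigma_noise < 0:
            raise ConfigError(f"sigma_noise must be >= 0, got {self.sigma_noise}")
        if self.tau_bead < 0:
            raise ConfigError(f"tau_bead must be >= 0, got {self.tau_bead}")


@dataclass(frozen=True)
class MotorLinkage:
    """Stiffness of the motor-bead linkage; ``rigid`` disables compliance."""

    k_motor: float = math.inf  # pN/nm
    rigid: bool = True

    def __post_init__(self) -> None:
        if not self.rigid and not self.k_motor > 0:
            raise ConfigError(f"k_motor must be positive, got {self.k_motor}")
        if math.isinf(self.k_motor):
            object.__setattr__(self, "rigid", True)

    @classmethod
    def compliant(cls, k_motor: float) -> "MotorLinkage":
        return cls(k_motor=k_motor, rigid=False)


@dataclass(frozen=True)
class PullingProtocol:
    """Stage/trap motion program.

    ``constant_pull``: the stage sweeps at TrapConfig.v_stage, reversing
    direction every ``sweep_duration`` seconds (forward sweep first).
    ``oscillatory``: the trap jumps between +/-``amplitude`` at
    ``trap_speed``, dwelling ``dwell_at_extremes`` at each end; only the
    loading-rate physics of this protocol is modelled.
    """

    mode: str = "constant_pull"
    sweep_duration: float = 10.0  # s per direction (constant_pull)
    amplitude: float = 250.0  # nm (oscillatory)
    trap_speed: float = 1e6  # nm/s (oscillatory)
    dwell_at_extremes: float = 0.5  # s (oscillatory)

    def __post_init__(self) -> None:
        if self.mode not in ("constant_pull", "oscillatory"):
            raise ConfigError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "constant_pull" and not self.sweep_duration > 0:
            raise ConfigError("sweep_duration must be positive")
        if self.mode == "oscillatory":
            if not self.amplitude > 0 or not self.trap_speed > 0:
                raise ConfigError("oscillatory amplitude and trap_speed must be positive")


@dataclass(frozen=True)
class RuptureEvent:
    """One bond rupture. ``F_unbind`` is signed (negative = forward load)."""

    F_unbind: float  # pN, signed
    F_start: float  # pN, magnitude at bond formation
    direction: str  # "forward" | "backward"
    r_local: float  # pN/s at detachment
    primary: bool
    t_bind: float  # s
    t_unbind: float  # s
    trace_id: str = ""
    censored: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ConfigError(f"unknown direction {self.direction!r}")


@dataclass
class EventSet:
    """Pooled rupture events from one experimental condition."""

    events: list[RuptureEvent]
    label: str = ""

    @property
    def N(self) -> int:
        return len(self.events)

    def __len__(self) -> int:
        return self.N

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trace_id": e.trace_id,
                "t_bind": e.t_bind,
                "t_unbind": e.t_unbind,
                "F_start": e.F_start,
                "F_unbind": e.F_unbind,
                "direction": e.direction,
                "r_local": e.r_local,
                "primary": e.primary,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "EventSet":
        events = [
            RuptureEvent(
                F_unbind=float(row.F_unbind),
                F_start=float(row.F_start),
                direction=str(row.direction),
                r_local=float(row.r_local),
                primary=bool(row.primary),
                t_bind=float(row.t_bind),
                t_unbind=float(row.t_unbind),
                trace_id=str(row.trace_id),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(events=events, label=label)

    def forces(self, direction: str | None = None, primary_only: bool = True) -> np.ndarray:
        """Rupture-force magnitudes, optionally one direction / primary only."""
        out = [
            abs(e.F_unbind)
            for e in self.events
            if (direction is None or e.direction == direction)
            and (not primary_only or e.primary)
            and not e.censored
        ]
        return np.asarray(out, dtype=float)

    def select(self, direction: str | None = None, primary_only: bool = True) -> "EventSet":
        evts = [
            e
            for e in self.events
            if (direction is None or e.direction == direction)
            and (not primary_only or e.primary)
            and not e.censored
        ]
        return EventSet(events=evts, label=self.label)


@dataclass
class ForceTrace:
    """Uniformly sampled signed force from one bead, with ground truth."""

    t: np.ndarray  # s
    F: np.ndarray  # pN, signed (negative = forward load)
    trap: TrapConfig
    linkage: MotorLinkage
    protocol: PullingProtocol
    seed: int
    trace_id: str = "trace0"
    truth: EventSet = field(default_factory=lambda: EventSet(events=[]))

    def __post_init__(self) -> None:
        if len(self.t) != len(self.F):
            raise ConfigError("time and force arrays differ in length")


@dataclass
class DwellSet:
    """Frame-quantized zero-load bound durations."""

    dwells: np.ndarray  # s, positive multiples of frame_interval
    frame_interval: float  # s
    true_rate: float | None = None  # 1/s, simulation ground truth
    n_discarded: int = 0  # sub-frame dwells dropped

    @property
    def n(self) -> int:
        return len(self.dwells)


@dataclass
class RunSet:
    """Processive runs: (velocity nm/s, run length um) pairs."""

    velocities: np.ndarray  # nm/s
    run_lengths: np.ndarray  # um
    true_v_mean: float | None = None
    true_v_sd: float | None = None
    true_L_char: float | None = None
    L_min: float = 0.0

    @property
    def n(self) -> int:
        return len(self.velocities)


# ---------------------------------------------------------------------------
# loading-rate physics


def effective_loading_rate(
    trap: TrapConfig, link: MotorLinkage, speed: float | None = None
) -> float:
    """Loading rate r = v * (1/k_trap + 1/k_motor)^-1 in pN/s.

    The trap and the motor-bead linkage act as springs in series; a rigid
    linkage reduces to r = k_trap * v.  ``speed`` overrides the stage
    speed (used for the oscillatory protocol's trap speed).
    """
    v = trap.v_stage if speed is None else speed
    if link.rigid:
        return trap.k_trap * v
    k_eff = 1.0 / (1.0 / trap.k_trap + 1.0 / link.k_motor)
    return v * k_eff


def serial_dilution(c0: float, factors: Sequence[float]) -> float:
    """Residual concentration after successive dilution steps.

    E.g. a 6 mM nucleotide stock pre-diluted 100-fold and twice
    resuspended 40-fold leaves 6e6 nM / (100*40*40) = 37.5 nM.
    """
    if not c0 >= 0 or any(f <= 0 for f in factors):
        raise ConfigError("concentration must be >= 0 and factors positive")
    out = float(c0)
    for f in factors:
        out /= f
    return out


def peak_loading_rate(
    trap: TrapConfig, link: MotorLinkage, protocol: PullingProtocol
) -> float:
    """Peak loading rate of a protocol; for oscillatory, at the trap jump."""
    if protocol.mode == "oscillatory":
        return effective_loading_rate(trap, link, speed=protocol.trap_speed)
    return effective_loading_rate(trap, link)


# ---------------------------------------------------------------------------
# event-level fast path


def _invert_hazard(
    law: RateLaw,
    exp_draws: np.ndarray,
    r_fn: Callable[[np.ndarray], np.ndarray] | None,
    r_const: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Map Exp(1) draws to rupture forces by inverting the force-domain hazard.

    With a force-dependent loading rate r(F) the survival is
    exp(-int_0^F k(u)/r(u) du); the integral is tabulated on a fine force
    grid and inverted by interpolation.  Returns (forces, censored mask);
    censored draws are clamped to the force cap.
    """
    F_cap = law.F_max * (1 - 1e-12)
    grid = np.arange(0.0, law.F_max + _SAMPLER_DF, _SAMPLER_DF)
    grid[-1] = min(grid[-1], F_cap)
    if r_fn is None:
        G = np.asarray(law.cumulative_hazard(grid)) / r_const
    else:
        integrand = np.asarray(law.rate(np.minimum(grid, F_cap))) / np.asarray(
            r_fn(grid), dtype=float
        )
        G = np.concatenate(
            [[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2.0 * np.diff(grid))]
        )
    censored = exp_draws > G[-1]
    F = np.interp(exp_draws, G, grid)
    F[censored] = F_cap
    return F, censored


def simulate_events(
    bond: AnisotropicBond,
    trap: TrapConfig,
    link: MotorLinkage,
    protocol: PullingProtocol,
    n_per_direction: int,
    seed: int,
    r_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    label: str = "",
) -> EventSet:
    """Sample rupture events directly from the ramp survival (no traces).

    Each event starts at zero force (no rebinding on this path) and
    ruptures at the force where its integrated hazard crosses an Exp(1)
    draw.  ``r_fn``, if given, is a force-dependent loading rate r(F) in
    pN/s overriding the protocol's constant rate.  Events that survive to
    the law's force cap are flagged censored.
    """
    if n_per_direction < 1:
        raise ConfigError("n_per_direction must be >= 1")
    rng = np.random.default_rng(seed)
    r_const = peak_loading_rate(trap, link, protocol)
    events: list[RuptureEvent] = []
    for direction, sign in (("forward", -1.0), ("backward", 1.0)):
        law = bond.law(direction)
        draws = rng.exponential(size=n_per_direction)
        F, censored = _invert_hazard(law, draws, r_fn, r_const)
        if r_fn is None:
            r_local = np.full_like(F, r_const)
            t_unbind = F / r_const
        else:
            r_local = np.asarray(r_fn(F), dtype=float)
            # time to reach F: int_0^F dF'/r(F')
            grid = np.arange(0.0, law.F_max + _SAMPLER_DF, _SAMPLER_DF)
            inv_r = 1.0 / np.asarray(r_fn(grid), dtype=float)
            T = np.concatenate(
                [[0.0], np.cumsum((inv_r[1:] + inv_r[:-1]) / 2.0 * np.diff(grid))]
            )
            t_unbind = np.interp(F, grid, T)
        for i in range(n_per_direction):
            events.append(
                RuptureEvent(
                    F_unbind=float(sign * F[i]),
                    F_start=0.0,
                    direction=direction,
                    r_local=float(r_local[i]),
                    primary=True,
                    t_bind=0.0,
                    t_unbind=float(t_unbind[i]),
                    trace_id=f"sim-{direction}-{i}",
                    censored=bool(censored[i]),
                )
            )
    return EventSet(events=events, label=label)


# ---------------------------------------------------------------------------
# trace-level path


def simulate_trace(
    bond: AnisotropicBond,
    trap: TrapConfig,
    link: MotorLinkage,
    protocol: PullingProtocol,
    duration: float,
    k_on: float,
    seed: int,
    trace_id: str = "trace0",
    bind_at_start: bool = True,
) -> ForceTrace:
    """Simulate a sampled force trace with rebinding and bead relaxation.

    While bound the force follows the deterministic ramp; rupture is a
    per-sample Bernoulli with hazard k(|F|).  After rupture the force
    relaxes exponentially with ``tau_bead`` and the head rebinds at rate
    ``k_on``; rebinding before relaxation completes starts the next event
    at F_start > 0 (a *secondary* event).  The stage reverses every
    ``sweep_duration``; the force re-zeroes at each reversal.  White
    Gaussian noise (``sigma_noise``) is added to the stored samples only;
    the embedded truth log records noiseless rupture values.
    """
    if not duration > 0:
        raise ConfigError("duration must be positive")
    if k_on < 0:
        raise ConfigError("k_on must be >= 0")
    if trap.tau_bead > 0 and trap.f_sample * trap.tau_bead < 5:
        raise ConfigError(
            f"f_sample={trap.f_sample} Hz cannot resolve tau_bead={trap.tau_bead} s "
            "(need >= 5 samples per relaxation time)"
        )
    rng = np.random.default_rng(seed)
    dt = 1.0 / trap.f_sample
    n = int(round(duration * trap.f_sample))
    t = np.arange(n) * dt
    r = effective_loading_rate(trap, link)
    F_cap = min(bond.forward.F_max, bond.backward.F_max) * (1 - 1e-9)

    F = np.zeros(n)
    truth: list[RuptureEvent] = []
    bound = bind_at_start
    F_now = 0.0  # signed, noiseless
    t_bind = 0.0
    F_start = 0.0
    p_on = -math.expm1(-k_on * dt) if k_on > 0 else 0.0
    decay = math.exp(-dt / trap.tau_bead) if trap.tau_bead > 0 else 0.0
    for i in range(n):
        sweep_idx = int(t[i] // protocol.sweep_duration)
        sign = -1.0 if sweep_idx % 2 == 0 else 1.0  # forward sweep first
        # at a stage reversal the ramp simply changes sign: a surviving
        # bond is unloaded through zero and re-loaded the other way
        if bound:
            direction = "forward" if (F_now < 0 or (F_now == 0 and sign < 0)) else "backward"
            law = bond.law("forward" if sign < 0 else "backward")
            k_now = float(law.rate(min(abs(F_now), F_cap)))
            if rng.random() < -math.expm1(-k_now * dt):
                truth.append(
                    RuptureEvent(
                        F_unbind=F_now,
                        F_start=F_start,
                        direction=direction,
                        r_local=r,
                        primary=F_start <= 0.3,
                        t_bind=t_bind,
                        t_unbind=t[i],
                        trace_id=trace_id,
                    )
                )
                bound = False
            else:
                F[i] = F_now
                F_now = F_now + sign * r * dt
                if abs(F_now) >= F_cap:
                    F_now = math.copysign(F_cap, F_now)
                continue
        # unbound: relax and possibly rebind
        F[i] = F_now
        F_now *= decay
        if k_on > 0 and rng.random() < p_on:
            bound = True
            t_bind = t[i]
            F_start = abs(F_now)
    if trap.sigma_noise > 0:
        F = F + rng.normal(0.0, trap.sigma_noise, size=n)
    return ForceTrace(
        t=t,
        F=F,
        trap=trap,
        linkage=link,
        protocol=protocol,
        seed=seed,
        trace_id=trace_id,
        truth=EventSet(events=truth, label=trace_id),
    )


# ---------------------------------------------------------------------------
# dwell and motility assays


def simulate_dwells(
    rate: float, n: int, frame_interval: float, seed: int
) -> DwellSet:
    """Frame-quantized exponential dwell times at a finite acquisition rate.

    Draws ``n`` exponential bound times with the given detachment rate,
    discards dwells shorter than one frame (unobservable at the camera's
    frame interval) and rounds the survivors up to whole frames.  The
    returned set may therefore hold fewer than ``n`` dwells; the number
    discarded is recorded.
    """
    if not rate > 0:
        raise ConfigError("rate must be positive")
    if n < 1:
        raise ConfigError("n must be >= 1")
    if not frame_interval > 0:
        raise ConfigError("frame_interval must be positive")
    rng = np.random.default_rng(seed)
    raw = rng.exponential(scale=1.0 / rate, size=n)
    kept = raw[raw >= frame_interval]
    dwells = np.ceil(kept / frame_interval) * frame_interval
    return DwellSet(
        dwells=dwells,
        frame_interval=frame_interval,
        true_rate=rate,
        n_discarded=int(n - len(kept)),
    )


def simulate_runs(
    v_mean: float,
    v_sd: float,
    L_char: float,
    L_min: float,
    n: int,
    seed: int,
) -> RunSet:
    """Motility runs: Gaussian velocities, shifted-exponential run lengths.

    Defaults elsewhere in the package emulate the measured processive
    motor: ~108 nm/s mean velocity and ~1.1 um characteristic run length.
    """
    if v_sd < 0 or not L_char > 0 or L_min < 0 or n < 1:
        raise ConfigError("invalid run-simulation parameters")
    rng = np.random.default_rng(seed)
    v = rng.normal(v_mean, v_sd, size=n) if v_sd > 0 else np.full(n, float(v_mean))
    L = L_min + rng.exponential(scale=L_char, size=n)
    return RunSet(
        velocities=v,
        run_lengths=L,
        true_v_mean=v_mean,
        true_v_sd=v_sd,
        true_L_char=L_char,
        L_min=L_min,
    )
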