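"""Piecewise force-dependent unbinding-rate laws and their ramp statistics.

A motor-track bond under load detaches at a force-dependent rate k(F).
The phenomenology seen in force-ramp experiments on dynein's
microtubule-binding domain is piecewise: *slip* stretches where the rate
grows exponentially with force (Bell's law, k0*exp(F/F_beta)) and *ideal*
plateaus where the rate is force-independent.  A :class:`RateLaw` is an
ordered, contiguous chain of such segments on [0, F_max); an
:class:`AnisotropicBond` pairs one law per pulling direction (forward =
toward the microtubule minus end, backward = toward the plus end).

Under a constant loading rate r the rupture-force density follows from
standard survival calculus,

    p(F) = (k(F) / r) * exp(-H(F) / r),      H(F) = int_0^F k(u) du,

and every quantity here (pdf, mean rupture force, sampling in the
companion synthetic module) is built on the analytic cumulative hazard
H(F), which has a closed form per segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "RateSegment",
    "RateLaw",
    "AnisotropicBond",
    "MeanRuptureForce",
    "eval_rate",
    "rupture_pdf",
    "mean_rupture_force",
]

#: Default upper edge of a law's domain (pN); far above observed ruptures.
DEFAULT_F_MAX = 25.0

#: Relative tolerance for the continuity check at segment junctions.
_JUNCTION_RTOL = 1e-9


class BondModelError(ValueError):
    """Invalid rate-law construction or evaluation."""


@dataclass(frozen=True)
class RateSegment:
    """One piece of a piecewise unbinding-rate law.

    ``k0`` is the rate at the segment's own lower edge ``F_lo``; a
    ``bell_slip`` segment then evolves as ``k0 * exp((F - F_lo)/F_scale)``,
    which makes continuity across junctions a matter of chaining ``k0``
    values rather than solving for offsets.
    """

    form: str  # "ideal" | "bell_slip"
    k0: float  # rate at F_lo (1/s)
    F_lo: float  # pN, inclusive
    F_hi: float  # pN, exclusive
    F_scale: float | None = None  # Bell force scale F_beta (pN); bell_slip only

    def __post_init__(self) -> None:
        if self.form not in ("ideal", "bell_slip"):
            raise BondModelError(f"unknown segment form {self.form!r}")
        if not self.k0 > 0:
            raise BondModelError(f"k0 must be positive, got {self.k0}")
        if not self.F_lo < self.F_hi:
            raise BondModelError(
                f"segment range invalid: F_lo={self.F_lo} >= F_hi={self.F_hi}"
            )
        if self.form == "bell_slip":
            if self.F_scale is None or not self.F_scale > 0:
                raise BondModelError(
                    f"bell_slip segment requires F_scale > 0, got {self.F_scale}"
                )

    def rate(self, F: np.ndarray | float) -> np.ndarray | float:
        """Rate at force magnitude F (assumed inside [F_lo, F_hi))."""
        if self.form == "ideal":
            return self.k0 * np.ones_like(np.asarray(F, dtype=float))
        return self.k0 * np.exp((np.asarray(F, dtype=float) - self.F_lo) / self.F_scale)

    def hazard_increment(self, F: np.ndarray | float) -> np.ndarray | float:
        """int_{F_lo}^{F} k(u) du for F inside the segment (closed form)."""
        dF = np.asarray(F, dtype=float) - self.F_lo
        if self.form == "ideal":
            return self.k0 * dF
        return self.k0 * self.F_scale * np.expm1(dF / self.F_scale)

    @property
    def rate_at_hi(self) -> float:
        """Left limit of the rate at the segment's upper edge."""
        if self.form == "ideal":
            return self.k0
        return self.k0 * math.exp((self.F_hi - self.F_lo) / self.F_scale)

    def to_dict(self) -> dict:
        d = {"form": self.form, "k0": self.k0, "F_lo": self.F_lo, "F_hi": self.F_hi}
        if self.F_scale is not None:
            d["F_scale"] = self.F_scale
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RateSegment":
        return cls(
            form=d["form"],
            k0=float(d["k0"]),
            F_lo=float(d["F_lo"]),
            F_hi=float(d["F_hi"]),
            F_scale=float(d["F_scale"]) if d.get("F_scale") is not None else None,
        )


@dataclass(frozen=True)
class RateLaw:
    """Piecewise unbinding-rate law k(F) on [0, F_max).

    Segments must tile [0, F_max) contiguously and match rates at every
    junction (the law is continuous by construction).  Use the factory
    classmethods for the laws seen experimentally: :meth:`ideal`,
    :meth:`bell_slip`, :meth:`slip_ideal`, :meth:`ideal_slip`.
    """

    segments: tuple[RateSegment, ...]
    # cached per-segment cumulative hazard at each F_lo
    _H_lo: tuple[float, ...] = field(default=(), compare=False, repr=False)

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise BondModelError("a RateLaw needs at least one segment")
        if segs[0].F_lo != 0.0:
            raise BondModelError(f"first segment must start at 0, got {segs[0].F_lo}")
        for a, b in zip(segs, segs[1:]):
            if not math.isclose(a.F_hi, b.F_lo, rel_tol=0, abs_tol=1e-12):
                raise BondModelError(
                    f"segments not contiguous: [{a.F_lo},{a.F_hi}) then [{b.F_lo},{b.F_hi})"
                )
            if not math.isclose(a.rate_at_hi, b.k0, rel_tol=_JUNCTION_RTOL):
                raise BondModelError(
                    f"rate discontinuity at F={a.F_hi}: {a.rate_at_hi} vs {b.k0}"
                )
        H = [0.0]
        for s in segs[:-1]:
            H.append(H[-1] + float(s.hazard_increment(s.F_hi)))
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "_H_lo", tuple(H))

    # -- factories ---------------------------------------------------------

    @classmethod
    def ideal(cls, k0: float, F_max: float = DEFAULT_F_MAX) -> "RateLaw":
        """Force-independent bond: k(F) = k0 everywhere."""
        return cls((RateSegment("ideal", k0, 0.0, F_max),))

    @classmethod
    def bell_slip(
        cls, k0: float, F_scale: float, F_max: float = DEFAULT_F_MAX
    ) -> "RateLaw":
        """Pure slip bond: k(F) = k0 * exp(F / F_scale)."""
        return cls((RateSegment("bell_slip", k0, 0.0, F_max, F_scale),))

    @classmethod
    def slip_ideal(
        cls,
        k0: float,
        F_scale: float,
        F_switch: float,
        F_max: float = DEFAULT_F_MAX,
    ) -> "RateLaw":
        """Slip up to F_switch, then a force-independent plateau.

        This is the behaviour of the dynein bond under backward load:
        rate grows up to ~2 pN and then saturates.
        """
        k_sw = k0 * math.exp(F_switch / F_scale)
        return cls(
            (
                RateSegment("bell_slip", k0, 0.0, F_switch, F_scale),
                RateSegment("ideal", k_sw, F_switch, F_max),
            )
        )

    @classmethod
    def ideal_slip(
        cls,
        k0: float,
        F_switch: float,
        F_scale: float,
        F_max: float = DEFAULT_F_MAX,
    ) -> "RateLaw":
        """Force-independent plateau up to F_switch, slip beyond it."""
        return cls(
            (
                RateSegment("ideal", k0, 0.0, F_switch),
                RateSegment("bell_slip", k0, F_switch, F_max, F_scale),
            )
        )

    # -- evaluation --------------------------------------------------------

    @property
    def F_max(self) -> float:
        return self.segments[-1].F_hi

    def _segment_index(self, F: np.ndarray) -> np.ndarray:
        edges = np.array([s.F_lo for s in self.segments[1:]])
        return np.searchsorted(edges, F, side="right")

    def rate(self, F: np.ndarray | float) -> np.ndarray | float:
        """Unbinding rate k(F) at force magnitude F (pN)."""
        F_arr = np.asarray(F, dtype=float)
        if np.any(F_arr < 0) or np.any(F_arr >= self.F_max):
            bad = F_arr[(F_arr < 0) | (F_arr >= self.F_max)]
            raise BondModelError(
                f"force {np.atleast_1d(bad)[0]:g} pN outside law domain [0, {self.F_max:g})"
            )
        idx = self._segment_index(F_arr)
        out = np.empty_like(F_arr)
        for i, seg in enumerate(self.segments):
            m = idx == i
            if np.any(m):
                out[m] = seg.rate(F_arr[m])
        return out if F_arr.ndim else float(out)

    def cumulative_hazard(self, F: np.ndarray | float) -> np.ndarray | float:
        """H(F) = int_0^F k(u) du, closed form per segment."""
        F_arr = np.asarray(F, dtype=float)
        if np.any(F_arr < 0) or np.any(F_arr > self.F_max):
            raise BondModelError(
                f"force outside [0, {self.F_max:g}] for cumulative hazard"
            )
        idx = np.minimum(self._segment_index(F_arr), len(self.segments) - 1)
        H_lo = np.asarray(self._H_lo)
        out = np.empty_like(F_arr)
        for i, seg in enumerate(self.segments):
            m = idx == i
            if np.any(m):
                out[m] = H_lo[i] + seg.hazard_increment(F_arr[m])
        return out if F_arr.ndim else float(out)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {"segments": [s.to_dict() for s in self.segments]}

    @classmethod
    def from_dict(cls, d: dict) -> "RateLaw":
        return cls(tuple(RateSegment.from_dict(s) for s in d["segments"]))


@dataclass(frozen=True)
class AnisotropicBond:
    """Direction-dependent bond: independent laws for the two load directions."""

    forward: RateLaw
    backward: RateLaw

    def law(self, direction: str) -> RateLaw:
        if direction == "forward":
            return self.forward
        if direction == "backward":
            return self.backward
        raise BondModelError(f"unknown direction {direction!r}")

    def to_dict(self) -> dict:
        return {"forward": self.forward.to_dict(), "backward": self.backward.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "AnisotropicBond":
        return cls(
            forward=RateLaw.from_dict(d["forward"]),
            backward=RateLaw.from_dict(d["backward"]),
        )


# ---------------------------------------------------------------------------
# module-level operations


def eval_rate(law: RateLaw, F: np.ndarray | float) -> np.ndarray | float:
    """Evaluate a rate law at force magnitude(s) F in pN."""
    return law.rate(F)


def rupture_pdf(law: RateLaw, r: float) -> Callable[[np.ndarray | float], np.ndarray]:
    """Rupture-force density under a constant loading rate r (pN/s).

    Returns a callable p(F) = (k(F)/r) * exp(-H(F)/r) on [0, F_max).  The
    density plus the residual survival mass at F_max sums to one: a bond
    that survives the full ramp is censored, not lost.
    """
    if not r > 0:
        raise BondModelError(f"loading rate must be positive, got {r}")

    def pdf(F: np.ndarray | float) -> np.ndarray:
        F_arr = np.asarray(F, dtype=float)
        k = np.asarray(law.rate(F_arr))
        H = np.asarray(law.cumulative_hazard(F_arr))
        out = (k / r) * np.exp(-H / r)
        return out if F_arr.ndim else float(out)

    return pdf


def survival(law: RateLaw, r: float) -> Callable[[np.ndarray | float], np.ndarray]:
    """Ramp survival S(F) = exp(-H(F)/r) for a constant loading rate."""
    if not r > 0:
        raise BondModelError(f"loading rate must be positive, got {r}")

    def S(F: np.ndarray | float) -> np.ndarray:
        H = np.asarray(law.cumulative_hazard(np.asarray(F, dtype=float)))
        return np.exp(-H / r)

    return S


@dataclass(frozen=True)
class MeanRuptureForce:
    """Expected rupture force; ``censored`` flags mass left at F_max."""

    value: float
    censored: bool
    censored_mass: float

    def __float__(self) -> float:
        return self.value


def mean_rupture_force(
    law: RateLaw, r: float, censor_tol: float = 1e-6
) -> MeanRuptureForce:
    """E[F] under a constant loading rate r, by adaptive quadrature.

    Uses E[min(F, F_max)] = int_0^F_max S(F) dF.  If the survival at F_max
    exceeds ``censor_tol`` the expectation is censored and flagged.
    """
    S = survival(law, r)
    val, _ = integrate.quad(
        S, 0.0, law.F_max, epsabs=1e-9, epsrel=1e-9, limit=400,
        points=[s.F_lo for s in law.segments],
    )
    mass = float(S(law.F_max))
    return MeanRuptureForce(value=float(val), censored=mass > censor_tol,
                            censored_mass=mass)


def rupture_mode(law: RateLaw, r: float) -> float:
    """Force at which the rupture-force density peaks (numeric)."""
    pdf = rupture_pdf(law, r)
    res = optimize.minimize_scalar(
        lambda F: -pdf(F), bounds=(0.0, law.F_max * (1 - 1e-9)), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)
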