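"""Force-dependent unbinding rates from rupture-force samples.

Under a force ramp the rupture-force density p(F), the survival S(F) and
the loading rate r(F) determine the force-dependent unbinding rate via
the hazard identity

    k(F) = r(F) * p(F) / S(F).

Statistics thin out at large forces, so p is estimated with a Gaussian
kernel density (Silverman bandwidth, reflected at zero to correct the
boundary) and S by integrating that same density.  The loading rate may
be constant (rigid linkage), the series-spring closed form, or an
empirical fit of the per-event pre-detachment slopes — the latter two
express the compliance correction: the motor-bead linkage softens the
ramp, so the rate the bond actually experiences is below the nominal
trap value and may vary with force.

Curves are reported only where the sample supports them: F >= 0.5 pN
(just above the instrument's ~0.3 pN detection limit) and survival above
``S_min`` with at least five events beyond the grid point.  Bootstrap
bands come from resampling events and recomputing the whole curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .synthetic import EventSet

__all__ = [
    "KDEDensity",
    "LoadingRateFn",
    "RateCurve",
    "ReconstructionError",
    "fit_kde",
    "loading_rate_fn",
    "unbinding_rate_curve",
    "bootstrap_rate_bands",
    "attach_zero_load_anchor",
]

F_REPORT_MIN = 0.5  # pN; below this the detection limit biases the sample
_SQRT2PI = np.sqrt(2.0 * np.pi)


class ReconstructionError(ValueError):
    """Sample or configuration unsuitable for rate reconstruction."""


@dataclass(frozen=True)
class KDEDensity:
    """Gaussian-kernel density of rupture-force magnitudes on [0, grid max]."""

    grid: np.ndarray  # pN
    density: np.ndarray
    bandwidth: float  # pN
    kernel: str = "gaussian"
    reflected: bool = True
    degenerate: bool = False  # minimum-bandwidth fallback was used

    def __call__(self, F: np.ndarray | float) -> np.ndarray:
        return np.interp(np.asarray(F, dtype=float), self.grid, self.density)

    def cdf(self, F: np.ndarray | float) -> np.ndarray:
        """Integrated density, trapezoid on the evaluation grid."""
        cum = np.concatenate(
            [[0.0], np.cumsum((self.density[1:] + self.density[:-1]) / 2.0
                              * np.diff(self.grid))]
        )
        return np.interp(np.asarray(F, dtype=float), self.grid, cum)


@dataclass(frozen=True)
class LoadingRateFn:
    """Loading rate r(F) in pN/s: constant, series-spring, or empirical."""

    method: str  # "constant" | "series_spring" | "empirical_fit"
    intercept: float
    slope: float = 0.0  # pN/s per pN; 0 for constant / linear series springs
    clipped: bool = False  # negative fitted slope clamped to zero

    def __call__(self, F: np.ndarray | float) -> np.ndarray | float:
        F_arr = np.asarray(F, dtype=float)
        out = self.intercept + self.slope * F_arr
        return out if F_arr.ndim else float(out)


@dataclass(frozen=True)
class RateCurve:
    """Reconstructed k(F) with bootstrap bands and sample-support counts."""

    F: np.ndarray  # pN, grid starting at 0.5
    k: np.ndarray  # 1/s
    lo: np.ndarray  # 95% band, NaN until bootstrapped
    hi: np.ndarray
    n_beyond: np.ndarray  # events with |F_unbind| > grid point
    S: np.ndarray  # estimated survival at each grid point
    bandwidth: float
    S_min: float
    n_events: int
    anchor_rate: float | None = None  # zero-load rate (1/s) from dwell data
    anchor_se: float | None = None
    meta: dict = field(default_factory=dict)


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def _gauss_kde_on_grid(
    x: np.ndarray, grid: np.ndarray, h: float, reflect: bool
) -> np.ndarray:
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    if reflect:
        z_r = (grid[:, None] + x[None, :]) / h
        dens += np.exp(-0.5 * z_r * z_r).sum(axis=1)
    return dens / (x.size * h * _SQRT2PI)


def fit_kde(
    forces: np.ndarray,
    bandwidth: float | None = None,
    reflect_at_zero: bool = True,
    grid_step: float = 0.02,
) -> KDEDensity:
    """Gaussian KDE of force magnitudes with boundary reflection at 0.

    ``bandwidth=None`` applies Silverman's rule.  Degenerate samples
    (zero spread) fall back to a minimum bandwidth and are flagged.
    Requires n >= 20; below 50 a pooling warning is emitted.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size < 20:
        raise ReconstructionError(
            f"KDE needs at least 20 forces, got {forces.size}; pool conditions"
        )
    if forces.size < 50:
        warnings.warn("fewer than 50 forces: KDE will be rough", stacklevel=2)
    if np.any(forces < 0):
        raise ReconstructionError("KDE expects force magnitudes (all >= 0)")
    degenerate = False
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(forces)
    if not h > 0:
        h = 0.05  # pN, minimum-bandwidth fallback for zero-spread samples
        degenerate = True
    grid = np.arange(0.0, forces.max() + 3.0 * h + grid_step, grid_step)
    dens = _gauss_kde_on_grid(forces, grid, h, reflect_at_zero)
    return KDEDensity(
        grid=grid,
        density=dens,
        bandwidth=float(h),
        reflected=reflect_at_zero,
        degenerate=degenerate,
    )


def loading_rate_fn(
    events: EventSet,
    method: str = "empirical_fit",
    k_trap: float | None = None,
    k_motor: float | None = None,
    v: float | None = None,
    constant: float | None = None,
) -> LoadingRateFn:
    """Build the loading-rate model r(F) used in the reconstruction.

    ``constant``: fixed r (given, or the mean of the events' r_local).
    ``series_spring``: r = v * (1/k_trap + 1/k_motor)^-1, force-independent
    for linear springs.  ``empirical_fit``: least-squares line of r_local
    vs. |F_unbind| with the slope constrained to be non-negative (the
    linkage stiffens under load); needs >= 20 events.
    """
    if method == "constant":
        if constant is not None:
            r0 = float(constant)
        else:
            r_loc = np.asarray([e.r_local for e in events.events], dtype=float)
            r_loc = r_loc[np.isfinite(r_loc)]
            if r_loc.size == 0:
                raise ReconstructionError("no finite r_local values for constant rate")
            r0 = float(r_loc.mean())
        if not r0 > 0:
            raise ReconstructionError(f"constant loading rate must be positive, got {r0}")
        return LoadingRateFn(method="constant", intercept=r0)
    if method == "series_spring":
        if k_trap is None or v is None:
            raise ReconstructionError("series_spring needs k_trap and v")
        k_eff = k_trap if k_motor is None else 1.0 / (1.0 / k_trap + 1.0 / k_motor)
        return LoadingRateFn(method="series_spring", intercept=float(v * k_eff))
    if method == "empirical_fit":
        F = np.asarray([abs(e.F_unbind) for e in events.events], dtype=float)
        r = np.asarray([e.r_local for e in events.events], dtype=float)
        ok = np.isfinite(F) & np.isfinite(r)
        F, r = F[ok], r[ok]
        if F.size < 20:
            raise ReconstructionError(
                f"empirical loading-rate fit needs >= 20 events, got {F.size}"
            )
        slope, intercept = np.polyfit(F, r, 1)
        clipped = False
        if slope < 0:
            slope, intercept, clipped = 0.0, float(r.mean()), True
        fn = LoadingRateFn(
            method="empirical_fit",
            intercept=float(intercept),
            slope=float(slope),
            clipped=clipped,
        )
        if fn(0.0) <= 0 or fn(F.max()) <= 0:
            raise ReconstructionError("fitted loading rate not positive on data range")
        return fn
    raise ReconstructionError(f"unknown loading-rate method {method!r}")


def unbinding_rate_curve(
    events: EventSet,
    loading: LoadingRateFn,
    grid_step: float = 0.1,
    S_min: float = 0.05,
    min_beyond: int = 5,
    bandwidth: float | None = None,
    survival_from: str = "kde",
) -> RateCurve:
    """Transform rupture forces into k(F) = r(F) * p(F) / S(F).

    Uses primary events of (what should be) a single direction.  The
    survival S comes from the integrated KDE by default
    (``survival_from="ecdf"`` switches to the raw empirical survival for
    sensitivity checks).  The grid runs from 0.5 pN upward in
    ``grid_step`` increments, truncated where S drops below ``S_min`` or
    fewer than ``min_beyond`` events remain beyond the grid point.
    """
    forces = events.forces()
    if forces.size < 50:
        raise ReconstructionError(
            f"rate reconstruction needs >= 50 primary events, got {forces.size}"
        )
    kde = fit_kde(forces, bandwidth=bandwidth)
    grid = np.arange(F_REPORT_MIN, forces.max() + grid_step, grid_step)
    p = kde(grid)
    if survival_from == "kde":
        S = 1.0 - kde.cdf(grid)
    elif survival_from == "ecdf":
        srt = np.sort(forces)
        S = 1.0 - np.searchsorted(srt, grid, side="right") / forces.size
    else:
        raise ReconstructionError(f"unknown survival estimator {survival_from!r}")
    n_beyond = forces.size - np.searchsorted(np.sort(forces), grid, side="right")
    keep = (S >= S_min) & (n_beyond >= min_beyond)
    if not np.any(keep):
        raise ReconstructionError(
            "sample too weak: survival below S_min everywhere above 0.5 pN"
        )
    last = int(np.max(np.flatnonzero(keep))) + 1
    grid, p, S, n_beyond = grid[:last], p[:last], S[:last], n_beyond[:last]
    ok = (S >= S_min) & (n_beyond >= min_beyond)
    grid, p, S, n_beyond = grid[ok], p[ok], S[ok], n_beyond[ok]
    r = np.asarray(loading(grid), dtype=float)
    k = r * p / S
    nan = np.full_like(k, np.nan)
    return RateCurve(
        F=grid,
        k=k,
        lo=nan.copy(),
        hi=nan.copy(),
        n_beyond=n_beyond,
        S=S,
        bandwidth=kde.bandwidth,
        S_min=S_min,
        n_events=int(forces.size),
        meta={
            "kernel": "gaussian",
            "reflected": True,
            "survival_from": survival_from,
            "loading_method": loading.method,
            "grid_step": grid_step,
        },
    )


def bootstrap_rate_bands(
    events: EventSet,
    loading: LoadingRateFn,
    n_boot: int = 1000,
    seed: int = 0,
    grid_step: float = 0.1,
    S_min: float = 0.05,
    min_beyond: int = 5,
    bandwidth: float | None = None,
) -> RateCurve:
    """Percentile 95% bands for the rate curve by resampling events.

    Each replicate resamples the primary events with replacement and
    recomputes the full curve (KDE bandwidth refit per replicate); bands
    are the pointwise 2.5/97.5 percentiles, widened if needed so the
    full-sample point estimate always lies inside its own band.
    """
    base = unbinding_rate_curve(
        events, loading, grid_step=grid_step, S_min=S_min,
        min_beyond=min_beyond, bandwidth=bandwidth,
    )
    forces = events.forces()
    rng = np.random.default_rng(seed)
    r_grid = np.asarray(loading(base.F), dtype=float)
    boot = np.full((n_boot, base.F.size), np.nan)
    for b in range(n_boot):
        fs = rng.choice(forces, size=forces.size, replace=True)
        h = bandwidth if bandwidth is not None else _silverman_bandwidth(fs)
        if not h > 0:
            h = 0.05
        kde_grid = np.arange(0.0, fs.max() + 3.0 * h + 0.05, 0.05)
        dens = _gauss_kde_on_grid(fs, kde_grid, h, True)
        cum = np.concatenate(
            [[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(kde_grid))]
        )
        p_b = np.interp(base.F, kde_grid, dens, right=0.0)
        S_b = 1.0 - np.interp(base.F, kde_grid, cum, right=1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot[b] = np.where(S_b > 0, r_grid * p_b / S_b, np.nan)
    lo = np.nanpercentile(boot, 2.5, axis=0)
    hi = np.nanpercentile(boot, 97.5, axis=0)
    lo = np.minimum(lo, base.k)
    hi = np.maximum(hi, base.k)
    meta = dict(base.meta, n_boot=n_boot, seed=seed)
    return RateCurve(
        F=base.F, k=base.k, lo=lo, hi=hi, n_beyond=base.n_beyond, S=base.S,
        bandwidth=base.bandwidth, S_min=base.S_min, n_events=base.n_events,
        anchor_rate=base.anchor_rate, anchor_se=base.anchor_se, meta=meta,
    )


def attach_zero_load_anchor(
    curve: RateCurve, dwell_rate: float, dwell_se: float = 0.0
) -> RateCurve:
    """Attach an independently measured zero-load rate at F=0.

    The anchor (typically the inverse time constant of a TIRF dwell-time
    CDF fit) is stored alongside the curve without altering it.
    """
    if not dwell_rate > 0:
        raise ReconstructionError("zero-load anchor rate must be positive")
    return RateCurve(
        F=curve.F, k=curve.k, lo=curve.lo, hi=curve.hi, n_beyond=curve.n_beyond,
        S=curve.S, bandwidth=curve.bandwidth, S_min=curve.S_min,
        n_events=curve.n_events, anchor_rate=float(dwell_rate),
        anchor_se=float(dwell_se), meta=dict(curve.meta),
    )
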