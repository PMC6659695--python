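"""Zero-load kinetics and motility estimators.

Dwell times from a TIRF binding assay are exponential but observed at a
finite frame interval: dwells shorter than one frame are missed and the
rest are quantized to whole frames.  Fitting the empirical CDF with
1 - exp(-k (t - t_min)), t_min fixed at one frame, is exactly unbiased
under this censoring: conditional on surviving one frame, the remaining
lifetime is again exponential (memorylessness), and the frame-quantized
ECDF equals the shifted exponential CDF at every recorded grid point.

Motility runs are summarized the way the emulated experiments do it:
a Gaussian fitted to the binned velocity histogram, and a shifted
exponential fitted to the run-length ECDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .synthetic import DwellSet, RunSet

__all__ = [
    "ExpFit",
    "GaussFit",
    "FitError",
    "fit_exponential_cdf",
    "fit_velocity_gaussian",
    "fit_runlength_exponential",
]


class FitError(ValueError):
    """Degenerate or misconfigured fit input."""


@dataclass(frozen=True)
class ExpFit:
    """Exponential fit result: a rate (1/s) or characteristic length (um)."""

    value: float
    se: float
    n: int
    offset: float  # t_min (s) or L_min (um) used in the shifted fit
    method: str = "cdf_lsq"

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise FitError(f"fitted value must be positive, got {self.value}")


@dataclass(frozen=True)
class GaussFit:
    """Gaussian fit to a velocity histogram."""

    mean: float
    sem: float
    sd: float
    n: int
    degenerate: bool = False


def _ecdf_points(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique sorted values and the ECDF evaluated there."""
    srt = np.sort(values)
    uniq, counts = np.unique(srt, return_counts=True)
    return uniq, np.cumsum(counts) / values.size


def _fit_shifted_exp_cdf(
    values: np.ndarray, offset: float
) -> tuple[float, float]:
    """LSQ fit of 1 - exp(-k (t - offset)) to the ECDF; returns (k, SE)."""
    t, F = _ecdf_points(values)
    mean_excess = float(np.mean(values - offset))
    k0 = 1.0 / mean_excess if mean_excess > 0 else 1.0

    def model(t_, k):
        return 1.0 - np.exp(-k * np.maximum(t_ - offset, 0.0))

    popt, pcov = optimize.curve_fit(model, t, F, p0=[k0], maxfev=10000)
    k = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    return k, se


def fit_exponential_cdf(dwells: DwellSet, mle: bool = False) -> ExpFit:
    """Unbinding rate from frame-quantized dwell times.

    Least-squares fit of the shifted exponential CDF to the dwell ECDF
    with t_min = one frame (the minimum detectable dwell).  ``mle=True``
    uses the closed-form conditional MLE k = 1/mean(t - t_min) instead,
    as an independent cross-check route.
    """
    x = np.asarray(dwells.dwells, dtype=float)
    if x.size < 30:
        raise FitError(f"dwell fit needs n >= 30, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError("all dwells identical; cannot fit an exponential")
    t_min = dwells.frame_interval
    if mle:
        # exact MLE under frame quantization: the excess frame count
        # (R - t_min)/frame is geometric with p = 1 - exp(-k*frame)
        f = dwells.frame_interval
        m_mean = float(np.mean((x - t_min) / f))
        if m_mean <= 1.0:
            raise FitError("dwell sample too quantized for the geometric MLE")
        k = -np.log(1.0 - 1.0 / m_mean) / f
        se = k / np.sqrt(x.size)
        return ExpFit(value=float(k), se=float(se), n=int(x.size), offset=t_min,
                      method="mle")
    k, _ = _fit_shifted_exp_cdf(x, t_min)
    # asymptotic SEM of an exponential-rate estimate; the LSQ covariance
    # understates the error because ECDF residuals are strongly correlated
    se = k / np.sqrt(x.size)
    return ExpFit(value=k, se=se, n=int(x.size), offset=t_min, method="cdf_lsq")


def _freedman_diaconis_width(x: np.ndarray) -> float:
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr == 0:
        return 0.0
    return 2.0 * iqr * x.size ** (-1.0 / 3.0)


def fit_velocity_gaussian(runs: RunSet, bin_width: float | None = None) -> GaussFit:
    """Gaussian fit to the binned velocity histogram.

    ``bin_width=None`` uses the Freedman-Diaconis rule.  The SEM is the
    fitted mean's standard error from the fit covariance.  A
    zero-variance sample returns its mean with SEM 0, flagged.
    """
    v = np.asarray(runs.velocities, dtype=float)
    if v.size < 30:
        raise FitError(f"velocity fit needs n >= 30, got {v.size}")
    if np.ptp(v) == 0:
        return GaussFit(mean=float(v[0]), sem=0.0, sd=0.0, n=int(v.size),
                        degenerate=True)
    w = bin_width if bin_width is not None else _freedman_diaconis_width(v)
    if not w > 0:
        w = np.ptp(v) / 10.0
    edges = np.arange(v.min(), v.max() + w, w)
    if edges.size < 6:
        edges = np.linspace(v.min(), v.max(), 8)
    counts, edges = np.histogram(v, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def gauss(x, a, mu, sigma):
        return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    p0 = [counts.max(), float(v.mean()), float(v.std(ddof=1))]
    popt, pcov = optimize.curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
    mu, sigma = float(popt[1]), abs(float(popt[2]))
    sem = float(np.sqrt(pcov[1, 1]))
    return GaussFit(mean=mu, sem=sem, sd=sigma, n=int(v.size))


def fit_runlength_exponential(runs: RunSet, L_min: float = 0.0) -> ExpFit:
    """Characteristic run length from a shifted-exponential CDF fit.

    Run lengths are offset by ``L_min`` (a detection cutoff for short
    runs); the estimate is invariant to shifting all runs and L_min by
    the same constant.  Errors if any run is shorter than L_min.
    """
    L = np.asarray(runs.run_lengths, dtype=float)
    if L.size < 30:
        raise FitError(f"run-length fit needs n >= 30, got {L.size}")
    if np.any(L < L_min):
        raise FitError(
            f"{int(np.sum(L < L_min))} runs shorter than L_min={L_min}; "
            "censoring misconfigured"
        )
    if np.ptp(L) == 0:
        raise FitError("all run lengths identical; cannot fit an exponential")
    k, k_se = _fit_shifted_exp_cdf(L, L_min)
    L_char = 1.0 / k
    se = k_se / k**2  # delta method for 1/k
    return ExpFit(value=float(L_char), se=float(se), n=int(L.size), offset=L_min)
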