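"""Fluorophore photophysics: on-time, photon-count and blinking-number fits,
and the theoretical localization precision.

The models are the standard single-molecule ones:

* on-period durations follow a stretched exponential
  phi(t) = phi0 * exp(-(t/tau)^alpha);
* photon counts per on-event are exponential, the decay constant being the
  mean photon number;
* the number of detections (on-events) per molecule is geometric,
  f(N) = p * (1-p)^(N-1), where p is the per-event bleaching probability and
  1/p the mean overcounting factor;
* the localization precision follows the Mortensen maximum-likelihood
  formula for Gaussian PSF fitting, scaled by an excess-noise factor F for
  electron-multiplying detectors.

Fitting errors are reported as 68.3%-confidence (1-sigma) limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StretchedExpFit",
    "GeometricBlinkFit",
    "PrecisionInputs",
    "fit_stretched_exponential",
    "fit_exponential_photons",
    "fit_geometric_blinking",
    "localization_precision",
    "spot_survival_curve",
]


@dataclass
class StretchedExpFit:
    phi0: float
    tau: float      # ms
    alpha: float
    se_tau: float
    se_alpha: float

    def __call__(self, t):
        return self.phi0 * np.exp(-((np.asarray(t, float) / self.tau)
                                    ** self.alpha))


@dataclass
class GeometricBlinkFit:
    p: float
    mean_detections: float   # = 1/p exactly
    se_p: float
    gof_pvalue: float | None = None

    def pmf(self, n):
        n = np.asarray(n)
        return self.p * (1 - self.p) ** (n - 1)


@dataclass
class PrecisionInputs:
    """Inputs to the localization-precision formula.

    photons: detected photons N; psf_sd: PSF Gaussian SD (nm); pixel: pixel
    size a (nm); background_var: background photon variance per pixel b^2;
    excess_noise: excess-noise factor F (>= 1; 1.2 for the EM camera regime).
    """

    photons: float
    psf_sd: float
    pixel: float
    background_var: float = 0.0
    excess_noise: float = 1.2

    def __post_init__(self):
        if self.photons <= 0:
            raise ValueError("photons must be > 0")
        if self.excess_noise < 1:
            raise ValueError("excess_noise must be >= 1")


def _hist_xy(hist):
    """Accept (centers, counts) or a pandas-like with two columns."""
    t, y = hist
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError("histogram centers and counts differ in shape")
    return t, y


def fit_stretched_exponential(on_period_histogram) -> StretchedExpFit:
    """Weighted least-squares fit of phi0*exp(-(t/tau)^alpha) to an
    on-period histogram given as (bin centers [ms], counts).

    Bins at t <= 0 and empty bins get Poisson weights from max(count, 1);
    refuses histograms with fewer than 4 nonzero bins.
    """
    t, y = _hist_xy(on_period_histogram)
    keep = t > 0
    t, y = t[keep], y[keep]
    if np.count_nonzero(y) < 4:
        raise ValueError("need at least 4 nonzero histogram bins")

    def model(t, phi0, tau, alpha):
        return phi0 * np.exp(-((t / tau) ** alpha))

    sigma = np.sqrt(np.maximum(y, 1.0))
    p0 = (y.max(), max(np.average(t, weights=y), t[0]), 0.8)
    popt, pcov = curve_fit(model, t, y, p0=p0, sigma=sigma,
                           bounds=([0, 1e-9, 1e-3], [np.inf, np.inf, 1.0]),
                           maxfev=20000)
    se = np.sqrt(np.diag(pcov))
    return StretchedExpFit(phi0=popt[0], tau=popt[1], alpha=popt[2],
                           se_tau=se[1], se_alpha=se[2])


def fit_exponential_photons(photon_histogram) -> tuple[float, float]:
    """Fit A*exp(-n/mean) to a photon-count histogram.

    Returns (mean_photons, se).  The decay constant of the single
    exponential is the mean number of detected photons per on-event.  A
    relative SE above 50% triggers a warning but still returns the fit.
    """
    n, y = _hist_xy(photon_histogram)
    if np.count_nonzero(y) < 4:
        raise ValueError("need at least 4 nonzero histogram bins")

    def model(n, a, mean):
        return a * np.exp(-n / mean)

    sigma = np.sqrt(np.maximum(y, 1.0))
    mean0 = max(np.average(n, weights=y), n[np.argmax(y > 0)] + 1e-6)
    popt, pcov = curve_fit(model, n, y, p0=(y.max(), mean0), sigma=sigma,
                           bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=20000)
    mean, se = popt[1], float(np.sqrt(pcov[1, 1]))
    if se > 0.5 * mean or mean > n.max():
        warnings.warn("photon-count exponential fit ill-constrained "
                      "(relative SE > 50% or decay beyond histogram range)")
    return float(mean), se


def fit_geometric_blinking(detection_counts) -> GeometricBlinkFit:
    """Maximum-likelihood geometric fit to per-molecule detection counts.

    For N_i ~ Geometric(p) the MLE is p_hat = 1/mean(N), so the reported
    mean_detections = 1/p_hat equals the sample mean exactly.  A chi-square
    goodness-of-fit p-value against the geometric pmf is attached when the
    sample is large enough.
    """
    n = np.asarray(detection_counts)
    if len(n) == 0:
        raise ValueError("empty detection-count sample")
    if np.any(n < 1) or not np.allclose(n, np.round(n)):
        raise ValueError("detection counts must be integers >= 1")
    n = n.astype(int)
    mean = n.mean()
    p_hat = 1.0 / mean
    # Fisher information of the geometric distribution: I(p) = 1/(p^2 q)
    q = 1.0 - p_hat
    se_p = p_hat * np.sqrt(q / len(n)) if q > 0 else 0.0

    gof = None
    if len(n) >= 100 and q > 0:
        from scipy.stats import chisquare, geom
        kmax = int(np.percentile(n, 99.5))
        obs = np.bincount(np.minimum(n, kmax + 1))[1:]
        exp_p = geom.pmf(np.arange(1, kmax + 1), p_hat)
        exp = np.append(exp_p, 1 - exp_p.sum()) * len(n)
        ok = exp > 1
        if ok.sum() > 2:
            stat = ((obs[ok] - exp[ok]) ** 2 / exp[ok]).sum()
            from scipy.stats import chi2
            gof = float(chi2.sf(stat, df=ok.sum() - 2))
    return GeometricBlinkFit(p=p_hat, mean_detections=mean, se_p=se_p,
                             gof_pvalue=gof)


def localization_precision(inp: PrecisionInputs) -> float:
    """Theoretical localization precision sigma (nm).

    sigma^2 = F * (sigma_a^2/N) * (16/9 + 8*pi*sigma_a^2*b^2 / (N*a^2)),
    with sigma_a^2 = psf_sd^2 + a^2/12 (pixelation-corrected PSF width),
    N the photon count, a the pixel size, b^2 the background variance per
    pixel and F the excess-noise factor.
    """
    sa2 = inp.psf_sd ** 2 + inp.pixel ** 2 / 12.0
    var = inp.excess_noise * (sa2 / inp.photons) * (
        16.0 / 9.0
        + 8.0 * np.pi * sa2 * inp.background_var
        / (inp.photons * inp.pixel ** 2))
    return float(np.sqrt(var))


def spot_survival_curve(locs, window: float, frame_time: float = 1.0):
    """Spot-count survival: % of the initial per-bin spot count vs time.

    ``locs`` is a localization table with a ``frame`` column; ``window`` is
    the bin width in ms.  Counts per bin are normalized to 100% at t = 0.
    Returns (bin start times [ms], percentages).
    """
    try:
        frames = np.asarray(locs["frame"])
    except (TypeError, KeyError, IndexError):
        frames = np.asarray(locs)
    if len(frames) == 0:
        raise ValueError("empty localization table")
    t_ms = frames * frame_time
    nbin = max(int(np.floor(t_ms.max() / window)) + 1, 1)
    edges = np.arange(nbin + 1) * window
    counts, _ = np.histogram(t_ms, bins=edges)
    if counts[0] == 0:
        raise ValueError("empty first time bin; cannot normalize to 100%")
    return edges[:-1], 100.0 * counts / counts[0]
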