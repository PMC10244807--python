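"""Single-molecule trajectory analysis: MSD, hop-diffusion fitting,
motional-mode classification and compartment residency times.

Membrane molecules in a picket-fence membrane diffuse rapidly (D_micro)
within compartments of size L delimited by the actin-based membrane
skeleton and hop between compartments at long times, giving a macroscopic
coefficient D_MACRO ~ L^2 / (4 tau) for mean residency tau.  The
time-averaged MSD of such motion rises with slope 4*D_micro, bends over on
the compartment scale and continues with slope 4*D_MACRO:

    MSD(t) = 4*sigma_off^2 + (L^2/3) * (1 - exp(-t/tau_c)) + 4*D_MACRO*t,
    tau_c = L^2 / (12 * D_micro),

where sigma_off is the static localization error.  Suppressed / simple /
directed motion is classified by the relative deviation RD — the ratio of
the observed MSD at a long lag to the Brownian expectation extrapolated
from short lags — against the 2.5/97.5 percentiles of RD for simulated
simple-Brownian trajectories of matched diffusivity, length and noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic import simulate_brownian_ensemble

__all__ = [
    "HopFitResult",
    "RDClassification",
    "ResidencyFit",
    "compute_msd",
    "hop_fit",
    "short_time_diffusion",
    "rd_statistic",
    "rd_classify",
    "fit_residency_times",
    "compare_distributions",
]

_D_UNIT = 1000.0   # nm^2/ms per um^2/s


@dataclass
class HopFitResult:
    L: float           # nm
    D_micro: float     # um^2/s
    D_MACRO: float     # um^2/s
    sigma_off: float   # nm
    rss: float
    converged: bool = True


@dataclass
class RDClassification:
    RD: float
    RD_min: float
    RD_max: float
    mode: str          # "suppressed" | "simple" | "directed"
    D_short: float     # um^2/s, from MSD lags 2-4


@dataclass
class ResidencyFit:
    tau: float         # ms
    se_tau: float
    n: int


# ---------------------------------------------------------------------------
# MSD


def _msd_fft(pos: np.ndarray) -> np.ndarray:
    """Time-averaged MSD over all start times for one trajectory (N, 2),
    via the FFT autocorrelation identity; returns msd[0..N-1]."""
    N = len(pos)
    nfft = 1 << int(np.ceil(np.log2(2 * N)))
    D = (pos ** 2).sum(axis=1)
    S2 = np.zeros(N)
    for k in range(pos.shape[1]):
        f = np.fft.rfft(pos[:, k], nfft)
        ac = np.fft.irfft(f * np.conj(f), nfft)[:N]
        S2 += ac
    Dpad = np.concatenate([D, [0.0]])
    Q = 2 * D.sum()
    S1 = np.empty(N)
    for m in range(N):
        Q -= Dpad[m - 1] + Dpad[N - m]
        S1[m] = Q / (N - m)
    return S1 - 2 * S2 / (np.arange(N, 0, -1))


def compute_msd(traj, max_lag_fraction: float = 0.25) -> pd.DataFrame:
    """Time-averaged MSD of one trajectory over all start-time pairs.

    ``traj`` is a DataFrame with x_nm/y_nm columns (or an (N, 2) array).
    Lags are reported up to ``max_lag_fraction`` of the trajectory length
    (long lags have too few independent pairs to be useful).  Requires at
    least 20 frames.  Returns a DataFrame (lag [frames], msd [nm^2]).
    """
    pos = np.asarray(traj[["x_nm", "y_nm"]]
                     if hasattr(traj, "columns") else traj, dtype=float)
    if len(pos) < 20:
        raise ValueError("need at least 20 frames")
    msd = _msd_fft(pos)
    kmax = max(int(len(pos) * max_lag_fraction), 4)
    lags = np.arange(1, kmax + 1)
    return pd.DataFrame({"lag": lags, "msd": msd[1:kmax + 1]})


def _msd_at_lags(pos: np.ndarray, lags) -> np.ndarray:
    """MSD at specific lags for an ensemble (M, N, 2); returns (M, len)."""
    out = np.empty((pos.shape[0], len(lags)))
    for i, k in enumerate(lags):
        d = pos[:, k:, :] - pos[:, :-k, :]
        out[:, i] = (d ** 2).sum(-1).mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# hop fit


def hop_fit(msd: pd.DataFrame, frame_time: float,
            loc_sigma: float | None = None) -> HopFitResult:
    """Fit the confined-plus-hop MSD model.

    ``frame_time`` in ms.  ``loc_sigma`` (nm), when known, fixes the static
    offset 4*sigma^2; otherwise sigma_off is a free parameter.  D_MACRO is
    parameterized as a fraction of D_micro so D_MACRO <= D_micro always
    holds.  Returns parameters in um^2/s and nm.
    """
    t = msd["lag"].to_numpy(dtype=float) * frame_time    # ms
    y = msd["msd"].to_numpy(dtype=float)                 # nm^2

    # initial guesses: short-lag slope, long-lag slope, plateau
    slope0 = max((y[2] - y[0]) / (t[2] - t[0]), 1e-6)
    n4 = max(len(t) // 4, 2)
    slope_inf = max(np.polyfit(t[-n4:], y[-n4:], 1)[0], 1e-9)
    plateau = max(np.median(y[len(y) // 4: len(y) // 2]) - slope_inf
                  * np.median(t[len(t) // 4: len(t) // 2]), 10.0)
    D0 = slope0 / 4.0
    L0 = np.sqrt(3 * plateau)

    # relative error of a time-averaged MSD grows with lag
    w = y * np.sqrt(t / t[-1] + 0.05)

    if loc_sigma is None:
        def model(t, L, Dm, frac, s):
            tau_c = L ** 2 / (12 * Dm)
            return (4 * s ** 2 + (L ** 2 / 3) * (1 - np.exp(-t / tau_c))
                    + 4 * frac * Dm * t)
        p0 = (L0, D0, min(slope_inf / (4 * D0), 0.5), 10.0)
        bounds = ([1, 1e-6, 0, 0], [5000, 1e6, 1, 500])
    else:
        s_fix = float(loc_sigma)

        def model(t, L, Dm, frac):
            tau_c = L ** 2 / (12 * Dm)
            return (4 * s_fix ** 2 + (L ** 2 / 3) * (1 - np.exp(-t / tau_c))
                    + 4 * frac * Dm * t)
        p0 = (L0, D0, min(slope_inf / (4 * D0), 0.5))
        bounds = ([1, 1e-6, 0], [5000, 1e6, 1])

    try:
        popt, _ = curve_fit(model, t, y, p0=p0, sigma=w, bounds=bounds,
                            maxfev=50000)
    except RuntimeError:
        return HopFitResult(L=np.nan, D_micro=np.nan, D_MACRO=np.nan,
                            sigma_off=np.nan, rss=np.inf, converged=False)
    L, Dm, frac = popt[0], popt[1], popt[2]
    s = popt[3] if loc_sigma is None else s_fix
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    return HopFitResult(L=float(L), D_micro=float(Dm / _D_UNIT),
                        D_MACRO=float(frac * Dm / _D_UNIT),
                        sigma_off=float(s), rss=rss)


# ---------------------------------------------------------------------------
# RD classification


def short_time_diffusion(msd: pd.DataFrame, frame_time: float,
                         lags=(2, 3, 4)) -> float:
    """Short-time diffusion coefficient D_{2-4} (um^2/s) from a linear fit
    of the MSD over lags 2-4 (an offset absorbs localization error)."""
    sel = msd[msd["lag"].isin(lags)]
    slope = np.polyfit(sel["lag"] * frame_time, sel["msd"], 1)[0]
    return float(slope / 4.0 / _D_UNIT)


def rd_statistic(pos: np.ndarray, frame_time: float,
                 lag_fraction: float = 1 / 3) -> tuple[float, float]:
    """(RD, D_short) for one trajectory.

    RD = MSD(t_N) / (4 * D_{2-4} * t_N) with t_N at ``lag_fraction`` of the
    trajectory length: 1 for simple Brownian motion, < 1 for suppressed
    (confined) and > 1 for directed motion.
    """
    N = len(pos)
    kN = max(int(round(N * lag_fraction)), 5)
    msd234 = _msd_at_lags(pos[None], (2, 3, 4))[0]
    slope = np.polyfit(np.array([2, 3, 4]) * frame_time, msd234, 1)[0]
    D24 = slope / 4.0
    msd_N = _msd_at_lags(pos[None], (kN,))[0, 0]
    if D24 <= 0:
        return np.nan, D24 / _D_UNIT
    return float(msd_N / (4 * D24 * kN * frame_time)), float(D24 / _D_UNIT)


def rd_classify(traj, frame_time: float, loc_sigma: float,
                null_size: int = 5000, seed: int = 0,
                lag_fraction: float = 1 / 3,
                null_rd: np.ndarray | None = None) -> RDClassification:
    """Classify a trajectory as suppressed / simple / directed.

    The trajectory's RD is compared with the 2.5th and 97.5th percentiles
    of RD over ``null_size`` Monte-Carlo simple-Brownian trajectories with
    matched short-time diffusion coefficient, length, frame time and
    localization noise.  A precomputed ``null_rd`` sample may be supplied
    when classifying an ensemble generated under identical conditions.
    """
    pos = np.asarray(traj[["x_nm", "y_nm"]]
                     if hasattr(traj, "columns") else traj, dtype=float)
    rd, D24 = rd_statistic(pos, frame_time, lag_fraction)
    if not np.isfinite(rd):
        raise ValueError("non-positive short-time diffusion coefficient; "
                         "trajectory unclassifiable")
    if null_rd is None:
        null_rd = brownian_null_rd(len(pos), D24, frame_time, loc_sigma,
                                   null_size, seed, lag_fraction)
    lo, hi = np.percentile(null_rd, [2.5, 97.5])
    mode = ("suppressed" if rd < lo else
            "directed" if rd > hi else "simple")
    return RDClassification(RD=rd, RD_min=float(lo), RD_max=float(hi),
                            mode=mode, D_short=D24)


def brownian_null_rd(n_frames: int, D: float, frame_time: float,
                     loc_sigma: float, null_size: int = 5000, seed: int = 0,
                     lag_fraction: float = 1 / 3) -> np.ndarray:
    """RD sample for the simple-Brownian null (D in um^2/s)."""
    pos = simulate_brownian_ensemble(null_size, n_frames, D, frame_time,
                                     loc_sigma, seed)
    kN = max(int(round(n_frames * lag_fraction)), 5)
    m = _msd_at_lags(pos, (2, 3, 4, kN))
    tl = np.array([2, 3, 4]) * frame_time
    # per-trajectory least-squares slope over lags 2-4
    tc = tl - tl.mean()
    slopes = (m[:, :3] * tc).sum(1) / (tc ** 2).sum()
    D24 = slopes / 4.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rd = m[:, 3] / (4 * D24 * kN * frame_time)
    return rd[np.isfinite(rd) & (D24 > 0)]


# ---------------------------------------------------------------------------
# residency times


def fit_residency_times(residency_samples, min_time: float | None = None,
                        frame_time: float | None = None) -> ResidencyFit:
    """Maximum-likelihood exponential fit of compartment dwell times.

    Samples below ``min_time`` (default two frames when ``frame_time`` is
    given, else 0) are left-censored: they are discarded and the fit uses
    the memorylessness of the exponential, tau = mean(kept) - min_time.
    The 68.3%-confidence SE is tau/sqrt(n).  Requires >= 10 samples.
    """
    t = np.asarray(residency_samples, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 residency samples")
    if min_time is None:
        min_time = 2 * frame_time if frame_time else 0.0
    kept = t[t >= min_time]
    if len(kept) < 10:
        raise ValueError("fewer than 10 samples above the censoring limit")
    if np.ptp(kept) == 0:
        warnings.warn("degenerate residency sample (all values equal)")
    tau = float(kept.mean() - min_time)
    return ResidencyFit(tau=tau, se_tau=tau / np.sqrt(len(kept)),
                        n=len(kept))


def compare_distributions(a, b, kind: str = "brunner-munzel"):
    """Two-sample comparison used for L / D_MACRO (Brunner-Munzel) and
    residency-time (log-rank) distributions; returns (statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind == "brunner-munzel":
        from scipy.stats import brunnermunzel
        res = brunnermunzel(a, b)
        return float(res.statistic), float(res.pvalue)
    if kind == "log-rank":
        from scipy.stats import CensoredData, logrank
        res = logrank(CensoredData(a), CensoredData(b))
        return float(res.statistic), float(res.pvalue)
    raise ValueError("kind must be 'brunner-munzel' or 'log-rank'")
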