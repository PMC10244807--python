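"""Monte-Carlo calibration of the Voronoi island-diameter estimate.

Localization error and blinking make tessellation-detected islands look
larger than the underlying molecular footprint.  The calibration simulates
single-island fields (one circular island at a known true diameter over a
10x dimmer background), runs the same Voronoi detection that is used on
real data, and records the estimated diameter as a function of the true
one.  A quadratic d_est(d_true), fitted for d_true >= 20 nm, is then
inverted to correct measured mean diameters; the same machinery yields the
fraction of islands of a given size that the segmentation can detect at
all, and the closeness metric used to select the thresholding density
factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import simulate_calibration_field, calibration_field_side
from .tessellation import (SegmentationConfig, VoronoiCells, detect_objects,
                           IslandRecord)

__all__ = [
    "CalibrationCurve",
    "build_calibration",
    "select_density_factor",
    "closeness_metric",
    "correct_diameter",
    "detectability",
    "find_central_island",
]

DEFAULT_GRID = tuple(range(20, 121, 10))


@dataclass
class CalibrationCurve:
    """Quadratic mapping d_true -> mean estimated diameter.

    ``coeffs`` are highest-power-first quadratic coefficients of
    d_est(d_true) fitted on the per-point table for d_true >= 20 nm;
    ``valid_range`` is the fitted d_true interval.
    """

    loc_sigma: float
    overcount_mean: float
    coeffs: np.ndarray
    valid_range: tuple[float, float]
    table: pd.DataFrame   # d_true, mean_d_est, sem, n_detected, n_images

    def predict(self, d_true):
        return np.polyval(self.coeffs, np.asarray(d_true, dtype=float))

    def to_dict(self):
        return {"loc_sigma": self.loc_sigma,
                "overcount_mean": self.overcount_mean,
                "coeffs": list(self.coeffs),
                "valid_range": list(self.valid_range),
                "table": self.table.to_dict(orient="list")}

    @classmethod
    def from_dict(cls, d):
        return cls(loc_sigma=d["loc_sigma"],
                   overcount_mean=d["overcount_mean"],
                   coeffs=np.asarray(d["coeffs"], dtype=float),
                   valid_range=tuple(d["valid_range"]),
                   table=pd.DataFrame(d["table"]))


def find_central_island(objs: list[IslandRecord], center: float,
                        d_true: float, loc_sigma: float
                        ) -> IslandRecord | None:
    """The detected object corresponding to the central ground-truth island:
    centroid within d_true/2 + loc_sigma + 5 nm of the field center (the
    largest such object by membership if several qualify)."""
    best = None
    tol = d_true / 2.0 + loc_sigma + 5.0
    for o in objs:
        r = np.hypot(o.centroid[0] - center, o.centroid[1] - center)
        if r <= tol and (best is None or o.n_locs > best.n_locs):
            best = o
    return best


def _measure_fields(d_true, loc_sigma, overcount_mean, n_images, cfg, seed,
                    island_density=0.02, background_density=0.002,
                    factors=None):
    """Central-island estimated diameters for n_images fields.

    When ``factors`` is given, the tessellation is computed once per field
    and thresholded at each candidate factor; returns {factor: list}.
    """
    side = calibration_field_side(d_true)
    center = side / 2.0
    tabs = simulate_calibration_field(
        d_true, loc_sigma, overcount_mean, n_images, seed,
        island_density=island_density, background_density=background_density)
    single = factors is None
    factors = [cfg.density_factor] if single else list(factors)
    out = {f: [] for f in factors}
    for tab in tabs:
        cells = VoronoiCells(tab, (0, 0, side, side))
        dens = cells.densities(cfg.neighbor_rank)
        ref = (float(np.mean(dens)) if cfg.threshold_reference == "mean_local"
               else cells.mean_density())
        for f in factors:
            objs = detect_objects(
                tab, (0, 0, side, side), threshold_density=f * ref,
                min_diameter=cfg.island_min_diameter,
                min_locs=cfg.island_min_locs,
                neighbor_rank=cfg.neighbor_rank, cells=cells)
            isl = find_central_island(objs, center, d_true, loc_sigma)
            if isl is not None:
                out[f].append(isl.diameter)
    return out[factors[0]] if single else out


def build_calibration(loc_sigma: float, overcount_mean: float,
                      d_true_grid=DEFAULT_GRID, n_images: int = 30,
                      cfg: SegmentationConfig | None = None,
                      seed: int = 0) -> CalibrationCurve:
    """Build the Monte-Carlo diameter calibration curve.

    For each true diameter on the grid, ``n_images`` single-island fields
    are simulated and segmented; the per-point mean estimated diameter and
    its SEM enter the table, and a quadratic is fitted over d_true >= 20 nm.
    Grid points where a >= 40-nm island at nonzero localization error is
    never detected are flagged (detectability there should be >= 85%).
    """
    cfg = cfg or SegmentationConfig()
    ss = np.random.SeedSequence(seed).spawn(len(d_true_grid))
    rows = []
    for d, s in zip(d_true_grid, ss):
        sub = int(np.random.default_rng(s).integers(2**31))
        est = _measure_fields(d, loc_sigma, overcount_mean, n_images, cfg,
                              sub)
        if not est and loc_sigma > 0 and d >= 40:
            warnings.warn(f"no detections at d_true={d} nm despite expected "
                          ">=85% detectability")
        est = np.asarray(est)
        rows.append({
            "d_true": d,
            "mean_d_est": est.mean() if len(est) else np.nan,
            "sem": est.std(ddof=1) / np.sqrt(len(est)) if len(est) > 1
            else np.nan,
            "n_detected": len(est), "n_images": n_images})
    table = pd.DataFrame(rows)
    fit = table[(table.d_true >= 20) & table.mean_d_est.notna()]
    if len(fit) < 3:
        raise RuntimeError("too few detected grid points for a quadratic fit")
    coeffs = np.polyfit(fit.d_true, fit.mean_d_est, 2)
    return CalibrationCurve(loc_sigma=loc_sigma,
                            overcount_mean=overcount_mean, coeffs=coeffs,
                            valid_range=(float(fit.d_true.min()),
                                         float(fit.d_true.max())),
                            table=table)


def closeness_metric(table: pd.DataFrame,
                     d_range=tuple(range(30, 101, 10))) -> float:
    """Sum of (d_est - d_true)^2 / d_true^2 over the 30-100 nm grid
    (every 10 nm), measuring how close an estimator is to the identity."""
    t = table.set_index("d_true")["mean_d_est"]
    return float(sum((t.get(d, np.nan) - d) ** 2 / d ** 2
                     for d in d_range if np.isfinite(t.get(d, np.nan))))


def select_density_factor(candidate_factors, seed: int = 0,
                          n_images: int = 30,
                          d_grid=tuple(range(30, 101, 10)),
                          cfg: SegmentationConfig | None = None
                          ) -> tuple[float, dict[float, float]]:
    """Choose the thresholding density factor by the closeness metric.

    Calibration fields are simulated at zero localization error and no
    overcounting (the ideal-imaging condition under which the published
    factor comparison was made); each candidate factor is applied to the
    same tessellations.  Returns (best factor, {factor: metric}).
    """
    cfg = cfg or SegmentationConfig()
    ss = np.random.SeedSequence(seed).spawn(len(d_grid))
    per_factor = {f: [] for f in candidate_factors}
    for d, s in zip(d_grid, ss):
        sub = int(np.random.default_rng(s).integers(2**31))
        res = _measure_fields(d, 0.0, 1.0, n_images, cfg, sub,
                              factors=candidate_factors)
        for f in candidate_factors:
            est = res[f]
            per_factor[f].append((d, np.mean(est) if est else np.nan))
    metrics = {}
    for f, pts in per_factor.items():
        metrics[f] = float(np.nansum([(e - d) ** 2 / d ** 2
                                      for d, e in pts]))
    best = min(metrics, key=metrics.get)
    return best, metrics


def correct_diameter(d_est_measured: float, curve: CalibrationCurve) -> float:
    """Invert the calibration quadratic at a measured (mean) diameter.

    Solves d_est(d_true) = d_est_measured on the increasing branch of the
    quadratic within (or nearest to) the calibrated range.  Measured values
    below the curve's output at the lower edge of the range are clipped to
    that edge with a warning.
    """
    c2, c1, c0 = curve.coeffs
    lo, hi = curve.valid_range
    out_lo, out_hi = curve.predict(lo), curve.predict(hi)
    if d_est_measured < out_lo:
        warnings.warn("measured diameter below calibrated output range; "
                      "clipping to the lower edge")
        return float(lo)
    roots = np.roots([c2, c1, c0 - d_est_measured])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9]
    # increasing branch: derivative positive at the root
    rising = [r for r in real if 2 * c2 * r + c1 > 0]
    cand = rising or real
    if not cand:
        raise RuntimeError("calibration quadratic cannot be inverted here")
    mid = 0.5 * (lo + hi)
    return float(min(cand, key=lambda r: abs(r - mid)))


def detectability(d_true: float, loc_sigma: float = 29.0,
                  island_density: float = 0.02, seed: int = 0,
                  n_images: int = 30, overcount_mean: float = 1.4,
                  background_density: float = 0.002,
                  cfg: SegmentationConfig | None = None) -> float:
    """Fraction of single-island fields whose central island is detected.

    Counts only the central ground-truth island (background false
    positives are ignored), in fields at the given localization-event
    densities with geometric blinking overcounting.
    """
    cfg = cfg or SegmentationConfig()
    est = _measure_fields(d_true, loc_sigma, overcount_mean, n_images, cfg,
                          seed, island_density=island_density,
                          background_density=background_density)
    return len(est) / n_images
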