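"""Localization post-processing: gap closing / merging of blinking events,
molecule grouping, and Gaussian rendering of images.

A fluorophore that stays on for several frames (possibly with 1-frame gaps)
produces several raw localizations; merging collapses them into one on-event
at the photon-weighted mean position.  On-events of the same molecule that
recur within a cutoff time are grouped into one molecule, yielding the
per-molecule detection count N used by the geometric blinking fit.

Rendering follows the SMLM convention of summing unit-integral 2-D
Gaussians at the localization positions on a regular pixel grid, so the
image integral equals the number of localizations (up to edge loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

__all__ = [
    "MergeConfig",
    "RenderConfig",
    "merge_cutoff_distance",
    "gap_close_and_merge",
    "group_molecule_detections",
    "render",
    "sliding_window_reconstruction",
    "recruitment_timecourse",
]


@dataclass
class MergeConfig:
    """Gap-closing / merging parameters.

    ``max_off_frames``: longest tolerated dark gap within one on-event (1
    frame in the standard post-processing).  ``max_distance``: spatial
    linking cutoff in nm (see :func:`merge_cutoff_distance`).
    ``cutoff_time``: molecule-grouping time window in seconds (3 s for
    mEos3.2 PALM, 10 s for HMSiR dSTORM).  ``frame_time`` in ms.
    """

    max_off_frames: int = 1
    max_distance: float = 82.0
    cutoff_time: float = 3.0
    frame_time: float = 1.0

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")


@dataclass
class RenderConfig:
    """pixel: nm/pixel (10 super-res, 55.1 diffraction-limited);
    sigma: rendering Gaussian SD in nm (the mean localization precision for
    super-res — 29 nm PALM, 19 nm dSTORM — or 129 nm for diffraction-limited
    rendering)."""

    pixel: float = 10.0
    sigma: float = 29.0

    def __post_init__(self):
        if self.pixel <= 0:
            raise ValueError("pixel must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def merge_cutoff_distance(sigma: float, k: int) -> float:
    """Spatial linking cutoff k*sqrt(2)*sigma, rounded to the nearest nm.

    sqrt(2)*sigma is the SD of the distance between two independent
    localizations of the same molecule, each with precision sigma; k = 2 is
    used for PALM (sigma 29 nm -> 82 nm) and k = 3 for dSTORM
    (sigma 19 nm -> 81 nm).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    return float(round(k * np.sqrt(2.0) * sigma))


def _greedy_link(starts, ends, xy, photons, max_gap_frames, max_distance):
    """Greedy nearest-neighbor linking in frame order.

    Records (possibly frame spans, for already-merged inputs) are processed
    in order of start frame; a record joins an open track when its start is
    within ``max_gap_frames`` of the track's end, it lies within
    ``max_distance`` of the track's running photon-weighted centroid, and
    the track has no record in that frame yet.  Ties are resolved by
    smaller distance, then lower index.  Returns a track id per record.
    """
    order = np.argsort(starts, kind="stable")
    track_of = np.full(len(starts), -1, dtype=int)
    # open tracks: centroid, end frame, photon weight
    tr_xy = np.empty((0, 2))
    tr_end = np.empty(0, dtype=int)
    tr_w = np.empty(0)
    tr_ids = np.empty(0, dtype=int)
    n_tracks = 0

    i = 0
    starts_sorted = starts[order]
    while i < len(order):
        f = starts_sorted[i]
        j = i
        while j < len(order) and starts_sorted[j] == f:
            j += 1
        pts_idx = order[i:j]
        pts = xy[pts_idx]

        alive = tr_end >= f - max_gap_frames
        tr_xy, tr_end, tr_w, tr_ids = (tr_xy[alive], tr_end[alive],
                                       tr_w[alive], tr_ids[alive])
        assigned_pt = np.zeros(len(pts_idx), dtype=bool)
        used_tr = np.zeros(len(tr_ids), dtype=bool)
        if len(tr_ids) and len(pts_idx):
            closable = tr_end < f   # at most one record per frame
            tree = cKDTree(tr_xy)
            pairs = tree.query_ball_point(pts, r=max_distance)
            cand = [(np.hypot(*(pts[a] - tr_xy[b])), a, b)
                    for a, row in enumerate(pairs) for b in row
                    if closable[b]]
            for dist, a, b in sorted(cand):
                if assigned_pt[a] or used_tr[b]:
                    continue
                assigned_pt[a] = True
                used_tr[b] = True
                k = pts_idx[a]
                track_of[k] = tr_ids[b]
                w = photons[k]
                tr_xy[b] = (tr_xy[b] * tr_w[b] + pts[a] * w) / (tr_w[b] + w)
                tr_w[b] += w
                tr_end[b] = max(tr_end[b], ends[k])
        # unassigned records open new tracks
        new = ~assigned_pt
        if np.any(new):
            k = pts_idx[new]
            track_of[k] = np.arange(n_tracks, n_tracks + len(k))
            tr_xy = np.vstack([tr_xy, pts[new]])
            tr_end = np.append(tr_end, ends[k])
            tr_w = np.append(tr_w, np.maximum(photons[k], 1e-12))
            tr_ids = np.append(tr_ids, np.arange(n_tracks, n_tracks + len(k)))
            n_tracks += len(k)
        i = j
    return track_of


def _merge_once(locs: pd.DataFrame, cfg: MergeConfig) -> pd.DataFrame:
    frames = locs["frame"].to_numpy()
    frame_end = (locs["frame_end"].to_numpy() if "frame_end" in locs
                 else frames)
    xy = locs[["x_nm", "y_nm"]].to_numpy()
    photons = locs["photons"].to_numpy(dtype=float)
    track = _greedy_link(frames, frame_end, xy, photons,
                         cfg.max_off_frames + 1, cfg.max_distance)

    df = locs.copy()
    df["_track"] = track
    df["_start"] = frames
    df["_end"] = frame_end
    w = np.maximum(photons, 1e-12)
    df["_wx"] = df["x_nm"] * w
    df["_wy"] = df["y_nm"] * w
    df["_wu"] = df["uncertainty_nm"] * w
    df["_w"] = w
    if "n_merged" not in df.columns:
        df["n_merged"] = 1
    g = df.groupby("_track", sort=True)
    out = pd.DataFrame({
        "frame": g["_start"].min(),
        "frame_end": g["_end"].max(),
        "x_nm": g["_wx"].sum() / g["_w"].sum(),
        "y_nm": g["_wy"].sum() / g["_w"].sum(),
        "photons": g["photons"].sum(),
        "uncertainty_nm": g["_wu"].sum() / g["_w"].sum(),
        "n_merged": g["n_merged"].sum(),
    })
    for col in ("molecule_id", "event_id"):
        if col in locs.columns:
            out[col] = g[col].first()
    return out.sort_values(["frame", "x_nm"], ignore_index=True)


def gap_close_and_merge(locs: pd.DataFrame, cfg: MergeConfig) -> pd.DataFrame:
    """Merge per-frame localizations of the same on-event.

    Localizations separated by at most ``max_off_frames`` dark frames and
    within ``max_distance`` nm of the on-event's running photon-weighted
    centroid are collapsed into one on-event (position = photon-weighted
    mean, photons summed).  Linking passes are repeated until a fixed
    point, so merging a merged table changes nothing; the output keeps
    ``frame`` (first frame) and ``frame_end`` (last frame).
    """
    if len(locs) == 0:
        return locs.copy()
    if not locs["frame"].is_monotonic_increasing:
        warnings.warn("input not frame-sorted; sorting internally")
        locs = locs.sort_values("frame", ignore_index=True)

    out = locs
    for _ in range(10):
        merged = _merge_once(out, cfg)
        if len(merged) == len(out):
            return merged
        out = merged
    return out


def group_molecule_detections(on_events: pd.DataFrame,
                              cfg: MergeConfig) -> pd.DataFrame:
    """Group merged on-events into putative molecules.

    On-events recurring within ``cutoff_time`` seconds and ``max_distance``
    nm are assigned to one molecule.  Returns one row per molecule with its
    detection count N (input to the geometric blinking fit) and mean
    position.
    """
    if len(on_events) == 0:
        return pd.DataFrame(columns=["n_detections", "x_nm", "y_nm"])
    cutoff_frames = int(round(cfg.cutoff_time * 1000.0 / cfg.frame_time))
    starts = on_events["frame"].to_numpy()
    ends = (on_events["frame_end"] if "frame_end" in on_events
            else on_events["frame"]).to_numpy()
    xy = on_events[["x_nm", "y_nm"]].to_numpy()
    photons = on_events["photons"].to_numpy(dtype=float)
    mol = _greedy_link(starts, ends, xy, photons, cutoff_frames,
                       cfg.max_distance)
    df = pd.DataFrame({"molecule": mol, "x_nm": xy[:, 0], "y_nm": xy[:, 1]})
    g = df.groupby("molecule")
    return pd.DataFrame({"n_detections": g.size(),
                         "x_nm": g["x_nm"].mean(),
                         "y_nm": g["y_nm"].mean()}).reset_index(drop=True)


def render(locs, cfg: RenderConfig, shape: tuple[int, int] | None = None,
           origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Gaussian rendering of a localization table.

    Localizations are binned to the pixel grid (pixel (i, j) covers the
    half-open square [j*a, (j+1)*a) x [i*a, (i+1)*a) from ``origin``) and
    convolved with a unit-integral Gaussian of SD ``cfg.sigma``; the image
    sum therefore equals the number of localizations up to edge loss.
    """
    x = np.asarray(locs["x_nm"]) - origin[0]
    y = np.asarray(locs["y_nm"]) - origin[1]
    if len(x) == 0:
        raise ValueError("empty localization table")
    if cfg.sigma < cfg.pixel / 2 and cfg.sigma > 0:
        warnings.warn("rendering sigma below half a pixel: aliasing likely")
    a = cfg.pixel
    if shape is None:
        shape = (int(np.floor(y.max() / a)) + 1, int(np.floor(x.max() / a)) + 1)
    j = np.floor(x / a).astype(int)
    i = np.floor(y / a).astype(int)
    ok = (i >= 0) & (i < shape[0]) & (j >= 0) & (j < shape[1])
    img = np.zeros(shape)
    np.add.at(img, (i[ok], j[ok]), 1.0)
    if cfg.sigma > 0:
        img = gaussian_filter(img, sigma=cfg.sigma / a, mode="constant",
                              truncate=6.0)
    return img


def sliding_window_reconstruction(locs, cfg: RenderConfig, *,
                                  window: float = 10.0, step: float = 1.0,
                                  frame_time: float = 1.0,
                                  shape: tuple[int, int] | None = None
                                  ) -> np.ndarray:
    """Render one image per sliding time window.

    ``window`` and ``step`` are in seconds, ``frame_time`` in ms.  Image k
    uses the localizations with time in [k*step, k*step + window).  A 60-s
    acquisition with a 10-s window every 1 s gives 51 images.
    """
    t_s = np.asarray(locs["frame"]) * frame_time / 1000.0
    total = t_s.max() + frame_time / 1000.0
    if window > total:
        raise ValueError("window longer than the acquisition")
    n_win = int(np.floor((total - window) / step)) + 1
    if shape is None:
        a = cfg.pixel
        shape = (int(np.floor(np.asarray(locs["y_nm"]).max() / a)) + 1,
                 int(np.floor(np.asarray(locs["x_nm"]).max() / a)) + 1)
    stack = np.zeros((n_win,) + shape)
    for k in range(n_win):
        t0 = k * step
        sel = (t_s >= t0) & (t_s < t0 + window)
        if np.any(sel):
            stack[k] = render(locs[sel], cfg, shape=shape)
    return stack


def recruitment_timecourse(locs, circles, fa_polygon, *,
                           window: float = 10.0, frame_time: float = 4.0
                           ) -> pd.DataFrame:
    """Per-circle percentage of FA localizations in consecutive windows.

    ``circles`` is a sequence of (cx, cy, diameter) in nm (e.g. 250-nm
    candidate loose clusters); ``fa_polygon`` a shapely polygon or vertex
    list.  For window w and circle c the value is
    100 * (count in c during w) / (count in FA during w); windows with zero
    FA count yield NaN.
    """
    poly = (fa_polygon if isinstance(fa_polygon, shapely.Polygon)
            else shapely.Polygon(fa_polygon))
    x = np.asarray(locs["x_nm"], dtype=float)
    y = np.asarray(locs["y_nm"], dtype=float)
    t_s = np.asarray(locs["frame"]) * frame_time / 1000.0
    in_fa = shapely.contains_xy(poly, x, y)
    n_win = max(int(np.floor(t_s.max() / window)) + 1, 1)
    rows = []
    for k in range(n_win):
        sel = (t_s >= k * window) & (t_s < (k + 1) * window) & in_fa
        denom = sel.sum()
        row = {"window": k, "t_start_s": k * window, "n_fa": int(denom)}
        for ci, (cx, cy, diam) in enumerate(circles):
            inc = sel & ((x - cx) ** 2 + (y - cy) ** 2 <= (diam / 2) ** 2)
            row[f"circle_{ci}_pct"] = (100.0 * inc.sum() / denom
                                       if denom else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
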