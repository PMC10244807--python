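"""Immobilization-event detection and intensity mapping.

Transmembrane proteins such as integrins are transiently immobilized at
FA-protein islands.  An immobilization event is a maximal run of
trajectory positions whose radius of gyration stays within a small
multiple of the localization precision; its footprint is drawn as a circle
of diameter 2*(gyration radius + precision).  To ask where events occur,
the super-resolved density image of the FA is normalized by its median
pixel intensity inside the FA mask (thermographic scale, median = 1), and
the normalized intensity is sampled at each event center; the fraction of
events above 1.0 measures enrichment at denser-than-median regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImmobilizationEvent",
    "detect_immobilization",
    "thermographic_normalize",
    "intensity_at_sites",
]


@dataclass
class ImmobilizationEvent:
    center: tuple[float, float]   # nm
    circle_diameter: float        # nm
    start_frame: int
    end_frame: int                # inclusive
    duration_ms: float


def _gyration_radius(pos):
    c = pos.mean(axis=0)
    return float(np.sqrt(((pos - c) ** 2).sum(axis=1).mean()))


def detect_immobilization(traj, loc_sigma: float,
                          min_duration_frames: int = 30,
                          k_immobile: float = 2.0,
                          frame_time: float = 4.0
                          ) -> list[ImmobilizationEvent]:
    """Detect temporary immobilization events in a trajectory.

    A maximal run of at least ``min_duration_frames`` consecutive positions
    whose radius of gyration does not exceed ``k_immobile * loc_sigma`` is
    one event; the event center is the mean position and the circle
    diameter 2*(gyration radius + loc_sigma).  ``frame_time`` in ms.
    """
    if loc_sigma <= 0:
        raise ValueError("loc_sigma must be > 0")
    pos = np.asarray(traj[["x_nm", "y_nm"]]
                     if hasattr(traj, "columns") else traj, dtype=float)
    thr = k_immobile * loc_sigma
    events = []
    i, n = 0, len(pos)
    while i + min_duration_frames <= n:
        j = i + min_duration_frames
        if _gyration_radius(pos[i:j]) <= thr:
            while j < n and _gyration_radius(pos[i:j + 1]) <= thr:
                j += 1
            seg = pos[i:j]
            rg = _gyration_radius(seg)
            events.append(ImmobilizationEvent(
                center=tuple(seg.mean(axis=0)),
                circle_diameter=2.0 * (rg + loc_sigma),
                start_frame=i, end_frame=j - 1,
                duration_ms=(j - i) * frame_time))
            i = j
        else:
            i += 1
    return events


def thermographic_normalize(image: np.ndarray,
                            fa_mask: np.ndarray) -> np.ndarray:
    """Normalize an intensity image by its median within the FA mask.

    After normalization the FA-median pixel equals 1; values are typically
    displayed on a linear thermographic scale clipped to [0, 6].
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(fa_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty FA mask")
    med = np.median(img[mask])
    if med == 0:
        raise ValueError("zero median intensity inside the mask")
    return img / med


def intensity_at_sites(normalized_map: np.ndarray, events,
                       pixel: float, origin=(0.0, 0.0),
                       circle_average: bool = False
                       ) -> tuple[np.ndarray, float]:
    """Normalized intensities at immobilization-event centers.

    Samples the map at the center pixel of each event (or averages over
    the event circle when ``circle_average``); events falling outside the
    map are skipped with a notice.  Returns (values, fraction of values
    above 1.0 — i.e. above the FA median).
    """
    img = np.asarray(normalized_map, dtype=float)
    vals = []
    skipped = 0
    for ev in events:
        cx, cy = ev.center if hasattr(ev, "center") else ev
        j = int(np.floor((cx - origin[0]) / pixel))
        i = int(np.floor((cy - origin[1]) / pixel))
        if not (0 <= i < img.shape[0] and 0 <= j < img.shape[1]):
            skipped += 1
            continue
        if circle_average and hasattr(ev, "circle_diameter"):
            r_px = max(ev.circle_diameter / 2.0 / pixel, 0.5)
            ii, jj = np.ogrid[:img.shape[0], :img.shape[1]]
            disk = (ii - i) ** 2 + (jj - j) ** 2 <= r_px ** 2
            vals.append(float(img[disk].mean()))
        else:
            vals.append(float(img[i, j]))
    if skipped:
        warnings.warn(f"{skipped} event(s) outside the map were skipped")
    vals = np.asarray(vals)
    frac = float(np.mean(vals > 1.0)) if len(vals) else np.nan
    return vals, frac
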