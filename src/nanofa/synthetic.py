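"""Synthetic SMLM scenes, blinking localization tables and hop-diffusion
trajectories.

The generators emulate the statistical structure the downstream analyses
assume, so that every stage of the pipeline has a parameter-recovery test
surface with known ground truth:

* focal-adhesion (FA) scenes: circular protein islands (true diameters
  typically 13–120 nm) at a localization density ~0.02/nm^2 against a
  ~0.002/nm^2 background, grouped into ~300-nm loose clusters inside an FA
  polygon;
* single-island calibration fields used to quantify the diameter bias of
  Voronoi segmentation under localization error and blinking overcounting;
* fluorophore photophysics: geometric per-molecule on-event counts,
  stretched-exponential on-times, exponential photon counts, isotropic
  Gaussian localization error;
* compartmentalized (picket-fence) 2-D diffusion with square compartments
  of edge L and a barrier-crossing (hop) probability per boundary encounter.

All generators take an integer seed and are bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "SceneConfig",
    "PhotophysicsConfig",
    "HopSimConfig",
    "SceneTruth",
    "HopSimResult",
    "generate_fa_scene",
    "generate_multi_fa_scene",
    "simulate_calibration_field",
    "simulate_blinking",
    "simulate_hop_trajectory",
    "simulate_hop_ensemble",
    "simulate_brownian_ensemble",
    "calibrate_hop_probability",
    "MEOS32",
    "HMSIR",
]

#: nm^2/ms per um^2/s
_D_UNIT = 1000.0


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class SceneConfig:
    """Ground-truth layout of one FA scene.

    ``island_diameter_law`` maps ``(rng, size) -> array of true diameters``
    (nm); a plain float is accepted for a fixed diameter.
    """

    fa_polygon: Sequence[tuple[float, float]]
    island_diameter_law: Callable | float = 32.0
    island_density: float = 0.02       # localizations / nm^2 inside islands
    background_density: float = 0.002  # localizations / nm^2 elsewhere in FA
    cluster_diameter: float = 300.0    # loose-cluster diameter, nm
    islands_per_cluster: int = 5
    n_clusters: int = 3
    seed: int = 0
    #: optional bulk-membrane surround: molecules at ``outside_density``
    #: between the FA polygon and ``field_bounds`` (xmin, ymin, xmax, ymax)
    field_bounds: tuple | None = None
    outside_density: float = 0.0

    def __post_init__(self):
        if not (self.island_density > self.background_density > 0):
            raise ValueError("require island_density > background_density > 0")
        if self.islands_per_cluster < 0 or self.n_clusters < 0:
            raise ValueError("counts must be non-negative")

    def polygon(self) -> Polygon:
        return Polygon(self.fa_polygon)

    def draw_diameters(self, rng, size: int) -> np.ndarray:
        if callable(self.island_diameter_law):
            d = np.asarray(self.island_diameter_law(rng, size), dtype=float)
        else:
            d = np.full(size, float(self.island_diameter_law))
        if np.any(d < 0):
            raise ValueError("island diameter law produced a negative diameter")
        return d


@dataclass
class PhotophysicsConfig:
    """Per-fluorophore emission statistics.

    ``p_bleach`` is the probability that an on-event is the molecule's last,
    so the on-event count per fluorescent molecule is geometric with mean
    1/p_bleach.  On-times follow a stretched exponential with time constant
    ``on_time_tau`` (ms) and stretching exponent ``on_time_alpha``.
    """

    p_bleach: float = 0.72
    on_time_tau: float = 1.5     # ms
    on_time_alpha: float = 0.7
    mean_photons: float = 49.0
    fluorescent_fraction: float = 0.60
    loc_sigma: float = 29.0      # nm
    frame_time: float = 1.0      # ms

    def __post_init__(self):
        if not (0 < self.p_bleach <= 1):
            raise ValueError("p_bleach must be in (0, 1]")
        if not (0 < self.on_time_alpha <= 1):
            raise ValueError("on_time_alpha must be in (0, 1]")
        if not (0 < self.fluorescent_fraction <= 1):
            raise ValueError("fluorescent_fraction must be in (0, 1]")
        if self.loc_sigma < 0:
            raise ValueError("loc_sigma must be >= 0")


#: mEos3.2 channel preset (PALM at 1 kHz).
MEOS32 = PhotophysicsConfig(p_bleach=0.72, on_time_tau=1.5, on_time_alpha=0.7,
                            mean_photons=49.0, fluorescent_fraction=0.60,
                            loc_sigma=29.0, frame_time=1.0)

#: HMSiR channel preset (dSTORM at 1 kHz).
HMSIR = PhotophysicsConfig(p_bleach=0.37, on_time_tau=2.1, on_time_alpha=0.7,
                           mean_photons=477.0, fluorescent_fraction=0.90,
                           loc_sigma=19.0, frame_time=1.0)


@dataclass
class HopSimConfig:
    """Square-lattice picket-fence diffusion simulation."""

    L_true: float = 109.0          # compartment edge, nm
    D_micro: float = 5.0           # um^2/s
    hop_probability: float = 0.05  # per boundary encounter
    frame_time: float = 1.0 / 6.0  # ms (6-kHz acquisition)
    n_steps: int = 1500            # frames
    substeps_per_frame: int = 50
    loc_sigma: float = 20.0        # nm
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.hop_probability <= 1):
            raise ValueError("hop_probability must be in [0, 1]")
        if self.substeps_per_frame < 10:
            raise ValueError("substeps_per_frame must be >= 10 so that a "
                             "single substep displacement is << L_true")


# ---------------------------------------------------------------------------
# FA scene generation


@dataclass
class SceneTruth:
    """Ground truth returned by :func:`generate_fa_scene`.

    ``island_id`` is -1 for FA-background molecules and -2 for
    bulk-membrane molecules outside the FA polygon (when simulated).
    """

    molecules: pd.DataFrame   # x_nm, y_nm, island_id
    islands: pd.DataFrame     # island_id, cluster_id, x_nm, y_nm, d_true
    clusters: pd.DataFrame    # cluster_id, x_nm, y_nm, diameter


def _uniform_in_polygon(poly: Polygon, n: int, rng, margin: float = 0.0):
    """Rejection-sample n points uniformly inside poly (eroded by margin)."""
    target = poly if margin <= 0 else poly.buffer(-margin)
    if target.is_empty:
        raise ValueError("polygon too small for requested margin")
    minx, miny, maxx, maxy = target.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(4 * (n - len(out)), 16)
        xy = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        keep = np.array([target.contains(Point(p)) for p in xy])
        out = np.vstack([out, xy[keep]])
    return out[:n]


def _uniform_in_disk(center, radius, n, rng):
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([center[0] + r * np.cos(th),
                            center[1] + r * np.sin(th)])


def generate_fa_scene(config: SceneConfig,
                      cluster_centers: np.ndarray | None = None
                      ) -> SceneTruth:
    """Generate ground-truth molecule positions for one FA scene.

    Loose-cluster centers are placed uniformly inside the FA polygon; island
    centers fall within the cluster disks, constrained so every island disk
    lies entirely inside the FA polygon.  Molecules are CSR at
    ``background_density`` outside islands and at ``island_density`` inside
    (background points falling inside an island are discarded, so the inside
    density is exactly ``island_density``).  Island disks may overlap.

    ``cluster_centers`` (n_clusters, 2) can be supplied to share the
    loose-cluster layout between two channels (different proteins in
    different islands of the same clusters).
    """
    rng = _rng(config.seed)
    poly = config.polygon()
    R_cl = config.cluster_diameter / 2.0

    n_islands = config.n_clusters * config.islands_per_cluster
    d_true = config.draw_diameters(rng, n_islands)

    if cluster_centers is None:
        cluster_centers = _uniform_in_polygon(
            poly, config.n_clusters, rng,
            margin=min(R_cl, 0.4 * np.sqrt(poly.area)))
    else:
        cluster_centers = np.asarray(cluster_centers, dtype=float)
        if len(cluster_centers) != config.n_clusters:
            raise ValueError("cluster_centers length != n_clusters")

    rows = []
    k = 0
    for ci, cc in enumerate(cluster_centers):
        for _ in range(config.islands_per_cluster):
            r_isl = d_true[k] / 2.0
            for _try in range(200):
                (pos,) = _uniform_in_disk(cc, R_cl, 1, rng)
                if poly.contains(Point(pos).buffer(r_isl, quad_segs=4)):
                    break
            else:
                raise ValueError("could not place island inside FA polygon")
            rows.append((k, ci, pos[0], pos[1], d_true[k]))
            k += 1
    islands = pd.DataFrame(
        rows, columns=["island_id", "cluster_id", "x_nm", "y_nm", "d_true"])

    # background molecules (CSR over the FA, minus island interiors)
    n_bg = rng.poisson(config.background_density * poly.area)
    bg = _uniform_in_polygon(poly, n_bg, rng)
    if len(islands):
        ic = islands[["x_nm", "y_nm"]].to_numpy()
        ir = islands["d_true"].to_numpy() / 2.0
        d2 = ((bg[:, None, :] - ic[None, :, :]) ** 2).sum(-1)
        inside_any = (d2 <= ir[None, :] ** 2).any(axis=1)
        bg = bg[~inside_any]

    parts = [pd.DataFrame({"x_nm": bg[:, 0], "y_nm": bg[:, 1],
                           "island_id": -1})]
    if config.field_bounds is not None and config.outside_density > 0:
        xmin, ymin, xmax, ymax = config.field_bounds
        area_field = (xmax - xmin) * (ymax - ymin)
        n_out = rng.poisson(config.outside_density * area_field)
        pts = rng.uniform((xmin, ymin), (xmax, ymax), size=(n_out, 2))
        outside = ~shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        pts = pts[outside]
        parts.append(pd.DataFrame({"x_nm": pts[:, 0], "y_nm": pts[:, 1],
                                   "island_id": -2}))
    for _, isl in islands.iterrows():
        r = isl.d_true / 2.0
        n_in = rng.poisson(config.island_density * np.pi * r ** 2)
        xy = _uniform_in_disk((isl.x_nm, isl.y_nm), r, n_in, rng)
        parts.append(pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1],
                                   "island_id": int(isl.island_id)}))
    molecules = pd.concat(parts, ignore_index=True)

    clusters = pd.DataFrame({
        "cluster_id": np.arange(config.n_clusters),
        "x_nm": cluster_centers[:, 0], "y_nm": cluster_centers[:, 1],
        "diameter": config.cluster_diameter})
    return SceneTruth(molecules=molecules, islands=islands, clusters=clusters)


def generate_multi_fa_scene(fa_polygons, field_bounds, *,
                            outside_density: float = 0.0002,
                            seed: int = 0, **scene_kwargs) -> SceneTruth:
    """Compose several FAs in one field of bulk membrane.

    Each polygon in ``fa_polygons`` gets its own island/cluster structure
    (``scene_kwargs`` forwarded to :class:`SceneConfig`); molecules outside
    all FAs are CSR at ``outside_density``.  The returned molecule table
    carries an ``fa_id`` column (-1 = outside).
    """
    ss = np.random.SeedSequence(seed).spawn(len(fa_polygons) + 1)
    parts, isl_parts, cl_parts = [], [], []
    offset_isl = offset_cl = 0
    for k, (poly, s) in enumerate(zip(fa_polygons, ss[:-1])):
        sub = int(np.random.default_rng(s).integers(2**31))
        cfg = SceneConfig(fa_polygon=poly, seed=sub, **scene_kwargs)
        truth = generate_fa_scene(cfg)
        mol = truth.molecules.copy()
        mol["fa_id"] = k
        mol.loc[mol.island_id >= 0, "island_id"] += offset_isl
        parts.append(mol)
        isl = truth.islands.copy()
        isl["island_id"] += offset_isl
        isl["cluster_id"] += offset_cl
        isl["fa_id"] = k
        isl_parts.append(isl)
        cl = truth.clusters.copy()
        cl["cluster_id"] += offset_cl
        cl["fa_id"] = k
        cl_parts.append(cl)
        offset_isl += len(isl)
        offset_cl += len(cl)

    rng = np.random.default_rng(ss[-1])
    xmin, ymin, xmax, ymax = field_bounds
    n_out = rng.poisson(outside_density * (xmax - xmin) * (ymax - ymin))
    pts = rng.uniform((xmin, ymin), (xmax, ymax), size=(n_out, 2))
    keep = np.ones(len(pts), dtype=bool)
    for poly in fa_polygons:
        keep &= ~shapely.contains_xy(Polygon(poly), pts[:, 0], pts[:, 1])
    parts.append(pd.DataFrame({"x_nm": pts[keep, 0], "y_nm": pts[keep, 1],
                               "island_id": -2, "fa_id": -1}))
    return SceneTruth(molecules=pd.concat(parts, ignore_index=True),
                      islands=pd.concat(isl_parts, ignore_index=True),
                      clusters=pd.concat(cl_parts, ignore_index=True))


# ---------------------------------------------------------------------------
# calibration fields (single centered island)


def calibration_field_side(d_true: float) -> float:
    """Side of the square calibration field: 10x the island diameter, or
    20x for islands of 20 nm and below (so the background still dominates
    the field statistics for the smallest islands)."""
    return (20.0 if d_true <= 20.0 else 10.0) * d_true


def simulate_calibration_field(d_true: float, loc_sigma: float,
                               overcount_mean: float, n_images: int,
                               seed: int, *,
                               island_density: float = 0.02,
                               background_density: float = 0.002,
                               ) -> list[pd.DataFrame]:
    """Simulate single-island fields for the tessellation size calibration.

    One circular island of true diameter ``d_true`` sits at the center of a
    square field.  ``island_density`` and ``background_density`` are the
    densities of *localizations* (on-events).  Molecules are drawn at
    density/overcount_mean and each produces a geometric number of on-events
    with mean ``overcount_mean``; every on-event is localized independently
    with isotropic Gaussian error of SD ``loc_sigma``, so repeated blinking
    of one molecule yields a tight sub-cluster of localizations, as in real
    data.

    Returns ``n_images`` independent localization tables.
    """
    if d_true < 13:
        raise ValueError("d_true must be >= 13 nm")
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if overcount_mean < 1:
        raise ValueError("overcount_mean must be >= 1")

    side = calibration_field_side(d_true)
    r = d_true / 2.0
    center = side / 2.0
    area_isl = np.pi * r ** 2
    area_bg = side ** 2 - area_isl
    p_geom = 1.0 / overcount_mean

    ss = np.random.SeedSequence(seed).spawn(n_images)
    tables = []
    for s in ss:
        rng = np.random.default_rng(s)
        # molecule positions
        n_isl = rng.poisson(island_density / overcount_mean * area_isl)
        xy_isl = _uniform_in_disk((center, center), r, n_isl, rng)
        n_bg = rng.poisson(background_density / overcount_mean * area_bg)
        xy_bg = np.empty((0, 2))
        while len(xy_bg) < n_bg:
            cand = rng.uniform(0, side, size=(2 * (n_bg - len(xy_bg)) + 8, 2))
            out = ((cand[:, 0] - center) ** 2
                   + (cand[:, 1] - center) ** 2) > r ** 2
            xy_bg = np.vstack([xy_bg, cand[out]])
        xy_bg = xy_bg[:n_bg]
        mol = np.vstack([xy_isl, xy_bg])

        n_events = rng.geometric(p_geom, size=len(mol))
        pos = np.repeat(mol, n_events, axis=0)
        mol_id = np.repeat(np.arange(len(mol)), n_events)
        if loc_sigma > 0:
            pos = pos + rng.normal(0, loc_sigma, size=pos.shape)
        n_loc = len(pos)
        tables.append(pd.DataFrame({
            "frame": rng.integers(0, 10_000, size=n_loc),
            "x_nm": pos[:, 0], "y_nm": pos[:, 1],
            "photons": rng.exponential(49.0, size=n_loc),
            "uncertainty_nm": np.full(n_loc, float(loc_sigma)),
            "molecule_id": mol_id,
        }).sort_values("frame", ignore_index=True))
    return tables


# ---------------------------------------------------------------------------
# blinking


def _sample_stretched_exp(rng, tau, alpha, size):
    """Durations whose probability density is proportional to
    exp(-(t/tau)^alpha) — the form on-period histograms are fitted with.

    With u = (t/tau)^alpha the density in u is Gamma(1/alpha, 1), so
    t = tau * Gamma(1/alpha)^(1/alpha); alpha = 1 recovers the plain
    exponential.
    """
    u = rng.gamma(1.0 / alpha, 1.0, size=size)
    return tau * u ** (1.0 / alpha)


def simulate_blinking(molecules, phot: PhotophysicsConfig, n_frames: int,
                      seed: int) -> pd.DataFrame:
    """Turn ground-truth molecule positions into a frame-stamped
    localization table.

    A fraction ``fluorescent_fraction`` of molecules emits at all.  Each
    fluorescent molecule produces N ~ Geometric(p_bleach) on-events whose
    start frames are uniform over the acquisition; an on-event lasts a
    stretched-exponential on-time and spans ceil(on_time/frame_time) frames,
    its exponential photon budget split evenly across them.  Every per-frame
    localization is the true position plus isotropic Gaussian noise of SD
    ``loc_sigma``.

    Output columns: frame, x_nm, y_nm, photons, uncertainty_nm,
    molecule_id, event_id (ground-truth labels for recovery tests).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    xy = np.asarray(molecules[["x_nm", "y_nm"]]
                    if isinstance(molecules, pd.DataFrame) else molecules,
                    dtype=float)
    rng = _rng(seed)
    n_mol = len(xy)
    fluor = rng.uniform(size=n_mol) < phot.fluorescent_fraction
    idx = np.flatnonzero(fluor)
    n_events = rng.geometric(phot.p_bleach, size=len(idx))

    ev_mol = np.repeat(idx, n_events)                  # molecule per event
    n_ev = len(ev_mol)
    start = rng.integers(0, n_frames, size=n_ev)
    on_t = _sample_stretched_exp(rng, phot.on_time_tau, phot.on_time_alpha,
                                 n_ev)
    span = np.maximum(1, np.ceil(on_t / phot.frame_time).astype(int))
    span = np.minimum(span, n_frames - start)          # truncate at movie end
    photons_ev = rng.exponential(phot.mean_photons, size=n_ev)

    frames = np.concatenate(
        [np.arange(s, s + k) for s, k in zip(start, span)]) \
        if n_ev else np.empty(0, dtype=int)
    loc_mol = np.repeat(ev_mol, span)
    loc_ev = np.repeat(np.arange(n_ev), span)
    loc_phot = np.repeat(photons_ev / span, span)
    pos = xy[loc_mol]
    if phot.loc_sigma > 0:
        pos = pos + rng.normal(0, phot.loc_sigma, size=pos.shape)
    return pd.DataFrame({
        "frame": frames, "x_nm": pos[:, 0], "y_nm": pos[:, 1],
        "photons": loc_phot,
        "uncertainty_nm": np.full(len(frames), phot.loc_sigma),
        "molecule_id": loc_mol, "event_id": loc_ev,
    }).sort_values(["frame", "molecule_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# hop diffusion


@dataclass
class HopSimResult:
    """Trajectory plus ground truth from :func:`simulate_hop_trajectory`."""

    trajectory: pd.DataFrame          # frame, x_nm, y_nm (observed)
    true_positions: np.ndarray        # (n_steps, 2), per-frame, noise-free
    residency_times_ms: np.ndarray    # complete (uncensored) dwell times
    config: HopSimConfig


def _hop_walk(rng, n_traj, n_sub, step_sd, L, p_hop):
    """Vectorized picket-fence walk: positions (n_sub+1, n_traj, 2)."""
    pos = np.zeros((n_sub + 1, n_traj, 2))
    cur = rng.uniform(0, L, size=(n_traj, 2))  # start inside compartment (0,0)
    pos[0] = cur
    for t in range(1, n_sub + 1):
        prop = cur + rng.normal(0, step_sd, size=(n_traj, 2))
        if p_hop < 1.0:
            c_cur = np.floor(cur / L)
            c_prop = np.floor(prop / L)
            cross = c_cur != c_prop
            if np.any(cross):
                allowed = rng.uniform(size=cross.shape) < p_hop
                block = cross & ~allowed
                # reflect across the boundary between the two compartments
                bound = np.where(c_prop > c_cur, (c_cur + 1) * L, c_cur * L)
                refl = 2 * bound - prop
                prop = np.where(block, refl, prop)
                # a reflected step that re-crossed the far boundary (rare,
                # step << L) is clamped into its original compartment
                lo, hi = c_cur * L, (c_cur + 1) * L
                eps = 1e-9 * L
                prop = np.where(block, np.clip(prop, lo + eps, hi - eps), prop)
        cur = prop
        pos[t] = cur
    return pos


def simulate_hop_trajectory(config: HopSimConfig) -> HopSimResult:
    """Simulate one trajectory of compartmentalized (hop) diffusion.

    The particle performs Brownian substeps of SD sqrt(2*D_micro*dt) per
    axis on a square compartment lattice of edge ``L_true``; a substep that
    crosses a compartment boundary succeeds with ``hop_probability`` and is
    otherwise reflected.  Per-frame positions carry Gaussian localization
    noise; the ground-truth compartment occupancy per substep is kept, and
    complete dwell episodes (excluding the censored first and last ones)
    are returned as residency times in ms.

    ``hop_probability = 1`` is the free Brownian null; ``0`` is full
    confinement.
    """
    rng = _rng(config.seed)
    dt_sub = config.frame_time / config.substeps_per_frame          # ms
    step_sd = np.sqrt(2 * config.D_micro * _D_UNIT * dt_sub)        # nm
    n_sub = config.n_steps * config.substeps_per_frame
    L = config.L_true

    pos = _hop_walk(rng, 1, n_sub, step_sd, L, config.hop_probability)[:, 0]

    comp = np.floor(pos / L).astype(np.int64)
    comp_id = comp[:, 0] * (2 ** 32) + comp[:, 1]
    change = np.flatnonzero(comp_id[1:] != comp_id[:-1]) + 1
    if len(change) >= 2:
        residency = np.diff(change) * dt_sub
    else:
        residency = np.empty(0)

    frame_pos = pos[::config.substeps_per_frame][:config.n_steps]
    obs = frame_pos.copy()
    if config.loc_sigma > 0:
        obs = obs + rng.normal(0, config.loc_sigma, size=obs.shape)
    traj = pd.DataFrame({"frame": np.arange(config.n_steps),
                         "x_nm": obs[:, 0], "y_nm": obs[:, 1]})
    return HopSimResult(trajectory=traj, true_positions=frame_pos,
                        residency_times_ms=residency, config=config)


def simulate_hop_ensemble(config: HopSimConfig, n_traj: int,
                          seed=None) -> list[HopSimResult]:
    """Simulate ``n_traj`` independent hop-diffusion trajectories sharing
    one configuration (the walk is vectorized across trajectories).  The
    per-trajectory seeds are derived from ``seed`` (default: the config
    seed)."""
    rng = _rng(config.seed if seed is None else seed)
    dt_sub = config.frame_time / config.substeps_per_frame
    step_sd = np.sqrt(2 * config.D_micro * _D_UNIT * dt_sub)
    n_sub = config.n_steps * config.substeps_per_frame
    L = config.L_true

    pos = _hop_walk(rng, n_traj, n_sub, step_sd, L,
                    config.hop_probability)   # (n_sub+1, n_traj, 2)
    results = []
    for k in range(n_traj):
        p = pos[:, k, :]
        comp = np.floor(p / L).astype(np.int64)
        cid = comp[:, 0] * (2 ** 32) + comp[:, 1]
        change = np.flatnonzero(cid[1:] != cid[:-1]) + 1
        residency = np.diff(change) * dt_sub if len(change) >= 2 \
            else np.empty(0)
        frame_pos = p[::config.substeps_per_frame][:config.n_steps]
        obs = frame_pos.copy()
        if config.loc_sigma > 0:
            obs = obs + rng.normal(0, config.loc_sigma, size=obs.shape)
        traj = pd.DataFrame({"frame": np.arange(config.n_steps),
                             "x_nm": obs[:, 0], "y_nm": obs[:, 1]})
        results.append(HopSimResult(trajectory=traj,
                                    true_positions=frame_pos,
                                    residency_times_ms=residency,
                                    config=config))
    return results


def simulate_brownian_ensemble(n_traj: int, n_frames: int, D: float,
                               frame_time: float, loc_sigma: float,
                               seed) -> np.ndarray:
    """Free-Brownian trajectories with localization noise.

    Returns positions of shape (n_traj, n_frames, 2) in nm; ``D`` in
    um^2/s, ``frame_time`` in ms.  Used as the Monte-Carlo null for
    motional-mode classification.
    """
    rng = _rng(seed)
    sd = np.sqrt(2 * D * _D_UNIT * frame_time)
    steps = rng.normal(0, sd, size=(n_traj, n_frames - 1, 2))
    pos = np.concatenate([np.zeros((n_traj, 1, 2)), np.cumsum(steps, axis=1)],
                         axis=1)
    if loc_sigma > 0:
        pos = pos + rng.normal(0, loc_sigma, size=pos.shape)
    return pos


def calibrate_hop_probability(L: float, D_micro: float, target_tau_ms: float,
                              *, frame_time: float = 1.0 / 6.0,
                              substeps_per_frame: int = 50,
                              n_frames: int = 1500, n_traj: int = 20,
                              seed: int = 0) -> float:
    """Find the hop probability giving a target mean compartment residency.

    Bisection on log10(p) against the mean ground-truth residency from pilot
    picket-fence simulations.  Residency scales roughly like 1/p, so a few
    iterations suffice for test purposes.
    """

    def mean_residency(p):
        cfg = HopSimConfig(L_true=L, D_micro=D_micro, hop_probability=p,
                           frame_time=frame_time, n_steps=n_frames,
                           substeps_per_frame=substeps_per_frame,
                           seed=int(seed + int(1e6 * p)) % (2**31))
        res = np.concatenate([r.residency_times_ms for r in
                              simulate_hop_ensemble(cfg, n_traj)])
        return res.mean() if len(res) else np.inf

    lo, hi = -4.0, 0.0   # log10 p
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        tau = mean_residency(10 ** mid)
        if tau > target_tau_ms:
            lo = mid     # too confined -> raise p
        else:
            hi = mid
    return 10 ** (0.5 * (lo + hi))
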