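"""Ground-truthed synthetic data emulating the study's time-lapse experiments.

Everything the measurement pipeline consumes can be generated here with
known ground truth: hard-core point monolayers on rectangular fields or
circular micropatterns, two-population competition scenes with a compacted
surrounded loser clone, nuclear marker intensities rank-correlated with
local crowding, contact-induced two-population migration trajectories with
a configurable winner-leads-loser onset lag, compression-dependent death
events, rendered nuclear-channel image stacks, and population count time
courses (homeostasis, collapse, treatment-triggered competition).

Named parameter presets describing the study conditions live in
``presets.yaml`` next to this module; see :func:`load_preset`.
"""

from __future__ import annotations

import copy
import math
import warnings
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, rankdata

from .geometry import CountSeries, ImageStack, PointScene, SceneGeometry, TrackSet

__all__ = [
    "load_preset",
    "geometry_from_config",
    "make_monolayer",
    "make_competition_scene",
    "make_marker_intensities",
    "make_trajectories",
    "render_images",
    "make_death_events",
    "compression_assay_pair",
    "count_death_events",
    "make_count_timecourse",
]

_PRESETS: dict | None = None


def load_preset(name: str) -> dict:
    """Return a deep copy of a named parameter preset from ``presets.yaml``."""
    global _PRESETS
    if _PRESETS is None:
        text = resources.files("mechcomp").joinpath("presets.yaml").read_text()
        _PRESETS = yaml.safe_load(text)
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return copy.deepcopy(_PRESETS[name])


def geometry_from_config(cfg: dict) -> SceneGeometry:
    """Build a :class:`SceneGeometry` from a preset's ``geometry`` mapping."""
    return SceneGeometry(**cfg)


# ---------------------------------------------------------------------------
# hard-core point placement


def _hexagonal_packing_max(area: float, min_spacing: float) -> int:
    # densest arrangement of points at pairwise distance >= s is the
    # triangular lattice: 2 / (sqrt(3) s^2) points per unit area
    return int(math.floor(area * 2.0 / (math.sqrt(3.0) * min_spacing**2)))


def _propose_uniform(geometry: SceneGeometry, n: int, rng) -> np.ndarray:
    if geometry.shape == "rectangle":
        return rng.uniform((0, 0), (geometry.width, geometry.height), size=(n, 2))
    r = geometry.diameter / 2.0
    rad = r * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0, 2 * math.pi, size=n)
    return np.column_stack([r + rad * np.cos(ang), r + rad * np.sin(ang)])


def _hardcore_sample(
    geometry: SceneGeometry,
    n: int,
    min_spacing: float,
    rng,
    region=None,
    max_proposals: int | None = None,
) -> np.ndarray:
    """Sequential-rejection hard-core sampling on a cell grid.

    ``region`` optionally restricts placement to a sub-region (callable
    mask over (n,2) positions).  Raises if the requested count is
    infeasible for the area or the proposal budget is exhausted.
    """
    if n == 0:
        return np.empty((0, 2))
    if min_spacing <= 0:
        pts = []
        while len(pts) < n:
            cand = _propose_uniform(geometry, n - len(pts), rng)
            if region is not None:
                cand = cand[region(cand)]
            pts.extend(cand.tolist())
        return np.asarray(pts[:n])

    area = geometry.area
    n_max = _hexagonal_packing_max(area, min_spacing)
    if n > 0.7 * n_max:
        raise ValueError(
            f"hard-core packing infeasible: requested {n} points at "
            f"min_spacing={min_spacing} μm; achievable maximum is about "
            f"{int(0.7 * n_max)} in {area:.0f} μm²"
        )

    ex, ey = geometry.bounds
    cell = min_spacing
    nx, ny = int(ex / cell) + 1, int(ey / cell) + 1
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    accepted = 0
    budget = max_proposals if max_proposals is not None else max(100_000, 400 * n)
    proposals = 0
    s2 = min_spacing**2
    while accepted < n:
        if proposals >= budget:
            raise RuntimeError(
                f"hard-core sampling stalled after {proposals} proposals "
                f"({accepted}/{n} placed); lower the density or min_spacing"
            )
        batch = min(4 * (n - accepted) + 64, budget - proposals)
        cand = _propose_uniform(geometry, batch, rng)
        proposals += batch
        if region is not None:
            cand = cand[region(cand)]
        for p in cand:
            cx, cy = int(p[0] / cell), int(p[1] / cell)
            ok = True
            for gx in range(cx - 1, cx + 2):
                for gy in range(cy - 1, cy + 2):
                    for idx in grid.get((gx, gy), ()):
                        d = pts[idx] - p
                        if d[0] * d[0] + d[1] * d[1] < s2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                pts[accepted] = p
                grid.setdefault((cx, cy), []).append(accepted)
                accepted += 1
                if accepted == n:
                    break
    return pts


def make_monolayer(
    geometry: SceneGeometry,
    target_density: float,
    min_spacing: float = 0.0,
    seed: int = 0,
    population: str = "cell",
    time: float = 0.0,
) -> PointScene:
    """Confluent monolayer at a configured homeostatic density.

    ``target_density`` is in cells per 10,000 μm²; the generated count is
    ``round(target_density × area / 10,000)`` exactly, so global-density
    measurements recover the preset up to rounding.  Placement is uniform
    with a hard-core exclusion of ``min_spacing`` μm between nuclei.
    """
    if target_density < 0:
        raise ValueError("target_density must be >= 0")
    n = int(round(target_density * geometry.area / 1e4))
    rng = np.random.default_rng(seed)
    pts = _hardcore_sample(geometry, n, min_spacing, rng)
    return PointScene(
        cell_id=np.arange(n),
        x=pts[:, 0],
        y=pts[:, 1],
        population=np.full(n, population, dtype=object),
        geometry=geometry,
        time=time,
    )


def make_competition_scene(config: dict | None = None, seed: int = 0) -> PointScene:
    """Two-population scene with a compacted, surrounded loser clone.

    A circular loser clone at the field centre is placed at
    ``density_ratio_clone_vs_pure × loser_pure_density``; winners fill the
    rest of the field at ``winner_density``.  A free annulus of
    ``clone_gap`` μm separates the populations so the hard-core constraint
    also holds across them.
    """
    cfg = load_preset("competition_scene") if config is None else config
    geometry = geometry_from_config(cfg["geometry"])
    if geometry.shape != "rectangle":
        raise ValueError("competition scenes are generated on rectangular fields")
    rc = float(cfg["clone_radius"])
    gap = float(cfg.get("clone_gap", cfg["min_spacing"]))
    ratio = float(cfg["density_ratio_clone_vs_pure"])
    if ratio <= 0:
        raise ValueError("density_ratio_clone_vs_pure must be > 0")
    if rc + gap >= min(geometry.width, geometry.height) / 2.0:
        raise ValueError(
            f"clone radius {rc} μm (+{gap} μm gap) does not fit inside the "
            f"{geometry.width}×{geometry.height} μm field"
        )
    cx, cy = geometry.width / 2.0, geometry.height / 2.0
    clone_density = ratio * float(cfg["loser_pure_density"])
    n_clone = int(round(clone_density * math.pi * rc**2 / 1e4))
    outer_area = geometry.area - math.pi * (rc + gap) ** 2
    n_win = int(round(float(cfg["winner_density"]) * outer_area / 1e4))

    rng = np.random.default_rng(seed)
    spacing = float(cfg["min_spacing"])
    clone_geom = SceneGeometry(
        shape="disc",
        diameter=2 * rc,
        pixel_size=geometry.pixel_size,
        frame_interval=geometry.frame_interval,
    )
    clone_pts = _hardcore_sample(clone_geom, n_clone, spacing, rng)
    clone_pts = clone_pts - rc + np.array([cx, cy])

    def outside_clone(p):
        return (p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2 >= (rc + gap) ** 2

    win_pts = _hardcore_sample(geometry, n_win, spacing, rng, region=outside_clone)
    n = n_clone + n_win
    return PointScene(
        cell_id=np.arange(n),
        x=np.concatenate([clone_pts[:, 0], win_pts[:, 0]]),
        y=np.concatenate([clone_pts[:, 1], win_pts[:, 1]]),
        population=np.array(["loser"] * n_clone + ["winner"] * n_win, dtype=object),
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# marker intensities (Gaussian copula against kernel local density)


def make_marker_intensities(
    scene: PointScene,
    rank_corr: float,
    seed: int = 0,
    sigma_um: float = 20.0,
    radius_um: float = 50.0,
    lognormal_sigma: float = 0.4,
    lognormal_median: float = 100.0,
) -> PointScene:
    """Assign per-cell nuclear marker intensities rank-correlated with
    kernel local density.

    A bivariate-normal (Gaussian) copula couples the empirical normal
    scores of each cell's local density to a latent normal, with Pearson
    parameter ρ = 2·sin(π·rank_corr/6) so the population Spearman
    correlation equals ``rank_corr``.  The marker marginal is log-normal
    (median ``lognormal_median``, log-sd ``lognormal_sigma``) regardless
    of ``rank_corr``.
    """
    if not -1.0 <= rank_corr <= 1.0:
        raise ValueError("rank_corr must lie in [-1, 1]")
    if scene.n_cells < 3:
        raise ValueError("need at least 3 cells to assign copula intensities")
    from .density import LocalDensityParams, local_density

    dens = local_density(scene, LocalDensityParams(sigma=sigma_um, radius=radius_um))
    if np.ptp(dens) == 0:
        warnings.warn(
            "all cells have identical local density; the density-marker "
            "correlation is undefined downstream",
            stacklevel=2,
        )
    n = scene.n_cells
    z_d = norm.ppf(rankdata(dens) / (n + 1.0))
    rho = 2.0 * math.sin(math.pi * rank_corr / 6.0)
    if abs(rank_corr) == 1.0:
        rho = math.copysign(1.0, rank_corr)  # avoid tie-breaking float dust
    rng = np.random.default_rng(seed)
    z = rho * z_d + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    marker = lognormal_median * np.exp(lognormal_sigma * z)
    out = scene.subset(np.ones(n, dtype=bool))
    out.marker = marker
    return out


# ---------------------------------------------------------------------------
# contact-induced migration trajectories


def _kappa(persistence: float) -> float:
    p = min(max(persistence, 0.0), 1.0 - 1e-9)
    return (p / (1.0 - p)) ** 2


def make_trajectories(config: dict | None = None, seed: int = 0) -> TrackSet:
    """Two-population contact-induced migration with a winner-leads lag.

    Before its onset a cell performs a persistent random walk (AR(1)
    heading, turn sd = (1−persistence)·π per step) at ``pre_contact_speed``.
    Winners switch to directed motion along the inter-population axis at
    ``t_contact_h``; losers at ``t_contact_h + onset_lag_h``.  Directed
    headings are von-Mises-concentrated on the axis (+x: winners advance
    toward the losers, losers retreat).  ``directed_fraction`` of cells per
    population adopt the directed mode; the rest keep random-walking at the
    post-contact speed.  True onsets are recorded in ``TrackSet.meta``.
    """
    cfg = load_preset("contact_migration") if config is None else config
    geometry = geometry_from_config(cfg["geometry"])
    dt = geometry.frame_interval
    duration = float(cfg["duration_h"])
    n_frames = int(round(duration / dt)) + 1
    if n_frames < 2:
        raise ValueError("trajectory series needs at least 2 frames")
    t_contact = float(cfg["t_contact_h"])
    lag = float(cfg["onset_lag_h"])
    if duration <= t_contact + lag:
        raise ValueError("duration must exceed t_contact + onset_lag")
    v_pre = float(cfg["pre_contact_speed"])
    v_post = float(cfg["post_contact_speed"])
    if v_pre < 0 or v_post < 0:
        raise ValueError("speeds must be >= 0")
    p_pre = float(cfg["pre_persistence"])
    p_post = float(cfg["post_persistence"])
    frac = float(cfg.get("directed_fraction", 1.0))
    n_pop = int(cfg["n_per_population"])
    gap = float(cfg.get("gap_um", 30.0))
    spacing = float(cfg.get("min_spacing", 0.0))

    rng = np.random.default_rng(seed)
    W, H = geometry.width, geometry.height
    half = SceneGeometry(
        shape="rectangle",
        width=W / 2.0 - gap / 2.0,
        height=H,
        pixel_size=geometry.pixel_size,
        frame_interval=dt,
    )
    win0 = _hardcore_sample(half, n_pop, spacing, rng)
    los0 = _hardcore_sample(half, n_pop, spacing, rng)
    los0[:, 0] += W / 2.0 + gap / 2.0

    onsets = {"winner": t_contact, "loser": t_contact + lag}
    pops = np.array(["winner"] * n_pop + ["loser"] * n_pop, dtype=object)
    pos = np.vstack([win0, los0])
    n = 2 * n_pop
    directed = rng.uniform(size=n) < frac
    heading = rng.uniform(0, 2 * math.pi, size=n)
    kappa = _kappa(p_post)
    turn_sd = (1.0 - p_pre) * math.pi

    rows_x = np.empty((n_frames, n))
    rows_y = np.empty((n_frames, n))
    rows_x[0] = pos[:, 0]
    rows_y[0] = pos[:, 1]
    onset_t = np.array([onsets[p] for p in pops])
    for f in range(1, n_frames):
        t = f * dt
        active = directed & (t > onset_t)
        # PRW update for everyone, then overwrite directed cells
        heading = heading + turn_sd * rng.standard_normal(n)
        if kappa > 1e8:
            directed_heading = np.zeros(n)
        else:
            directed_heading = rng.vonmises(0.0, kappa, size=n)
        heading = np.where(active, directed_heading, heading)
        speed = np.where(t > onset_t, v_post, v_pre)
        pos = pos + (speed * dt)[:, None] * np.column_stack(
            [np.cos(heading), np.sin(heading)]
        )
        # no boundary reflection: the field is a view into an extended
        # monolayer, so migrating cells may leave the nominal bounds
        rows_x[f] = pos[:, 0]
        rows_y[f] = pos[:, 1]

    frames = np.repeat(np.arange(n_frames), n)
    df = pd.DataFrame(
        {
            "frame": frames,
            "time_h": frames * dt,
            "cell_id": np.tile(np.arange(n), n_frames),
            "x_um": rows_x.ravel(),
            "y_um": rows_y.ravel(),
            "population": np.tile(pops, n_frames),
        }
    )
    return TrackSet(
        df=df,
        frame_interval=dt,
        meta={
            "onset_winner_h": onsets["winner"],
            "onset_loser_h": onsets["loser"],
            "onset_lag_h": lag,
            "geometry": geometry,
            "directed_fraction": frac,
        },
    )


# ---------------------------------------------------------------------------
# image rendering


def render_images(
    scenes: list[PointScene] | PointScene,
    psf_sigma_px: float,
    noise_model: dict | None = None,
    bit_depth: int = 16,
    amplitude: float = 1000.0,
    background: float = 0.0,
    seed: int = 0,
) -> ImageStack:
    """Render point scenes as a nuclear-channel movie of Gaussian spots.

    Each alive cell becomes an isotropic Gaussian of sd ``psf_sigma_px``
    and peak ``amplitude`` counts.  ``noise_model`` may contain
    ``{"poisson": bool, "read_sigma": float}`` (shot noise plus additive
    Gaussian read noise); ``None`` renders noiselessly.  Ground-truth
    scenes are stored on the returned stack.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    if isinstance(scenes, PointScene):
        scenes = [scenes]
    geometry = scenes[0].geometry
    Hpx, Wpx = geometry.raster_shape
    rng = np.random.default_rng(seed)
    halo = max(2, int(math.ceil(4 * psf_sigma_px)))
    frames = np.empty((len(scenes), Hpx, Wpx), dtype=float)
    n_clipped = 0
    for t, scene in enumerate(scenes):
        img = np.full((Hpx, Wpx), background, dtype=float)
        px = scene.x / geometry.pixel_size
        py = scene.y / geometry.pixel_size
        for cx, cy, ok in zip(px, py, scene.alive):
            if not ok:
                continue
            if not (0 <= cx < Wpx and 0 <= cy < Hpx):
                n_clipped += 1
                continue
            x0, x1 = max(0, int(cx) - halo), min(Wpx, int(cx) + halo + 1)
            y0, y1 = max(0, int(cy) - halo), min(Hpx, int(cy) + halo + 1)
            xs = np.arange(x0, x1) - cx
            ys = np.arange(y0, y1) - cy
            img[y0:y1, x0:x1] += amplitude * np.exp(
                -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * psf_sigma_px**2)
            )
        frames[t] = img
    if n_clipped:
        warnings.warn(f"{n_clipped} cells fell outside the raster and were clipped")
    if noise_model:
        if noise_model.get("poisson", False):
            frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
        read = float(noise_model.get("read_sigma", 0.0))
        if read > 0:
            frames = frames + read * rng.standard_normal(frames.shape)
    vmax = 2**bit_depth - 1
    dtype = np.uint16 if bit_depth > 8 else np.uint8
    data = np.clip(np.round(frames), 0, vmax).astype(dtype)
    return ImageStack(
        data=data,
        pixel_size=geometry.pixel_size,
        frame_interval=geometry.frame_interval,
        ground_truth=list(scenes),
    )


# ---------------------------------------------------------------------------
# death events


def make_death_events(
    config: dict,
    scene_series: list[PointScene],
    compressed: bool,
    seed: int = 0,
) -> list[PointScene]:
    """Annotate a scene series with Bernoulli death events.

    Between consecutive frames each alive cell dies with probability
    ``baseline_death_rate × Δt`` (× ``compression_death_multiplier`` under
    compression).  Dead cells stay dead.  Raises if a per-interval
    probability exceeds 1.
    """
    rate = float(config["baseline_death_rate"])
    mult = float(config["compression_death_multiplier"]) if compressed else 1.0
    if rate < 0 or mult < 0:
        raise ValueError("death rates and multipliers must be >= 0")
    rng = np.random.default_rng(seed)
    out = [scene_series[0].subset(np.ones(scene_series[0].n_cells, dtype=bool))]
    alive = out[0].alive.copy()
    for prev, scene in zip(scene_series[:-1], scene_series[1:]):
        dt = scene.time - prev.time
        p = rate * dt * mult
        if not 0.0 <= p <= 1.0:
            raise ValueError(
                f"per-interval death probability {p:.3f} outside [0, 1]; "
                "shorten the frame interval or lower the rate"
            )
        dies = alive & (rng.uniform(size=alive.size) < p)
        alive = alive & ~dies
        s = scene.subset(np.ones(scene.n_cells, dtype=bool))
        s.alive = alive.copy()
        out.append(s)
    return out


def count_death_events(scenes: list[PointScene]) -> tuple[int, int]:
    """(death events, total nuclei) over an annotated series."""
    first, last = scenes[0], scenes[-1]
    events = int(np.sum(first.alive & ~last.alive))
    return events, int(np.sum(first.alive))


def compression_assay_pair(
    config: dict | None = None, seed: int = 0
) -> dict[str, list[PointScene]]:
    """Paired compressed/uncompressed single-exposure death-event series.

    Emulates a fix-and-stain compression assay: one Bernoulli exposure
    interval per cell, so the expected compressed/uncompressed
    death-fraction ratio equals the configured multiplier exactly
    (multi-frame movies would saturate the ratio below it).
    """
    cfg = load_preset("compression_assay") if config is None else config
    geometry = geometry_from_config(cfg["geometry"])
    n = int(cfg["n_cells"])
    exposure = float(cfg["exposure_h"])
    rng = np.random.default_rng(seed)
    out = {}
    for i, (key, compressed) in enumerate(
        [("uncompressed", False), ("compressed", True)]
    ):
        pts = _propose_uniform(geometry, n, rng)
        base = PointScene(
            cell_id=np.arange(n),
            x=pts[:, 0],
            y=pts[:, 1],
            population=np.full(n, "loser", dtype=object),
            geometry=geometry,
            time=0.0,
        )
        end = base.subset(np.ones(n, dtype=bool))
        end.time = exposure
        out[key] = make_death_events(
            cfg, [base, end], compressed=compressed, seed=seed * 2 + i + 1
        )
    return out


# ---------------------------------------------------------------------------
# count time courses


def _noisy_counts(mean: np.ndarray, cv: float, rng) -> np.ndarray:
    if cv > 0:
        mean = mean * np.exp(cv * rng.standard_normal(mean.size) - cv**2 / 2.0)
    return np.clip(np.round(mean), 0, None).astype(int)


def make_count_timecourse(
    config: dict | None = None, scenario: str = "homeostasis", seed: int = 0
) -> CountSeries:
    """Population count time courses for the study's growth scenarios.

    Scenarios: ``homeostasis`` (logistic growth to a carrying density,
    then a maintained plateau), ``loser_collapse`` (growth then decline),
    ``treatment_monoculture`` (stable baseline, then post-treatment
    relaxation to a reduced plateau) and ``treatment_competition``
    (loser-population exponential decline after treatment, calibrated to a
    configured day-6 endpoint).  Ground-truth endpoint fractions are
    recorded in ``CountSeries.meta``.
    """
    rng = np.random.default_rng(seed)
    if scenario == "homeostasis":
        cfg = load_preset("wt_homeostasis") if config is None else config
        geometry = geometry_from_config(cfg["geometry"])
        dt = geometry.frame_interval
        t = np.arange(0.0, float(cfg["duration_h"]) + dt / 2, dt)
        K = round(float(cfg["target_density"]) * geometry.area / 1e4)
        n0 = max(1.0, float(cfg.get("seed_fraction", 0.3)) * K)
        r = float(cfg.get("growth_rate", 0.08))
        if r == 0:
            mean = np.full_like(t, n0)
        else:
            mean = K / (1.0 + (K - n0) / n0 * np.exp(-r * t))
        counts = _noisy_counts(mean, float(cfg.get("noise_cv", 0.0)), rng)
        return CountSeries(
            time_h=t,
            counts={"cell": counts},
            area_um2=geometry.area,
            meta={
                "scenario": scenario,
                "carrying_count": K,
                "carrying_density": K / (geometry.area / 1e4),
            },
        )

    if scenario == "loser_collapse":
        cfg = load_preset("loser_collapse") if config is None else config
        dt = float(cfg["frame_interval_h"])
        t = np.arange(0.0, float(cfg["duration_h"]) + dt / 2, dt)
        K = float(cfg["baseline_count"])
        r = float(cfg["growth_rate"])
        tp = float(cfg["peak_time_h"])
        frac = float(cfg["collapse_fraction"])
        n0 = 0.3 * K
        lam = -math.log(frac) / (t[-1] - tp)
        rise = K / (1.0 + (K - n0) / n0 * np.exp(-r * np.minimum(t, tp)))
        mean = np.where(t <= tp, rise, K * np.exp(-lam * np.clip(t - tp, 0, None)))
        counts = _noisy_counts(mean, float(cfg.get("noise_cv", 0.0)), rng)
        return CountSeries(
            time_h=t,
            counts={"loser": counts},
            area_um2=float(cfg["area_um2"]),
            meta={"scenario": scenario, "peak_time_h": tp, "collapse_fraction": frac},
        )

    if scenario == "treatment_monoculture":
        cfg = load_preset("treatment_monoculture") if config is None else config
        dt = float(cfg["frame_interval_h"])
        t = np.arange(0.0, float(cfg["duration_h"]) + dt / 2, dt)
        B = float(cfg["baseline_count"])
        te = float(cfg["t_event_h"])
        f = float(cfg["endpoint_fraction"])
        tau = float(cfg["decay_tau_h"])
        mean = np.where(
            t < te, B, B * (f + (1.0 - f) * np.exp(-np.clip(t - te, 0, None) / tau))
        )
        counts = _noisy_counts(mean, float(cfg.get("noise_cv", 0.0)), rng)
        return CountSeries(
            time_h=t,
            counts={"cell": counts},
            area_um2=float(cfg["area_um2"]),
            meta={"scenario": scenario, "t_event_h": te, "endpoint_fraction": f},
        )

    if scenario == "treatment_competition":
        cfg = load_preset("treatment_competition") if config is None else config
        dt = float(cfg["frame_interval_h"])
        t = np.arange(0.0, float(cfg["duration_h"]) + dt / 2, dt)
        B = float(cfg["baseline_count"])
        te = float(cfg["t_event_h"])
        f6 = float(cfg["day6_fraction"])
        lam = -math.log(f6) / 144.0  # hit the day-6 endpoint exactly
        loser_mean = np.where(t < te, B, B * np.exp(-lam * np.clip(t - te, 0, None)))
        other_mean = np.full_like(t, float(cfg["other_count"]))
        loser = _noisy_counts(loser_mean, float(cfg.get("noise_cv", 0.0)), rng)
        other = _noisy_counts(other_mean, float(cfg.get("noise_cv", 0.0)), rng)
        return CountSeries(
            time_h=t,
            counts={"loser": loser, "other": other},
            area_um2=float(cfg["area_um2"]),
            meta={"scenario": scenario, "t_event_h": te, "day6_fraction": f6},
        )

    raise ValueError(
        f"unknown scenario {scenario!r}; expected homeostasis, loser_collapse, "
        "treatment_monoculture or treatment_competition"
    )
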