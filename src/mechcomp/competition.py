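"""Population-level competition readouts: growth and doubling time, death
fractions, clone-surround classification, treatment-normalised time
courses, and standard two-sample comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, cKDTree

from .geometry import CountSeries, PointScene

__all__ = [
    "DeathStats",
    "CloneClassification",
    "NormalizedTimecourse",
    "growth_stats",
    "death_fraction",
    "classify_clone",
    "normalized_timecourse",
    "compare_groups",
    "significance_stars",
]


@dataclass(frozen=True)
class DeathStats:
    death_events: int
    total_nuclei: int
    fraction: float


@dataclass(frozen=True)
class CloneClassification:
    clone_label: str
    status: str  # surrounded | contacted | isolated
    boundary_contact_fraction: float
    contact_radius_um: float


def growth_stats(
    count_series: CountSeries, population: str | None = None
) -> pd.DataFrame:
    """Per-interval growth rate and doubling time from a count series.

    rate = Δlog₂(count)/Δt in 1/h; doubling time = 1/rate in h (negative
    rates give a signed halving time; zero rates give ±inf).  Intervals
    touching a zero count are skipped.
    """
    if population is None:
        if len(count_series.populations) != 1:
            raise ValueError("specify a population for multi-population series")
        population = count_series.populations[0]
    c = count_series.counts[population].astype(float)
    t = count_series.time_h
    rows = []
    for i in range(len(t) - 1):
        if c[i] <= 0 or c[i + 1] <= 0:
            continue
        rate = (math.log2(c[i + 1]) - math.log2(c[i])) / (t[i + 1] - t[i])
        doubling = 1.0 / rate if rate != 0 else math.inf
        rows.append(((t[i] + t[i + 1]) / 2.0, rate, doubling))
    return pd.DataFrame(rows, columns=["t_mid_h", "rate_per_h", "doubling_time_h"])


def death_fraction(events: int, nuclei: int) -> DeathStats:
    """Death events divided by total nuclei (the caspase-positive events /
    DAPI-positive nuclei readout)."""
    if nuclei <= 0:
        raise ValueError("total nuclei must be > 0")
    if events < 0 or events > nuclei:
        raise ValueError("events must lie in [0, nuclei]")
    return DeathStats(
        death_events=int(events), total_nuclei=int(nuclei), fraction=events / nuclei
    )


def classify_clone(
    scene: PointScene, clone_label: str, contact_radius_um: float | None = None
) -> CloneClassification:
    """Classify a clone as surrounded, contacted or isolated.

    Clone boundary cells are the clone members on the clone's convex hull.
    The clone is *surrounded* when every boundary cell has at least one
    other-population neighbour within ``contact_radius_um`` and no clone
    cell lies within that radius of the field edge; *contacted* when some
    but not all boundary cells have such neighbours (or the clone touches
    the field edge); *isolated* when none do.  The default contact radius
    is the 90th percentile nearest-neighbour distance of the whole scene.
    """
    in_clone = scene.population == clone_label
    clone_pts = scene.positions[in_clone]
    other_pts = scene.positions[~in_clone]
    if len(clone_pts) == 0:
        raise ValueError(f"clone {clone_label!r} is empty")
    if contact_radius_um is None:
        if scene.n_cells < 2:
            raise ValueError("cannot derive a contact radius from < 2 cells")
        tree_all = cKDTree(scene.positions)
        nn = tree_all.query(scene.positions, k=2)[0][:, 1]
        contact_radius_um = float(np.percentile(nn, 90))
    if contact_radius_um <= 0:
        raise ValueError("contact_radius_um must be > 0")
    if len(other_pts) == 0:
        return CloneClassification(clone_label, "isolated", 0.0, contact_radius_um)

    if len(clone_pts) >= 3:
        try:
            boundary = clone_pts[ConvexHull(clone_pts).vertices]
        except Exception:  # degenerate (collinear) clone
            boundary = clone_pts
    else:
        boundary = clone_pts
    tree = cKDTree(other_pts)
    touched = np.array(
        [len(tree.query_ball_point(p, contact_radius_um)) > 0 for p in boundary]
    )
    frac = float(touched.mean())
    on_edge = bool(
        np.any(scene.geometry.edge_distance(clone_pts[:, 0], clone_pts[:, 1]) < contact_radius_um)
    )
    if frac == 1.0 and not on_edge:
        status = "surrounded"
    elif frac > 0.0:
        status = "contacted"
    else:
        status = "isolated"
    return CloneClassification(clone_label, status, frac, contact_radius_um)


@dataclass
class NormalizedTimecourse:
    """A count series as percent of its pre-event baseline."""

    time_h: np.ndarray
    percent: np.ndarray
    baseline: float
    event_time_h: float
    final_percent: float
    plateau_percent: float
    percent_change: float  # plateau − 100 (negative = reduction)

    def percent_at(self, time_h: float) -> float:
        """Percent-of-baseline at the frame nearest the given time."""
        i = int(np.argmin(np.abs(self.time_h - time_h)))
        return float(self.percent[i])


def normalized_timecourse(
    count_series: CountSeries,
    event_time: float,
    population: str | None = None,
    plateau_frames: int = 5,
) -> NormalizedTimecourse:
    """Express a count series as percent of its pre-event baseline.

    The baseline is the mean count over frames strictly before
    ``event_time``; the post-event plateau is the mean over the last
    ``plateau_frames`` frames.  ``percent_change`` is plateau − 100, so a
    26% density reduction reads −26.
    """
    if population is None:
        if len(count_series.populations) != 1:
            raise ValueError("specify a population for multi-population series")
        population = count_series.populations[0]
    c = count_series.counts[population].astype(float)
    t = count_series.time_h
    if not (t[0] <= event_time <= t[-1]):
        raise ValueError("event_time outside the series")
    pre = c[t < event_time]
    if len(pre) == 0 or pre.mean() == 0:
        raise ValueError("no usable pre-event baseline frames")
    baseline = float(pre.mean())
    percent = 100.0 * c / baseline
    plateau = float(percent[-plateau_frames:].mean())
    return NormalizedTimecourse(
        time_h=t,
        percent=percent,
        baseline=baseline,
        event_time_h=float(event_time),
        final_percent=float(percent[-1]),
        plateau_percent=plateau,
        percent_change=plateau - 100.0,
    )


def significance_stars(p: float) -> str:
    """Star string: *P<0.05, **P<0.005, ***P<0.0005 (else 'ns')."""
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(sample_a, sample_b, test: str = "ks") -> dict:
    """Two-sample comparison via a stock statistics routine.

    ``test`` is "ks" (two-sample Kolmogorov–Smirnov, the default used for
    non-normal data), "t" (Student's t) or "wilcoxon" (rank-sum).
    Returns the statistic, the two-sided p-value and the star string.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both samples need at least 3 observations")
    if test == "ks":
        res = stats.ks_2samp(a, b)
    elif test == "t":
        res = stats.ttest_ind(a, b)
    elif test == "wilcoxon":
        res = stats.ranksums(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    stat, p = float(res.statistic), float(res.pvalue)
    return {"test": test, "statistic": stat, "p_value": p, "stars": significance_stars(p)}
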