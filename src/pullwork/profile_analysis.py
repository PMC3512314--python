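"""Replica-averaged force profiles, convergence diagnostics and partitions.

This module carries the descriptive half of the analysis chain:

* the mean |F| vs. spring-end displacement profile across replicas, with its
  standard deviation per bin;
* the error-bar-crossing convergence criterion — the displacement where the
  bound and viscous profiles' mean ± SD intervals start to overlap, doubled
  to give the production cutoff;
* the binding-pocket-plane partition of the trajectory into an interior
  (conformationally determined) and exterior region, with the interior work;
* work-histogram summaries with moment-matched Gaussian overlays and a
  population-separation report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .errors import ConvergenceError, GeometryError, ValidationError
from .pull_io import ReplicaSet
from .work_integration import WorkSample, WorkSeries, work_at

__all__ = [
    "ForceProfile",
    "RegionPartition",
    "HistogramSummary",
    "mean_force_profile",
    "errorbar_crossing",
    "plane_crossing_index",
    "partition_work",
    "work_histogram_summary",
    "gaussian_overlap",
]


@dataclass
class ForceProfile:
    """Binned mean |F| and its SD vs. spring-end displacement."""

    bin_centers: np.ndarray
    mean_force_magnitude: np.ndarray
    sd_force: np.ndarray
    n_per_bin: np.ndarray
    bin_width: float = float("nan")

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValidationError("bin centers must be strictly increasing")
        if np.any(np.asarray(self.n_per_bin) < 1):
            raise ValidationError("reported bins must contain >= 1 sample")


@dataclass(frozen=True)
class RegionPartition:
    """Interior/exterior split of the pull at the binding-pocket threshold."""

    boundary_coordinate: float
    total_distance: float
    interior_fraction: float
    interior_work: float
    interior_work_se: float


@dataclass
class HistogramSummary:
    """Work histograms of two populations with moment-matched Gaussians."""

    edges: np.ndarray
    counts_bound: np.ndarray
    counts_viscous: np.ndarray
    mean_bound: float
    sd_bound: float
    mean_viscous: float
    sd_viscous: float
    standardized_mean_difference: float
    overlap_coefficient: float
    extras: dict = field(default_factory=dict)


def mean_force_profile(replicas: ReplicaSet,
                       bin_width: float) -> ForceProfile:
    """Pool |F| from all replicas into displacement bins.

    Per bin the mean and SD (ddof=1) of the pooled force magnitudes are
    reported; empty bins are omitted.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if len(replicas) < 2:
        raise ValidationError(
            "need >= 2 replicas for the profile SD to be defined")
    disp = np.concatenate([t.spring_displacement for t in replicas])
    fmag = np.concatenate([np.linalg.norm(t.force, axis=1) for t in replicas])
    n_bins = int(np.ceil((disp.max() + 1e-12) / bin_width))
    idx = np.minimum((disp // bin_width).astype(int), n_bins - 1)
    centers, means, sds, counts = [], [], [], []
    order = np.argsort(idx, kind="stable")
    idx_s, f_s = idx[order], fmag[order]
    boundaries = np.searchsorted(idx_s, np.arange(n_bins + 1))
    for b in range(n_bins):
        lo, hi = boundaries[b], boundaries[b + 1]
        if hi == lo:
            continue
        vals = f_s[lo:hi]
        centers.append((b + 0.5) * bin_width)
        means.append(vals.mean())
        sds.append(vals.std(ddof=1) if vals.size > 1 else 0.0)
        counts.append(vals.size)
    return ForceProfile(
        bin_centers=np.asarray(centers),
        mean_force_magnitude=np.asarray(means),
        sd_force=np.asarray(sds),
        n_per_bin=np.asarray(counts),
        bin_width=bin_width)


def _align(profile: ForceProfile, centers: np.ndarray):
    """Interpolate a profile's mean and SD onto a common center grid."""
    m = np.interp(centers, profile.bin_centers, profile.mean_force_magnitude)
    s = np.interp(centers, profile.bin_centers, profile.sd_force)
    return m, s


def errorbar_crossing(profile_bound: ForceProfile,
                      profile_viscous: ForceProfile,
                      m_consecutive: int = 3,
                      sd_multiplier: float = 1.0) -> tuple[float, float]:
    """Convergence displacement and production cutoff from two profiles.

    The crossing is where the separation between the bound and viscous
    profiles ends: the center of the first bin, after the profiles have been
    separated at least once, from which the mean ± ``sd_multiplier``·SD
    intervals overlap for ``m_consecutive`` consecutive bins.  (Profiles
    that never separate cross at the first bin.)  Skipping overlap bins that
    precede any separation matters for thermally noisy records, where the
    two force distributions coincide for a short transient while the spring
    is still unloaded.  The production cutoff is twice the crossing
    displacement.  Returns ``(crossing, cutoff)``.
    """
    if m_consecutive < 1:
        raise ValidationError("m_consecutive must be >= 1")
    lo = max(profile_bound.bin_centers[0], profile_viscous.bin_centers[0])
    hi = min(profile_bound.bin_centers[-1], profile_viscous.bin_centers[-1])
    if hi < lo:
        raise ConvergenceError("profiles do not share a displacement range")
    centers = profile_bound.bin_centers[
        (profile_bound.bin_centers >= lo - 1e-12)
        & (profile_bound.bin_centers <= hi + 1e-12)]
    mb, sb = _align(profile_bound, centers)
    mv, sv = _align(profile_viscous, centers)
    overlap = np.abs(mb - mv) <= sd_multiplier * (sb + sv) + 1e-12
    if overlap.all():
        return float(centers[0]), 2.0 * float(centers[0])
    first_sep = int(np.argmin(overlap))  # first False
    run = 0
    for i in range(first_sep + 1, overlap.size):
        run = run + 1 if overlap[i] else 0
        if run >= m_consecutive:
            crossing = float(centers[i - m_consecutive + 1])
            return crossing, 2.0 * crossing
    raise ConvergenceError(
        "error bars never overlap for the required run of bins; the pull "
        "likely ends before the ligand leaves the binding region — use "
        "longer pulls")


def plane_crossing_index(positions, p1, p2, p3,
                         pull_direction=None) -> int | None:
    """First sample index at which a path crosses the plane through three
    points (the binding-pocket threshold).

    The plane normal is oriented along ``pull_direction`` when given,
    otherwise so that the first position lies on the negative side.  A sample
    exactly on the plane counts as the crossing.  Returns ``None`` when the
    path never crosses.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    normal = np.cross(p2 - p1, p3 - p1)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1.0)
    if np.linalg.norm(normal) <= 1e-12 * scale ** 2:
        raise GeometryError("plane points are collinear")
    normal = normal / np.linalg.norm(normal)
    if pull_direction is not None:
        proj = float(np.dot(normal, np.asarray(pull_direction, dtype=float)))
        if proj < 0:
            normal = -normal
    signed = (pos - p1) @ normal
    if pull_direction is None and signed[0] > 0:
        normal, signed = -normal, -signed
    s0 = np.sign(signed[0])
    if s0 == 0:
        return 0
    changed = np.nonzero(np.sign(signed) != s0)[0]  # zero counts as crossed
    return int(changed[0]) if changed.size else None


def partition_work(series_set: list[WorkSeries], boundary_coordinate: float,
                   total_distance: float) -> RegionPartition:
    """Interior-region fraction and interior work at a boundary displacement.

    ``interior_fraction = boundary/total``; the interior work is the replica
    mean of W(boundary) with its standard error SD/√N.
    """
    if not (0.0 <= boundary_coordinate <= total_distance):
        raise ValidationError(
            "boundary must lie within [0, total_distance]")
    works = np.array([work_at(s, boundary_coordinate) for s in series_set])
    se = float(np.std(works, ddof=1) / np.sqrt(works.size)) \
        if works.size > 1 else 0.0
    return RegionPartition(
        boundary_coordinate=float(boundary_coordinate),
        total_distance=float(total_distance),
        interior_fraction=float(boundary_coordinate / total_distance),
        interior_work=float(works.mean()),
        interior_work_se=se)


def gaussian_overlap(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Overlap coefficient ∫ min(φ₁, φ₂) of two Gaussian densities.

    Closed form 2Φ(−|Δμ|/2σ) for equal widths, numerical quadrature
    otherwise.  1 for identical populations, → 0 for disjoint ones.
    """
    if min(sd1, sd2) <= 0:
        return 1.0 if (mu1 == mu2 and sd1 == sd2) else 0.0
    if np.isclose(sd1, sd2, rtol=1e-9):
        return float(2.0 * norm.cdf(-abs(mu1 - mu2) / (2.0 * sd1)))
    lo = min(mu1 - 10 * sd1, mu2 - 10 * sd2)
    hi = max(mu1 + 10 * sd1, mu2 + 10 * sd2)
    val, _ = quad(lambda x: np.minimum(norm.pdf(x, mu1, sd1),
                                       norm.pdf(x, mu2, sd2)),
                  lo, hi, points=[mu1, mu2], limit=200)
    return float(min(val, 1.0))


def work_histogram_summary(sample_bound: WorkSample,
                           sample_viscous: WorkSample,
                           n_bins: int = 20) -> HistogramSummary:
    """Histograms of the two work populations plus separation statistics.

    Gaussian overlays are moment-matched (sample mean and SD, not a fit).
    The separation report gives the standardized mean difference
    |μ_b − μ_v| / sqrt((σ_b² + σ_v²)/2) and the Gaussian overlap
    coefficient of the two overlays.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    wb, wv = sample_bound.works, sample_viscous.works
    lo = min(wb.min(), wv.min())
    hi = max(wb.max(), wv.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    cb, _ = np.histogram(wb, bins=edges)
    cv, _ = np.histogram(wv, bins=edges)
    mb, sb = float(wb.mean()), float(wb.std(ddof=1)) if wb.size > 1 else 0.0
    mv, sv = float(wv.mean()), float(wv.std(ddof=1)) if wv.size > 1 else 0.0
    pooled = np.sqrt((sb ** 2 + sv ** 2) / 2.0)
    smd = abs(mb - mv) / pooled if pooled > 0 else \
        (0.0 if mb == mv else float("inf"))
    ovl = gaussian_overlap(mb, sb, mv, sv)
    return HistogramSummary(
        edges=edges, counts_bound=cb, counts_viscous=cv,
        mean_bound=mb, sd_bound=sb, mean_viscous=mv, sd_viscous=sv,
        standardized_mean_difference=float(smd),
        overlap_coefficient=float(ovl))
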