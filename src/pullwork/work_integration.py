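"""Cumulative mechanical work from force/position traces.

Work is accumulated by the trapezoidal rule under one of two conventions:

``control_parameter`` (default)
    W = ∫ F∥ dz, the force component along the pull axis integrated against
    the spring-end position z(t).  This is the work conjugate to the schedule
    z(t), the quantity for which the Jarzynski identity is exact.
``com_path``
    W = Σ_c ∫ F_c dr_c, each force component integrated against the matching
    component of the pulled-point center-of-mass path — the convention in
    which the component-wise force-vs-position records are usually plotted.

Either way the resulting series is indexed by the spring-end displacement
|z(t) − z(0)| so both conventions are comparable on one axis.  Thermal
backtracking of the pulled point is kept signed (no rectification): work is
path-signed and rectifying would bias it upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .pull_io import PullTrajectory, ReplicaSet
from .units import thermal_energy

__all__ = ["WorkSeries", "WorkSample", "accumulate_work", "work_at",
           "collect_work_sample", "CONVENTIONS"]

CONVENTIONS = ("control_parameter", "com_path")


@dataclass
class WorkSeries:
    """Cumulative work vs. spring-end displacement for one replica."""

    pull_coordinate: np.ndarray
    cumulative_work: np.ndarray
    convention: str = "control_parameter"
    replica_id: int = 0

    def __post_init__(self):
        self.pull_coordinate = np.asarray(self.pull_coordinate, dtype=float)
        self.cumulative_work = np.asarray(self.cumulative_work, dtype=float)
        if self.pull_coordinate.shape != self.cumulative_work.shape:
            raise ValidationError("coordinate/work length mismatch")
        if np.any(np.diff(self.pull_coordinate) < 0):
            raise ValidationError("pull coordinate must be non-decreasing")
        if self.cumulative_work[0] != 0.0:
            raise ValidationError("cumulative work must start at 0")


@dataclass
class WorkSample:
    """Terminal work values of N_s replicas at a fixed cutoff displacement."""

    works: np.ndarray
    cutoff: float = float("nan")
    temperature_T: float = 1.0
    convention: str = "control_parameter"
    unit_system: str = "reduced"

    def __post_init__(self):
        self.works = np.atleast_1d(np.asarray(self.works, dtype=float))
        if self.works.size < 1:
            raise ValidationError("work sample must contain >= 1 value")
        if not np.all(np.isfinite(self.works)):
            bad = int(np.nonzero(~np.isfinite(self.works))[0][0])
            raise ValidationError(f"non-finite work at index {bad}")

    @property
    def n(self) -> int:
        return self.works.size

    @property
    def kBT(self) -> float:
        return thermal_energy(self.temperature_T, self.unit_system)


def _check_finite(name: str, arr: np.ndarray) -> None:
    bad = np.nonzero(~np.isfinite(arr))[0]
    if bad.size:
        raise ValidationError(f"NaN/inf in {name} at index {int(bad[0])}")


def accumulate_work(trajectory: PullTrajectory,
                    convention: str = "control_parameter") -> WorkSeries:
    """Trapezoid-integrate one replica's force record into cumulative work."""
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown convention {convention!r}")
    _check_finite("force", trajectory.force)
    _check_finite("position", trajectory.position)
    _check_finite("spring_end", trajectory.spring_end)
    if convention == "control_parameter":
        f_par = trajectory.force @ trajectory.direction_vector()
        incr = 0.5 * (f_par[:-1] + f_par[1:]) * np.diff(trajectory.spring_end)
    else:
        pair = 0.5 * (trajectory.force[:-1] + trajectory.force[1:])
        incr = np.sum(pair * np.diff(trajectory.position, axis=0), axis=1)
    work = np.concatenate([[0.0], np.cumsum(incr)])
    return WorkSeries(
        pull_coordinate=trajectory.spring_displacement,
        cumulative_work=work,
        convention=convention,
        replica_id=trajectory.meta.replica_id,
    )


def work_at(series: WorkSeries, coordinate: float) -> float:
    """Cumulative work at a displacement, linearly interpolated.

    Exact on grid points; raises if the series ends before the coordinate.
    """
    pc = series.pull_coordinate
    if coordinate < pc[0] - 1e-12 or coordinate > pc[-1] + 1e-12:
        raise ValidationError(
            f"replica {series.replica_id}: series spans "
            f"[{pc[0]:g}, {pc[-1]:g}], cannot evaluate work at "
            f"{coordinate:g}")
    return float(np.interp(coordinate, pc, series.cumulative_work))


def collect_work_sample(replicas: ReplicaSet, cutoff: float,
                        convention: str = "control_parameter") -> WorkSample:
    """Terminal work of every replica at the production cutoff displacement."""
    works = []
    for traj in replicas:
        series = accumulate_work(traj, convention=convention)
        works.append(work_at(series, cutoff))
    meta = replicas.meta
    return WorkSample(
        works=np.asarray(works), cutoff=float(cutoff),
        temperature_T=meta.temperature_T, convention=convention,
        unit_system=meta.unit_system,
    )
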