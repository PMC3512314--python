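"""Reading, writing and pairing of steered-pull trajectories.

Trajectories travel as the two-file XVG (xmgrace) text dialect that MD pull
codes emit: a *position* file (time, spring-end position, pulled-point
center-of-mass components) and a *force* file (time, applied-force
components).  Lines starting with ``#`` are comments, lines starting with
``@`` are plot metadata; data lines are whitespace-separated numbers with the
time in the first column.

The in-memory containers are :class:`PullTrajectory` (one replica) and
:class:`ReplicaSet` (the 30-odd replicas of one pulling experiment, sharing a
protocol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AlignmentError, ParseError, ValidationError
from .units import UNIT_SYSTEMS, conversion_factors, thermal_energy

__all__ = [
    "TrajectoryMeta",
    "PullTrajectory",
    "ReplicaSet",
    "XVGTable",
    "read_pull_xvg",
    "write_pull_xvg",
    "pair_replicas",
    "convert_trajectory",
]

# Deterministic numeric format: 17 significant digits round-trips any double.
_FMT = "%.17g"


@dataclass(frozen=True)
class TrajectoryMeta:
    """Protocol metadata shared by the position and force records."""

    spring_k: float
    pull_rate_v: float
    temperature_T: float
    unit_system: str = "reduced"
    replica_id: int = 0
    direction: tuple[float, ...] | None = None  # pull axis, 3-D runs only

    def __post_init__(self):
        if self.unit_system not in UNIT_SYSTEMS:
            raise ValidationError(f"unknown unit system {self.unit_system!r}")

    @property
    def kBT(self) -> float:
        return thermal_energy(self.temperature_T, self.unit_system)


@dataclass
class PullTrajectory:
    """One replica's time series of control parameter, position and force.

    ``position`` and ``force`` are ``(n, d)`` arrays with ``d`` = 1 or 3
    spatial components; ``spring_end`` is the scalar control parameter z(t)
    (the distance of the spring's free end along the pull axis).
    """

    times: np.ndarray
    spring_end: np.ndarray
    position: np.ndarray
    force: np.ndarray
    meta: TrajectoryMeta

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.spring_end = np.asarray(self.spring_end, dtype=float)
        self.position = np.atleast_2d(np.asarray(self.position, dtype=float))
        self.force = np.atleast_2d(np.asarray(self.force, dtype=float))
        if self.position.shape[0] == 1 and self.times.size > 1:
            self.position = self.position.T
        if self.force.shape[0] == 1 and self.times.size > 1:
            self.force = self.force.T
        n = self.times.size
        if n < 2:
            raise ValidationError("trajectory needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        for name, arr in (("spring_end", self.spring_end),
                          ("position", self.position), ("force", self.force)):
            if arr.shape[0] != n:
                raise ValidationError(
                    f"{name} has {arr.shape[0]} rows, expected {n}")
        if self.position.shape != self.force.shape:
            raise ValidationError("position and force shapes differ")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def n_dim(self) -> int:
        return self.position.shape[1]

    @property
    def spring_displacement(self) -> np.ndarray:
        """|z(t) − z(0)|, the pull coordinate reported downstream."""
        return np.abs(self.spring_end - self.spring_end[0])

    def direction_vector(self) -> np.ndarray:
        """Unit pull axis (defaults to +x̂ of the recorded components)."""
        if self.meta.direction is not None:
            d = np.asarray(self.meta.direction, dtype=float)
        else:
            d = np.zeros(self.n_dim)
            d[0] = 1.0
        return d / np.linalg.norm(d)


@dataclass
class ReplicaSet:
    """Trajectories of one pulling experiment sharing k, v, T and units."""

    trajectories: list[PullTrajectory]
    label: str = "bound"

    def __post_init__(self):
        if not self.trajectories:
            raise ValidationError("replica set must contain >= 1 trajectory")
        ref = self.trajectories[0].meta
        for t in self.trajectories[1:]:
            m = t.meta
            if m.unit_system != ref.unit_system:
                raise ValidationError("replicas mix unit systems")
            for attr in ("spring_k", "pull_rate_v", "temperature_T"):
                if not np.isclose(getattr(m, attr), getattr(ref, attr),
                                  rtol=1e-12, atol=0.0):
                    raise ValidationError(f"replicas disagree on {attr}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def meta(self) -> TrajectoryMeta:
        return self.trajectories[0].meta


@dataclass
class XVGTable:
    """Parsed XVG file: the numeric block plus header metadata."""

    data: np.ndarray                      # (rows, cols), first col = time
    labels: list[str] = field(default_factory=list)   # '@' axis/legend lines
    metadata: dict[str, str] = field(default_factory=dict)  # '# key = value'

    @property
    def times(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def values(self) -> np.ndarray:
        return self.data[:, 1:]


def read_pull_xvg(path: str | Path, kind: str | None = None) -> XVGTable:
    """Parse an XVG pull record into a column table.

    ``kind`` ('force' | 'position') is advisory: when given and the file
    declares a kind in its metadata, a mismatch raises.  Duplicate time stamps
    (checkpoint-restart concatenation) keep the first occurrence with a
    warning.  Comma decimal separators are rejected outright rather than
    locale-guessed.
    """
    path = Path(path)
    labels: list[str] = []
    metadata: dict[str, str] = {}
    rows: list[list[float]] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("@"):
                labels.append(line[1:].strip())
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    metadata[key.strip()] = val.strip()
                continue
            tokens = line.split()
            if any("," in t for t in tokens):
                raise ParseError(
                    "comma decimal separator found; this reader only accepts "
                    "'.' decimals", lineno)
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                raise ParseError(f"non-numeric data: {exc}", lineno) from None
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ParseError(
                    f"ragged row: {len(values)} columns, expected {ncols}",
                    lineno)
            rows.append(values)
    if not rows:
        raise ParseError(f"no data lines in {path}")
    data = np.asarray(rows, dtype=float)
    # keep-first duplicate-time policy (restart artifacts)
    _, first_idx = np.unique(data[:, 0], return_index=True)
    if first_idx.size != data.shape[0]:
        warnings.warn(
            f"{path.name}: {data.shape[0] - first_idx.size} duplicate time "
            "stamp(s) dropped (kept first occurrence)", stacklevel=2)
        data = data[np.sort(first_idx)]
    declared = metadata.get("kind")
    if kind is not None and declared is not None and declared != kind:
        raise ParseError(f"file declares kind={declared!r}, expected {kind!r}")
    return XVGTable(data=data, labels=labels, metadata=metadata)


def _meta_header(meta: TrajectoryMeta, kind: str) -> list[str]:
    lines = [
        "# pullwork pull record",
        f"# kind = {kind}",
        f"# unit_system = {meta.unit_system}",
        f"# spring_k = {_FMT % meta.spring_k}",
        f"# pull_rate_v = {_FMT % meta.pull_rate_v}",
        f"# temperature_T = {_FMT % meta.temperature_T}",
        f"# replica_id = {meta.replica_id}",
    ]
    if meta.direction is not None:
        lines.append("# direction = " +
                     " ".join(_FMT % c for c in meta.direction))
    return lines


_AXIS_LABELS = {
    "reduced": ("time", "length", "force"),
    "gromacs": ("Time (ps)", "Position (nm)", "Force (kJ/mol/nm)"),
    "SI": ("Time (s)", "Position (m)", "Force (N)"),
}


def write_pull_xvg(trajectory: PullTrajectory, path: str | Path,
                   kind: str) -> Path:
    """Write the force or position record of one replica as XVG text.

    Output is bit-identical for identical input: fixed header order and a
    17-significant-digit numeric format.
    """
    if kind not in ("force", "position"):
        raise ValidationError(f"kind must be 'force' or 'position', got {kind!r}")
    path = Path(path)
    t_lab, x_lab, f_lab = _AXIS_LABELS[trajectory.meta.unit_system]
    comps = "xyz"[: trajectory.n_dim]
    if kind == "position":
        cols = np.column_stack(
            [trajectory.times, trajectory.spring_end, trajectory.position])
        legends = ["spring end z"] + [f"{c} COM" for c in comps]
        y_lab = x_lab
    else:
        cols = np.column_stack([trajectory.times, trajectory.force])
        legends = [f"F{c}" for c in comps]
        y_lab = f_lab
    lines = _meta_header(trajectory.meta, kind)
    lines.append(f'@    title "pull {kind}, replica '
                 f'{trajectory.meta.replica_id}"')
    lines.append(f'@    xaxis  label "{t_lab}"')
    lines.append(f'@    yaxis  label "{y_lab}"')
    for i, leg in enumerate(legends):
        lines.append(f'@ s{i} legend "{leg}"')
    for row in cols:
        lines.append(" ".join(_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def _table_meta(table: XVGTable) -> TrajectoryMeta:
    md = table.metadata
    try:
        direction = None
        if "direction" in md:
            direction = tuple(float(c) for c in md["direction"].split())
        return TrajectoryMeta(
            spring_k=float(md["spring_k"]),
            pull_rate_v=float(md["pull_rate_v"]),
            temperature_T=float(md["temperature_T"]),
            unit_system=md.get("unit_system", "reduced"),
            replica_id=int(md.get("replica_id", 0)),
            direction=direction,
        )
    except KeyError as exc:
        raise ParseError(f"missing required metadata key {exc}") from None


def pair_replicas(force_tables: Sequence[XVGTable],
                  position_tables: Sequence[XVGTable],
                  tolerance: float = 1e-6,
                  label: str = "bound") -> ReplicaSet:
    """Align force/position table pairs on their time stamps.

    Tables are matched positionally (i-th force with i-th position).  Time
    stamps must agree within ``tolerance``; the merged trajectory uses the
    position file's times.
    """
    if len(force_tables) != len(position_tables):
        raise AlignmentError(
            f"{len(force_tables)} force tables vs "
            f"{len(position_tables)} position tables")
    trajectories = []
    for i, (ft, pt) in enumerate(zip(force_tables, position_tables)):
        if ft.data.shape[0] != pt.data.shape[0]:
            raise AlignmentError(
                f"pair {i}: {ft.data.shape[0]} force rows vs "
                f"{pt.data.shape[0]} position rows")
        dt_miss = np.abs(ft.times - pt.times)
        bad = np.nonzero(dt_miss > tolerance)[0]
        if bad.size:
            j = bad[0]
            raise AlignmentError(
                f"pair {i}: time stamps differ by {dt_miss[j]:g} "
                f"(> tolerance {tolerance:g}) first at t = {pt.times[j]:g}")
        max_off = float(dt_miss.max())
        if max_off > 0:
            warnings.warn(
                f"pair {i}: force/position grids offset by up to "
                f"{max_off:g} (within tolerance)", stacklevel=2)
        meta = _table_meta(pt)
        d = ft.values.shape[1]
        if pt.values.shape[1] != d + 1:
            raise AlignmentError(
                f"pair {i}: position table must have spring-end plus {d} "
                f"component columns, found {pt.values.shape[1]}")
        trajectories.append(PullTrajectory(
            times=pt.times.copy(),
            spring_end=pt.values[:, 0].copy(),
            position=pt.values[:, 1:].copy(),
            force=ft.values.copy(),
            meta=meta,
        ))
    return ReplicaSet(trajectories=trajectories, label=label)


def load_replica_set(force_paths: Iterable[str | Path],
                     position_paths: Iterable[str | Path],
                     tolerance: float = 1e-6,
                     label: str = "bound") -> ReplicaSet:
    """Convenience: read sorted file lists and pair them."""
    ft = [read_pull_xvg(p, kind="force") for p in sorted(map(str, force_paths))]
    pt = [read_pull_xvg(p, kind="position")
          for p in sorted(map(str, position_paths))]
    return pair_replicas(ft, pt, tolerance=tolerance, label=label)


def write_replica_set(replicas: ReplicaSet, outdir: str | Path,
                      prefix: str = "pull") -> list[Path]:
    """Write every replica's force and position XVG files into *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for traj in replicas:
        rid = traj.meta.replica_id
        paths.append(write_pull_xvg(
            traj, outdir / f"{prefix}f_{rid:03d}.xvg", "force"))
        paths.append(write_pull_xvg(
            traj, outdir / f"{prefix}x_{rid:03d}.xvg", "position"))
    return paths


def convert_trajectory(trajectory: PullTrajectory, dst: str) -> PullTrajectory:
    """Convert a trajectory between the gromacs and SI unit systems."""
    src = trajectory.meta.unit_system
    f = conversion_factors(src, dst)
    k = trajectory.meta.spring_k * f["energy"] / f["length"] ** 2
    v = trajectory.meta.pull_rate_v * f["length"] / f["time"]
    meta = replace(trajectory.meta, spring_k=k, pull_rate_v=v, unit_system=dst)
    return PullTrajectory(
        times=trajectory.times * f["time"],
        spring_end=trajectory.spring_end * f["length"],
        position=trajectory.position * f["length"],
        force=trajectory.force * f["force"],
        meta=meta,
    )
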