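"""End-to-end orchestration: simulate/load → integrate → estimate → report.

One :class:`RunConfig` describes a whole experiment — where the bound and
viscous replica sets come from (synthetic generator or XVG files on disk),
the cutoff policy, estimator settings and the optional experimental affinity
constant — and :func:`run_pipeline` turns it into a :class:`PipelineReport`.
Identical config + seeds give bit-identical numeric output; every file the
pipeline writes declares its units, and a manifest records the config hash
and all seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .errors import PullworkError, ValidationError
from .estimators import (EstimatorResult, delta_g_from_ka, estimate,
                         ordering_check, viscous_correction)
from .profile_analysis import (ForceProfile, errorbar_crossing,
                               mean_force_profile, partition_work,
                               work_histogram_summary)
from .pull_io import ReplicaSet, load_replica_set, write_replica_set
from .synthetic_pull import (BindingPotential, PullConfig,
                             analytic_pull_delta_g, simulate_replica_set)
from .work_integration import accumulate_work, collect_work_sample

log = logging.getLogger("pullwork")

__all__ = ["ReplicaSource", "RunConfig", "PipelineReport", "run_pipeline"]


@dataclass(frozen=True)
class ReplicaSource:
    """Exactly one of: a synthetic PullConfig, or XVG file path lists."""

    synthetic: PullConfig | None = None
    force_paths: tuple[str, ...] | None = None
    position_paths: tuple[str, ...] | None = None

    def __post_init__(self):
        has_files = self.force_paths is not None
        if has_files != (self.position_paths is not None):
            raise ValidationError(
                "force_paths and position_paths must be given together")
        if (self.synthetic is None) == (not has_files):
            raise ValidationError(
                "give exactly one of {synthetic config, file paths} "
                "per replica set")

    def realize(self, label: str) -> ReplicaSet:
        if self.synthetic is not None:
            log.info("simulating %s set: %d replicas, seed %d", label,
                     self.synthetic.n_replicas, self.synthetic.seed)
            return simulate_replica_set(self.synthetic, label=label)
        log.info("loading %s set from %d file pairs", label,
                 len(self.force_paths))
        return load_replica_set(self.force_paths, self.position_paths,
                                label=label)


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs, with explicit units and seeds."""

    bound: ReplicaSource
    viscous: ReplicaSource | None = None
    cutoff: float | str = "auto"        # displacement, or "auto" (2×crossing)
    convention: str = "control_parameter"
    bin_width: float | None = None      # default: pull distance / 100
    m_consecutive: int = 3
    sd_multiplier: float = 1.0
    bootstrap_B: int = 1000
    seed: int = 0
    ka_per_molar: float | None = None   # experimental affinity constant, 1/M
    ka_temperature_K: float = 300.0
    boundary_coordinate: float | None = None
    n_hist_bins: int = 20

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        """Load a JSON or TOML run configuration."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib
            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict[str, Any],
                  seed: int | None = None) -> "RunConfig":
        def source(d: dict[str, Any] | None) -> ReplicaSource | None:
            if d is None:
                return None
            if "synthetic" in d:
                syn = dict(d["synthetic"])
                if "potential" in syn:
                    syn["potential"] = BindingPotential(**syn["potential"])
                return ReplicaSource(synthetic=PullConfig(**syn))
            return ReplicaSource(
                force_paths=tuple(d["force_paths"]),
                position_paths=tuple(d["position_paths"]))

        kwargs = dict(raw)
        kwargs["bound"] = source(raw["bound"])
        kwargs["viscous"] = source(raw.get("viscous"))
        cfg = cls(**kwargs)
        if seed is not None:
            cfg = cfg.with_seed(seed)
        return cfg

    def with_seed(self, seed: int) -> "RunConfig":
        """Re-seed the run: synthetic sets get seed and seed+1."""
        bound, viscous = self.bound, self.viscous
        if bound.synthetic is not None:
            bound = ReplicaSource(synthetic=replace(bound.synthetic, seed=seed))
        if viscous is not None and viscous.synthetic is not None:
            viscous = ReplicaSource(
                synthetic=replace(viscous.synthetic, seed=seed + 1))
        return replace(self, bound=bound, viscous=viscous, seed=seed)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """All numeric outputs of one run, JSON-serialisable via to_dict()."""

    bound_estimate: EstimatorResult
    viscous_estimate: EstimatorResult | None
    corrected_estimate: EstimatorResult | None
    crossing: float | None
    cutoff: float
    ordering: dict | None
    analytic_delta_g: float | None
    experimental_delta_g_J: float | None
    partition: dict | None
    histogram: dict | None
    profile_bound: ForceProfile
    profile_viscous: ForceProfile | None
    unit_system: str
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def est(e):
            return None if e is None else {
                "Wa": e.Wa, "Wx": e.Wx, "se_Wa": e.se_Wa, "se_Wx": e.se_Wx,
                "se_Wa_naive": e.se_Wa_naive, "N_s": e.N_s,
                "temperature_T": e.temperature_T, "kBT": e.kBT,
                "label": e.label}
        return {
            "unit_system": self.unit_system,
            "bound": est(self.bound_estimate),
            "viscous": est(self.viscous_estimate),
            "corrected": est(self.corrected_estimate),
            "crossing": self.crossing,
            "cutoff": self.cutoff,
            "ordering": self.ordering,
            "analytic_delta_g": self.analytic_delta_g,
            "experimental_delta_g_J": self.experimental_delta_g_J,
            "partition": self.partition,
            "histogram": self.histogram,
            "manifest": self.manifest,
        }


def _profile_to_csv(profile: ForceProfile, path: Path, unit_system: str):
    import pandas as pd
    df = pd.DataFrame({
        "bin_center": profile.bin_centers,
        "mean_force_magnitude": profile.mean_force_magnitude,
        "sd_force": profile.sd_force,
        "n_per_bin": profile.n_per_bin,
    })
    with open(path, "w") as fh:
        fh.write(f"# mean |F| profile vs spring-end displacement "
                 f"(unit system: {unit_system})\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig,
                 outdir: str | Path | None = None,
                 export_trajectories: bool = False) -> PipelineReport:
    """Run the full analysis described by *config*.

    Stages: realize replica sets → force profiles → (auto) cutoff → work
    samples → W^a/W^x estimates → viscous correction → ordering checks →
    region partition → histogram summary.  Any stage failure is re-raised
    with the stage name attached.
    """
    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PullworkError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    bound_set = stage("simulate/load bound", config.bound.realize, "bound")
    viscous_set = None
    if config.viscous is not None:
        viscous_set = stage("simulate/load viscous",
                            config.viscous.realize, "viscous")

    meta = bound_set.meta
    travel = float(max(t.spring_displacement[-1] for t in bound_set))
    bin_width = config.bin_width or travel / 100.0

    profile_bound = stage("profile bound", mean_force_profile,
                          bound_set, bin_width)
    profile_viscous = None
    crossing = None
    if viscous_set is not None:
        profile_viscous = stage("profile viscous", mean_force_profile,
                                viscous_set, bin_width)

    if config.cutoff == "auto":
        if profile_viscous is None:
            raise ValidationError(
                "[stage cutoff] auto cutoff needs a viscous set; give a "
                "fixed cutoff instead")
        crossing, cutoff = stage("errorbar crossing", errorbar_crossing,
                                 profile_bound, profile_viscous,
                                 config.m_consecutive, config.sd_multiplier)
        if cutoff > travel:
            warnings.warn(
                f"doubled crossing ({cutoff:g}) exceeds the spring-end "
                f"travel; clamping production cutoff to {travel:g}",
                stacklevel=2)
            cutoff = travel
    else:
        cutoff = float(config.cutoff)
        if viscous_set is not None:
            try:
                crossing, _ = errorbar_crossing(
                    profile_bound, profile_viscous,
                    config.m_consecutive, config.sd_multiplier)
            except PullworkError:
                crossing = None

    sample_bound = stage("work sample bound", collect_work_sample,
                         bound_set, cutoff, config.convention)
    est_bound = stage("estimate bound", estimate, sample_bound, "bound",
                      config.bootstrap_B, config.seed + 101)

    est_viscous = corrected = None
    sample_viscous = None
    if viscous_set is not None:
        sample_viscous = stage("work sample viscous", collect_work_sample,
                               viscous_set, cutoff, config.convention)
        est_viscous = stage("estimate viscous", estimate, sample_viscous,
                            "viscous", config.bootstrap_B, config.seed + 202)
        corrected = stage("viscous correction", viscous_correction,
                          est_bound, est_viscous)
    else:
        warnings.warn("no viscous set configured: corrected estimate "
                      "omitted", stacklevel=2)

    analytic_dg = None
    ordering = None
    if config.bound.synthetic is not None:
        syn = config.bound.synthetic
        end_to_end = replace(syn, total_time_ts=cutoff / syn.pull_rate_v) \
            if cutoff != syn.travel else syn
        analytic_dg = stage("analytic delta G", analytic_pull_delta_g,
                            end_to_end)
        rep = ordering_check(analytic_dg, est_bound)
        ordering = {
            "delta_g": rep.delta_g, "Wx": rep.Wx, "Wa": rep.Wa,
            "margin_dg_wx_kbt": rep.margin_dg_wx_kbt,
            "margin_wx_wa_kbt": rep.margin_wx_wa_kbt,
            "dg_le_wx": rep.dg_le_wx, "wx_le_wa": rep.wx_le_wa,
            "passed": rep.passed,
        }

    experimental_dg = None
    if config.ka_per_molar is not None:
        experimental_dg = delta_g_from_ka(config.ka_per_molar,
                                          config.ka_temperature_K)

    partition = None
    boundary = config.boundary_coordinate
    if boundary is None and config.bound.synthetic is not None:
        pot = config.bound.synthetic.potential
        if pot.form != "flat":
            # pocket threshold proxy: two well-widths past the last well
            boundary = max(pot._centers()) + 2.0 * pot.width \
                - config.bound.synthetic.z0
    if boundary is not None and 0 < boundary <= cutoff:
        series = [accumulate_work(t, config.convention) for t in bound_set]
        part = stage("partition", partition_work, series, boundary, cutoff)
        partition = {
            "boundary_coordinate": part.boundary_coordinate,
            "total_distance": part.total_distance,
            "interior_fraction": part.interior_fraction,
            "interior_fraction_pct": 100.0 * part.interior_fraction,
            "interior_work": part.interior_work,
            "interior_work_se": part.interior_work_se,
        }

    histogram = None
    if sample_viscous is not None:
        hs = stage("histogram", work_histogram_summary, sample_bound,
                   sample_viscous, config.n_hist_bins)
        histogram = {
            "edges": hs.edges.tolist(),
            "counts_bound": hs.counts_bound.tolist(),
            "counts_viscous": hs.counts_viscous.tolist(),
            "mean_bound": hs.mean_bound, "sd_bound": hs.sd_bound,
            "mean_viscous": hs.mean_viscous, "sd_viscous": hs.sd_viscous,
            "standardized_mean_difference": hs.standardized_mean_difference,
            "overlap_coefficient": hs.overlap_coefficient,
        }

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "replica_seeds": {
            "bound": (config.bound.synthetic.seed
                      if config.bound.synthetic else None),
            "viscous": (config.viscous.synthetic.seed
                        if config.viscous and config.viscous.synthetic
                        else None),
        },
        "bootstrap_B": config.bootstrap_B,
        "convention": config.convention,
        "cutoff_policy": config.cutoff,
    }

    report = PipelineReport(
        bound_estimate=est_bound, viscous_estimate=est_viscous,
        corrected_estimate=corrected, crossing=crossing, cutoff=cutoff,
        ordering=ordering, analytic_delta_g=analytic_dg,
        experimental_delta_g_J=experimental_dg, partition=partition,
        histogram=histogram, profile_bound=profile_bound,
        profile_viscous=profile_viscous, unit_system=meta.unit_system,
        manifest=manifest)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        _profile_to_csv(profile_bound, outdir / "profile_bound.csv",
                        meta.unit_system)
        if profile_viscous is not None:
            _profile_to_csv(profile_viscous, outdir / "profile_viscous.csv",
                            meta.unit_system)
        np.savetxt(outdir / "works_bound.csv", sample_bound.works,
                   header=f"terminal work at cutoff {cutoff:g} "
                          f"({meta.unit_system} energy units)")
        if sample_viscous is not None:
            np.savetxt(outdir / "works_viscous.csv", sample_viscous.works,
                       header=f"terminal work at cutoff {cutoff:g} "
                              f"({meta.unit_system} energy units)")
        if export_trajectories:
            write_replica_set(bound_set, outdir / "bound_xvg")
            if viscous_set is not None:
                write_replica_set(viscous_set, outdir / "viscous_xvg")
        log.info("report written to %s", outdir)

    return report
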