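"""Force profiles, convergence crossing, partitions and histograms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import pullwork as pw
from pullwork.errors import ConvergenceError, GeometryError, ValidationError

from conftest import make_trajectory


def _const_force_traj(f, n=11, L=2.0):
    t = np.linspace(0.0, 1.0, n)
    z = L * t
    return make_trajectory(times=t, spring_end=z, position=z,
                           force=np.full(n, float(f)))


def _profile(centers, means, sds):
    return pw.ForceProfile(
        bin_centers=np.asarray(centers, dtype=float),
        mean_force_magnitude=np.asarray(means, dtype=float),
        sd_force=np.asarray(sds, dtype=float),
        n_per_bin=np.ones(len(centers), dtype=int))


class TestMeanForceProfile:
    def test_two_constant_replicas(self):
        # one sample per replica per bin: mean 4, SD sqrt(2) in every bin
        rs = pw.ReplicaSet(
            trajectories=[_const_force_traj(3.0), _const_force_traj(5.0)])
        # bin width below the grid spacing: each bin holds one sample per
        # replica, so the pooled pair is exactly {3, 5}
        prof = pw.mean_force_profile(rs, bin_width=0.19)
        assert np.allclose(prof.mean_force_magnitude, 4.0)
        assert np.allclose(prof.sd_force, np.sqrt(2.0))
        assert np.all(prof.n_per_bin >= 1)

    def test_single_replica_rejected(self):
        rs = pw.ReplicaSet(trajectories=[_const_force_traj(3.0)])
        with pytest.raises(ValidationError, match="2 replicas"):
            pw.mean_force_profile(rs, bin_width=0.2)

    def test_nonpositive_bin_width_rejected(self, bound_set):
        with pytest.raises(ValidationError):
            pw.mean_force_profile(bound_set, bin_width=0.0)

    def test_flat_region_mean_force_is_drag(self):
        # deterministic stiff-spring pulls: steady-state |F| = gamma*v
        cfg = pw.PullConfig(spring_k=100.0, temperature_T=0.0,
                            potential=pw.BindingPotential(form="flat"),
                            n_replicas=2)
        rs = pw.ReplicaSet(trajectories=pw.simulate_batch(cfg, [0, 1]))
        prof = pw.mean_force_profile(rs, bin_width=0.25)
        tail = prof.mean_force_magnitude[prof.bin_centers > 2.5]
        gv = cfg.drag_gamma * cfg.pull_rate_v
        assert np.all(np.abs(tail - gv) < 0.1 * gv)


class TestErrorbarCrossing:
    def test_constructed_linear_profiles(self):
        x = np.arange(0.0, 13.0)
        pa = _profile(x, 5.0 - 0.5 * x, np.full_like(x, 0.5))
        pb = _profile(x, np.ones_like(x), np.full_like(x, 0.5))
        crossing, cutoff = pw.errorbar_crossing(pa, pb, m_consecutive=1)
        assert (crossing, cutoff) == (6.0, 12.0)
        # a sustained-overlap requirement does not move the crossing here
        crossing3, cutoff3 = pw.errorbar_crossing(pa, pb, m_consecutive=3)
        assert (crossing3, cutoff3) == (6.0, 12.0)

    def test_identical_profiles_cross_at_first_bin(self):
        x = np.arange(0.0, 5.0)
        p = _profile(x, 2.0 + x, np.ones_like(x))
        crossing, _ = pw.errorbar_crossing(p, p)
        assert crossing == 0.0

    def test_disjoint_profiles_raise(self):
        x = np.arange(0.0, 5.0)
        pa = _profile(x, np.full_like(x, 10.0), np.full_like(x, 0.1))
        pb = _profile(x, np.ones_like(x), np.full_like(x, 0.1))
        with pytest.raises(ConvergenceError, match="longer pulls"):
            pw.errorbar_crossing(pa, pb)

    def test_initial_noise_overlap_is_skipped(self):
        # both profiles coincide in the unloaded transient, separate, then
        # converge: the crossing is where separation ends, not bin 0
        x = np.arange(0.0, 10.0)
        mean_a = np.array([1.0, 1.0, 5.0, 5.0, 5.0, 5.0, 1.2, 1.0, 1.0, 1.0])
        pa = _profile(x, mean_a, np.full_like(x, 0.5))
        pb = _profile(x, np.ones_like(x), np.full_like(x, 0.5))
        crossing, cutoff = pw.errorbar_crossing(pa, pb, m_consecutive=3)
        assert crossing == 6.0

    def test_rebinning_moves_crossing_at_most_one_bin(self):
        # smooth synthetic profiles evaluated at two bin widths
        def profiles(width):
            x = np.arange(width / 2, 12.0, width)
            pa = _profile(x, 6.0 - 0.5 * x, np.full_like(x, 0.4))
            pb = _profile(x, np.ones_like(x), np.full_like(x, 0.4))
            return pw.errorbar_crossing(pa, pb, m_consecutive=1)[0]
        c1 = profiles(1.0)
        c2 = profiles(0.5)
        assert abs(c1 - c2) <= 1.0

    def test_synthetic_default_crossing_inside_pull(self, bound_set,
                                                    viscous_set):
        pb = pw.mean_force_profile(bound_set, 0.05)
        pv = pw.mean_force_profile(viscous_set, 0.05)
        crossing, cutoff = pw.errorbar_crossing(pb, pv)
        assert 1.0 < crossing < 4.0
        assert cutoff == 2.0 * crossing


class TestPlaneCrossing:
    PLANE = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (-1.0, -1.0, 0.0))

    def test_path_through_plane(self):
        pos = [(0.0, 0.0, -1.0), (0.0, 0.0, -0.5), (0.0, 0.0, 0.5)]
        assert pw.plane_crossing_index(pos, *self.PLANE) == 2

    def test_exact_zero_lands_on_index(self):
        pos = [(0.0, 0.0, -1.0), (0.0, 0.0, 0.0), (0.0, 0.0, 0.5)]
        assert pw.plane_crossing_index(pos, *self.PLANE) == 1

    def test_no_crossing_returns_sentinel(self):
        pos = [(0.0, 0.0, -3.0), (0.0, 0.0, -2.0)]
        assert pw.plane_crossing_index(pos, *self.PLANE) is None

    def test_collinear_plane_points_rejected(self):
        with pytest.raises(GeometryError, match="collinear"):
            pw.plane_crossing_index([(0, 0, 0)], (0, 0, 0), (1, 1, 1),
                                    (2, 2, 2))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        # keep samples off the plane so the crossing index is insensitive
        # to rounding after rotation
        pos = np.column_stack([np.zeros(5), np.zeros(5),
                               np.linspace(-2.0, 2.0, 5) + 0.1])
        plane = np.asarray(self.PLANE, dtype=float)
        idx0 = pw.plane_crossing_index(pos, *plane)
        rot = Rotation.random(random_state=np.random.RandomState(
            seed % (2 ** 31))).as_matrix()
        shift = rng.normal(size=3)
        pos_r = pos @ rot.T + shift
        plane_r = plane @ rot.T + shift
        assert pw.plane_crossing_index(pos_r, *plane_r) == idx0


class TestPartition:
    def _series(self, total=5.0, slope=2.0):
        x = np.linspace(0.0, total, 51)
        return pw.WorkSeries(pull_coordinate=x, cumulative_work=slope * x)

    def test_reference_fraction(self):
        # boundary 1.47 of a 5-unit pull: interior region is 29.4%
        part = pw.partition_work([self._series(), self._series()], 1.47, 5.0)
        assert part.interior_fraction == pytest.approx(0.294, rel=1e-12)
        assert part.interior_work == pytest.approx(2.0 * 1.47, rel=1e-12)

    def test_boundary_at_total_gives_terminal_work(self):
        part = pw.partition_work([self._series()], 5.0, 5.0)
        assert part.interior_fraction == 1.0
        assert part.interior_work == pytest.approx(10.0)

    def test_zero_boundary(self):
        part = pw.partition_work([self._series()], 0.0, 5.0)
        assert part.interior_fraction == 0.0
        assert part.interior_work == 0.0

    def test_boundary_beyond_series_rejected(self):
        with pytest.raises(ValidationError):
            pw.partition_work([self._series(total=1.0)], 3.0, 5.0)

    def test_partition_consistency_with_terminal_work(self, bound_set):
        series = [pw.accumulate_work(t) for t in bound_set]
        part = pw.partition_work(series, 2.0, 5.0)
        exterior = np.mean([pw.work_at(s, 5.0) - pw.work_at(s, 2.0)
                            for s in series])
        terminal = np.mean([pw.work_at(s, 5.0) for s in series])
        assert part.interior_work + exterior == pytest.approx(terminal,
                                                              rel=1e-10)


class TestHistogram:
    def test_well_separated_gaussian_populations(self):
        rng = np.random.default_rng(2)
        sb = pw.WorkSample(works=rng.normal(10.0, 1.0, 30), temperature_T=1.0)
        sv = pw.WorkSample(works=rng.normal(2.0, 1.0, 30), temperature_T=1.0)
        summ = pw.work_histogram_summary(sb, sv, n_bins=15)
        assert summ.standardized_mean_difference == pytest.approx(8.0,
                                                                  abs=1.5)
        assert summ.overlap_coefficient < 0.01
        assert summ.counts_bound.sum() == 30
        assert summ.counts_viscous.sum() == 30

    def test_identical_samples_fully_overlap(self):
        s = pw.WorkSample(works=np.arange(10.0), temperature_T=1.0)
        summ = pw.work_histogram_summary(s, s, n_bins=5)
        assert summ.standardized_mean_difference == 0.0
        assert summ.overlap_coefficient == pytest.approx(1.0, rel=1e-6)

    def test_count_conservation(self, bound_set, viscous_set):
        sb = pw.collect_work_sample(bound_set, 5.0)
        sv = pw.collect_work_sample(viscous_set, 5.0)
        summ = pw.work_histogram_summary(sb, sv, n_bins=12)
        assert summ.counts_bound.sum() == sb.n
        assert summ.counts_viscous.sum() == sv.n

    def test_too_few_bins_rejected(self):
        s = pw.WorkSample(works=np.arange(4.0), temperature_T=1.0)
        with pytest.raises(ValidationError):
            pw.work_histogram_summary(s, s, n_bins=1)

    def test_gaussian_overlap_closed_form(self):
        # equal widths: OVL = 2*Phi(-|dmu|/2sigma)
        from scipy.stats import norm
        assert pw.gaussian_overlap(0.0, 1.0, 2.0, 1.0) == pytest.approx(
            2.0 * norm.cdf(-1.0), rel=1e-9)
        # unequal widths agree with quadrature route
        assert 0.0 < pw.gaussian_overlap(0.0, 1.0, 3.0, 2.0) < 1.0
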