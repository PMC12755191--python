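import numpy as np
import pytest

from pulsediv import (
    AllSpeciesExcludedError,
    TemperatureProfile,
    TrajectoryPair,
    filter_rare_species,
    run_pair,
    step,
    temperature_at,
)
from pulsediv.community import (
    Community,
    SpeciesParams,
    assemble_community,
    carrying_capacity,
)
from pulsediv.stability import stability_record


def single_species_community(bopt=22.0, **kwargs):
    sp = SpeciesParams(bopt=bopt, **kwargs)
    return Community((sp,), np.ones((1, 1)), 0.0, bopt, 0.0)


class TestTemperatureProfile:
    def test_pulse_window_boundaries(self):
        p = TemperatureProfile()
        assert temperature_at(p, 499, disturbed=True) == 22.0
        assert temperature_at(p, 500, disturbed=True) == 15.0
        assert temperature_at(p, 549, disturbed=True) == 15.0
        assert temperature_at(p, 550, disturbed=True) == 22.0

    def test_control_always_baseline(self):
        p = TemperatureProfile()
        assert all(temperature_at(p, t, disturbed=False) == 22.0 for t in (0, 500, 549, 750))

    def test_out_of_range_rejected(self):
        p = TemperatureProfile()
        with pytest.raises(ValueError):
            temperature_at(p, 751, disturbed=True)
        with pytest.raises(ValueError):
            temperature_at(p, -1, disturbed=False)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            TemperatureProfile(t_onset=0)
        with pytest.raises(ValueError):
            TemperatureProfile(t_onset=700, pulse_len=100, t_total=750)


class TestStep:
    def test_carrying_capacity_is_fixed_point(self):
        c = single_species_community(bopt=22.0)
        K = carrying_capacity(c.species[0], 22.0)
        out = step(c, np.array([K]), 22.0)
        assert out[0] == pytest.approx(K, rel=1e-12)

    def test_low_density_growth_factor(self):
        c = single_species_community(bopt=22.0)
        r = c.species[0].bmax - c.species[0].d0
        out = step(c, np.array([1e-12]), 22.0)
        assert out[0] / 1e-12 == pytest.approx(np.exp(r), rel=1e-9)

    def test_zero_abundance_is_absorbing(self):
        c = single_species_community()
        assert step(c, np.array([0.0]), 22.0)[0] == 0.0

    def test_negative_abundance_rejected(self):
        c = single_species_community()
        with pytest.raises(ValueError):
            step(c, np.array([-0.1]), 22.0)

    def test_no_interactions_equals_independent_logistics(self):
        """Two species with zero off-diagonals follow their own logistic maps."""
        sp1, sp2 = SpeciesParams(bopt=18.0), SpeciesParams(bopt=21.0)
        pair = Community((sp1, sp2), np.eye(2), 0.0, 19.5, 3.0)
        N = np.array([0.3, 0.6])
        for _ in range(50):
            N = step(pair, N, 22.0)
        for i, sp in enumerate((sp1, sp2)):
            solo = Community((sp,), np.ones((1, 1)), 0.0, sp.bopt, 0.0)
            n = np.array([[0.3, 0.6][i]])
            for _ in range(50):
                n = step(solo, n, 22.0)
            assert n[0] == pytest.approx(N[i], rel=1e-12)


class TestRunPair:
    def test_trajectories_identical_before_onset(self, short_profile):
        c = assemble_community(5, 19.0, 8.0, 0.25, seed=3)
        traj = run_pair(c, short_profile)
        onset = short_profile.t_onset
        assert np.array_equal(traj.N_control[:onset], traj.N_disturbed[:onset])
        assert not np.allclose(traj.N_control[onset + 1], traj.N_disturbed[onset + 1])

    def test_no_pulse_means_no_deviation(self):
        profile = TemperatureProfile(t_total=150, t_onset=100, pulse_len=0)
        c = assemble_community(5, 19.0, 8.0, 0.25, seed=3)
        traj = run_pair(c, profile)
        assert np.array_equal(traj.N_control, traj.N_disturbed)
        assert stability_record(traj).oev == 0.0

    def test_logistic_convergence_to_carrying_capacity(self):
        c = single_species_community(bopt=22.0)
        traj = run_pair(c)
        K = carrying_capacity(c.species[0], 22.0)
        assert traj.N_control[750, 0] == pytest.approx(K, abs=1e-6)

    def test_equilibration_by_pulse_onset_without_interactions(self):
        c = assemble_community(10, 19.0, 8.0, 0.0, seed=7)
        traj = run_pair(c)
        K = np.array([carrying_capacity(sp, 22.0) for sp in c.species])
        assert np.max(np.abs(traj.N_control[500] - K)) < 1e-4

    def test_run_pair_matches_repeated_step(self, short_profile):
        c = assemble_community(4, 19.0, 6.0, 0.25, seed=9)
        traj = run_pair(c, short_profile)
        N = traj.N_disturbed[0].copy()
        for t in range(short_profile.t_total):
            T = temperature_at(short_profile, t, disturbed=True)
            N = step(c, N, T)
        assert np.allclose(N, traj.N_disturbed[-1], rtol=1e-12)

    def test_bitwise_determinism(self, short_profile):
        c1 = assemble_community(6, 19.0, 8.0, 0.5, seed=21)
        c2 = assemble_community(6, 19.0, 8.0, 0.5, seed=21)
        t1, t2 = run_pair(c1, short_profile), run_pair(c2, short_profile)
        assert np.array_equal(t1.N_disturbed, t2.N_disturbed)

    @pytest.mark.parametrize("alpha_sd", [0.0, 0.25, 0.5])
    def test_abundances_stay_non_negative_and_finite(self, alpha_sd, short_profile):
        for seed in range(30):
            c = assemble_community(10, 19.0, 8.0, alpha_sd, seed=seed)
            traj = run_pair(c, short_profile)
            for m in (traj.N_control, traj.N_disturbed):
                assert np.all(m >= 0.0) and np.all(np.isfinite(m))

    def test_identical_species_stay_identical(self, short_profile):
        """Permutation equivariance: species with equal parameters and equal
        interaction rows remain equal over all time."""
        sp = SpeciesParams(bopt=20.0)
        alpha = np.full((3, 3), 0.4)
        np.fill_diagonal(alpha, 1.0)
        c = Community((sp, sp, sp), alpha, 0.4, 20.0, 0.0)
        traj = run_pair(c, short_profile)
        assert np.allclose(traj.N_disturbed, traj.N_disturbed[:, [1, 2, 0]])

    def test_nonpositive_initial_abundance_rejected(self, short_profile):
        c = assemble_community(3, 19.0, 2.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            run_pair(c, short_profile, N0=np.array([0.0, 0.1, 0.1]))


class TestRareSpeciesFilter:
    def _fake_traj(self, control, disturbed, profile):
        c = assemble_community(control.shape[1], 19.0, 0.0, 0.0, seed=0)
        times = np.arange(profile.t_total + 1)
        return TrajectoryPair(times, control, disturbed, c, profile)

    def test_threshold_and_count_boundaries(self):
        profile = TemperatureProfile(t_total=30, t_onset=10, pulse_len=5)
        n_t = profile.t_total + 1
        control = np.zeros((n_t, 3))
        control[:, 0] = 0.5  # always common -> included
        control[:, 1] = 1e-4  # always below threshold -> excluded
        # exactly 10 window entries above threshold -> included
        control[profile.t_onset : profile.t_onset + 10, 2] = 0.01
        traj = self._fake_traj(control, control.copy(), profile)
        mask = filter_rare_species(traj)
        assert mask.tolist() == [True, False, True]
        # one fewer entry -> excluded
        control[profile.t_onset + 9, 2] = 0.0
        traj = self._fake_traj(control, control.copy(), profile)
        assert filter_rare_species(traj).tolist() == [True, False, False]

    def test_union_counts_either_arm(self):
        profile = TemperatureProfile(t_total=30, t_onset=10, pulse_len=5)
        n_t = profile.t_total + 1
        control = np.zeros((n_t, 1))
        disturbed = np.zeros((n_t, 1))
        disturbed[profile.t_onset :, 0] = 0.02  # present only when disturbed
        traj = self._fake_traj(control, disturbed, profile)
        assert filter_rare_species(traj, series="union").tolist() == [True]
        with pytest.raises(AllSpeciesExcludedError):
            filter_rare_species(traj, series="control")

    def test_all_excluded_is_signalled(self):
        profile = TemperatureProfile(t_total=30, t_onset=10, pulse_len=5)
        zeros = np.zeros((profile.t_total + 1, 2))
        traj = self._fake_traj(zeros, zeros.copy(), profile)
        with pytest.raises(AllSpeciesExcludedError):
            filter_rare_species(traj)
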