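import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratssm.behavior import SwimTrial, cipl, day_means, learning_index

POOL = 0.9
PLAT = (0.3, 0.3)
PRAD = 0.06


def make_trial(t, x, y, release=None, platform=PLAT, **kw):
    return SwimTrial(
        subject_id="s", day=1, trial=1, t=np.asarray(t, float),
        x=np.asarray(x, float), y=np.asarray(y, float),
        platform_center=platform, platform_radius=PRAD,
        release_point=release if release is not None else (x[0], y[0]),
        pool_radius=POOL, **kw,
    )


def straight_trial(release, platform=PLAT, speed=0.25, n=60):
    d = np.hypot(release[0] - platform[0], release[1] - platform[1])
    travel = max(d - PRAD, 0.0)
    tt = np.linspace(0.0, travel / speed, n)
    frac = (tt * speed) / max(d, 1e-12)
    x = release[0] + frac * (platform[0] - release[0])
    y = release[1] + frac * (platform[1] - release[1])
    return make_trial(tt, x, y, release=release, platform=platform)


def semicircle_trial(n_samples=50, radius=0.35, speed=0.25):
    """Semicircular detour from release to platform at constant speed."""
    center = (PLAT[0], PLAT[1] - radius)    # arc center below the platform
    angles = np.linspace(np.pi / 2, -np.pi / 2, n_samples)  # half circle
    x = center[0] + radius * np.cos(angles)
    y = center[1] + radius * np.sin(angles)
    arc_len = np.pi * radius
    t = np.linspace(0.0, arc_len / speed, n_samples)
    return make_trial(t, x, y, release=(x[0], y[0]))


class TestCipl:
    def test_release_on_platform_edge_scores_zero(self):
        rel = (PLAT[0] + PRAD, PLAT[1])
        t = np.linspace(0, 2, 10)
        # drift along the platform edge: distance stays zero
        ang = np.linspace(0, 0.5, 10)
        x = PLAT[0] + PRAD * np.cos(ang)
        y = PLAT[1] + PRAD * np.sin(ang)
        assert cipl(make_trial(t, x, y, release=rel)) == pytest.approx(
            0.0, abs=1e-12)

    def test_straight_constant_speed_swim_scores_zero(self):
        trial = straight_trial(release=(-0.5, -0.5))
        assert cipl(trial) == pytest.approx(0.0, abs=1e-9)

    def test_semicircular_detour_matches_fine_grid_oracle(self):
        trial = semicircle_trial(n_samples=50)
        # oracle: same parametric path integrated on a 200k-point grid,
        # ideal term evaluated analytically
        fine = semicircle_trial(n_samples=200_000)
        d = fine.platform_distance()
        ipl_oracle = np.trapezoid(d, fine.t)
        speed = fine.path_length() / fine.duration()
        d0 = np.hypot(fine.release_point[0] - PLAT[0],
                      fine.release_point[1] - PLAT[1]) - PRAD
        ideal = d0**2 / (2 * speed)
        oracle = ipl_oracle - ideal
        assert cipl(trial) == pytest.approx(oracle, rel=0.01)

    @pytest.mark.parametrize("angle", [0.0, 0.7, np.pi / 2, 2.4])
    def test_rigid_rotation_invariance(self, angle):
        trial = semicircle_trial()
        c, s = np.cos(angle), np.sin(angle)
        rot = lambda x, y: (c * x - s * y, s * x + c * y)  # noqa: E731
        x2, y2 = rot(trial.x, trial.y)
        t2 = make_trial(trial.t, x2, y2, release=rot(*trial.release_point),
                        platform=rot(*PLAT))
        assert cipl(t2) == pytest.approx(cipl(trial), rel=1e-9)

    def test_deforming_path_toward_platform_never_increases_cipl(self):
        trial = semicircle_trial()
        prev = cipl(trial)
        for lam in (0.25, 0.5, 0.75):
            x = trial.x + lam * (PLAT[0] - trial.x)
            y = trial.y + lam * (PLAT[1] - trial.y)
            shrunk = make_trial(trial.t, x, y, release=(x[0], y[0]))
            cur = cipl(shrunk)
            assert cur <= prev + 1e-12
            prev = cur

    def test_time_rescaling_doubles_cipl_for_constant_speed_path(self):
        trial = semicircle_trial()
        slow = make_trial(2 * trial.t, trial.x, trial.y,
                          release=trial.release_point)
        assert cipl(slow) == pytest.approx(2 * cipl(trial), rel=1e-9)

    def test_stationary_rat_scores_zero_by_velocity_correction(self):
        # zero path length: the 0-speed ideal equals the actual integral
        t = np.linspace(0, 30, 20)
        x = np.full(20, -0.4)
        y = np.full(20, 0.0)
        assert cipl(make_trial(t, x, y)) == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            make_trial([0.0, 1.0, 1.0], [0, 0.1, 0.2], [0, 0, 0])

    def test_path_outside_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            make_trial([0.0, 1.0], [0.0, 1.5], [0.0, 0.0])


class TestLearningIndex:
    def test_no_learning_gives_zero(self):
        assert learning_index([12.0, 10.0, 11.0, 12.0]) == 0.0

    def test_thirty_to_ten_gives_half(self):
        assert learning_index([30.0, 20.0, 15.0, 10.0]) == pytest.approx(0.5)

    def test_perfect_final_day_gives_one(self):
        assert learning_index([8.0, 4.0, 1.0, 0.0]) == 1.0

    def test_undefined_when_both_days_zero(self):
        with pytest.raises(ValueError, match="day1 \\+ day4"):
            learning_index([0.0, 1.0, 1.0, 0.0])

    @given(st.floats(0.01, 100), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval_for_nonnegative_days(self, d1, d4):
        assert -1.0 <= learning_index([d1, 0, 0, d4]) <= 1.0


class TestDayMeans:
    def _trials(self, values, day=1):
        out = []
        for i, v in enumerate(values):
            # straight trial time-rescaled to produce CIPL exactly v is
            # fiddly; instead park the rat at a distance giving IPL = v
            tr = straight_trial(release=(-0.5, -0.5))
            out.append(tr)
        return out

    def test_six_known_trials_average(self, monkeypatch):
        import ratssm.behavior as bh
        trials = [straight_trial(release=(-0.5, -0.5)) for _ in range(6)]
        fake = iter([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        monkeypatch.setattr(bh, "cipl", lambda tr: next(fake))
        assert bh.day_means(trials, "s", n_days=1)[0] == pytest.approx(2.5)

    def test_identical_trials_mean_equals_single_cipl(self):
        trials = [semicircle_trial() for _ in range(4)]
        for tr in trials:
            tr.subject_id = "s"
        assert day_means(trials, "s", n_days=1)[0] == pytest.approx(
            cipl(trials[0]))

    def test_missing_day_yields_nan_with_warning(self):
        trials = [semicircle_trial()]
        trials[0].subject_id = "s"
        with pytest.warns(UserWarning, match="day 2"):
            means = day_means(trials, "s", n_days=2)
        assert np.isnan(means[1]) and not np.isnan(means[0])
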