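"""ITM/TACO binding-class classification and per-class mobility."""

import numpy as np
import pytest

from chromokin.binding import (
    EXCLUDED,
    LONG,
    SHORT,
    SPOT,
    BindingClassCounts,
    SchemeError,
    class_fractions,
    classify_itm,
    classify_track,
    taco_mobility,
)
from chromokin.schemes import continuous_scheme, itm_scheme, taco_scheme
from chromokin.synth import simulate_binding_tracks

from conftest import make_track

SCHEME = itm_scheme(repeats=20)
FRAME_T = SCHEME.frame_times()
RADIUS = 0.5


def _track_on_frames(frames, jitter=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    xy = np.tile([2.0, 2.0], (len(frames), 1))
    if jitter > 0:
        xy += rng.normal(0, jitter, xy.shape)
    return make_track(frames, xy)


class TestClassifyTrack:
    def test_single_detection_is_spot(self):
        assert classify_track(_track_on_frames([4]), SCHEME, RADIUS) == SPOT

    def test_two_long_dark_survivals_is_long(self):
        # ITM cycle: frame 0 (short dark) frame 1 (long dark) frame 2 ...
        # detections at frames 1, 3 and 3, 5 flank two long dark times
        assert classify_track(_track_on_frames([1, 3, 5]), SCHEME, RADIUS) == LONG

    def test_single_short_dark_survival_is_short(self):
        assert classify_track(_track_on_frames([0, 1]), SCHEME, RADIUS) == SHORT

    def test_single_long_dark_survival_is_excluded(self):
        assert classify_track(_track_on_frames([1, 3]), SCHEME, RADIUS) == EXCLUDED

    def test_unconfined_survival_not_counted(self):
        # detections flank the long dark but move far apart: not a survival
        track = make_track([1, 3], [(0.0, 0.0), (3.0, 0.0)])
        assert classify_track(track, SCHEME, RADIUS) == SPOT

    def test_scheme_without_two_dark_classes_rejected(self):
        with pytest.raises(SchemeError):
            classify_track(_track_on_frames([0, 1]), continuous_scheme(n_frames=10), RADIUS)

    def test_every_track_lands_in_exactly_one_class(self):
        tracks, _ = simulate_binding_tracks(
            SCHEME, 300, {"long": 0.3, "short": 0.3, "spot": 0.4}, seed=17
        )
        counts = classify_itm(tracks, SCHEME, RADIUS)
        assert counts.total == len(tracks)

    def test_invariant_to_track_id_relabeling(self):
        tracks, _ = simulate_binding_tracks(SCHEME, 50, {"long": 0.5, "spot": 0.5}, seed=3)
        relabeled = [make_track(t.frames, t.xy, track_id=999 - i) for i, t in enumerate(tracks)]
        a = classify_itm(tracks, SCHEME, RADIUS)
        b = classify_itm(relabeled, SCHEME, RADIUS)
        assert a == b


class TestClassFractions:
    def test_direct_arithmetic(self):
        fr = class_fractions(BindingClassCounts(n_long=5, n_short=15, n_spot=80))
        assert fr.long_fraction == pytest.approx(0.05)
        assert fr.short_fraction == pytest.approx(0.15)

    def test_no_long_tracks_gives_zero_fraction(self):
        fr = class_fractions(BindingClassCounts(n_long=0, n_short=3, n_spot=7))
        assert fr.long_fraction == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            class_fractions(BindingClassCounts())

    def test_movie_wise_mean_and_sd(self):
        movies = [
            BindingClassCounts(n_long=1, n_short=1, n_spot=8),
            BindingClassCounts(n_long=3, n_short=1, n_spot=6),
        ]
        fr = class_fractions(movies)
        assert fr.long_fraction == pytest.approx(0.2)
        assert fr.long_sd == pytest.approx(np.std([0.1, 0.3], ddof=1))

    def test_recovers_long_bound_proportion(self):
        # shield-like composition: 13% long-bound events
        tracks, labels = simulate_binding_tracks(
            SCHEME, 2000, {"long": 0.13, "short": 0.15, "spot": 0.72}, seed=5
        )
        fr = class_fractions(classify_itm(tracks, SCHEME, RADIUS))
        truth = labels.count("long") / len(labels)
        binomial_sd = np.sqrt(truth * (1 - truth) / len(labels))
        assert abs(fr.long_fraction - truth) < 3 * binomial_sd


class TestClassificationAccuracy:
    def test_perfect_on_noise_free_extreme_dwells(self):
        # dwells far above (long) or below (spot) the dark times
        tracks, labels = simulate_binding_tracks(
            SCHEME,
            400,
            {"long": 0.5, "spot": 0.5},
            seed=6,
            bound_diffusion=0.0,
            loc_error_sigma=0.0,
            max_start_frame=SCHEME.n_frames - 8,
        )
        predicted = [classify_track(t, SCHEME, RADIUS) for t in tracks]
        assert predicted == labels

    def test_exponential_dwells_match_enumerated_survival_probability(self):
        # analytic misclassification oracle: a binding event starting at
        # frame 0 with rate k is detected at frames {f : t_f < dwell}; the
        # class is a deterministic function of the number n of surviving
        # frames, so P(class) follows from the exponential dwell law
        k = 0.5
        classes_by_n = {}
        for n in range(1, SCHEME.n_frames + 1):
            track = _track_on_frames(list(range(n)))
            classes_by_n[n] = classify_track(track, SCHEME, RADIUS)
        p_n = {}
        for n in range(1, SCHEME.n_frames + 1):
            p_live_n = np.exp(-k * FRAME_T[n - 1])  # alive at frame n-1
            p_live_next = np.exp(-k * FRAME_T[n]) if n < SCHEME.n_frames else 0.0
            p_n[n] = p_live_n - p_live_next
        expected_long = sum(p for n, p in p_n.items() if classes_by_n[n] == LONG)
        tracks, _ = simulate_binding_tracks(
            SCHEME,
            4000,
            {"short": 1.0},
            seed=8,
            dwell_means={"short": 1.0 / k},
            bound_diffusion=0.0,
            loc_error_sigma=0.0,
            max_start_frame=0,
        )
        observed_long = np.mean([classify_track(t, SCHEME, RADIUS) == LONG for t in tracks])
        assert observed_long == pytest.approx(expected_long, abs=0.02)


class TestTacoMobility:
    DT = 0.0117

    def test_stationary_molecule_mean_jump_is_sigma_root_pi(self, rng):
        # localization noise sigma on both endpoints: jumps are Rayleigh
        # with scale sigma * sqrt(2), mean sigma * sqrt(pi)
        sigma = 0.03
        scheme = taco_scheme("long", repeats=2)
        tracks = []
        for i in range(300):
            xy = np.tile([1.0, 1.0], (12, 1)) + rng.normal(0, sigma, (12, 2))
            tracks.append(make_track(range(12), xy, track_id=i))
        mob = taco_mobility(tracks, scheme, "long", confinement_radius=RADIUS)
        assert mob.n_tracks == 300
        assert mob.mean == pytest.approx(sigma * np.sqrt(np.pi), rel=0.05)

    def test_diffusing_molecule_mean_jump_is_sqrt_pi_d_dt(self, rng):
        # Brownian steps with D over dt: Rayleigh mean sqrt(pi * D * dt)
        d = 0.5
        scheme = taco_scheme("short", repeats=2)
        step_sigma = np.sqrt(2 * d * self.DT)
        tracks = []
        for i in range(300):
            # burst frames are consecutive (dt apart); classification frames
            # add one short-dark interval at the start
            start = np.array([1.0, 1.0])
            steps = rng.normal(0, step_sigma, (10, 2))
            xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
            tracks.append(make_track(range(11), xy, track_id=i))
        mob = taco_mobility(tracks, scheme, "short", confinement_radius=5.0)
        assert mob.n_tracks == 300
        assert mob.mean == pytest.approx(np.sqrt(np.pi * d * self.DT), rel=0.05)

    def test_long_class_less_mobile_than_short_class(self, rng):
        # two-population input by construction
        long_scheme = taco_scheme("long", repeats=2)
        short_scheme = taco_scheme("short", repeats=2)
        long_tracks, short_tracks = [], []
        for i in range(100):
            xy = np.tile([1.0, 1.0], (12, 1)) + rng.normal(0, 0.02, (12, 2))
            long_tracks.append(make_track(range(12), xy, track_id=i))
            xy = np.tile([1.0, 1.0], (11, 1)) + rng.normal(0, 0.08, (11, 2))
            short_tracks.append(make_track(range(11), xy, track_id=i))
        mob_long = taco_mobility(long_tracks, long_scheme, "long", confinement_radius=RADIUS)
        mob_short = taco_mobility(short_tracks, short_scheme, "short", confinement_radius=RADIUS)
        assert mob_long.mean < mob_short.mean

    def test_track_with_gap_in_burst_skipped(self):
        scheme = taco_scheme("short", repeats=2)
        frames = [0, 1, 2, 4, 5, 6, 7, 8, 9, 10]  # frame 3 missing from burst
        track = make_track(frames, [(1.0, 1.0)] * len(frames))
        mob = taco_mobility([track], scheme, "short", confinement_radius=RADIUS)
        assert mob.n_tracks == 0
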