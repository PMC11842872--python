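"""Survival-time datasets and dissociation-rate spectrum inversion."""

import numpy as np
import pytest

from chromokin.schemes import Localization, Track
from chromokin.survival import (
    InversionError,
    RateSpectrum,
    default_grid,
    invert_spectrum,
    resample_spectrum,
    summarize_residence,
    survival_distribution,
    to_event_spectrum,
    to_state_spectrum,
)
from chromokin.synth import sample_dwell_times

P_LOSS = 0.0025


def observed_counts(spectrum, frame_cycle, dark, n, seed, p_loss=P_LOSS):
    """Detection counts per binding event under a time-lapse condition.

    The dwell covers floor(tau / cycle) + 1 detection opportunities; after
    each recorded detection the molecule is lost with probability p_loss.
    """
    rng = np.random.default_rng(seed)
    dwells = sample_dwell_times(spectrum, n, seed + 1)
    cycle = frame_cycle + dark
    n_bound = np.floor(dwells / cycle).astype(int) + 1
    g = rng.geometric(p_loss, size=n) if p_loss > 0 else np.full(n, np.iinfo(np.int32).max)
    return np.minimum(n_bound, g)


def two_condition_datasets(spectrum, n, seed, p_loss=P_LOSS):
    d1 = survival_distribution(
        observed_counts(spectrum, 0.5017, 0.0, n, seed), 0.5017, 0.0, p_loss=p_loss
    )
    d2 = survival_distribution(
        observed_counts(spectrum, 0.5017, 4.0136, n, seed + 100), 0.5017, 4.0136, p_loss=p_loss
    )
    return [d1, d2]


class TestSurvivalDistribution:
    def test_three_frame_track_survival_time(self):
        ds = survival_distribution(np.array([3]), frame_cycle=0.5017)
        assert ds.times == pytest.approx([1.0034])

    def test_two_frame_tracks_excluded(self):
        ds = survival_distribution(np.array([2, 2, 3]), frame_cycle=0.5017)
        assert ds.n_events == 1

    def test_unconfined_tracks_rejected(self):
        locs = [Localization(i, i * 0.5, 0.1 * i, 0.0) for i in range(5)]
        wandering = Track(id=0, localizations=locs)
        still = Track(
            id=1, localizations=[Localization(i, i * 0.5, 0.0, 0.0) for i in range(5)]
        )
        ds = survival_distribution([wandering, still], 0.5, confinement_radius=0.05)
        assert ds.n_events == 1

    def test_single_exponential_matches_discrete_survival_law(self):
        # frozen oracle: P(survival >= j*c | >= 2*c) = exp(-k (j-2) c)
        k, c, n = 0.05, 0.5017, 4000
        counts = observed_counts([(k, 1.0)], c, 0.0, n, seed=9, p_loss=0.0)
        ds = survival_distribution(counts, c, 0.0, p_loss=0.0)
        j = np.arange(2, 40)
        emp = (ds.times[:, None] >= j[None, :] * c - 1e-9).mean(axis=0)
        exact = np.exp(-k * (j - 2) * c)
        assert np.max(np.abs(emp - exact)) < 1.36 / np.sqrt(ds.n_events)


class TestInvertSpectrum:
    def test_noiseless_single_exponential_concentrates_at_truth(self):
        k = 0.01
        datasets = two_condition_datasets([(k, 1.0)], 20_000, seed=1)
        spec = invert_spectrum(datasets)
        near = (spec.rates > k / 1.5) & (spec.rates < k * 1.5)
        assert spec.amplitudes[near].sum() > 0.95

    def test_two_exponential_cluster_weights_recovered(self):
        spectrum = [(0.01, 0.3), (1.0, 0.7)]
        spec = invert_spectrum(two_condition_datasets(spectrum, 10_000, seed=2))
        slow = spec.amplitudes[spec.rates < 0.1].sum()
        assert slow == pytest.approx(0.3, abs=0.05)
        assert spec.amplitudes[spec.rates >= 0.1].sum() == pytest.approx(0.7, abs=0.05)

    def test_default_grid_spans_prescribed_decades(self):
        grid = default_grid()
        assert grid[0] == pytest.approx(1e-3)
        assert grid[-1] == pytest.approx(1e1)
        assert len(grid) == 200

    def test_single_condition_warns_about_identifiability(self):
        datasets = two_condition_datasets([(0.1, 1.0)], 500, seed=3)[:1]
        with pytest.warns(RuntimeWarning):
            invert_spectrum(datasets)

    def test_empty_input_raises(self):
        with pytest.raises(InversionError):
            invert_spectrum([])

    def test_residual_nonincreasing_on_nested_grids(self):
        # noiseless-ish input; nested grids (51 ⊂ 101 ⊂ 201 points) can only
        # enlarge the feasible set, so the NNLS residual cannot grow
        spectrum = [(0.02, 0.5), (0.7, 0.5)]
        datasets = two_condition_datasets(spectrum, 30_000, seed=4, p_loss=0.0)

        def residual(grid):
            spec = invert_spectrum(datasets, grid)
            total = 0.0
            for ds in datasets:
                t = np.unique(ds.times)[:60]
                emp = (ds.times[:, None] >= t[None, :] - 1e-9).mean(axis=0)
                basis = np.exp(-np.outer(t, spec.rates))
                t0 = np.exp(-ds.t_min * spec.rates)
                model = basis @ spec.amplitudes / (t0 @ spec.amplitudes)
                total += np.sum((model - emp) ** 2) / len(t)
            return total

        res = [residual(np.geomspace(1e-3, 1e1, n)) for n in (51, 101, 201)]
        assert res[1] <= res[0] + 1e-10
        assert res[2] <= res[1] + 1e-10

    def test_slow_rate_separated_from_bleaching(self):
        # identifiability: dark times differing ~9-fold decouple the 0.01/s
        # truth from the 0.0025-per-frame loss; residence error < 20%
        spectrum = [(0.01, 0.4), (0.8, 0.6)]
        spec = invert_spectrum(two_condition_datasets(spectrum, 10_000, seed=6))
        tau = summarize_residence(spec).tau_s
        assert abs(tau - 100.0) / 100.0 < 0.20


class TestSpectrumAlgebra:
    def test_event_to_state_example(self):
        spec = RateSpectrum(np.array([0.01, 1.0]), np.array([0.5, 0.5]), kind="event")
        state = to_state_spectrum(spec)
        assert state.amplitudes == pytest.approx([50 / 50.5, 0.5 / 50.5])

    def test_single_rate_is_fixed_point(self):
        spec = RateSpectrum(np.array([0.2]), np.array([1.0]), kind="event")
        assert to_state_spectrum(spec).amplitudes == pytest.approx([1.0])

    def test_state_event_round_trip_identity(self, rng):
        for _ in range(20):
            rates = np.sort(rng.uniform(1e-3, 10, size=6))
            amps = rng.dirichlet(np.ones(6))
            spec = RateSpectrum(rates, amps, kind="event")
            back = to_event_spectrum(to_state_spectrum(spec))
            assert back.amplitudes == pytest.approx(spec.amplitudes)


class TestSummarizeResidence:
    def test_all_mass_slow(self):
        spec = RateSpectrum(np.array([0.01]), np.array([1.0]), kind="event")
        summ = summarize_residence(spec)
        assert summ.tau_s == pytest.approx(100.0)
        assert summ.tau_u is None

    def test_threshold_defaults_to_point_one(self):
        spec = RateSpectrum(np.array([0.05, 0.5]), np.array([0.5, 0.5]), kind="event")
        summ = summarize_residence(spec)
        assert summ.threshold == 0.1
        assert summ.tau_s == pytest.approx(20.0)
        assert summ.tau_u == pytest.approx(2.0)

    def test_event_fraction_uses_event_amplitudes(self):
        spec = RateSpectrum(np.array([0.01, 1.0]), np.array([0.3, 0.7]), kind="event")
        assert summarize_residence(spec).event_fraction_s == pytest.approx(0.3)
        # state fraction re-weights by 1/k
        assert summarize_residence(spec).state_fraction_s == pytest.approx(30 / 30.7)


class TestResampleSpectrum:
    def test_full_fraction_duplicates_have_zero_sd(self):
        datasets = two_condition_datasets([(0.05, 1.0)], 500, seed=7)
        sd_event, sd_state = resample_spectrum(datasets, n_resamples=3, frac=1.0, seed=0)
        assert np.allclose(sd_event, 0, atol=1e-12) and np.allclose(sd_state, 0, atol=1e-12)

    def test_sd_shrinks_with_event_count(self):
        spectrum = [(0.01, 0.4), (1.0, 0.6)]
        small = two_condition_datasets(spectrum, 400, seed=8)
        large = two_condition_datasets(spectrum, 8000, seed=8)
        sd_small, _ = resample_spectrum(small, n_resamples=25, seed=1)
        sd_large, _ = resample_spectrum(large, n_resamples=25, seed=1)
        slow = default_grid() < 0.1
        assert sd_large[slow].sum() < sd_small[slow].sum()

    def test_defaults_are_500_resamples_of_80_percent(self):
        import inspect

        sig = inspect.signature(resample_spectrum)
        assert sig.parameters["n_resamples"].default == 500
        assert sig.parameters["frac"].default == 0.8
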