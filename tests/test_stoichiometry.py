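"""Step detection, stoichiometry MLE and binomial dose-response fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chancoupler import stoichiometry as stoich
from chancoupler import synthgen as sg


def _trace(values, frame_interval_s=0.1):
    return sg.BleachTrace(
        molecule_id=0, intensity=np.asarray(values, float), frame_interval_s=frame_interval_s
    )


class TestDetectSteps:
    def test_noiseless_two_step_staircase(self):
        tr = _trace([2.0] * 10 + [1.0] * 10 + [0.0] * 10)
        count, times = stoich.detect_steps(tr)
        assert count == 2
        assert times == [10 * 0.1, 20 * 0.1]

    def test_constant_trace_has_no_steps(self):
        assert stoich.detect_steps(_trace([1.0] * 20)) == (0, [])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stoich.detect_steps(_trace([1.0, np.nan, 0.0, 0.0]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            stoich.detect_steps(_trace([1.0, 0.0, 0.0]))

    def test_upward_steps_ignored(self):
        tr = _trace([1.0] * 10 + [2.0] * 10 + [0.0] * 10)
        count, _ = stoich.detect_steps(tr)
        assert count == 1  # only the downward 2 -> 0 step

    def test_recovers_true_counts_on_simulated_dimers(self, dimer_bleach_population):
        """>= 95% of detectable dimer traces yield the true step count."""
        detectable = [t for t in dimer_bleach_population if t.detectable]
        hits = [
            stoich.detect_steps(t)[0] == t.true_step_count for t in detectable
        ]
        assert np.mean(hits) >= 0.95

    def test_greedy_equals_exhaustive_on_noiseless_short_traces(self):
        """Oracle equivalence of the greedy search on <= 30-frame traces."""
        params = sg.BleachPopulationParams(
            n_molecules=150, n_frames=30, bleach_rate=1.0, noise_sd=0.0
        )
        traces = sg.simulate_bleach_population(params, seed=11)
        for tr in traces:
            if not tr.detectable:
                continue
            greedy = stoich._greedy_changepoints(tr.intensity)
            optimal = stoich.exhaustive_changepoints(tr.intensity, max_changepoints=8)
            assert greedy == optimal

    def test_count_agreement_with_exhaustive_under_noise(self):
        """Filtered step counts track the exhaustive-search oracle with noise."""
        params = sg.BleachPopulationParams(
            n_molecules=100, n_frames=30, bleach_rate=1.0, noise_sd=0.1
        )
        traces = sg.simulate_bleach_population(params, seed=11)

        def oracle_count(tr):
            y = tr.intensity
            cps = stoich.exhaustive_changepoints(y, max_changepoints=8)
            if not cps:
                return 0
            b = [0] + cps + [len(y)]
            means = [y[a:c].mean() for a, c in zip(b[:-1], b[1:])]
            drops = [
                means[i] - means[i + 1]
                for i in range(len(cps))
                if means[i] - means[i + 1] > 0
            ]
            if not drops:
                return 0
            unit = max(drops)
            for _ in range(10):
                kept = [d for d in drops if d >= 0.5 * unit]
                nu = float(np.median(kept))
                if nu == unit:
                    break
                unit = nu
            return len(kept)

        pairs = [
            (stoich.detect_steps(t)[0], oracle_count(t)) for t in traces if t.detectable
        ]
        assert np.mean([a == b for a, b in pairs]) >= 0.9


class TestStepHistogram:
    def test_basic_tally(self):
        h = stoich.step_histogram([2, 2, 1])
        assert h.counts == {1: 1, 2: 2}
        assert h.n_undetected == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stoich.step_histogram([])

    def test_zeros_go_to_undetected(self):
        h = stoich.step_histogram([0, 0, 1, 2])
        assert h.n_undetected == 2
        assert h.n_detected == 2

    def test_large_dimer_population_tally(self):
        """True step counts of 1e5 dimers at p=0.7: ~42k ones, ~49k twos, ~9k dark."""
        params = sg.BleachPopulationParams(p_active=0.7, n_molecules=100_000, n_frames=2)
        traces = sg.simulate_bleach_population(params, seed=42)
        h = stoich.step_histogram([t.true_step_count for t in traces])
        assert h.counts[1] == pytest.approx(42_000, abs=1500)
        assert h.counts[2] == pytest.approx(49_000, abs=1500)
        assert h.n_undetected == pytest.approx(9_000, abs=1000)


class TestFitSubunitCount:
    def test_conditional_pmf_normalizes(self):
        for n in (1, 2, 3, 4, 6):
            for p in (0.3, 0.7, 1.0):
                assert sum(stoich.conditional_step_pmf(n, p).values()) == pytest.approx(1.0)

    def test_enumerated_dimer_distribution_gives_two(self):
        # 462:538 is the conditional dimer distribution at p=0.7
        fit = stoich.fit_subunit_count(
            stoich.StepCountHistogram({1: 462, 2: 538}), p_active=0.7
        )
        assert fit.n_hat == 2

    def test_full_maturation_single_steps_give_monomer(self):
        fit = stoich.fit_subunit_count(stoich.StepCountHistogram({1: 1000}), p_active=1.0)
        assert fit.n_hat == 1

    def test_recovers_tetramer_from_sampled_counts(self):
        rng = np.random.default_rng(12)
        ks = rng.binomial(4, 0.7, size=10_000)
        hist = stoich.step_histogram([int(k) for k in ks])
        fit = stoich.fit_subunit_count(hist, p_active=0.7, n_max=6)
        assert fit.n_hat == 4

    @pytest.mark.parametrize("true_n", [1, 2, 3, 4])
    def test_mle_consistency_with_population_size(self, true_n):
        """Recovery rate grows toward 1 as the molecule count grows."""
        rng = np.random.default_rng(100 + true_n)
        rates = []
        for n_mol in (100, 1000, 10_000):
            hits = 0
            for _ in range(20):
                ks = rng.binomial(true_n, 0.7, size=n_mol)
                ks = ks[ks > 0]
                hist = stoich.step_histogram([int(k) for k in ks])
                hits += stoich.fit_subunit_count(hist, p_active=0.7, n_max=6).n_hat == true_n
            rates.append(hits / 20)
        assert rates[-1] == 1.0
        assert rates[-1] >= rates[0]

    def test_observed_exceeding_n_max_rejected(self):
        with pytest.raises(ValueError):
            stoich.fit_subunit_count(stoich.StepCountHistogram({5: 10}), n_max=4)


class TestBleachTimeStats:
    def test_closed_form_means_for_two_fluorophore_molecules(self):
        """First step ~ min of two exponentials (mean 1/2kb); total ~ 3/(2kb)."""
        kb = 0.4
        rng = np.random.default_rng(8)
        two_step = []
        for _ in range(20_000):
            t = np.sort(rng.exponential(1 / kb, size=2))
            two_step.append((list(t), 2))
        one_step = [([float(rng.exponential(1 / kb))], 1) for _ in range(20_000)]
        mean_first, mean_total, mean_one = stoich.bleach_time_stats(two_step + one_step)
        assert mean_first == pytest.approx(1 / (2 * kb), rel=0.05)
        assert mean_total == pytest.approx(3 / (2 * kb), rel=0.05)
        assert mean_one == pytest.approx(1 / kb, rel=0.05)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            stoich.bleach_time_stats([([1.0, 2.0], 2)])


class TestBinomialTheoretical:
    @pytest.mark.parametrize(
        "x,n,expected", [(0.0, 2, 1.0), (1.0, 3, 0.0), (0.5, 2, 0.25), (0.5, 3, 0.125)]
    )
    def test_printed_formula_values(self, x, n, expected):
        assert stoich.binomial_theoretical(x, n) == pytest.approx(expected)

    @given(x=st.floats(min_value=0, max_value=1))
    @settings(deadline=None, max_examples=50)
    def test_nesting_order(self, x):
        """(1-x)^3 <= (1-x)^2 <= (1-x) on [0, 1]."""
        y1 = stoich.binomial_theoretical(x, 1)
        y2 = stoich.binomial_theoretical(x, 2)
        y3 = stoich.binomial_theoretical(x, 3)
        assert y3 <= y2 + 1e-12 and y2 <= y1 + 1e-12


class TestNormalizeDoseResponse:
    def test_scaling(self):
        dr = stoich.normalize_dose_response([(0.0, 100.0, 0.0), (0.5, 25.0, 5.0)])
        assert dr.y[dr.x == 0.5][0] == pytest.approx(0.25)
        assert dr.sem[dr.x == 0.5][0] == pytest.approx(0.05)

    def test_reference_replicates_averaged(self):
        dr = stoich.normalize_dose_response(
            [(0.0, 90.0, 0.0), (0.0, 110.0, 0.0), (0.5, 50.0, 0.0)]
        )
        assert dr.y[dr.x == 0.0][0] == pytest.approx(1.0)
        assert dr.y[dr.x == 0.5][0] == pytest.approx(0.5)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            stoich.normalize_dose_response([(0.5, 25.0, 5.0)])


FIG_RATIOS = [0, 1 / 11, 1 / 5, 1 / 2, 4 / 5, 10 / 11, 1]


class TestFitBinomialExponent:
    def test_exact_dimer_data(self):
        dr = sg.simulate_dose_response(n=2, ratios=FIG_RATIOS, noise_sd=0.0, seed=0)
        fit = stoich.fit_binomial_exponent(dr)
        assert fit.n_best == 2
        assert fit.rss[2] == pytest.approx(0.0, abs=1e-20)
        assert fit.n_continuous == pytest.approx(2.0, abs=1e-3)

    def test_exact_linear_data_gives_monomer(self):
        dr = sg.simulate_dose_response(n=1, ratios=FIG_RATIOS, noise_sd=0.0, seed=0)
        assert stoich.fit_binomial_exponent(dr).n_best == 1

    def test_exact_trimer_data(self):
        dr = sg.simulate_dose_response(n=3, ratios=FIG_RATIOS, noise_sd=0.0, seed=0)
        assert stoich.fit_binomial_exponent(dr).n_best == 3

    def test_degenerate_response_rejected(self):
        dr = stoich.DoseResponse(
            x=np.array([0.0, 0.5, 1.0]), y=np.ones(3), sem=np.zeros(3)
        )
        with pytest.raises(ValueError, match="degenerate"):
            stoich.fit_binomial_exponent(dr)

    def test_scale_free(self):
        """Multiplying raw currents and reference by a constant changes nothing."""
        raw = [(x, 80.0 * (1 - x) ** 2 + (0.01 if 0 < x < 1 else 0), 4.0) for x in FIG_RATIOS]
        scaled = [(x, 7.5 * y, 7.5 * s) for x, y, s in raw]
        fit_a = stoich.fit_binomial_exponent(stoich.normalize_dose_response(raw))
        fit_b = stoich.fit_binomial_exponent(stoich.normalize_dose_response(scaled))
        assert fit_a.n_best == fit_b.n_best
        for n in (1, 2, 3):
            assert fit_a.rss[n] == pytest.approx(fit_b.rss[n], rel=1e-9)
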