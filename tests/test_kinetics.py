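"""Tracer-strategy enrichment, pool-chain simulation and curve fitting."""

import itertools

import numpy as np
import pytest

from mrmtrace.kinetics import (
    PoolChainModel,
    Strategy,
    StrategySpec,
    compare_moieties,
    fit_labeling_curve,
    precursor_enrichment,
    simulate_chain,
    simulate_multi_input,
)


class TestPrecursorEnrichment:
    def test_conditioning_half_and_half(self):
        s = StrategySpec(Strategy.CONDITIONING, labeled=0.5, unlabeled_medium=0.5)
        assert precursor_enrichment(s) == pytest.approx(0.5)

    def test_medium_swap_no_internal_pool(self):
        s = StrategySpec(Strategy.MEDIUM_SWAP, labeled=1.0)
        assert precursor_enrichment(s) == 1.0

    def test_spike_in_dilution(self):
        s = StrategySpec(
            Strategy.SPIKE_IN, labeled=1.0, unlabeled_medium=1.0, unlabeled_internal=1.0
        )
        assert precursor_enrichment(s) == pytest.approx(1 / 3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            precursor_enrichment(StrategySpec(Strategy.SPIKE_IN, labeled=0.0))

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            StrategySpec(Strategy.SPIKE_IN, labeled=-1.0)


class TestSimulateChain:
    times = np.linspace(0, 10, 60)

    def test_single_pool_matches_closed_form(self):
        F, P, A = 2.0, 4.0, 0.5
        model = PoolChainModel((P,), F, input_enrichment=A)
        traj = simulate_chain(model, self.times)[0]
        closed = A * (1 - np.exp(-(F / P) * self.times))
        assert np.allclose(traj, closed, atol=1e-6)

    def test_zero_input_stays_zero(self):
        model = PoolChainModel((1.0, 2.0), 1.0, input_enrichment=0.0)
        assert np.allclose(simulate_chain(model, self.times), 0.0, atol=1e-12)

    def test_higher_flux_labels_faster(self):
        def half_time(flux):
            model = PoolChainModel((2.0,), flux, input_enrichment=0.5)
            t = np.linspace(0, 50, 2000)
            traj = simulate_chain(model, t)[0]
            return t[np.searchsorted(traj, 0.25)]

        assert half_time(10.0) < half_time(1.0)

    def test_bounded_by_plateau_and_monotone(self):
        model = PoolChainModel((1.0, 3.0, 2.0), 1.5, input_enrichment=0.5)
        traj = simulate_chain(model, self.times)
        assert np.all(traj <= 0.5 + 1e-9)
        assert np.all(traj >= -1e-12)
        assert np.all(np.diff(traj, axis=1) >= -1e-9)  # h=1 linear chain

    def test_added_pool_increases_terminal_half_time(self):
        t = np.linspace(0, 100, 4000)

        def terminal_half_time(n_pools):
            model = PoolChainModel((2.0,) * n_pools, 1.0, input_enrichment=1.0)
            traj = simulate_chain(model, t)[-1]
            return t[np.searchsorted(traj, 0.5)]

        hts = [terminal_half_time(n) for n in (1, 2, 3)]
        assert hts[0] < hts[1] < hts[2]

    def test_steady_state_equals_input_enrichment(self):
        model = PoolChainModel((0.5, 0.8), 4.0, input_enrichment=0.5)
        traj = simulate_chain(model, np.linspace(0, 200, 50))
        assert np.allclose(traj[:, -1], 0.5, atol=1e-6)

    def test_cyclic_recycle_slows_early_labeling(self):
        t = np.linspace(0, 5, 50)
        lin = PoolChainModel((1.0, 1.0), 1.0, input_enrichment=1.0)
        cyc = PoolChainModel(
            (1.0, 1.0), 1.0, topology="cyclic", recycle_fraction=0.5,
            input_enrichment=1.0,
        )
        l1 = simulate_chain(lin, t)[0]
        c1 = simulate_chain(cyc, t)[0]
        assert c1[1:].max() <= l1[1:].max() + 1e-9
        assert c1[10] < l1[10]

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            PoolChainModel((0.0,), 1.0)
        with pytest.raises(ValueError):
            PoolChainModel((1.0,), 1.0, topology="branched")


class TestMultiInput:
    def test_product_of_moiety_fractions(self):
        out = simulate_multi_input(
            [np.array([0.5]), np.array([0.5])], atom_counts=[1, 1]
        )
        assert out["fully_labeled"][0] == pytest.approx(0.25)

    def test_unlabeled_moiety_blocks_full_labeling(self):
        out = simulate_multi_input(
            [np.zeros(5), np.linspace(0, 1, 5)], atom_counts=[3, 2]
        )
        assert np.allclose(out["fully_labeled"], 0.0)

    def test_convolution_matches_exhaustive_enumeration(self):
        """Brute force over all joint atom-labeling states (<= 10 atoms)."""
        p = [0.3, 0.7]
        counts = [4, 3]
        out = simulate_multi_input([np.array([pi]) for pi in p], counts)
        dist = out["distribution"][0]
        n_total = sum(counts)
        brute = np.zeros(n_total + 1)
        atom_p = [p[0]] * counts[0] + [p[1]] * counts[1]
        for states in itertools.product([0, 1], repeat=n_total):
            prob = 1.0
            for s, pi in zip(states, atom_p):
                prob *= pi if s else (1 - pi)
            brute[sum(states)] += prob
        assert np.allclose(dist, brute, atol=1e-12)
        assert dist.sum() == pytest.approx(1.0)

    def test_composition_exceeding_analyte_rejected(self):
        with pytest.raises(ValueError):
            simulate_multi_input(
                [np.array([0.5])] * 2, atom_counts=[6, 6], total_atoms=10
            )


class TestFitLabelingCurve:
    def test_exponential_recovery_noise_free(self):
        t = np.linspace(0, 20, 30)
        y = 0.5 * (1 - np.exp(-0.3 * t))
        fit = fit_labeling_curve(t, y, model="exponential")
        assert fit.converged
        assert fit.plateau == pytest.approx(0.5, abs=1e-4)
        assert fit.rate == pytest.approx(0.3, abs=1e-4)
        assert fit.half_time == pytest.approx(np.log(2) / 0.3, rel=1e-3)

    def test_constant_zero_is_degenerate(self):
        fit = fit_labeling_curve([0, 1, 2, 3, 4], [0, 0, 0, 0, 0])
        assert fit.degenerate
        assert fit.plateau == 0.0

    def test_lagged_model_self_recovery(self):
        from mrmtrace.kinetics import _lagged_model

        t = np.linspace(0, 30, 40)
        y = _lagged_model(t, 0.5, 0.8, 0.25)
        fit = fit_labeling_curve(t, y, model="lagged")
        assert fit.plateau == pytest.approx(0.5, abs=1e-3)
        assert sorted([fit.rate, fit.shape]) == pytest.approx(
            [0.25, 0.8], rel=0.01
        )

    def test_sigmoidal_model_self_recovery(self):
        t = np.linspace(0, 30, 40)
        y = 0.6 * t**2 / (5.0**2 + t**2)
        fit = fit_labeling_curve(t, y, model="sigmoidal")
        assert fit.plateau == pytest.approx(0.6, abs=1e-3)
        assert fit.half_time == pytest.approx(5.0, rel=0.01)
        assert fit.shape == pytest.approx(2.0, rel=0.01)

    def test_rate_recovery_under_noise(self):
        """Median relative rate error <= 15% at 5% noise over 50 replicates."""
        rng = np.random.default_rng(42)
        t = np.linspace(0, 15, 12)
        errors = []
        for _ in range(50):
            y = 0.5 * (1 - np.exp(-0.3 * t)) + rng.normal(0, 0.05 * 0.5, t.size)
            fit = fit_labeling_curve(t, np.clip(y, 0, 1), model="exponential")
            errors.append(abs(fit.rate - 0.3) / 0.3)
        assert np.median(errors) <= 0.15

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_labeling_curve([0, 1, 2], [0, 0.1, 0.2])

    def test_fractions_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_labeling_curve([0, 1, 2, 3], [0, 0.5, 1.2, 1.0])


class TestCompareMoieties:
    t = np.linspace(0, 20, 15)

    def _fit(self, rate, plateau=0.5):
        y = plateau * (1 - np.exp(-rate * self.t))
        return fit_labeling_curve(self.t, y)

    def test_fivefold_rate_ratio(self):
        report = compare_moieties(self._fit(1.0), self._fit(0.2))
        assert report.rate_ratio == pytest.approx(5.0, rel=1e-3)
        assert report.half_time_ratio == pytest.approx(5.0, rel=1e-3)
        assert report.faster == "first"

    def test_identical_fits_give_unit_ratio(self):
        report = compare_moieties(self._fit(0.5), self._fit(0.5))
        assert report.rate_ratio == pytest.approx(1.0, rel=1e-6)

    def test_degenerate_fit_rejected(self):
        zero = fit_labeling_curve([0, 1, 2, 3, 4], [0] * 5)
        with pytest.raises(ValueError):
            compare_moieties(self._fit(0.5), zero)

    def test_bootstrap_interval_covers_true_ratio(self):
        """Seeded coverage check: the 95% bootstrap interval on the rate
        ratio contains the true value in >= 90% of noisy replicates."""
        rng = np.random.default_rng(7)
        true_ratio = 1.0 / 0.25
        covered = n_ok = 0
        for rep in range(25):
            ya = np.clip(
                0.5 * (1 - np.exp(-1.0 * self.t)) + rng.normal(0, 0.02, self.t.size),
                0, 1,
            )
            yb = np.clip(
                0.5 * (1 - np.exp(-0.25 * self.t)) + rng.normal(0, 0.02, self.t.size),
                0, 1,
            )
            fa = fit_labeling_curve(self.t, ya)
            fb = fit_labeling_curve(self.t, yb)
            report = compare_moieties(
                fa, fb, (self.t, ya), (self.t, yb), n_boot=80, seed=rep
            )
            if report.rate_ratio_ci is None:
                continue
            n_ok += 1
            lo, hi = report.rate_ratio_ci
            if lo <= true_ratio <= hi:
                covered += 1
        assert n_ok >= 20
        assert covered / n_ok >= 0.9
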