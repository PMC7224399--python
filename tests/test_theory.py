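"""Analytic tethered-polymer references, run-length laws, stiffness estimators."""

import numpy as np
import pytest
from scipy.integrate import quad

from diabodysim.fixtures import ideal_tethered_chain, two_state_chain
from diabodysim.theory import (
    GaussianChainModel,
    fit_effective_Nk,
    persistence_length,
    run_length_distribution,
    sample_wlc_chain,
    tail_constants_theory,
    tethered_end_pdf,
    threshold_probabilities,
)


class TestTetheredEndPdf:
    @pytest.mark.parametrize("nk, b, zt", [(50, 3, 7.5), (10, 1, 2.0), (200, 3, 0.5)])
    def test_normalized_and_zero_at_wall(self, nk, b, zt):
        model = GaussianChainModel(nk, b, zt)
        assert tethered_end_pdf(np.array([0.0]), model)[0] == pytest.approx(0.0)
        total, _ = quad(lambda z: float(tethered_end_pdf(z, model)), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_wall_limit_normalization(self):
        model = GaussianChainModel(30, 3, 0.0)
        total, _ = quad(lambda z: float(tethered_end_pdf(z, model)), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_wall_form_mode(self):
        # mode of (3z/<d^2>) exp(-3z^2/2<d^2>) sits at sqrt(<d^2>/3)
        model = GaussianChainModel(27, 1.0, 0.0)
        z = np.linspace(0.01, 20, 20_000)
        mode = z[np.argmax(tethered_end_pdf(z, model))]
        assert mode == pytest.approx(np.sqrt(27 / 3), abs=1e-2)

    def test_reduces_to_wall_form_as_zt_vanishes(self):
        d2 = 90.0
        near = GaussianChainModel(10, 3.0, 1e-4)
        wall = GaussianChainModel(10, 3.0, 0.0)
        z = np.linspace(0.5, 25, 200)
        rel = tethered_end_pdf(z, near) / tethered_end_pdf(z, wall) - 1.0
        assert np.max(np.abs(rel)) < 1e-3

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            tethered_end_pdf(np.array([-0.1]), GaussianChainModel(10, 3))


class TestThresholdProbabilities:
    def test_zero_threshold(self):
        p = threshold_probabilities(0.0, GaussianChainModel(10, 3))
        assert p.p_above == 1.0

    def test_unit_exponent_point(self):
        # z0^2 = 2 <d^2> / 3 makes the exponent exactly -1
        model = GaussianChainModel(6, 1.0)  # <d^2> = 6
        p = threshold_probabilities(2.0, model)
        assert p.p_above == pytest.approx(np.exp(-1))
        assert p.p_above + p.p_below == pytest.approx(1.0)

    def test_empirical_branch_matches_analytic(self):
        model = GaussianChainModel(50, 3.0)
        z = ideal_tethered_chain(50, 3.0, 0.0, 200_000, seed=4)
        density, edges = np.histogram(z, bins=200, density=True)
        z0 = 10.0
        emp = threshold_probabilities(z0, histogram=(density, edges))
        ana = threshold_probabilities(z0, model)
        # binomial MC error on 2e5 samples
        assert emp.p_above == pytest.approx(ana.p_above, abs=0.01)

    def test_invalid(self):
        with pytest.raises(ValueError):
            threshold_probabilities(-1.0, GaussianChainModel(10, 3))
        with pytest.raises(ValueError):
            threshold_probabilities(1.0)


class TestRunLengths:
    def test_geometric_ratio(self):
        k = np.arange(1, 10)
        pa, _ = run_length_distribution(0.8, 0.2, k)
        np.testing.assert_allclose(pa[1:] / pa[:-1], 0.8)

    def test_brute_force_enumeration(self):
        # exact: sum over all 2^m binary frame sequences of an iid process
        p_above, p_below = 0.65, 0.35
        m = 10
        for k in (1, 2, 4):
            prob = 0.0
            for word in range(2**m):
                bits = [(word >> i) & 1 for i in range(m)]
                if all(bits[i] for i in range(k)) and not bits[k]:
                    w = 1.0
                    for bit in bits:
                        w *= p_above if bit else p_below
                    prob += w
            pa, _ = run_length_distribution(p_above, p_below, k)
            assert prob == pytest.approx(float(pa), rel=1e-12)

    def test_two_state_chain_empirical(self):
        frames = two_state_chain(p_below=0.3, n=400_000, seed=8)
        # empirical probability of (k frames above, then below) at a random t
        for k in (1, 2, 3, 5):
            pat = np.ones(len(frames) - k, dtype=bool)
            for i in range(k):
                pat &= frames[i : len(frames) - k + i]
            pat &= ~frames[k:]
            emp = pat.mean()
            pa, _ = run_length_distribution(0.7, 0.3, k)
            assert emp == pytest.approx(float(pa), abs=3e-3)

    def test_concentration_and_approximation(self):
        # P_< -> 1 concentrates the above-runs at k = 1 (ratio 1/(1-P_<))
        pa, _ = run_length_distribution(0.01, 0.99, np.arange(1, 6))
        assert pa[0] >= 99 * pa[1]
        k = np.arange(1, 30)
        exact_a, _ = run_length_distribution(0.98, 0.02, k)
        approx_a, _ = run_length_distribution(0.98, 0.02, k, approximate=True)
        np.testing.assert_allclose(exact_a, approx_a, rtol=0.1)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            run_length_distribution(0.5, 0.5, 0)


class TestTailConstants:
    def test_worked_values(self):
        # 3 z0^2 / (2 <d^2>) = 0.15 with dt_c = 1
        tc = tail_constants_theory(z0=1.0, d2=10.0, dt_c=1.0)
        assert tc.tau_flight == pytest.approx(7.179, abs=1e-3)
        assert tc.tau_flight_expanded == pytest.approx(20 / 3, abs=1e-3)
        assert tc.tau_residence == pytest.approx(np.exp(0.15), abs=1e-4)
        assert tc.expansion_valid

    def test_flight_tail_linear_in_chain_size(self):
        # tau_f grows linearly with <d^2> (hence with N) at fixed z0
        taus = [tail_constants_theory(1.0, d2, 1.0).tau_flight for d2 in (200.0, 400.0)]
        assert taus[1] / taus[0] == pytest.approx(2.0, abs=0.01)

    def test_closes_loop_with_event_statistics(self):
        # synthetic uncorrelated frame process with known P_<: the fitted
        # exponential tail of the flight survival matches dt_c / P_<
        from diabodysim.kinetics import EventConfig, decompose_events, fit_exponential_tail, survival_curve

        p_below = 0.05
        frames = two_state_chain(p_below=p_below, n=400_000, seed=2)
        z = np.where(frames, 5.0, 1.0)
        ev = decompose_events(z, EventConfig(z0=3.5, min_duration=0.0, frame_interval=1.0))
        s = survival_curve(ev, "flight")
        fit = fit_exponential_tail(s, t_min=5.0)
        assert fit.value == pytest.approx(1.0 / p_below, rel=0.1)


class TestPersistenceLength:
    def test_unbiased_on_direct_wlc_samples(self):
        conf = sample_wlc_chain(60, 700, bend_k=1.8, style="cosine", seed=1)
        fit = persistence_length(conf)
        # coth(k) - 1/k deflection average gives 1.445 sigma at k = 1.8
        assert fit.persistence_length == pytest.approx(1.445, abs=0.12)
        assert fit.kuhn_length == pytest.approx(2 * fit.persistence_length)

    def test_freely_jointed_loses_correlation(self):
        conf = sample_wlc_chain(60, 400, bend_k=0.0, seed=2)
        fit = persistence_length(conf)
        assert fit.persistence_length < 1.0
        assert abs(fit.correlations[1]) < 0.05  # ~zero beyond the first bond

    def test_stiffness_ordering(self):
        soft = persistence_length(sample_wlc_chain(60, 300, bend_k=1.8, seed=3))
        stiff = persistence_length(sample_wlc_chain(60, 300, bend_k=10.0, seed=3))
        assert stiff.persistence_length > soft.persistence_length

    def test_rigid_rod_warns_with_lower_bound(self):
        t = np.linspace(0, 1, 31)
        straight = np.zeros((4, 31, 3))
        straight[:, :, 2] = t * 30
        fit = persistence_length(straight)
        assert fit.warning is not None
        assert fit.persistence_length >= 15.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            persistence_length(np.zeros((5, 2, 3)))


class TestEffectiveFit:
    def test_self_consistency_on_exact_samples(self):
        z = ideal_tethered_chain(50.0, 3.0, 7.5, 300_000, seed=6)
        density, edges = np.histogram(z, bins=80, density=True)
        fit = fit_effective_Nk(density, edges, b=3.0, z_t=7.5, linker_length=40)
        assert fit.n_kuhn_eff == pytest.approx(50.0, rel=0.05)
        # naive contour guess (N + 2r)/b with r = 5.65
        assert fit.naive_guess == pytest.approx((40 + 11.3) / 3.0)

    def test_wall_form_variant(self):
        z = ideal_tethered_chain(30.0, 3.0, 0.0, 200_000, seed=7)
        density, edges = np.histogram(z, bins=80, density=True)
        fit = fit_effective_Nk(density, edges, b=3.0, z_t=0.0, use_reflected=False)
        assert fit.n_kuhn_eff == pytest.approx(30.0, rel=0.05)

    def test_renormalizes_with_warning(self):
        z = ideal_tethered_chain(50.0, 3.0, 7.5, 50_000, seed=8)
        density, edges = np.histogram(z, bins=60, density=True)
        with pytest.warns(UserWarning):
            fit = fit_effective_Nk(3.0 * density, edges, b=3.0, z_t=7.5)
        assert fit.n_kuhn_eff == pytest.approx(50.0, rel=0.1)
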