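import numpy as np
import pytest
from hypothesis import given, strategies as st

from stenoflow.errors import DomainError
from stenoflow.footprint import (ActivationCriterion, activation_fraction,
                                 analyze_population, bootstrap_population,
                                 build_sa_pdf, scalar_stress,
                                 shear_stress_tensor, split_bulk_tail,
                                 stress_accumulation)


def _traj(sigma, times):
    class T:
        pass

    t = T()
    t.scalar_stress = np.asarray(sigma, float)
    t.times = np.asarray(times, float)
    return t


def _von_mises_over_sqrt3(S):
    """Independent oracle: classical von Mises stress divided by sqrt(3)."""
    vm = np.sqrt(0.5 * ((S[..., 0, 0] - S[..., 1, 1]) ** 2
                        + (S[..., 1, 1] - S[..., 2, 2]) ** 2
                        + (S[..., 2, 2] - S[..., 0, 0]) ** 2
                        + 6 * (S[..., 0, 1] ** 2 + S[..., 1, 2] ** 2
                               + S[..., 0, 2] ** 2)))
    return vm / np.sqrt(3.0)


class TestShearStressTensor:
    def test_zero_gradient_gives_zero_tensor(self):
        assert np.all(shear_stress_tensor(np.zeros((2, 2)), 3.5e-3) == 0.0)

    def test_simple_shear(self):
        mu, k = 3.5e-3, 40.0
        G = np.zeros((2, 2))
        G[0, 1] = k  # du1/dx2
        tau = shear_stress_tensor(G, mu)
        assert tau[0, 1] == pytest.approx(mu * k)
        assert tau[1, 0] == pytest.approx(mu * k)
        off = np.abs(tau).sum() - 2 * mu * k
        assert off == pytest.approx(0.0, abs=1e-18)

    def test_random_gradients_match_matrix_oracle(self):
        rng = np.random.default_rng(11)
        G = rng.normal(size=(500, 3, 3))
        mu = 2.7e-3
        tau = shear_stress_tensor(G, mu)
        ref = mu * (G + np.swapaxes(G, 1, 2))
        np.testing.assert_allclose(tau, ref, rtol=1e-14)
        assert np.allclose(tau, np.swapaxes(tau, 1, 2))


class TestScalarStress:
    def test_hydrostatic_tensor_vanishes(self):
        # exact cancellation up to sqrt(machine epsilon) after the root
        assert scalar_stress(7.3 * np.eye(3)) == pytest.approx(0.0, abs=1e-6)

    def test_pure_shear_recovers_shear_component(self):
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = 1.7
        assert scalar_stress(t) == pytest.approx(1.7, rel=1e-14)

    def test_uniaxial_gives_t_over_sqrt3(self):
        t = np.zeros((3, 3))
        t[0, 0] = 4.2
        assert scalar_stress(t) == pytest.approx(4.2 / np.sqrt(3), rel=1e-14)

    def test_matches_von_mises_oracle_on_random_tensors(self):
        """1000 random symmetric tensors agree with the independently
        coded von-Mises/sqrt(3) invariant to 1e-12 relative."""
        rng = np.random.default_rng(4)
        A = rng.normal(size=(1000, 3, 3))
        S = A + np.swapaxes(A, 1, 2)
        ours = scalar_stress(S)
        ref = _von_mises_over_sqrt3(S)
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_asymmetric_input_rejected(self):
        t = np.zeros((3, 3))
        t[0, 1] = 1.0
        with pytest.raises(DomainError, match="asymmetric"):
            scalar_stress(t)

    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10))
    def test_non_negative(self, a, b, c):
        t = np.diag([a, b, c])
        assert scalar_stress(t) >= 0.0


class TestStressAccumulation:
    def test_constant_stress_reaches_activation_threshold_exactly(self):
        """Constant 7 Pa over 0.5 s accumulates exactly 3.5 Pa s — the
        activation threshold — and strict inequality leaves the platelet
        unactivated."""
        n = 51
        tr = _traj(np.full(n, 7.0), np.linspace(0, 0.5, n))
        sa = stress_accumulation(tr)
        assert sa == pytest.approx(3.5, rel=1e-12)
        assert activation_fraction([sa]) == 0.0

    def test_zero_stress_trajectory(self):
        tr = _traj(np.zeros(10), np.linspace(0, 1, 10))
        assert stress_accumulation(tr) == 0.0

    def test_linear_ramp_quadrature_refinement(self):
        """sigma = a t integrates to a T^2/2; the left-Riemann error
        halves when the step halves."""
        a, T = 3.0, 1.0
        errs = []
        for n in (64, 128):
            t = np.linspace(0, T, n + 1)
            tr = _traj(a * t, t)
            errs.append(abs(stress_accumulation(tr) - a * T**2 / 2))
        assert errs[1] == pytest.approx(errs[0] / 2, rel=0.05)

    def test_additive_over_concatenated_segments(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 101)
        sig = rng.uniform(0, 5, 101)
        whole = stress_accumulation(_traj(sig, t))
        first = stress_accumulation(_traj(sig[:51], t[:51]))
        second = stress_accumulation(_traj(sig[50:], t[50:]))
        assert first + second == pytest.approx(whole, rel=1e-14)

    def test_trapezoid_rule_available(self):
        t = np.linspace(0, 1, 11)
        tr = _traj(t.copy(), t)
        assert stress_accumulation(tr, rule="trapezoid") == pytest.approx(0.5)


class TestSAPdf:
    def test_identical_values_give_flagged_single_bin(self):
        pdf = build_sa_pdf(np.full(50, 2.0))
        assert pdf.degenerate
        assert pdf.integral() == pytest.approx(1.0, rel=1e-9)

    def test_lognormal_mode_recovered(self):
        rng = np.random.default_rng(8)
        sa = rng.lognormal(mean=0.0, sigma=0.5, size=100_000)
        pdf = build_sa_pdf(sa, n_bins=64)
        analytic_mode = np.exp(0.0 - 0.5**2)
        centers = pdf.bin_centers
        width = np.diff(np.log(pdf.bin_edges)).mean()
        assert abs(np.log(pdf.mode) - np.log(analytic_mode)) < 2 * width

    def test_uniform_sample_density_near_one(self):
        rng = np.random.default_rng(9)
        sa = rng.uniform(1.0, 2.0, 100_000)
        pdf = build_sa_pdf(sa, n_bins=20, bin_scale="linear")
        assert np.abs(pdf.density - 1.0).max() < 0.05

    def test_normalization_with_zero_atom(self):
        sa = np.concatenate([np.zeros(100), np.full(100, 1.0),
                             np.full(100, 2.0)])
        pdf = build_sa_pdf(sa, bin_scale="log")
        assert pdf.zero_atom_mass == pytest.approx(1 / 3)
        assert pdf.integral() + pdf.zero_atom_mass == pytest.approx(
            1.0, abs=1e-6)


class TestActivation:
    def test_direct_count(self):
        assert activation_fraction([1.0, 2.0, 4.0, 5.0]) == 0.5

    def test_all_below_threshold(self):
        assert activation_fraction([0.1, 0.2]) == 0.0

    def test_exponential_tail_matches_analytic(self):
        """Exponential(mean 1) SA: activated fraction ~ exp(-3.5)
        within 3 standard errors at n = 1e5."""
        n = 100_000
        rng = np.random.default_rng(12)
        sa = rng.exponential(1.0, n)
        frac = activation_fraction(sa)
        p = np.exp(-3.5)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(13)
        sa = rng.lognormal(0, 1, 5000)
        fracs = [activation_fraction(sa, ActivationCriterion(t))
                 for t in np.linspace(0.1, 10, 25)]
        assert np.all(np.diff(fracs) <= 0)

    def test_empty_population_rejected(self):
        with pytest.raises(DomainError):
            activation_fraction([])


class TestBootstrap:
    def test_degenerate_population_gives_zero_cis(self):
        sa = np.full(2000, 1.0)
        boot = bootstrap_population(sa, resample_sizes=[500, 1000],
                                    n_replicates=200, rng_seed=0)
        for lo, hi in boot.fraction_ci.values():
            assert (lo, hi) == (0.0, 0.0)
        assert boot.compatible

    def test_full_size_ci_contains_plain_fraction(self):
        rng = np.random.default_rng(3)
        sa = rng.exponential(2.0, 5000)
        boot = bootstrap_population(sa, resample_sizes=[5000],
                                    n_replicates=500, rng_seed=1)
        lo, hi = boot.fraction_ci[5000]
        assert lo <= boot.full_population_fraction <= hi

    def test_ci_width_shrinks_like_inverse_sqrt_size(self):
        """Quadrupling the resample size halves the CI width (within
        25%)."""
        rng = np.random.default_rng(5)
        sa = np.concatenate([rng.exponential(1.0, 50_000),
                             rng.exponential(6.0, 10_000)])
        boot = bootstrap_population(sa, resample_sizes=[500, 2000, 8000],
                                    n_replicates=1000, rng_seed=2)
        w = {s: hi - lo for s, (lo, hi) in boot.fraction_ci.items()}
        for s_small, s_big in [(500, 2000), (2000, 8000)]:
            ratio = w[s_small] / w[s_big]
            assert ratio == pytest.approx(2.0, rel=0.25)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        sa = rng.exponential(2.0, 3000)
        a = bootstrap_population(sa, resample_sizes=[1000], rng_seed=9)
        b = bootstrap_population(sa, resample_sizes=[1000], rng_seed=9)
        assert a.fraction_ci == b.fraction_ci

    def test_few_replicates_warn(self):
        with pytest.warns(UserWarning):
            bootstrap_population(np.ones(100), resample_sizes=[50],
                                 n_replicates=50)


class TestBulkTail:
    def test_all_below_threshold_gives_empty_tail(self):
        sa = np.random.default_rng(1).uniform(0.1, 1.0, 1000)
        pdf = build_sa_pdf(sa)
        split = split_bulk_tail(pdf, sa)
        assert split["tail"].mass == 0.0
        assert split["bulk"].mass == pytest.approx(1.0)

    def test_mixture_tail_mass_recovered(self):
        """Two-component mixture with known mass p above threshold."""
        rng = np.random.default_rng(2)
        p, n = 0.07, 50_000
        n_tail = int(p * n)
        sa = np.concatenate([rng.uniform(0.01, 3.0, n - n_tail),
                             rng.uniform(4.0, 9.0, n_tail)])
        pdf = build_sa_pdf(sa)
        split = split_bulk_tail(pdf, sa)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(split["tail"].mass - p) < 3 * se
        assert split["bulk"].mass + split["tail"].mass == pytest.approx(1.0)

    def test_default_threshold_is_hellum(self):
        assert ActivationCriterion().threshold == 3.5


def test_analyze_population_bundles_consistent_statistics():
    rng = np.random.default_rng(21)
    sa = rng.lognormal(-1.0, 1.2, 20_000)
    pop = analyze_population(sa, rng_seed=4)
    assert pop.n == 20_000
    assert pop.activation_fraction == activation_fraction(sa)
    assert pop.bootstrap.compatible
    masses = (pop.regions["bulk"].mass + pop.regions["tail"].mass
              + pop.pdf.zero_atom_mass)
    assert masses == pytest.approx(1.0, abs=1e-12)
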