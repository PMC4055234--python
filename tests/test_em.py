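import numpy as np
import pytest

from countem import (
    CountTable,
    EMConfig,
    ErrorRates,
    FrequencyModel,
    LowInformationWarning,
    NoDataError,
    SamplingBias,
    SimConfig,
    e_step,
    m_step_errors,
    m_step_frequencies,
    observed_loglik,
    run_em,
    simulate_counts,
)
from countem.em import ExpectedCounts, _argmax_q
from countem.likelihood import loglik_matrix

from conftest import make_table


def expected_counts(D_g=(0.0, 0.0, 0.0), H_g=(0.0, 0.0), **kw):
    defaults = dict(R0=0.0, R2=0.0, A0=0.0, A2=0.0, C1r=0.0, C1a=0.0)
    defaults.update(kw)
    return ExpectedCounts(D_g=np.asarray(D_g, float), H_g=np.asarray(H_g, float), **defaults)


class TestEStep:
    def test_no_data_posterior_equals_hwe_prior(self):
        table = make_table([0.0], [0.0])
        post, exp = e_step(table, FrequencyModel.hwe(0.5), ErrorRates(), SamplingBias())
        assert np.allclose(post[0], [0.25, 0.5, 0.25])
        assert np.allclose(exp.D_g, [0.25, 0.5, 0.25])

    def test_single_reference_read(self):
        # one sample, one read showing the reference allele (l = k = 1)
        table = make_table([1.0], [0.0])
        post, _ = e_step(table, FrequencyModel.hwe(0.5), ErrorRates(0, 0), SamplingBias(1))
        assert np.allclose(post[0], [0.0, 0.5, 0.5])

    def test_posterior_mass_accounting(self, rng):
        ref = rng.poisson(3, size=30).astype(float)
        alt = rng.poisson(1, size=30).astype(float)
        ploidy = rng.choice([1, 2], size=30)
        table = make_table(ref, alt, ploidy)
        post, exp = e_step(table, FrequencyModel.hwe(0.3), ErrorRates(0.01, 0.02),
                           SamplingBias(2.0))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)
        assert exp.D == pytest.approx(np.sum(ploidy == 2))
        assert exp.H == pytest.approx(np.sum(ploidy == 1))
        # every modelled count lands in exactly one of the expected-mass bins
        assert exp.R0 + exp.R2 + exp.C1r == pytest.approx(
            ref[ploidy == 2].sum() + ref[ploidy == 1].sum()
        )
        assert exp.A0 + exp.A2 + exp.C1a == pytest.approx(alt.sum())


class TestMStepFrequencies:
    def test_hwe_update_diploid(self):
        model = m_step_frequencies(expected_counts(D_g=(10, 20, 70)), "HWE")
        assert model.psi == pytest.approx(40 / 200)

    def test_hwe_update_all_hemizygous(self):
        model = m_step_frequencies(expected_counts(H_g=(30, 70)), "HWE")
        assert model.psi == pytest.approx(0.3)

    def test_free_update_is_normalization(self):
        model = m_step_frequencies(expected_counts(D_g=(25, 50, 25)), "FREE")
        assert np.allclose(model.psi_g, [0.25, 0.5, 0.25])

    def test_free_update_without_individuals_fails(self):
        with pytest.raises(NoDataError):
            m_step_frequencies(expected_counts(), "FREE")


def grid_argmax_q(u, v, w, p, q, step=1e-7):
    xs = np.arange(step, 0.5, step)
    with np.errstate(divide="ignore", invalid="ignore"):
        qv = u * np.log(xs) + v * np.log(p + q * xs) + w * np.log(1 - xs)
    qv[~np.isfinite(qv)] = -np.inf
    return xs[int(np.argmax(qv))]


class TestMStepErrors:
    def test_closed_form_at_unit_bias(self):
        exp = expected_counts(A0=990.0, A2=10.0, C1a=123.0, R0=5.0, R2=495.0, C1r=7.0)
        err, halted = m_step_errors(exp, SamplingBias(1.0))
        assert not halted
        assert err.eps_alt == pytest.approx(10 / 1000)
        assert err.eps_ref == pytest.approx(5 / 500)

    def test_zero_denominators_give_zero(self):
        err, halted = m_step_errors(expected_counts(C1r=50.0, C1a=10.0), SamplingBias(1.0))
        assert (err.eps_ref, err.eps_alt, halted) == (0.0, 0.0, False)

    def test_biased_update_matches_grid_oracle(self):
        exp = expected_counts(R0=5.0, C1r=100.0, R2=900.0)
        err, halted = m_step_errors(exp, SamplingBias(4.0))
        assert not halted
        assert err.eps_ref == pytest.approx(grid_argmax_q(5, 100, 900, 4.0, -3.0), abs=1e-6)

    @pytest.mark.parametrize("lam", [0.25, 1.0, 3.0])
    def test_quadratic_solution_matches_grid_over_random_masses(self, lam, rng):
        for _ in range(10):
            u, v, w = rng.uniform(0, 50), rng.uniform(0, 200), rng.uniform(200, 2000)
            exp = expected_counts(R0=u, C1r=v, R2=w, A2=u, C1a=v, A0=w)
            err, halted = m_step_errors(exp, SamplingBias(lam))
            assert not halted
            assert err.eps_ref == pytest.approx(
                grid_argmax_q(u, v, w, lam, 1.0 - lam), abs=1e-6)
            assert err.eps_alt == pytest.approx(
                grid_argmax_q(u, v, w, 1.0, lam - 1.0), abs=1e-6)

    def test_majority_erroneous_counts_trigger_halt(self):
        exp = expected_counts(R0=600.0, R2=400.0)
        prev = ErrorRates(0.01, 0.01)
        err, halted = m_step_errors(exp, SamplingBias(1.0), current=prev)
        assert halted and err == prev

    def test_argmax_boundary_cases(self):
        assert _argmax_q(0.0, 0.0, 0.0, 1.0, 0.0) == (0.0, False)
        assert _argmax_q(0.0, 10.0, 0.0, 0.5, 0.5) == (0.5, True)  # increasing middle term
        assert _argmax_q(0.0, 10.0, 5.0, 1.0, -0.5)[0] == 0.0      # decreasing at zero


class TestObservedLoglik:
    def test_empty_count_sample_contributes_zero(self):
        table = make_table([0.0], [0.0])
        ll = observed_loglik(table, FrequencyModel.hwe(0.37), ErrorRates(), SamplingBias())
        assert ll == pytest.approx(0.0)

    def test_hand_computed_single_sample(self):
        # one reference read: 0.25*0 + 0.5*0.5 + 0.25*1 = 0.5
        table = make_table([1.0], [0.0])
        ll = observed_loglik(table, FrequencyModel.hwe(0.5), ErrorRates(0, 0), SamplingBias(1))
        assert ll == pytest.approx(np.log(0.5))

    def test_additivity_over_identical_samples(self):
        one = make_table([3.0], [1.0])
        five = make_table([3.0] * 5, [1.0] * 5)
        args = (FrequencyModel.hwe(0.3), ErrorRates(0.01, 0.01), SamplingBias(2.0))
        assert observed_loglik(five, *args) == pytest.approx(5 * observed_loglik(one, *args))


def grid_ml_psi(table, err, bias, step=1e-5):
    """Brute-force ML of psi on a grid (HWE mode, errors fixed)."""
    ll = loglik_matrix(table.ref_counts, table.alt_counts, table.ploidies, err, bias)
    scaled = np.exp(ll - np.nan_to_num(ll.max(axis=1, keepdims=True), neginf=0.0))
    psis = np.arange(0.0, 1.0 + step / 2, step)
    dip = table.ploidies == 2
    prior_dip = np.stack([psis**2, 2 * psis * (1 - psis), (1 - psis) ** 2], axis=1)
    prior_hemi = np.stack([psis, 1 - psis, np.zeros_like(psis)], axis=1)
    with np.errstate(divide="ignore"):
        total = np.log(prior_dip @ scaled[dip].T).sum(axis=1)
        if np.any(~dip):
            total = total + np.log(prior_hemi @ scaled[~dip].T).sum(axis=1)
    return psis[int(np.argmax(total))]


class TestRunEM:
    def test_all_reference_data_drives_psi_to_zero(self, no_error_config):
        table = make_table([5.0] * 50, [0.0] * 50)
        fit = run_em(table, no_error_config)
        assert fit.psi == pytest.approx(0.0, abs=1e-4)
        assert fit.converged

    def test_symmetric_two_sample_table(self, no_error_config):
        fit = run_em(make_table([2.0, 0.0], [0.0, 2.0]), no_error_config)
        assert fit.psi == pytest.approx(0.5, abs=1e-6)

    def test_empty_or_uninformative_table_refused(self, no_error_config):
        with pytest.raises(NoDataError):
            run_em(CountTable([]), no_error_config)
        with pytest.raises(NoDataError):
            run_em(make_table([0.0, 0.0], [0.0, 0.0]), no_error_config)

    def test_matches_grid_search_on_small_tables(self, rng):
        config = EMConfig(lam=2.0, err=ErrorRates(0.02, 0.05), tol=1e-12, max_iter=100_000)
        for _ in range(5):
            n = int(rng.integers(2, 10))
            table = make_table(
                rng.poisson(2, n).astype(float), rng.poisson(2, n).astype(float),
                rng.choice([1, 2], n),
            )
            if not np.any(table.totals > 0):
                continue
            fit = run_em(table, config)
            assert fit.psi == pytest.approx(
                grid_ml_psi(table, config.err, config.bias), abs=1e-4)

    def test_loglik_never_decreases(self, rng):
        for estimate_errors in (False, True):
            tt = simulate_counts(SimConfig(n=150, psi=0.35, mean_coverage=3.0,
                                           flip_error=0.02, lam=1.7,
                                           seed=rng.integers(2**31)))
            fit = run_em(tt.table, EMConfig(lam=1.7, err=ErrorRates(0.02, 0.02),
                                            estimate_errors=estimate_errors))
            assert np.all(np.diff(fit.loglik_trajectory) >= -1e-9)

    def test_label_swap_equivariance(self, rng):
        ref = rng.poisson(3, 40).astype(float)
        alt = rng.poisson(2, 40).astype(float)
        cfg = EMConfig(lam=2.5, err=ErrorRates(0.01, 0.03))
        fit = run_em(make_table(ref, alt), cfg)
        swapped = run_em(
            make_table(alt, ref),
            EMConfig(lam=1 / 2.5, err=ErrorRates(0.03, 0.01)),
        )
        assert swapped.psi == pytest.approx(1.0 - fit.psi, abs=1e-6)
        free = run_em(make_table(ref, alt), EMConfig(lam=2.5, err=ErrorRates(0.01, 0.03),
                                                     mode="FREE"))
        free_swapped = run_em(make_table(alt, ref),
                              EMConfig(lam=1 / 2.5, err=ErrorRates(0.03, 0.01), mode="FREE"))
        assert np.allclose(free_swapped.model.psi_g, free.model.psi_g[::-1], atol=1e-6)

    def test_unbiased_and_near_optimal_precision(self):
        """Mean of psi-hat over replicates is unbiased and its spread stays
        close to the known-genotype binomial bound sqrt(psi(1-psi)/2n)."""
        psi, n = 0.2, 100
        cfg = EMConfig(err=ErrorRates(0.005, 0.005))
        seeds = np.random.SeedSequence(42).spawn(100)
        est = np.array([
            run_em(simulate_counts(SimConfig(n=n, psi=psi, mean_coverage=4.0,
                                             flip_error=0.005, seed=s)).table, cfg).psi
            for s in seeds
        ])
        binom_se = np.sqrt(psi * (1 - psi) / (2 * n))
        assert abs(est.mean() - psi) < 3 * est.std(ddof=1) / 10
        assert est.std(ddof=1) < 1.3 * binom_se

    def test_extreme_bias_tolerates_even_more_extreme_guess(self):
        """Data at lam=100 fitted with lam-hat=1000 stays unbiased."""
        psi = 0.4
        seeds = np.random.SeedSequence(77).spawn(30)
        est = np.array([
            run_em(simulate_counts(SimConfig(n=500, psi=psi, mean_coverage=4.0,
                                             flip_error=0.005, lam=100.0, seed=s)).table,
                   EMConfig(lam=1000.0, err=ErrorRates(0.005, 0.005))).psi
            for s in seeds
        ])
        assert abs(est.mean() - psi) < 3 * est.std(ddof=1) / np.sqrt(30) + 0.005

    def test_hemizygous_table_recovers_frequency(self):
        tt = simulate_counts(SimConfig(n=3000, psi=0.3, mean_coverage=4.0,
                                       flip_error=0.005, ploidy=1, seed=11))
        fit = run_em(tt.table, EMConfig(err=ErrorRates(0.005, 0.005)))
        assert fit.psi == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / 3000) + 0.01)

    def test_free_mode_with_mixed_ploidy(self):
        tt = simulate_counts(SimConfig(n=400, psi=0.4, mean_coverage=6.0, flip_error=0.0,
                                       ploidy=[1, 2] * 200, seed=5))
        fit = run_em(tt.table, EMConfig(mode="FREE", err=ErrorRates(0, 0)))
        assert fit.model.psi_g.sum() == pytest.approx(1.0)
        assert fit.model.phi_g.sum() == pytest.approx(1.0)
        assert fit.model.psi_g[1] == pytest.approx(2 * 0.4 * 0.6, abs=0.1)

    def test_error_coestimation_recovers_flip_rate(self):
        tt = simulate_counts(SimConfig(n=2000, psi=0.5, mean_coverage=8.0,
                                       flip_error=0.02, seed=3))
        fit = run_em(tt.table, EMConfig(estimate_errors=True, err=ErrorRates(0.1, 0.1)))
        assert fit.err.eps_ref == pytest.approx(0.02, abs=0.01)
        assert fit.err.eps_alt == pytest.approx(0.02, abs=0.01)
        assert not fit.halted_eps

    def test_low_information_error_estimation_warns(self, rng):
        table = make_table(rng.poisson(1, 10).astype(float) + 1, rng.poisson(1, 10).astype(float))
        with pytest.warns(LowInformationWarning):
            run_em(table, EMConfig(estimate_errors=True))

    def test_halting_on_majority_errors(self):
        # a lone ref count on otherwise all-alt samples is best explained as
        # error mass concentrated in the alt-homozygote class
        table = make_table([1.0] * 20, [19.0] * 20)
        fit = run_em(table, EMConfig(estimate_errors=True, err=ErrorRates(0.01, 0.01)))
        assert fit.halted_eps

    def test_fixed_errors_stay_fixed(self):
        tt = simulate_counts(SimConfig(n=100, psi=0.4, seed=9))
        err = ErrorRates(0.007, 0.003)
        fit = run_em(tt.table, EMConfig(err=err))
        assert fit.err == err
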