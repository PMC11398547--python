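import math

import numpy as np
import pytest

from polyfock import builtin_fixture
from polyfock.equilibrium import (
    DivergenceError,
    EquilibriumParams,
    branched_bulk,
    detailed_balance_rates,
    exact_partition_oracle,
    homodimer_effective_potentials,
    homopolymer_bulk,
    homopolymer_species_potentials,
    isotropic_bulk,
    monomer_equilibrium,
)


class TestMonomer:
    def test_Z_matches_enumeration_N3(self):
        """Z = (1+lam)^N; cross-checked by exhaustive microstate enumeration."""
        lam = 0.5
        params = EquilibriumParams(mu=math.log(lam), N=3)
        res = monomer_equilibrium(params)
        assert res["Z"] == pytest.approx(3.375)
        model = builtin_fixture("monomer", 3, mu=math.log(lam))
        oracle = exact_partition_oracle(model)
        assert oracle["Z"] == pytest.approx(res["Z"], rel=1e-12)

    def test_mean_count(self):
        params = EquilibriumParams(mu=0.4, N=10)
        lam = math.exp(0.4)
        assert monomer_equilibrium(params)["mean"] == pytest.approx(10 * lam / (1 + lam))

    def test_lambda_zero_vacuum(self):
        params = EquilibriumParams(mu=-math.inf, N=4)
        res = monomer_equilibrium(params)
        assert res["Z"] == pytest.approx(1.0)
        assert res["pmf"](0) == pytest.approx(1.0)

    def test_poisson_limit_converges(self):
        """Binomial -> Poisson at fixed lam' as N grows (monotone at n=0)."""
        lam_prime = 0.8
        errs = []
        for N in (2, 4, 8, 64):
            params = EquilibriumParams(mu=math.log(lam_prime / N), N=N, V=1.0)
            res = monomer_equilibrium(params)
            big = monomer_equilibrium(params, large_N=True)
            errs.append(abs(res["pmf"](0) - big["pmf"](0)))
        assert all(a > b for a, b in zip(errs, errs[1:]))


class TestHomodimer:
    def test_effective_dimer_potential(self):
        # mu' = 0, eps' = 0 -> mu'_D = -log 2
        params = EquilibriumParams(mu=0.0, eps=0.0, N=4, V=4.0)
        # mu' = mu + log(N/V) = 0; eps' = eps - log V = -log 4 != 0, so adjust
        params = EquilibriumParams(mu=0.0, eps=math.log(4.0), N=4, V=4.0)
        table = homodimer_effective_potentials(params)
        assert table["monomer"]["mu_prime"] == pytest.approx(0.0)
        assert table["dimer"]["mu_prime"] == pytest.approx(-math.log(2.0))

    def test_exact_renormalizability(self):
        """Fixed (mu', eps') gives fixed outputs under changes of (mu, N, V)."""
        ref = None
        for N, V in ((4, 1.0), (16, 2.5), (100, 7.0)):
            mu = 0.3 - math.log(N / V)
            eps = -0.2 + math.log(V)
            table = homodimer_effective_potentials(
                EquilibriumParams(mu=mu, eps=eps, N=N, V=V)
            )
            pair = (table["monomer"]["mu_prime"], table["dimer"]["mu_prime"])
            if ref is None:
                ref = pair
            assert pair == pytest.approx(ref)

    def test_dimer_mode_count(self):
        table = homodimer_effective_potentials(EquilibriumParams(mu=0, N=10))
        assert table["dimer"]["modes"] == 45  # C(10,2) ~ N^2/2


class TestHomopolymerPotentials:
    def test_chain_ring_fugacities(self):
        params = EquilibriumParams(mu=0.2, eps=0.1, N=8, V=2.0)
        b = params.beta
        eta = params.eta("homopolymer")
        epsp = params.eps_prime("homopolymer")
        for x in (1, 2, 5):
            muC, muR = homopolymer_species_potentials(params, x)
            assert math.exp(b * muC) == pytest.approx(math.exp(b * epsp) * eta**x)
            assert math.exp(b * muR) == pytest.approx(eta**x / (x * params.V))

    def test_x1_chain_matches_free_monomer(self):
        params = EquilibriumParams(mu=0.2, eps=0.1, N=8, V=2.0)
        muC1, _ = homopolymer_species_potentials(params, 1)
        assert muC1 == pytest.approx(params.mu_prime)

    def test_ring_concentration_scales_inverse_V(self):
        mu_p, eps_p = 0.1, 0.5
        vals = []
        for V in (1.0, 10.0):
            params = EquilibriumParams(
                mu=mu_p - math.log(4 / V), eps=eps_p - math.log(V), N=4, V=V
            )
            _, muR = homopolymer_species_potentials(params, 3)
            vals.append(math.exp(params.beta * muR))
        assert vals[0] / vals[1] == pytest.approx(10.0)

    def test_x_validation(self):
        with pytest.raises(ValueError):
            homopolymer_species_potentials(EquilibriumParams(mu=0), 0)


def series_sum(f, xmin=1, tol=1e-14, xcap=100_000):
    total = 0.0
    for x in range(xmin, xcap):
        term = f(x)
        total += term
        if abs(term) < tol * max(abs(total), 1.0) and x > 10:
            return total
    raise RuntimeError("series did not converge")


class TestHomopolymerBulk:
    def test_mean_and_variance_at_half(self):
        res = homopolymer_bulk(eta=0.5)
        assert res["chain_mean"] == pytest.approx(1.0)
        assert res["chain_var"] == pytest.approx(2.0)

    def test_closed_forms_match_series(self):
        """Direct species-series summation reproduces every closed form to 1e-10."""
        eta, epsp, V, b = 0.61, 0.3, 3.0, 1.0
        w = math.exp(b * epsp)
        res = homopolymer_bulk(eta=eta, eps_prime=epsp, V=V, beta=b)
        logZ = series_sum(lambda x: w * eta**x) + series_sum(lambda x: eta**x / (x * V))
        assert res["logZ_per_V"] == pytest.approx(logZ, abs=1e-10)
        conc = series_sum(lambda x: x * w * eta**x) + series_sum(lambda x: eta**x / V)
        assert res["concentration"] == pytest.approx(conc, abs=1e-10)
        norm = series_sum(lambda x: eta**x)
        mean_links = series_sum(lambda x: (x - 1) * eta**x) / norm
        var_links = series_sum(lambda x: (x - 1) ** 2 * eta**x) / norm - mean_links**2
        assert res["chain_mean"] == pytest.approx(mean_links, abs=1e-10)
        assert res["chain_var"] == pytest.approx(var_links, abs=1e-10)

    def test_exponential_length_distribution(self):
        """Chain-species concentrations are proportional to eta^x."""
        params = EquilibriumParams(mu=-0.9, eps=0.2, N=10, V=1.0)
        eta = params.eta("homopolymer")
        b = params.beta
        concs = [
            math.exp(b * homopolymer_species_potentials(params, x)[0]) for x in (1, 2, 3, 4)
        ]
        ratios = [c2 / c1 for c1, c2 in zip(concs, concs[1:])]
        assert all(r == pytest.approx(eta) for r in ratios)

    @pytest.mark.parametrize("eta", [1.0, 1.5])
    def test_divergence_error(self, eta):
        with pytest.raises(DivergenceError):
            homopolymer_bulk(eta=eta)


class TestIsotropicBulk:
    def test_series_cross_check(self):
        eta, epsp, V = 0.55, -0.2, 2.0
        w = math.exp(epsp)
        res = isotropic_bulk(eta=eta, eps_prime=epsp, V=V)
        odd = series_sum(lambda x: w * eta ** (2 * x - 1))
        even = series_sum(lambda x: 2 * w * eta ** (2 * x))
        ring2 = eta**2 / (2 * V)
        rings = series_sum(lambda x: eta ** (2 * x) / (4 * x * V), xmin=2)
        assert res["logZ_per_V"] == pytest.approx(odd + even + ring2 + rings, abs=1e-10)

    def test_even_chains_carry_factor_two(self):
        """Removing the factor 2 from even chains breaks the series identity."""
        eta, w = 0.4, 1.0
        res = isotropic_bulk(eta=eta)
        with_factor = series_sum(lambda x: w * eta ** (2 * x - 1)) + series_sum(
            lambda x: 2 * w * eta ** (2 * x)
        )
        without = series_sum(lambda x: w * eta ** (2 * x - 1)) + series_sum(
            lambda x: w * eta ** (2 * x)
        )
        chains_closed = w * (eta + 2 * eta**2) / (1 - eta**2)
        assert chains_closed == pytest.approx(with_factor, abs=1e-12)
        assert chains_closed != pytest.approx(without, abs=1e-3)

    def test_divergence_ratio_three_halves(self):
        """Isotropic/directed divergence coefficient ratio = 3/2 near eta -> 1."""
        delta = 1e-3
        eta = 1.0 - delta
        iso = isotropic_bulk(eta=eta)["concentration"]
        hom = homopolymer_bulk(eta=eta)["concentration"]
        assert iso / hom == pytest.approx(1.5, rel=5e-3)
        assert isotropic_bulk(eta=0.5)["divergence_coeff"] == pytest.approx(1.5)

    def test_no_odd_rings_in_fixture(self):
        """The isotropic fixture admits even rings only (structural property)."""
        from polyfock.master import enumerate_reachable
        from polyfock.census import species_count_labeler
        from polyfock.fock import compile_model

        iso = builtin_fixture("isotropic_homopolymer", 4)
        space = enumerate_reachable(iso)
        labeler = species_count_labeler(space.compiled)
        ring_sizes = set()
        for mask in space.masks:
            for name, _ in labeler(int(mask), space.compiled):
                if name.startswith("ring-"):
                    ring_sizes.add(int(name.split("-")[1].split(":")[0]))
        assert ring_sizes == {2, 4}

    def test_divergence_error(self):
        with pytest.raises(DivergenceError):
            isotropic_bulk(eta=1.01)


class TestBranchedBulk:
    def test_xi_at_quarter(self):
        assert branched_bulk(eta=0.25)["xi"] == pytest.approx(1.0)

    def test_recursion_residual_on_grid(self):
        for eta in np.linspace(0.005, 0.25, 50):
            xi = branched_bulk(eta=float(eta))["xi"]
            assert abs(xi - eta * (1 + xi) ** 2) < 1e-12

    def test_xi_small_eta_limit(self):
        for eta in (1e-4, 1e-6):
            xi = branched_bulk(eta=eta)["xi"]
            assert xi == pytest.approx(eta, rel=1e-3)

    def test_divergence_error_above_quarter(self):
        with pytest.raises(DivergenceError, match="1/4"):
            branched_bulk(eta=0.26)

    def test_grove_series_cross_check(self):
        eta, V = 0.2, 3.0
        res = branched_bulk(eta=eta, V=V)
        xi = res["xi"]
        groves = series_sum(lambda x: (2**x) * eta**x * (1 + xi) ** x / (x * V))
        trees = 1.0 * xi  # eps' = 0
        assert res["logZ_per_V"] == pytest.approx(trees + groves, abs=1e-10)


class TestOracle:
    def test_homodimer_N2_partition_function(self):
        """Z = 1 + 2 lam + lam^2 + lam^2 e^{-beta eps} over the 5 valid states."""
        mu, eps = 0.4, -0.3
        lam = math.exp(mu)
        model = builtin_fixture("homodimer", 2, mu=mu, eps=eps)
        oracle = exact_partition_oracle(model)
        assert oracle["Z"] == pytest.approx(
            1 + 2 * lam + lam**2 + lam**2 * math.exp(-eps)
        )

    def test_beta_zero_counts_states(self):
        model = builtin_fixture("homodimer", 2, mu=1.0, eps=1.0)
        oracle = exact_partition_oracle(model, beta=0.0)
        assert oracle["Z"] == pytest.approx(5.0)

    def test_macrostate_marginals_sum_to_one(self):
        model = builtin_fixture("homodimer", 3, mu=0.2, eps=0.1)
        oracle = exact_partition_oracle(model)
        assert sum(oracle["macrostates"].values()) == pytest.approx(1.0)

    def test_cap(self):
        with pytest.raises(ValueError, match="cap"):
            exact_partition_oracle(builtin_fixture("homodimer", 8))


class TestDetailedBalanceRates:
    def test_symmetric_at_mu_zero(self):
        rates = detailed_balance_rates(EquilibriumParams(mu=0.0, eps=0.5))
        assert rates["create"] == pytest.approx(rates["destroy"])

    def test_strong_eps_suppresses_dimer(self):
        """eps -> +inf: bind/unbind -> 0 and the stationary dimer weight vanishes."""
        from polyfock.master import build_generator, enumerate_reachable, stationary_distribution
        from polyfock.census import species_count_labeler
        from polyfock.master import macrostate_distribution

        params = EquilibriumParams(mu=0.0, eps=12.0, N=2)
        base = builtin_fixture("homodimer", 2)
        rates = detailed_balance_rates(params, base)
        assert rates["bind"] / rates["unbind"] < 1e-5
        m = builtin_fixture("homodimer", 2, rates=rates)
        space = enumerate_reachable(m)
        pi = stationary_distribution(build_generator(m, space))
        dist = macrostate_distribution(pi, space, species_count_labeler(space.compiled))
        dimer_prob = sum(v for k, v in dist.items() if dict(k).get("dimer"))
        assert dimer_prob < 1e-4
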