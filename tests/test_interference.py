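"""Stahl likelihood internals: densities, subset-sum, fitting, LRT."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from recombkit import (
    StahlModel,
    StahlParams,
    carrier_lrt,
    fit_stahl,
    interxo_density,
    interxo_survival,
    records_from_meioses,
    simulate_stahl_process,
    stahl_loglik,
    uniform_rate_genome,
)
from recombkit.simulate import CarrierEffectSpec, simulate_recombination_cohort

FAST_FIT = dict(
    nu_grid=np.array([2.0, 6.0, 12.0]),
    p_grid=np.array([0.01, 0.05, 0.2]),
    xatol=5e-4,
    fatol=1e-6,
)


class TestDensity:
    def test_exponential_reduction(self):
        # nu=1, p=0: thinned Poisson gaps are exponential(1)
        assert interxo_density(0.5, StahlParams(1.0, 0.0))[0] == pytest.approx(
            np.exp(-0.5), rel=1e-10
        )

    @pytest.mark.parametrize("nu,p", [(2.0, 0.0), (6.59, 0.039), (11.3, 0.2)])
    def test_normalization(self, nu, p):
        model = StahlModel(StahlParams(nu, p))
        integral, _ = quad(lambda x: float(model.density(x)[0]), 0, 60, limit=300)
        assert integral == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("nu,p", [(1.7, 0.1), (6.59, 0.039), (4.0, 0.3)])
    def test_mean_gap_moment_identity(self, nu, p):
        # E[gap] = sum 2^-k * k nu / (2 nu (1-p)) = 1 / (1 - p)
        model = StahlModel(StahlParams(nu, p))
        mean, _ = quad(lambda x: x * float(model.density(x)[0]), 0, 80, limit=300)
        assert mean == pytest.approx(1.0 / (1.0 - p), abs=1e-7)

    def test_survival_complements_cdf(self):
        model = StahlModel(StahlParams(6.59, 0.039))
        xs = np.linspace(0.01, 4.0, 25)
        assert np.allclose(model.survival(xs) + model.cdf(xs), 1.0)

    def test_cdf_integral_closed_form(self):
        model = StahlModel(StahlParams(3.0, 0.1))
        num, _ = quad(lambda x: float(model.cdf(np.array([x]))[0]), 0, 2.0, limit=200)
        assert float(model.cdf_integral(2.0)[0]) == pytest.approx(num, abs=1e-8)

    def test_pure_poisson_branch_rejected(self):
        with pytest.raises(ValueError, match="Poisson"):
            StahlModel(StahlParams(2.0, 1.0))


def _brute_force_loglik(records, params):
    """Independent exhaustive subset-sum implementation (exponential)."""
    model = StahlModel(params)
    p = params.p
    total = 0.0
    for L, ys in records:
        ys = np.asarray(ys, dtype=float)
        n = len(ys)
        lik = 0.0
        for r in range(n + 1):
            for subset in itertools.combinations(range(n), r):
                if r == 0:
                    part = float(model.empty_prob(L)[0])
                else:
                    s = ys[list(subset)]
                    part = float(model.first_point_density(s[0])[0])
                    for a, b in zip(s[:-1], s[1:]):
                        part *= float(model.density(b - a)[0])
                    part *= float(model.survival(L - s[-1])[0])
                lik += p ** (n - r) * part
        total += -p * L + np.log(lik)
    return total


class TestLoglik:
    def test_poisson_reduction_exact(self, rng):
        records = []
        tot = 0.0
        for _ in range(100):
            L = rng.uniform(1, 3)
            xs = np.sort(rng.uniform(0, L, rng.poisson(L)))
            records.append((L, xs))
            tot += L
        for p in (0.0, 0.039, 0.7):
            assert stahl_loglik(records, StahlParams(1.0, p)) == pytest.approx(
                -tot, abs=1e-8
            )

    def test_empty_chromosome_matches_simulated_frequency(self, rng):
        params = StahlParams(6.59, 0.039)
        L = 1.0
        ll = stahl_loglik([(L, np.empty(0))], params)
        theory = np.exp(ll)
        reps = 30_000
        emp = np.mean(
            [len(simulate_stahl_process(params, L, rng)) == 0 for _ in range(reps)]
        )
        mc_sd = np.sqrt(theory * (1 - theory) / reps)
        assert emp == pytest.approx(theory, abs=3.5 * mc_sd)

    @pytest.mark.parametrize("nu,p", [(2.0, 0.1), (6.59, 0.039), (1.3, 0.4)])
    def test_dp_matches_exhaustive_enumeration(self, nu, p, rng):
        params = StahlParams(nu, p)
        records = []
        for _ in range(12):
            L = rng.uniform(1.0, 2.5)
            n = int(rng.integers(0, 5))  # brute force up to n = 4
            records.append((L, np.sort(rng.uniform(0, L, n))))
        assert stahl_loglik(records, params) == pytest.approx(
            _brute_force_loglik(records, params), rel=1e-10
        )

    def test_position_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            stahl_loglik([(1.0, np.array([1.5]))], StahlParams(2.0, 0.1))

    def test_crossover_count_guard(self):
        ys = np.linspace(0.01, 1.9, 30)
        with pytest.raises(ValueError, match="audit"):
            stahl_loglik([(2.0, ys)], StahlParams(2.0, 0.1))

    def test_empty_prob_normalization_grid(self, rng):
        # likelihood-implied empty-interval probability vs simulation on a grid
        reps = 8_000
        for nu in (1.0, 3.0, 6.59):
            for p in (0.0, 0.039, 0.2):
                params = StahlParams(nu, p)
                theory = np.exp(stahl_loglik([(0.8, np.empty(0))], params))
                emp = np.mean(
                    [len(simulate_stahl_process(params, 0.8, rng)) == 0 for _ in range(reps)]
                )
                sd = max(np.sqrt(theory * (1 - theory) / reps), 1e-6)
                assert abs(emp - theory) < 3.5 * sd


@pytest.fixture(scope="module")
def simulated_records():
    rng = np.random.default_rng(101)
    truth = StahlParams(2.0, 0.0)
    lengths = [2.0, 2.0]
    return [
        (L, simulate_stahl_process(truth, L, rng))
        for _ in range(2500)
        for L in lengths
    ]


class TestFitStahl:
    def test_recovery_with_boundary_p(self, simulated_records):
        fit = fit_stahl(simulated_records, **FAST_FIT)
        assert fit.converged
        assert 0.0 <= fit.p_hat <= 1.0
        assert fit.nu_hat == pytest.approx(2.0, rel=0.10)
        assert fit.p_hat < 0.03  # true p = 0: estimate pinned near the boundary

    def test_mle_beats_truth(self, simulated_records):
        fit = fit_stahl(simulated_records, **FAST_FIT)
        ll_truth = stahl_loglik(simulated_records, StahlParams(2.0, 1e-5))
        assert fit.loglik >= ll_truth - 1e-6

    def test_profile_agrees_with_joint(self, simulated_records):
        from scipy.optimize import minimize_scalar

        fit = fit_stahl(simulated_records, **FAST_FIT)
        best = -np.inf
        for p_fixed in (0.001, 0.005, 0.02):
            res = minimize_scalar(
                lambda z: -stahl_loglik(simulated_records, StahlParams(np.exp(z), p_fixed)),
                bounds=(np.log(0.5), np.log(25)),
                method="bounded",
            )
            best = max(best, -res.fun)
        assert abs(best - fit.loglik) < 2.0  # profile grid is coarse in p
        assert fit.loglik >= best - 1e-6

    def test_no_records_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            fit_stahl([])


class TestCarrierLrt:
    def test_duplicated_dataset_gives_zero(self, rng):
        params = StahlParams(5.0, 0.08)
        records = [
            (2.0, simulate_stahl_process(params, 2.0, rng)) for _ in range(400)
        ]
        res = carrier_lrt(records, records, **FAST_FIT)
        assert res.chi2 == pytest.approx(0.0, abs=1e-4)
        assert res.p_value > 0.99

    def test_empty_group_rejected(self, rng):
        records = [(2.0, simulate_stahl_process(StahlParams(5.0, 0.08), 2.0, rng))]
        with pytest.raises(ValueError, match="non-empty"):
            carrier_lrt(records, [])

    def test_detects_simulated_carrier_contrast(self):
        # carrier shift of the magnitude seen in human data, oversampled
        # carriers so the test has power at desk scale
        genome = uniform_rate_genome([2.0, 2.5, 3.0])
        carrier = CarrierEffectSpec.null(StahlParams(4.5, 0.10))
        noncarrier = CarrierEffectSpec.null(StahlParams(6.61, 0.039))
        car = simulate_recombination_cohort(genome, carrier, 1200, 0.0, seed=41)
        non = simulate_recombination_cohort(genome, noncarrier, 1200, 0.0, seed=42)
        res = carrier_lrt(
            records_from_meioses(car, genome),
            records_from_meioses(non, genome),
            **FAST_FIT,
        )
        assert res.p_value < 1e-4


class TestRecordsFromMeioses:
    def test_zero_crossover_meioses_become_empty_records(self, null_spec):
        genome = uniform_rate_genome([0.3])
        cohort = simulate_recombination_cohort(genome, null_spec, 50, 0.0, seed=55)
        records = records_from_meioses(cohort, genome)
        assert len(records) == 50
        n_empty = sum(1 for _, ys in records if len(ys) == 0)
        assert n_empty == sum(1 for m in cohort if m.n_crossovers() == 0)
        total = sum(len(ys) for _, ys in records)
        assert total == sum(m.n_crossovers() for m in cohort)
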