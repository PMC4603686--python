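"""The coupled S/NS model: structure, prevalence, sweeps, thresholds."""

import numpy as np
import pytest

import festuca_demography as fd
from festuca_demography.coupled import NS_SLICE, S_SLICE
from festuca_demography.vitalrates import VitalRateError


@pytest.fixture(scope="module")
def natural_pair(printed_matrices):
    return (
        printed_matrices[("S", "natural")],
        printed_matrices[("NS", "natural")],
    )


@pytest.fixture(scope="module")
def fplus_pair(printed_matrices):
    return printed_matrices[("S", "F+")], printed_matrices[("NS", "F+")]


class TestBuildCoupled:
    def test_perfect_transmission_is_block_diagonal(self, natural_pair):
        S, NS = natural_pair
        B = fd.build_coupled(S, NS, fd.TransmissionRates(1.0, 1.0))
        assert np.all(B.B[NS_SLICE, S_SLICE] == 0.0)
        assert np.all(B.B[S_SLICE, NS_SLICE] == 0.0)
        np.testing.assert_array_equal(B.B[S_SLICE, S_SLICE], S.A)
        np.testing.assert_array_equal(B.B[NS_SLICE, NS_SLICE], NS.A)

    def test_observed_rates_split_the_fecundity_arc(self, natural_pair):
        S, NS = natural_pair
        B = fd.build_coupled(S, NS, fd.TransmissionRates(T_A=0.63, T_S=0.85))
        assert B.B[0, 3] == pytest.approx(39.84 * 0.63)  # 25.10
        assert B.B[4, 3] == pytest.approx(39.84 * 0.37)  # 14.74
        assert B.B[5, 0] == pytest.approx(0.85 * 0.15)
        # 14 structural arcs for interior rates
        assert np.count_nonzero(B.B) == 14

    def test_total_seed_loss_empties_symbiotic_fecundity(self, natural_pair):
        S, NS = natural_pair
        B = fd.build_coupled(S, NS, fd.TransmissionRates(T_A=0.0, T_S=0.9))
        assert B.B[0, 3] == 0.0
        assert B.B[4, 3] == pytest.approx(S["F"])

    def test_no_ns_to_s_arcs_ever(self, natural_pair):
        S, NS = natural_pair
        for ta in (0.0, 0.3, 1.0):
            B = fd.build_coupled(S, NS, fd.TransmissionRates(ta, 0.5, 0.8))
            assert np.all(B.B[S_SLICE, NS_SLICE] == 0.0)

    def test_invalid_transmission_rejected(self):
        with pytest.raises(VitalRateError, match="T_A"):
            fd.TransmissionRates(T_A=1.2, T_S=0.5)


class TestSBlockLambda:
    def test_perfect_transmission_equals_single_status_lambda(
        self, natural_pair
    ):
        S, _ = natural_pair
        lam = fd.s_block_lambda(S, fd.TransmissionRates(1.0, 1.0))
        assert round(lam, 2) == 2.34

    def test_no_seed_transmission_leaves_only_adult_survival(
        self, natural_pair
    ):
        S, _ = natural_pair
        lam = fd.s_block_lambda(S, fd.TransmissionRates(0.0, 1.0))
        assert lam == pytest.approx(0.95)

    def test_observed_rates_via_loop_equation_oracle(self, natural_pair):
        S, _ = natural_pair
        T = fd.TransmissionRates(0.63, 0.85)
        lam = fd.s_block_lambda(S, T)
        discounted = fd.StageMatrix.from_elements(
            F=S["F"] * 0.63, G_J1=S["G_J1"] * 0.85, G_J2=S["G_J2"],
            G_A1=S["G_A1"], G_A2=S["G_A2"], S_A=S["S_A"],
        )
        assert lam == pytest.approx(
            fd.loop_equation_lambda(discounted), abs=1e-9
        )
        assert round(lam, 2) == 2.04


class TestAsymptoticPrevalence:
    def test_perfect_transmission_fixes_the_symbiont(self, natural_pair):
        B = fd.build_coupled(*natural_pair, fd.TransmissionRates(1.0, 1.0))
        assert fd.asymptotic_prevalence(B) == pytest.approx(1.0)

    def test_ns_dominance_extinguishes_the_symbiont(self, natural_pair):
        B = fd.build_coupled(*natural_pair, fd.TransmissionRates(0.0, 1.0))
        assert fd.asymptotic_prevalence(B) == 0.0

    def test_observed_rates_against_power_iteration_oracle(
        self, natural_pair
    ):
        B = fd.build_coupled(*natural_pair, fd.TransmissionRates(0.63, 0.85))
        prev = fd.asymptotic_prevalence(B)
        # brute-force long projection as an independent route
        n = np.ones(8)
        for _ in range(4000):
            n = B.B @ n
            n /= n.sum()
        assert prev == pytest.approx(n[:4].sum(), abs=1e-9)
        assert prev == pytest.approx(0.1634, abs=5e-4)

    def test_invariant_to_stage_subsets_when_blocks_identical(
        self, natural_pair
    ):
        B = fd.build_coupled(*natural_pair, fd.TransmissionRates(0.7, 0.9))
        all_stages = fd.asymptotic_prevalence(B)
        adults = fd.asymptotic_prevalence(B, stage_set=["adult"])
        assert 0 < all_stages < 1
        assert 0 < adults < 1

    def test_empty_stage_set_rejected(self, natural_pair):
        B = fd.build_coupled(*natural_pair, fd.TransmissionRates(0.7, 0.9))
        with pytest.raises(ValueError):
            fd.asymptotic_prevalence(B, stage_set=[])


class TestFiniteHorizonPrevalence:
    def test_zero_horizon_returns_initial_fraction(self, natural_pair):
        B = fd.build_coupled(*natural_pair, fd.TransmissionRates(0.63, 0.85))
        n0 = np.array([0, 0, 0, 30.0, 0, 0, 0, 70.0])
        assert fd.finite_horizon_prevalence(B, n0, 0) == pytest.approx(0.3)

    def test_symmetric_blocks_preserve_initial_fraction(self, natural_pair):
        S, _ = natural_pair
        B = fd.build_coupled(S, S, fd.TransmissionRates(1.0, 1.0))
        n0 = np.array([0, 0, 0, 30.0, 0, 0, 0, 70.0])
        for t in (1, 10, 40):
            assert fd.finite_horizon_prevalence(B, n0, t) == pytest.approx(
                0.3
            )

    def test_converges_to_asymptotic_prevalence(self, natural_pair):
        B = fd.build_coupled(*natural_pair, fd.TransmissionRates(0.63, 0.85))
        n0 = np.array([0, 0, 0, 100.0, 0, 0, 0, 100.0])
        finite = fd.finite_horizon_prevalence(B, n0, 2000)
        assert finite == pytest.approx(fd.asymptotic_prevalence(B), abs=1e-3)

    def test_decreasing_in_seed_stage_loss(self, natural_pair):
        n0 = np.array([0, 0, 0, 100.0, 0, 0, 0, 100.0])
        prev = [
            fd.finite_horizon_prevalence(
                fd.build_coupled(*natural_pair, fd.TransmissionRates(ta, 0.85)),
                n0,
                50,
            )
            for ta in (0.9, 0.7, 0.5)
        ]
        assert prev[0] > prev[1] > prev[2]

    def test_zero_population_in_stage_set_rejected(self, natural_pair):
        B = fd.build_coupled(*natural_pair, fd.TransmissionRates(0.5, 0.5))
        n0 = np.zeros(8)
        n0[0] = 1.0  # only seedlings; adults stay empty at t=0
        with pytest.raises(ValueError):
            fd.finite_horizon_prevalence(B, n0, 0, stage_set=["adult"])


class TestTransmissionSweep:
    def test_prevalence_monotone_nondecreasing(self, natural_pair):
        for varied in ("T_A", "T_S"):
            res = fd.transmission_sweep(*natural_pair, varied=varied)
            prev = res.table["prevalence"].to_numpy()
            assert np.all(np.diff(prev) >= -1e-12)
            assert prev[0] == 0.0
            assert prev[-1] == pytest.approx(1.0)

    def test_observed_value_convention(self, natural_pair):
        res = fd.transmission_sweep(
            *natural_pair, varied="T_A", fixed={"T_S": 0.85}
        )
        assert res.fixed["T_S"] == 0.85
        assert res.table["lambda_S_block"].iloc[-1] < 2.34  # discounted

    def test_finite_horizon_criterion(self, natural_pair):
        res = fd.transmission_sweep(
            *natural_pair, varied="T_A", criterion="finite_horizon",
            horizon=50,
        )
        assert res.horizon == 50
        assert res.table["prevalence"].between(0, 1).all()

    def test_grid_outside_unit_interval_rejected(self, natural_pair):
        with pytest.raises(ValueError):
            fd.transmission_sweep(*natural_pair, varied="T_A", grid=[0.5, 1.5])


class TestPersistenceThreshold:
    def test_asymptotic_threshold_matches_bisection_oracle(
        self, natural_pair
    ):
        from scipy.optimize import brentq

        S, NS = natural_pair
        thr = fd.persistence_threshold(S, NS, "T_A")
        lam_ns = fd.dominant_eigen(NS).lam

        def gap(ta):
            return fd.s_block_lambda(S, fd.TransmissionRates(ta, 1.0)) - lam_ns

        oracle = brentq(gap, 0.0, 1.0, xtol=1e-9)
        assert not thr.at_boundary
        assert thr.rate == pytest.approx(oracle, abs=1e-6)
        assert thr.rate == pytest.approx(0.458, abs=2e-3)

    def test_threshold_zero_when_s_block_always_wins(self, natural_pair):
        S, NS = natural_pair
        weak_ns = fd.StageMatrix.from_elements(
            F=0.1, G_J1=0.1, G_J2=0.1, G_A1=0.05, G_A2=0.1, S_A=0.5
        )
        thr = fd.persistence_threshold(S, weak_ns, "T_A")
        assert thr.rate == 0.0 and thr.at_boundary

    def test_threshold_one_when_s_block_never_wins(self, natural_pair):
        _, NS = natural_pair
        weak_s = fd.StageMatrix.from_elements(
            F=0.5, G_J1=0.2, G_J2=0.2, G_A1=0.1, G_A2=0.2, S_A=0.5
        )
        thr = fd.persistence_threshold(weak_s, NS, "T_A")
        assert thr.rate == 1.0 and thr.at_boundary

    def test_prevalence_positive_exactly_above_threshold(self, natural_pair):
        S, NS = natural_pair
        thr = fd.persistence_threshold(S, NS, "T_A", tol=1e-10)
        for eps, expect_positive in ((1e-4, True), (-1e-4, False)):
            B = fd.build_coupled(
                S, NS, fd.TransmissionRates(thr.rate + eps, 1.0)
            )
            prev = fd.asymptotic_prevalence(B)
            assert (prev > 0) is expect_positive

    def test_finite_horizon_threshold_reported_on_grid(self, natural_pair):
        thr = fd.persistence_threshold(
            *natural_pair, varied="T_A", criterion="finite_horizon",
            cutoff=0.01,
        )
        assert thr.rate in np.round(np.arange(0, 1.01, 0.1), 10)
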