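import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.special import comb

from kaikinetics import (
    ModelSpec,
    RateConstants,
    atpase_activity,
    bound_fraction,
    build_rate_matrix,
    build_state_space,
    initial_condition_with_kaib,
    integrate,
    steady_state,
)

rates_strategy = st.builds(
    RateConstants,
    k_h=st.floats(0.05, 3.0),
    k_h_star=st.floats(0.05, 3.0),
    k_e=st.floats(0.05, 3.0),
    k_e_star=st.floats(0.0, 1.0),
)


class TestStateSpace:
    def test_model6_only_fully_adp_state_bound(self):
        space = build_state_space(ModelSpec(threshold_n=6))
        assert len(space) == 7
        assert list(space.atp_counts) == [6, 5, 4, 3, 2, 1, 0]
        assert list(space.bound_mask) == [False] * 6 + [True]

    def test_model4_bound_states_are_low_atp(self):
        space = build_state_space(ModelSpec(threshold_n=4))
        # ADP >= 4 means ATP <= 2
        assert [s.atp_count for s in space.states if s.bound] == [2, 1, 0]
        assert [s.adp_count for s in space.states if s.bound] == [4, 5, 6]

    @pytest.mark.parametrize("n", range(1, 7))
    def test_without_kaib_no_state_is_bound(self, n):
        space = build_state_space(ModelSpec(threshold_n=n, kaib_present=False))
        assert not space.bound_mask.any()

    def test_monomer_two_states(self):
        space = build_state_space(ModelSpec(kind="monomer"))
        assert len(space) == 2
        assert list(space.bound_mask) == [False, True]
        assert [s.adp_count for s in space.states] == [0, 1]
        no_b = build_state_space(ModelSpec(kind="monomer", kaib_present=False))
        assert not no_b.bound_mask.any()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(threshold_n=7)
        with pytest.raises(ValueError):
            ModelSpec(kind="dimer")
        with pytest.raises(ValueError):
            ModelSpec(dead_sites_m=9)
        with pytest.raises(ValueError):
            RateConstants(k_h=-1, k_h_star=1, k_e=1, k_e_star=1)


class TestRateMatrix:
    def test_model6_transitions(self, rc):
        M = build_rate_matrix(rc, ModelSpec(threshold_n=6))
        # last unbound (atp=1, index 5) -> bound (atp=0, index 6) by hydrolysis k_h
        assert M[6, 5] == pytest.approx(rc.k_h)
        # bound state leaves by exchange at 6 k_e*
        assert M[5, 6] == pytest.approx(6 * rc.k_e_star)
        # top of chain: 6 k_h down, 1 k_e up
        assert M[1, 0] == pytest.approx(6 * rc.k_h)
        assert M[0, 1] == pytest.approx(rc.k_e)

    def test_model4_transitions(self, rc):
        M = build_rate_matrix(rc, ModelSpec(threshold_n=4))
        i = {k: 6 - k for k in range(7)}  # atp count -> index
        # crossing into the first bound state keeps the unstarred constant
        assert M[i[2], i[3]] == pytest.approx(3 * rc.k_h)
        assert M[i[3], i[2]] == pytest.approx(4 * rc.k_e_star)
        # within the bound block hydrolysis uses k_h*
        assert M[i[1], i[2]] == pytest.approx(2 * rc.k_h_star)

    def test_all_dead_sites_give_triangular_matrix(self, rc):
        M = build_rate_matrix(rc, ModelSpec(threshold_n=6, dead_sites_m=6))
        assert np.all(np.tril(M, -1) == 0)  # no hydrolysis: no downward flux

    def test_monomer_matrices(self, rc):
        M = build_rate_matrix(rc, ModelSpec(kind="monomer", kaib_present=False))
        assert M[1, 0] == pytest.approx(rc.k_h)
        assert M[0, 1] == pytest.approx(rc.k_e)
        Mb = build_rate_matrix(rc, ModelSpec(kind="monomer", kaib_present=True))
        assert Mb[0, 1] == pytest.approx(rc.k_e_star)

    @given(rc=rates_strategy, n=st.integers(1, 6), m=st.integers(0, 6), kaib=st.booleans())
    def test_conservation_structure(self, rc, n, m, kaib):
        """Columns sum to zero and off-diagonal rates are non-negative."""
        M = build_rate_matrix(rc, ModelSpec(threshold_n=n, dead_sites_m=m, kaib_present=kaib))
        assert np.allclose(M.sum(axis=0), 0.0, atol=1e-12)
        off = M - np.diag(np.diag(M))
        assert np.all(off >= 0)


class TestSteadyState:
    @given(rc=rates_strategy)
    def test_no_kaib_steady_state_is_binomial_per_site(self, rc):
        """Independent sites: [C6k] = C(6,k) p^k (1-p)^(6-k), p = ke/(kh+ke)."""
        M = build_rate_matrix(rc, ModelSpec(threshold_n=6, kaib_present=False))
        ss = steady_state(M)
        p = rc.k_e / (rc.k_h + rc.k_e)
        expect = np.array([comb(6, k) * p**k * (1 - p) ** (6 - k) for k in range(6, -1, -1)])
        assert np.abs(ss - expect).max() < 1e-10

    def test_equal_rates_give_uniform_site_occupancy(self, rc):
        M = build_rate_matrix(
            rc.replace(k_e=rc.k_h), ModelSpec(threshold_n=6, kaib_present=False)
        )
        ss = steady_state(M)
        expect = np.array([comb(6, k) / 64 for k in range(6, -1, -1)])
        assert np.abs(ss - expect).max() < 1e-12

    def test_no_exchange_absorbs_at_zero_atp(self, rc):
        M = build_rate_matrix(
            rc.replace(k_e=0.0, k_e_star=0.0), ModelSpec(threshold_n=6, kaib_present=False)
        )
        ss = steady_state(M)
        assert ss[-1] == pytest.approx(1.0, abs=1e-12)

    def test_monomer_balance(self, rc):
        M = build_rate_matrix(rc, ModelSpec(kind="monomer", kaib_present=False))
        ss = steady_state(M)
        assert ss[1] == pytest.approx(rc.k_h / (rc.k_h + rc.k_e), abs=1e-12)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="ambiguous|closed"):
            steady_state(np.zeros((3, 3)))


class TestInitialCondition:
    def test_model6_relabels_only_the_fully_adp_state(self, rc, model6):
        no_kaib = steady_state(build_rate_matrix(rc, model6.replace(kaib_present=False)))
        x0 = initial_condition_with_kaib(no_kaib, model6)
        assert np.array_equal(x0, no_kaib)  # same populations, new bound labels
        space = build_state_space(model6)
        assert bound_fraction(x0, space) == pytest.approx(no_kaib[-1])

    def test_uniform_input_model4_binds_three_sevenths(self, model4):
        x = np.full(7, 1 / 7)
        x0 = initial_condition_with_kaib(x, model4)
        space = build_state_space(model4)
        assert bound_fraction(x0, space) == pytest.approx(3 / 7)
        assert x0.sum() == pytest.approx(1.0)


class TestIntegrate:
    def test_time_zero_is_identity_and_mass_conserved(self, rc, model6):
        M = build_rate_matrix(rc, model6)
        space = build_state_space(model6)
        x0 = np.full(7, 1 / 7)
        tc = integrate(M, x0, [0.0, 1.0, 5.0, 24.0], space=space, rc=rc)
        assert np.array_equal(tc.populations[0], x0)
        assert np.abs(tc.populations.sum(axis=1) - 1.0).max() < 1e-12

    def test_long_time_limit_is_steady_state(self, rc, model6):
        M = build_rate_matrix(rc, model6)
        x0 = np.zeros(7)
        x0[0] = 1.0
        ss = steady_state(M)
        tc = integrate(M, x0, [1000.0])
        assert np.abs(tc.populations[-1] - ss).max() < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_adaptive_ode_oracle(self, seed):
        """Matrix-exponential propagation vs an independent LSODA solve."""
        rng = np.random.default_rng(seed)
        rc = RateConstants(*rng.uniform(0.05, 2.0, size=4))
        spec = ModelSpec(threshold_n=int(rng.integers(1, 7)))
        M = build_rate_matrix(rc, spec)
        x0 = rng.dirichlet(np.ones(7))
        times = np.linspace(0.0, 24.0, 9)[1:]
        tc = integrate(M, x0, times)
        sol = solve_ivp(
            lambda t, x: M @ x, (0, times[-1]), x0, t_eval=times,
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        assert np.abs(tc.populations - sol.y.T).max() < 1e-8

    def test_bad_time_grids_rejected(self, rc, model6):
        M = build_rate_matrix(rc, model6)
        x0 = np.full(7, 1 / 7)
        with pytest.raises(ValueError):
            integrate(M, x0, [-1.0, 1.0])
        with pytest.raises(ValueError):
            integrate(M, x0, [0.0, 2.0, 1.0])


class TestObservables:
    def test_bound_fraction_limits(self, model6):
        space = build_state_space(model6)
        all_unbound = np.array([1, 0, 0, 0, 0, 0, 0.0])
        all_bound = np.array([0, 0, 0, 0, 0, 0, 1.0])
        assert bound_fraction(all_unbound, space) == 0.0
        assert bound_fraction(all_bound, space) == 1.0

    def test_absorbing_bound_state_binds_everything(self, rc, model6):
        M = build_rate_matrix(rc.replace(k_e_star=0.0), model6)
        ss = steady_state(M)
        assert bound_fraction(ss, build_state_space(model6)) == pytest.approx(1.0)

    def test_atpase_extremes(self, model6):
        space = build_state_space(model6)
        rc = RateConstants(k_h=0.1, k_h_star=0.1, k_e=1.0, k_e_star=0.0)
        on_c60 = np.array([0, 0, 0, 0, 0, 0, 1.0])
        assert atpase_activity(on_c60, rc, space) == 0.0  # no ATP left
        on_c66 = np.array([1.0, 0, 0, 0, 0, 0, 0])
        # 6 sites at k_h = 0.1/h -> 24 * 0.1 per monomer per day
        assert atpase_activity(on_c66, rc, space) == pytest.approx(2.4)

    def test_dead_sites_lower_activity(self, rc, model6):
        space = build_state_space(model6)
        x = np.full(7, 1 / 7)
        a0 = atpase_activity(x, rc, space, dead_sites_m=0)
        a3 = atpase_activity(x, rc, space, dead_sites_m=3)
        assert a3 < a0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_model6_activity_decreases_during_binding(self, seed):
        """KaiB binding shifts nucleotide occupancy to ADP: activity falls."""
        rng = np.random.default_rng(seed)
        rc = RateConstants(
            k_h=rng.uniform(0.2, 1.5),
            k_h_star=rng.uniform(0.2, 1.5),
            k_e=rng.uniform(0.3, 2.0),
            k_e_star=0.0,
        )
        rc = rc.replace(k_e_star=rng.uniform(0.0, 0.9) * rc.k_e)
        spec = ModelSpec(threshold_n=6)
        no_kaib = steady_state(build_rate_matrix(rc, spec.replace(kaib_present=False)))
        x0 = initial_condition_with_kaib(no_kaib, spec)
        M = build_rate_matrix(rc, spec)
        tc = integrate(M, x0, np.linspace(0.01, 48, 120), space=build_state_space(spec), rc=rc)
        assert np.all(np.diff(tc.atpase_activity) <= 1e-12)
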