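"""Semi-discrete Nicholson-Bailey: season ODE, map, equilibrium, Jury."""

import math

import numpy as np
import pytest

from hpstab.attack_rates import AttackRateModel
from hpstab.core import PreconditionError, StabilityStatus
from hpstab.discrete import (
    DiscreteParams,
    MapState,
    SeasonSpec,
    critical_fp,
    jury_slacks,
    nb_classify_trajectory,
    nb_equilibrium,
    nb_generalized_map,
    nb_iterate,
    nb_jacobian,
    nb_phenomenological_map,
    nb_stability,
    season_integrate,
)


def monomial(fh, fp, c=1.0):
    return AttackRateModel("monomial", {"c": c, "a": fh, "b": fp})


CONSTANT_1 = AttackRateModel("constant", {"c": 1.0})


class TestSeasonIntegration:
    def test_constant_attack_recovers_classical_escape_fraction(self):
        """With constant rate c and no mortality the surviving fraction is
        exp(-c*P): the classical discrete map emerges mechanically."""
        for c, H, P, R in [(1.0, 0.6, 0.8, 2.0), (0.37, 1.9, 0.25, 5.0)]:
            spec = SeasonSpec(AttackRateModel("constant", {"c": c}))
            L, I = season_integrate(spec, (H, P), R)
            assert L == pytest.approx(R * H * math.exp(-c * P), rel=1e-8)
            assert I == pytest.approx(R * H * (1 - math.exp(-c * P)), rel=1e-8)

    def test_within_season_conservation(self):
        """Zero mortalities: L + I = R*H at every time in the season."""
        spec = SeasonSpec(monomial(0.7, -0.3))
        tau, P, L, I = season_integrate(spec, (1.2, 0.9), 3.0, full_output=True)
        assert np.max(np.abs((L + I) / (3.0 * 1.2) - 1.0)) < 1e-9
        assert np.all(P == pytest.approx(0.9, rel=1e-12))

    def test_no_parasitoids_means_pure_mortality(self):
        spec = SeasonSpec(CONSTANT_1, gammaL=0.4)
        L, I = season_integrate(spec, (2.0, 0.0), 2.5)
        assert L == pytest.approx(2.5 * 2.0 * math.exp(-0.4), rel=1e-8)
        assert I == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_map_matches_integration_sweep(self):
        """The year-to-year map must equal brute-force integration of the
        within-season dynamics to 1e-8 relative (zero mortality, T=1)."""
        rng = np.random.default_rng(20220412)
        done = 0
        while done < 25:
            fh = rng.uniform(-0.8, 2.0)
            fp = rng.uniform(-0.8, 1.5)
            R = rng.uniform(1.2, 10.0)
            H = rng.uniform(0.1, 2.0)
            P = rng.uniform(0.1, 2.0)
            state = MapState(H, P)
            Hn, Pn = nb_generalized_map(state, (fh, fp), R)
            if Hn < 1e-6:  # depletion edge: comparison dominated by atol
                continue
            spec = SeasonSpec(monomial(fh, fp))
            L, I = season_integrate(spec, state, R)
            assert Hn == pytest.approx(L, rel=1e-8)
            assert Pn == pytest.approx(I, rel=1e-8)
            done += 1


class TestGeneralizedMap:
    def test_zero_sensitivities_give_classical_map(self):
        H, P, R = 0.8, 1.3, 2.0
        Hn, Pn = nb_generalized_map((H, P), (0.0, 0.0), R)
        assert Hn == pytest.approx(R * H * math.exp(-P), rel=1e-12)
        assert Pn == pytest.approx(R * H * (1 - math.exp(-P)), rel=1e-12)

    def test_known_fixed_point(self):
        s = 1.0 / math.sqrt(2.0)
        Hn, Pn = nb_generalized_map((s, s), (1.0, 0.0), 2.0)
        assert (Hn, Pn) == pytest.approx((s, s), rel=1e-12)

    def test_extinction_is_absorbing(self):
        assert tuple(nb_generalized_map((0.0, 1.0), (0.5, 0.2), 2.0)) == (0.0, 0.0)

    def test_host_depletion_branch(self):
        """f_h < 0 with an overwhelming parasitoid density parasitises
        every larva within the season."""
        Hn, Pn = nb_generalized_map((1.0, 50.0), (-0.5, 0.0), 2.0)
        assert Hn == 0.0
        assert Pn == 2.0
        # oracle: the within-season larval density indeed hits zero
        L, I = season_integrate(SeasonSpec(monomial(-0.5, 0.0)), (1.0, 50.0), 2.0)
        assert L < 1e-6
        assert I == pytest.approx(2.0, rel=1e-5)

    def test_continuity_across_the_exponential_switch(self):
        for fh in (1e-9, -1e-9, 2e-8, -2e-8):
            a = nb_generalized_map((0.7, 1.1), (fh, 0.3), 3.0)
            b = nb_generalized_map((0.7, 1.1), (0.0, 0.3), 3.0)
            assert a.H == pytest.approx(b.H, rel=1e-6)

    def test_phenomenological_map_substitutes_attack_rate(self):
        m = AttackRateModel("type2", {"c1": 1.0, "Th": 0.5})
        H, P, R = 0.9, 1.1, 2.0
        f = m(H, P)
        Hn, Pn = nb_phenomenological_map((H, P), m, R)
        assert Hn == pytest.approx(R * H * math.exp(-f * P), rel=1e-12)
        assert Hn + Pn == pytest.approx(R * H, rel=1e-12)


class TestEquilibrium:
    def test_known_equilibrium(self):
        eq = nb_equilibrium((1.0, 0.0), 2.0)
        assert eq.hstar == pytest.approx(1 / math.sqrt(2), rel=1e-10)
        assert eq.pstar == pytest.approx(1 / math.sqrt(2), rel=1e-10)

    def test_classical_limit(self):
        """f_h -> 0, f_p = 0 recovers H* = ln R/(R-1), P* = ln R."""
        for R in (2.0, 5.0):
            eq = nb_equilibrium((1e-12, 0.0), R)
            assert eq.hstar == pytest.approx(math.log(R) / (R - 1), rel=1e-9)
            assert eq.pstar == pytest.approx(math.log(R), rel=1e-9)

    def test_parasitoid_host_ratio_is_R_minus_1(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            fh = rng.uniform(-0.9, 2.0)
            fp = rng.uniform(-0.9, 2.0)
            R = rng.uniform(1.1, 20.0)
            if 1 + fh + fp <= 0.01:
                continue
            eq = nb_equilibrium((fh, fp), R)
            assert eq.pstar / eq.hstar == pytest.approx(R - 1, rel=1e-10)
            Hn, Pn = nb_generalized_map(tuple(eq), (fh, fp), R)
            assert Hn == pytest.approx(eq.hstar, rel=1e-10)

    def test_precondition_errors_name_the_violation(self):
        with pytest.raises(PreconditionError, match="R > 1"):
            nb_equilibrium((0.5, 0.0), 0.9)
        with pytest.raises(PreconditionError, match="1 \\+ fh \\+ fp"):
            nb_equilibrium((-0.5, -0.6), 2.0)


class TestJacobian:
    def test_classical_model_spectral_radius_exceeds_one(self):
        lam = np.linalg.eigvals(nb_jacobian((1e-14, 0.0), 2.0))
        assert np.all(np.abs(lam) > 1.0)

    @pytest.mark.parametrize("R", [1.5, 2.0, 8.0])
    def test_type3_threshold_is_marginal(self, R):
        lam = np.linalg.eigvals(nb_jacobian((1.0, 0.0), R))
        assert np.max(np.abs(lam)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_central_difference_jacobian_of_the_map(self):
        """100 random admissible draws against a numeric Jacobian."""
        rng = np.random.default_rng(20220412)
        done = 0
        while done < 100:
            fh = rng.uniform(-0.9, 2.0)
            fp = rng.uniform(-0.9, 2.0)
            R = rng.uniform(1.1, 20.0)
            if 1 + fh + fp <= 0.05:
                continue
            eq = nb_equilibrium((fh, fp), R)
            d = 1e-6
            J = np.zeros((2, 2))
            for j, (dH, dP) in enumerate(
                [(d * eq.hstar, 0.0), (0.0, d * eq.pstar)]
            ):
                up = nb_generalized_map((eq.hstar + dH, eq.pstar + dP), (fh, fp), R)
                dn = nb_generalized_map((eq.hstar - dH, eq.pstar - dP), (fh, fp), R)
                J[:, j] = [(up.H - dn.H) / (2 * (dH + dP)),
                           (up.P - dn.P) / (2 * (dH + dP))]
            A = nb_jacobian((fh, fp), R)
            assert np.allclose(A, J, rtol=1e-6, atol=1e-6)
            done += 1


class TestStability:
    def test_classical_model_is_unstable(self):
        v = nb_stability((0.0, 0.0), 2.0)
        assert v.status is StabilityStatus.UNSTABLE
        assert v.details["spectral_radius"] > 1

    @pytest.mark.parametrize(
        "fh, fp, expected",
        [
            (0.5, -0.3, StabilityStatus.STABLE),
            (0.0, -0.2, StabilityStatus.UNSTABLE),
            (0.5, -0.2, StabilityStatus.STABLE),
        ],
    )
    def test_interference_and_acceleration_combine(self, fh, fp, expected):
        """Moderate interference or moderate acceleration alone fail at
        R = 2, but their combination stabilizes the map."""
        v = nb_stability((fh, fp), 2.0)
        assert v.status is expected
        assert v.details["jury_status"] is expected

    def test_shared_necessary_condition(self):
        for R in (1.5, 2.0, 50.0):
            v = nb_stability((-0.5, -0.6), R)
            assert v.status is StabilityStatus.UNSTABLE

    def test_boundary_at_fh_zero_matches_interference_limit(self):
        for R in (2.0, 5.0, 20.0):
            expected = -(R * math.log(R) + 1 - R) / (R * math.log(R))
            assert critical_fp(0.0, R) == pytest.approx(expected, rel=1e-12)
            assert critical_fp(1e-8, R) == pytest.approx(expected, rel=1e-6)
            assert critical_fp(-1e-8, R) == pytest.approx(expected, rel=1e-6)

    def test_jury_third_condition_always_holds_on_admissible_grid(self):
        """1 + Tr + Det > 0 at every admissible lattice point scanned."""
        fh, fp = np.meshgrid(
            np.linspace(-0.99, 3.0, 120), np.linspace(-1.0, 1.5, 120)
        )
        for R in (1.1, 2.0, 20.0, 1e3):
            _, _, j3 = jury_slacks(fh, fp, R)
            assert np.all(j3 > 0)

    def test_analytic_agrees_with_jury_on_sweep(self):
        rng = np.random.default_rng(20220412)
        checked = 0
        while checked < 200:
            fh = rng.uniform(-1.0, 2.0)
            fp = rng.uniform(-1.0, 2.0)
            R = rng.uniform(1.05, 50.0)
            v = nb_stability((fh, fp), R)
            if min(abs(v.cond1_slack), abs(v.cond2_slack)) <= 0.05:
                continue
            checked += 1
            assert v.status == v.details["jury_status"]
            if v.cond2_slack > 0:
                assert v.status == v.details["eigen_status"]


class TestIteration:
    def test_fixed_point_stays_fixed(self):
        eq = nb_equilibrium((0.5, -0.3), 2.0)
        traj = nb_iterate(tuple(eq), (0.5, -0.3), 2.0, 50)
        assert np.max(np.abs(traj.host / eq.hstar - 1)) < 1e-10

    def test_classical_map_diverges_in_oscillations(self):
        eq = nb_equilibrium((1e-12, 0.0), 2.0)
        traj = nb_iterate(
            (eq.hstar * 1.001, eq.pstar * 1.001), (0.0, 0.0), 2.0, 120
        )
        assert nb_classify_trajectory(traj, eq) == "diverging"
        # oscillatory approach: host crosses its equilibrium many times
        crossings = np.count_nonzero(np.diff(np.sign(traj.host[:60] - eq.hstar)))
        assert crossings > 5

    def test_strong_acceleration_damps(self):
        eq = nb_equilibrium((1.5, 0.0), 2.0)
        traj = nb_iterate(
            (eq.hstar * 1.001, eq.pstar * 1.001), (1.5, 0.0), 2.0, 200
        )
        assert nb_classify_trajectory(traj, eq) == "damped"

    def test_divergence_is_capped_at_the_ceiling(self):
        eq = nb_equilibrium((0.0, 0.5), 2.0)
        traj = nb_iterate(
            (eq.hstar * 1.01, eq.pstar * 1.01), (0.0, 0.5), 2.0, 400
        )
        ceiling = 1e12 * eq.hstar
        assert np.max(traj.host) <= ceiling
        assert np.max(traj.parasitoid) <= ceiling
        assert nb_classify_trajectory(traj, eq) == "diverging"

    def test_classification_matches_stability_away_from_boundary(self):
        rng = np.random.default_rng(7)
        label = {
            StabilityStatus.STABLE: "damped",
            StabilityStatus.UNSTABLE: "diverging",
        }
        done = 0
        while done < 20:
            fh = rng.uniform(-0.9, 2.0)
            fp = rng.uniform(-0.9, 1.0)
            R = rng.uniform(1.2, 10.0)
            v = nb_stability((fh, fp), R)
            if min(abs(v.cond1_slack), abs(v.cond2_slack)) <= 0.1:
                continue
            if v.cond2_slack < 0:
                continue
            eq = nb_equilibrium((fh, fp), R)
            traj = nb_iterate(
                (eq.hstar * 1.001, eq.pstar * 1.001), (fh, fp), R, 400
            )
            assert nb_classify_trajectory(traj, eq) == label[v.status]
            done += 1


class TestParams:
    def test_R_must_exceed_one(self):
        with pytest.raises(PreconditionError):
            DiscreteParams(1.0)

    def test_negative_state_rejected(self):
        with pytest.raises(PreconditionError):
            MapState(-0.1, 1.0)

    def test_season_spec_validation(self):
        with pytest.raises(PreconditionError):
            SeasonSpec(AttackRateModel("type2", {"c1": 1.0, "Th": 1.0}))
        with pytest.raises(PreconditionError):
            SeasonSpec(CONSTANT_1, gammaL=-0.5)
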