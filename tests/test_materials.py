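"""Constitutive laws and score-driven parameter maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvmech.materials import (
    ActiveLaw,
    GlobalParameters,
    PassiveLaw,
    ScoreMap17,
    SectorParameters,
    StrainTensorFiberFrame,
    active_stress,
    contractility_map,
    passive_stiffness_map,
    passive_stress,
    strain_energy,
)


def scoremap(lge_val, sp_val):
    return ScoreMap17(np.full(17, lge_val), np.full(17, sp_val))


class TestParameterMaps:
    @pytest.mark.parametrize(
        "C_H, lge, expected",
        [
            (1.0, 4, 10.0),        # transmural infarct: tenfold stiffening
            (0.7, 0, 0.7),         # healthy sector keeps C_H
            (0.192, 2, 1.056),     # mid-range hand evaluation
        ],
    )
    def test_stiffness_map_values(self, C_H, lge, expected):
        C_n = passive_stiffness_map(C_H, scoremap(lge, 0))
        assert C_n == pytest.approx(np.full(17, expected))

    @pytest.mark.parametrize(
        "Tmax_H, alpha, lge, sp, expected",
        [
            (300.0, 0.7, 4, 2, 0.0),       # infarcted sector loses contraction
            (300.0, 0.0, 0, 3, 300.0),     # alpha = 0 removes the SP effect
            (336.8, 0.44, 0, 3, 188.608),  # hand evaluation
        ],
    )
    def test_contractility_map_values(self, Tmax_H, alpha, lge, sp, expected):
        Tn = contractility_map(Tmax_H, alpha, scoremap(lge, sp))
        assert Tn == pytest.approx(np.full(17, expected))

    def test_score_and_alpha_validation(self):
        with pytest.raises(ValueError):
            ScoreMap17(np.full(17, 5), np.zeros(17, int))
        with pytest.raises(ValueError):
            ScoreMap17(np.zeros(17, int), np.full(17, 4))
        with pytest.raises(ValueError):
            contractility_map(300.0, 1.2, scoremap(0, 0))
        with pytest.raises(ValueError):
            GlobalParameters(C_H=0.2, Tmax_H=300.0, alpha=-0.1)

    def test_alpha_zero_identity_over_all_score_combinations(self):
        # with alpha = 0 the SP score must drop out exactly
        for lge in range(5):
            for sp in range(4):
                Tn = contractility_map(300.0, 0.0, scoremap(lge, sp))
                ref = contractility_map(300.0, 0.0, scoremap(lge, 0))
                assert (Tn == ref).all()

    @given(
        lge=st.integers(0, 4), sp=st.integers(0, 3),
        alpha=st.floats(0.0, 1.0), d_alpha=st.floats(0.0, 0.5),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_map_monotonicity(self, lge, sp, alpha, d_alpha):
        s = scoremap(lge, sp)
        assert (passive_stiffness_map(1.0, s) >= 1.0).all()
        if lge < 4:
            up = scoremap(lge + 1, sp)
            assert passive_stiffness_map(1.0, up)[0] > passive_stiffness_map(1.0, s)[0]
            assert contractility_map(300.0, alpha, up)[0] \
                <= contractility_map(300.0, alpha, s)[0]
        if sp < 3:
            assert contractility_map(300.0, alpha, scoremap(lge, sp + 1))[0] \
                <= contractility_map(300.0, alpha, s)[0]
        a2 = min(alpha + d_alpha, 1.0)
        assert contractility_map(300.0, a2, s)[0] <= contractility_map(300.0, alpha, s)[0]

    def test_sector_parameters_respect_bounds(self):
        params = GlobalParameters(0.2, 300.0, 0.6)
        rng = np.random.default_rng(5)
        scores = ScoreMap17(rng.integers(0, 5, 17), rng.integers(0, 4, 17))
        sp = SectorParameters.from_scores(params, scores)
        assert (sp.C_n >= params.C_H).all()
        assert (sp.Tmax_n >= 0.0).all()
        assert (sp.Tmax_n <= params.Tmax_H).all()


class TestPassiveStress:
    def test_stress_free_reference(self):
        S = passive_stress(StrainTensorFiberFrame(), PassiveLaw())
        assert np.allclose(S, 0.0)

    def test_finite_difference_oracle_on_random_admissible_strains(self):
        # dW = S : dE, checked component-wise by central differences of the
        # scalar energy on 120 random small strains
        law = PassiveLaw(C=0.15)
        rng = np.random.default_rng(42)
        h = 1e-6
        for _ in range(120):
            A = rng.uniform(-0.05, 0.05, (3, 3))
            E = 0.5 * (A + A.T)
            S = passive_stress(E, law)
            for i in range(3):
                for j in range(i, 3):
                    dE = np.zeros((3, 3))
                    dE[i, j] = dE[j, i] = h
                    dW = (strain_energy(E + dE, law) - strain_energy(E - dE, law)) / (2 * h)
                    S_sym = S[i, j] * (2.0 if i != j else 1.0)
                    assert dW == pytest.approx(S_sym, rel=1e-5, abs=1e-8)

    def test_pure_fiber_strain_matches_analytic_derivative(self):
        law = PassiveLaw(C=0.3)
        eps = 0.04
        E = np.diag([eps, 0.0, 0.0])
        S = passive_stress(E, law)
        S_fib = law.C * law.b_f * eps * np.exp(law.b_f * eps**2)
        # remove the volumetric part to isolate the Guccione term
        J = np.sqrt(np.linalg.det(2 * E + np.eye(3)))
        S_vol = law.kappa * (J - 1.0) * J * np.linalg.inv(2 * E + np.eye(3))
        assert S[0, 0] - S_vol[0, 0] == pytest.approx(S_fib, rel=1e-12)

    def test_non_invertible_deformation_rejected(self):
        from lvmech.materials import MechanicsError

        E = np.diag([-0.6, 0.0, 0.0])  # 2E+I loses positive definiteness
        with pytest.raises(MechanicsError):
            passive_stress(E, PassiveLaw())

    def test_kappa_floor_enforced(self):
        with pytest.raises(ValueError):
            PassiveLaw(C=1.0, kappa=50.0)


class TestActiveStress:
    def test_zero_contractility_gives_zero_tension(self):
        assert active_stress(0.1, 0.0, ActiveLaw()) == 0.0

    def test_zero_activation_variable_gives_zero_tension(self):
        law = ActiveLaw(Ct_ES=0.0)
        assert active_stress(0.1, 300.0, law) == 0.0

    def test_tension_vanishes_continuously_at_the_slack_limit(self):
        law = ActiveLaw()
        # E11 at which l = l0
        e_limit = 0.5 * ((law.l0 / law.lR) ** 2 - 1.0)
        below = active_stress(e_limit - 1e-4, 300.0, law)
        just_above = active_stress(e_limit + 1e-6, 300.0, law)
        above = active_stress(e_limit + 0.05, 300.0, law)
        assert below == 0.0
        assert 0.0 < just_above < 1.0      # T0 -> 0 as l -> l0+
        assert above > just_above

    def test_tension_increases_with_stretch_and_contractility(self):
        law = ActiveLaw()
        assert active_stress(0.15, 300.0, law) > active_stress(0.0, 300.0, law)
        assert active_stress(0.1, 400.0, law) > active_stress(0.1, 300.0, law)
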