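"""Transition moments, deperturbation, GVPT2 projection, pseudoeigenvectors."""

import math

import numpy as np
import pytest

from gvpt2 import (
    AnharmonicField,
    GVPT2Result,
    HarmonicModel,
    Polyad,
    PolyadDB,
    PropertySurface,
    ResonanceDB,
    SingularDenominatorError,
    VibData,
    VibState,
    assemble_and_diagonalize,
    build_resonance_db,
    project_gvpt2,
    pseudo_eigenvector,
    tm_fundamental,
    tm_two_quanta,
    transition_moment,
    variational_oracle,
)
from conftest import make_fermi_dyad


def _dipole_only(n, p1):
    return PropertySurface(name="electric_dipole", n_components=3, S=+1,
                           P1=np.asarray(p1, dtype=float))


class TestHarmonicLimits:
    def test_double_harmonic_fundamental_is_p1_over_sqrt2(self):
        harm = HarmonicModel(n_atoms=3, omega=np.array([900.0, 1400.0]))
        surf = _dipole_only(2, [[0.05, 0.0, 0.01], [0.0, 0.03, 0.0]])
        b = VibData(harm, AnharmonicField(), [surf])
        tm = tm_fundamental(1, b, surf, level="VPT2")
        assert np.allclose(tm.value, surf.P1[0] / math.sqrt(2.0))
        # no anharmonicity: VPT2 equals the double-harmonic value
        tmh = tm_fundamental(1, b, surf, level="harmonic")
        assert np.allclose(tm.value, tmh.value)

    def test_all_zero_derivatives_give_zero_moment(self):
        harm = HarmonicModel(n_atoms=3, omega=np.array([900.0, 1400.0]))
        surf = PropertySurface(name="electric_dipole", n_components=3)
        b = VibData(harm, AnharmonicField(), [surf])
        assert np.all(tm_fundamental(1, b, surf).value == 0.0)

    def test_two_quanta_dark_at_double_harmonic(self):
        harm = HarmonicModel(n_atoms=3, omega=np.array([900.0, 1400.0]))
        surf = _dipole_only(2, [[0.05, 0.0, 0.0], [0.0, 0.03, 0.0]])
        b = VibData(harm, AnharmonicField(), [surf])
        for s in (VibState.overtone(1), VibState.combination(1, 2)):
            assert np.all(tm_two_quanta(s, b, surf, level="harmonic").value == 0.0)

    def test_pure_electrical_anharmonicity_matches_ho_integrals(self):
        """P2-only overtone/combination moments against analytic harmonic
        oscillator integrals: <0|q^2|2> = sqrt(2)/2 and <00|q_i q_j|11> = 1/2."""
        harm = HarmonicModel(n_atoms=3, omega=np.array([900.0, 1400.0]))
        p2 = np.zeros((2, 2, 3))
        p2[0, 0, 0] = 0.004
        p2[0, 1, 1] = p2[1, 0, 1] = 0.003
        surf = PropertySurface(name="electric_dipole", n_components=3, P2=p2)
        b = VibData(harm, AnharmonicField(), [surf])
        ot = tm_two_quanta(VibState.overtone(1), b, surf)
        # s2 * P2_11 * <0|q^2|2> = 0.5 * 0.004 * sqrt(2)/2
        assert ot.value[0] == pytest.approx(0.5 * 0.004 * math.sqrt(2) / 2)
        cb = tm_two_quanta(VibState.combination(1, 2), b, surf)
        # s2 * (P2_12 + P2_21) * <00|q_i q_j|11> = 0.5 * 0.006 * 0.5
        assert cb.value[1] == pytest.approx(0.5 * 0.006 * 0.5)

    def test_two_quanta_moment_requires_two_quanta(self):
        harm = HarmonicModel(n_atoms=3, omega=np.array([900.0, 1400.0]))
        surf = _dipole_only(2, np.zeros((2, 3)))
        b = VibData(harm, AnharmonicField(), [surf])
        with pytest.raises(ValueError):
            tm_two_quanta(VibState.fundamental(1), b, surf)


class TestOracleAgreement:
    def test_vpt2_moments_within_one_percent_of_oracle(self, two_mode_rich):
        orc = variational_oracle(two_mode_rich, n_max_quanta=14)
        for surf in two_mode_rich.properties:
            for s in [VibState.fundamental(1), VibState.fundamental(2),
                      VibState.overtone(1), VibState.combination(1, 2)]:
                tm = transition_moment(s, two_mode_rich, surf, level="VPT2")
                ref = orc.moments[(surf.name, s)]
                # eigenvector phases are arbitrary: compare absolute values
                assert np.allclose(np.abs(tm.value), np.abs(ref),
                                   rtol=0.01, atol=1e-9)


class TestDeperturbation:
    def test_vpt2_diverges_and_dvpt2_stays_bounded(self):
        norms_v, norms_d = [], []
        for delta in (5.0, 1.0, 0.2):
            b = make_fermi_dyad(delta=delta, phi=38.0, with_dipole=True)
            surf = b.properties[0]
            resdb = build_resonance_db(b.harmonic, b.field)
            f2 = VibState.fundamental(2)
            norms_v.append(np.linalg.norm(
                transition_moment(f2, b, surf, level="VPT2").value))
            tm_d = transition_moment(f2, b, surf, resdb, level="DVPT2")
            norms_d.append(np.linalg.norm(tm_d.value))
            assert tm_d.removed_terms   # the resonant term is ledgered
        assert norms_v[-1] > 10 * norms_v[0]          # unbounded growth
        assert max(norms_d) < 2 * min(norms_d)        # bounded

    def test_untreated_singular_denominator_is_hard_error(self):
        b = make_fermi_dyad(delta=1e-9, phi=38.0, with_dipole=True)
        with pytest.raises(SingularDenominatorError, match="resonance"):
            transition_moment(VibState.fundamental(2), b, b.properties[0],
                              level="VPT2")

    def test_dvpt2_equals_vpt2_with_empty_resonance_list(self, two_mode_rich):
        surf = two_mode_rich.properties[0]
        s = VibState.fundamental(1)
        a = transition_moment(s, two_mode_rich, surf, level="VPT2")
        d = transition_moment(s, two_mode_rich, surf, ResonanceDB(), level="DVPT2")
        assert np.allclose(a.value, d.value)


class TestProjection:
    def _rotation_result(self, theta):
        a, b = VibState.fundamental(1), VibState.fundamental(2)
        c, s = math.cos(theta), math.sin(theta)
        from gvpt2.variational import PolyadSolution
        sol = PolyadSolution(
            states=[a, b], matrix=np.eye(2),
            eigenvalues=np.array([990.0, 1020.0]),
            eigenvectors=np.array([[c, -s], [s, c]]))
        return GVPT2Result(solutions=[sol], passthrough={}), a, b

    def test_identity_eigenvectors_leave_moments_unchanged(self):
        res, a, b = self._rotation_result(0.0)
        m = {a: np.array([1.0, 0, 0]), b: np.array([0, 2.0, 0])}
        proj = project_gvpt2(m, res)
        assert np.allclose(proj[(0, 0)], m[a])
        assert np.allclose(proj[(0, 1)], m[b])

    def test_two_state_rotation(self):
        theta = 0.3
        res, a, b = self._rotation_result(theta)
        m1 = np.array([1.0, 0.5, 0.0])
        m2 = np.array([-0.2, 1.0, 0.3])
        proj = project_gvpt2({a: m1, b: m2}, res)
        c, s = math.cos(theta), math.sin(theta)
        assert np.allclose(proj[(0, 0)], c * m1 + s * m2)
        assert np.allclose(proj[(0, 1)], -s * m1 + c * m2)

    def test_norm_conservation_random_polyads(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            k = int(rng.integers(2, 6))
            states = [VibState.fundamental(i) for i in range(1, k + 1)]
            coup = {frozenset((states[i], states[j])): float(rng.normal(0, 10))
                    for i in range(k) for j in range(i + 1, k)}
            pdb = PolyadDB([Polyad(states, coup)], [])
            energies = {s: float(rng.uniform(900, 1100)) for s in states}
            res = assemble_and_diagonalize(pdb, energies)
            moments = {s: rng.normal(0, 1, 3) + 1j * rng.normal(0, 0.1, 3)
                       for s in states}
            proj = project_gvpt2(moments, res)
            before = sum(float(np.sum(np.abs(v) ** 2)) for v in moments.values())
            after = sum(float(np.sum(np.abs(v) ** 2)) for v in proj.values())
            assert after == pytest.approx(before, rel=1e-10)

    def test_missing_state_moment_raises(self):
        res, a, b = self._rotation_result(0.1)
        with pytest.raises(ValueError, match="v2"):
            project_gvpt2({a: np.zeros(3)}, res)


class TestPseudoEigenvector:
    def _harm_with_modes(self, omega):
        n = len(omega)
        n_atoms = max(3, (n + 6 + 2) // 3)
        rng = np.random.default_rng(2)
        L = rng.normal(0, 1, (3 * n_atoms, n))
        return HarmonicModel(n_atoms=n_atoms, omega=np.asarray(omega), L=L)

    def test_no_anharmonicity_returns_l_column(self):
        harm = self._harm_with_modes([1000.0, 1030.0])
        field = AnharmonicField()
        db = build_resonance_db(harm, field)
        v = pseudo_eigenvector(VibState.fundamental(1), harm, field, db)
        assert np.allclose(v, harm.L[:, 0])

    def test_cache_and_recompute_agree(self):
        harm = self._harm_with_modes([1000.0, 1060.0])
        field = AnharmonicField(quartic={(1, 1, 1, 2): 8 * 3.0})
        db = build_resonance_db(harm, field)
        a = pseudo_eigenvector(VibState.fundamental(1), harm, field, db,
                               use_cache=True)
        b = pseudo_eigenvector(VibState.fundamental(1), harm, field, db,
                               use_cache=False)
        assert np.allclose(a, b)

    def test_partner_weight_matches_r11coef_index(self):
        from gvpt2 import dd_index
        from gvpt2.resonance import ResonanceCandidate, ResonanceKind
        harm = self._harm_with_modes([1000.0, 1060.0])
        field = AnharmonicField(quartic={(1, 1, 1, 2): 8 * 3.0})
        db = build_resonance_db(harm, field)
        v = pseudo_eigenvector(VibState.fundamental(1), harm, field, db)
        # decompose on the L columns: weights are 1 and the mixing coefficient
        coeffs, *_ = np.linalg.lstsq(harm.L, v, rcond=None)
        cand = ResonanceCandidate(
            kind=ResonanceKind.DD11, bra=VibState.fundamental(1),
            ket=VibState.fundamental(2), delta=-60.0, indices=(1, 2))
        idx = dd_index(cand, harm, field, "R11COEF")
        weights = sorted(np.abs(coeffs), reverse=True)
        assert weights[0] == pytest.approx(1.0)
        assert weights[1] == pytest.approx(idx, rel=1e-9)

    def test_two_quanta_state_built_from_fermi_coefficients(self):
        harm = self._harm_with_modes([600.0, 1500.0])
        field = AnharmonicField(cubic={(1, 1, 2): 10.0})
        db = build_resonance_db(harm, field)
        v = pseudo_eigenvector(VibState.overtone(1), harm, field, db)
        # overtone of mode 1 mixes with fundamental 2: weight = -c1(2;1,1)
        delta = harm.omega[1] - 2 * harm.omega[0]
        c1 = (10.0 / 4.0) / delta
        assert np.allclose(v, -c1 * harm.L[:, 1])
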