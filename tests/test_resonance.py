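"""Candidate enumeration, resonance indices, and database construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gvpt2 import (
    AnharmonicField,
    HarmonicModel,
    KindConfig,
    ResonanceConfig,
    VibData,
    VibState,
    build_resonance_db,
    count_dd_pairs,
    count_fermi_triads,
    dd_index,
    enumerate_dd_candidates,
    enumerate_fermi_candidates,
    fermi_index,
)
from gvpt2.oracle import _diagonalize
from gvpt2.resonance import ResonanceCandidate, ResonanceKind


class TestEnumeration:
    def test_no_partner_modes(self):
        assert enumerate_fermi_candidates(np.array([1000.0])) == []

    def test_constructed_window(self):
        w = np.array([995.0, 1010.0, 2000.0])
        cands = enumerate_fermi_candidates(w, window=6.0)
        assert len(cands) == 1
        (c,) = cands
        assert c.indices == (3, 1, 2)
        assert c.delta == pytest.approx(-5.0)
        assert c.kind is ResonanceKind.FERMI_II

    def test_fermi_count_matches_closed_form_pinene(self):
        w = np.linspace(100.0, 3200.0, 72)
        cands = enumerate_fermi_candidates(w, window=math.inf)
        assert len(cands) == count_fermi_triads(72) == 184032

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8, 13, 24])
    def test_counts_match_closed_forms(self, n):
        w = np.linspace(100.0, 3000.0, n)
        assert len(enumerate_fermi_candidates(w)) == count_fermi_triads(n)
        assert len(enumerate_dd_candidates(w, "DD11")) == count_dd_pairs(n, "DD11")
        full = enumerate_dd_candidates(w, "DD22", restricted=False)
        assert len(full) == count_dd_pairs(n, "DD22")

    def test_dd11_pair_counts(self):
        w = np.linspace(100.0, 3200.0, 72)
        assert len(enumerate_dd_candidates(w, "DD11")) == 2556
        assert count_dd_pairs(2, "DD11") == 1

    def test_two_quanta_pair_closed_form_pinene(self):
        assert count_dd_pairs(72, "DD22") == 3_451_878

    def test_restricted_dd22_patterns(self):
        w = np.array([500.0, 505.0, 1000.0])
        cands = enumerate_dd_candidates(w, "DD22", window=50.0)
        kinds = {c.kind for c in cands}
        assert kinds <= {ResonanceKind.DD22, ResonanceKind.DD211}
        # overtone-overtone between modes 1 and 2 (gap 10) must be present
        assert any(c.indices == (1, 1, 2, 2) for c in cands)
        # combination partners never repeat the overtone mode
        for c in cands:
            if c.kind is ResonanceKind.DD211:
                i = c.indices[0]
                assert i not in c.indices[2:]

    def test_deterministic_ordering(self):
        w = np.linspace(200.0, 2500.0, 10)
        a = [c.indices for c in enumerate_fermi_candidates(w, 300.0)]
        b = [c.indices for c in enumerate_fermi_candidates(w, 300.0)]
        assert a == b == sorted(a)


def _fermi_cand(kind, delta, i=2, j=1, k=1):
    return ResonanceCandidate(
        kind=kind, bra=VibState.fundamental(i),
        ket=VibState.combination(j, k), delta=delta, indices=(i, j, k))


class TestFermiIndices:
    def test_martin_printed_gas_phase_value(self):
        """|phi| = 33, gap 17.5: the type-I Martin index is ~0.8 cm-1."""
        f = AnharmonicField(cubic={(1, 1, 2): 33.0})
        c = _fermi_cand(ResonanceKind.FERMI_I, 17.5)
        assert fermi_index(c, f, "R12MART") == pytest.approx(0.864, abs=0.07)

    def test_martin_liquid_over_gas_ratio_exceeds_500(self):
        f_gas = AnharmonicField(cubic={(1, 1, 2): 33.0})
        f_liq = AnharmonicField(cubic={(1, 1, 2): 38.0})
        gas = fermi_index(_fermi_cand(ResonanceKind.FERMI_I, 17.5), f_gas, "R12MART")
        liq = fermi_index(_fermi_cand(ResonanceKind.FERMI_I, 2.6), f_liq, "R12MART")
        assert liq / gas > 500.0

    def test_zero_coupling_zeroes_every_scheme(self):
        f = AnharmonicField()
        c = _fermi_cand(ResonanceKind.FERMI_I, 5.0)
        for scheme in ("R12MART", "R12CVPT", "R12WFRQ", "R12COEF"):
            assert fermi_index(c, f, scheme) == 0.0

    def test_exact_degeneracy_auto_accepts(self):
        f = AnharmonicField(cubic={(1, 1, 2): 5.0})
        c = _fermi_cand(ResonanceKind.FERMI_I, 0.0)
        assert math.isinf(fermi_index(c, f, "R12MART"))
        assert math.isinf(fermi_index(c, f, "R12COEF"))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            fermi_index(_fermi_cand(ResonanceKind.FERMI_I, 5.0),
                        AnharmonicField(), "R99")

    @given(phi=st.floats(0.5, 60.0), delta=st.floats(0.5, 150.0),
           factor=st.floats(1.1, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, phi, delta, factor):
        """Every index grows with |phi| at fixed gap and shrinks with the gap
        at fixed coupling."""
        for scheme in ("R12MART", "R12CVPT", "R12WFRQ", "R12COEF"):
            f1 = AnharmonicField(cubic={(1, 1, 2): phi})
            f2 = AnharmonicField(cubic={(1, 1, 2): phi * factor})
            c = _fermi_cand(ResonanceKind.FERMI_I, delta)
            c_far = _fermi_cand(ResonanceKind.FERMI_I, delta * factor)
            base = fermi_index(c, f1, scheme)
            assert fermi_index(c, f2, scheme) >= base
            assert fermi_index(c_far, f1, scheme) <= base

    def test_coef_matches_perturbative_mixing_coefficient(self):
        """R12COEF equals the first-order wave-function coefficient extracted
        from a dense diagonalization in the small-coupling limit."""
        harm = HarmonicModel(n_atoms=3, omega=np.array([750.0, 1520.0]))
        field = AnharmonicField(cubic={(1, 1, 2): 2.0})
        c = ResonanceCandidate(
            kind=ResonanceKind.FERMI_I, bra=VibState.fundamental(2),
            ket=VibState.overtone(1), delta=20.0, indices=(2, 1, 1))
        idx = fermi_index(c, field, "R12COEF")
        _, vals, vecs = _diagonalize(VibData(harm, field, []), 12)
        dim = 13
        col = int(np.argmax(np.abs(vecs[0 * dim + 1, :])))   # |1_2>
        mix = abs(vecs[2 * dim + 0, col] / vecs[0 * dim + 1, col])  # |2_1>
        assert idx == pytest.approx(mix, rel=1e-3)

    def test_cvpt_and_coef_differ_by_sqrt2_for_overtones(self):
        f = AnharmonicField(cubic={(1, 1, 2): 10.0})
        c1 = _fermi_cand(ResonanceKind.FERMI_I, 8.0)
        ratio = fermi_index(c1, f, "R12CVPT") / fermi_index(c1, f, "R12COEF")
        assert ratio == pytest.approx(math.sqrt(2.0))
        f2 = AnharmonicField(cubic={(1, 2, 3): 10.0})
        c2 = ResonanceCandidate(
            kind=ResonanceKind.FERMI_II, bra=VibState.fundamental(3),
            ket=VibState.combination(1, 2), delta=8.0, indices=(3, 1, 2))
        assert fermi_index(c2, f2, "R12CVPT") == pytest.approx(
            fermi_index(c2, f2, "R12COEF"))


class TestDDIndices:
    def _dd_cand(self, delta=-30.0):
        return ResonanceCandidate(
            kind=ResonanceKind.DD11, bra=VibState.fundamental(1),
            ket=VibState.fundamental(2), delta=delta, indices=(1, 2))

    def test_uncoupled_modes_score_zero(self):
        harm = HarmonicModel(n_atoms=3, omega=np.array([1000.0, 1030.0]))
        f = AnharmonicField()
        for scheme in ("R11HRS", "R11WFRQ", "R11COEF"):
            assert dd_index(self._dd_cand(), harm, f, scheme) == 0.0

    def test_hrs_recovers_planted_quartic_coupling(self):
        harm = HarmonicModel(n_atoms=3, omega=np.array([1000.0, 1030.0]))
        f = AnharmonicField(quartic={(1, 1, 1, 2): 8 * 5.0})
        assert dd_index(self._dd_cand(), harm, f, "R11HRS") == pytest.approx(5.0)

    def test_coef_matches_second_order_mixing_coefficient(self):
        harm = HarmonicModel(n_atoms=3, omega=np.array([1000.0, 1030.0]))
        w_plant = 0.1
        f = AnharmonicField(quartic={(1, 1, 1, 2): 8 * w_plant})
        idx = dd_index(self._dd_cand(), harm, f, "R11COEF")
        _, vals, vecs = _diagonalize(VibData(harm, f, []), 12)
        dim = 13
        col = int(np.argmax(np.abs(vecs[1 * dim + 0, :])))   # |1_1>
        mix = abs(vecs[0 * dim + 1, col] / vecs[1 * dim + 0, col])
        assert idx == pytest.approx(mix, rel=1e-3)

    def test_coef_below_one_on_perturbative_candidates(self, two_mode_rich):
        harm, f = two_mode_rich.harmonic, two_mode_rich.field
        idx = dd_index(self._dd_cand(delta=float(harm.omega[0] - harm.omega[1])),
                       harm, f, "R11COEF")
        assert 0.0 <= idx < 1.0


class TestDatabase:
    def test_infinite_thresholds_empty_db(self, two_mode_rich):
        cfg = ResonanceConfig(
            fermi=KindConfig(window=500.0, energy_scheme="R12MART",
                             energy_threshold=math.inf),
            dd11=KindConfig(window=500.0, energy_scheme="R11HRS",
                            energy_threshold=math.inf),
            dd22=KindConfig(window=500.0, energy_scheme="R22HRS",
                            energy_threshold=math.inf),
        )
        db = build_resonance_db(two_mode_rich.harmonic, two_mode_rich.field, cfg)
        assert len(db) == 0

    def test_strong_fermi_accepted_by_martin(self, fermi_dyad):
        db = build_resonance_db(fermi_dyad.harmonic, fermi_dyad.field)
        entry = db.get(VibState.fundamental(2), VibState.overtone(1))
        assert entry is not None
        assert "R12MART" in entry.triggered_by
        assert entry.indices_by_scheme["R12MART"] > 400.0

    def test_weak_close_fermi_caught_only_by_intensity_test(self):
        """phi = 3, gap 2: Martin stays below 1 while the first-order
        coefficient (0.375) exceeds the 0.1 intensity threshold."""
        w1 = (1500.0 - 2.0) / 2.0
        harm = HarmonicModel(n_atoms=3, omega=np.array([w1, 1500.0]))
        field = AnharmonicField(cubic={(1, 1, 2): 3.0})
        energy_only = ResonanceConfig(
            fermi=KindConfig(window=200.0, energy_scheme="R12MART",
                             energy_threshold=1.0))
        db0 = build_resonance_db(harm, field, energy_only)
        assert len(db0.fermi_entries()) == 0
        db1 = build_resonance_db(harm, field)   # default adds R12COEF at 0.1
        entry = db1.get(VibState.fundamental(2), VibState.overtone(1))
        assert entry is not None
        assert entry.triggered_by == ("R12COEF",)

    def test_or_acceptance_is_superset_of_single_tests(self, fermi_dyad):
        harm, field = fermi_dyad.harmonic, fermi_dyad.field

        def keys(db):
            return {tuple(e.candidate.indices) for e in db}

        both = build_resonance_db(harm, field)
        energy = build_resonance_db(harm, field, ResonanceConfig(
            fermi=KindConfig(window=200.0, energy_scheme="R12MART",
                             energy_threshold=1.0)))
        intensity = build_resonance_db(harm, field, ResonanceConfig(
            fermi=KindConfig(window=200.0, intensity_scheme="R12COEF",
                             intensity_threshold=0.1)))
        assert keys(both) >= keys(energy)
        assert keys(both) >= keys(intensity)

    def test_user_amendment(self, fermi_dyad):
        db = build_resonance_db(fermi_dyad.harmonic, fermi_dyad.field)
        bra, ket = VibState.fundamental(2), VibState.overtone(1)
        assert db.remove(bra, ket)
        assert not db.is_fermi(2, 1, 1)
        cand = ResonanceCandidate(
            kind=ResonanceKind.FERMI_I, bra=bra, ket=ket,
            delta=2.6, indices=(2, 1, 1), coupling=9.5)
        db.add(cand, user_added=True)
        assert db.is_fermi(2, 1, 1)
        assert db.get(bra, ket).triggered_by == ("user",)

    def test_unknown_scheme_in_config_rejected(self, two_mode_rich):
        cfg = ResonanceConfig(fermi=KindConfig(
            window=200.0, energy_scheme="NOT_A_SCHEME"))
        with pytest.raises(ValueError, match="NOT_A_SCHEME"):
            build_resonance_db(two_mode_rich.harmonic, two_mode_rich.field, cfg)
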