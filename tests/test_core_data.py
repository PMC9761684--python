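"""Domain types, VibData I/O, validation, masking."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gvpt2 import (
    AnharmonicField,
    HarmonicModel,
    MissingConstantError,
    PropertySurface,
    ValidationError,
    VibData,
    load_vibdata,
    mask_active_modes,
    n_normal_modes,
    save_vibdata,
    validate_force_field,
)
from gvpt2.io import ParseError
from gvpt2.model import fix_mode_phases
from gvpt2.resonance import ResonanceKind
from gvpt2.synthetic import PlantedFeature, ResonancePlan, generate


class TestHarmonicModel:
    def test_negative_frequency_rejected_with_mode_indices(self):
        with pytest.raises(ValidationError, match="modes 1"):
            HarmonicModel(n_atoms=3, omega=np.array([-5.0, 100.0]))

    def test_unsorted_omega_rejected(self):
        with pytest.raises(ValidationError, match="ascending"):
            HarmonicModel(n_atoms=3, omega=np.array([200.0, 100.0]))

    def test_zeta_antisymmetry_enforced(self):
        z = np.zeros((3, 2, 2))
        z[0, 0, 1] = 0.5
        z[0, 1, 0] = 0.5  # should be -0.5
        with pytest.raises(ValidationError, match="antisymmetric"):
            HarmonicModel(n_atoms=3, omega=np.array([100.0, 200.0]), zeta=z)

    def test_mode_columns_unit_norm_and_phase(self):
        L = np.array([[2.0, 0.0], [0.0, -3.0], [0.0, 0.0],
                      [0.0, 0.0], [0.0, 0.0], [0.0, 0.0],
                      [0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        h = HarmonicModel(n_atoms=3, omega=np.array([100.0, 200.0]), L=L)
        assert np.allclose(np.linalg.norm(h.L, axis=0), 1.0)
        # largest-magnitude element positive in every column
        for c in range(2):
            assert h.L[np.argmax(np.abs(h.L[:, c])), c] > 0

    def test_normal_mode_counts(self):
        assert n_normal_modes(10) == 24      # methyloxirane
        assert n_normal_modes(42) == 120     # artemisinin
        assert n_normal_modes(2, linear=True) == 1


class TestAnharmonicField:
    def test_permutation_symmetric_retrieval(self):
        f = AnharmonicField(cubic={(1, 2, 2): 30.0})
        assert f.get_cubic(2, 1, 2) == 30.0
        assert f.get_cubic(2, 2, 1) == 30.0

    @given(st.tuples(st.integers(1, 6), st.integers(1, 6), st.integers(1, 6)),
           st.floats(-100, 100, allow_nan=False),
           st.permutations([0, 1, 2]))
    @settings(max_examples=200, deadline=None)
    def test_cubic_permutation_invariance(self, idx, val, perm):
        f = AnharmonicField()
        f.set_cubic(*idx, value=val)
        shuffled = tuple(idx[p] for p in perm)
        assert f.get_cubic(*shuffled) == val

    @given(st.tuples(st.integers(1, 5), st.integers(1, 5), st.integers(1, 5)),
           st.floats(-100, 100, allow_nan=False),
           st.permutations([0, 1, 2, 3]))
    @settings(max_examples=200, deadline=None)
    def test_quartic_permutation_invariance(self, idx3, val, perm):
        # semidiagonal pattern: duplicate one index
        idx = (idx3[0], idx3[0], idx3[1], idx3[2])
        f = AnharmonicField()
        f.set_quartic(*idx, value=val)
        shuffled = tuple(idx[p] for p in perm)
        assert f.get_quartic(*shuffled) == val

    def test_off_semidiagonal_unavailable_not_zero(self):
        f = AnharmonicField()
        with pytest.raises(MissingConstantError):
            f.get_quartic(1, 2, 3, 4)
        assert f.get_quartic(1, 2, 3, 4, missing_as_zero=True) == 0.0
        g = AnharmonicField(has_full_quartic=True)
        assert g.get_quartic(1, 2, 3, 4) == 0.0

    def test_off_semidiagonal_storage_requires_flag(self):
        f = AnharmonicField()
        with pytest.raises(ValidationError):
            f.set_quartic(1, 2, 3, 4, value=1.0)


class TestVibDataIO:
    def test_minimal_one_mode_bundle(self, tmp_path):
        b = VibData(HarmonicModel(n_atoms=3, omega=np.array([1000.0])),
                    AnharmonicField(), [])
        p = tmp_path / "one.json"
        save_vibdata(b, p)
        loaded = load_vibdata(p)
        assert loaded.n_modes == 1
        assert loaded.field.cubic == {} and loaded.field.quartic == {}

    def test_round_trip_is_bit_exact(self, tmp_path):
        gen = generate(ResonancePlan(n_modes=24, seed=11, planted=[
            PlantedFeature(ResonanceKind.FERMI_I, delta=2.6, coupling=38.0)]))
        p1 = tmp_path / "a.json"
        p2 = tmp_path / "b.json"
        save_vibdata(gen.bundle, p1)
        loaded = load_vibdata(p1)
        save_vibdata(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert loaded.field == gen.bundle.field
        assert np.array_equal(loaded.harmonic.omega, gen.bundle.harmonic.omega)
        for a, b in zip(loaded.properties, gen.bundle.properties):
            assert np.array_equal(a.P1, b.P1)

    def test_hdf5_container_round_trip(self, tmp_path):
        gen = generate(ResonancePlan(n_modes=12, seed=4, planted=[
            PlantedFeature(ResonanceKind.DD11, delta=3.0, coupling=12.0)]))
        p = tmp_path / "bundle.h5"
        save_vibdata(gen.bundle, p)
        loaded = load_vibdata(p)
        assert loaded.field == gen.bundle.field
        assert np.array_equal(loaded.harmonic.omega, gen.bundle.harmonic.omega)
        for a, b in zip(loaded.properties, gen.bundle.properties):
            assert a.name == b.name and a.S == b.S
            assert np.array_equal(a.P1, b.P1)

    def test_malformed_json_names_line(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{\n  broken\n}")
        with pytest.raises(ParseError, match="line"):
            load_vibdata(p)

    def test_missing_format_declaration(self, tmp_path):
        p = tmp_path / "noformat.json"
        p.write_text(json.dumps({"version": 1}))
        with pytest.raises(ParseError, match="format"):
            load_vibdata(p)

    def test_out_of_range_constant_index(self, tmp_path):
        doc = {"format": "vibdata", "version": 1,
               "harmonic": {"n_atoms": 3, "omega": [100.0, 200.0]},
               "cubic": [[1, 2, 5, 3.0]]}
        p = tmp_path / "shape.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="outside"):
            load_vibdata(p)

    def test_negative_frequency_in_file(self, tmp_path):
        doc = {"format": "vibdata", "version": 1,
               "harmonic": {"n_atoms": 3, "omega": [-50.0, 200.0]}}
        p = tmp_path / "neg.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="modes 1"):
            load_vibdata(p)


class TestValidateForceField:
    def test_agreeing_estimates_pass_with_mean(self):
        rep = validate_force_field({(1, 2, 3): [50.2, 50.6, 49.9]}, tol=1.0)
        assert rep.passed
        assert rep.canonical[(1, 2, 3)] == pytest.approx(50.2333333, abs=1e-6)

    def test_deviating_estimates_fail(self):
        rep = validate_force_field({(1, 2, 3): [50.0, 51.5]}, tol=1.0)
        assert not rep.passed
        assert rep.deviations[(1, 2, 3)] == pytest.approx(1.5)

    def test_single_estimate_trivially_passes(self):
        rep = validate_force_field({(1, 1, 2): [12.0]}, tol=1.0)
        assert rep.passed and rep.max_deviation == 0.0

    def test_empty_group_and_bad_tol(self):
        with pytest.raises(ValueError):
            validate_force_field({(1, 2, 3): []})
        with pytest.raises(ValueError):
            validate_force_field({(1, 2, 3): [1.0]}, tol=0.0)


class TestMasking:
    def _bundle(self, n=6):
        gen = generate(ResonancePlan(n_modes=n, seed=3))
        return gen.bundle

    def test_full_active_set_is_identity(self):
        b = self._bundle()
        m = mask_active_modes(b, set(range(1, 7)))
        assert m.field == b.field

    def test_masked_modes_carry_no_constants(self):
        b = self._bundle()
        m = mask_active_modes(b, {1, 3, 6})
        dropped = {2, 4, 5}
        for idx in list(m.field.cubic) + list(m.field.quartic):
            assert not (set(idx) & dropped)
        for p in m.properties:
            for d in dropped:
                assert np.all(p.P1[d - 1] == 0.0)
                if p.P2 is not None:
                    assert np.all(p.P2[d - 1] == 0.0)
                    assert np.all(p.P2[:, d - 1] == 0.0)

    def test_masking_is_idempotent(self):
        b = self._bundle()
        once = mask_active_modes(b, {1, 2, 3})
        twice = mask_active_modes(once, {1, 2, 3})
        assert once.field == twice.field

    def test_harmonic_data_untouched(self):
        b = self._bundle()
        m = mask_active_modes(b, {1, 2})
        assert np.array_equal(m.harmonic.omega, b.harmonic.omega)

    def test_empty_active_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mask_active_modes(self._bundle(), set())

    def test_masking_commutes_with_symmetrized_retrieval(self):
        b = self._bundle()
        m = mask_active_modes(b, {1, 2, 3, 4})
        # any permuted query of a surviving constant returns the stored value
        for (i, j, k), v in m.field.cubic.items():
            assert m.field.get_cubic(k, i, j) == v
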