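import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inhibmap.morphology import (
    Morphology,
    MorphologyError,
    MorphometricRelations,
    Section,
    SpineGeometry,
    attach_spine,
    ellipse_geometry,
    elliptical_equivalent,
    neck_resistance,
    read_swc,
    section_geometry_from_distal_length,
    write_swc,
)
from inhibmap.synthdata import SyntheticConfig, make_pyramidal_morphology


class TestEllipticalEquivalence:
    def test_circle_is_identity(self):
        d, scale = elliptical_equivalent(math.pi, 2 * math.pi)
        assert d == pytest.approx(2.0)
        assert scale == pytest.approx(1.0)

    def test_closed_form_case(self):
        d, scale = elliptical_equivalent(0.5, 3.0)
        assert d == pytest.approx(2 * math.sqrt(0.5 / math.pi), abs=1e-4)
        assert d == pytest.approx(0.7979, abs=1e-4)
        assert scale == pytest.approx(3.0 / (math.pi * 0.7979), abs=1e-3)

    def test_true_ellipse_scale_matches_perimeter_ratio(self):
        area, perim = ellipse_geometry(1.0, 0.25)
        d, scale = elliptical_equivalent(area, perim)
        equal_area_circle_perimeter = math.pi * d
        assert scale > 1.0
        assert scale * equal_area_circle_perimeter == pytest.approx(perim, rel=1e-9)

    def test_sub_circular_perimeter_rejected(self):
        with pytest.raises(ValueError, match="not a valid ellipse"):
            elliptical_equivalent(math.pi, 2 * math.pi * 0.9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        a=st.floats(0.05, 5.0),
        ratio=st.floats(0.05, 1.0),
    )
    def test_membrane_total_conserved_for_any_ellipse(self, a, ratio):
        """Total conductance per unit length: ellipse perimeter x density
        equals circle perimeter x scaled density, for any valid ellipse."""
        b = a * ratio
        area, perim = ellipse_geometry(a, b)
        d, scale = elliptical_equivalent(area, perim)
        assert scale >= 1.0
        assert math.pi * d * scale == pytest.approx(perim, rel=1e-9)


class TestDistalLengthRelations:
    def test_intercepts_at_zero(self):
        area, circ = section_geometry_from_distal_length(0.0)
        assert area == pytest.approx(0.048097)
        assert circ == pytest.approx(1.3206)

    def test_linear_evaluation(self):
        area, circ = section_geometry_from_distal_length(100.0)
        assert area == pytest.approx(0.081355)
        assert circ == pytest.approx(1.44721)

    def test_composition_with_equivalence(self):
        area, circ = section_geometry_from_distal_length(0.0)
        _d, scale = elliptical_equivalent(area, circ)
        assert scale == pytest.approx(1.3206 / (2 * math.sqrt(math.pi * 0.048097)), rel=1e-4)
        assert scale == pytest.approx(1.699, abs=1e-3)

    def test_negative_distal_length_rejected(self):
        with pytest.raises(ValueError):
            section_geometry_from_distal_length(-1.0)


class TestSpine:
    def test_default_neck_resistance_is_500_megaohm(self):
        geom = SpineGeometry()
        assert geom.neck_resistance_megaohm == pytest.approx(500.0, rel=0.01)

    def test_neck_resistance_inverse_square_diameter(self):
        geom = SpineGeometry(neck_diameter=0.14)
        assert geom.neck_resistance_megaohm == pytest.approx(500.2 / 4.0, rel=0.01)

    def test_head_cylinder_diameter_from_volume(self):
        assert SpineGeometry().head_diameter == pytest.approx(
            (4 * 0.043 / math.pi) ** (1 / 3), rel=1e-9
        )
        assert SpineGeometry().head_diameter == pytest.approx(0.3797, abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        length=st.floats(0.1, 5.0),
        diameter=st.floats(0.02, 1.0),
        ra=st.floats(50.0, 500.0),
    )
    def test_neck_resistance_analytic_everywhere(self, length, diameter, ra):
        r = neck_resistance(length, diameter, ra)
        assert r == pytest.approx(
            4 * ra * 1e4 * length / (math.pi * diameter**2) / 1e6, rel=1e-12
        )

    def test_attach_spine_geometry(self):
        m = make_pyramidal_morphology(SyntheticConfig(seed=0, n_basal_dendrites=2))
        shaft = m.sections("basal")[0]
        neck_id, head_id = attach_spine(m, shaft.id, 0.4)
        neck, head = m[neck_id], m[head_id]
        assert neck.kind == "spine_neck" and head.kind == "spine_head"
        assert neck.length == 0.5 and neck.diameter == 0.07
        assert neck.axial_resistivity == 385.0
        assert head.length == head.diameter
        assert math.pi * head.diameter**2 / 4 * head.length == pytest.approx(0.043)

    def test_attach_spine_rejects_bad_position_and_target(self):
        m = make_pyramidal_morphology(SyntheticConfig(seed=0, n_basal_dendrites=2))
        shaft = m.sections("basal")[0]
        with pytest.raises(ValueError):
            attach_spine(m, shaft.id, 1.5)
        with pytest.raises(MorphologyError):
            attach_spine(m, m.root.id, 0.5)


class TestSWC:
    def test_three_point_file(self, tmp_path):
        p = tmp_path / "cell.swc"
        p.write_text(
            "1 1 0 0 0 5 -1\n"
            "2 3 6 0 0 0.5 1\n"
            "3 3 16 0 0 0.5 2\n"
        )
        m = read_swc(p)
        assert len(m) == 2  # soma + one merged dendrite section
        dend = m.sections("basal")[0]
        assert dend.length == pytest.approx(10.0)
        assert m.path_distance(dend.id, 1.0) == pytest.approx(10.0)

    def test_child_before_parent_is_structural_error(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text(
            "2 3 6 0 0 0.5 1\n"
            "1 1 0 0 0 5 -1\n"
        )
        with pytest.raises(MorphologyError):
            read_swc(p)

    def test_unknown_type_code_maps_to_basal_with_warning(self, tmp_path):
        p = tmp_path / "odd.swc"
        p.write_text(
            "1 1 0 0 0 5 -1\n"
            "2 9 6 0 0 0.5 1\n"
        )
        with pytest.warns(UserWarning, match="unknown type code"):
            m = read_swc(p)
        assert m.sections("basal")

    def test_round_trip_preserves_geometry(self, tmp_path):
        m = make_pyramidal_morphology(
            SyntheticConfig(seed=11, n_basal_dendrites=8, spine_density=0.05)
        )
        assert len(m) >= 50
        p1, p2, p3 = tmp_path / "a.swc", tmp_path / "b.swc", tmp_path / "c.swc"
        write_swc(m, p1)
        m2 = read_swc(p1)
        write_swc(m2, p2)
        assert len(m2) == len(m)

        def geometry(morph):
            return sorted((s.kind, s.length, s.diameter) for s in morph)

        for (k1, l1, d1), (k2, l2, d2) in zip(geometry(m), geometry(m2)):
            assert k1 == k2
            assert l1 == pytest.approx(l2, abs=2e-6)
            assert d1 == pytest.approx(d2, abs=2e-6)
        # a second round trip is the identity byte-for-byte
        write_swc(read_swc(p2), p3)
        assert p2.read_text() == p3.read_text()


class TestTreeInvariants:
    def test_section_validation(self):
        with pytest.raises(MorphologyError):
            Section(id=1, parent_id=None, kind="soma", length=0.0, diameter=1.0)
        with pytest.raises(MorphologyError):
            Section(id=1, parent_id=None, kind="soma", length=1.0, diameter=1.0,
                    density_scale=0.5)
        with pytest.raises(MorphologyError):
            Section(id=1, parent_id=None, kind="mystery", length=1.0, diameter=1.0)

    def test_single_root_enforced(self):
        m = Morphology()
        m.add(Section(id=1, parent_id=None, kind="soma", length=10, diameter=10))
        with pytest.raises(MorphologyError, match="already has a root"):
            m.add(Section(id=2, parent_id=None, kind="soma", length=10, diameter=10))

    def test_parent_must_precede_child(self):
        m = Morphology()
        m.add(Section(id=1, parent_id=None, kind="soma", length=10, diameter=10))
        with pytest.raises(MorphologyError, match="parent must precede"):
            m.add(Section(id=3, parent_id=2, kind="basal", length=10, diameter=1))

    def test_path_distance_accumulates_along_tree(self):
        m = Morphology()
        m.add(Section(id=1, parent_id=None, kind="soma", length=10, diameter=10))
        m.add(Section(id=2, parent_id=1, kind="basal", length=40, diameter=1))
        m.add(Section(id=3, parent_id=2, kind="basal", length=60, diameter=0.8))
        assert m.path_distance(3, 0.5) == pytest.approx(40 + 30)
        assert m.path_distance(1, 1.0) == 0.0  # soma centre convention
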