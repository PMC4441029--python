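"""Prototype construction and nearest-prototype classification."""

import numpy as np
import pytest

from rhythmcat import (ActivationPattern, ActivationWindow, CategoryLabel,
                       NO_METER, build_prototypes, classify,
                       convexity_report, default_category_labels,
                       prototype_rhythm)
from rhythmcat.categorize import Categorization, PrototypeSet
from rhythmcat.errors import ValidationError


class TestLabels:
    def test_canonical_form_divides_by_gcd(self):
        assert CategoryLabel((2, 2, 2)) == CategoryLabel((1, 1, 1))
        assert CategoryLabel((2, 4, 2)).ratio == (1, 2, 1)

    def test_display_does_not_affect_identity(self):
        assert CategoryLabel((1, 2, 1), "x") == CategoryLabel((1, 2, 1), "y")

    def test_default_list_has_12_entries(self):
        labels = default_category_labels()
        assert len(labels) == 12
        assert CategoryLabel((1, 1, 1)) in labels
        assert CategoryLabel((1, 2, 1)) in labels


class TestPrototypeRhythm:
    @pytest.mark.parametrize("ratio,iois", [
        ((1, 2, 1), (0.25, 0.5, 0.25)),
        ((1, 1, 1), (1 / 3, 1 / 3, 1 / 3)),
        ((1, 1, 2), (0.25, 0.25, 0.5)),
    ])
    def test_integer_ratio_to_iois(self, ratio, iois):
        r = prototype_rhythm(CategoryLabel(ratio))
        assert np.allclose(r.iois, iois)
        assert r.total == pytest.approx(1.0)


def _proto_set(patterns, labels=None):
    patterns = np.asarray(patterns, dtype=float)
    labels = labels or [CategoryLabel((1, 1, i + 1)) for i in range(len(patterns))]
    return PrototypeSet(tuple(labels), patterns,
                        np.arange(1, patterns.shape[1] + 1))


def _pattern(values):
    values = np.asarray(values, dtype=float)
    return ActivationPattern(values, np.arange(1, values.size + 1),
                             ActivationWindow(0, 1))


class TestClassify:
    def test_prototype_classifies_as_itself(self):
        ps = _proto_set([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        for i, lab in enumerate(ps.labels):
            assert classify(_pattern(ps.patterns[i]), ps) == lab

    def test_equidistant_tie_breaks_to_list_order(self):
        ps = _proto_set([[1, 0], [0, 1]])
        assert classify(_pattern([0.5, 0.5]), ps) == ps.labels[0]
        flipped = _proto_set([[0, 1], [1, 0]],
                             labels=[ps.labels[1], ps.labels[0]])
        assert classify(_pattern([0.5, 0.5]), flipped) == ps.labels[1]

    def test_euclidean_distance_is_scale_sensitive(self):
        # scaling the pattern but not the prototypes can change the label
        ps = _proto_set([[1, 0], [10, 0]])
        assert classify(_pattern([1.2, 0]), ps) == ps.labels[0]
        assert classify(_pattern([12, 0]), ps) == ps.labels[1]

    def test_dimension_mismatch_rejected(self):
        ps = _proto_set([[1, 0, 0]])
        with pytest.raises(ValidationError):
            classify(_pattern([1, 0]), ps)


class TestBuildPrototypes:
    def test_twelve_patterns_of_bank_dimension(self, default_prototypes,
                                               default_config):
        assert default_prototypes.n == 12
        assert default_prototypes.patterns.shape == (12, default_config.bank.n)
        assert default_prototypes.source_condition == NO_METER
        assert (default_prototypes.patterns >= 0).all()

    def test_deterministic(self, tiny_config):
        labels = [CategoryLabel((1, 1, 1)), CategoryLabel((1, 2, 1))]
        a = build_prototypes(labels, tiny_config)
        b = build_prototypes(labels, tiny_config)
        assert np.array_equal(a.patterns, b.patterns)

    def test_isochronous_prototype_peaks_at_three_hz(self, default_prototypes):
        """The 1-1-1 prototype is a 3-Hz pulse train; its most activated
        oscillator should sit at 3 Hz or a harmonic within one bank step."""
        i = default_prototypes.labels.index(CategoryLabel((1, 1, 1)))
        pat = default_prototypes.patterns[i]
        peak = default_prototypes.frequencies[int(np.argmax(pat))]
        step = 2 ** (4 / 144)
        assert any(h / step <= peak <= h * step for h in (3.0, 1.5, 1.0))


class TestCategorizeCondition:
    def test_total_function_over_grid(self, condition_categorizations, grid66):
        cat = condition_categorizations["none"]
        assert set(cat.ids) == {r.id for r in grid66}
        assert all(isinstance(lab, CategoryLabel)
                   for lab in cat.assignments.values())

    def test_near_isochronous_rhythm_is_111(self, condition_categorizations):
        """One grid step off the simplex center still falls in the
        central 1-1-1 region."""
        assert condition_categorizations["none"].label_of("7-6-6") == \
            CategoryLabel((1, 1, 1))

    def test_repeated_call_identical(self, grid66, default_prototypes,
                                     default_config, condition_categorizations):
        from rhythmcat import categorize_condition
        again = categorize_condition(grid66, NO_METER, default_prototypes,
                                     default_config)
        assert again.assignments == condition_categorizations["none"].assignments


class TestConvexity:
    def _grid_categorization(self, grid, rule):
        return Categorization({r.id: rule(r.grid_units) for r in grid},
                              NO_METER)

    def test_single_point_and_halfplane_regions_are_convex(self, grid66):
        a, b = CategoryLabel((1, 1, 1)), CategoryLabel((1, 1, 2))
        cat = self._grid_categorization(
            grid66, lambda k: a if k == (3, 3, 13) else b)
        rep = convexity_report(cat, grid66)
        assert (rep["convex_fraction"] == 1.0).all()
        # half-plane split along k1 is convex too
        cat = self._grid_categorization(
            grid66, lambda k: a if k[0] <= 7 else b)
        rep = convexity_report(cat, grid66)
        assert (rep["convex_fraction"] == 1.0).all()

    def test_disconnected_islands_are_not_convex(self, grid66):
        a, b = CategoryLabel((1, 1, 1)), CategoryLabel((1, 1, 2))
        corners = {(3, 3, 13), (13, 3, 3)}  # two far-apart islands
        cat = self._grid_categorization(
            grid66, lambda k: a if k in corners else b)
        rep = convexity_report(cat, grid66).set_index("label")
        assert rep.loc["1-1-1", "convex_fraction"] < 1.0
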