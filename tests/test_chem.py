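import math

import pytest
from hypothesis import given, strategies as st

from fragiso.chem import (
    DEFAULT_ISOTOPES,
    SMX,
    ElementalFormula,
    IsotopologueSpec,
    MoleculeDef,
    bulk_from_fragments,
    exact_bulk_from_fragments,
    fragment_calc_from_bulk,
    match_peak,
    monoisotopic_mz,
    position_enrichment_from_mixing,
    smx_catalog,
    stochastic_isotopologue_ratio,
)
from fragiso.errors import AmbiguousPeakError, ValidationError

# the six monitored species and their published m/z values
PRINTED_MZ = {
    "F92": 92.0493,
    "F92-15N": 93.0465,
    "F92-13C": 93.0532,
    "F99": 99.0552,
    "F99-15N": 100.0525,
    "F99-13C": 100.0587,
}


class TestFormula:
    def test_parse_hill_notation(self):
        formula = ElementalFormula.from_string("C10H11N3O3S")
        assert formula.counts == {"C": 10, "H": 11, "N": 3, "O": 3, "S": 1}

    def test_implicit_count_of_one(self):
        assert ElementalFormula.from_string("C6H6N").n("N") == 1

    def test_rejects_garbage(self):
        with pytest.raises(ValidationError):
            ElementalFormula.from_string("C6H6N!")

    def test_rejects_empty(self):
        with pytest.raises(ValidationError):
            ElementalFormula({})

    def test_rejects_all_zero(self):
        with pytest.raises(ValidationError):
            ElementalFormula({"C": 0})


class TestIsotopeTable:
    def test_abundances_sum_to_one(self):
        for element in ("H", "C", "N", "O", "S"):
            total = sum(a for _, _, a in DEFAULT_ISOTOPES.isotopes(element))
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_unknown_nuclide_named_in_error(self):
        with pytest.raises(ValidationError, match="14C"):
            DEFAULT_ISOTOPES.mass("C", 14)


class TestMonoisotopicMz:
    @pytest.mark.parametrize("label,expected", sorted(PRINTED_MZ.items()))
    def test_printed_masses(self, catalog, label, expected):
        spec = next(s for s in catalog if s.label == label)
        assert monoisotopic_mz(spec) == pytest.approx(expected, abs=1e-3)

    def test_charge_zero_rejected(self):
        with pytest.raises(ValidationError):
            IsotopologueSpec("H", ElementalFormula({"H": 1}), {}, charge=0)

    def test_oversubstitution_rejected(self):
        with pytest.raises(ValidationError):
            IsotopologueSpec(
                "F92", ElementalFormula.from_string("C6H6N"), {"N": (15, 2)}
            )

    def test_doubly_charged_halves_mz(self, catalog):
        base = next(s for s in catalog if s.label == "F92")
        doubled = IsotopologueSpec("F92", base.formula, {}, charge=2, label="z2")
        mz1 = monoisotopic_mz(base)
        # (m - 2 me) / 2 vs (m - me) / 1
        me = DEFAULT_ISOTOPES.electron_mass
        assert monoisotopic_mz(doubled) == pytest.approx((mz1 + me) / 2 - me, abs=1e-9)


class TestMatchPeak:
    def test_base_f92(self, catalog):
        spec = match_peak(92.0493, catalog, tolerance_ppm=20)
        assert spec is not None and spec.label == "F92"

    def test_15n_not_confused_with_13c(self, catalog):
        spec = match_peak(93.0465, catalog, tolerance_ppm=20)
        assert spec is not None and spec.label == "F92-15N"

    def test_far_off_mass_returns_none(self, catalog):
        assert match_peak(500.0, catalog, tolerance_ppm=20) is None

    def test_ambiguity_raises_listing_both(self, catalog):
        with pytest.raises(AmbiguousPeakError, match="F92-15N") as excinfo:
            match_peak(93.05, catalog, tolerance_ppm=1000)
        assert "F92-13C" in str(excinfo.value)

    def test_nonpositive_tolerance_rejected(self, catalog):
        with pytest.raises(ValidationError):
            match_peak(92.0, catalog, tolerance_ppm=0)


class TestStochasticRatio:
    def test_six_carbons(self):
        formula = ElementalFormula.from_string("C6H6N")
        assert stochastic_isotopologue_ratio(formula, "C", 0.011) == pytest.approx(
            6 * 0.011
        )

    def test_two_nitrogens(self):
        formula = ElementalFormula.from_string("C4H7N2O")
        assert stochastic_isotopologue_ratio(formula, "N", 0.004) == pytest.approx(
            2 * 0.004
        )

    def test_single_atom_identity(self):
        formula = ElementalFormula.from_string("C6H6N")
        assert stochastic_isotopologue_ratio(formula, "N", 0.003678) == pytest.approx(
            0.003678
        )

    def test_absent_element_raises(self):
        with pytest.raises(ValidationError):
            stochastic_isotopologue_ratio(
                ElementalFormula.from_string("C6H6N"), "O", 0.002
            )

    @given(n=st.integers(1, 30), r=st.floats(1e-6, 0.5))
    def test_linear_in_atom_count(self, n, r):
        formula = ElementalFormula({"C": n, "H": 1})
        single = stochastic_isotopologue_ratio(ElementalFormula({"C": 1, "H": 1}), "C", r)
        assert stochastic_isotopologue_ratio(formula, "C", r) == pytest.approx(
            n * single, rel=1e-12
        )


class TestMixing:
    def test_no_enrichment_at_natural_fraction(self):
        with pytest.warns(UserWarning):
            delta = position_enrichment_from_mixing(1.0, 1000.0, 0.0107, 0.0107)
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_one_mg_per_gram_spike(self):
        # independent oracle: mole-weighted atom-fraction mixing
        spike = 1.0 / (1.0 + 1000.0)
        x = spike * 0.99 + (1 - spike) * 0.0107
        expected = (
            (x / (1 - x)) / (0.0107 / (1 - 0.0107)) - 1.0
        ) * 1000.0
        delta = position_enrichment_from_mixing(1.0, 1000.0, 0.99, 0.0107)
        assert delta == pytest.approx(expected, rel=1e-12)
        assert 85.0 < delta < 105.0  # the published order-of-magnitude target

    def test_first_order_linearity_in_spike(self):
        d1 = position_enrichment_from_mixing(1.0, 10000.0, 0.99, 0.0107)
        d2 = position_enrichment_from_mixing(2.0, 10000.0, 0.99, 0.0107)
        assert d2 == pytest.approx(2 * d1, rel=0.01)

    @given(
        moles=st.floats(0.1, 10.0),
        extra=st.floats(0.01, 5.0),
    )
    def test_strictly_increasing_in_labeled_moles(self, moles, extra):
        lo = position_enrichment_from_mixing(moles, 1000.0, 0.99, 0.0107)
        hi = position_enrichment_from_mixing(moles + extra, 1000.0, 0.99, 0.0107)
        assert hi > lo

    @given(
        x_label=st.floats(0.02, 0.98),
        bump=st.floats(0.001, 0.01),
    )
    def test_strictly_increasing_in_label_fraction(self, x_label, bump):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lo = position_enrichment_from_mixing(1.0, 100.0, x_label, 0.0107)
            hi = position_enrichment_from_mixing(1.0, 100.0, x_label + bump, 0.0107)
        assert hi > lo

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            position_enrichment_from_mixing(1.0, 1.0, 1.5, 0.0107)


class TestMassBalance:
    def test_nitrogen_three_halves_factor(self, molecule):
        assert fragment_calc_from_bulk(12.0, molecule, "F99", "N") == pytest.approx(
            18.0
        )

    def test_carbon_ten_fourths_factor(self, molecule):
        assert fragment_calc_from_bulk(2.5, molecule, "F99", "C") == pytest.approx(
            6.25
        )

    def test_zero_shift_maps_to_zero(self, molecule):
        assert fragment_calc_from_bulk(0.0, molecule, "F92", "C") == 0.0

    def test_fragment_without_element_raises(self, molecule):
        with pytest.raises(ValidationError):
            fragment_calc_from_bulk(1.0, molecule, "F92", "O")

    def test_bulk_from_fragments_nitrogen(self, molecule):
        assert bulk_from_fragments(
            {"F92": 30.0, "F99": 0.0}, molecule, "N"
        ) == pytest.approx(10.0)

    def test_bulk_from_fragments_carbon(self, molecule):
        assert bulk_from_fragments(
            {"F92": 0.0, "F99": 25.0}, molecule, "C"
        ) == pytest.approx(10.0)

    def test_equal_fragments_conserved(self, molecule):
        assert bulk_from_fragments(
            {"F92": -7.5, "F99": -7.5}, molecule, "C"
        ) == pytest.approx(-7.5)

    def test_incomplete_partition_raises(self, molecule):
        with pytest.raises(ValidationError, match="partition"):
            bulk_from_fragments({"F92": 5.0}, molecule, "N")

    @given(shift=st.floats(-50, 300), element=st.sampled_from(["C", "N"]))
    def test_round_trip_bulk_fragment_bulk(self, shift, element):
        for fragment, other in (("F92", "F99"), ("F99", "F92")):
            frag_delta = fragment_calc_from_bulk(shift, SMX, fragment, element)
            back = bulk_from_fragments(
                {fragment: frag_delta, other: 0.0}, SMX, element
            )
            assert back == pytest.approx(shift, abs=1e-9)

    def test_exact_oracle_close_to_first_order(self, molecule):
        approx = bulk_from_fragments({"F92": 30.0, "F99": 10.0}, molecule, "N")
        exact = exact_bulk_from_fragments({"F92": 30.0, "F99": 10.0}, molecule, "N")
        assert exact == pytest.approx(approx, abs=0.05)


class TestMoleculeDef:
    def test_partition_counts(self, molecule):
        assert molecule.fragment_count("F92", "N") == 1
        assert molecule.fragment_count("F99", "N") == 2
        assert molecule.fragment_count("F92", "C") == 6
        assert molecule.fragment_count("F99", "C") == 4

    def test_overfull_partition_rejected(self):
        with pytest.raises(ValidationError):
            MoleculeDef(
                "bad",
                ElementalFormula.from_string("C2H2"),
                {"A": {"C": 2}, "B": {"C": 1}},
            )

    def test_unknown_fragment_raises(self, molecule):
        with pytest.raises(ValidationError):
            molecule.fragment_count("F50", "C")


def test_catalog_has_six_unique_labels():
    labels = [s.label for s in smx_catalog()]
    assert len(labels) == len(set(labels)) == 6
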