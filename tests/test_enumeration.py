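"""Constraint derivation and formula enumeration vs the brute-force oracle."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npsid.enumeration import (
    ConstraintError,
    EnumerationConstraints,
    audit_candidate,
    brute_force_enumerate,
    derive_constraints,
    enumerate_formulas,
)
from npsid.isotopes import exclude_a2_elements
from npsid.precursor import PrecursorCall
from npsid.spectrum_io import Peak

AMT_CONSTRAINTS = EnumerationConstraints(
    target_mass=174,
    element_bounds={"C": (8, 15), "H": (7, 20), "N": (2, 4), "O": (0, 2), "F": (0, 1)},
    n_parity="even",
    min_rdbe=4.0,
)


def _hills(candidates):
    return [c.formula.hill() for c in candidates]


class TestEnumerate:
    def test_amt_case_yields_exactly_four_formulas(self):
        assert set(_hills(enumerate_formulas(AMT_CONSTRAINTS))) == {
            "C10H7FN2",
            "C9H10N4",
            "C10H10N2O",
            "C11H14N2",
        }

    def test_benzene_is_sole_hit_at_78(self):
        c = EnumerationConstraints(
            target_mass=78, element_bounds={"C": (0, 6), "H": (0, 6)}
        )
        assert _hills(enumerate_formulas(c)) == ["C6H6"]

    def test_contradictory_bounds_empty(self):
        c = EnumerationConstraints(target_mass=50, element_bounds={"C": (10, 12), "H": (0, 20)})
        assert enumerate_formulas(c) == []

    def test_rdbe_filter_removes_saturated_isobars(self):
        relaxed = EnumerationConstraints(
            target_mass=174,
            element_bounds=AMT_CONSTRAINTS.element_bounds,
            n_parity="even",
            min_rdbe=0.0,
        )
        unfiltered = set(_hills(enumerate_formulas(relaxed)))
        filtered = set(_hills(enumerate_formulas(AMT_CONSTRAINTS)))
        assert "C8H18N2O2" in unfiltered
        assert "C8H18N2O2" not in filtered
        assert filtered < unfiltered

    def test_output_order_stable(self):
        a = _hills(enumerate_formulas(AMT_CONSTRAINTS))
        b = _hills(enumerate_formulas(AMT_CONSTRAINTS))
        assert a == b
        rdbes = [c.rdbe for c in enumerate_formulas(AMT_CONSTRAINTS)]
        assert rdbes == sorted(rdbes, reverse=True)

    def test_exact_mode(self):
        c = EnumerationConstraints(
            target_mass=174.1157,
            element_bounds={"C": (0, 15), "H": (0, 20), "N": (0, 4), "O": (0, 2)},
            mode="exact",
            tolerance=0.001,  # ~6 ppm; 0.005 Da would also admit C6H14N4O2
        )
        assert _hills(enumerate_formulas(c)) == ["C11H14N2"]

    def test_every_candidate_passes_audit(self):
        for cand in enumerate_formulas(AMT_CONSTRAINTS):
            assert audit_candidate(cand, AMT_CONSTRAINTS)


bounded = st.tuples(st.integers(0, 4), st.integers(0, 12)).map(
    lambda t: (min(t), max(t))
)


@st.composite
def random_constraints(draw):
    bounds = {
        "C": draw(bounded),
        "H": (0, draw(st.integers(0, 20))),
        "N": draw(bounded),
        "O": draw(bounded),
    }
    if draw(st.booleans()):
        bounds["Cl"] = draw(bounded)
    return EnumerationConstraints(
        target_mass=draw(st.integers(16, 250)),
        element_bounds=bounds,
        n_parity=draw(st.sampled_from(["even", "odd", "any"])),
        min_rdbe=draw(st.sampled_from([0.0, 2.0, 4.0])),
        max_rdbe=draw(st.sampled_from([None, 8.0])),
    )


@settings(max_examples=100)
@given(random_constraints())
def test_enumerate_equals_brute_force_oracle(c):
    fast = {cf.formula.hill() for cf in enumerate_formulas(c)}
    slow = {cf.formula.hill() for cf in brute_force_enumerate(c)}
    assert fast == slow


def test_brute_force_refuses_huge_grids():
    c = EnumerationConstraints(
        target_mass=500,
        element_bounds={s: (0, 100) for s in ("C", "H", "N", "O", "S")},
    )
    with pytest.raises(ConstraintError):
        brute_force_enumerate(c, max_cells=10**6)


class TestDeriveConstraints:
    def _amt_evidence(self):
        call = PrecursorCall(mz=175, best_fragmentor=70.0, abundance_profile={})
        fragments = [Peak(77, 35), Peak(91, 48), Peak(103, 40), Peak(158, 100)]
        exclusions = exclude_a2_elements([100, 9.8, 0.7])
        return call, fragments, exclusions

    def test_amt_evidence_reproduces_generic_formula(self):
        call, fragments, exclusions = self._amt_evidence()
        c = derive_constraints(call, fragments, exclusions)
        assert c.target_mass == 174
        assert c.element_bounds["C"] == (8, 15)
        assert c.element_bounds["H"] == (7, 20)
        assert c.element_bounds["N"] == (2, 4)
        assert c.element_bounds["O"] == (0, 2)
        assert c.element_bounds["F"] == (0, 1)
        assert c.n_parity == "even"
        assert c.min_rdbe == 4.0
        for sym in ("S", "Cl", "Br", "I"):
            assert c.element_bounds[sym] == (0, 0)
        assert {"S", "Cl", "Br", "I"} <= set(c.excluded_elements)
        assert set(_hills(enumerate_formulas(c))) == {
            "C10H7FN2", "C9H10N4", "C10H10N2O", "C11H14N2",
        }

    def test_no_aromatic_markers_relaxes_rdbe_and_carbon(self):
        call = PrecursorCall(mz=175, best_fragmentor=70.0, abundance_profile={})
        exclusions = exclude_a2_elements([100, 9.8, 0.7])
        c = derive_constraints(call, [Peak(130, 10)], exclusions)
        assert c.min_rdbe == 0.0
        assert c.element_bounds["C"][0] == 0

    def test_iodine_excluded_by_mass_budget(self):
        call = PrecursorCall(mz=121, best_fragmentor=70.0, abundance_profile={})
        exclusions = exclude_a2_elements([100, 5, 0.2])
        c = derive_constraints(
            call, [Peak(103, 10)], exclusions
        )  # target 120, C >= 8: 120 - 127 < 96
        assert "I" in c.excluded_elements
        assert c.element_bounds["I"] == (0, 0)

    def test_missing_precursor_errors(self):
        with pytest.raises(ConstraintError, match="precursor"):
            derive_constraints(PrecursorCall(mz=None, best_fragmentor=None), [], [])
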