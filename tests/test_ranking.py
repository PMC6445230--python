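"""Database lookup, composite ranking, and the end-to-end pipeline."""

import dataclasses

import pytest

from npsid.enumeration import CandidateFormula
from npsid.formulas import nominal_mass, parse_formula, rdbe
from npsid.ranking_db import (
    PipelineError,
    lookup_formula,
    packaged_compound_db,
    rank_candidates,
    run_pipeline,
)


def _candidate(formula, iso=None, cov=None, hits=()):
    f = parse_formula(formula)
    return CandidateFormula(
        formula=f,
        nominal_mass=nominal_mass(f),
        rdbe=rdbe(f),
        isotope_score=iso,
        fragment_coverage=cov,
        db_hits=tuple(hits),
    )


class TestDatabase:
    def test_packaged_db_loads_and_validates(self, compound_db):
        assert len(compound_db) >= 50
        names = {rec.name for rec in compound_db}
        for expected in ("AMT", "5-IT", "5-MAPB", "bk-2C-B", "2C-B", "MDMA",
                         "amphetamine", "ketamine", "cocaine", "morphine"):
            assert expected in names
        # (name, formula) pairs unique
        keys = [(r.name, r.neutral_formula.hill()) for r in compound_db]
        assert len(keys) == len(set(keys))

    def test_amt_isomer_ambiguity_set(self, compound_db):
        hits = lookup_formula(compound_db, parse_formula("C11H14N2"))
        names = [h.name for h in hits]
        assert "AMT" in names and "5-IT" in names
        assert len(hits) >= 2
        assert names == sorted(names, key=str.lower)

    def test_5mapb_lookup(self, compound_db):
        names = {h.name for h in lookup_formula(compound_db, parse_formula("C12H15NO"))}
        assert "5-MAPB" in names

    def test_unknown_formula_empty(self, compound_db):
        assert lookup_formula(compound_db, parse_formula("C1H4")) == []

    def test_db_round_trips_through_csv(self, tmp_path, compound_db):
        from npsid.ranking_db import load_compound_db

        path = tmp_path / "db.csv"
        lines = ["name,synonyms,formula,class"]
        for rec in compound_db:
            syns = "|".join(rec.synonyms) or "-"
            lines.append(
                f"{rec.name},{syns},{rec.neutral_formula.hill()},{rec.compound_class}"
            )
        path.write_text("\n".join(lines) + "\n")
        back = load_compound_db(path)
        assert [(r.name, r.neutral_formula.hill()) for r in back] == [
            (r.name, r.neutral_formula.hill()) for r in compound_db
        ]


class TestRankCandidates:
    def test_single_candidate_first(self):
        ranked = rank_candidates([_candidate("C11H14N2", iso=0.9, cov=1.0)])
        assert len(ranked) == 1
        assert ranked[0].composite_score == pytest.approx(0.3 * 0.9 + 0.5)

    def test_monotone_in_each_component(self):
        base = _candidate("C11H14N2", iso=0.5, cov=0.5)
        better_iso = dataclasses.replace(base, isotope_score=0.9)
        better_cov = dataclasses.replace(base, fragment_coverage=0.9)
        with_db = dataclasses.replace(base, db_hits=("AMT",))
        score = lambda c: rank_candidates([c])[0].composite_score
        assert score(better_iso) > score(base)
        assert score(better_cov) > score(base)
        assert score(with_db) > score(base)

    def test_tie_break_by_rdbe_then_hill(self):
        # identical evidence: C10H10N2O (rdbe 7) loses to C11H14N2 (rdbe 6)
        a = _candidate("C10H10N2O", iso=0.8, cov=1.0)
        b = _candidate("C11H14N2", iso=0.8, cov=1.0)
        ranked = rank_candidates([a, b])
        assert ranked[0].formula.hill() == "C11H14N2"

    def test_weights_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="renormaliz"):
            ranked = rank_candidates(
                [_candidate("C11H14N2", iso=1.0, cov=1.0, hits=("AMT",))],
                weights=(3.0, 5.0, 2.0),
            )
        assert ranked[0].composite_score == pytest.approx(1.0)


class TestPipeline:
    def test_amt_fixture_end_to_end(self, amt_fixture):
        report = run_pipeline(*amt_fixture)
        assert report.precursor.mz == 175
        assert report.precursor.best_fragmentor == 70
        assert {c.formula.hill() for c in report.candidates} == {
            "C10H7FN2", "C9H10N4", "C10H10N2O", "C11H14N2",
        }
        assert report.top.formula.hill() == "C11H14N2"
        assert set(report.top.db_hits) == {"AMT", "5-IT"}
        stages = [r["stage"] for r in report.applied_rules]
        for stage in ("precursor_selection", "a2_exclusion", "nitrogen_rule",
                      "derive_constraints", "enumerate_formulas", "rank_candidates"):
            assert stage in stages

    def test_synthetic_5mapb_recovered(self):
        from npsid.ranking_db import packaged_compound_db
        from npsid.synthetic import (
            SimulationConfig,
            default_fragment_template,
            simulate_ms1,
            simulate_ms2,
        )

        rec = next(r for r in packaged_compound_db() if r.name == "5-MAPB")
        cfg = SimulationConfig(
            compound=rec,
            fragment_template=default_fragment_template(rec),
            intensity_noise_sigma=0.0,
            seed=11,
        )
        report = run_pipeline(simulate_ms1(cfg), simulate_ms2(cfg))
        assert report.top.formula.hill() == "C12H15NO"
        assert "5-MAPB" in report.top.db_hits

    def test_empty_ms2_degraded_mode(self, amt_fixture):
        ms1, _ = amt_fixture
        report = run_pipeline(ms1, [])
        assert report.candidates  # still ranked, by isotope score alone
        assert all(c.fragment_coverage is None for c in report.candidates)
        assert any(
            "no fragment evidence" in r["description"] for r in report.applied_rules
        )

    def test_report_deterministic(self, tmp_path, amt_fixture):
        from npsid.spectrum_io import write_report

        r1 = run_pipeline(*amt_fixture)
        r2 = run_pipeline(*amt_fixture)
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_report(r1, p1)
        write_report(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_no_precursor_without_fallback_errors(self):
        from npsid.spectrum_io import Peak, Spectrum

        scans = [
            Spectrum(peaks=(Peak(120, 9000),), scan_type="MS1", fragmentor_voltage=110),
            Spectrum(peaks=(Peak(120, 1000),), scan_type="MS1", fragmentor_voltage=40),
        ]
        with pytest.raises(PipelineError, match="precursor"):
            run_pipeline(scans, [])

    def test_user_supplied_precursor_fallback(self, amt_fixture):
        from npsid.config import load_config
        from npsid.spectrum_io import Peak, Spectrum

        scans = [
            Spectrum(peaks=(Peak(175, 9000), Peak(176, 990)), scan_type="MS1",
                     fragmentor_voltage=110),
            Spectrum(peaks=(Peak(175, 1000), Peak(176, 110)), scan_type="MS1",
                     fragmentor_voltage=40),
        ]
        cfg = load_config(precursor_mz=175)
        report = run_pipeline(scans, amt_fixture[1], cfg)
        assert report.precursor.mz == 175
        assert report.top.formula.hill() == "C11H14N2"
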