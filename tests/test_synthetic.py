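"""The synthetic acquisition generator: determinism, closed forms, physics."""

import json
import math

import numpy as np
import pytest

from npsid.formulas import nominal_mass
from npsid.isotopes import simulate_pattern
from npsid.ranking_db import packaged_compound_db, run_pipeline
from npsid.synthetic import (
    SimulationConfig,
    TemplateError,
    benchmark_eligible,
    default_fragment_template,
    make_benchmark,
    simulate_ms1,
    simulate_ms2,
)


def _record(name):
    return next(r for r in packaged_compound_db() if r.name == name)


def _config(name, sigma=0.0, seed=1, **kw):
    rec = _record(name)
    return SimulationConfig(
        compound=rec,
        fragment_template=default_fragment_template(rec),
        intensity_noise_sigma=sigma,
        seed=seed,
        **kw,
    )


class TestDeterminismAndClosedForm:
    def test_same_seed_identical_spectra(self):
        a = simulate_ms1(_config("AMT", sigma=0.05))
        b = simulate_ms1(_config("AMT", sigma=0.05))
        for s1, s2 in zip(a, b):
            assert s1.peaks == s2.peaks

    def test_different_seed_differs(self):
        a = simulate_ms1(_config("AMT", sigma=0.05, seed=1))
        b = simulate_ms1(_config("AMT", sigma=0.05, seed=2))
        assert any(s1.peaks != s2.peaks for s1, s2 in zip(a, b))

    def test_noiseless_ms1_matches_logistic_times_pattern(self):
        cfg = _config("AMT", sigma=0.0)
        mh = cfg.compound.neutral_formula.protonated()
        mh_mz = nominal_mass(mh)
        pattern = simulate_pattern(mh, prune_threshold=1e-4)
        for scan in simulate_ms1(cfg):
            v = scan.fragmentor_voltage
            surv = 1.0 / (1.0 + math.exp((v - cfg.survival_midpoint) / cfg.survival_width))
            trans = min(1.0, v / 60.0)
            expected = 10000.0 * surv * trans
            assert scan.intensity_at(mh_mz, tol=0.25) == pytest.approx(expected, rel=1e-9)
            assert scan.intensity_at(mh_mz + 1, tol=0.25) == pytest.approx(
                expected * pattern.abundance(1), rel=1e-9
            )

    def test_precursor_peaks_at_interior_voltage(self):
        cfg = _config("AMT", sigma=0.0)
        mh_mz = nominal_mass(cfg.compound.neutral_formula.protonated())
        profile = {
            s.fragmentor_voltage: s.intensity_at(mh_mz, tol=0.25)
            for s in simulate_ms1(cfg)
        }
        assert max(profile, key=profile.get) == 70.0


class TestMs2:
    def test_amt_diagnostic_fragments_at_exact_mz(self):
        rec = _record("AMT")
        cfg = SimulationConfig(
            compound=rec,
            fragment_template=(("C6H5+", 35.0), ("C7H7+", 48.0),
                               ("C8H7+", 40.0), ("ammonia", 100.0)),
            intensity_noise_sigma=0.0,
            seed=1,
        )
        scan = simulate_ms2(cfg)[-1]  # highest CE: fragments dominant
        for mz in (77, 91, 103, 158):
            assert scan.intensity_at(mz, tol=0.25) > 0

    def test_bk2cb_bromine_doublet_ratio(self):
        """274/276 'at similar intensities' within 3 sigma of the isotope ratio."""
        cfg = _config("bk-2C-B", sigma=0.05)
        mh = cfg.compound.neutral_formula.protonated()
        assert nominal_mass(mh) == 274
        theory = simulate_pattern(mh).abundance(2)
        scan = simulate_ms2(cfg)[0]  # low CE: precursor cluster dominant
        ratio = scan.intensity_at(276, tol=0.25) / scan.intensity_at(274, tol=0.25)
        # two lognormal(sigma=0.05) factors: 3 sigma on the log-ratio
        assert abs(math.log(ratio / theory)) < 3 * 0.05 * math.sqrt(2)

    def test_precursor_survival_decreases_with_ce(self):
        cfg = _config("AMT", sigma=0.0)
        mh_mz = nominal_mass(cfg.compound.neutral_formula.protonated())
        intensities = [s.intensity_at(mh_mz, tol=0.25) for s in simulate_ms2(cfg)]
        assert intensities == sorted(intensities, reverse=True)

    def test_empty_template_precursor_only(self):
        rec = _record("AMT")
        cfg = SimulationConfig(compound=rec, fragment_template=(), seed=0,
                               intensity_noise_sigma=0.0)
        for scan in simulate_ms2(cfg):
            assert all(p.mz >= 175 for p in scan.peaks)

    def test_inapplicable_loss_names_entry(self):
        rec = _record("amphetamine")  # C9H13N: no oxygen
        cfg = SimulationConfig(compound=rec, fragment_template=(("water", 50.0),),
                               seed=0)
        with pytest.raises(TemplateError, match="water"):
            simulate_ms2(cfg)


def test_cluster_ratio_converges_over_replicates():
    """Mean simulated M+1/M+0 ratio approaches theory (law of large numbers)."""
    rec = _record("AMT")
    mh = rec.neutral_formula.protonated()
    theory = simulate_pattern(mh).abundance(1)
    mh_mz = nominal_mass(mh)
    ratios = []
    for seed in range(100):
        cfg = SimulationConfig(compound=rec, fragment_template=(),
                               intensity_noise_sigma=0.05, seed=seed)
        scan = simulate_ms1(cfg)[2]  # 70 eV
        ratios.append(scan.intensity_at(mh_mz + 1, 0.25) / scan.intensity_at(mh_mz, 0.25))
    ratios = np.asarray(ratios)
    # ratio of two lognormals is lognormal; compare means on the log scale
    se = ratios.std(ddof=1) / math.sqrt(len(ratios))
    assert abs(ratios.mean() - theory * math.exp(0.05**2)) < 3 * se


class TestBenchmark:
    def test_eligible_compounds_have_unique_in_bounds_masses(self):
        eligible = benchmark_eligible()
        assert len(eligible) >= 20
        by_mass = {}
        for rec in eligible:
            by_mass.setdefault(nominal_mass(rec.neutral_formula), set()).add(
                rec.neutral_formula.hill()
            )
        assert all(len(v) == 1 for v in by_mass.values())

    def test_bundle_deterministic_and_processable(self, tmp_path):
        cases = make_benchmark(3, seed=7, noise_sigma=0.05, out_dir=tmp_path / "b1")
        again = make_benchmark(3, seed=7, noise_sigma=0.05, out_dir=tmp_path / "b2")
        assert [c["compound"] for c in cases] == [c["compound"] for c in again]
        for c1, c2 in zip(cases, again):
            for s1, s2 in zip(c1["ms1"] + c1["ms2"], c2["ms1"] + c2["ms2"]):
                assert s1.peaks == s2.peaks
        manifest = json.loads((tmp_path / "b1" / "manifest.json").read_text())
        assert len(manifest["cases"]) == 3
        for entry, case in zip(manifest["cases"], cases):
            assert entry["formula"] == case["formula"]
            for fname in entry["files"]:
                assert (tmp_path / "b1" / fname).exists()
        # every synthetic case is fully processable end to end
        for case in cases:
            report = run_pipeline(case["ms1"], case["ms2"])
            assert report.candidates

    def test_invalid_n_cases(self):
        with pytest.raises(ValueError):
            make_benchmark(0)
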