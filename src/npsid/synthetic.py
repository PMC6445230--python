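"""Synthetic unit-resolution QQQ acquisitions for end-to-end testing.

The generator emulates the phenomena the identification strategy relies
on, with a typical QQQ screening acquisition grid (MS1 scans at
fragmentor voltages 110/90/70/40 eV; product-ion scans at collision
energies 10/20/30/40 eV):

* the isotope cluster of the protonated molecule, from the exact
  multinomial isotope model;
* in-source fragmentation that grows with fragmentor voltage, modelled as
  logistic precursor survival, combined with ion transmission that falls
  linearly below 60 eV — so precursor abundance peaks at an interior
  voltage, as observed on real instruments;
* CE-dependent fragment spectra from a per-compound template of diagnostic
  ions and neutral losses;
* multiplicative lognormal intensity noise (no m/z noise at unit
  resolution), fully determined by an explicit seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .enumeration import DEFAULT_ELEMENT_BOUNDS
from .formulas import Formula, nominal_mass, parse_formula
from .fragments import DIAGNOSTIC_IONS, packaged_loss_table
from .isotopes import simulate_pattern
from .ranking_db import CompoundRecord, packaged_compound_db
from .spectrum_io import Peak, Spectrum, write_peaklist

__all__ = [
    "SimulationConfig",
    "TemplateError",
    "default_fragment_template",
    "simulate_ms1",
    "simulate_ms2",
    "grey_red_powder_fixture",
    "benchmark_eligible",
    "make_benchmark",
]

#: Arbitrary full-scale intensity of an undepleted precursor.
_FULL_SCALE = 10000.0

#: Fragmentor voltage below which ion transmission falls off linearly.
_TRANSMISSION_KNEE = 60.0


class TemplateError(ValueError):
    """A fragment-template entry that cannot apply to the compound."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to simulate one compound's acquisition, reproducibly."""

    compound: CompoundRecord
    fragmentor_voltages: Tuple[float, ...] = (110.0, 90.0, 70.0, 40.0)
    collision_energies: Tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)
    fragment_template: Tuple[Tuple[str, float], ...] = ()
    survival_midpoint: float = 90.0
    survival_width: float = 15.0
    ce_midpoint: float = 20.0
    ce_width: float = 8.0
    intensity_noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.fragmentor_voltages)) != len(self.fragmentor_voltages):
            raise ValueError("fragmentor voltages must be distinct")
        if len(set(self.collision_energies)) != len(self.collision_energies):
            raise ValueError("collision energies must be distinct")
        if any(i <= 0 for _, i in self.fragment_template):
            raise ValueError("template intensities must be positive")
        if self.intensity_noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def default_fragment_template(compound: CompoundRecord) -> Tuple[Tuple[str, float], ...]:
    """A generic fragment template from the compound's elemental composition.

    Adds the neutral losses applicable to the protonated molecule
    (ammonia/HCN for nitrogen compounds, water/CO for oxygen compounds,
    methylamine where removable) and the aromatic marker cations that fit
    inside it.  This is compositional plumbing, not compound-specific
    fragmentation chemistry.
    """
    mh = compound.neutral_formula.protonated()
    template: List[Tuple[str, float]] = []
    wanted_losses = [
        ("ammonia", 100.0),
        ("methylamine", 50.0),
        ("water", 60.0),
        ("hydrogen cyanide", 30.0),
    ]
    table = {entry.name: entry for entry in packaged_loss_table()}
    for name, rel in wanted_losses:
        entry = table[name]
        if mh.contains(entry.formula) and nominal_mass(mh) - entry.nominal_mass > 40:
            template.append((name, rel))
    for mz, (formula_str, _label) in sorted(DIAGNOSTIC_IONS.items()):
        ion = parse_formula(formula_str)
        if mh.contains(Formula(ion.counts)):
            template.append((formula_str, 40.0 + 0.15 * mz))
    return tuple(template)


def _resolve_template(
    config: SimulationConfig,
) -> List[Tuple[int, float]]:
    """Template entries -> (fragment m/z, relative intensity), validated."""
    mh = config.compound.neutral_formula.protonated()
    mh_mz = nominal_mass(mh)
    losses = {entry.name: entry for entry in packaged_loss_table()}
    out: List[Tuple[int, float]] = []
    for name, rel in config.fragment_template:
        if name in losses:
            entry = losses[name]
            if not mh.contains(entry.formula):
                raise TemplateError(
                    f"loss {name!r} ({entry.formula.hill()}) not applicable to "
                    f"{config.compound.name} [M+H]+ = {mh.hill()}"
                )
            out.append((mh_mz - entry.nominal_mass, rel))
        else:
            try:
                ion = parse_formula(name)
            except Exception as exc:
                raise TemplateError(f"template entry {name!r} is neither a known "
                                    f"loss nor a formula") from exc
            if not mh.contains(Formula(ion.counts)):
                raise TemplateError(
                    f"template ion {name!r} is not a subformula of "
                    f"{config.compound.name} [M+H]+ = {mh.hill()}"
                )
            out.append((nominal_mass(ion), rel))
    return out


def _survival_fragmentor(v: float, config: SimulationConfig) -> float:
    return 1.0 / (1.0 + math.exp((v - config.survival_midpoint) / config.survival_width))


def _transmission(v: float) -> float:
    return min(1.0, v / _TRANSMISSION_KNEE)


def _survival_ce(ce: float, config: SimulationConfig) -> float:
    return 1.0 / (1.0 + math.exp((ce - config.ce_midpoint) / config.ce_width))


def _noisy(value: float, rng: np.random.Generator, sigma: float) -> float:
    if sigma == 0:
        return value
    return value * float(rng.lognormal(mean=0.0, sigma=sigma))


def _cluster_peaks(
    mh_mz: int, pattern_lines: Dict[int, float], scale: float,
    rng: np.random.Generator, sigma: float,
) -> List[Peak]:
    peaks = []
    for offset, rel in sorted(pattern_lines.items()):
        inten = _noisy(scale * rel, rng, sigma)
        if inten > 0:
            peaks.append(Peak(float(mh_mz + offset), inten))
    return peaks


def simulate_ms1(config: SimulationConfig) -> List[Spectrum]:
    """MS1 scans across the fragmentor-voltage series.

    Per voltage v: the precursor isotope cluster scaled by
    survival(v) x transmission(v), plus in-source fragment peaks from the
    template scaled by (1 - survival(v)) x transmission(v), with
    multiplicative lognormal noise.  Deterministic for a fixed seed.
    """
    mh = config.compound.neutral_formula.protonated()
    mh_mz = nominal_mass(mh)
    pattern = simulate_pattern(mh, prune_threshold=1e-4)
    template = _resolve_template(config)
    rng = np.random.default_rng(config.seed)
    scans: List[Spectrum] = []
    for v in config.fragmentor_voltages:
        surv = _survival_fragmentor(v, config)
        trans = _transmission(v)
        peaks = _cluster_peaks(
            mh_mz, pattern.lines, _FULL_SCALE * surv * trans,
            rng, config.intensity_noise_sigma,
        )
        for fmz, rel in template:
            inten = _noisy(
                _FULL_SCALE * (rel / 100.0) * (1.0 - surv) * trans,
                rng, config.intensity_noise_sigma,
            )
            if inten > 0:
                peaks.append(Peak(float(fmz), inten))
        scans.append(
            Spectrum(
                peaks=tuple(peaks),
                scan_type="MS1",
                fragmentor_voltage=v,
                polarity="positive",
                label=f"{config.compound.name} MS1 @ {v:g} eV",
            )
        )
    return scans


def simulate_ms2(config: SimulationConfig) -> List[Spectrum]:
    """Product-ion scans across the collision-energy series.

    Per CE: surviving precursor cluster (logistic decay in CE) plus
    template fragments scaled by (1 - survival).  Noise and seed semantics
    as in :func:`simulate_ms1` (a distinct stream derived from the seed).
    """
    mh = config.compound.neutral_formula.protonated()
    mh_mz = nominal_mass(mh)
    pattern = simulate_pattern(mh, prune_threshold=1e-4)
    template = _resolve_template(config)
    rng = np.random.default_rng((config.seed, 1))
    scans: List[Spectrum] = []
    for ce in config.collision_energies:
        surv = _survival_ce(ce, config)
        peaks = _cluster_peaks(
            mh_mz, pattern.lines, _FULL_SCALE * surv,
            rng, config.intensity_noise_sigma,
        )
        for fmz, rel in template:
            inten = _noisy(
                _FULL_SCALE * (rel / 100.0) * (1.0 - surv),
                rng, config.intensity_noise_sigma,
            )
            if inten > 0:
                peaks.append(Peak(float(fmz), inten))
        scans.append(
            Spectrum(
                peaks=tuple(peaks),
                scan_type="MS2",
                collision_energy=ce,
                polarity="positive",
                label=f"{config.compound.name} MS2 @ CE {ce:g} eV",
            )
        )
    return scans


# ---------------------------------------------------------------------------
# the grey/red-powder AMT case, as a packaged fixture


def grey_red_powder_fixture() -> Tuple[List[Spectrum], List[Spectrum]]:
    """The grey/red-powder unknown with its canonical measured values, noiseless.

    MS1 scans at 110/90/70/40 eV in which the m/z 175 ion is most abundant
    at 70 eV, carrying the reported isotope cluster 175:100 / 176:9.8 /
    177:0.7 (relative %), with the dominant in-source fragment at 158;
    MS2 scans whose merged fragment list is 77, 91, 103, 158.
    """
    cluster = {0: 1.0, 1: 0.098, 2: 0.007}
    profile = {110.0: 0.21, 90.0: 0.50, 70.0: 0.79, 40.0: 0.61}
    ms1 = []
    for v, surv in profile.items():
        peaks = [Peak(175.0 + off, _FULL_SCALE * surv * rel) for off, rel in cluster.items()]
        peaks.append(Peak(158.0, _FULL_SCALE * (1.0 - surv) * min(1.0, v / _TRANSMISSION_KNEE)))
        ms1.append(
            Spectrum(
                peaks=tuple(peaks), scan_type="MS1", fragmentor_voltage=v,
                label=f"unknown MS1 @ {v:g} eV",
            )
        )
    fragments = {77.0: 35.0, 91.0: 48.0, 103.0: 40.0, 158.0: 100.0}
    ms2 = []
    for ce in (10.0, 20.0, 30.0, 40.0):
        surv = 1.0 / (1.0 + math.exp((ce - 20.0) / 8.0))
        peaks = [Peak(175.0 + off, _FULL_SCALE * surv * rel) for off, rel in cluster.items()]
        peaks.extend(
            Peak(mz, _FULL_SCALE * (rel / 100.0) * (1.0 - surv))
            for mz, rel in fragments.items()
        )
        ms2.append(
            Spectrum(
                peaks=tuple(peaks), scan_type="MS2", collision_energy=ce,
                label=f"unknown MS2 @ CE {ce:g} eV",
            )
        )
    return ms1, ms2


# ---------------------------------------------------------------------------
# benchmark bundles


def benchmark_eligible(
    db: Optional[Sequence[CompoundRecord]] = None,
    bounds: Optional[Dict[str, Tuple[int, int]]] = None,
) -> List[CompoundRecord]:
    """DB compounds whose formula the default pipeline can recover.

    A compound is eligible when its formula lies inside the default
    enumeration bounds and no *different* in-bounds DB formula shares its
    nominal mass: at unit resolution two distinct same-mass database
    formulas are genuinely undecidable without compound-specific spectral
    libraries, which is not what the recovery benchmark measures.
    """
    db = list(db) if db is not None else packaged_compound_db()
    bounds = bounds or DEFAULT_ELEMENT_BOUNDS

    def in_bounds(f: Formula) -> bool:
        return all(
            sym in bounds and n <= bounds[sym][1] for sym, n in f.counts.items()
        )

    by_mass: Dict[int, set] = {}
    for rec in db:
        if in_bounds(rec.neutral_formula):
            by_mass.setdefault(nominal_mass(rec.neutral_formula), set()).add(
                rec.neutral_formula.hill()
            )
    return [
        rec for rec in db
        if in_bounds(rec.neutral_formula)
        and len(by_mass[nominal_mass(rec.neutral_formula)]) == 1
    ]


def make_benchmark(
    n_cases: int,
    seed: int = 0,
    noise_sigma: float = 0.05,
    out_dir: Optional[Union[str, Path]] = None,
) -> List[dict]:
    """Generate a labelled bundle of simulated cases from the packaged DB.

    Each case holds MS1 + MS2 simulations of one eligible compound with a
    per-case seed derived from ``seed``.  When ``out_dir`` is given the
    spectra are written as CSV peak lists with a JSON manifest; the
    in-memory bundle is returned either way.  Identical seeds give
    identical bundles.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    pool = benchmark_eligible()
    # unique formulas, deterministic order
    by_formula: Dict[str, CompoundRecord] = {}
    for rec in sorted(pool, key=lambda r: r.name.lower()):
        by_formula.setdefault(rec.neutral_formula.hill(), rec)
    records = list(by_formula.values())
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))
    chosen = [records[idx[i % len(records)]] for i in range(n_cases)]
    cases: List[dict] = []
    manifest = {"seed": seed, "noise_sigma": noise_sigma, "cases": []}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i, rec in enumerate(chosen):
        case_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SimulationConfig(
            compound=rec,
            fragment_template=default_fragment_template(rec),
            intensity_noise_sigma=noise_sigma,
            seed=case_seed,
        )
        ms1, ms2 = simulate_ms1(cfg), simulate_ms2(cfg)
        entry = {
            "case": i,
            "compound": rec.name,
            "formula": rec.neutral_formula.hill(),
            "nominal_mass": nominal_mass(rec.neutral_formula),
            "seed": case_seed,
            "files": [],
        }
        if out_path is not None:
            for s in ms1 + ms2:
                tag = (
                    f"f{s.fragmentor_voltage:g}" if s.scan_type == "MS1"
                    else f"ce{s.collision_energy:g}"
                )
                fname = f"case{i:03d}_{s.scan_type.lower()}_{tag}.csv"
                write_peaklist(s, out_path / fname)
                entry["files"].append(fname)
        manifest["cases"].append(
            {k: v for k, v in entry.items() if k != "files"} | {"files": entry["files"]}
        )
        cases.append({**entry, "ms1": ms1, "ms2": ms2, "config": cfg})
    if out_path is not None:
        (out_path / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )
    return cases
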