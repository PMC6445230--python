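"""Candidate ranking, compound-database resolution, and the full pipeline.

The final stage of the identification workflow: each enumerated candidate
formula is scored by (i) how well its simulated isotope cluster matches
the measured one, (ii) how much of the product-ion signal it explains,
and (iii) whether it resolves to named compounds in the packaged NPS
table.  Identification is at formula level only — isomers sharing a
formula (e.g. AMT and 5-IT, both C11H14N2) are reported together as an
ambiguity set, to be separated by an orthogonal technique such as NMR.

:func:`run_pipeline` chains every stage in the order an analyst applies
them and logs each rule with its parameters and outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from . import __version__ as _VERSION
from .config import RunConfig
from .enumeration import (
    CandidateFormula,
    EnumerationConstraints,
    derive_constraints,
    enumerate_formulas,
)
from .formulas import Formula, nominal_mass, parse_formula, rdbe
from .fragments import (
    assign_subformulas,
    explanation_coverage,
    load_loss_table,
    packaged_loss_table,
)
from .isotopes import ElementExclusion, exclude_a2_elements, isotope_fit_score, nitrogen_parity
from .precursor import PrecursorCall, select_precursor
from .spectrum_io import Peak, Spectrum, bin_to_unit_resolution, normalize_to_base_peak

__all__ = [
    "CompoundRecord",
    "IdentificationReport",
    "PipelineError",
    "load_compound_db",
    "packaged_compound_db",
    "lookup_formula",
    "rank_candidates",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass(frozen=True)
class CompoundRecord:
    """One entry of the compound table: a named compound and its neutral formula."""

    name: str
    synonyms: Tuple[str, ...]
    neutral_formula: Formula
    compound_class: str = ""

    def __post_init__(self) -> None:
        if nominal_mass(self.neutral_formula) <= 0:
            raise ValueError(f"{self.name}: formula has non-positive mass")


def _records_from_frame(df: pd.DataFrame) -> List[CompoundRecord]:
    records: List[CompoundRecord] = []
    seen = set()
    for row in df.to_dict("records"):
        syns = tuple(
            s.strip() for s in str(row.get("synonyms", "")).split("|")
            if s.strip() and s.strip() != "-"
        )
        rec = CompoundRecord(
            name=str(row["name"]).strip(),
            synonyms=syns,
            neutral_formula=parse_formula(str(row["formula"]).strip()),
            compound_class=str(row.get("class", "")).strip(),
        )
        key = (rec.name, rec.neutral_formula.hill())
        if key in seen:
            raise ValueError(f"duplicate compound record: {key}")
        seen.add(key)
        records.append(rec)
    return records


def load_compound_db(path: Union[str, Path]) -> List[CompoundRecord]:
    """Load a compound table from CSV (name, synonyms |-separated, formula, class)."""
    df = pd.read_csv(path, comment="#")
    return _records_from_frame(df)


def packaged_compound_db() -> List[CompoundRecord]:
    """The packaged, versioned table of NPS and common drugs of abuse."""
    with resources.as_file(
        resources.files("npsid.data").joinpath("nps_compounds.csv")
    ) as p:
        return load_compound_db(p)


def lookup_formula(db: Sequence[CompoundRecord], f: Formula) -> List[CompoundRecord]:
    """All records whose neutral formula equals ``f``, alphabetical by name.

    Canonical Hill-string comparison; multiple hits are an isomer
    ambiguity set.
    """
    target = Formula(f.counts).hill()
    hits = [rec for rec in db if rec.neutral_formula.hill() == target]
    return sorted(hits, key=lambda rec: rec.name.lower())


@dataclass(frozen=True)
class IdentificationReport:
    """The pipeline's final product: ranked candidates plus full rationale."""

    precursor: PrecursorCall
    constraints: Optional[EnumerationConstraints]
    candidates: Tuple[CandidateFormula, ...]
    applied_rules: Tuple[Dict[str, str], ...]
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def top(self) -> Optional[CandidateFormula]:
        return self.candidates[0] if self.candidates else None

    def to_dict(self) -> dict:
        return {
            "precursor": {
                "mz": self.precursor.mz,
                "best_fragmentor": self.precursor.best_fragmentor,
                "abundance_profile": {
                    str(v): i for v, i in sorted(self.precursor.abundance_profile.items())
                },
            },
            "constraints": None
            if self.constraints is None
            else {
                "target_mass": self.constraints.target_mass,
                "element_bounds": {
                    s: list(b) for s, b in sorted(self.constraints.element_bounds.items())
                },
                "n_parity": self.constraints.n_parity,
                "min_rdbe": self.constraints.min_rdbe,
                "max_rdbe": self.constraints.max_rdbe,
                "excluded_elements": sorted(self.constraints.excluded_elements),
                "mode": self.constraints.mode,
            },
            "candidates": [c.to_dict() for c in self.candidates],
            "no_candidates": not self.candidates,
            "applied_rules": [dict(r) for r in self.applied_rules],
            "provenance": dict(self.provenance),
        }


def rank_candidates(
    candidates: Sequence[CandidateFormula],
    weights: Tuple[float, float, float] = (0.3, 0.5, 0.2),
) -> List[CandidateFormula]:
    """Rank candidates by the composite evidence score.

    composite = w1*isotope_score + w2*fragment_coverage + w3*[has DB hit];
    absent components contribute 0.  Ties break by lower |RDBE - 6| (the
    unsaturation typical of one aromatic ring plus a fused/substituted
    system in this compound class), then by Hill string.  Weights not
    summing to 1 are renormalized with a warning.
    """
    total = sum(weights)
    if abs(total - 1.0) > 1e-9:
        warnings.warn(f"ranking weights sum to {total:g}; renormalizing", stacklevel=2)
        weights = tuple(w / total for w in weights)  # type: ignore[assignment]
    w_iso, w_cov, w_db = weights
    scored = []
    for c in candidates:
        composite = (
            w_iso * (c.isotope_score or 0.0)
            + w_cov * (c.fragment_coverage or 0.0)
            + w_db * (1.0 if c.db_hits else 0.0)
        )
        scored.append(replace(c, composite_score=composite))
    scored.sort(
        key=lambda c: (
            -c.composite_score,
            abs(c.rdbe - 6.0),
            c.formula.hill(),
        )
    )
    return scored


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _merged_fragments(
    ms2_scans: Sequence[Spectrum], precursor_mz: int
) -> List[Peak]:
    """Union of integer-binned MS2 peaks below the precursor isotope region.

    Each scan is normalized to base peak 100 and binned; across collision
    energies a fragment keeps its maximum relative intensity.  Peaks at or
    above precursor - 2 (the surviving precursor and its isotope lines)
    are not fragments.
    """
    merged: Dict[int, float] = {}
    for scan in ms2_scans:
        if not scan.peaks:
            continue
        binned = bin_to_unit_resolution(normalize_to_base_peak(scan))
        for p in binned.peaks:
            mz = int(p.mz)
            if mz >= precursor_mz - 2:
                continue
            merged[mz] = max(merged.get(mz, 0.0), p.intensity)
    return [Peak(float(mz), inten) for mz, inten in sorted(merged.items())]


def run_pipeline(
    ms1_scans: Sequence[Spectrum],
    ms2_scans: Sequence[Spectrum],
    config: Optional[RunConfig] = None,
) -> IdentificationReport:
    """Execute the full identification strategy on acquired spectra.

    Stages, in order: precursor selection from the fragmentor series;
    isotope-cluster extraction and A+2 element exclusion; nitrogen rule;
    constraint derivation; formula enumeration; per-candidate isotope fit,
    fragment annotation and database lookup; composite ranking.  Every
    stage appends a human-readable entry to ``applied_rules``.
    """
    cfg = config or RunConfig()
    rules: List[Dict[str, str]] = []

    def log(stage: str, description: str) -> None:
        rules.append({"stage": stage, "description": description})

    # --- stage 1: precursor -------------------------------------------------
    try:
        call = select_precursor(ms1_scans)
    except Exception as exc:
        raise PipelineError(f"precursor_selection: {exc}") from exc
    if not call.found:
        if cfg.precursor_mz is not None:
            call = PrecursorCall(
                mz=int(cfg.precursor_mz), best_fragmentor=None, abundance_profile={}
            )
            log("precursor_selection", f"no ion satisfied the selection rule; "
                f"using user-supplied precursor m/z {call.mz}")
        else:
            raise PipelineError(
                "precursor_selection: no precursor found and none supplied"
            )
    else:
        log(
            "precursor_selection",
            f"[M+H]+ called at m/z {call.mz} (abundance maximal at "
            f"{call.best_fragmentor:g} eV over voltages "
            f"{sorted(call.abundance_profile)})",
        )

    # --- stage 2: isotope cluster and A+2 exclusions ------------------------
    cluster = _measured_cluster(ms1_scans, call)
    log(
        "isotope_cluster",
        f"measured MH+0/+1/+2 = {cluster[0]:.1f}/{cluster[1]:.1f}/{cluster[2]:.1f} "
        f"(relative %, from the {_best_scan_desc(call)} scan)",
    )
    try:
        exclusions = exclude_a2_elements(cluster)
    except Exception as exc:
        raise PipelineError(f"a2_exclusion: {exc}") from exc
    for exc_rec in exclusions:
        log("a2_exclusion", f"{exc_rec.element}: {exc_rec.rationale}")

    # --- stage 3: nitrogen rule ---------------------------------------------
    target = call.mz - 1
    parity = nitrogen_parity(target)
    log("nitrogen_rule", f"neutral nominal mass {target} is {'even' if target % 2 == 0 else 'odd'} "
        f"=> nitrogen count must be {parity}")

    # --- stage 4: fragments and constraints ----------------------------------
    fragments = _merged_fragments(ms2_scans, call.mz)
    if fragments:
        log("fragments", f"{len(fragments)} merged fragment ions below the precursor: "
            + ", ".join(str(int(p.mz)) for p in fragments))
    else:
        log("fragments", "no fragment evidence; ranking will use the isotope score only")
    try:
        constraints = derive_constraints(call, fragments, exclusions, defaults=cfg.bounds)
        if cfg.mode == "exact":
            tol = cfg.tolerance
            if cfg.tolerance_unit == "ppm":
                tol = cfg.tolerance * 1e-6 * constraints.target_mass
            constraints = replace(constraints, mode="exact", tolerance=tol)
    except Exception as exc:
        raise PipelineError(f"derive_constraints: {exc}") from exc
    log("derive_constraints", _describe_constraints(constraints))

    # --- stage 5: enumeration -------------------------------------------------
    try:
        candidates = enumerate_formulas(constraints)
    except Exception as exc:
        raise PipelineError(f"enumerate_formulas: {exc}") from exc
    log("enumerate_formulas", f"{len(candidates)} candidate formulas at nominal mass "
        f"{int(constraints.target_mass)}: "
        + (", ".join(c.formula.hill() for c in candidates) or "none"))

    # --- stage 6: per-candidate evidence and ranking --------------------------
    db = (
        packaged_compound_db()
        if cfg.db_path == "packaged"
        else load_compound_db(cfg.db_path)
    )
    loss_table = (
        packaged_loss_table()
        if cfg.loss_table_path == "packaged"
        else load_loss_table(cfg.loss_table_path)
    )
    scored: List[CandidateFormula] = []
    for cand in candidates:
        iso = isotope_fit_score(cand.formula.protonated(), cluster)
        coverage = None
        if fragments:
            assignments = assign_subformulas(
                cand.formula, fragments, tolerance=cfg.tolerance, loss_table=loss_table
            )
            coverage = explanation_coverage(assignments, fragments)
        hits = tuple(rec.name for rec in lookup_formula(db, cand.formula))
        scored.append(
            replace(cand, isotope_score=iso, fragment_coverage=coverage, db_hits=hits)
        )
    ranked = rank_candidates(scored, cfg.weights)
    log("rank_candidates", f"composite = {cfg.weights[0]:g}*isotope + "
        f"{cfg.weights[1]:g}*coverage + {cfg.weights[2]:g}*db_hit; "
        + (f"top candidate {ranked[0].formula.hill()}" if ranked else "no candidates"))
    if ranked and ranked[0].db_hits:
        log("database", f"formula {ranked[0].formula.hill()} resolves to isomer "
            f"ambiguity set: {', '.join(ranked[0].db_hits)}")

    provenance = {
        "package_version": _VERSION,
        "config": cfg.to_dict(),
        "n_ms1_scans": len(ms1_scans),
        "n_ms2_scans": len(ms2_scans),
        "input_labels": [s.label for s in list(ms1_scans) + list(ms2_scans)],
    }
    return IdentificationReport(
        precursor=call,
        constraints=constraints,
        candidates=tuple(ranked),
        applied_rules=tuple(rules),
        provenance=provenance,
    )


def _measured_cluster(
    ms1_scans: Sequence[Spectrum], call: PrecursorCall
) -> Tuple[float, float, float]:
    """MH+0/+1/+2 intensities at the called precursor, normalized to 100."""
    best = None
    if call.best_fragmentor is not None:
        for s in ms1_scans:
            if float(s.fragmentor_voltage or -1) == float(call.best_fragmentor):
                best = s
                break
    if best is None:
        best = max(ms1_scans, key=lambda s: s.intensity_at(call.mz))
    binned = bin_to_unit_resolution(best)
    base = binned.intensity_at(call.mz, tol=0.25)
    if base <= 0:
        raise PipelineError(f"isotope_cluster: precursor m/z {call.mz} absent from MS1 scan")
    plus1 = binned.intensity_at(call.mz + 1, tol=0.25)
    plus2 = binned.intensity_at(call.mz + 2, tol=0.25)
    return (100.0, 100.0 * plus1 / base, 100.0 * plus2 / base)


def _best_scan_desc(call: PrecursorCall) -> str:
    if call.best_fragmentor is None:
        return "most intense"
    return f"{call.best_fragmentor:g} eV"


def _describe_constraints(c: EnumerationConstraints) -> str:
    bounds = ", ".join(
        f"{s}:{lo}-{hi}" for s, (lo, hi) in sorted(c.element_bounds.items()) if hi > 0
    )
    excl = ", ".join(sorted(c.excluded_elements)) or "none"
    return (
        f"target neutral mass {c.target_mass:g} ({c.mode}); bounds {bounds}; "
        f"N parity {c.n_parity}; RDBE >= {c.min_rdbe:g}; excluded: {excl}"
    )
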