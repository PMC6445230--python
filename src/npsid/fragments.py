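"""Fragment-ion annotation against a candidate precursor formula.

Product-ion spectra are explained in two complementary ways: a fragment
m/z may match a named small-molecule neutral loss from the protonated
precursor (ammonia, water, methylamine, ...), and/or an even-electron
cation subformula of the precursor.  Per-candidate explanation coverage —
the intensity-weighted fraction of fragment signal carrying at least one
explanation — is the main discriminator between isobaric candidate
formulas at unit resolution.

The subformula search allows the fragment to retain the ionizing proton
(+1 H over the neutral precursor counts) and requires cation RDBE >= 0.5,
the minimum for an even-electron cation; no further hydrogen
rearrangement is modelled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .formulas import Formula, nominal_mass, parse_formula, rdbe
from .spectrum_io import Peak

__all__ = [
    "NeutralLossEntry",
    "FragmentAssignment",
    "DIAGNOSTIC_IONS",
    "packaged_loss_table",
    "load_loss_table",
    "neutral_loss",
    "assign_subformulas",
    "brute_force_subformulas",
    "explanation_coverage",
]

#: Diagnostic aromatic cations: m/z -> (canonical formula, label).
DIAGNOSTIC_IONS: Dict[int, Tuple[str, str]] = {
    77: ("C6H5+", "phenyl"),
    91: ("C7H7+", "tropylium"),
    103: ("C8H7+", "phenylvinyl"),
}

#: Minimum RDBE for an even-electron cation (half-integer arithmetic).
_MIN_CATION_RDBE = 0.5


@dataclass(frozen=True)
class NeutralLossEntry:
    """A named neutral loss with its formula and diagnostic meaning."""

    name: str
    formula: Formula
    diagnostic_of: str = ""
    radical: bool = False

    @property
    def nominal_mass(self) -> int:
        return nominal_mass(self.formula)


@dataclass(frozen=True)
class FragmentAssignment:
    """One explanation of one fragment peak.

    A fragment with several valid cation subformulas yields several
    assignments; a fragment with none yields a single assignment with
    ``ion_formula`` absent (and possibly a loss match only).
    """

    fragment_mz: int
    ion_formula: Optional[Formula] = None
    loss_from_precursor: Optional[NeutralLossEntry] = None
    diagnostic_label: Optional[str] = None

    @property
    def explained(self) -> bool:
        return self.ion_formula is not None or self.loss_from_precursor is not None


def load_loss_table(path: Union[str, Path]) -> List[NeutralLossEntry]:
    """Load a neutral-loss table from CSV (name, formula, diagnostic_of, radical)."""
    text = Path(path).read_text(encoding="utf-8")
    return _parse_loss_table(text)


def _parse_loss_table(text: str) -> List[NeutralLossEntry]:
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    out = []
    for row in csv.DictReader(rows):
        out.append(
            NeutralLossEntry(
                name=row["name"].strip(),
                formula=parse_formula(row["formula"].strip()),
                diagnostic_of=row.get("diagnostic_of", "").strip(),
                radical=row.get("radical", "0").strip() in ("1", "true", "yes"),
            )
        )
    return out


def packaged_loss_table() -> List[NeutralLossEntry]:
    """The packaged table of common small-molecule neutral losses."""
    text = resources.files("npsid.data").joinpath("neutral_losses.csv").read_text()
    return _parse_loss_table(text)


def neutral_loss(
    precursor_mz: int,
    fragment_mz: int,
    loss_table: Optional[Sequence[NeutralLossEntry]] = None,
) -> List[NeutralLossEntry]:
    """Table entries whose nominal mass equals precursor_mz - fragment_mz.

    An identity difference (0 Da) and unmatched differences both return an
    empty list; a fragment heavier than the precursor is an error.
    """
    if fragment_mz > precursor_mz:
        raise ValueError(
            f"fragment ({fragment_mz}) heavier than precursor ({precursor_mz})"
        )
    table = packaged_loss_table() if loss_table is None else list(loss_table)
    diff = int(precursor_mz) - int(fragment_mz)
    return [entry for entry in table if entry.nominal_mass == diff]


def _subformula_search(pool: Formula, target_mz: int, tolerance: float) -> List[Formula]:
    """All cation subformulas of ``pool`` within tolerance of target_mz."""
    syms = sorted(pool.counts)
    ranges = [range(pool.get(s) + 1) for s in syms]
    out: List[Formula] = []
    for combo in product(*ranges):
        counts = {s: n for s, n in zip(syms, combo) if n}
        if not counts:
            continue
        ion = Formula(counts, charge=+1)
        if abs(nominal_mass(ion) - target_mz) > tolerance:
            continue
        if rdbe(ion) < _MIN_CATION_RDBE - 1e-9:
            continue
        out.append(ion)
    out.sort(key=lambda f: f.hill())
    return out


def brute_force_subformulas(
    precursor: Formula, fragment_mz: int, tolerance: float = 0.5
) -> List[Formula]:
    """Independent oracle: exhaustive subset enumeration of the [M+H]+ pool.

    Same filters as the production path but expressed as one flat product
    over per-element count ranges, kept deliberately naive.
    """
    pool = precursor.protonated()
    syms = sorted(pool.counts)
    out = []
    for combo in product(*[range(pool.get(s) + 1) for s in syms]):
        counts = {s: n for s, n in zip(syms, combo) if n}
        if not counts:
            continue
        ion = Formula(counts, charge=+1)
        ok_mass = abs(nominal_mass(ion) - fragment_mz) <= tolerance
        ok_rdbe = rdbe(ion) >= _MIN_CATION_RDBE - 1e-9
        if ok_mass and ok_rdbe:
            out.append(ion)
    return sorted(out, key=lambda f: f.hill())


def assign_subformulas(
    precursor: Formula,
    fragments: Sequence[Peak],
    tolerance: float = 0.5,
    loss_table: Optional[Sequence[NeutralLossEntry]] = None,
) -> List[FragmentAssignment]:
    """Explain each fragment as cation subformulas and/or neutral losses.

    For every fragment peak, all cation subformulas of the precursor
    (+1 H proton allowance) whose nominal mass lies within ``tolerance``
    of the fragment m/z and whose RDBE is >= 0.5 become assignments;
    losses are attached when the mass difference from [M+H]+ matches a
    table entry that is element-wise removable from the assigned ion's
    complement.  Diagnostic labels mark the canonical aromatic ions
    (phenyl, tropylium, phenylvinyl).  Fragments with no valid subformula
    get one assignment with ``ion_formula`` absent.
    """
    if precursor.charge != 0:
        raise ValueError("precursor must be a neutral formula")
    if not fragments:
        raise ValueError("no fragments to assign")
    pool = precursor.protonated()
    mh_mz = nominal_mass(pool)
    table = packaged_loss_table() if loss_table is None else list(loss_table)

    assignments: List[FragmentAssignment] = []
    for peak in sorted(fragments, key=lambda p: p.mz):
        fmz = round(peak.mz)
        losses = (
            neutral_loss(mh_mz, fmz, table) if fmz <= mh_mz else []
        )
        ions = _subformula_search(pool, fmz, tolerance)
        if not ions:
            assignments.append(
                FragmentAssignment(
                    fragment_mz=fmz,
                    ion_formula=None,
                    loss_from_precursor=losses[0] if losses else None,
                )
            )
            continue
        for ion in ions:
            # neutral residue left after the ion departs with the proton
            complement = Formula(
                {s: pool.get(s) - ion.get(s) for s in pool.counts}
            )
            matched_loss = None
            for entry in losses:
                if complement == entry.formula:
                    matched_loss = entry
                    break
            label = None
            canonical = DIAGNOSTIC_IONS.get(fmz)
            if canonical and ion == parse_formula(canonical[0]):
                label = canonical[1]
            assignments.append(
                FragmentAssignment(
                    fragment_mz=fmz,
                    ion_formula=ion,
                    loss_from_precursor=matched_loss,
                    diagnostic_label=label,
                )
            )
    return assignments


def explanation_coverage(
    assignments: Sequence[FragmentAssignment], fragments: Sequence[Peak]
) -> float:
    """Intensity-weighted fraction of fragment signal that is explained.

    A fragment counts as explained when at least one of its assignments
    carries an ion formula or a neutral-loss match.
    """
    if not fragments:
        raise ValueError("no fragments")
    explained_mzs = {a.fragment_mz for a in assignments if a.explained}
    total = sum(p.intensity for p in fragments)
    if total <= 0:
        raise ValueError("fragment intensities sum to zero")
    hit = sum(p.intensity for p in fragments if round(p.mz) in explained_mzs)
    return hit / total
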