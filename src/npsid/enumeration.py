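"""Constraint derivation and exhaustive molecular-formula enumeration.

At unit resolution the molecular formula of an unknown is recovered by
enumerating every elemental composition whose nominal mass equals the
neutral target, subject to evidence-derived constraints: element bounds,
the nitrogen-rule parity, an RDBE (unsaturation) window, and hard element
exclusions from the isotope pattern.  An exact-mass mode with a Da/ppm
tolerance is provided for high-resolution inputs.

Two independent enumeration routes exist: the production algorithm
(:func:`enumerate_formulas`, hydrogen solved by mass closure) and a plain
nested-loop oracle (:func:`brute_force_enumerate`) used to audit it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

from .formulas import Formula, element_table, monoisotopic_mass, nominal_mass, rdbe
from .isotopes import ElementExclusion, nitrogen_parity
from .precursor import PrecursorCall
from .spectrum_io import Peak

__all__ = [
    "DEFAULT_ELEMENT_BOUNDS",
    "AROMATIC_MARKER_IONS",
    "EnumerationConstraints",
    "CandidateFormula",
    "ConstraintError",
    "derive_constraints",
    "enumerate_formulas",
    "brute_force_enumerate",
    "audit_candidate",
]

#: Default per-element (min, max) bounds for the generic NPS search space.
#: C/H/N/O/F replicate the generic small-drug formula C8-15 H7-20 N2-4 O0-2
#: F0-1 used for unknowns of this class (the C/H/N minima are derived from
#: evidence at run time, not hard-coded here); S/Cl/Br/I are admitted with
#: small caps so that isotope-pattern and mass-budget exclusions — not the
#: bounds themselves — are what remove them.
DEFAULT_ELEMENT_BOUNDS: Dict[str, Tuple[int, int]] = {
    "C": (0, 15),
    "H": (0, 20),
    "N": (0, 4),
    "O": (0, 2),
    "F": (0, 1),
    "S": (0, 1),
    "Cl": (0, 2),
    "Br": (0, 2),
    "I": (0, 1),
}

#: Diagnostic aromatic fragment ions: phenyl (77), tropylium (91),
#: phenylvinyl (103).  Their presence implies at least one benzene ring.
AROMATIC_MARKER_IONS = (77, 91, 103)

#: Ammonia neutral-loss mass; [M+H]+ - 17 marks a primary amine and hence
#: at least one nitrogen.
_NH3_LOSS = 17


class ConstraintError(ValueError):
    """Raised for invalid or unsatisfiable enumeration setups."""


@dataclass(frozen=True)
class EnumerationConstraints:
    """The evidence-derived search space for formula enumeration."""

    target_mass: float
    element_bounds: Dict[str, Tuple[int, int]]
    n_parity: str = "any"  # even / odd / any
    min_rdbe: float = 0.0
    max_rdbe: Optional[float] = None
    excluded_elements: frozenset = frozenset()
    mode: str = "nominal"  # nominal / exact
    tolerance: float = 0.5  # Da (exact mode only)

    def __post_init__(self) -> None:
        if self.n_parity not in ("even", "odd", "any"):
            raise ConstraintError(f"n_parity must be even/odd/any, got {self.n_parity!r}")
        if self.mode not in ("nominal", "exact"):
            raise ConstraintError(f"mode must be nominal/exact, got {self.mode!r}")
        table = element_table()
        for sym, (lo, hi) in self.element_bounds.items():
            if sym not in table:
                raise ConstraintError(f"unsupported element in bounds: {sym}")
            if lo < 0 or lo > hi:
                raise ConstraintError(f"invalid bounds for {sym}: ({lo}, {hi})")
        for sym in self.excluded_elements:
            lo, hi = self.element_bounds.get(sym, (0, 0))
            if (lo, hi) != (0, 0):
                raise ConstraintError(f"excluded element {sym} has non-zero bounds")

    def bounds_for(self, sym: str) -> Tuple[int, int]:
        return self.element_bounds.get(sym, (0, 0))


@dataclass(frozen=True)
class CandidateFormula:
    """An enumerated neutral formula with its evidence scores."""

    formula: Formula
    nominal_mass: int
    rdbe: float
    isotope_score: Optional[float] = None
    fragment_coverage: Optional[float] = None
    db_hits: Tuple[str, ...] = ()
    composite_score: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "formula": self.formula.hill(),
            "nominal_mass": self.nominal_mass,
            "rdbe": self.rdbe,
            "isotope_score": self.isotope_score,
            "fragment_coverage": self.fragment_coverage,
            "db_hits": list(self.db_hits),
            "composite_score": self.composite_score,
        }


def _parity_ok(n: int, parity: str) -> bool:
    if parity == "any":
        return True
    return n % 2 == (0 if parity == "even" else 1)


def derive_constraints(
    precursor: PrecursorCall,
    fragments: Sequence[Peak],
    exclusions: Sequence[ElementExclusion],
    defaults: Optional[Dict[str, Tuple[int, int]]] = None,
) -> EnumerationConstraints:
    """Turn the collected MS evidence into an enumeration search space.

    Rules applied, mirroring how a forensic analyst reasons from a
    unit-resolution spectrum:

    * neutral target mass = precursor m/z - 1 (protonation);
    * any aromatic marker ion (77/91/103) among the fragments raises the
      minimum RDBE to 4 (one benzene ring);
    * the phenylvinyl marker (103, C8H7+) additionally forces C >= 8 and
      H >= 7 in the neutral;
    * an ammonia loss ([M+H]+ - 17) marks a primary amine: N >= 1, then
      raised to the nearest count satisfying the nitrogen-rule parity;
    * the nitrogen rule fixes the N-count parity from the target mass;
    * isotope-pattern exclusions collapse element bounds to (0, 0);
    * iodine is dropped when target - 127 cannot accommodate the minimum
      carbon budget at 12 Da per carbon.
    """
    if precursor.mz is None:
        raise ConstraintError(
            "no precursor call; re-run with an explicit precursor m/z (--precursor)"
        )
    target = int(precursor.mz) - 1
    bounds = {sym: tuple(b) for sym, b in (defaults or DEFAULT_ELEMENT_BOUNDS).items()}

    frag_mzs = {round(p.mz) for p in fragments}
    min_rdbe = 4.0 if frag_mzs.intersection(AROMATIC_MARKER_IONS) else 0.0
    if 103 in frag_mzs:
        c_lo, c_hi = bounds.get("C", (0, 0))
        bounds["C"] = (max(c_lo, 8), c_hi)
        h_lo, h_hi = bounds.get("H", (0, 0))
        bounds["H"] = (max(h_lo, 7), h_hi)

    parity = nitrogen_parity(target)

    if (precursor.mz - _NH3_LOSS) in frag_mzs:
        n_lo, n_hi = bounds.get("N", (0, 0))
        n_lo = max(n_lo, 1)
        while not _parity_ok(n_lo, parity):
            n_lo += 1
        bounds["N"] = (n_lo, n_hi)

    excluded = {exc.element for exc in exclusions if exc.excluded}
    c_min = bounds.get("C", (0, 0))[0]
    if "I" in bounds and bounds["I"][1] > 0 and target - 127 < 12 * c_min:
        excluded.add("I")
    for sym in excluded:
        bounds[sym] = (0, 0)

    return EnumerationConstraints(
        target_mass=float(target),
        element_bounds={s: (int(lo), int(hi)) for s, (lo, hi) in bounds.items()},
        n_parity=parity,
        min_rdbe=min_rdbe,
        excluded_elements=frozenset(excluded),
    )


def _passes_filters(f: Formula, c: EnumerationConstraints) -> bool:
    if not _parity_ok(f.get("N"), c.n_parity):
        return False
    u = rdbe(f)
    if u < c.min_rdbe - 1e-9:
        return False
    if c.max_rdbe is not None and u > c.max_rdbe + 1e-9:
        return False
    return True


def _mass_ok(f: Formula, c: EnumerationConstraints) -> bool:
    if c.mode == "nominal":
        return nominal_mass(f) == int(round(c.target_mass))
    return abs(monoisotopic_mass(f) - c.target_mass) <= c.tolerance


def _sorted_candidates(found: List[Formula]) -> List[CandidateFormula]:
    cands = [
        CandidateFormula(formula=f, nominal_mass=nominal_mass(f), rdbe=rdbe(f))
        for f in set(found)
    ]
    cands.sort(key=lambda cf: (-cf.rdbe, cf.formula.hill()))
    return cands


def enumerate_formulas(c: EnumerationConstraints) -> List[CandidateFormula]:
    """Enumerate every neutral formula consistent with the constraints.

    Iterates over the bounded non-hydrogen element grid and solves the
    hydrogen count by mass closure (nominal mode: H = target - sum of
    other nominal contributions, exact within the bounds; exact mode: the
    small window of H counts inside the mass tolerance).  Output is
    deterministic: descending RDBE, then Hill string.
    """
    table = element_table()
    others = [
        sym for sym in sorted(c.element_bounds)
        if sym != "H" and c.bounds_for(sym)[1] > 0
    ]
    h_lo, h_hi = c.bounds_for("H")
    if any(c.bounds_for(sym)[1] >= 10**6 for sym in others) or h_hi >= 10**6:
        raise ConstraintError("unbounded search space: set finite element bounds")

    found: List[Formula] = []
    ranges = [range(c.bounds_for(sym)[0], c.bounds_for(sym)[1] + 1) for sym in others]
    target_n = int(round(c.target_mass))
    for combo in product(*ranges):
        counts = dict(zip(others, combo))
        if c.mode == "nominal":
            remainder = target_n - sum(n * table[s].nominal for s, n in counts.items())
            if remainder < h_lo or remainder > h_hi:
                continue
            h_candidates = [remainder]
        else:
            base = sum(n * table[s].exact for s, n in counts.items())
            h_mass = table["H"].exact
            centre = (c.target_mass - base) / h_mass
            lo = max(h_lo, math.ceil(centre - (c.tolerance / h_mass) - 1))
            hi = min(h_hi, math.floor(centre + (c.tolerance / h_mass) + 1))
            h_candidates = [
                h for h in range(lo, hi + 1)
                if abs(base + h * h_mass - c.target_mass) <= c.tolerance
            ]
        for h in h_candidates:
            if h < 0:
                continue
            f = Formula({**counts, "H": h})
            if not f:
                continue
            if _passes_filters(f, c) and _mass_ok(f, c):
                found.append(f)
    return _sorted_candidates(found)


def brute_force_enumerate(
    c: EnumerationConstraints, max_cells: int = 10**7
) -> List[CandidateFormula]:
    """Independent oracle: plain nested iteration over ALL element grids.

    Every element (hydrogen included) is looped over its full bounded
    range and the mass and constraint filters are applied one candidate at
    a time.  Refuses grids larger than ``max_cells``.
    """
    syms = [sym for sym in sorted(c.element_bounds) if c.bounds_for(sym)[1] > 0]
    ranges = [range(c.bounds_for(sym)[0], c.bounds_for(sym)[1] + 1) for sym in syms]
    cells = 1
    for r in ranges:
        cells *= len(r)
        if cells > max_cells:
            raise ConstraintError(f"search space exceeds {max_cells} cells")
    found: List[Formula] = []
    for combo in product(*ranges):
        counts = {s: n for s, n in zip(syms, combo) if n}
        if not counts:
            continue
        f = Formula(counts)
        if _passes_filters(f, c) and _mass_ok(f, c):
            found.append(f)
    return _sorted_candidates(found)


def audit_candidate(cf: CandidateFormula, c: EnumerationConstraints) -> bool:
    """Re-check one candidate against every constraint, independently."""
    f = cf.formula
    for sym, (lo, hi) in c.element_bounds.items():
        if not (lo <= f.get(sym) <= hi):
            return False
    for sym in f.counts:
        if sym not in c.element_bounds or sym in c.excluded_elements:
            return False
    return _passes_filters(f, c) and _mass_ok(f, c)
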