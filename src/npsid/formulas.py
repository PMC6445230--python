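"""Element data and molecular-formula arithmetic.

Every other stage of the identification pipeline reduces to integer or
exact-mass arithmetic on element counts: nominal (unit-resolution) masses
for a triple-quadrupole instrument, monoisotopic masses for the optional
exact-mass mode, and ring-plus-double-bond equivalents (RDBE) for the
unsaturation constraints.  The supported element set is the one relevant
to small-molecule drug chemistry: H, C, N, O, F, S, Cl, Br, I.

The isotope table ships as a versioned CSV inside the package
(``data/elements.csv``); masses and abundances are the NIST standard
values.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Tuple

__all__ = [
    "ELECTRON_MASS",
    "ElementRecord",
    "Formula",
    "FormulaError",
    "element_table",
    "parse_formula",
    "nominal_mass",
    "monoisotopic_mass",
    "rdbe",
]

#: Electron rest mass in Da; subtracted per positive charge in exact-mass mode.
ELECTRON_MASS = 0.000548579909

_HILL_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unsupported elements."""


@dataclass(frozen=True)
class ElementRecord:
    """Isotope data for one element.

    ``isotopes`` is a list of ``(mass_number, exact_mass, abundance)``
    tuples sorted by mass number.  ``valence_class`` groups elements by the
    offset of their second-most-abundant isotope: ``A`` (monoisotopic),
    ``A+1`` (e.g. carbon) or ``A+2`` (S, Cl, Br and, marginally, O) — the
    classification that drives the isotope-pattern element exclusions.
    """

    symbol: str
    isotopes: Tuple[Tuple[int, float, float], ...]
    valence_class: str = field(init=False)

    def __post_init__(self) -> None:
        total = sum(ab for _, _, ab in self.isotopes)
        if abs(total - 1.0) > 1e-4:
            raise ValueError(f"{self.symbol}: abundances sum to {total}, not 1")
        ranked = sorted(self.isotopes, key=lambda iso: -iso[2])
        if len(ranked) == 1:
            cls = "A"
        else:
            offset = ranked[1][0] - ranked[0][0]
            cls = "A+2" if abs(offset) == 2 else "A+1"
        object.__setattr__(self, "valence_class", cls)

    @property
    def principal(self) -> Tuple[int, float, float]:
        """Most abundant isotope (mass number, exact mass, abundance)."""
        return max(self.isotopes, key=lambda iso: iso[2])

    @property
    def nominal(self) -> int:
        """Integer mass contribution per atom (mass number of the principal isotope)."""
        return self.principal[0]

    @property
    def exact(self) -> float:
        """Exact mass of the principal isotope in Da."""
        return self.principal[1]


def _load_elements() -> Dict[str, ElementRecord]:
    text = resources.files("npsid.data").joinpath("elements.csv").read_text()
    rows = [
        line for line in text.splitlines() if line.strip() and not line.startswith("#")
    ]
    table: Dict[str, List[Tuple[int, float, float]]] = {}
    for row in csv.DictReader(rows):
        table.setdefault(row["symbol"], []).append(
            (int(row["mass_number"]), float(row["exact_mass"]), float(row["abundance"]))
        )
    return {
        sym: ElementRecord(sym, tuple(sorted(isos)))
        for sym, isos in table.items()
    }


_ELEMENTS: Dict[str, ElementRecord] = _load_elements()

#: Order used when rendering formulas: Hill convention (C, H, then alphabetical).
_HILL_ORDER = ("C", "H", "Br", "Cl", "F", "I", "N", "O", "S")


def element_table() -> Mapping[str, ElementRecord]:
    """The packaged isotope table, keyed by element symbol."""
    return dict(_ELEMENTS)


class Formula:
    """An elemental composition with an integer charge.

    ``counts`` maps element symbols to non-negative integers; zero counts
    are dropped.  ``charge`` is 0 for neutrals and +1 for the even-electron
    cations this pipeline deals in ([M+H]+ and its fragments).
    """

    __slots__ = ("_counts", "charge")

    def __init__(self, counts: Mapping[str, int], charge: int = 0):
        clean: Dict[str, int] = {}
        for sym, n in counts.items():
            if sym not in _ELEMENTS:
                raise FormulaError(f"unsupported element symbol: {sym!r}")
            if n < 0:
                raise FormulaError(f"negative count for {sym}: {n}")
            if n:
                clean[sym] = int(n)
        self._counts = clean
        self.charge = int(charge)

    @property
    def counts(self) -> Dict[str, int]:
        return dict(self._counts)

    def get(self, symbol: str) -> int:
        return self._counts.get(symbol, 0)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self._counts == other._counts and self.charge == other.charge

    def __hash__(self) -> int:
        return hash((tuple(sorted(self._counts.items())), self.charge))

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for sym, n in other._counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return Formula(merged, self.charge + other.charge)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for sym, n in other._counts.items():
            merged[sym] = merged.get(sym, 0) - n
            if merged[sym] < 0:
                raise FormulaError(
                    f"cannot subtract {other.hill()} from {self.hill()}: {sym} deficit"
                )
        return Formula(merged, self.charge - other.charge)

    def contains(self, other: "Formula") -> bool:
        """True if ``other``'s counts fit element-wise inside this formula."""
        return all(self.get(sym) >= n for sym, n in other._counts.items())

    def protonated(self) -> "Formula":
        """[M+H]+ of this (neutral) composition."""
        return self + Formula({"H": 1}, charge=+1)

    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical), with charge sign."""
        parts = []
        for sym in _HILL_ORDER:
            n = self._counts.get(sym, 0)
            if n == 1:
                parts.append(sym)
            elif n > 1:
                parts.append(f"{sym}{n}")
        body = "".join(parts)
        if self.charge > 0:
            body += "+" * self.charge
        elif self.charge < 0:
            body += "-" * (-self.charge)
        return body

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string, e.g. ``"C11H14N2"`` or ``"C6H5+"``.

    A bare element symbol means count 1.  A trailing run of ``+`` or ``-``
    sets the charge.  Raises :class:`FormulaError` naming the offending
    symbol or position on malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    s = text.strip()
    charge = 0
    while s and s[-1] in "+-":
        charge += 1 if s[-1] == "+" else -1
        s = s[:-1]
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _HILL_TOKEN.match(s, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in _ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        pos = m.end()
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
    if not counts:
        raise FormulaError(f"no elements parsed from {text!r}")
    return Formula(counts, charge)


def nominal_mass(f: Formula) -> int:
    """Unit-resolution mass: sum of count x principal-isotope mass number.

    The charge does not alter the nominal mass (the electron is far below
    unit resolution), so [M+H]+ is simply the neutral nominal mass + 1.
    """
    return sum(n * _ELEMENTS[sym].nominal for sym, n in f.counts.items())


def monoisotopic_mass(f: Formula) -> float:
    """Exact mass in Da: principal-isotope masses, minus charge x electron mass."""
    m = sum(n * _ELEMENTS[sym].exact for sym, n in f.counts.items())
    return m - f.charge * ELECTRON_MASS


def rdbe(f: Formula) -> float:
    """Ring-plus-double-bond equivalents: C - (H + halogens)/2 + N/2 + 1.

    Evaluated on the counts as given; half-integer values arise for
    even-electron cations (e.g. C6H5+ -> 4.5).  A benzene ring contributes
    4 degrees of unsaturation.
    """
    halogens = sum(f.get(x) for x in ("F", "Cl", "Br", "I"))
    return f.get("C") - (f.get("H") + halogens) / 2.0 + f.get("N") / 2.0 + 1.0


def sum_formulas(parts: Iterable[Formula]) -> Formula:
    """Element-wise sum of several formulas (charges add)."""
    total = Formula({})
    for p in parts:
        total = total + p
    return total
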