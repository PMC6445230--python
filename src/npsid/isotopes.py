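"""Isotope-pattern simulation and element-level deductions at unit resolution.

A triple quadrupole reports integer m/z only, but the isotope cluster of
the protonated molecule still carries elemental information: the A+2
elements (S, Cl, Br) each contribute a large, element-specific M+2 line,
and the parity of the molecular mass fixes the parity of the nitrogen
count (nitrogen rule).  This module simulates isotopologue distributions
binned to integer mass offsets, scores measured clusters against them,
and turns the absence of an M+2 line into hard element exclusions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .formulas import Formula, element_table

__all__ = [
    "IsotopePattern",
    "ElementExclusion",
    "A2_ELEMENTS",
    "simulate_pattern",
    "exhaustive_pattern",
    "single_atom_m2_ratio",
    "exclude_a2_elements",
    "nitrogen_parity",
    "isotope_fit_score",
]

#: The A+2 elements the exclusion rule tests, with deterministic order.
A2_ELEMENTS = ("S", "Cl", "Br")


@dataclass(frozen=True)
class IsotopePattern:
    """Unit-resolution isotope pattern, base line = 1.

    ``lines`` maps integer mass offsets (relative to the all-principal
    isotopologue, which is also the lightest for the supported elements)
    to relative abundances; the most abundant line is normalized to 1.
    """

    lines: Dict[int, float]
    prune_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("empty isotope pattern")
        if any(v < 0 for v in self.lines.values()):
            raise ValueError("negative abundance in isotope pattern")
        top = max(self.lines.values())
        if abs(top - 1.0) > 1e-9:
            raise ValueError(f"pattern base line is {top}, expected 1")

    def abundance(self, offset: int) -> float:
        return self.lines.get(offset, 0.0)

    def vector(self, n_offsets: int = 3) -> np.ndarray:
        """Abundances at offsets 0..n_offsets-1 as an array."""
        return np.array([self.abundance(k) for k in range(n_offsets)])


def _single_atom_distribution(symbol: str) -> Dict[int, float]:
    """Offset -> abundance for one atom, offsets relative to the lightest isotope."""
    rec = element_table()[symbol]
    lightest = min(mn for mn, _, _ in rec.isotopes)
    return {mn - lightest: ab for mn, _, ab in rec.isotopes}


def _convolve(a: Dict[int, float], b: Dict[int, float]) -> Dict[int, float]:
    out: Dict[int, float] = {}
    for ka, va in a.items():
        for kb, vb in b.items():
            out[ka + kb] = out.get(ka + kb, 0.0) + va * vb
    return out


def _element_power(symbol: str, n: int) -> Dict[int, float]:
    """Isotopologue distribution of n atoms of one element (binary exponentiation)."""
    result: Dict[int, float] = {0: 1.0}
    base = _single_atom_distribution(symbol)
    while n:
        if n & 1:
            result = _convolve(result, base)
        base = _convolve(base, base)
        n >>= 1
    return result


def simulate_pattern(f: Formula, prune_threshold: float = 1e-6) -> IsotopePattern:
    """Simulate the unit-resolution isotope pattern of a formula.

    Per-element multinomial isotopologue distributions are convolved
    across elements, binned at integer offsets, pruned below
    ``prune_threshold`` (relative to the base line) and renormalized so
    the most abundant line equals 1.  The charge is irrelevant at unit
    resolution.
    """
    if not (0 < prune_threshold < 1):
        raise ValueError("prune_threshold must be in (0, 1)")
    dist: Dict[int, float] = {0: 1.0}
    for sym, n in sorted(f.counts.items()):
        dist = _convolve(dist, _element_power(sym, n))
    top = max(dist.values())
    lines = {k: v / top for k, v in sorted(dist.items()) if v / top >= prune_threshold}
    return IsotopePattern(lines=lines, prune_threshold=prune_threshold)


def exhaustive_pattern(f: Formula) -> Dict[int, float]:
    """Independent oracle: explicit product over every isotope assignment.

    Enumerates all per-atom isotope choices (exponential; intended for
    formulas with a handful of atoms) and accumulates probability mass at
    integer offsets.  Returned un-normalized (probabilities summing to 1).
    """
    table = element_table()
    atoms: List[str] = []
    for sym, n in sorted(f.counts.items()):
        atoms.extend([sym] * n)
    dist: Dict[int, float] = {0: 1.0}
    for sym in atoms:
        rec = table[sym]
        lightest = min(mn for mn, _, _ in rec.isotopes)
        new: Dict[int, float] = {}
        for off, p in dist.items():
            for mn, _, ab in rec.isotopes:
                k = off + (mn - lightest)
                new[k] = new.get(k, 0.0) + p * ab
        dist = new
    return dist


def single_atom_m2_ratio(symbol: str) -> float:
    """Expected (M+2)/(M+0) contribution of a single atom of an A+2 element."""
    dist = _single_atom_distribution(symbol)
    return dist.get(2, 0.0) / dist[0]


@dataclass(frozen=True)
class ElementExclusion:
    """Outcome of the A+2 test for one element."""

    element: str
    excluded: bool
    measured_ratio: float
    threshold_ratio: float
    rationale: str

    def __post_init__(self) -> None:
        if self.excluded != (self.measured_ratio < self.threshold_ratio):
            raise ValueError("exclusion flag inconsistent with ratios")


def exclude_a2_elements(
    cluster: Sequence[float], safety_factor: float = 0.5
) -> List[ElementExclusion]:
    """Exclude S, Cl and Br when the measured M+2 line is too small.

    ``cluster`` holds the measured MH+0, MH+1, MH+2 intensities with
    MH+0 = 100 (relative %).  For each A+2 element the minimal expected
    (M+2)/(M+0) contribution of ONE atom is computed from the isotope
    table (about 0.044 for S, 0.32 for Cl, 0.97 for Br); the element is
    excluded iff the measured ratio falls below ``safety_factor`` times
    that contribution.  The factor of 0.5 tolerates the ±50%-scale
    intensity error of a unit-resolution instrument while still separating
    e.g. a measured 0.7% M+2 from sulfur's 4.4%.
    """
    cluster = list(cluster)
    if not cluster or abs(cluster[0] - 100.0) > 1e-6:
        raise ValueError("cluster must be normalized with MH+0 = 100")
    if len(cluster) < 3:
        warnings.warn("missing MH+2 entry; treated as 0", stacklevel=2)
        cluster = cluster + [0.0] * (3 - len(cluster))
    if any(x < 0 for x in cluster):
        raise ValueError("cluster intensities must be non-negative")
    measured = float(cluster[2]) / float(cluster[0])
    out: List[ElementExclusion] = []
    for sym in A2_ELEMENTS:
        contrib = single_atom_m2_ratio(sym)
        threshold = safety_factor * contrib
        excluded = bool(measured < threshold)
        verdict = "excluded" if excluded else "not excluded"
        out.append(
            ElementExclusion(
                element=sym,
                excluded=excluded,
                measured_ratio=measured,
                threshold_ratio=threshold,
                rationale=(
                    f"measured (M+2)/(M+0) = {measured:.4f} vs single-atom "
                    f"{sym} contribution {contrib:.4f} (threshold "
                    f"{threshold:.4f}): {verdict}"
                ),
            )
        )
    return out


def nitrogen_parity(neutral_nominal_mass: int) -> str:
    """Nitrogen rule: even neutral nominal mass -> even N count; odd -> odd.

    Valid for compositions over C, H, N, O, F, S, Cl, Br, I (every element
    except N has matching mass/valence parity).
    """
    if neutral_nominal_mass <= 0:
        raise ValueError("mass must be positive")
    return "even" if neutral_nominal_mass % 2 == 0 else "odd"


def isotope_fit_score(f: Formula, cluster: Sequence[float], n_offsets: int = 3) -> float:
    """Cosine similarity between simulated and measured isotope clusters.

    Both the simulated pattern of ``f`` and the measured cluster are taken
    at offsets 0..n_offsets-1; 1.0 means identical shape.
    """
    sim = simulate_pattern(f).vector(n_offsets)
    meas = np.array([float(x) for x in cluster[:n_offsets]])
    if len(meas) < n_offsets:
        meas = np.pad(meas, (0, n_offsets - len(meas)))
    denom = np.linalg.norm(sim) * np.linalg.norm(meas)
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(sim, meas) / denom, 0.0, 1.0))
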