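"""Protonated-molecule determination from a fragmentor-voltage series.

Electrospray in-source fragmentation depletes the precursor ion at high
fragmentor voltages; acquiring MS1 scans at a decreasing series of
voltages (e.g. 110, 90, 70, 40 eV) lets the intact [M+H]+ re-emerge.  The
selection rule implemented here: among integer-binned ions present in the
lowest-voltage scan (isotope satellites removed), call the highest-m/z ion
whose abundance is maximal at a voltage no greater than the median of the
scanned range.  The optimum can be an interior voltage — below it, overall
ion transmission also falls — so a strict "lowest voltage wins" rule would
be wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

from .spectrum_io import Spectrum, bin_to_unit_resolution

__all__ = ["PrecursorCall", "PrecursorError", "select_precursor"]


class PrecursorError(ValueError):
    """Raised when the scan series cannot support a precursor call."""


@dataclass(frozen=True)
class PrecursorCall:
    """The called [M+H]+ with its abundance-vs-voltage profile.

    ``mz`` is None when no ion satisfied the selection rule ("no
    precursor"); the pipeline can then proceed with a user-supplied value.
    """

    mz: Optional[int]
    best_fragmentor: Optional[float]
    abundance_profile: Dict[float, float] = field(default_factory=dict)

    @property
    def found(self) -> bool:
        return self.mz is not None


def _is_isotope_satellite(mz: int, peaks: Dict[int, float]) -> bool:
    """A peak 1 or 2 Da above a stronger peak is an isotope line, not an ion."""
    for delta in (1, 2):
        parent = peaks.get(mz - delta)
        if parent is not None and parent > peaks[mz]:
            return True
    return False


def select_precursor(scans: Sequence[Spectrum]) -> PrecursorCall:
    """Call the [M+H]+ from MS1 scans at distinct fragmentor voltages.

    Candidate ions are the integer-binned peaks of the lowest-voltage scan
    with isotope satellites (+1/+2 lines weaker than their parent)
    removed.  Each candidate's raw abundance is profiled across voltages;
    the call is the highest-m/z candidate whose argmax voltage is at or
    below the median scanned voltage (ties in abundance resolve to the
    lower voltage, and candidates tie-break to higher m/z).  The result is
    independent of the order in which scans are supplied.
    """
    if len(scans) < 2:
        raise PrecursorError("need at least two MS1 scans at distinct fragmentor voltages")
    for s in scans:
        if s.fragmentor_voltage is None:
            raise PrecursorError(f"scan {s.label!r} lacks a fragmentor_voltage")
        if s.scan_type != "MS1":
            raise PrecursorError(f"scan {s.label!r} is not an MS1 scan")
    polarities = {s.polarity for s in scans}
    if len(polarities) > 1:
        raise PrecursorError("scans mix polarities")
    voltages = sorted({float(s.fragmentor_voltage) for s in scans})
    if len(voltages) != len(scans):
        raise PrecursorError("fragmentor voltages must be distinct")

    by_voltage: Dict[float, Dict[int, float]] = {}
    for s in scans:
        binned = bin_to_unit_resolution(s)
        by_voltage[float(s.fragmentor_voltage)] = {
            int(p.mz): p.intensity for p in binned.peaks
        }

    n = len(voltages)
    median_voltage = (
        voltages[n // 2] if n % 2 else 0.5 * (voltages[n // 2 - 1] + voltages[n // 2])
    )

    low_scan = by_voltage[voltages[0]]
    candidates = [
        mz for mz in sorted(low_scan, reverse=True)
        if not _is_isotope_satellite(mz, low_scan)
    ]

    for mz in candidates:  # descending m/z: first qualifying candidate wins
        profile = {v: by_voltage[v].get(mz, 0.0) for v in voltages}
        best_v = min(
            voltages, key=lambda v: (-profile[v], v)
        )  # argmax abundance, ties to lower voltage
        if best_v <= median_voltage and profile[best_v] > 0:
            return PrecursorCall(mz=mz, best_fragmentor=best_v, abundance_profile=profile)

    return PrecursorCall(mz=None, best_fragmentor=None, abundance_profile={})
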