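"""Peak lists, acquisition metadata, and the pipeline's file formats.

Two plain-text exchange formats are supported:

* CSV: two numeric columns ``mz,intensity``, with ``#``-prefixed header
  lines carrying ``key=value`` acquisition metadata (scan_type,
  fragmentor_voltage, collision_energy, polarity, label).
* A minimal MSP-like record: ``Name:``, ``Comment:`` (key=value pairs),
  ``Num Peaks:``, then ``mz intensity`` lines; blank line between records.

Identification reports are written as human-readable text with an embedded
machine-readable JSON block.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

__all__ = [
    "Peak",
    "Spectrum",
    "SpectrumError",
    "read_peaklist",
    "write_peaklist",
    "normalize_to_base_peak",
    "bin_to_unit_resolution",
    "write_report",
    "read_report_json",
]


class SpectrumError(ValueError):
    """Raised for malformed peak-list input or invalid spectra."""


@dataclass(frozen=True)
class Peak:
    """One mass-spectral peak: m/z in Da, intensity in arbitrary units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise SpectrumError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise SpectrumError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """An acquired or simulated peak list plus acquisition metadata.

    Peaks are kept sorted by ascending m/z.  MS2 spectra carry a collision
    energy; MS1 spectra may carry an in-source fragmentor voltage.
    """

    peaks: Tuple[Peak, ...]
    scan_type: str = "MS1"
    fragmentor_voltage: Optional[float] = None
    collision_energy: Optional[float] = None
    polarity: str = "positive"
    label: str = ""

    def __post_init__(self) -> None:
        if self.scan_type not in ("MS1", "MS2"):
            raise SpectrumError(f"scan_type must be MS1 or MS2, got {self.scan_type!r}")
        if self.polarity not in ("positive", "negative"):
            raise SpectrumError(f"polarity must be positive/negative, got {self.polarity!r}")
        ordered = tuple(sorted(self.peaks, key=lambda p: p.mz))
        object.__setattr__(self, "peaks", ordered)

    @property
    def mz(self) -> List[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensity(self) -> List[float]:
        return [p.intensity for p in self.peaks]

    def base_peak(self) -> Peak:
        if not self.peaks:
            raise SpectrumError("empty spectrum has no base peak")
        return max(self.peaks, key=lambda p: p.intensity)

    def intensity_at(self, mz: float, tol: float = 0.5) -> float:
        """Summed intensity of peaks within ``tol`` Da of ``mz``."""
        return sum(p.intensity for p in self.peaks if abs(p.mz - mz) <= tol)


def bin_to_unit_resolution(s: Spectrum) -> Spectrum:
    """Merge peaks whose m/z round to the same integer, summing intensities.

    Triple-quadrupole data are reported at integer m/z; all downstream
    reasoning is at unit resolution.
    """
    binned: Dict[int, float] = {}
    for p in s.peaks:
        binned[round(p.mz)] = binned.get(round(p.mz), 0.0) + p.intensity
    peaks = tuple(Peak(float(mz), inten) for mz, inten in sorted(binned.items()))
    return replace(s, peaks=peaks)


def normalize_to_base_peak(s: Spectrum) -> Spectrum:
    """Rescale intensities so the base peak is exactly 100 (relative %)."""
    if not s.peaks:
        raise SpectrumError("cannot normalize an empty spectrum")
    top = s.base_peak().intensity
    if top <= 0:
        raise SpectrumError("cannot normalize: all intensities are zero")
    peaks = tuple(Peak(p.mz, p.intensity * 100.0 / top) for p in s.peaks)
    return replace(s, peaks=peaks)


# ---------------------------------------------------------------------------
# readers / writers

_META_KEYS = ("scan_type", "fragmentor_voltage", "collision_energy", "polarity", "label")


def _spectrum_from_meta(peaks: Sequence[Peak], meta: Dict[str, str]) -> Spectrum:
    def _num(key: str) -> Optional[float]:
        v = meta.get(key)
        return float(v) if v not in (None, "", "None") else None

    return Spectrum(
        peaks=tuple(peaks),
        scan_type=meta.get("scan_type", "MS1"),
        fragmentor_voltage=_num("fragmentor_voltage"),
        collision_energy=_num("collision_energy"),
        polarity=meta.get("polarity", "positive"),
        label=meta.get("label", ""),
    )


def _read_csv(lines: Iterable[str], origin: str) -> List[Spectrum]:
    meta: Dict[str, str] = {}
    peaks: List[Peak] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        fields = [f.strip() for f in line.split(",")]
        if len(fields) < 2:
            raise SpectrumError(f"{origin}: line {lineno}: expected 'mz,intensity'")
        try:
            mz, inten = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise SpectrumError(f"{origin}: line {lineno}: non-numeric value ({exc})") from exc
        peaks.append(Peak(mz, inten))
    if not peaks:
        warnings.warn(f"{origin}: empty spectrum retained", stacklevel=3)
    return [_spectrum_from_meta(peaks, meta)]


def _read_msp(lines: Iterable[str], origin: str) -> List[Spectrum]:
    spectra: List[Spectrum] = []
    meta: Dict[str, str] = {}
    peaks: List[Peak] = []
    n_declared: Optional[int] = None
    in_record = False

    def _flush() -> None:
        nonlocal meta, peaks, n_declared, in_record
        if not in_record:
            return
        if n_declared is not None and n_declared != len(peaks):
            warnings.warn(
                f"{origin}: record {meta.get('label', '?')!r} declares "
                f"{n_declared} peaks, found {len(peaks)}",
                stacklevel=4,
            )
        if not peaks:
            warnings.warn(f"{origin}: empty spectrum retained", stacklevel=4)
        spectra.append(_spectrum_from_meta(peaks, meta))
        meta, peaks, n_declared, in_record = {}, [], None, False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            _flush()
            continue
        low = line.lower()
        if low.startswith("name:"):
            _flush()
            in_record = True
            meta["label"] = line.partition(":")[2].strip()
        elif low.startswith("comment:"):
            in_record = True
            for token in line.partition(":")[2].split():
                if "=" in token:
                    key, _, val = token.partition("=")
                    meta[key.strip()] = val.strip()
        elif low.startswith("num peaks:"):
            in_record = True
            n_declared = int(line.partition(":")[2].strip())
        else:
            in_record = True
            fields = line.replace(",", " ").split()
            if len(fields) < 2:
                raise SpectrumError(f"{origin}: line {lineno}: expected 'mz intensity'")
            try:
                peaks.append(Peak(float(fields[0]), float(fields[1])))
            except ValueError as exc:
                raise SpectrumError(f"{origin}: line {lineno}: non-numeric value ({exc})") from exc
    _flush()
    return spectra


def read_peaklist(
    source: Union[str, Path, io.TextIOBase], format: str = "csv"
) -> List[Spectrum]:
    """Read spectra from a CSV or MSP-like peak list.

    ``source`` may be a path or an open text stream.  Peaks are returned
    sorted ascending in m/z; metadata comes from ``#key=value`` header
    lines (CSV) or Name/Comment fields (MSP).
    """
    if format not in ("csv", "msp"):
        raise SpectrumError(f"unsupported format: {format!r}")
    if isinstance(source, (str, Path)):
        origin = str(source)
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        origin = getattr(source, "name", "<stream>")
        lines = source.readlines()
    if format == "csv":
        return _read_csv(lines, origin)
    return _read_msp(lines, origin)


def write_peaklist(s: Spectrum, path: Union[str, Path]) -> None:
    """Write one spectrum in the CSV dialect (metadata header + mz,intensity rows)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in _META_KEYS:
            val = getattr(s, key)
            if val not in (None, ""):
                fh.write(f"# {key}={val}\n")
        for p in s.peaks:
            fh.write(f"{p.mz:.6g},{p.intensity:.6g}\n")


# ---------------------------------------------------------------------------
# identification reports

_JSON_BEGIN = "=== BEGIN JSON REPORT ==="
_JSON_END = "=== END JSON REPORT ==="


def write_report(report: "npsid.ranking_db.IdentificationReport", path: Union[str, Path]) -> None:
    """Write an identification report: readable text plus an embedded JSON block."""
    payload = report.to_dict()
    lines: List[str] = []
    lines.append("NPS identification report")
    lines.append("=" * 60)
    prec = payload.get("precursor") or {}
    if prec.get("mz") is not None:
        lines.append(f"Precursor [M+H]+ : m/z {prec['mz']}"
                     + (f" (best fragmentor {prec['best_fragmentor']} eV)"
                        if prec.get("best_fragmentor") is not None else ""))
    else:
        lines.append("Precursor [M+H]+ : not determined")
    lines.append("")
    lines.append("Applied rules:")
    for rule in payload.get("applied_rules", []):
        lines.append(f"  - [{rule['stage']}] {rule['description']}")
    lines.append("")
    cands = payload.get("candidates", [])
    if not cands:
        lines.append("No candidates.")
    else:
        lines.append(f"{'rank':>4}  {'formula':<12} {'score':>6}  {'isotope':>7}  "
                     f"{'coverage':>8}  database hits")
        for i, c in enumerate(cands, start=1):
            hits = ", ".join(c.get("db_hits", [])) or "-"
            lines.append(
                f"{i:>4}  {c['formula']:<12} {c.get('composite_score', float('nan')):>6.3f}  "
                f"{_fmt(c.get('isotope_score')):>7}  {_fmt(c.get('fragment_coverage')):>8}  {hits}"
            )
    lines.append("")
    lines.append(_JSON_BEGIN)
    lines.append(json.dumps(payload, indent=2, sort_keys=True))
    lines.append(_JSON_END)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fmt(x: Optional[float]) -> str:
    return "-" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.3f}"


def read_report_json(path: Union[str, Path]) -> dict:
    """Recover the machine-readable JSON block from a written report."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        start = text.index(_JSON_BEGIN) + len(_JSON_BEGIN)
        end = text.index(_JSON_END)
    except ValueError as exc:
        raise SpectrumError(f"{path}: no JSON report block found") from exc
    return json.loads(text[start:end])
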