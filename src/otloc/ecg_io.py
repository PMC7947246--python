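"""Reading, writing and normalizing 12-lead ECG records.

Supported on-disk formats:

* CSV — one header row of lead names, then one row per sample (voltages in
  mV by default; a ``units="uV"`` flag converts on read).  Beat annotations
  travel in a JSON sidecar (``<record>.annotations.json``).
* A minimal WFDB subset — a ``.hea`` header plus a 16-bit little-endian
  ``.dat`` file (format 16, one frame per sample).  This covers records this
  package writes itself; exotic WFDB features are out of scope.

All indices are 0-based and windows are half-open ``[start, stop)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .errors import BadRateError, IncompleteLeadsError, RaggedRecordError

#: Canonical lead ordering used throughout the package.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

LEAD_INDEX: dict[str, int] = {name.lower(): i for i, name in enumerate(LEAD_NAMES)}

TARGET_FS = 2000.0

BEAT_CLASSES = ("SR", "PVC")


@dataclass(frozen=True)
class BeatAnnotation:
    """One expert-selected beat: its class and an approximate R-peak index."""

    beat_class: str  # "SR" or "PVC"
    approx_r_index: int

    def __post_init__(self):
        if self.beat_class not in BEAT_CLASSES:
            raise ValueError(f"beat_class must be one of {BEAT_CLASSES}")
        if self.approx_r_index < 0:
            raise ValueError("approx_r_index must be non-negative")


@dataclass
class TwelveLeadECG:
    """A 12-lead voltage record (mV) with sampling rate and beat annotations.

    ``signals`` is a ``(12, n)`` array in canonical lead order.
    """

    signals: np.ndarray
    fs: float
    annotations: list[BeatAnnotation] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] != len(LEAD_NAMES):
            raise IncompleteLeadsError(
                f"expected {len(LEAD_NAMES)} leads, got shape {self.signals.shape}"
            )
        if self.fs <= 0:
            raise BadRateError(f"fs must be positive, got {self.fs}")
        for ann in self.annotations:
            if not (0 <= ann.approx_r_index < self.n_samples):
                raise ValueError(
                    f"annotation index {ann.approx_r_index} outside record "
                    f"of length {self.n_samples}"
                )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def lead(self, name: str) -> np.ndarray:
        """Voltage trace of one lead by (case-insensitive) name."""
        return self.signals[LEAD_INDEX[name.lower()]]

    def annotation(self, beat_class: str) -> BeatAnnotation:
        """First annotation of the given class."""
        for ann in self.annotations:
            if ann.beat_class == beat_class:
                return ann
        raise KeyError(f"no {beat_class} annotation on record {self.record_id!r}")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _canonicalize_columns(columns) -> list[int]:
    """Map arbitrary-case header names onto canonical lead positions."""
    lower = [str(c).strip().lower() for c in columns]
    order = []
    for name in LEAD_NAMES:
        key = name.lower()
        if key not in lower:
            raise IncompleteLeadsError(f"lead {name} missing from header {list(columns)}")
        order.append(lower.index(key))
    return order


def _read_csv(path: Path, fs: float, units: str) -> TwelveLeadECG:
    df = pd.read_csv(path)
    order = _canonicalize_columns(df.columns)
    sig = df.to_numpy(dtype=float).T[order]
    if units == "uV":
        sig = sig / 1000.0
    elif units != "mV":
        raise ValueError(f"unknown units {units!r}")
    anns = _read_annotation_sidecar(path)
    return TwelveLeadECG(sig, fs, anns, record_id=path.stem)


def _write_csv(record: TwelveLeadECG, path: Path) -> None:
    df = pd.DataFrame(record.signals.T, columns=list(LEAD_NAMES))
    df.to_csv(path, index=False, float_format="%.9f")
    _write_annotation_sidecar(record.annotations, path)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".annotations.json")


def _read_annotation_sidecar(path: Path) -> list[BeatAnnotation]:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return []
    entries = json.loads(sidecar.read_text())
    return [BeatAnnotation(e["beat_class"], int(e["approx_r_index"])) for e in entries]


def _write_annotation_sidecar(anns: list[BeatAnnotation], path: Path) -> None:
    sidecar = _sidecar_path(path)
    payload = [
        {"beat_class": a.beat_class, "approx_r_index": int(a.approx_r_index)}
        for a in anns
    ]
    sidecar.write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Minimal WFDB subset (format 16)
# ---------------------------------------------------------------------------

_WFDB_GAIN = 1000.0  # ADC units per mV -> 1 uV resolution


def _read_wfdb(path: Path) -> TwelveLeadECG:
    hea = path.with_suffix(".hea")
    lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_name, n_sig, fs, n_samp = lines[0].split()[:4]
    n_sig, n_samp, fs = int(n_sig), int(n_samp), float(fs)
    names, gains = [], []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        # file fmt gain(baseline)/mV ... description(last token)
        gain_tok = parts[2].split("(")[0].split("/")[0]
        gains.append(float(gain_tok) if float(gain_tok) != 0 else _WFDB_GAIN)
        names.append(parts[-1])
    dat = path.with_suffix(".dat")
    raw = np.fromfile(dat, dtype="<i2").reshape(n_samp, n_sig).T.astype(float)
    sig = raw / np.asarray(gains)[:, None]
    lengths = {raw.shape[1]}
    if len(lengths) != 1:
        raise RaggedRecordError("unequal lead lengths")
    order = _canonicalize_columns(names)
    anns = _read_annotation_sidecar(path)
    return TwelveLeadECG(sig[order], fs, anns, record_id=rec_name)


def _write_wfdb(record: TwelveLeadECG, path: Path) -> None:
    path = path.with_suffix("")
    n_samp = record.n_samples
    lines = [f"{path.name} {len(LEAD_NAMES)} {record.fs:g} {n_samp}"]
    for name in LEAD_NAMES:
        lines.append(f"{path.name}.dat 16 {_WFDB_GAIN:g}(0)/mV 16 0 0 0 0 {name}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc = np.clip(np.round(record.signals * _WFDB_GAIN), -32768, 32767)
    adc.T.astype("<i2").tofile(path.with_suffix(".dat"))
    _write_annotation_sidecar(record.annotations, path.with_suffix(".dat"))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_record(
    path, format: str | None = None, fs: float = TARGET_FS, units: str = "mV"
) -> TwelveLeadECG:
    """Read a 12-lead record from CSV or the WFDB subset.

    Parameters
    ----------
    path:
        CSV file, or WFDB record path (with or without ``.hea`` suffix).
    format:
        ``"csv"`` or ``"wfdb"``; inferred from the suffix when omitted.
    fs:
        Sampling rate of CSV data (WFDB headers carry their own).
    units:
        ``"mV"`` (default) or ``"uV"`` for CSV voltage columns.
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in (".hea", ".dat") or not path.suffix else "csv"
    if format == "csv":
        return _read_csv(path, fs, units)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown format {format!r}")


def write_record(record: TwelveLeadECG, path, format: str | None = None) -> None:
    """Write a record (plus annotation sidecar) as CSV or the WFDB subset."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "wfdb"
    if format == "csv":
        _write_csv(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def resample_to_2khz(record: TwelveLeadECG) -> TwelveLeadECG:
    """Band-limited resampling of a record to 2 kHz.

    Annotation indices are rescaled by ``2000 / fs`` and rounded half-up.
    A record already at 2 kHz is returned unchanged.
    """
    if record.fs <= 0:
        raise BadRateError(f"fs must be positive, got {record.fs}")
    if record.fs == TARGET_FS:
        return record
    ratio = Fraction(TARGET_FS / record.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    sig = resample_poly(record.signals, up, down, axis=1)
    n_out = sig.shape[1]
    anns = []
    for a in record.annotations:
        idx = int(np.floor(a.approx_r_index * TARGET_FS / record.fs + 0.5))
        anns.append(replace(a, approx_r_index=min(idx, n_out - 1)))
    return TwelveLeadECG(sig, TARGET_FS, anns, record_id=record.record_id)
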