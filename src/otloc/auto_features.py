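"""Automated morphology extractor: peaks/valleys, eight slots per lead, eight
measurements per slot, and the ratio/difference expansion.

Per beat window and lead, every interior local maximum (peak) and minimum
(valley) is described by eight numbers (see :data:`MEASUREMENT_NAMES`); a
peak/valley flag travels as descriptor metadata.  The extremum nearest the
V6 reference plus its three predecessors and four successors fill eight
slots (zero-padded when absent), yielding a 192 x 8 per-patient matrix
(2 beats x 12 leads x 8 slots).  The matrix is then expanded into a named
high-dimensional vector of ratios and differences.

Valley measurements are computed on the negated signal, so a valley mirrors
its peak counterpart exactly.  Prominence follows the contour-line
definition: the drop from the extremum to the higher of the two minima
flanking it out to the nearest higher sample (or window edge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences, peak_widths

from .beats import BeatWindow
from .ecg_io import LEAD_NAMES

#: Matrix columns, in order.
MEASUREMENT_NAMES: tuple[str, ...] = (
    "location",        # sample index of the extremum within the window
    "prominence",      # contour-line prominence, mV
    "dist_left",       # extremum to left prominence base, samples
    "dist_right",      # extremum to right prominence base, samples
    "width_half_prom", # interpolated width at half prominence, samples
    "span",            # left base to right base, samples
    "amplitude",       # signed height above the zero baseline, mV
    "contour_height",  # prominence - amplitude, mV
)

N_SLOTS = 8
N_ROWS = 2 * len(LEAD_NAMES) * N_SLOTS  # 192
N_COLS = len(MEASUREMENT_NAMES)  # 8


@dataclass(frozen=True)
class ExtremumDescriptor:
    kind: str  # "peak" | "valley" | "pad"
    location: float
    prominence: float
    dist_left: float
    dist_right: float
    width_half_prom: float
    span: float
    amplitude: float
    contour_height: float

    def values(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in MEASUREMENT_NAMES], dtype=float)


PAD = ExtremumDescriptor("pad", 0, 0, 0, 0, 0, 0, 0, 0)


def _describe(sign: str, y: np.ndarray) -> list[ExtremumDescriptor]:
    """Descriptors of all interior local maxima of ``y`` (already negated for
    valleys).  Plateau extrema are reported at the plateau's first sample."""
    idx, props = find_peaks(y, plateau_size=(1, None))
    if idx.size == 0:
        return []
    prom, lbase, rbase = peak_prominences(y, idx)
    with warnings.catch_warnings():
        # zero-width plateau peaks are legitimate descriptors here
        warnings.simplefilter("ignore")
        widths, _, _, _ = peak_widths(y, idx, rel_height=0.5,
                                      prominence_data=(prom, lbase, rbase))
    locs = props["left_edges"]
    out = []
    for k in range(idx.size):
        loc = int(locs[k])
        dl = float(loc - lbase[k])
        dr = float(rbase[k] - loc)
        amp = float(y[idx[k]])
        out.append(ExtremumDescriptor(
            kind=sign,
            location=float(loc),
            prominence=float(prom[k]),
            dist_left=dl,
            dist_right=dr,
            width_half_prom=float(widths[k]),
            span=dl + dr,
            amplitude=amp,
            contour_height=float(prom[k]) - amp,
        ))
    return out


def find_extrema(segment: np.ndarray) -> list[ExtremumDescriptor]:
    """All interior peaks and valleys of a segment, sorted by location."""
    y = np.asarray(segment, dtype=float)
    if y.size < 3:
        raise ValueError("segment must have at least 3 samples")
    peaks = _describe("peak", y)
    valleys = _describe("valley", -y)
    return sorted(peaks + valleys, key=lambda e: e.location)


def measure_extremum(segment: np.ndarray, location: int, kind: str) -> ExtremumDescriptor:
    """Full descriptor of one known extremum of ``segment``."""
    for e in find_extrema(segment):
        if e.location == location and e.kind == kind:
            return e
    raise ValueError(f"no {kind} at sample {location}")


def select_eight(extrema: list[ExtremumDescriptor], ref_offset: int) -> list[ExtremumDescriptor]:
    """Slot the extremum nearest the reference (slot 4, ties to the earlier
    one) plus its three predecessors and four successors; pad missing slots."""
    if not extrema:
        return [PAD] * N_SLOTS
    locs = np.array([e.location for e in extrema])
    c = int(np.argmin(np.abs(locs - ref_offset)))
    before = extrema[max(c - 3, 0):c]
    after = extrema[c + 1:c + 5]
    return (
        [PAD] * (3 - len(before)) + before + [extrema[c]] + after
        + [PAD] * (4 - len(after))
    )


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def matrix_row_keys() -> tuple[str, ...]:
    """The 192 row keys: ``<beat>.<lead>.<slot>`` in canonical order."""
    return tuple(
        f"{beat}.{lead}.{slot}"
        for beat in ("SR", "PVC")
        for lead in LEAD_NAMES
        for slot in range(1, N_SLOTS + 1)
    )


@dataclass
class FeatureMatrix:
    """The 192 x 8 per-patient measurement matrix."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_ROWS, N_COLS):
            raise ValueError(f"feature matrix must be {(N_ROWS, N_COLS)}")

    @property
    def row_keys(self) -> tuple[str, ...]:
        return matrix_row_keys()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_keys),
                            columns=list(MEASUREMENT_NAMES))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="row")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="row")
        return cls(df.loc[list(matrix_row_keys()), list(MEASUREMENT_NAMES)].to_numpy())


def build_feature_matrix(sr: BeatWindow, pvc: BeatWindow) -> FeatureMatrix:
    """Extract and slot extrema for both windows on every lead."""
    if sr.beat_class != "SR" or pvc.beat_class != "PVC":
        raise ValueError("expected one SR window and one PVC window")
    rows = []
    for win in (sr, pvc):
        for segment in win.segments:
            selected = select_eight(find_extrema(segment), win.ref_offset)
            rows.extend(e.values() for e in selected)
    return FeatureMatrix(np.vstack(rows))


# ---------------------------------------------------------------------------
# Ratio/difference expansion
# ---------------------------------------------------------------------------
#
# Two documented recipes over the 192 x 8 matrix M (rows r = beat.lead.slot,
# columns m = measurements).  SR rows are 0..95 and PVC rows 96..191, in the
# same lead/slot order.  Ratios with zero denominator are defined as 0.
#
# "compact" blocks, in order:
#   1. raw cells                                   raw(r.m)          1,536
#   2. within-row ordered ratios (i != j)          ratio(r.mi, r.mj) 10,752
#   3. cross-beat same-lead/slot measurement-pair  ratio(SR.l.s.mi,
#      ratios                                            PVC.l.s.mj)  6,144
#   4. cross-beat same-lead/slot measurement-pair  diff(PVC.l.s.mi,
#      differences                                       SR.l.s.mj)   6,144
#   5. cross-lead same-beat/slot/measurement       ratio(b.l1.s.m,
#      ordered ratios                                    b.l2.s.m)   16,896
#                                                          total     41,472
# "full" appends:
#   6. within-column ordered ratios (r1 != r2),    ratio(r1.m, r2.m) 276,480
#      excluding same-beat/slot pairs already in block 5
#   7. within-column ordered differences           diff(r1.m, r2.m)  293,376
#                                                          total    611,328

RECIPES = ("compact", "full")

COMPACT_LENGTH = 41_472
FULL_LENGTH = 611_328

_N_HALF = N_ROWS // 2  # 96 lead/slot rows per beat


def expansion_length(recipe: str = "compact") -> int:
    if recipe == "compact":
        return COMPACT_LENGTH
    if recipe == "full":
        return FULL_LENGTH
    raise ValueError(f"unknown recipe {recipe!r}")


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros(np.broadcast(num, den).shape)
    np.divide(num, den, out=out, where=den != 0)
    return out


@dataclass
class FeatureVector:
    """A named, flat feature vector (no non-finite values)."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def to_csv(self, path) -> None:
        pd.DataFrame([self.values], columns=list(self.names)).to_csv(path, index=False)


@lru_cache(maxsize=None)
def expansion_names(recipe: str = "compact") -> tuple[str, ...]:
    """Deterministic names of the expansion, matching value order."""
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}")
    keys = matrix_row_keys()
    meas = MEASUREMENT_NAMES
    names: list[str] = []
    names += [f"raw({k}.{m})" for k in keys for m in meas]
    names += [
        f"ratio({k}.{mi}, {k}.{mj})"
        for k in keys for mi in meas for mj in meas if mi != mj
    ]
    half = keys[:_N_HALF], keys[_N_HALF:]
    names += [
        f"ratio({sr_k}.{mi}, {pvc_k}.{mj})"
        for sr_k, pvc_k in zip(*half) for mi in meas for mj in meas
    ]
    names += [
        f"diff({pvc_k}.{mi}, {sr_k}.{mj})"
        for sr_k, pvc_k in zip(*half) for mi in meas for mj in meas
    ]
    names += [
        f"ratio({beat}.{l1}.{slot}.{m}, {beat}.{l2}.{slot}.{m})"
        for beat in ("SR", "PVC")
        for l1 in LEAD_NAMES for l2 in LEAD_NAMES if l1 != l2
        for slot in range(1, N_SLOTS + 1) for m in meas
    ]
    if recipe == "full":
        same_bs = _same_beat_slot_mask()
        pairs = [(k1, k2) for i, k1 in enumerate(keys)
                 for j, k2 in enumerate(keys) if i != j and not same_bs[i, j]]
        names += [f"ratio({k1}.{m}, {k2}.{m})" for m in meas for k1, k2 in pairs]
        names += [
            f"diff({k1}.{m}, {k2}.{m})"
            for m in meas for k1 in keys for k2 in keys if k1 != k2
        ]
    assert len(names) == expansion_length(recipe)
    return tuple(names)


@lru_cache(maxsize=1)
def _same_beat_slot_mask() -> np.ndarray:
    """(192, 192) mask of row pairs sharing beat and slot (any lead)."""
    keys = matrix_row_keys()
    beat = np.array([k.split(".")[0] for k in keys])
    slot = np.array([k.split(".")[2] for k in keys])
    return (beat[:, None] == beat[None, :]) & (slot[:, None] == slot[None, :])


def expand_ratio_features(matrix: FeatureMatrix, recipe: str = "compact",
                          with_names: bool = True) -> FeatureVector:
    """Expand the matrix into the documented ratio/difference vector.

    ``with_names=False`` skips name materialization (the values are what the
    model consumes; names are recoverable via :func:`expansion_names`).
    """
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}")
    M = matrix.values
    blocks = [M.ravel()]
    # within-row ordered ratios
    rr = _safe_div(M[:, :, None], M[:, None, :])
    off = ~np.eye(N_COLS, dtype=bool)
    blocks.append(rr[:, off].ravel())
    # cross-beat ratios / differences, same lead & slot
    A, B = M[:_N_HALF], M[_N_HALF:]
    blocks.append(_safe_div(A[:, :, None], B[:, None, :]).ravel())
    blocks.append((B[:, :, None] - A[:, None, :]).ravel())
    # cross-lead, same beat/slot/measurement
    R = M.reshape(2, len(LEAD_NAMES), N_SLOTS, N_COLS)
    offl = ~np.eye(len(LEAD_NAMES), dtype=bool)
    cl = _safe_div(R[:, :, None, :, :], R[:, None, :, :, :])
    blocks.append(cl[:, offl].ravel())
    if recipe == "full":
        offr = ~np.eye(N_ROWS, dtype=bool)
        cc = _safe_div(M.T[:, :, None], M.T[:, None, :])  # (8, 192, 192)
        blocks.append(cc[:, offr & ~_same_beat_slot_mask()].ravel())
        cd = M.T[:, :, None] - M.T[:, None, :]
        blocks.append(cd[:, offr].ravel())
    values = np.concatenate(blocks)
    names = expansion_names(recipe) if with_names else tuple(
        f"f{i}" for i in range(values.size)
    )
    return FeatureVector(names=names, values=values)
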