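"""Conventional QRS morphology: Q/R/S amplitudes and durations, baselines,
precordial transition scoring, published localization indices, and the
rule-based criterion registry.

Wave decomposition works on the baseline-corrected window: QRS onset/offset
are the edges of the sustained-deflection region containing the reference
sample (|v - baseline| above a configurable threshold, gaps shorter than the
sustain time closed).  Within the complex, R is the dominant positive wave,
Q the negative wave preceding it and S the negative wave following it;
absent waves score exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .auto_features import FeatureVector, _safe_div
from .beats import BeatWindow
from .ecg_io import LEAD_NAMES
from .errors import UnknownCriterionError

#: Default deflection threshold (mV) and sustain time (ms) for QRS bounds.
DEFLECTION_MV = 0.02
SUSTAIN_MS = 4.0

#: Sub-threshold interludes shorter than this are treated as part of the
#: same complex (baseline crossings between Q/R/S waves); the QRS-to-T
#: gap is far longer, so the complex never merges with a T wave.
MERGE_MS = 20.0

#: Baseline span: first 40 ms of the window (stand-in for the T-P segment).
BASELINE_MS = 40.0

PRECORDIAL = ("V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class LeadMeasurements:
    """Conventional measurements of one lead of one beat.

    Amplitudes are magnitudes in mV relative to the estimated baseline
    (``*_amp``) plus alternative-reference R amplitudes; durations in ms.
    Missing waves are exactly zero throughout.
    """

    q_amp: float = 0.0
    r_amp: float = 0.0
    s_amp: float = 0.0
    q_dur: float = 0.0
    r_dur: float = 0.0
    s_dur: float = 0.0
    qrs_dur: float = 0.0
    qrs_onset: int = 0
    qrs_offset: int = 0
    baseline: float = 0.0
    r_peak_index: int = -1  # -1 when no R wave
    # alternative-reference R amplitudes (see expand_classic_features)
    r_amp_zero: float = 0.0   # == r_amp (zero/isoelectric baseline)
    r_amp_qon: float = 0.0    # relative to the voltage at QRS onset
    r_amp_soff: float = 0.0   # relative to the voltage at QRS offset
    r_amp_q: float = 0.0      # relative to the Q-wave nadir voltage
    r_amp_s: float = 0.0      # relative to the S-wave nadir voltage


#: Per-lead measurement names used by the classic ratio expansion.
CLASSIC_MEASUREMENT_NAMES: tuple[str, ...] = (
    "q_amp", "r_amp_zero", "s_amp", "q_dur", "r_dur", "s_dur", "qrs_dur",
    "r_amp_qon", "r_amp_soff", "r_amp_q", "r_amp_s",
)

ClassicMeasurements = dict  # lead name -> LeadMeasurements


def estimate_baseline(window: BeatWindow, lead: str) -> float:
    """Median voltage over the first 40 ms of the window."""
    n = max(int(round(BASELINE_MS / 1000.0 * window.fs)), 1)
    return float(np.median(window.lead(lead)[:n]))


def _qrs_bounds(v: np.ndarray, ref: int, fs: float,
                threshold: float, sustain_ms: float,
                merge_ms: float = MERGE_MS) -> tuple[int, int]:
    """Edges of the sustained active region around ``ref`` (half-open)."""
    sustain = max(int(round(sustain_ms / 1000.0 * fs)), 1)
    merge_gap = max(int(round(merge_ms / 1000.0 * fs)), sustain)
    active = np.abs(v) >= threshold
    if not active.any():
        return 0, 0
    # close sub-threshold gaps shorter than `merge_gap` (crossings between
    # the waves of one complex), then drop blips shorter than `sustain`
    padded = np.concatenate([[False], active, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = edges.reshape(-1, 2)  # [start, stop) of active runs
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    merged = [(a, b) for a, b in merged if b - a >= sustain]
    if not merged:
        return 0, 0
    # the run containing (or nearest to) the reference sample
    best = min(merged, key=lambda ab: 0 if ab[0] <= ref < ab[1]
               else min(abs(ref - ab[0]), abs(ref - ab[1])))
    return best[0], best[1]


def measure_qrs(window: BeatWindow, deflection_mv: float = DEFLECTION_MV,
                sustain_ms: float = SUSTAIN_MS) -> ClassicMeasurements:
    """Conventional Q/R/S measurements on every lead of a beat window."""
    out: ClassicMeasurements = {}
    ms = 1000.0 / window.fs
    for lead in LEAD_NAMES:
        baseline = estimate_baseline(window, lead)
        v = window.lead(lead) - baseline
        onset, offset = _qrs_bounds(v, window.ref_offset, window.fs,
                                    deflection_mv, sustain_ms)
        m = LeadMeasurements(baseline=baseline, qrs_onset=onset, qrs_offset=offset)
        if offset > onset:
            m.qrs_dur = (offset - onset) * ms
            seg = v[onset:offset]
            if seg.max() > 0:
                r_rel = int(np.argmax(seg))
                m.r_amp = m.r_amp_zero = float(seg[r_rel])
                m.r_peak_index = onset + r_rel
                # R-wave support: between baseline crossings flanking the peak
                neg = seg <= 0
                left = np.flatnonzero(neg[:r_rel])
                r_start = int(left[-1]) + 1 if left.size else 0
                right = np.flatnonzero(neg[r_rel:])
                r_stop = r_rel + int(right[0]) if right.size else seg.size
                m.r_dur = (r_stop - r_start) * ms
                if r_start > 0 and seg[:r_start].min() < 0:
                    m.q_amp = float(-seg[:r_start].min())
                    m.q_dur = r_start * ms
                if r_stop < seg.size and seg[r_stop:].min() < 0:
                    m.s_amp = float(-seg[r_stop:].min())
                    m.s_dur = (seg.size - r_stop) * ms
                m.r_amp_qon = float(seg[r_rel] - seg[0])
                m.r_amp_soff = float(seg[r_rel] - seg[-1])
                if m.q_amp:
                    m.r_amp_q = float(seg[r_rel] + m.q_amp)
                if m.s_amp:
                    m.r_amp_s = float(seg[r_rel] + m.s_amp)
            elif seg.min() < 0:
                # monophasic negative (QS): no R wave, all duration to Q
                m.q_amp = float(-seg.min())
                m.q_dur = m.qrs_dur
        out[lead] = m
    return out


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexSet:
    """Published localization indices; ``None`` marks an undefined value."""

    transition_lead_sr: float | None
    transition_lead_pvc: float | None
    tz_index: float | None
    v2_transition_ratio: float | None
    v2s_v3r: float | None
    r_dur_index: float | None
    rs_amp_index: float | None
    r_deflection_interval_v3: float | None
    r_amp_v1: float | None
    y_score: float | None


def transition_score(meas: ClassicMeasurements) -> float | None:
    """Precordial transition-zone score (V1=1 .. V6=6, half steps).

    The transition is the first precordial lead with R/S ratio > 1; a lead
    with exactly equal (nonzero) R and S scores half a step beyond it.
    ``None`` when no lead transitions.
    """
    for k, lead in enumerate(PRECORDIAL, start=1):
        r, s = meas[lead].r_amp, meas[lead].s_amp
        if r == 0 and s == 0:
            continue
        if r > s:
            return float(k)
        if r == s:
            return k + 0.5
    return None


def compute_indices(sr: ClassicMeasurements, pvc: ClassicMeasurements,
                    fs: float = 2000.0) -> IndexSet:
    """All published indices from the SR/PVC measurement pair."""
    tz_sr = transition_score(sr)
    tz_pvc = transition_score(pvc)
    tz_index = tz_pvc - tz_sr if tz_sr is not None and tz_pvc is not None else None

    def pct_r(m: LeadMeasurements) -> float | None:
        tot = m.r_amp + m.s_amp
        return m.r_amp / tot if tot > 0 else None

    pr_pvc, pr_sr = pct_r(pvc["V2"]), pct_r(sr["V2"])
    v2tr = pr_pvc / pr_sr if pr_pvc is not None and pr_sr not in (None, 0.0) else None

    v2s_v3r = (pvc["V2"].s_amp / pvc["V3"].r_amp) if pvc["V3"].r_amp > 0 else None

    def max_over_v1v2(num, den):
        vals = []
        for lead in ("V1", "V2"):
            d = den(pvc[lead])
            if d > 0:
                vals.append(num(pvc[lead]) / d)
        return max(vals) if vals else None

    r_dur_index = max_over_v1v2(lambda m: m.r_dur, lambda m: m.qrs_dur)
    rs_amp_index = max_over_v1v2(lambda m: m.r_amp, lambda m: m.s_amp)

    v3 = pvc["V3"]
    rdi = ((v3.r_peak_index - v3.qrs_onset) * 1000.0 / fs
           if v3.r_peak_index >= 0 else None)

    r_amp_v1 = pvc["V1"].r_amp

    y = (-1.15 * tz_pvc - 0.494 * v2s_v3r
         if tz_pvc is not None and v2s_v3r is not None else None)

    return IndexSet(
        transition_lead_sr=tz_sr,
        transition_lead_pvc=tz_pvc,
        tz_index=tz_index,
        v2_transition_ratio=v2tr,
        v2s_v3r=v2s_v3r,
        r_dur_index=r_dur_index,
        rs_amp_index=rs_amp_index,
        r_deflection_interval_v3=rdi,
        r_amp_v1=r_amp_v1,
        y_score=y,
    )


# ---------------------------------------------------------------------------
# Criterion registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CriterionResult:
    criterion_id: str
    value: float | None
    prediction: str  # "RVOT" | "LVOT" | "indeterminate"


@dataclass(frozen=True)
class _Criterion:
    criterion_id: str
    index: str            # IndexSet attribute
    inequality: str       # one of <, <=, >, >=, ==
    threshold: float
    predicts: str         # class when the inequality holds
    description: str

    def apply(self, idx: IndexSet) -> CriterionResult:
        v = getattr(idx, self.index)
        if v is None:
            return CriterionResult(self.criterion_id, None, "indeterminate")
        ops = {
            "<": v < self.threshold, "<=": v <= self.threshold,
            ">": v > self.threshold, ">=": v >= self.threshold,
            "==": v == self.threshold,
        }
        holds = ops[self.inequality]
        other = "LVOT" if self.predicts == "RVOT" else "RVOT"
        return CriterionResult(self.criterion_id, float(v),
                               self.predicts if holds else other)


def _both(idx: IndexSet) -> CriterionResult:
    """R-duration index < 0.5 AND R/S amplitude index < 0.3 predicts RVOT."""
    rd, rs = idx.r_dur_index, idx.rs_amp_index
    if rd is None or rs is None:
        return CriterionResult("r_dur_and_rs_amp_rvot", None, "indeterminate")
    pred = "RVOT" if (rd < 0.5 and rs < 0.3) else "LVOT"
    return CriterionResult("r_dur_and_rs_amp_rvot", float(rd), pred)


def _later_transition(idx: IndexSet) -> CriterionResult:
    """PVC precordial transition later than the SR transition predicts RVOT."""
    if idx.tz_index is None:
        return CriterionResult("pvc_transition_later_rvot", None, "indeterminate")
    pred = "RVOT" if idx.tz_index > 0 else "LVOT"
    return CriterionResult("pvc_transition_later_rvot", float(idx.tz_index), pred)


_SIMPLE_CRITERIA = [
    _Criterion("rs_transition_v3_lvot", "transition_lead_pvc", "==", 3.0, "LVOT",
               "R/S transition exactly at V3 predicts LVOT"),
    _Criterion("tz_ge_v4_rvot", "transition_lead_pvc", ">=", 4.0, "RVOT",
               "Transitional zone at V4 or later predicts RVOT"),
    _Criterion("v2_transition_ratio_lvot", "v2_transition_ratio", ">=", 0.6, "LVOT",
               "V2 transition ratio >= 0.6 predicts LVOT"),
    _Criterion("v2s_v3r_lvot", "v2s_v3r", "<=", 1.5, "LVOT",
               "V2S/V3R index <= 1.5 predicts LVOT"),
    _Criterion("transition_v1v2_lvot", "transition_lead_pvc", "<=", 2.0, "LVOT",
               "R/S transition at V1 or V2 predicts LVOT"),
    _Criterion("transition_ge_v4_rvot", "transition_lead_pvc", ">=", 4.0, "RVOT",
               "R/S transition at V4 or later predicts RVOT"),
    _Criterion("tz_index_lvot", "tz_index", "<", 0.0, "LVOT",
               "Negative transition-zone index predicts LVOT"),
    _Criterion("rs_index_gt_0p3_lvot", "rs_amp_index", ">", 0.3, "LVOT",
               "R/S amplitude index > 0.3 in V1/V2 predicts LVOT"),
    _Criterion("r_deflection_v3_gt_80_lvot", "r_deflection_interval_v3", ">", 80.0,
               "LVOT", "R-wave deflection interval in V3 > 80 ms predicts LVOT"),
    _Criterion("r_amp_v1_ge_0p1_lvot", "r_amp_v1", ">=", 0.1, "LVOT",
               "PVC R-wave amplitude >= 0.1 mV in V1 predicts LVOT"),
]

CRITERIA: dict[str, object] = {c.criterion_id: c for c in _SIMPLE_CRITERIA}
CRITERIA["r_dur_and_rs_amp_rvot"] = _both
CRITERIA["pvc_transition_later_rvot"] = _later_transition


def criterion_table() -> pd.DataFrame:
    """Auditable registry: id, index, inequality, threshold, predicted class."""
    rows = []
    for c in _SIMPLE_CRITERIA:
        rows.append((c.criterion_id, c.index, c.inequality, c.threshold,
                     c.predicts, c.description))
    rows.append(("r_dur_and_rs_amp_rvot", "r_dur_index & rs_amp_index",
                 "< 0.5 & < 0.3", math.nan, "RVOT",
                 _both.__doc__.strip()))
    rows.append(("pvc_transition_later_rvot", "tz_index", ">", 0.0, "RVOT",
                 _later_transition.__doc__.strip()))
    return pd.DataFrame(rows, columns=["id", "index", "inequality", "threshold",
                                       "predicts", "description"])


def classify_by_criterion(idx: IndexSet, criterion_id: str) -> CriterionResult:
    """Apply one registered criterion; undefined index -> indeterminate."""
    try:
        crit = CRITERIA[criterion_id]
    except KeyError:
        raise UnknownCriterionError(f"unknown criterion {criterion_id!r}") from None
    return crit.apply(idx) if isinstance(crit, _Criterion) else crit(idx)


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

_INDEX_NAMES = tuple(f.name for f in fields(IndexSet))


def classic_table(sr: ClassicMeasurements, pvc: ClassicMeasurements) -> np.ndarray:
    """(24, len(CLASSIC_MEASUREMENT_NAMES)) table: (beat, lead) rows."""
    rows = []
    for meas in (sr, pvc):
        for lead in LEAD_NAMES:
            m = meas[lead]
            rows.append([getattr(m, name) for name in CLASSIC_MEASUREMENT_NAMES])
    return np.asarray(rows, dtype=float)


def classic_expansion_names() -> tuple[str, ...]:
    keys = [f"{beat}.{lead}" for beat in ("SR", "PVC") for lead in LEAD_NAMES]
    cells = [f"{k}.{m}" for k in keys for m in CLASSIC_MEASUREMENT_NAMES]
    names = [f"raw({c})" for c in cells]
    names += [f"ratio({a}, {b})" for a in cells for b in cells if a != b]
    names += [f"index({n})" for n in _INDEX_NAMES]
    return tuple(names)


def expand_classic_features(sr: ClassicMeasurements, pvc: ClassicMeasurements,
                            idx: IndexSet) -> FeatureVector:
    """Raw measurements, all ordered pairwise ratios across the full
    (beat, lead, measurement) table, and the published indices.

    Undefined indices and zero-denominator ratios contribute 0.
    """
    table = classic_table(sr, pvc).ravel()
    n = table.size
    ratios = _safe_div(table[:, None], table[None, :])
    off = ~np.eye(n, dtype=bool)
    idx_vals = np.array(
        [0.0 if getattr(idx, name) is None else float(getattr(idx, name))
         for name in _INDEX_NAMES]
    )
    values = np.concatenate([table, ratios[off].ravel(), idx_vals])
    return FeatureVector(names=classic_expansion_names(), values=values)
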