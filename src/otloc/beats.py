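"""Beat windowing around the lead-V6 reference point.

The reference for each annotated beat is the sample of maximum absolute V6
voltage near the annotation.  Windows are fixed-width at 2 kHz: 215 samples
(0.11 s) either side of the reference for a sinus beat (430 total) and 335
samples (0.17 s) either side for a PVC (670 total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_io import LEAD_NAMES, BeatAnnotation, TwelveLeadECG
from .errors import FlatSignalError, WindowOutOfRangeError

#: Half-widths (samples at 2 kHz) either side of the reference.
SR_HALF = 215
PVC_HALF = 335

HALF_WIDTH = {"SR": SR_HALF, "PVC": PVC_HALF}

#: Default refinement radius around the annotated R index (50 ms at 2 kHz).
DEFAULT_SEARCH_HALFWIDTH = 100


@dataclass
class BeatWindow:
    """Fixed-width 12-lead segment centred on the V6 reference sample."""

    beat_class: str
    segments: np.ndarray  # (12, 430) for SR, (12, 670) for PVC
    ref_offset: int
    fs: float = 2000.0

    def __post_init__(self):
        half = HALF_WIDTH[self.beat_class]
        self.segments = np.asarray(self.segments, dtype=float)
        if self.segments.shape != (len(LEAD_NAMES), 2 * half):
            raise ValueError(
                f"{self.beat_class} window must have shape "
                f"{(len(LEAD_NAMES), 2 * half)}, got {self.segments.shape}"
            )
        if self.ref_offset != half:
            raise ValueError(f"ref_offset must be {half}, got {self.ref_offset}")

    def lead(self, name: str) -> np.ndarray:
        from .ecg_io import LEAD_INDEX

        return self.segments[LEAD_INDEX[name.lower()]]


def locate_reference(
    record: TwelveLeadECG,
    ann: BeatAnnotation,
    search_halfwidth: int = DEFAULT_SEARCH_HALFWIDTH,
) -> int:
    """Refine an approximate R index to the V6 absolute-voltage maximum.

    The search covers ``ann.approx_r_index ± search_halfwidth``; ties break
    toward the earliest sample.  The absolute value lets deeply negative PVC
    complexes anchor as well as positive R waves.
    """
    lo = ann.approx_r_index - search_halfwidth
    hi = ann.approx_r_index + search_halfwidth + 1
    if lo < 0 or hi > record.n_samples:
        raise WindowOutOfRangeError(
            f"search window [{lo}, {hi}) outside record of length {record.n_samples}"
        )
    v6 = record.lead("V6")[lo:hi]
    if np.ptp(v6) == 0:
        raise FlatSignalError("V6 is constant in the search window")
    return lo + int(np.argmax(np.abs(v6)))


def extract_window(record: TwelveLeadECG, ref: int, beat_class: str) -> BeatWindow:
    """Cut the fixed-width 12-lead window ``[ref - half, ref + half)``."""
    half = HALF_WIDTH[beat_class]
    if ref - half < 0 or ref + half > record.n_samples:
        raise WindowOutOfRangeError(
            f"window [{ref - half}, {ref + half}) outside record "
            f"of length {record.n_samples}"
        )
    return BeatWindow(
        beat_class=beat_class,
        segments=record.signals[:, ref - half : ref + half].copy(),
        ref_offset=half,
        fs=record.fs,
    )
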