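"""Synthetic labeled 12-lead records: sinus beats plus PVCs whose precordial
morphology encodes a latent RVOT/LVOT origin, contaminated by power-line
interference, baseline wander and white noise.

Each wave (P, Q, R, S, T) is a Gaussian bump; per-lead Q/R/S amplitudes for
the precordial leads follow a logistic R-fraction curve in the lead number
so the R/S ratio crosses 1 at a configurable transition lead.  An RVOT-like
PVC transitions late (net-negative V1, LBBB-like); an LVOT-like PVC
transitions early (dominant V1 R).  Ground truth (clean signals, R indices,
wave parameters) is retained for every record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .ecg_io import LEAD_NAMES, BeatAnnotation, TwelveLeadECG
from .errors import BadPvcPositionError

ORIGINS = ("RVOT", "LVOT")

#: Default PVC precordial transition per origin class.
DEFAULT_TRANSITION = {"RVOT": 4.5, "LVOT": 1.5}
DEFAULT_TRANSITION_SR = 3.2

#: Precordial QRS total (R+S) amplitude envelope, mV, V1..V6.
_PRECORDIAL_AMP = np.array([1.1, 1.5, 1.6, 1.6, 1.5, 1.4])

#: Limb-lead (R, S) amplitudes, mV.
_LIMB_RS = {
    "I": (0.50, 0.10), "II": (0.90, 0.15), "III": (0.45, 0.20),
    "aVR": (0.10, 0.80), "aVL": (0.30, 0.15), "aVF": (0.70, 0.15),
}

_LOGISTIC_SLOPE = 1.2

QRS_DUR_RANGE = {"SR": (0.070, 0.110), "PVC": (0.120, 0.180)}


@dataclass(frozen=True)
class SynthParams:
    origin: str = "RVOT"
    fs: float = 2000.0
    duration_s: float = 3.2
    heart_rate_bpm: float = 75.0
    pvc_positions: tuple[int, ...] = (2,)
    transition_lead_pvc: float | None = None  # default per origin
    transition_lead_sr: float = DEFAULT_TRANSITION_SR
    qrs_dur_sr_s: float | None = None   # drawn from QRS_DUR_RANGE when None
    qrs_dur_pvc_s: float | None = None
    amp_scale: float = 1.0
    lead_profiles: dict | None = None   # optional {lead: {wave: multiplier}}
    noise: dict = field(default_factory=lambda: {
        "powerline_mv": 0.05, "wander_mv": 0.15, "white_mv": 0.03,
    })
    seed: int = 0

    def __post_init__(self):
        if self.origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}")

    @property
    def tz_pvc(self) -> float:
        return (self.transition_lead_pvc if self.transition_lead_pvc is not None
                else DEFAULT_TRANSITION[self.origin])


@dataclass
class SynthRecord:
    record: TwelveLeadECG
    truth: dict


def _gauss(t: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def _lead_rs(lead: str, tz: float, amp_scale: float) -> tuple[float, float]:
    """(R, S) amplitudes for one lead given the precordial transition."""
    if lead in _LIMB_RS:
        r, s = _LIMB_RS[lead]
        return r * amp_scale, s * amp_scale
    k = int(lead[1])  # V1..V6 -> 1..6
    # R fraction crosses 0.5 at lead position tz - 0.5, so the first lead
    # whose R exceeds S is round(tz): the measured transition score
    # recovers the configured value to within half a lead.
    frac = 1.0 / (1.0 + np.exp(-(k - tz + 0.5) * _LOGISTIC_SLOPE))
    total = _PRECORDIAL_AMP[k - 1] * amp_scale
    return total * frac, total * (1.0 - frac)


def _wave_multiplier(params: SynthParams, lead: str, wave: str,
                     beat_class: str = "SR") -> float:
    """Profile multiplier for one wave; a ``"R:PVC"``-style key scopes the
    multiplier to one beat class, a bare ``"R"`` applies to both."""
    if params.lead_profiles and lead in params.lead_profiles:
        prof = params.lead_profiles[lead]
        return float(prof.get(f"{wave}:{beat_class}", prof.get(wave, 1.0)))
    return 1.0


def generate_beat_template(
    beat_class: str,
    lead: str,
    params: SynthParams,
    qrs_dur_s: float | None = None,
    half_span_s: float = 0.40,
) -> np.ndarray:
    """One clean beat template for a lead, R peak at the centre sample.

    SR beats carry a P wave and an upright T; PVCs are wide, P-less, with a
    discordant T.  The template is deterministic given its arguments
    (``qrs_dur_s`` defaults to the class range's midpoint).
    """
    fs = params.fs
    if qrs_dur_s is None:
        qrs_dur_s = (params.qrs_dur_sr_s if beat_class == "SR"
                     else params.qrs_dur_pvc_s)
    if qrs_dur_s is None:
        lo, hi = QRS_DUR_RANGE[beat_class]
        qrs_dur_s = 0.5 * (lo + hi)
    tz = params.transition_lead_sr if beat_class == "SR" else params.tz_pvc
    r_amp, s_amp = _lead_rs(lead, tz, params.amp_scale)
    r_amp *= _wave_multiplier(params, lead, "R", beat_class)
    s_amp *= _wave_multiplier(params, lead, "S", beat_class)

    half = int(round(half_span_s * fs))
    t = (np.arange(2 * half + 1) - half) / fs
    sig_r = 0.13 * qrs_dur_s
    sig_s = 0.11 * qrs_dur_s
    y = _gauss(t, r_amp, 0.0, sig_r)
    y -= _gauss(t, s_amp, 0.38 * qrs_dur_s, sig_s)
    y -= _gauss(t, 0.06 * r_amp, -0.34 * qrs_dur_s, sig_s)  # small Q
    if beat_class == "SR":
        y += _gauss(t, 0.10 * params.amp_scale * _wave_multiplier(params, lead, "P", beat_class),
                    -0.18, 0.022)
        y += _gauss(t, 0.25 * params.amp_scale, 0.28, 0.055)
    else:
        y -= _gauss(t, 0.22 * params.amp_scale, 0.30, 0.065)  # discordant T
    return y


def _noise(params: SynthParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Power line + baseline wander + white noise for one lead."""
    t = np.arange(n) / params.fs
    nz = params.noise
    out = np.zeros(n)
    pl = float(nz.get("powerline_mv", 0.0))
    if pl:
        out += pl * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    wa = float(nz.get("wander_mv", 0.0))
    if wa:
        for _ in range(3):
            f = rng.uniform(0.05, 0.45)
            out += (wa / 3.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    wh = float(nz.get("white_mv", 0.0))
    if wh:
        out += rng.normal(0.0, wh, n)
    return out


def generate_record(params: SynthParams) -> SynthRecord:
    """A full record: beat train, PVCs at the stated positions, noise added.

    Annotations carry one SR and one PVC beat with the approximate R index
    jittered by up to ±10 samples around the truth.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration_s * fs))
    period = 60.0 / params.heart_rate_bpm
    n_beats = int(params.duration_s / period)
    if n_beats < 4:
        raise ValueError("duration must cover at least 4 beats")
    for p in params.pvc_positions:
        if not 0 <= p < n_beats:
            raise BadPvcPositionError(f"PVC position {p} beyond {n_beats} beats")

    qrs_sr = params.qrs_dur_sr_s or rng.uniform(*QRS_DUR_RANGE["SR"])
    qrs_pvc = params.qrs_dur_pvc_s or rng.uniform(*QRS_DUR_RANGE["PVC"])

    centers = [int(round((i + 0.5) * period * fs)) for i in range(n_beats)]
    classes = ["PVC" if i in params.pvc_positions else "SR" for i in range(n_beats)]

    clean = np.zeros((len(LEAD_NAMES), n))
    templates = {
        (bc, lead): generate_beat_template(
            bc, lead, params, qrs_dur_s=(qrs_sr if bc == "SR" else qrs_pvc))
        for bc in ("SR", "PVC") for lead in LEAD_NAMES
    }
    half = (next(iter(templates.values())).size - 1) // 2
    for center, bc in zip(centers, classes):
        lo, hi = center - half, center + half + 1
        slo, shi = max(lo, 0), min(hi, n)
        for li, lead in enumerate(LEAD_NAMES):
            clean[li, slo:shi] += templates[(bc, lead)][slo - lo : shi - lo]

    noisy = clean + np.vstack([_noise(params, n, rng) for _ in LEAD_NAMES])

    margin = 680
    sr_beats = [i for i, bc in enumerate(classes)
                if bc == "SR" and margin <= centers[i] < n - margin]
    pvc_beats = [i for i, bc in enumerate(classes)
                 if bc == "PVC" and margin <= centers[i] < n - margin]
    anns = []
    if sr_beats:
        anns.append(BeatAnnotation(
            "SR", centers[sr_beats[0]] + int(rng.integers(-10, 11))))
    if pvc_beats:
        anns.append(BeatAnnotation(
            "PVC", centers[pvc_beats[0]] + int(rng.integers(-10, 11))))

    record = TwelveLeadECG(noisy, fs, anns, record_id=f"synth-{params.seed}")
    truth = {
        "origin": params.origin,
        "clean": clean,
        "r_indices": centers,
        "beat_classes": classes,
        "wave_params": {
            "transition_lead_pvc": params.tz_pvc,
            "transition_lead_sr": params.transition_lead_sr,
            "qrs_dur_sr_s": qrs_sr,
            "qrs_dur_pvc_s": qrs_pvc,
            "amp_scale": params.amp_scale,
        },
    }
    return SynthRecord(record=record, truth=truth)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Class-conditional PVC transition draw: mean and sd per origin.  The sd
#: makes the classes overlap enough that single-criterion rules sit in the
#: 70–90% accuracy band while the full model can do better.
TRANSITION_DRAW = {"RVOT": (4.4, 0.7), "LVOT": (1.8, 0.7)}

#: Class-conditional PVC V1 R-wave multiplier range (uniform draw): LVOT
#: PVCs carry a boosted V1 R (RBBB-like balance), RVOT a damped one.  The
#: continuous amplitude signal is usable by the model but lies mostly off
#: the fixed published amplitude cutoffs.
V1_R_MULT = {"RVOT": (0.5, 0.9), "LVOT": (1.1, 1.8)}


def dataset_params(n: int, class_balance: float = 0.77, seed: int = 0) -> list[SynthParams]:
    """Per-record jittered parameters for a reproducible labeled cohort."""
    if n < 2:
        raise ValueError("need at least 2 records")
    n_rvot = int(round(n * class_balance))
    origins = ["RVOT"] * n_rvot + ["LVOT"] * (n - n_rvot)
    root = np.random.SeedSequence(seed)
    out = []
    for i, (origin, child) in enumerate(zip(origins, root.spawn(n))):
        rng = np.random.default_rng(child)
        mu, sd = TRANSITION_DRAW[origin]
        tz = float(np.clip(rng.normal(mu, sd), 1.0, 6.0))
        tz_sr = float(np.clip(rng.normal(DEFAULT_TRANSITION_SR, 0.4), 1.5, 5.0))
        noise = {
            "powerline_mv": 0.05 * rng.uniform(0.5, 1.5),
            "wander_mv": 0.15 * rng.uniform(0.5, 1.5),
            "white_mv": 0.03 * rng.uniform(0.5, 1.5),
        }
        out.append(SynthParams(
            origin=origin,
            transition_lead_pvc=tz,
            transition_lead_sr=tz_sr,
            lead_profiles={"V1": {"R:PVC": float(rng.uniform(*V1_R_MULT[origin]))}},
            qrs_dur_sr_s=float(rng.uniform(*QRS_DUR_RANGE["SR"])),
            qrs_dur_pvc_s=float(rng.uniform(*QRS_DUR_RANGE["PVC"])),
            amp_scale=float(rng.uniform(0.8, 1.2)),
            noise=noise,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return out


def iter_dataset(n: int, class_balance: float = 0.77, seed: int = 0
                 ) -> Iterator[tuple[SynthRecord, str]]:
    """Generate (record, label) pairs lazily — memory-friendly for cohorts."""
    for p in dataset_params(n, class_balance, seed):
        yield generate_record(p), p.origin


def generate_dataset(n: int, class_balance: float = 0.77, seed: int = 0
                     ) -> tuple[list[SynthRecord], list[str]]:
    """Materialized cohort: list of records plus RVOT/LVOT labels."""
    records, labels = [], []
    for rec, label in iter_dataset(n, class_balance, seed):
        records.append(rec)
        labels.append(label)
    return records, labels
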