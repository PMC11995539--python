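"""Raw hip-worn accelerometry to daily movement-behaviour minutes.

The processing chain mirrors standard free-living protocols: tri-axial
acceleration (g units, constant sampling rate) is segmented into 6-s
epochs; each epoch's intensity is summarised by the mean amplitude
deviation (MAD) of the acceleration resultant; non-wear is detected as
prolonged stillness with a small artifact tolerance; epochs overlapping the
self-reported nightly sleep window are discarded; the remainder are
classified as sedentary, standing, LPA or MVPA using MAD cut-points plus a
gravity-based posture estimate; and per-day minutes are averaged over valid
days (>= 10 h awake wear), requiring >= 4 valid days per participant.

Timestamps are seconds from an arbitrary midnight, so time-of-day is
``t % 86400`` and the date index is ``t // 86400``.

MAD cut-points are device- and protocol-specific; the defaults here
(sedentary < 0.0225 g, MVPA >= 0.0915 g) are configurable operator choices,
not universal constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EPOCH_S = 6.0
SECONDS_PER_DAY = 86400.0

LABELS = ("nonwear", "sleep_excluded", "sedentary", "standing", "LPA", "MVPA")


@dataclass(frozen=True)
class Cutpoints:
    """MAD intensity cut-points in g: [0, sed_upper) low, [mvpa_lower, inf) MVPA."""

    sed_upper: float = 0.0225
    mvpa_lower: float = 0.0915

    def __post_init__(self) -> None:
        if not 0.0 < self.sed_upper < self.mvpa_lower:
            raise ValueError("require 0 < sed_upper < mvpa_lower")


@dataclass
class DaySummary:
    date: int
    wear_min: float
    sedentary_min: float
    standing_min: float
    lpa_min: float
    mvpa_min: float
    valid: bool


@dataclass
class ParticipantSummary:
    """Mean daily minutes over valid days; LPA includes standing time."""

    days: list[DaySummary]
    n_valid_days: int
    valid: bool
    mean_minutes: dict[str, float] = field(default_factory=dict)


def compute_mad(samples: np.ndarray) -> float:
    """Mean amplitude deviation of the acceleration resultant (g).

    ``samples`` is an (n, 3) array of ax, ay, az within one epoch;
    MAD = mean |r_i - mean(r)| with r_i the Euclidean resultant.  Rotation
    of the sensor leaves the resultant, hence MAD, unchanged.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty epoch")
    r = np.linalg.norm(samples.reshape(-1, 3), axis=1)
    return float(np.abs(r - r.mean()).mean())


def segment_epochs(raw: pd.DataFrame, rate: float, epoch_s: float = EPOCH_S) -> pd.DataFrame:
    """Segment raw samples into fixed epochs aligned at the first sample.

    ``raw`` has columns t (s), ax, ay, az (g).  Partial trailing epochs are
    dropped.  Returns a frame with columns start, mad, mean_x, mean_y,
    mean_z, one row per epoch.
    """
    n_per = int(round(rate * epoch_s))
    t = raw["t"].to_numpy(dtype=float)
    A = raw[["ax", "ay", "az"]].to_numpy(dtype=float)
    n_epochs = len(t) // n_per
    if n_epochs == 0:
        return pd.DataFrame(columns=["start", "mad", "mean_x", "mean_y", "mean_z"])
    A = A[: n_epochs * n_per].reshape(n_epochs, n_per, 3)
    r = np.linalg.norm(A, axis=2)
    mad = np.abs(r - r.mean(axis=1, keepdims=True)).mean(axis=1)
    means = A.mean(axis=1)
    return pd.DataFrame({
        "start": t[::n_per][:n_epochs],
        "mad": mad,
        "mean_x": means[:, 0],
        "mean_y": means[:, 1],
        "mean_z": means[:, 2],
    })


def detect_nonwear(
    epochs: pd.DataFrame,
    window_min: float = 60.0,
    artifact_tolerance_s: float = 30.0,
    stillness_threshold: float = 0.0067,
    epoch_s: float = EPOCH_S,
) -> np.ndarray:
    """Boolean non-wear mask over time-ordered epochs.

    A maximal run of below-threshold MAD lasting at least ``window_min``
    minutes is non-wear; short active interruptions totalling at most
    ``artifact_tolerance_s`` seconds inside the run are absorbed into it
    (movement artifacts while the device lies still).  Interruptions at run
    edges are never absorbed.
    """
    mad = epochs["mad"].to_numpy(dtype=float)
    n = mad.size
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    still = mad < stillness_threshold

    # maximal still segments as (start, stop) half-open epoch index ranges
    edges = np.flatnonzero(np.diff(np.r_[False, still, False]))
    segments = list(zip(edges[::2], edges[1::2]))

    i = 0
    while i < len(segments):
        run_start, run_end = segments[i]
        gap_total = 0.0
        j = i
        while j + 1 < len(segments):
            gap = (segments[j + 1][0] - segments[j][1]) * epoch_s
            if gap_total + gap > artifact_tolerance_s:
                break
            gap_total += gap
            j += 1
            run_end = segments[j][1]
        if (run_end - run_start) * epoch_s >= window_min * 60.0:
            mask[run_start:run_end] = True
        i = j + 1
    return mask


def _parse_clock(t) -> float:
    """Clock time ('HH:MM' or seconds-of-day number) to seconds of day."""
    if isinstance(t, str):
        h, m = t.split(":")
        return float(int(h) * 3600 + int(m) * 60)
    return float(t) % SECONDS_PER_DAY


def sleep_window_mask(
    starts: np.ndarray, bed_time, wake_time, epoch_s: float = EPOCH_S
) -> np.ndarray:
    """True where the epoch interval intersects the nightly [bed, wake) window.

    The window repeats every day and may cross midnight.  ``bed == wake``
    is rejected as degenerate.
    """
    bed = _parse_clock(bed_time)
    wake = _parse_clock(wake_time)
    if bed == wake:
        raise ValueError("degenerate sleep window: bed time equals wake time")
    tod = np.asarray(starts, dtype=float) % SECONDS_PER_DAY
    t0, t1 = tod, tod + epoch_s  # epoch interval on the clock circle

    def intersects(lo: float, hi: float) -> np.ndarray:
        # epoch [t0, t1) vs window [lo, hi), both within one day; t1 may
        # spill past midnight so also test the wrapped copy.
        a = (t0 < hi) & (t1 > lo)
        b = (t0 - SECONDS_PER_DAY < hi) & (t1 - SECONDS_PER_DAY > lo)
        return a | b

    if bed < wake:
        return intersects(bed, wake)
    return intersects(bed, SECONDS_PER_DAY) | intersects(0.0, wake)


def estimate_posture(
    epochs: pd.DataFrame,
    reference_vector: np.ndarray | None = None,
    walk_mad_band: tuple[float, float] = (0.091, 0.6),
    upright_threshold_deg: float = 45.0,
) -> pd.DataFrame:
    """Trunk inclination per epoch relative to an upright reference.

    The reference orientation is the mean acceleration vector over detected
    walking epochs (MAD inside ``walk_mad_band``), exploiting the constant
    gravity vector and the upright posture of walking.  Returns the frame
    with added columns ``angle`` (degrees, NaN when uncalibrated) and
    ``posture`` in {upright, non_upright, unknown}.
    """
    out = epochs.copy()
    V = out[["mean_x", "mean_y", "mean_z"]].to_numpy(dtype=float)
    if reference_vector is None:
        walking = (out["mad"].to_numpy() >= walk_mad_band[0]) & (
            out["mad"].to_numpy() < walk_mad_band[1]
        )
        if not walking.any():
            log.warning("no walking epochs found for posture calibration; "
                        "postures set to unknown")
            out["angle"] = np.nan
            out["posture"] = "unknown"
            return out
        reference_vector = V[walking].mean(axis=0)
    ref = np.asarray(reference_vector, dtype=float)
    ref = ref / np.linalg.norm(ref)
    norms = np.linalg.norm(V, axis=1)
    with np.errstate(invalid="ignore"):
        cosang = np.clip((V @ ref) / np.where(norms > 0, norms, np.nan), -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    out["angle"] = angle
    out["posture"] = np.where(
        np.isnan(angle), "unknown",
        np.where(angle > upright_threshold_deg, "non_upright", "upright"),
    )
    return out


def classify_epoch(mad: float, cutpoints: Cutpoints, posture: str = "unknown") -> str:
    """Intensity + posture classification of a single worn, awake epoch.

    MVPA at or above ``mvpa_lower`` (boundary inclusive upward), LPA in
    between, and below ``sed_upper`` the posture decides sedentary versus
    standing; unknown posture defaults to sedentary.
    """
    if mad >= cutpoints.mvpa_lower:
        return "MVPA"
    if mad >= cutpoints.sed_upper:
        return "LPA"
    if posture == "upright":
        return "standing"
    if posture == "unknown":
        log.debug("unknown posture for low-intensity epoch; defaulting to sedentary")
    return "sedentary"


def classify_epochs(epochs: pd.DataFrame, cutpoints: Cutpoints) -> pd.DataFrame:
    """Vectorised :func:`classify_epoch` honouring nonwear/sleep labels."""
    out = epochs.copy()
    mad = out["mad"].to_numpy(dtype=float)
    posture = out["posture"].to_numpy() if "posture" in out else np.full(len(out), "unknown")
    label = np.where(
        mad >= cutpoints.mvpa_lower, "MVPA",
        np.where(
            mad >= cutpoints.sed_upper, "LPA",
            np.where(posture == "upright", "standing", "sedentary"),
        ),
    )
    if "label" in out:
        keep = out["label"].isin(["nonwear", "sleep_excluded"]).to_numpy()
        label = np.where(keep, out["label"].to_numpy(), label)
    out["label"] = label
    return out


def process_raw(
    raw: pd.DataFrame,
    rate: float,
    bed_time,
    wake_time,
    cutpoints: Cutpoints | None = None,
    window_min: float = 60.0,
    artifact_tolerance_s: float = 30.0,
    stillness_threshold: float = 0.0067,
) -> pd.DataFrame:
    """Full epoch-level chain: segment, non-wear, sleep exclusion, posture,
    classification.  Returns the labelled epoch frame."""
    cutpoints = cutpoints or Cutpoints()
    ep = segment_epochs(raw, rate)
    if ep.empty:
        return ep.assign(label=pd.Series(dtype=str))
    nonwear = detect_nonwear(ep, window_min, artifact_tolerance_s, stillness_threshold)
    asleep = sleep_window_mask(ep["start"].to_numpy(), bed_time, wake_time)
    ep = estimate_posture(ep)
    ep["label"] = np.where(nonwear, "nonwear",
                           np.where(asleep, "sleep_excluded", ""))
    ep = classify_epochs(ep, cutpoints)
    return ep


def summarize_participant(
    epochs: pd.DataFrame,
    min_valid_days: int = 4,
    min_wear_min: float = 600.0,
    epoch_s: float = EPOCH_S,
) -> ParticipantSummary:
    """Daily summaries and mean daily behaviour minutes over valid days.

    Wear time is awake wear (non-wear and sleep-window epochs excluded); a
    day is valid with >= ``min_wear_min`` minutes of it, and a participant
    with >= ``min_valid_days`` valid days.  Output LPA is standing + light
    activity.  With zero valid days the participant is invalid and the
    means are empty.
    """
    per_epoch_min = epoch_s / 60.0
    days: list[DaySummary] = []
    if len(epochs):
        date = (epochs["start"].to_numpy(dtype=float) // SECONDS_PER_DAY).astype(int)
        for d in np.unique(date):
            sub = epochs.loc[date == d, "label"]
            counts = sub.value_counts()
            mins = {lab: counts.get(lab, 0) * per_epoch_min for lab in LABELS}
            wear = mins["sedentary"] + mins["standing"] + mins["LPA"] + mins["MVPA"]
            days.append(DaySummary(
                date=int(d), wear_min=wear,
                sedentary_min=mins["sedentary"], standing_min=mins["standing"],
                lpa_min=mins["LPA"], mvpa_min=mins["MVPA"],
                valid=wear >= min_wear_min,
            ))
    valid_days = [d for d in days if d.valid]
    ok = len(valid_days) >= min_valid_days
    means: dict[str, float] = {}
    if valid_days:
        nv = len(valid_days)
        means = {
            "ST": sum(d.sedentary_min for d in valid_days) / nv,
            "LPA": sum(d.standing_min + d.lpa_min for d in valid_days) / nv,
            "MVPA": sum(d.mvpa_min for d in valid_days) / nv,
        }
    return ParticipantSummary(days=days, n_valid_days=len(valid_days),
                              valid=ok, mean_minutes=means)
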