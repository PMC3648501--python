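"""Oscillation measurement: periods, amplitudes, phases, response delays.

Period is defined as the mean inter-peak interval over the analysis window
(a peak-based reading, robust at the ten-or-fewer cycles these simulations
produce), amplitude as max - min over the last complete cycle, and a signal
counts as oscillating if it shows at least three peaks with a relative
amplitude of at least 5% of its maximum.  Phase lags are circular means of
nearest-peak offsets; |lag| < T/6 is "in phase" and |lag - T/2| < T/6 is
"antiphase".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .simulate import Trajectory

__all__ = [
    "OscillationSummary",
    "PhaseClass",
    "PhaseRelation",
    "NO_RESPONSE",
    "detect_peaks",
    "measure",
    "phase_relation",
    "count_periods",
    "response_delay",
    "peak_envelope",
]

# default relative-amplitude floor below which a signal is "not oscillating"
AMPLITUDE_FLOOR = 0.05
# absolute floor (a.u.): solver-noise ripples around zero are not oscillation
ABS_AMPLITUDE_FLOOR = 1e-6
# peak prominence threshold, as a fraction of the signal range in the window
PROMINENCE_FRACTION = 0.10


@dataclass
class OscillationSummary:
    species: str
    peak_times: np.ndarray
    period: float  # minutes; 0.0 when not oscillating
    amplitude: float  # a.u., max - min over the last full cycle
    relative_amplitude: float  # (max - min)/max over the window
    is_oscillating: bool
    n_peaks: int


class PhaseClass(str, enum.Enum):
    IN_PHASE = "in_phase"
    ANTIPHASE = "antiphase"
    OFFSET = "offset"


@dataclass
class PhaseRelation:
    species_a: str
    species_b: str
    lag: float  # minutes, in [-T/2, T/2]
    period: float
    classification: PhaseClass


NO_RESPONSE = float("nan")


def detect_peaks(traj: Trajectory, species: str) -> np.ndarray:
    """Times of local maxima with prominence >= 10% of the signal range.

    Endpoints are never reported as peaks; a flat signal yields no peaks.
    """
    y = traj[species]
    rng = float(np.ptp(y))
    if rng <= 0:
        return np.array([])
    idx, _ = find_peaks(y, prominence=PROMINENCE_FRACTION * rng)
    return traj.times[idx]


def measure(
    traj: Trajectory, species: str, window: float | None = None
) -> OscillationSummary:
    """Summarize one species' oscillation over the trailing ``window`` minutes."""
    t0, t1 = traj.t_span
    if window is not None:
        if window > t1 - t0:
            raise ValueError("analysis window exceeds trajectory span")
        traj = traj.window(t1 - window, t1)
    y = traj[species]
    peaks = detect_peaks(traj, species)
    ymax = float(np.max(y))
    span = float(np.ptp(y))
    rel_amp = float(span / ymax) if ymax > ABS_AMPLITUDE_FLOOR else 0.0

    oscillating = (
        len(peaks) >= 3
        and rel_amp >= AMPLITUDE_FLOOR
        and span >= ABS_AMPLITUDE_FLOOR
    )
    if oscillating:
        period = float(np.mean(np.diff(peaks)))
        # amplitude over the last complete cycle
        cyc = traj.window(peaks[-2], peaks[-1] + (peaks[-1] - peaks[-2]))
        ycyc = cyc[species]
        amplitude = float(np.max(ycyc) - np.min(ycyc))
    else:
        period = 0.0
        amplitude = 0.0
    return OscillationSummary(
        species=species,
        peak_times=peaks,
        period=period,
        amplitude=amplitude,
        relative_amplitude=rel_amp,
        is_oscillating=oscillating,
        n_peaks=len(peaks),
    )


def phase_relation(
    traj: Trajectory, species_a: str, species_b: str, window: float | None = None
) -> PhaseRelation:
    """Phase lag of b relative to a from nearest-peak time differences.

    The lag is the circular mean of (nearest b-peak - a-peak) offsets mapped
    to [-T/2, T/2]; classification thresholds split the cycle into thirds.
    Raises ValueError if either species is not oscillating.
    """
    sa = measure(traj, species_a, window)
    sb = measure(traj, species_b, window)
    for s in (sa, sb):
        if not s.is_oscillating:
            raise ValueError(f"species {s.species!r} is not oscillating")
    period = float((sa.period + sb.period) / 2)

    # circular mean of per-peak offsets
    angles = []
    for ta in sa.peak_times:
        tb = sb.peak_times[np.argmin(np.abs(sb.peak_times - ta))]
        angles.append(2 * np.pi * (tb - ta) / period)
    mean_angle = float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))
    lag = mean_angle / (2 * np.pi) * period  # in [-T/2, T/2]

    if abs(lag) < period / 6:
        cls = PhaseClass.IN_PHASE
    elif abs(abs(lag) - period / 2) < period / 6:
        cls = PhaseClass.ANTIPHASE
    else:
        cls = PhaseClass.OFFSET
    return PhaseRelation(species_a, species_b, lag, period, cls)


def count_periods(
    traj: Trajectory, species: str, t_span: tuple[float, float] | None = None
) -> int:
    """Number of complete peak-to-peak cycles within ``t_span``."""
    if t_span is not None:
        traj = traj.window(*t_span)
    peaks = detect_peaks(traj, species)
    return max(len(peaks) - 1, 0)


def peak_envelope(traj: Trajectory, species: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle upper envelope: (peak times, peak values)."""
    pk = detect_peaks(traj, species)
    if len(pk) == 0:
        return np.array([]), np.array([])
    vals = np.interp(pk, traj.times, traj[species])
    return pk, vals


def response_delay(
    traj_perturbed: Trajectory,
    traj_reference: Trajectory,
    species: str,
    event_time: float,
    threshold: float = 0.20,
) -> float:
    """Minutes from an event to a >20% departure of the peak envelope.

    Both envelopes are linear interpolations through (peak time, peak value)
    points.  Where the perturbed signal stops peaking (oscillation death) its
    envelope is continued by the signal's running maximum over a trailing
    reference period, so monotone collapses still register.  Returns NaN
    (``NO_RESPONSE``) if no departure exceeds the threshold.
    """
    ref_pk, ref_v = peak_envelope(traj_reference, species)
    if len(ref_pk) < 2:
        raise ValueError(f"reference for {species!r} shows too few peaks")
    period = float(np.mean(np.diff(ref_pk)))

    t = traj_reference.times
    mask = t >= event_time
    tq = t[mask]
    env_ref = np.interp(tq, ref_pk, ref_v)

    pert_pk, pert_v = peak_envelope(traj_perturbed, species)
    yp = traj_perturbed[species]
    if len(pert_pk) >= 2:
        env_p = np.interp(tq, pert_pk, pert_v)
        # beyond the last perturbed peak, fall back to a trailing-window max
        beyond = tq > pert_pk[-1]
    else:
        env_p = np.empty_like(tq)
        beyond = np.ones_like(tq, dtype=bool)
    if np.any(beyond):
        tp = traj_perturbed.times
        for j in np.nonzero(beyond)[0]:
            w = (tp >= tq[j] - period) & (tp <= tq[j])
            env_p[j] = float(np.max(yp[w])) if np.any(w) else yp[-1]

    with np.errstate(divide="ignore", invalid="ignore"):
        departure = np.abs(env_p - env_ref) / env_ref
    hit = np.nonzero(departure > threshold)[0]
    if hit.size == 0:
        return NO_RESPONSE
    return float(tq[hit[0]] - event_time)
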