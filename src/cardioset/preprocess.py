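"""Delay-and-sum beamforming, windowing, S2 detection and diastolic windows.

The four recorded channels are aligned by cross-correlation against a
reference channel (search bounded to +/-25 ms) and averaged.  The beamformed
signal is cut into 1.5 s windows with 50% overlap ("full cycle" samples) and,
after locating second heart sounds, into 128 ms diastolic windows starting
100 ms after each S2 onset.

S2 onsets come either from a simplified homomorphic-envelope detector or
verbatim from an annotation sidecar, so exact onsets can be injected when a
stronger external segmenter is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .synthetic import Recording

__all__ = [
    "BeamformedSignal",
    "Segment",
    "beamform",
    "sliding_windows",
    "detect_s2",
    "extract_diastolic_windows",
    "WINDOW_SECONDS",
    "WINDOW_OVERLAP",
    "DW_OFFSET_SECONDS",
    "DW_LENGTH_SECONDS",
]

logger = logging.getLogger(__name__)

WINDOW_SECONDS = 1.5
WINDOW_OVERLAP = 0.5
DW_OFFSET_SECONDS = 0.100
DW_LENGTH_SECONDS = 0.128

#: delay search bound for beamforming; microphones are co-located so true
#: delays are far below this — the bound guards against locking onto the
#: wrong beat.
MAX_DELAY_SECONDS = 0.025

#: nominal S2 transient length assumed when converting an envelope peak
#: (transient centre) into an onset estimate.
S2_NOMINAL_SECONDS = 0.070


@dataclass
class BeamformedSignal:
    samples: np.ndarray
    sample_rate: float
    applied_delays: tuple[int, ...]
    subject_id: str = "unknown"
    condition: str = "unknown"


@dataclass
class Segment:
    samples: np.ndarray
    start_sample: int         # 0-based index into the parent beamformed signal
    kind: str                 # "full_cycle_window" | "diastolic_window"
    subject_id: str = "unknown"
    condition: str = "unknown"
    sample_rate: float = 4000.0


def beamform(recording: Recording, reference_channel: int = 0) -> BeamformedSignal:
    """Delay-and-sum the channels of a recording into one signal.

    Per-channel delay = argmax of cross-correlation with the reference
    channel within +/-25 ms; channels are shifted back by their delay,
    truncated to the common support and averaged.
    """
    x = np.asarray(recording.samples, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("recording samples must be (channels, time)")
    if not np.all(np.isfinite(x)):
        raise ValueError("recording contains non-finite samples")
    n_ch, n = x.shape
    fs = recording.sample_rate
    if n_ch == 1:
        return BeamformedSignal(x[0].copy(), fs, (0,), recording.subject_id, recording.condition)
    ref = x[reference_channel]
    if not np.any(ref):
        raise ValueError("reference channel is all zero; correlation undefined")
    max_lag = int(round(MAX_DELAY_SECONDS * fs))
    delays = []
    for ch in range(n_ch):
        if not np.any(x[ch]):
            raise ValueError(f"channel {ch} is all zero; correlation undefined")
        delays.append(_xcorr_delay(x[ch], ref, max_lag))
    delays = tuple(delays)

    # channel ch ~= template delayed by delays[ch]; aligned[t] = x[ch][t + d].
    # Crop to the support where every aligned channel is defined.
    lo = max(0, -min(delays))
    hi = n - max(0, max(delays))
    out = np.zeros(hi - lo)
    for ch, d in enumerate(delays):
        out += x[ch, lo + d : hi + d]
    out /= n_ch
    return BeamformedSignal(out, fs, delays, recording.subject_id, recording.condition)


def _xcorr_delay(sig: np.ndarray, ref: np.ndarray, max_lag: int) -> int:
    """Delay d (samples) maximising sum ref[t] * sig[t + d] over |d| <= max_lag."""
    best_d, best_v = 0, -np.inf
    for d in range(-max_lag, max_lag + 1):
        if d >= 0:
            v = float(ref[: len(ref) - d] @ sig[d:])
        else:
            v = float(ref[-d:] @ sig[:d])
        if v > best_v:
            best_v, best_d = v, d
    return best_d


def sliding_windows(signal: BeamformedSignal) -> list[Segment]:
    """1.5 s windows with 50% overlap; only fully contained windows."""
    fs = signal.sample_rate
    win = int(round(WINDOW_SECONDS * fs))
    hop = int(round(WINDOW_SECONDS * (1.0 - WINDOW_OVERLAP) * fs))
    n = len(signal.samples)
    segments = []
    for start in range(0, n - win + 1, hop):
        segments.append(
            Segment(
                samples=signal.samples[start : start + win].copy(),
                start_sample=start,
                kind="full_cycle_window",
                subject_id=signal.subject_id,
                condition=signal.condition,
                sample_rate=fs,
            )
        )
    return segments


def _homomorphic_envelope(x: np.ndarray, fs: float, cutoff: float = 20.0) -> np.ndarray:
    log_energy = np.log(np.abs(x) + 1e-12)
    b, a = butter(2, cutoff, btype="low", fs=fs)
    return np.exp(filtfilt(b, a, log_energy))


def detect_s2(
    signal: BeamformedSignal,
    annotations: np.ndarray | None = None,
) -> np.ndarray:
    """S2 onset indices, strictly increasing.

    With ``annotations`` supplied the sidecar onsets are returned verbatim.
    Otherwise a simplified detector is used: homomorphic envelope ->
    peak picking (minimum inter-peak distance 0.2 s) -> pair consecutive
    peaks within a beat and label the second, lower-energy transient S2 ->
    reject solutions outside a 40-180 bpm rate.
    """
    if annotations is not None:
        out = np.asarray(annotations, dtype=int)
        if np.any(np.diff(out) <= 0):
            raise ValueError("annotation onsets must be strictly increasing")
        return out
    x = signal.samples
    fs = signal.sample_rate
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal to detect S2")
    env = _homomorphic_envelope(x, fs)
    floor = np.median(env)
    peaks, props = find_peaks(env, distance=int(0.2 * fs), height=floor * 1.2)
    if len(peaks) == 0:
        logger.warning("detect_s2: no envelope peaks found")
        return np.asarray([], dtype=int)
    heights = props["peak_heights"]

    # beat anchors: S1 transients dominate the envelope
    s1_mask = heights > 0.6 * np.percentile(heights, 90)
    s1_peaks = peaks[s1_mask]
    if len(s1_peaks) < 2:
        logger.warning("detect_s2: too few beat anchors")
        return np.asarray([], dtype=int)
    period = float(np.median(np.diff(s1_peaks)))
    if not (60.0 * fs / 180.0 <= period <= 60.0 * fs / 40.0):
        logger.warning("detect_s2: beat period outside 40-180 bpm; rejecting")
        return np.asarray([], dtype=int)

    # within each beat, S2 is the strongest remaining (lower-energy) transient
    # in the expected post-S1 region
    s2_centres = []
    for p1 in s1_peaks:
        lo, hi = p1 + int(0.15 * fs), p1 + int(0.65 * period)
        cand = [(h, p) for p, h in zip(peaks, heights) if lo <= p <= hi]
        if cand:
            s2_centres.append(max(cand)[1])
    s2_centres = np.asarray(sorted(set(s2_centres)), dtype=int)
    onsets = s2_centres - int(round(S2_NOMINAL_SECONDS / 2 * fs))
    onsets = onsets[onsets >= 0]
    if len(onsets) >= 2:
        rate = 60.0 * fs / np.median(np.diff(onsets))
        if not (40.0 <= rate <= 180.0):
            logger.warning("detect_s2: rate %.1f bpm outside 40-180; rejecting", rate)
            return np.asarray([], dtype=int)
    return onsets


def extract_diastolic_windows(
    signal: BeamformedSignal, s2_onsets: np.ndarray
) -> list[Segment]:
    """128 ms windows beginning 100 ms after each S2 onset.

    Windows that would run past the end of the signal are dropped.
    """
    fs = signal.sample_rate
    offset = int(round(DW_OFFSET_SECONDS * fs))
    length = int(round(DW_LENGTH_SECONDS * fs))
    n = len(signal.samples)
    segments = []
    for o in np.asarray(s2_onsets, dtype=int):
        start = o + offset
        if start < 0 or start + length > n:
            continue
        segments.append(
            Segment(
                samples=signal.samples[start : start + length].copy(),
                start_sample=int(start),
                kind="diastolic_window",
                subject_id=signal.subject_id,
                condition=signal.condition,
                sample_rate=fs,
            )
        )
    return segments
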