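"""Synthetic multichannel phonocardiogram fixtures with planted structure.

Generates 4-channel heart-sound recordings containing an S1/S2 transient
train at a configurable heart rate, optional band-limited diastolic "murmur"
noise planted only in the pre-treatment class, per-channel integer sample
delays and additive white noise — everything a downstream beamform /
segment / decompose / classify / attribute pipeline needs, with full ground
truth for oracle-style testing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "Recording",
    "generate_recording",
    "write_fixture_set",
    "read_manifest",
    "read_ground_truth",
]


@dataclass(frozen=True)
class SynthConfig:
    sample_rate: float = 4000.0
    duration: float = 15.0
    n_channels: int = 4
    heart_rate: float = 60.0          # beats per minute
    s1_s2_interval: float = 0.30      # seconds, S1 onset -> S2 onset
    murmur_band: tuple[float, float] = (150.0, 400.0)
    murmur_snr_db: float = 0.0        # murmur energy re: S1+S2 energy
    murmur_attenuation_db: float | None = None  # post-condition murmur level; None = absent
    channel_delays: tuple[int, ...] = (0, 3, -2, 5)
    noise_snr_db: float = 20.0
    seed: int = 0
    # transient morphology (free parameters; plausible PCG values)
    s1_freq: float = 35.0
    s2_freq: float = 55.0
    s1_duration: float = 0.090
    s2_duration: float = 0.070
    s2_rel_amplitude: float = 0.6
    # optional third heart sound, present in BOTH conditions: a
    # condition-independent diastolic structure (control for attribution)
    s3_rel_amplitude: float = 0.0
    s3_freq: float = 35.0
    s3_duration: float = 0.080
    s3_delay: float = 0.150  # seconds after the S2 onset

    def __post_init__(self):
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")
        lo, hi = self.murmur_band
        if not (0.0 < lo < hi < self.sample_rate / 2):
            raise ValueError("murmur_band must lie within (0, Nyquist)")
        if len(self.channel_delays) != self.n_channels:
            raise ValueError("channel_delays length must equal n_channels")
        n = int(round(self.duration * self.sample_rate))
        if any(abs(d) > 0.1 * n for d in self.channel_delays):
            raise ValueError("channel delay exceeds 10% of signal length")


@dataclass
class GroundTruth:
    s1_onsets: np.ndarray            # sample indices
    s2_onsets: np.ndarray
    murmur_support: list[tuple[int, int]]  # half-open [start, end) intervals
    condition: str                   # "pre" | "post"


@dataclass
class Recording:
    samples: np.ndarray              # (n_channels, n_samples) float
    sample_rate: float
    subject_id: str
    condition: str


def _transient(fs: float, freq: float, duration: float) -> np.ndarray:
    """Gaussian-windowed sinusoid; support = duration, peak at the centre."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    centre = duration / 2.0
    sigma = duration / 6.0
    return np.exp(-0.5 * ((t - centre) / sigma) ** 2) * np.sin(2 * np.pi * freq * (t - centre))


def generate_recording(config: SynthConfig, condition: str) -> tuple[Recording, GroundTruth]:
    """Deterministic synthetic recording plus full ground truth.

    The mono template carries S1/S2 trains; ``condition="pre"`` adds
    band-passed noise bursts (the murmur) inside every diastolic interval at
    ``murmur_snr_db`` relative to the total S1/S2 energy.  Each channel is
    the template shifted by its configured integer delay plus independent
    white noise at ``noise_snr_db``.
    """
    if condition not in ("pre", "post"):
        raise ValueError("condition must be 'pre' or 'post'")
    fs = config.sample_rate
    n = int(round(config.duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0 if condition == "pre" else 1]))

    period = 60.0 / config.heart_rate
    s1 = _transient(fs, config.s1_freq, config.s1_duration)
    s2 = config.s2_rel_amplitude * _transient(fs, config.s2_freq, config.s2_duration)

    template = np.zeros(n)
    s1_onsets, s2_onsets = [], []
    beat = 0
    while True:
        t1 = int(round(beat * period * fs))
        if t1 >= n:
            break
        if t1 + len(s1) <= n:
            template[t1 : t1 + len(s1)] += s1
            s1_onsets.append(t1)
        t2 = int(round((beat * period + config.s1_s2_interval) * fs))
        if t2 + len(s2) <= n:
            template[t2 : t2 + len(s2)] += s2
            s2_onsets.append(t2)
        beat += 1
    s1_onsets = np.asarray(s1_onsets, dtype=int)
    s2_onsets = np.asarray(s2_onsets, dtype=int)
    if config.s3_rel_amplitude > 0:
        s3 = config.s3_rel_amplitude * _transient(fs, config.s3_freq, config.s3_duration)
        for t2 in s2_onsets:
            t3 = t2 + int(round(config.s3_delay * fs))
            if t3 + len(s3) <= n:
                template[t3 : t3 + len(s3)] += s3
    heart_energy = float(template @ template)

    # diastolic intervals: end of S2 transient -> next S1 onset (small guard)
    guard = int(round(0.020 * fs))
    intervals = []
    for t2 in s2_onsets:
        start = t2 + len(s2)
        nxt = s1_onsets[s1_onsets > t2]
        end = int(nxt[0]) - guard if len(nxt) else n
        if end - start > int(0.05 * fs):
            intervals.append((int(start), int(end)))

    murmur_db = None
    if condition == "pre":
        murmur_db = config.murmur_snr_db
    elif config.murmur_attenuation_db is not None:
        murmur_db = config.murmur_snr_db - config.murmur_attenuation_db

    murmur_support: list[tuple[int, int]] = []
    if murmur_db is not None and intervals:
        sos = butter(4, config.murmur_band, btype="bandpass", fs=fs, output="sos")
        murmur = np.zeros(n)
        for start, end in intervals:
            burst = sosfiltfilt(sos, rng.standard_normal(end - start))
            ramp = min(int(0.010 * fs), (end - start) // 4)
            window = np.ones(end - start)
            window[:ramp] = np.linspace(0, 1, ramp)
            window[-ramp:] = np.linspace(1, 0, ramp)
            murmur[start:end] = burst * window
        m_energy = float(murmur @ murmur)
        if m_energy > 0:
            murmur *= np.sqrt(heart_energy / m_energy) * 10.0 ** (murmur_db / 20.0)
            template = template + murmur
            murmur_support = intervals

    clean_power = float(template @ template) / n
    noise_sigma = np.sqrt(clean_power) * 10.0 ** (-config.noise_snr_db / 20.0)

    channels = np.zeros((config.n_channels, n))
    for ch, delay in enumerate(config.channel_delays):
        shifted = np.zeros(n)
        if delay >= 0:
            shifted[delay:] = template[: n - delay]
        else:
            shifted[: n + delay] = template[-delay:]
        channels[ch] = shifted + noise_sigma * rng.standard_normal(n)

    rec = Recording(samples=channels, sample_rate=fs, subject_id="synthetic", condition=condition)
    truth = GroundTruth(
        s1_onsets=s1_onsets,
        s2_onsets=s2_onsets,
        murmur_support=murmur_support,
        condition=condition,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Fixture sets on disk
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "condition", "wav_path", "truth_path"]


def write_fixture_set(
    config: SynthConfig, n_subjects: int, out_dir: str, force: bool = False
) -> pd.DataFrame:
    """Write ``2 * n_subjects`` multichannel WAVs plus sidecars and a manifest.

    Subject sub-seeds derive deterministically from ``config.seed`` so the
    whole set is reproducible bit-for-bit.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    if os.path.exists(manifest_path) and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")

    sub_seeds = [int(ss.generate_state(1)[0]) for ss in np.random.SeedSequence(config.seed).spawn(n_subjects)]
    rows = []
    for i, sub_seed in enumerate(sub_seeds):
        subject_id = f"S{i + 1:02d}"
        cfg = replace(config, seed=sub_seed)
        for condition in ("pre", "post"):
            rec, truth = generate_recording(cfg, condition)
            wav_path = os.path.join(out_dir, f"{subject_id}_{condition}.wav")
            truth_path = os.path.join(out_dir, f"{subject_id}_{condition}_truth.csv")
            _write_wav(wav_path, rec)
            _write_truth(truth_path, truth)
            rows.append(
                {
                    "subject_id": subject_id,
                    "condition": condition,
                    "wav_path": os.path.basename(wav_path),
                    "truth_path": os.path.basename(truth_path),
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def _write_wav(path: str, rec: Recording) -> None:
    peak = np.max(np.abs(rec.samples))
    scaled = rec.samples / peak * 0.9 if peak > 0 else rec.samples
    pcm = np.round(scaled * 32767.0).astype(np.int16)
    wavfile.write(path, int(rec.sample_rate), pcm.T.copy())  # frames x channels


def _write_truth(path: str, truth: GroundTruth) -> None:
    rows = [("s1_onset", int(o), int(o)) for o in truth.s1_onsets]
    rows += [("s2_onset", int(o), int(o)) for o in truth.s2_onsets]
    rows += [("murmur", int(a), int(b)) for a, b in truth.murmur_support]
    pd.DataFrame(rows, columns=["event_type", "start_sample", "end_sample"]).to_csv(path, index=False)


def read_manifest(out_dir: str) -> pd.DataFrame:
    return pd.read_csv(os.path.join(out_dir, "manifest.csv"))


def read_ground_truth(path: str) -> GroundTruth:
    df = pd.read_csv(path)
    return GroundTruth(
        s1_onsets=df.loc[df.event_type == "s1_onset", "start_sample"].to_numpy(dtype=int),
        s2_onsets=df.loc[df.event_type == "s2_onset", "start_sample"].to_numpy(dtype=int),
        murmur_support=[
            (int(a), int(b))
            for a, b in df.loc[df.event_type == "murmur", ["start_sample", "end_sample"]].itertuples(index=False)
        ],
        condition="unknown",
    )


def read_recording(wav_path: str, subject_id: str, condition: str) -> Recording:
    """Load a multichannel fixture WAV back into a float Recording."""
    fs, data = wavfile.read(wav_path)
    if data.ndim == 1:
        data = data[:, None]
    samples = data.T.astype(np.float64) / 32767.0
    return Recording(samples=samples, sample_rate=float(fs), subject_id=subject_id, condition=condition)
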