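"""Per-atom feature computation and scaling for the set classifier.

Each atom contributes a fixed-order feature row: scaled coefficient
magnitude, phase decomposed into sine/cosine, min-max scaled frequency and
octave, four atomic-influence counts, and an integer-encoded patient ID.
Phase is split into two columns, so the nine per-atom features occupy ten
columns; see ``FEATURE_COLUMNS``.

Atomic influence counts temporally overlapping atoms — two atoms overlap
when their centres are closer than the mean of their envelope scales — split
by extraction order (given/received) and by relative octave (lower/higher).
This injects relative temporal structure while absolute translation stays
out of the feature set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .mp import Decomposition

__all__ = [
    "FEATURE_COLUMNS",
    "SampleRecord",
    "FeatureScaler",
    "influence_features",
    "raw_features",
    "assemble_samples",
]

logger = logging.getLogger(__name__)

#: fixed column order of the per-atom feature matrix (phase occupies two
#: columns, so 9 features -> 10 columns)
FEATURE_COLUMNS = (
    "coefficient_magnitude",
    "phase_sin",
    "phase_cos",
    "frequency",
    "octave",
    "influence_given",
    "influence_received",
    "low_octave_influence",
    "high_octave_influence",
    "patient_id",
)

FREQ_BOUNDS = (0.0, 1000.0)   # Hz, fixed min-max bounds
OCTAVE_BOUNDS = (2.0, 12.0)   # fixed min-max bounds

LABELS = {"pre": 0, "post": 1}


@dataclass
class SampleRecord:
    """One classification sample: the feature rows of one segment's atoms."""

    features: np.ndarray      # (n_atoms, len(FEATURE_COLUMNS))
    label: int                # pre=0, post=1
    subject_id: str
    segment_ref: dict = field(default_factory=dict)


def influence_features(decomposition: Decomposition) -> np.ndarray:
    """(n, 4) integer array: given, received, low-octave, high-octave counts.

    Atoms a, b overlap iff ``|u_a - u_b| < (2**j_a + 2**j_b) / 2``; all
    counts exclude the atom itself.
    """
    atoms = decomposition.atoms
    n = len(atoms)
    out = np.zeros((n, 4), dtype=np.int64)
    if n == 0:
        return out
    u = np.array([a.translation for a in atoms], dtype=np.float64)
    j = np.array([a.octave for a in atoms], dtype=np.float64)
    it = np.array([a.iteration for a in atoms], dtype=np.int64)
    scale = 2.0**j
    overlap = np.abs(u[:, None] - u[None, :]) < (scale[:, None] + scale[None, :]) / 2.0
    np.fill_diagonal(overlap, False)
    out[:, 0] = np.sum(overlap & (it[None, :] > it[:, None]), axis=1)  # given
    out[:, 1] = np.sum(overlap & (it[None, :] < it[:, None]), axis=1)  # received
    out[:, 2] = np.sum(overlap & (j[None, :] < j[:, None]), axis=1)    # low octave
    out[:, 3] = np.sum(overlap & (j[None, :] > j[:, None]), axis=1)    # high octave
    return out


def raw_features(decomposition: Decomposition) -> np.ndarray:
    """Unscaled per-atom rows: magnitude, phase, frequency, octave + influence."""
    atoms = decomposition.atoms
    out = np.zeros((len(atoms), 8))
    for i, a in enumerate(atoms):
        out[i, :4] = (a.coefficient_magnitude, a.phase, a.frequency, a.octave)
    out[:, 4:8] = influence_features(decomposition)
    return out


class FeatureScaler:
    """Applies the fixed per-column scalings; magnitude moments are fitted.

    magnitude -> (x - mean) / std with moments from the fit corpus (training
    split only); frequency -> x / 1000; octave -> (j - 2) / 10; phase ->
    (sin, cos); influence counts pass through; patient IDs map through a
    persisted label table that rejects unseen IDs at transform time.
    """

    def __init__(self) -> None:
        self.magnitude_mean: float | None = None
        self.magnitude_std: float | None = None
        self.patient_codes: dict[str, int] = {}

    # -- fitting ----------------------------------------------------------
    def fit(self, raw_rows: np.ndarray, patient_ids: list[str]) -> "FeatureScaler":
        mags = np.asarray(raw_rows)[:, 0]
        self.magnitude_mean = float(np.mean(mags))
        std = float(np.std(mags))
        self.magnitude_std = std if std > 0 else 1.0
        for pid in patient_ids:
            if pid not in self.patient_codes:
                self.patient_codes[pid] = len(self.patient_codes)
        return self

    # -- transform --------------------------------------------------------
    def transform(self, raw_rows: np.ndarray, patient_id: str) -> np.ndarray:
        if self.magnitude_mean is None:
            raise RuntimeError("scaler not fitted")
        if patient_id not in self.patient_codes:
            raise KeyError(f"unseen patient ID {patient_id!r} at transform time")
        raw = np.asarray(raw_rows, dtype=np.float64)
        out = np.zeros((raw.shape[0], len(FEATURE_COLUMNS)))
        out[:, 0] = (raw[:, 0] - self.magnitude_mean) / self.magnitude_std
        out[:, 1] = np.sin(raw[:, 1])
        out[:, 2] = np.cos(raw[:, 1])
        out[:, 3] = (raw[:, 2] - FREQ_BOUNDS[0]) / (FREQ_BOUNDS[1] - FREQ_BOUNDS[0])
        out[:, 4] = (raw[:, 3] - OCTAVE_BOUNDS[0]) / (OCTAVE_BOUNDS[1] - OCTAVE_BOUNDS[0])
        out[:, 5:9] = raw[:, 4:8]
        out[:, 9] = self.patient_codes[patient_id]
        return out

    def inverse_magnitude(self, scaled: np.ndarray) -> np.ndarray:
        return scaled * self.magnitude_std + self.magnitude_mean

    # -- persistence ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "magnitude_mean": self.magnitude_mean,
                "magnitude_std": self.magnitude_std,
                "patient_codes": self.patient_codes,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureScaler":
        data = json.loads(text)
        scaler = cls()
        scaler.magnitude_mean = data["magnitude_mean"]
        scaler.magnitude_std = data["magnitude_std"]
        scaler.patient_codes = dict(data["patient_codes"])
        return scaler


def assemble_samples(
    decompositions: list[Decomposition],
    scaler: FeatureScaler,
    ablate_patient_id: bool = False,
) -> list[SampleRecord]:
    """One SampleRecord per decomposition, in input order.

    Decompositions must carry ``subject_id`` and ``condition`` provenance.
    Zero-atom decompositions are skipped with a warning.
    """
    samples = []
    for dec in decompositions:
        if len(dec.atoms) == 0:
            logger.warning("skipping zero-atom decomposition %s", dec.segment_ref)
            continue
        subject = dec.segment_ref.get("subject_id")
        condition = dec.segment_ref.get("condition")
        if subject is None or condition not in LABELS:
            raise ValueError(f"decomposition lacks subject/condition provenance: {dec.segment_ref}")
        feats = scaler.transform(raw_features(dec), subject)
        if ablate_patient_id:
            feats = feats[:, :9]
        samples.append(
            SampleRecord(
                features=feats,
                label=LABELS[condition],
                subject_id=subject,
                segment_ref=dict(dec.segment_ref),
            )
        )
    return samples
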