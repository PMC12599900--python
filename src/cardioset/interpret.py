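"""Latent extraction, embedding, clustering, selective reconstruction and
band-power change attribution.

The best classifier's atom-encoder output is collected for every atom in the
dataset, embedded to 2-D with UMAP (cohort-wide or per subject), and
clustered with DBSCAN (eps 0.5, min 5 points).  Each cluster's atoms are
selectively reconstructed back into the recording timeline per condition
(overlap-add, halving doubly covered regions), smoothed with a Gaussian
kernel (sigma = 5 samples) and band-passed 65-400 Hz with a zero-phase
5th-order Butterworth filter.  Cluster-level change is quantified as mean
cardiac-cycle power and as STFT power deltas in eight 50 Hz bands from 0 to
400 Hz, with clusters grouped by whether 0-150 Hz power monotonically
increases or decreases within a +/-1e-6 tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, sosfiltfilt, welch
from sklearn.cluster import DBSCAN

from .features import SampleRecord
from .model import DeepSetsClassifier, pack_batch
from .mp import Decomposition, reconstruct

__all__ = [
    "BAND_EDGES",
    "extract_latents",
    "embed_latents",
    "cluster_atoms",
    "cluster_reconstruction",
    "cycle_power",
    "band_power_change",
    "band_powers",
    "group_clusters",
    "smooth_and_filter",
]

logger = logging.getLogger(__name__)

BAND_EDGES = tuple(np.arange(0, 401, 50))  # 0, 50, ..., 400 Hz
GAUSSIAN_SIGMA = 5.0        # samples
BUTTER_ORDER = 5
BUTTER_BAND = (65.0, 400.0)  # Hz
GROUP_TOLERANCE = 1e-6
STFT_NPERSEG = 256
STFT_HOP = 128
DBSCAN_EPS = 0.5
DBSCAN_MIN_POINTS = 5


def extract_latents(
    model: DeepSetsClassifier, samples: list[SampleRecord]
) -> tuple[np.ndarray, pd.DataFrame]:
    """Atom-encoder outputs for every atom, with provenance.

    Returns (latents (n_atoms_total, latent_dim), provenance frame with
    sample_index, atom_index, subject_id, condition, segment_kind,
    segment_start columns).
    """
    if samples and samples[0].features.shape[1] != model.config.input_dim:
        raise ValueError(
            f"feature dimension {samples[0].features.shape[1]} does not match "
            f"model input_dim {model.config.input_dim}"
        )
    flat, offsets = pack_batch([s.features for s in samples])
    _, latents = model.forward(flat, offsets, train=False)
    rows = []
    for i, s in enumerate(samples):
        for a in range(len(s.features)):
            rows.append(
                {
                    "sample_index": i,
                    "atom_index": a,
                    "subject_id": s.subject_id,
                    "condition": "pre" if s.label == 0 else "post",
                    "segment_kind": s.segment_ref.get("kind"),
                    "segment_start": s.segment_ref.get("start_sample"),
                }
            )
    return latents, pd.DataFrame(rows)


def embed_latents(
    latents: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 15,
    scope: str = "cohort",
    subject_ids: np.ndarray | None = None,
) -> np.ndarray:
    """2-D UMAP embedding; ``scope="per_subject"`` embeds each subject alone."""
    import umap  # deferred: numba compilation is slow at import time

    latents = np.asarray(latents, dtype=np.float64)
    if len(latents) < 10:
        raise ValueError("need at least 10 latents to embed")
    if scope == "per_subject":
        if subject_ids is None:
            raise ValueError("per_subject scope requires subject_ids")
        out = np.zeros((len(latents), 2))
        for subject in np.unique(subject_ids):
            mask = subject_ids == subject
            out[mask] = embed_latents(latents[mask], seed=seed, n_neighbors=n_neighbors)
        return out
    if scope != "cohort":
        raise ValueError(f"unknown scope {scope!r}")
    k = n_neighbors
    if len(latents) <= k:
        k = max(2, len(latents) - 1)
        logger.warning("reducing n_neighbors to %d for %d points", k, len(latents))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=k, random_state=seed, n_jobs=1)
        return np.asarray(reducer.fit_transform(latents), dtype=np.float64)


def cluster_atoms(
    embedding: np.ndarray, eps: float = DBSCAN_EPS, min_points: int = DBSCAN_MIN_POINTS
) -> np.ndarray:
    """DBSCAN labels renumbered 0..K-1 by descending cluster size; noise = -1."""
    raw = DBSCAN(eps=eps, min_samples=min_points).fit_predict(np.asarray(embedding))
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[x] if x >= 0 else -1 for x in raw], dtype=int)


def smooth_and_filter(
    signal: np.ndarray,
    fs: float,
    sigma: float = GAUSSIAN_SIGMA,
    band: tuple[float, float] = BUTTER_BAND,
    order: int = BUTTER_ORDER,
) -> np.ndarray:
    """Gaussian smoothing then zero-phase Butterworth band-pass."""
    signal = np.asarray(signal, dtype=np.float64)
    smoothed = gaussian_filter1d(signal, sigma) if sigma > 0 else signal
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, smoothed)


def cluster_reconstruction(
    decompositions: list[Decomposition],
    atom_cluster_ids: np.ndarray,
    signal_length: int,
    fs: float = 4000.0,
    apply_filter: bool = True,
) -> dict[int, dict[str, np.ndarray]]:
    """Per-cluster, per-condition reconstructions on the recording timeline.

    ``atom_cluster_ids`` aligns with atoms flattened over ``decompositions``
    in order.  Each segment's cluster atoms are summed into the timeline at
    the segment's start with weight 1/coverage, so 50%-overlap regions are
    not double-counted.  Returns ``{cluster_id: {"pre": ..., "post": ...,
    "pre_raw": ..., "post_raw": ...}}`` (raw = before smoothing/filtering).
    """
    atom_cluster_ids = np.asarray(atom_cluster_ids, dtype=int)
    counts = [len(d.atoms) for d in decompositions]
    if sum(counts) != len(atom_cluster_ids):
        raise ValueError("cluster id array does not align with decompositions")
    offsets = np.concatenate([[0], np.cumsum(counts)])

    # coverage per condition over the timeline
    coverage = {c: np.zeros(signal_length) for c in ("pre", "post")}
    for dec in decompositions:
        cond = dec.segment_ref["condition"]
        start = int(dec.segment_ref["start_sample"])
        coverage[cond][start : start + dec.segment_length] += 1.0
    weight = {c: np.where(cov > 0, 1.0 / np.maximum(cov, 1.0), 0.0) for c, cov in coverage.items()}

    cluster_ids = sorted(set(atom_cluster_ids.tolist()))
    out: dict[int, dict[str, np.ndarray]] = {
        cid: {"pre_raw": np.zeros(signal_length), "post_raw": np.zeros(signal_length)}
        for cid in cluster_ids
    }
    for di, dec in enumerate(decompositions):
        cond = dec.segment_ref["condition"]
        start = int(dec.segment_ref["start_sample"])
        ids_here = atom_cluster_ids[offsets[di] : offsets[di + 1]]
        for cid in np.unique(ids_here):
            subset = np.flatnonzero(ids_here == cid)
            seg = reconstruct(dec, subset)
            out[int(cid)][f"{cond}_raw"][start : start + dec.segment_length] += seg
    for cid in cluster_ids:
        for cond in ("pre", "post"):
            out[cid][f"{cond}_raw"] *= weight[cond]
            if not np.any(out[cid][f"{cond}_raw"]):
                logger.warning("cluster %s has empty %s reconstruction", cid, cond)
            if apply_filter:
                out[cid][cond] = smooth_and_filter(out[cid][f"{cond}_raw"], fs)
            else:
                out[cid][cond] = out[cid][f"{cond}_raw"].copy()
    return out


def cycle_power(signal: np.ndarray, diastole_starts: np.ndarray) -> tuple[float, float]:
    """Mean and standard error of per-cycle mean squared amplitude.

    Cycles run diastole start to diastole start; needs at least 2 starts.
    """
    starts = np.asarray(diastole_starts, dtype=int)
    if len(starts) < 2:
        raise ValueError("need at least 2 diastole starts")
    powers = []
    for a, b in zip(starts[:-1], starts[1:]):
        cyc = signal[a:b]
        powers.append(float(np.mean(cyc**2)))
    powers = np.asarray(powers)
    return float(powers.mean()), float(powers.std(ddof=1) / np.sqrt(len(powers))) if len(powers) > 1 else 0.0


def band_powers(
    signal: np.ndarray,
    fs: float,
    edges: tuple = BAND_EDGES,
    nperseg: int = STFT_NPERSEG,
    hop: int = STFT_HOP,
) -> np.ndarray:
    """Mean STFT power in each band (Hann window, averaged over frames).

    Computed as the frame-averaged periodogram (Welch with detrending off),
    integrated over each band's bins; the top band includes its upper edge.
    """
    freqs, psd = welch(
        np.asarray(signal, dtype=np.float64),
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - hop,
        detrend=False,
        scaling="density",
    )
    df = freqs[1] - freqs[0]
    out = np.zeros(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        if i == len(edges) - 2:
            mask = (freqs >= lo) & (freqs <= hi)
        else:
            mask = (freqs >= lo) & (freqs < hi)
        out[i] = float(psd[mask].sum() * df)
    return out


def band_power_change(pre: np.ndarray, post: np.ndarray, fs: float = 4000.0) -> np.ndarray:
    """Eight per-band deltas (post minus pre) over 0-400 Hz in 50 Hz bands."""
    return band_powers(post, fs) - band_powers(pre, fs)


def group_clusters(band_deltas: np.ndarray, tolerance: float = GROUP_TOLERANCE) -> str:
    """Label a cluster by its 0-50, 50-100, 100-150 Hz deltas.

    increase: all three above -tolerance with at least one above +tolerance;
    decrease: mirror image; everything else (including all-within-tolerance)
    is mixed.
    """
    d = np.asarray(band_deltas, dtype=np.float64)[:3]
    if np.all(d > -tolerance) and np.any(d > tolerance):
        return "increase"
    if np.all(d < tolerance) and np.any(d < -tolerance):
        return "decrease"
    return "mixed"


def cluster_report(
    reconstructions: dict[int, dict[str, np.ndarray]],
    diastole_starts: dict[str, np.ndarray],
    fs: float = 4000.0,
    tolerance: float = GROUP_TOLERANCE,
) -> pd.DataFrame:
    """One row per cluster: cycle power (pre/post, with SE), eight band
    deltas and the monotonic group label."""
    rows = []
    for cid in sorted(reconstructions):
        rec = reconstructions[cid]
        pre_p, pre_se = cycle_power(rec["pre"], diastole_starts["pre"])
        post_p, post_se = cycle_power(rec["post"], diastole_starts["post"])
        deltas = band_power_change(rec["pre"], rec["post"], fs)
        row = {
            "cluster_id": cid,
            "cycle_power_pre": pre_p,
            "cycle_power_pre_se": pre_se,
            "cycle_power_post": post_p,
            "cycle_power_post_se": post_se,
            "group": group_clusters(deltas, tolerance),
        }
        for i, (lo, hi) in enumerate(zip(BAND_EDGES[:-1], BAND_EDGES[1:])):
            row[f"delta_{lo}_{hi}"] = float(deltas[i])
        rows.append(row)
    return pd.DataFrame(rows)
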