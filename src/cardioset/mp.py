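"""Gabor dictionary matching pursuit with an FFT-accelerated atom search.

A segment is greedily decomposed into Gabor atoms

    g(t) = K * exp(-pi ((t - u) / s)^2) * cos(2 pi f (t - u) / fs + phi)

with dyadic scale ``s = 2**octave``, frequency ``f`` on a per-octave grid
``k * fs / s``, integer translation ``u`` and a per-candidate analytically
optimal phase.  ``K`` normalises the atom to unit L2 norm after truncating
the envelope to ``|t - u| <= 4 s`` and to the segment support.

Per iteration every (octave, frequency, translation) candidate is scored by
the exact energy of the residual's orthogonal projection onto the 2-D span
of the envelope-windowed cosine and sine, so the FFT path is numerically
equivalent to exhaustively enumerating the dictionary (``method="exhaustive"``
does exactly that and exists as an oracle for small inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GaborAtom",
    "Decomposition",
    "DictionarySpec",
    "atom_waveform",
    "build_dictionary",
    "decompose",
    "reconstruct",
]

#: envelope support half-width in units of the scale s
ENVELOPE_RADIUS = 4

#: residual energy fraction below which the greedy loop stops early
EARLY_STOP_FRACTION = 1e-12

_DEGENERATE_DET = 1e-10


@dataclass(frozen=True)
class GaborAtom:
    """One extracted dictionary element."""

    octave: int
    frequency: float          # Hz
    translation: int          # centre sample u, 0-based within the segment
    phase: float              # radians in (-pi, pi]
    coefficient_magnitude: float
    iteration: int


@dataclass
class Decomposition:
    """Ordered greedy decomposition of one segment."""

    atoms: list[GaborAtom]
    residual_energy: float
    segment_length: int
    sample_rate: float
    segment_ref: dict = field(default_factory=dict)
    residual_energies: list[float] = field(default_factory=list)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.atoms)


@dataclass(frozen=True)
class DictionarySpec:
    """Implicit parameter grid of the Gabor dictionary.

    Translations are every integer sample in ``[0, length)`` and are searched
    implicitly via FFT correlation; they are never enumerated here.
    """

    length: int
    sample_rate: float
    octaves: tuple[int, ...]
    #: per octave, the modulation indices k such that f = k * fs / 2**j <= cap
    k_indices: dict[int, np.ndarray]
    freq_cap: float

    def frequencies(self, octave: int) -> np.ndarray:
        """Frequency grid (Hz) for one octave."""
        return self.k_indices[octave] * self.sample_rate / 2.0**octave


def atom_waveform(
    octave: int,
    frequency: float,
    translation: int,
    phase: float,
    length: int,
    sample_rate: float = 4000.0,
) -> np.ndarray:
    """Unit-norm real Gabor atom sampled on ``[0, length)``.

    Raises
    ------
    ValueError
        If the truncated waveform has (near-)zero norm, i.e. the translation
        places the envelope entirely outside the segment.
    """
    s = 2.0**octave
    t = np.arange(length, dtype=np.float64)
    tau = t - translation
    g = np.zeros(length)
    mask = np.abs(tau) <= ENVELOPE_RADIUS * s
    g[mask] = np.exp(-np.pi * (tau[mask] / s) ** 2) * np.cos(
        2.0 * np.pi * frequency * tau[mask] / sample_rate + phase
    )
    norm = np.linalg.norm(g)
    if norm < 1e-300:
        raise ValueError(
            f"atom (octave={octave}, f={frequency}, u={translation}, phi={phase}) "
            "has zero norm after truncation to the segment"
        )
    return g / norm


def build_dictionary(
    length: int,
    octave_range: tuple[int, int] = (2, 12),
    freq_cap: float = 1000.0,
    sample_rate: float = 4000.0,
) -> DictionarySpec:
    """Describe the implicit Gabor grid for a segment length.

    Octaves are clipped to ``[2, floor(log2(length))]``; for each octave j the
    frequencies are ``k * fs / 2**j`` for every integer k with frequency at or
    below ``freq_cap`` (and below Nyquist).
    """
    if length < 4:
        raise ValueError("segment too short for any dictionary octave")
    j_lo = max(2, octave_range[0])
    j_hi = min(octave_range[1], int(np.floor(np.log2(length))))
    if j_hi < j_lo:
        raise ValueError(
            f"octave range {octave_range} empty after clipping to segment length {length}"
        )
    octaves = tuple(range(j_lo, j_hi + 1))
    k_indices: dict[int, np.ndarray] = {}
    for j in octaves:
        s = 2**j
        k_max = int(np.floor(freq_cap * s / sample_rate + 1e-9))
        k_max = min(k_max, s // 2)  # stay at or below Nyquist
        k_indices[j] = np.arange(k_max + 1)
    return DictionarySpec(
        length=length,
        sample_rate=float(sample_rate),
        octaves=octaves,
        k_indices=k_indices,
        freq_cap=float(freq_cap),
    )


# ---------------------------------------------------------------------------
# FFT search internals
# ---------------------------------------------------------------------------

# Gram-matrix terms depend only on (length, octave), not on the signal:
# cache them across segments and iterations.
_gram_cache: dict[tuple[int, int, int], tuple] = {}

# chunk rows so the (chunk, 8s) sliding-window workspace stays under ~256 MB
_CHUNK_BYTES = 256 * 2**20


def _envelope(j: int) -> np.ndarray:
    """Envelope sampled on tau in [-4s, 4s) — 8s points, divisible by s."""
    s = 2**j
    tau = np.arange(-ENVELOPE_RADIUS * s, ENVELOPE_RADIUS * s, dtype=np.float64)
    return np.exp(-np.pi * (tau / s) ** 2)


def _folded_spectrum(x_padded: np.ndarray, kernel: np.ndarray, n: int, s: int) -> np.ndarray:
    """rfft over tau (period s) of kernel(tau) * x(u + tau) for all u in [0, n).

    ``x_padded`` has 4s zeros on each side of the length-n signal.  Returns a
    complex array of shape (n, s // 2 + 1) holding
    ``sum_tau kernel(tau) x(u+tau) exp(-2i pi k tau / s)``.
    """
    width = len(kernel)          # 8 s
    folds = width // s
    out = np.empty((n, s // 2 + 1), dtype=np.complex128)
    windows = sliding_window_view(x_padded, s)
    chunk = max(1, _CHUNK_BYTES // (s * 8 * 3))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        folded = np.zeros((hi - lo, s))
        for p in range(folds):
            # fold p contributes kernel[p*s:(p+1)*s] * x[u + m + p*s - 4s]
            folded += windows[lo + p * s : hi + p * s] * kernel[p * s : (p + 1) * s]
        out[lo:hi] = np.fft.rfft(folded, axis=1)
    return out


def _gram_terms(n: int, j: int, n_freq: int) -> tuple:
    """Per-translation Gram entries (Gcc, Gss, Gcs) for one octave.

    Shapes are (n, n_freq).  Depends only on geometry (envelope truncated to
    the segment), so results are cached on (n, j, n_freq).
    """
    key = (n, j, n_freq)
    if key in _gram_cache:
        return _gram_cache[key]
    s = 2**j
    env2 = _envelope(j) ** 2
    ind = np.zeros(n + 2 * ENVELOPE_RADIUS * s)
    ind[ENVELOPE_RADIUS * s : ENVELOPE_RADIUS * s + n] = 1.0
    spec = _folded_spectrum(ind, env2, n, s)  # bins 0 .. s/2
    e = spec[:, 0].real  # sum env^2 over the segment support
    # B(u, k) = sum env^2 ind exp(+2i omega tau) -> conj of rfft bin 2k
    ks = np.arange(n_freq)
    two_k = 2 * ks
    half = s // 2
    b = np.empty((n, n_freq), dtype=np.complex128)
    low = two_k <= half
    b[:, low] = np.conj(spec[:, two_k[low]])
    if not low.all():  # bins above Nyquist via conjugate symmetry
        b[:, ~low] = spec[:, s - two_k[~low]]
    gcc = 0.5 * (e[:, None] + b.real)
    gss = 0.5 * (e[:, None] - b.real)
    gcs = 0.5 * b.imag
    _gram_cache[key] = (gcc, gss, gcs)
    return _gram_cache[key]


def _octave_scores(residual: np.ndarray, j: int, ks: np.ndarray) -> tuple:
    """Projection energies and correlation components for one octave.

    Returns (p2, x, y, gram) where p2[u, k] is the squared magnitude of the
    orthogonal projection of the residual onto span(cos, sin) at translation u
    and modulation index ks[k].
    """
    n = len(residual)
    s = 2**j
    n_freq = len(ks)
    pad = np.zeros(n + 2 * ENVELOPE_RADIUS * s)
    pad[ENVELOPE_RADIUS * s : ENVELOPE_RADIUS * s + n] = residual
    spec = _folded_spectrum(pad, _envelope(j), n, s)
    # modulation indices are a contiguous range; basic slicing avoids a gather
    a = np.conj(spec[:, : len(ks)])  # sum r env exp(+i omega tau)
    x = a.real  # <r, env cos>
    y = a.imag  # <r, env sin>
    gcc, gss, gcs = _gram_terms(n, j, n_freq)
    det = gcc * gss - gcs * gcs
    degenerate = det <= _DEGENERATE_DET * np.maximum(gcc * gcc, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        p2 = (gss * x * x - 2.0 * gcs * x * y + gcc * y * y) / det
        p2_1d = x * x / gcc
    p2 = np.where(degenerate, p2_1d, p2)
    p2 = np.where(gcc <= 0, 0.0, p2)
    return p2, x, y, (gcc, gss, gcs, det, degenerate)


def _best_candidate_fft(residual: np.ndarray, dictionary: DictionarySpec):
    """Arg-max candidate over the whole grid, ties broken by (j, k, u)."""
    best = None  # (p2, j, k, u, phi)
    for j in dictionary.octaves:
        ks = dictionary.k_indices[j]
        p2, x, y, gram = _octave_scores(residual, j, ks)
        # transpose -> flat argmax scans (k, u) in lexical order, matching the
        # "lower frequency, earlier translation" tie-break
        flat = np.argmax(p2.T)
        ki, u = divmod(flat, p2.shape[0])
        val = p2[u, ki]
        if best is None or val > best[0]:
            phi = _optimal_phase(x[u, ki], y[u, ki], gram, u, ki)
            best = (val, j, int(ks[ki]), int(u), phi)
    return best


def _optimal_phase(x: float, y: float, gram, u: int, ki: int) -> float:
    gcc, gss, gcs, det, degenerate = gram
    if degenerate[u, ki]:
        return 0.0 if x >= 0 else np.pi
    d = det[u, ki]
    xp = (gss[u, ki] * x - gcs[u, ki] * y) / d
    yp = (gcc[u, ki] * y - gcs[u, ki] * x) / d
    return float(np.arctan2(-yp, xp))


# ---------------------------------------------------------------------------
# Exhaustive search oracle (small inputs only)
# ---------------------------------------------------------------------------


def _best_candidate_exhaustive(residual: np.ndarray, dictionary: DictionarySpec):
    n = len(residual)
    fs = dictionary.sample_rate
    t = np.arange(n, dtype=np.float64)
    best = None
    for j in dictionary.octaves:
        s = 2.0**j
        for k in dictionary.k_indices[j]:
            omega = 2.0 * np.pi * k / 2.0**j  # radians per sample
            for u in range(n):
                tau = t - u
                mask = np.abs(tau) <= ENVELOPE_RADIUS * s
                env = np.where(mask, np.exp(-np.pi * (tau / s) ** 2), 0.0)
                c = env * np.cos(omega * tau)
                sv = env * np.sin(omega * tau)
                x = float(residual @ c)
                y = float(residual @ sv)
                gcc = float(c @ c)
                gss = float(sv @ sv)
                gcs = float(c @ sv)
                det = gcc * gss - gcs * gcs
                if det <= _DEGENERATE_DET * max(gcc * gcc, 1e-300):
                    if gcc <= 0:
                        continue
                    p2 = x * x / gcc
                    phi = 0.0 if x >= 0 else np.pi
                else:
                    p2 = (gss * x * x - 2.0 * gcs * x * y + gcc * y * y) / det
                    xp = (gss * x - gcs * y) / det
                    yp = (gcc * y - gcs * x) / det
                    phi = float(np.arctan2(-yp, xp))
                if best is None or p2 > best[0]:
                    best = (p2, j, int(k), int(u), phi)
    return best


# ---------------------------------------------------------------------------
# Greedy loop
# ---------------------------------------------------------------------------


def decompose(
    segment,
    n_atoms: int = 100,
    dictionary: DictionarySpec | None = None,
    octave_range: tuple[int, int] = (2, 12),
    freq_cap: float = 1000.0,
    sample_rate: float | None = None,
    method: str = "fft",
    segment_ref: dict | None = None,
) -> Decomposition:
    """Greedy matching pursuit of a segment into up to ``n_atoms`` Gabor atoms.

    ``segment`` may be a 1-D array or any object with ``samples`` (and
    optionally ``sample_rate``/provenance) attributes.  Stops early once the
    residual energy falls below ``1e-12`` of the original energy.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    samples, fs, ref = _coerce_segment(segment, sample_rate)
    if segment_ref is not None:
        ref = segment_ref
    if not np.all(np.isfinite(samples)):
        raise ValueError("segment contains non-finite samples")
    n = len(samples)
    if dictionary is None:
        dictionary = build_dictionary(n, octave_range, freq_cap, fs)
    elif dictionary.length != n:
        raise ValueError("dictionary built for a different segment length")
    if method not in ("fft", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    searcher = _best_candidate_fft if method == "fft" else _best_candidate_exhaustive

    residual = samples.astype(np.float64).copy()
    energy0 = float(residual @ residual)
    energies = [energy0]
    atoms: list[GaborAtom] = []
    if energy0 == 0.0:
        return Decomposition(atoms, 0.0, n, fs, ref, energies)

    for it in range(n_atoms):
        p2, j, k, u, phi = searcher(residual, dictionary)
        freq = k * fs / 2.0**j
        g = atom_waveform(j, freq, u, phi, n, fs)
        coef = float(residual @ g)
        if coef < 0.0:  # guard: fold the sign into the phase
            phi = phi - np.pi if phi > 0 else phi + np.pi
            g = -g
            coef = -coef
        residual -= coef * g
        atoms.append(
            GaborAtom(
                octave=j,
                frequency=float(freq),
                translation=u,
                phase=float(phi),
                coefficient_magnitude=coef,
                iteration=it,
            )
        )
        energy = float(residual @ residual)
        energies.append(energy)
        if energy < EARLY_STOP_FRACTION * energy0:
            break
    return Decomposition(atoms, energies[-1], n, fs, ref, energies)


def reconstruct(
    decomposition: Decomposition,
    atom_subset: Sequence[int] | str = "all",
    length: int | None = None,
) -> np.ndarray:
    """Sum the selected atoms' waveforms; linear in disjoint subsets."""
    n = length if length is not None else decomposition.segment_length
    out = np.zeros(n)
    if isinstance(atom_subset, str):
        if atom_subset != "all":
            raise ValueError(f"unknown subset spec {atom_subset!r}")
        selected: Iterable[GaborAtom] = decomposition.atoms
    else:
        selected = [decomposition.atoms[i] for i in atom_subset]
    for atom in selected:
        out += atom.coefficient_magnitude * atom_waveform(
            atom.octave,
            atom.frequency,
            atom.translation,
            atom.phase,
            n,
            decomposition.sample_rate,
        )
    return out


def _coerce_segment(segment, sample_rate):
    if hasattr(segment, "samples"):
        samples = np.asarray(segment.samples, dtype=np.float64)
        fs = float(getattr(segment, "sample_rate", sample_rate or 4000.0))
        ref = {
            "subject_id": getattr(segment, "subject_id", None),
            "condition": getattr(segment, "condition", None),
            "kind": getattr(segment, "kind", None),
            "start_sample": getattr(segment, "start_sample", None),
        }
    else:
        samples = np.asarray(segment, dtype=np.float64)
        fs = float(sample_rate or 4000.0)
        ref = {}
    if samples.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    return samples, fs, ref
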