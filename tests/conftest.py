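import numpy as np
import pytest

from cardioset.mp import Decomposition, GaborAtom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def make_decomposition(
    atoms_spec,
    segment_length=512,
    sample_rate=4000.0,
    segment_ref=None,
):
    """Build a Decomposition directly from (octave, freq, u, phase, mag) specs."""
    atoms = [
        GaborAtom(
            octave=int(j),
            frequency=float(f),
            translation=int(u),
            phase=float(p),
            coefficient_magnitude=float(m),
            iteration=i,
        )
        for i, (j, f, u, p, m) in enumerate(atoms_spec)
    ]
    return Decomposition(
        atoms=atoms,
        residual_energy=0.0,
        segment_length=segment_length,
        sample_rate=sample_rate,
        segment_ref=segment_ref or {},
    )


def random_decomposition(rng, n_atoms, segment_length=512, octaves=(2, 9)):
    spec = []
    for _ in range(n_atoms):
        j = int(rng.integers(octaves[0], octaves[1] + 1))
        f = float(rng.integers(0, 9)) * 4000.0 / 2.0**j
        spec.append(
            (
                j,
                min(f, 1000.0),
                int(rng.integers(0, segment_length)),
                float(rng.uniform(-np.pi, np.pi)),
                float(rng.uniform(0.1, 3.0)),
            )
        )
    return make_decomposition(spec, segment_length)
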