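import numpy as np
import pytest

from beandry import synthetic
from beandry.workflows import preprocess_cube


@pytest.fixture(scope="session")
def small_cube_bundle():
    """Twelve noise-free synthetic bean cubes with ground-truth scores."""
    spec = synthetic.CubeGenSpec(n_samples=12, noise_sd=0.0, seed=11)
    return synthetic.gen_hypercube(spec)


@pytest.fixture(scope="session")
def noisy_cube_dataset():
    """Preprocessed spectra matrix from 80 noisy cubes (the PLSR test bed)."""
    spec = synthetic.CubeGenSpec(n_samples=80, noise_sd=0.02, seed=7)
    bundle = synthetic.gen_hypercube(spec)
    X = np.stack([preprocess_cube(s.cube, bundle.refs, spec.sg).values
                  for s in bundle.samples])
    y = np.array([s.truth_score for s in bundle.samples])
    temps = np.array([s.temperature for s in bundle.samples])
    return bundle, X, y, temps
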