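import numpy as np
import pytest

from viadyn.synthetic import PhantomSpec, generate_phantom, random_lesion_mask


def make_clean_spec(n_frames=120, seed=11, with_lesion=True, **overrides):
    """Phantom spec with no jitter, noise, or reflections."""
    rng = np.random.default_rng(seed)
    masks = [random_lesion_mask(150, rng)] if with_lesion else []
    params = dict(lesion_masks=masks, n_frames=n_frames, jitter_sigma=0.0,
                  noise_sigma=0.0, reflection_count=0, rng_seed=seed)
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, jitter-free positive phantom with its spec and truth."""
    spec = make_clean_spec()
    seq, truth = generate_phantom(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def default_phantom():
    """Positive phantom at the default (study-condition) noise settings."""
    rng = np.random.default_rng(5)
    spec = PhantomSpec(lesion_masks=[random_lesion_mask(150, rng)], rng_seed=5)
    seq, truth = generate_phantom(spec)
    return spec, seq, truth
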