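import numpy as np
import pytest

from spinemap import GeneratorConfig, LabeledSpinePattern


def straight_pattern(arc_positions, labels, dendrite_id="d0", slice_id="s0",
                     region="CA1", condition="home_cage"):
    """Spines on a straight dendrite along x: arc distance == 3D distance."""
    arc = np.asarray(arc_positions, float)
    positions = np.column_stack([arc, np.zeros_like(arc), np.zeros_like(arc)])
    return LabeledSpinePattern(dendrite_id=dendrite_id, positions=positions,
                               labels=np.asarray(labels, int),
                               slice_id=slice_id, region=region,
                               condition=condition)


def random_pattern(rng, n_spines, label_fraction=0.3, box=20.0,
                   dendrite_id="d0"):
    """Random 3D point pattern with Bernoulli labels (≥1 positive forced)."""
    positions = rng.uniform(0.0, box, size=(n_spines, 3))
    labels = (rng.uniform(size=n_spines) < label_fraction).astype(int)
    if labels.sum() == 0:
        labels[rng.integers(n_spines)] = 1
    return LabeledSpinePattern(dendrite_id=dendrite_id, positions=positions,
                               labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A fast generator configuration for pipeline-level tests."""
    return GeneratorConfig(n_animals=1, n_slices_per_animal=2,
                           n_dendrites_per_slice=3,
                           spines_per_dendrite=(30, 40), rng_seed=11)
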