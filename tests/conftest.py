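import numpy as np
import pytest

import mfoct


@pytest.fixture(scope="session")
def carpet5():
    return mfoct.make_sierpinski_carpet(5)


@pytest.fixture(scope="session")
def cascade8():
    """Level-8 binomial cascade, p = 0.7, fixed seed."""
    return mfoct.make_binomial_cascade(8, 0.7, seed=1)


@pytest.fixture(scope="session")
def filled256():
    return mfoct.make_filled_rect(256)


@pytest.fixture(scope="session")
def phantom_study():
    """The seeded 200-image synthetic study table (100 per class)."""
    return mfoct.phantom_feature_table(n_per_class=100, seed=42)


@pytest.fixture(scope="session")
def small_phantom_masks():
    """A few preprocessed phantom masks per class for identity checks."""
    masks = []
    for s in range(3):
        for label in ("DR", "Normal"):
            img = mfoct.make_retina_phantom(
                mfoct.PhantomSpec(class_label=label, seed=s)
            )
            masks.append(mfoct.preprocess_image(img))
    return masks
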