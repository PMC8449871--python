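import numpy as np
import pytest

from emulstab import datasets, synthetic


@pytest.fixture(scope="session")
def study_table():
    """Bundled 24-run design merged with its responses."""
    return datasets.design_with_responses()


@pytest.fixture(scope="session")
def responses_table():
    """Bundled response table including the published derived columns."""
    return datasets.load_responses()


@pytest.fixture(scope="session")
def creaming_table():
    """Bundled five-sample creaming-index table."""
    return datasets.load_creaming_table()


@pytest.fixture(scope="session")
def small_micrograph():
    """A quick noise-free micrograph with its ground truth (20 droplets)."""
    spec = synthetic.MicrographSpec(
        image_width_px=512, image_width_um=128.0, n_droplets=20, noise_sd=0.0, seed=7
    )
    image, truth = synthetic.generate_micrograph(spec)
    return spec, image, truth


def floodfill_diameters(image: np.ndarray, threshold: float = 128.0) -> np.ndarray:
    """Independent sizing oracle: scipy flood fill + area-equivalent circles."""
    from scipy import ndimage

    labels, n = ndimage.label(image < threshold)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return 2.0 * np.sqrt(np.asarray(areas) / np.pi)
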