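import numpy as np
import pytest

from cytoctc.classify import classify_cells
from cytoctc.quant import cells_to_frame, quantify_image
from cytoctc.simulate import ImageParams, generate_cytospin

# expected morphotype label per planted class
PLANTED_TO_MORPHOTYPE = {
    "leukocyte": "non_tumor",
    "classical_ctc": "classical",
    "large_cell": "large",
    "multinucleated_cell": "multinucleated",
    "cluster_member": "cluster_member",
}


@pytest.fixture(scope="session")
def slide_params():
    """A mixed slide with every morphotype at default noise and pixel size."""
    return ImageParams(
        shape=(1200, 1200),
        n_leukocytes=40,
        n_classical=6,
        n_large=2,
        n_multinucleated=2,
        cluster_sizes=(2, 3),
    )


@pytest.fixture(scope="session")
def slide(slide_params):
    return generate_cytospin(slide_params, seed=42)


@pytest.fixture(scope="session")
def quantified_slide(slide):
    """Segmented + measured cells for the session slide."""
    return quantify_image(slide.image, slide.pixel_size_um)


@pytest.fixture(scope="session")
def classified_slide(quantified_slide):
    return classify_cells(cells_to_frame(quantified_slide))


def match_planted(gt, detected_centroids):
    """Index of the nearest detected cell for each planted cell, plus distances."""
    det = np.asarray(detected_centroids, dtype=float)
    idx, dist = [], []
    for spec in gt.cells:
        d = np.hypot(det[:, 0] - spec.centroid[0], det[:, 1] - spec.centroid[1])
        j = int(np.argmin(d))
        idx.append(j)
        dist.append(float(d[j]))
    return idx, dist
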