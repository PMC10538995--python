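import numpy as np
import pytest

import fiberredox as fr


def match_rois_to_truth(rois, truth):
    """Match each recovered ROI to the truth fiber with maximal pixel overlap.

    Returns a list of (roi, truth_fiber_id, jaccard).
    """
    out = []
    for roi in rois:
        labs = truth.label_map[roi.coords[:, 0], roi.coords[:, 1]]
        inside = labs[labs > 0]
        if len(inside) == 0:
            out.append((roi, 0, 0.0))
            continue
        lab = int(np.bincount(inside).argmax())
        truth_n = int((truth.label_map == lab).sum())
        inter = int((labs == lab).sum())
        jac = inter / (truth_n + len(labs) - inter)
        out.append((roi, lab, jac))
    return out


@pytest.fixture(scope="session")
def small_params():
    """A compact section that still hosts ~60 well-formed fibers."""
    return fr.SectionParams(n_fibers=60, image_size=(384, 384), seed=7)


@pytest.fixture(scope="session")
def small_section(small_params):
    return fr.generate_section(small_params)


@pytest.fixture(scope="session")
def noiseless_section():
    params = fr.SectionParams(n_fibers=60, image_size=(384, 384),
                              noise_sd=0.0, seed=11)
    return fr.generate_section(params)
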