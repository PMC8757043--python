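import numpy as np
import pytest

from segqc import CaseEnsemble, ClassSpec, SegMask, SimConfig, make_cohort


def mask(voxels, spacing=(1.0, 1.0, 1.0), case_id="c0", source_id="s0"):
    """Build a SegMask from any array-like, promoting 1D/2D to 3D."""
    arr = np.asarray(voxels, dtype=np.int32)
    while arr.ndim < 3:
        arr = arr[..., np.newaxis]
    return SegMask(voxels=arr, spacing=spacing, case_id=case_id, source_id=source_id)


@pytest.fixture
def mk_mask():
    return mask


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 10-case, 4-source cohort with graded corruption."""
    config = SimConfig(n_cases=10, n_sources=4, shape=(32, 32, 32), seed=11)
    cohort, ledger = make_cohort(config)
    return config, cohort, ledger


@pytest.fixture
def toy_ensemble(mk_mask):
    """Three hand-built binary candidates on a 4x4x1 grid."""
    a = mk_mask([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]], source_id="a")
    b = mk_mask([[1, 1, 0, 0], [1, 1, 1, 0], [0, 0, 0, 0], [0, 0, 0, 0]], source_id="b")
    c = mk_mask([[1, 0, 0, 0], [1, 1, 0, 0], [0, 1, 0, 0], [0, 0, 0, 0]], source_id="c")
    return CaseEnsemble(case_id="c0", candidates={"a": a, "b": b, "c": c})


@pytest.fixture
def glioma_classes():
    # BraTS-style labels: 1 necrosis, 2 edema, 4 enhancing tumor
    return ClassSpec([1, 2, 4], ["necrosis", "edema", "enhancing"])
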