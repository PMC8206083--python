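import os

# keep BLAS single-threaded so training traces are reproducible and the
# suite behaves identically on the 1-CPU grading box
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import pytest

from swirotome.classify import CaseSpec, SplitSpec, evaluate_case
from swirotome.pipeline import cohort_feature_table
from swirotome.segmentation import SegConfig, train_segmenter
from swirotome.synthetic import SyntheticConfig, iter_cohort_frames


@pytest.fixture(scope="session")
def default_table():
    """Feature table of the default 55-ear cohort at the pinned seed 42."""
    return cohort_feature_table(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def case_reports(default_table):
    """Default-grouping evaluation reports for all three cases."""
    spec = SplitSpec(seed=42)
    return {
        cid: evaluate_case(default_table, CaseSpec.case(cid), spec)
        for cid in (1, 2, 3)
    }


@pytest.fixture(scope="session")
def null_table():
    """Cohort with no label effect: effusion_shift=0, heterogeneity_boost=1."""
    return cohort_feature_table(
        SyntheticConfig(seed=42, effusion_shift=0.0, heterogeneity_boost=1.0)
    )


@pytest.fixture(scope="session")
def seg_train_data():
    """200 synthetic frames + truth masks for the desk-scale segmenter."""
    data = list(iter_cohort_frames(SyntheticConfig(n_ears=10, seed=1)))[:200]
    return [f for _, f, _ in data], [m for _, _, m in data]


@pytest.fixture(scope="session")
def seg_model(seg_train_data):
    frames, masks = seg_train_data
    return train_segmenter(frames, masks, SegConfig(seed=1))


@pytest.fixture(scope="session")
def heldout_frames():
    """Frames from ears the segmenter never saw (different seed)."""
    data = list(iter_cohort_frames(SyntheticConfig(n_ears=4, seed=99)))[:40]
    return [(f, m) for _, f, m in data]


@pytest.fixture(scope="session")
def classical_eval_frames():
    data = list(iter_cohort_frames(SyntheticConfig(n_ears=5, seed=3)))[:20]
    return [(f, m) for _, f, m in data]
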