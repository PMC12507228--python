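import numpy as np
import pytest

from metaecg.backbone import MLPBackbone
from metaecg.cohort import CohortSpec, make_cohort
from metaecg.windowing import resample_record, segment_record


@pytest.fixture(scope="session")
def small_cohort():
    """Six noisy subjects, short records, deterministic."""
    spec = CohortSpec(n_subjects=6, duration_s=240.0, seed=11,
                      min_windows_per_class=40)
    records, profiles = make_cohort(spec)
    return spec, records, profiles


@pytest.fixture(scope="session")
def segmented_subject(small_cohort):
    _, records, _ = small_cohort
    return segment_record(resample_record(records[0]))


@pytest.fixture()
def tiny_mlp():
    """A deterministic few-parameter model for gradient oracles."""
    return MLPBackbone(in_len=2, hidden=(2,), n_classes=2, dropout=0.0)


@pytest.fixture()
def window_mlp():
    return MLPBackbone(in_len=400, hidden=(16,), n_classes=2, dropout=0.0)


class QuadraticSurrogate:
    """Scalar surrogate with loss L(theta) = 0.5 * theta^2.

    Implements the same model protocol as the backbones so the meta-learning
    code paths can be checked against closed forms.
    """

    def init_params(self, seed=0, theta0=1.0):
        from collections import OrderedDict
        from metaecg.backbone import WeightsHandle
        return WeightsHandle(OrderedDict(theta=np.array(float(theta0))))

    def forward(self, params, x, training=False, rng=None):
        raise NotImplementedError("surrogate has no forward pass")

    def loss_on(self, params, X, y, training=False, rng=None,
                reduction="mean"):
        from metaecg import autodiff as ad
        theta = params["theta"] if not hasattr(params, "as_tensors") \
            else params.as_tensors(False)["theta"]
        return ad.mul(ad.power(theta, 2.0), 0.5)


@pytest.fixture()
def quadratic():
    return QuadraticSurrogate()
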