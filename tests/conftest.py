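import numpy as np
import pytest

from attnrisk import PatientCohort, RawTable, SyntheticSpec, generate_cohort


def numerical_gradients(model, X, Y, step=1e-5):
    """Central finite differences of the penalized loss for every parameter."""
    grads = {}
    for name, arr in model.params.items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + step
            lp = model.compute_loss(X, Y)
            arr[i] = orig - step
            lm = model.compute_loss(X, Y)
            arr[i] = orig
            g[i] = (lp - lm) / (2 * step)
        grads[name] = g
    return grads


def max_relative_gradient_error(model, X, Y, step=1e-5):
    _, analytic = model.loss_and_grads(X, Y)
    numeric = numerical_gradients(model, X, Y, step)
    worst = 0.0
    for name in analytic:
        denom = np.maximum(np.abs(numeric[name]), 1e-8)
        worst = max(worst, float(np.max(np.abs(analytic[name] - numeric[name]) / denom)))
    return worst


@pytest.fixture
def toy_raw_table() -> RawTable:
    """3 patients x 3 features with one missing cell."""
    values = np.array(
        [
            [1.0, 10.0, 0.5],
            [np.nan, 20.0, 0.6],
            [3.0, 30.0, 0.7],
        ]
    )
    return RawTable(values, ["f1", "f2", "f3"], "outcome", np.array([1.0, 0.0, 1.0]))


@pytest.fixture
def blobs_cohort() -> PatientCohort:
    """Two linearly separable Gaussian blobs, n=200, m=2."""
    rng = np.random.default_rng(7)
    X0 = rng.normal(loc=-2.0, scale=0.4, size=(100, 2))
    X1 = rng.normal(loc=2.0, scale=0.4, size=(100, 2))
    X = np.vstack([X0, X1])
    Y = np.array([0] * 100 + [1] * 100)
    return PatientCohort(X, ["f1", "f2"], Y)


@pytest.fixture(scope="session")
def informative_cohort():
    """n=600, m=8, three strong informative features — fast fit fixture."""
    spec = SyntheticSpec(
        n=600, m=8, informative_idx=[0, 1, 2], beta=[2.0, -2.0, 2.0], seed=19
    )
    return generate_cohort(spec)
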