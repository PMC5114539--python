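import numpy as np
import pytest

import testmat as tm


@pytest.fixture(scope="session")
def study_pool_params() -> tm.GeneratedPool:
    """One generated study pool shared across tests (324 Rasch items)."""
    return tm.generate_pool(np.random.default_rng(20260929))


@pytest.fixture(scope="session")
def pool3(study_pool_params) -> tm.ItemPool:
    return study_pool_params.pool(3)


@pytest.fixture()
def small_pool() -> tm.ItemPool:
    """Hand-built 3-dimensional pool: 5 testlets of 3 items each."""
    rng = np.random.default_rng(7)
    items = []
    for t in range(5):
        for i in range(3):
            a = np.zeros(3)
            a[t % 3] = 1.0
            items.append(
                tm.Item(
                    id=f"i{t}{i}",
                    a=a,
                    b=float(rng.uniform(-2, 2)),
                    c=0.0,
                    testlet_id=f"t{t}",
                )
            )
    return tm.ItemPool(items)


def response_loglik(theta, gamma_map, items, responses):
    """Independent scalar oracle for the response log likelihood.

    Evaluates 1 - p as (1 - c) * logistic(-exponent) so the oracle stays
    accurate for items answered far from their difficulty (p near 1).
    """
    from scipy.special import expit

    theta = np.asarray(theta, float)
    total = 0.0
    for it, u in zip(items, responses):
        x = float(it.a @ (theta - (it.b + gamma_map.get(it.testlet_id, 0.0))))
        if u:
            total += np.log(it.c + (1.0 - it.c) * expit(x))
        else:
            total += np.log1p(-it.c) + np.log(expit(-x))
    return total
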