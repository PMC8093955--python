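import numpy as np
import pytest

from disgrou import Config, Dataset, Selector, IntervalSet, Interval
from disgrou.selectors import SelectorVocabulary


@pytest.fixture
def toy_dataset():
    """Values (1,2,3,2), targets (10,10,10,0): pos(T) = {t0,t1,t2}.

    Grid over pos values is (1,2,3) with one positive transaction each;
    the negative transaction at value 2 keeps Min/Max at [1;3].
    """
    return Dataset(
        ["x"],
        np.array([[1.0], [2.0], [3.0], [2.0]]),
        np.array([10.0, 10.0, 10.0, 0.0]),
    )


@pytest.fixture
def tree_dataset():
    """3 transactions, targets (4, 1, 6); s1 matches all, s2 matches t0, t2."""
    return Dataset(
        ["x", "y"],
        np.array([[0.0, 0.0], [5.0, 5.0], [1.0, 1.0]]),
        np.array([4.0, 1.0, 6.0]),
    )


@pytest.fixture
def tree_vocabulary(tree_dataset):
    s1 = Selector("x", IntervalSet([Interval(0.0, 5.0)]), pos_support=2)
    s2 = Selector("y", IntervalSet([Interval(0.0, 1.0)]), pos_support=1)
    return SelectorVocabulary.from_selectors([s1, s2], tree_dataset)


def assert_subgroups_match(a, b, tol=1e-9):
    """Same subgroup up to floating-point summation order."""
    assert a.n == b.n
    assert abs(a.target_sum - b.target_sum) <= tol * max(1.0, abs(b.target_sum))
    assert abs(a.quality - b.quality) <= tol * max(1.0, abs(b.quality))
    assert dict(a.description) == dict(b.description)
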