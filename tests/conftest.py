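import numpy as np
import pytest

from gsanova.io_formats import CountMatrix, GeneSetCollection, SampleDesign
from gsanova.normalize import ExpressionMatrix


@pytest.fixture
def two_group_design() -> SampleDesign:
    return SampleDesign(
        ["a", "b", "c", "d"],
        {"a": "ctrl", "b": "ctrl", "c": "trt", "d": "trt"},
    )


@pytest.fixture
def three_group_design() -> SampleDesign:
    samples = [f"s{i}" for i in range(6)]
    groups = ["A", "A", "B", "B", "C", "C"]
    return SampleDesign(samples, dict(zip(samples, groups)))


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    counts = rng.poisson(50, size=(20, 6))
    return CountMatrix(
        [f"g{i}" for i in range(20)], [f"s{i}" for i in range(6)], counts
    )


@pytest.fixture
def expr_matrix(small_counts, three_group_design) -> ExpressionMatrix:
    from gsanova.normalize import vst_log

    return vst_log(small_counts)


@pytest.fixture
def toy_sets() -> GeneSetCollection:
    coll = GeneSetCollection()
    coll.add("SetA", {"g0", "g1", "g2"}, "first")
    coll.add("SetB", {"g3", "g4", "g5", "g6"}, "second")
    return coll
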