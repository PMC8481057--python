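import numpy as np
import pytest

from rackstack import ResponseMatrix, calibrate, infant_design, simulate_prepost

# fixed complete matrices with no extreme margins, every category observed,
# and enough response disorder that the joint maximum likelihood is interior;
# used for oracle-equivalence and sufficiency checks
MAT_5x4 = np.array([
    [1, 1, 2, 2],
    [0, 0, 2, 2],
    [0, 0, 2, 1],
    [0, 2, 0, 1],
    [1, 1, 0, 0],
], dtype=float)

MAT_6x5 = np.array([
    [2, 1, 1, 0, 0],
    [0, 0, 0, 0, 2],
    [1, 2, 1, 1, 2],
    [2, 1, 1, 1, 2],
    [0, 2, 2, 0, 1],
    [2, 1, 0, 2, 2],
], dtype=float)


def make_matrix(values: np.ndarray, m: int = 2,
                occasion: str = "") -> ResponseMatrix:
    n, k = values.shape
    return ResponseMatrix([f"p{r + 1}" for r in range(n)],
                          [f"i{c + 1}" for c in range(k)],
                          values, m, occasion)


@pytest.fixture(scope="session")
def mat_5x4() -> ResponseMatrix:
    return make_matrix(MAT_5x4)


@pytest.fixture(scope="session")
def mat_6x5() -> ResponseMatrix:
    return make_matrix(MAT_6x5)


@pytest.fixture(scope="session")
def infant_sim():
    """One study-shaped simulated pre/post pair (41 persons x 11 items)."""
    return simulate_prepost(infant_design(seed=11))


@pytest.fixture(scope="session")
def infant_pre_cal(infant_sim):
    pre, _, _ = infant_sim
    return calibrate(pre)
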