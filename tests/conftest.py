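import numpy as np
import pytest

from csecsi import Tensor3


def cp_tensor(factors):
    return Tensor3(np.einsum("ir,jr,kr->ijk", *factors))


def random_factors(seed, dims, rank, complex_field=False):
    rng = np.random.default_rng(seed)
    out = []
    for m in dims:
        f = rng.standard_normal((m, rank))
        if complex_field:
            f = (f + 1j * rng.standard_normal((m, rank))) / np.sqrt(2)
        out.append(f)
    return out


def coupled_pair(seed, dims1=(8, 8, 8), dims2=None, rank=3, complex_field=False):
    """Noiseless coupled CP pair with shared first factor; returns truths + tensors."""
    dims2 = dims2 or dims1
    assert dims1[0] == dims2[0]
    rng = np.random.default_rng(seed)

    def draw(m, r):
        f = rng.standard_normal((m, r))
        if complex_field:
            f = (f + 1j * rng.standard_normal((m, r))) / np.sqrt(2)
        return f

    f1 = draw(dims1[0], rank)
    t = []
    truths = []
    for dims in (dims1, dims2):
        f2, f3 = draw(dims[1], rank), draw(dims[2], rank)
        truths.append([f1, f2, f3])
        t.append(cp_tensor([f1, f2, f3]))
    return truths[0], truths[1], t[0], t[1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
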