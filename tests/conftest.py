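import numpy as np
import pytest

from smafbi.core import Bounds


class FixedRng:
    """Deterministic stand-in for a Generator: replays preset draws.

    ``random`` values are consumed from ``uniforms`` (scalars broadcast
    to any requested size); ``choice``/``integers`` replay ``indices``.
    """

    def __init__(self, uniforms=(), indices=()):
        self._uniforms = list(uniforms)
        self._indices = list(indices)

    def random(self, size=None):
        u = self._uniforms.pop(0) if self._uniforms else 0.5
        if size is None:
            return float(u)
        return np.full(size, float(u))

    def uniform(self, lo, hi, size=None):
        u = self.random()
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        out = lo + u * (hi - lo)
        if size is not None and np.ndim(out) == 0:
            out = np.full(size, out)
        return out

    def choice(self, n, size=1, replace=False):
        out = [self._indices.pop(0) for _ in range(size)]
        return np.asarray(out)

    def integers(self, *args, **kwargs):
        return self._indices.pop(0) if self._indices else 0


@pytest.fixture
def fixed_rng():
    return FixedRng


@pytest.fixture
def unit_bounds():
    return Bounds.cube(-1.0, 1.0, 1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
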