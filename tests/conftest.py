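import numpy as np
import pytest


class StubRng:
    """Deterministic stand-in for numpy's Generator with a preset draw queue.

    Each call to ``random`` / ``standard_normal`` / ``integers`` /
    ``permutation`` pops the next queued value, so formula-level tests can pin
    every random draw to printed constants.
    """

    def __init__(self, *values):
        self.queue = list(values)

    def _pop(self, size):
        if not self.queue:
            raise AssertionError("StubRng queue exhausted")
        val = self.queue.pop(0)
        arr = np.asarray(val, dtype=float)
        if size is None:
            return float(arr) if arr.ndim == 0 else arr
        expected = (size,) if np.isscalar(size) else tuple(size)
        if arr.shape != expected:
            raise AssertionError(
                f"queued draw has shape {arr.shape}, caller wants {expected}")
        return arr

    def random(self, size=None):
        return self._pop(size)

    def standard_normal(self, size=None):
        return self._pop(size)

    def integers(self, low, high=None, size=None):
        val = self.queue.pop(0)
        return int(val) if size is None else np.asarray(val, dtype=int)

    def permutation(self, n):
        return np.asarray(self.queue.pop(0), dtype=int)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def stub_rng_factory():
    return StubRng


@pytest.fixture(scope="session")
def small_phantom():
    """A 96x96 easy-tier multimodal pair shared across read-only tests."""
    from nvsa.phantoms import make_tier_pair

    return make_tier_pair("easy", seed=11, size=(96, 96))
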