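import numpy as np
import pytest

from topomap import SampledMap


@pytest.fixture
def perfect_line():
    """5 collinear units with monotone labels: a perfectly ordered 1-D map."""
    return SampledMap(
        positions=np.column_stack([np.arange(5.0), np.zeros(5)]),
        labels=np.arange(5.0),
    )


@pytest.fixture
def jittered_grid_factory():
    """k x k grid with small positional jitter (valid Delaunay geometry)."""

    def make(k=4, seed=0, labels="x", periodic=False):
        rng = np.random.default_rng(seed)
        xs, ys = np.meshgrid(np.arange(float(k)), np.arange(float(k)))
        pos = np.column_stack([xs.ravel(), ys.ravel()])
        pos = pos + rng.normal(0, 0.08, pos.shape)
        if labels == "x":
            lab = np.repeat(np.arange(float(k)), 1)[xs.ravel().astype(int)]
        elif labels == "random":
            lab = rng.normal(size=k * k)
        else:
            raise ValueError(labels)
        if periodic:
            lab = lab / max(lab.max(), 1) * 4 - 2  # into (-pi, pi)
            return SampledMap(positions=pos, labels=lab, periodic=True, period=2 * np.pi)
        return SampledMap(positions=pos, labels=lab)

    return make


@pytest.fixture
def random_map_factory():
    """Random scattered maps, optionally periodic, with distinct labels."""

    def make(n=12, seed=0, periodic=False, duplicates=False):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 1, size=(n, 2))
        if periodic:
            lab = rng.uniform(-np.pi, np.pi, size=n)
            if duplicates:
                lab[: n // 3] = lab[n // 3 : 2 * (n // 3)]
            return SampledMap(positions=pos, labels=lab, periodic=True, period=2 * np.pi)
        lab = rng.normal(size=n)
        if duplicates:
            lab = np.round(lab, 1)
        return SampledMap(positions=pos, labels=lab)

    return make
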