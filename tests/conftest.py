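import numpy as np
import pytest

import startshift as ss
from startshift.quant import BinScheme, LaneSignal


@pytest.fixture(scope="session")
def promoter():
    return ss.default_promoter()


@pytest.fixture(scope="session")
def scheme():
    return BinScheme([[20, 33], [33, 45], [45, 52], [52, 60], [60, 75], [75, 90]])


@pytest.fixture(scope="session")
def demo_config():
    return ss.load_config(ss.default_config_path())


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory, demo_config):
    """The shipped demo pipeline, run once per session."""
    outdir = tmp_path_factory.mktemp("demo_run")
    ss.run_pipeline(demo_config, outdir)
    return outdir


def random_lane(rng, scheme: BinScheme, n_positions=12, strain="s", replicate="1"):
    """A random lane whose positions all fall inside the scheme."""
    lo, hi = int(scheme.edges[0]), int(scheme.edges[-1])
    positions = rng.choice(np.arange(lo, hi), size=min(n_positions, hi - lo), replace=False)
    positions.sort()
    intensities = rng.gamma(2.0, 50.0, size=positions.size) + 1e-6
    return LaneSignal(
        positions=positions, intensities=intensities, strain=strain, replicate=replicate
    )


def brute_force_bin(lane: LaneSignal, scheme: BinScheme) -> np.ndarray:
    """Independent per-position summation oracle (deliberately naive)."""
    sums = [0.0] * scheme.K
    for pos, inten in zip(lane.positions.tolist(), lane.intensities.tolist()):
        hit = None
        for b, (start, end) in enumerate(scheme.boundaries):
            if start <= pos < end:
                hit = b
                break
        if hit is None:
            raise AssertionError(f"position {pos} outside scheme")
        sums[hit] += inten
    return np.array(sums)
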