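"""Shared fixtures: small geometries and the (lazily built) scaled-down study.

The ``study`` fixture runs the full scaled-down experiment once per session
via :func:`sosvn.experiments.reconstruction_benchmark` — dataset generation,
LBFGS baseline, VN training, BVI training, posterior RMSEs on the held-out
test set — and is only computed when a test requests it.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sosvn.experiments import reconstruction_benchmark
from sosvn.geometry import AcquisitionSpec, ImagingGrid, build_forward_model

STUDY_SEED = 0


@pytest.fixture(scope="session")
def tiny_model():
    """6x6 grid, 4 transmits / 3 pairs: the small instance for oracles."""
    grid = ImagingGrid(6, 6, 1.0, 1.0)
    spec = AcquisitionSpec(
        n_transmits=4, pair_offset=1, vs_angles_deg=(-15.0, -5.0, 5.0, 15.0)
    )
    return build_forward_model(spec, grid)


@pytest.fixture(scope="session")
def study():
    """The scaled-down study: data, baselines, trained VN/MCD/BVI and RMSEs."""
    return reconstruction_benchmark(seed=STUDY_SEED)
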