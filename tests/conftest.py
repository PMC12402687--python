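"""Shared fixtures: small deterministic geometries and field models."""

from __future__ import annotations

import numpy as np
import pytest

from axonmetrics.axon import AxonModelSpec, PulseWaveform, build_axon
from axonmetrics.fibers import Fiber, PathwayAtlas
from axonmetrics.volume_conductor import ContactSource, PointSourceField


def straight_fiber(
    length_mm: float = 12.0,
    n_pts: int = 121,
    axis: str = "x",
    offset=(0.0, 0.0, 0.0),
    fiber_id: int = 0,
) -> Fiber:
    t = np.linspace(-length_mm / 2, length_mm / 2, n_pts)
    pts = np.zeros((n_pts, 3))
    pts[:, "xyz".index(axis)] = t
    pts += np.asarray(offset)[None, :]
    return Fiber(fiber_id, pts, "test", "right")


@pytest.fixture
def fiber_x() -> Fiber:
    """12 mm straight fibre along x through the origin."""
    return straight_fiber()


@pytest.fixture
def cathodic_field() -> PointSourceField:
    """1 mA cathodic point source 1 mm above the x-axis."""
    return PointSourceField(
        sources=(ContactSource((0.0, 1.0, 0.0), -1.0),), sigma=0.1
    )


@pytest.fixture
def pulse_60us() -> PulseWaveform:
    return PulseWaveform(amplitude_scale=1.0, pulse_width_us=60.0)


@pytest.fixture
def tiny_atlas() -> PathwayAtlas:
    """Two pathways, five fibres, mixed hemispheres."""
    fibers = [
        Fiber(0, [[0, 0, 0], [0, 0, 5]], "alpha", "right"),
        Fiber(1, [[1, 0, 0], [1, 0, 5]], "alpha", "right"),
        Fiber(2, [[2, 0, 0], [2, 0, 5]], "alpha", "right", flagged=True),
        Fiber(3, [[-1, 0, 0], [-1, 0, 5]], "beta", "left"),
        Fiber(4, [[-2, 0, 0], [-2, 3, 5]], "beta", "left"),
    ]
    return PathwayAtlas.from_fibers(fibers)


@pytest.fixture(scope="session")
def threshold_cache():
    """Memoized activation thresholds shared across slow tests."""
    from axonmetrics.cable import find_threshold
    from axonmetrics.pam import node_potentials_mv

    cache: dict = {}

    def get(diameter_um: float, pulse_width_us: float = 60.0,
            anodic: bool = False, length_mm: float = 12.0) -> float:
        key = (diameter_um, pulse_width_us, anodic, length_mm)
        if key not in cache:
            fib = straight_fiber(length_mm)
            spec = AxonModelSpec(diameter_um=diameter_um)
            geom = build_axon(fib, spec)
            field = PointSourceField(
                sources=(ContactSource((0.0, 1.0, 0.0), -1.0),), sigma=0.1
            )
            drive = node_potentials_mv(geom, field)
            if anodic:
                drive = -drive
            wf = PulseWaveform(amplitude_scale=1.0,
                               pulse_width_us=pulse_width_us)
            cache[key] = find_threshold(geom, spec, drive, wf)
        return cache[key]

    return get
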