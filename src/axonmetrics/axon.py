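"""Myelinated axon morphology and discretization along fibre trajectories.

A McNeal-style model: excitable nodes of Ranvier connected by perfectly
insulating myelinated internodes, so the state lives only at the nodes.
Node positions are placed along the fibre's arc length at the internodal
spacing, centred on the fibre midpoint, with sealed ends.  Morphology scales
with the outer fibre diameter D: internodal length L = 100 D, axial (axon)
diameter d = 0.7 D, node length 2.5 µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Tuple

import numpy as np

from .fibers import Fiber

__all__ = ["AxonModelSpec", "AxonGeometry", "PulseWaveform",
           "AxonGeometryError", "build_axon"]


class AxonGeometryError(ValueError):
    """Fibre cannot support the requested axon discretization."""


@dataclass(frozen=True)
class AxonModelSpec:
    """Morphological and electrical parameters of a model axon.

    Parameters
    ----------
    diameter_um
        Outer fibre diameter D in µm; the operating range is 1–4 µm.
    internode_ratio
        Internodal length per unit diameter (L/D); 100 by default, so
        L = 0.1 mm for D = 1 µm.
    node_length_um
        Length of the node of Ranvier (µm).
    axon_diameter_ratio
        Axial (axon) diameter as a fraction of D.
    nodal_capacitance_uf_cm2
        Specific membrane capacitance of the nodal membrane (µF/cm²).
    axoplasmic_resistivity_ohm_cm
        Axial resistivity of the axoplasm (Ω·cm).
    temperature_c
        Simulation temperature (°C); membrane kinetics are Q10-scaled.
    """

    diameter_um: float = 2.0
    internode_ratio: float = 100.0
    node_length_um: float = 2.5
    axon_diameter_ratio: float = 0.7
    nodal_capacitance_uf_cm2: float = 2.0
    axoplasmic_resistivity_ohm_cm: float = 110.0
    temperature_c: float = 37.0

    def __post_init__(self) -> None:
        for name in ("diameter_um", "internode_ratio", "node_length_um",
                     "axon_diameter_ratio", "nodal_capacitance_uf_cm2",
                     "axoplasmic_resistivity_ohm_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def internode_length_mm(self) -> float:
        """Internodal spacing in mm (= 0.1 mm per µm of D by default)."""
        return self.internode_ratio * self.diameter_um * 1e-3

    @property
    def axon_diameter_um(self) -> float:
        return self.axon_diameter_ratio * self.diameter_um

    @property
    def node_area_cm2(self) -> float:
        """Nodal membrane area (cm²): cylinder side pi * d * node length."""
        d_cm = self.axon_diameter_um * 1e-4
        l_cm = self.node_length_um * 1e-4
        return np.pi * d_cm * l_cm

    @property
    def node_capacitance_uf(self) -> float:
        return self.nodal_capacitance_uf_cm2 * self.node_area_cm2

    @property
    def axial_conductance_ms(self) -> float:
        """Internodal axial conductance (mS): G = pi d^2 / (4 rho L)."""
        d_cm = self.axon_diameter_um * 1e-4
        l_cm = self.internode_length_mm * 1e-1
        area_cm2 = np.pi * d_cm**2 / 4.0
        g_s = area_cm2 / (self.axoplasmic_resistivity_ohm_cm * l_cm)
        return g_s * 1e3


@dataclass(frozen=True)
class AxonGeometry:
    """Node-of-Ranvier positions for one fibre at one diameter."""

    fiber_id: int
    node_positions: np.ndarray  # (n_nodes, 3) mm
    node_arc_mm: np.ndarray  # arc position of each node
    spec: AxonModelSpec

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]


@dataclass(frozen=True)
class PulseWaveform:
    """Rectangular stimulation pulse and simulation window.

    The spatial field is scaled by ``amplitude_scale`` and gated on during
    ``[onset, onset + pulse_width]``.  The window extends at least 3 ms past
    the pulse so a propagating action potential can reach the axon ends.
    """

    amplitude_scale: float = 1.0
    pulse_width_us: float = 60.0
    onset_ms: float = 0.1
    sim_window_ms: float | None = None
    shape: str = "rectangular"

    def __post_init__(self) -> None:
        if self.pulse_width_us <= 0:
            raise ValueError("pulse_width_us must be > 0")
        if self.shape != "rectangular":
            raise ValueError("only rectangular pulses are supported")
        min_window = self.onset_ms + self.pulse_width_us * 1e-3 + 3.0
        if self.sim_window_ms is None:
            object.__setattr__(self, "sim_window_ms", min_window)
        elif self.sim_window_ms < min_window:
            raise ValueError(
                f"sim_window_ms must be >= onset + pulse width + 3 ms "
                f"(= {min_window:g} ms)"
            )

    def envelope(self, t_ms: np.ndarray) -> np.ndarray:
        """Dimensionless gate value w(t) in {0, amplitude_scale}."""
        t = np.asarray(t_ms, dtype=float)
        on = (t >= self.onset_ms) & (
            t < self.onset_ms + self.pulse_width_us * 1e-3
        )
        return np.where(on, self.amplitude_scale, 0.0)


def build_axon(fiber: Fiber, spec: AxonModelSpec) -> AxonGeometry:
    """Place nodes of Ranvier along the fibre at the internodal spacing.

    The node chain is centred on the fibre midpoint (arc length S/2), so for
    an odd node count one node sits exactly at mid-arc.  Requires
    ``S >= 2 L``; shorter fibres cannot hold the minimum three nodes and are
    rejected (callers typically exclude and report them).
    """
    length = fiber.length
    internode = spec.internode_length_mm
    if length < 2.0 * internode:
        raise AxonGeometryError(
            f"fiber {fiber.fiber_id}: length {length:.3f} mm < 2 internodes "
            f"({2 * internode:.3f} mm) at D = {spec.diameter_um:g} um"
        )
    n_nodes = int(np.floor(length / internode + 1e-9)) + 1
    chain = (n_nodes - 1) * internode
    offset = 0.5 * (length - chain)
    arcs = offset + internode * np.arange(n_nodes)
    s = fiber.arc_lengths()
    pts = np.column_stack(
        [np.interp(arcs, s, fiber.points[:, k]) for k in range(3)]
    )
    return AxonGeometry(
        fiber_id=fiber.fiber_id, node_positions=pts, node_arc_mm=arcs,
        spec=spec,
    )
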