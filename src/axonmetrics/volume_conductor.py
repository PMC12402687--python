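"""Extracellular potential and electric field for contact configurations.

Two field providers share one query interface:

* an analytic point-source model in a homogeneous isotropic medium, where
  each active contact is an ideal monopole and fields superpose,
* a precomputed vector-field lattice imported from a 4-D NIfTI volume
  (e.g. exported by an external finite-element solver), sampled trilinearly.

Units: positions mm, currents mA, conductivity S/m, potential V, field V/m.
For a single monopole ``V = I / (4 pi sigma r)`` and ``E = -grad V`` points
radially with magnitude ``I / (4 pi sigma r^2)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ContactSource",
    "StimulationProtocol",
    "FieldSample",
    "PointSourceField",
    "GridField",
    "FieldError",
    "potential_at",
    "efield_at",
    "voltage_to_current",
    "load_field_grid",
    "save_field_grid",
    "grid_sample",
    "DEFAULT_SIGMA",
    "DEFAULT_CONTACT_RADIUS",
    "SINGULARITY_RADIUS",
]

#: default bulk conductivity of brain tissue (S/m), homogeneous isotropic
DEFAULT_SIGMA = 0.1
#: sphere radius equivalent to a cylindrical DBS contact (mm)
DEFAULT_CONTACT_RADIUS = 0.635
#: queries closer than this to a point source raise, never silently clip (mm)
SINGULARITY_RADIUS = 0.05


class FieldError(ValueError):
    """Field-model configuration or evaluation error."""


@dataclass(frozen=True)
class ContactSource:
    """A point current source: position (mm) and signed current (mA).

    Negative current = cathode (conventional current flowing into the
    electrode), positive = anode.
    """

    position: Tuple[float, float, float]
    current: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise FieldError("source position must be a finite 3-vector")
        if not np.isfinite(self.current):
            raise FieldError("source current must be finite")
        object.__setattr__(self, "position", tuple(pos))


@dataclass(frozen=True)
class StimulationProtocol:
    """One stimulation setting: sources, drive mode and pulse parameters.

    ``polarity_signature`` follows the clinical shorthand ``"1+2-"`` (contact
    1 anodic, contact 2 cathodic).  In current mode, ``sources`` carry the
    resolved per-contact currents; bipolar settings must be charge balanced
    unless ``distant_return`` declares a return electrode at infinity.
    """

    sources: Tuple[ContactSource, ...]
    mode: str = "current"  # current | voltage
    set_amplitude: float = 0.0  # mA (current mode) or V (voltage mode)
    pulse_width_us: float = 60.0
    frequency_hz: float = 130.0
    polarity_signature: str = ""
    distant_return: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("current", "voltage"):
            raise FieldError(f"unknown mode {self.mode!r}")
        if self.pulse_width_us <= 0:
            raise FieldError("pulse_width_us must be > 0")
        if self.frequency_hz <= 0:
            raise FieldError("frequency_hz must be > 0")
        object.__setattr__(self, "sources", tuple(self.sources))
        if self.mode == "current" and len(self.sources) > 1 and not self.distant_return:
            total = sum(s.current for s in self.sources)
            if abs(total) > 1e-9:
                raise FieldError(
                    f"bipolar configuration not charge-balanced "
                    f"(sum I = {total:g} mA)"
                )

    def scaled(self, factor: float) -> "StimulationProtocol":
        """Protocol with every source current multiplied by ``factor``."""
        return replace(
            self,
            sources=tuple(
                replace(s, current=s.current * factor) for s in self.sources
            ),
        )

    def flipped(self) -> "StimulationProtocol":
        """Polarity-inverted protocol (all currents negated)."""
        return self.scaled(-1.0)


@dataclass(frozen=True)
class FieldSample:
    """Potential (V) and field vector (V/m) at one point."""

    potential: float
    field: Tuple[float, float, float]


def _check_points(
    sources: Sequence[ContactSource], x: np.ndarray
) -> np.ndarray:
    """Return (n_query, n_src, 3) displacement array; guard singularities."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    src = np.asarray([s.position for s in sources], dtype=float)
    disp = x[:, None, :] - src[None, :, :]
    r = np.linalg.norm(disp, axis=2)
    if np.any(r < SINGULARITY_RADIUS):
        raise FieldError(
            f"query point within {SINGULARITY_RADIUS} mm of a source"
        )
    return disp


def potential_at(
    sources: Sequence[ContactSource], sigma: float, x
) -> np.ndarray | float:
    """Extracellular potential (V) of superposed point sources.

    ``x`` may be a single 3-vector or an ``(n, 3)`` array.  With r in mm and
    I in mA the monopole potential is ``I / (4 pi sigma r)`` volts.
    """
    if sigma <= 0:
        raise FieldError("sigma must be > 0")
    scalar_in = np.asarray(x).ndim == 1
    disp = _check_points(sources, x)
    r_mm = np.linalg.norm(disp, axis=2)
    currents = np.asarray([s.current for s in sources])
    v = (currents[None, :] / (4.0 * np.pi * sigma * r_mm)).sum(axis=1)
    return float(v[0]) if scalar_in else v


def efield_at(
    sources: Sequence[ContactSource], sigma: float, x
) -> np.ndarray:
    """Electric field vector(s) (V/m), ``E = -grad V``.

    Returns shape ``(3,)`` for a single query point, ``(n, 3)`` for a batch.
    """
    if sigma <= 0:
        raise FieldError("sigma must be > 0")
    scalar_in = np.asarray(x).ndim == 1
    disp = _check_points(sources, x)
    r_mm = np.linalg.norm(disp, axis=2)
    currents = np.asarray([s.current for s in sources])
    # I[mA]/(4 pi sigma r[mm]^2) is V/mm -> x1000 for V/m
    coef = 1000.0 * currents[None, :] / (4.0 * np.pi * sigma * r_mm**3)
    e = (coef[:, :, None] * disp).sum(axis=1)
    return e[0] if scalar_in else e


_POLARITY_RE = re.compile(r"(\d+)\s*([+-])")


def parse_polarity(signature: str) -> List[Tuple[int, int]]:
    """Parse ``"1+2-"`` style signatures to [(contact_index, sign), ...]."""
    matches = _POLARITY_RE.findall(signature)
    cleaned = re.sub(r"[\s]", "", signature)
    reconstructed = "".join(f"{c}{s}" for c, s in matches)
    if not matches or reconstructed != cleaned:
        raise FieldError(f"unparseable polarity signature {signature!r}")
    return [(int(c), 1 if s == "+" else -1) for c, s in matches]


def voltage_to_current(
    protocol: StimulationProtocol,
    sigma: float = DEFAULT_SIGMA,
    contact_radius: float = DEFAULT_CONTACT_RADIUS,
    contact_positions: Optional[Sequence[Tuple[float, float, float]]] = None,
) -> StimulationProtocol:
    """Convert a voltage-controlled protocol to current control.

    Uses the isolated-sphere access-resistance approximation: a contact of
    equivalent sphere radius ``r_c`` driven at ``V_set`` injects
    ``I = 4 pi sigma r_c V_set``.  Signs are taken from the polarity
    signature; cathodes carry ``-I``, anodes ``+I``, so bipolar settings come
    out charge balanced.  ``contact_positions`` maps contact indices in the
    signature to positions; if omitted, ``protocol.sources`` must already
    hold one source per signature entry, in order.
    """
    if protocol.mode != "voltage":
        raise FieldError("protocol is not voltage-controlled")
    if contact_radius <= 0:
        raise FieldError("contact_radius must be > 0")
    roles = parse_polarity(protocol.polarity_signature)
    # SI: 4*pi*sigma*r_c[m]*V -> amps; express in mA
    i_mag = 4.0 * np.pi * sigma * (contact_radius * 1e-3) * protocol.set_amplitude
    i_mag_ma = i_mag * 1e3
    if contact_positions is not None:
        positions = [tuple(contact_positions[c]) for c, _ in roles]
    else:
        if len(protocol.sources) != len(roles):
            raise FieldError(
                "protocol sources do not match polarity signature entries"
            )
        positions = [s.position for s in protocol.sources]
    new_sources = tuple(
        ContactSource(position=pos, current=sign * i_mag_ma)
        for pos, (_, sign) in zip(positions, roles)
    )
    return replace(protocol, sources=new_sources, mode="current")


@dataclass(frozen=True)
class PointSourceField:
    """Analytic field provider bundling sources and conductivity."""

    sources: Tuple[ContactSource, ...]
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if self.sigma <= 0:
            raise FieldError("sigma must be > 0")

    @classmethod
    def from_protocol(
        cls, protocol: StimulationProtocol, sigma: float = DEFAULT_SIGMA
    ) -> "PointSourceField":
        if protocol.mode != "current":
            protocol = voltage_to_current(protocol, sigma=sigma)
        return cls(sources=protocol.sources, sigma=sigma)

    def potential(self, x) -> np.ndarray | float:
        return potential_at(self.sources, self.sigma, x)

    def efield(self, x) -> np.ndarray:
        return efield_at(self.sources, self.sigma, x)


# ---------------------------------------------------------------------------
# Imported field grids (NIfTI)
# ---------------------------------------------------------------------------

@dataclass
class GridField:
    """Vector field on a regular lattice with an affine voxel->mm map.

    ``values`` has shape ``(nx, ny, nz, 3)`` (Ex, Ey, Ez in V/m); optional
    ``potential_values`` is ``(nx, ny, nz)`` in volts.  Queries outside the
    lattice raise — no extrapolation.
    """

    values: np.ndarray
    affine: np.ndarray
    potential_values: Optional[np.ndarray] = None
    _interp: object = dc_field(init=False, repr=False, default=None)
    _pot_interp: object = dc_field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        from scipy.interpolate import RegularGridInterpolator

        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4 or v.shape[3] != 3:
            raise FieldError("grid values must have shape (nx, ny, nz, 3)")
        if min(v.shape[:3]) < 2:
            raise FieldError("lattice needs >= 2 samples per axis")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-15:
            raise FieldError("affine must be an invertible 4x4 matrix")
        self.values = v
        self.affine = aff
        axes = [np.arange(n, dtype=float) for n in v.shape[:3]]
        self._interp = RegularGridInterpolator(
            axes, v, method="linear", bounds_error=True
        )
        if self.potential_values is not None:
            p = np.asarray(self.potential_values, dtype=float)
            if p.shape != v.shape[:3]:
                raise FieldError("potential lattice shape mismatch")
            self.potential_values = p
            self._pot_interp = RegularGridInterpolator(
                axes, p, method="linear", bounds_error=True
            )

    def _to_voxel(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        inv = np.linalg.inv(self.affine)
        return x @ inv[:3, :3].T + inv[:3, 3]

    def efield(self, x) -> np.ndarray:
        scalar_in = np.asarray(x).ndim == 1
        try:
            e = self._interp(self._to_voxel(x))
        except ValueError as err:
            raise FieldError(f"query outside grid domain: {err}") from None
        return e[0] if scalar_in else e

    def potential(self, x) -> np.ndarray | float:
        if self._pot_interp is None:
            raise FieldError("grid carries no potential lattice")
        scalar_in = np.asarray(x).ndim == 1
        try:
            p = self._pot_interp(self._to_voxel(x))
        except ValueError as err:
            raise FieldError(f"query outside grid domain: {err}") from None
        return float(p[0]) if scalar_in else p


def grid_sample(grid: GridField, x) -> FieldSample:
    """Trilinearly interpolated :class:`FieldSample` at a single point."""
    e = grid.efield(np.asarray(x, dtype=float))
    pot = grid.potential(x) if grid._pot_interp is not None else float("nan")
    return FieldSample(potential=pot, field=tuple(np.asarray(e, dtype=float)))


def load_field_grid(path: Path) -> GridField:
    """Read a 4-D NIfTI field grid: 3 field components, optional 4th
    volume holding the scalar potential."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4 or data.shape[3] not in (3, 4):
        raise FieldError(
            f"{path}: expected 4-D NIfTI with 3 (or 3+1) components, "
            f"got shape {data.shape}"
        )
    pot = data[..., 3] if data.shape[3] == 4 else None
    return GridField(values=data[..., :3], affine=img.affine,
                     potential_values=pot)


def save_field_grid(grid: GridField, path: Path) -> Path:
    """Write a :class:`GridField` (plus potential, if any) as 4-D NIfTI."""
    import nibabel as nib

    if grid.potential_values is not None:
        data = np.concatenate(
            [grid.values, grid.potential_values[..., None]], axis=3
        )
    else:
        data = grid.values
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))
    return Path(path)
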