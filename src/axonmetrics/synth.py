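"""Seeded synthetic fixtures: fibre atlases, electrodes, protocols, cohorts.

Everything downstream is testable without any clinical download: the
generators build a four-level DBS lead, fibre bundles of controlled
geometry around it (passing perpendicular, parallel, short-terminating near
a contact, and crossing the lead body), and a patient cohort whose outcome
is driven — by construction — by activation of one designated pathway.

Geometry emulates an STN-like implantation in a template-like frame: the
mid-sagittal plane is x = 0, the right-hemisphere lead sits near
(+12, -13, -7) mm, and the left hemisphere is the exact mirror image.  No
attempt is made to mimic real pathway shapes; bundle *orientations relative
to the lead* are what the activation metrics are sensitive to, and those
are controlled explicitly.

All randomness flows from one integer seed through named
:class:`numpy.random.SeedSequence` substreams, so atlas, protocols and
outcomes are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .axon import PulseWaveform
from .field_metrics import MetricConfig, fiber_metric
from .fibers import Fiber, PathwayAtlas, mirror_fibers
from .volume_conductor import (ContactSource, PointSourceField,
                               StimulationProtocol, voltage_to_current,
                               DEFAULT_CONTACT_RADIUS, DEFAULT_SIGMA)

__all__ = [
    "Electrode",
    "BundleSpec",
    "SyntheticAtlasSpec",
    "SyntheticCohortSpec",
    "make_electrode",
    "make_synthetic_atlas",
    "make_cohort",
    "default_atlas_spec",
    "LEAD_RADIUS_MM",
]

#: lead body radius (mm), cylindrical-contact equivalent
LEAD_RADIUS_MM = 0.635

#: default right-hemisphere lead tip, STN-like target in a template frame
DEFAULT_TIP = (12.0, -13.0, -10.0)


@dataclass(frozen=True)
class Electrode:
    """Four-level omnidirectional lead: contact centres on a straight axis."""

    tip: Tuple[float, float, float]
    axis: Tuple[float, float, float]
    contact_spacing_mm: float
    contact_positions: np.ndarray  # (4, 3)
    radius_mm: float = LEAD_RADIUS_MM

    def mirrored(self) -> "Electrode":
        """The homologous lead in the opposite hemisphere (x -> -x)."""
        flip = np.array([-1.0, 1.0, 1.0])
        return Electrode(
            tip=tuple(np.asarray(self.tip) * flip),
            axis=tuple(np.asarray(self.axis) * flip),
            contact_spacing_mm=self.contact_spacing_mm,
            contact_positions=self.contact_positions * flip,
            radius_mm=self.radius_mm,
        )

    def min_distance_to_axis(self, points: np.ndarray) -> float:
        """Minimum distance from a polyline to the lead axis segment."""
        a = np.asarray(self.tip, dtype=float)
        b = self.contact_positions[-1] + np.asarray(self.axis) * (
            2.0 * self.contact_spacing_mm
        )
        ab = b - a
        t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
        nearest = a + t[:, None] * ab
        return float(np.min(np.linalg.norm(points - nearest, axis=1)))

    def intersects(self, points: np.ndarray) -> bool:
        return self.min_distance_to_axis(points) < self.radius_mm


def make_electrode(
    tip: Sequence[float] = DEFAULT_TIP,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    contact_spacing_mm: float = 2.0,
) -> Electrode:
    """Four contact centres along ``axis`` starting at ``tip``."""
    ax = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(ax)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError("axis must be a unit vector")
    ax = ax / norm
    contacts = np.asarray(tip, dtype=float)[None, :] + (
        contact_spacing_mm * np.arange(4.0)[:, None] * ax[None, :]
    )
    return Electrode(
        tip=tuple(np.asarray(tip, dtype=float)),
        axis=tuple(ax),
        contact_spacing_mm=contact_spacing_mm,
        contact_positions=contacts,
    )


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BundleSpec:
    """One synthetic bundle: template geometry plus per-fibre scatter.

    ``offset_mm`` is the template's closest distance to the lead axis;
    ``orientation`` the fibre run direction; ``spread_mm`` a systematic
    fan-out of fibre offsets across the bundle (so activation varies
    across stimulation amplitudes); ``jitter_sd_mm`` adds seeded Gaussian
    scatter on top.
    """

    label: str
    geometry: str  # straight | arc | helix
    n_fibers: int
    offset_mm: float
    orientation: Tuple[float, float, float]
    length_mm: float
    jitter_sd_mm: float = 0.3
    spread_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.jitter_sd_mm < 0:
            raise ValueError("jitter_sd_mm must be >= 0")
        if self.geometry not in ("straight", "arc", "helix"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass(frozen=True)
class SyntheticAtlasSpec:
    bundles: Tuple[BundleSpec, ...]
    seed: int = 0
    points_per_fiber: int = 41

    def __post_init__(self) -> None:
        object.__setattr__(self, "bundles", tuple(self.bundles))


def default_atlas_spec(seed: int = 0) -> SyntheticAtlasSpec:
    """Five bundles covering the geometries the metrics disagree on.

    * ``motor_hyperdirect`` — perpendicular passing bundle, fanned offsets
      (the designated effect pathway in the default cohort);
    * ``pallidosubthalamic`` — short bundle terminating near the contacts
      (the scenario where anodic vs cathodic placement matters);
    * ``cerebellothalamic`` — close bundle parallel to the lead;
    * ``corticospinal`` — remote parallel bundle;
    * ``lead_crossing`` — traverses the lead cylinder, hence flagged.
    """
    return SyntheticAtlasSpec(
        bundles=(
            BundleSpec("motor_hyperdirect", "straight", 60, 1.2,
                       (0.0, 1.0, 0.0), 24.0, jitter_sd_mm=0.2,
                       spread_mm=2.2),
            BundleSpec("pallidosubthalamic", "straight", 30, 1.8,
                       (1.0, 0.0, 0.0), 7.0, jitter_sd_mm=0.2,
                       spread_mm=2.5),
            BundleSpec("cerebellothalamic", "helix", 30, 2.8,
                       (0.0, 0.0, 1.0), 20.0, jitter_sd_mm=0.25,
                       spread_mm=2.5),
            BundleSpec("corticospinal", "arc", 30, 6.0,
                       (0.0, 0.0, 1.0), 26.0, jitter_sd_mm=0.3,
                       spread_mm=2.0),
            BundleSpec("lead_crossing", "straight", 10, 0.0,
                       (0.0, 1.0, 0.0), 14.0, jitter_sd_mm=0.2,
                       spread_mm=0.3),
        ),
        seed=seed,
    )


def _template_curve(spec: BundleSpec, electrode: Electrode,
                    n_pts: int) -> np.ndarray:
    """Template polyline for a bundle, anchored near the contact array."""
    centre = electrode.contact_positions.mean(axis=0)
    ax = np.asarray(electrode.axis)
    ori = np.asarray(spec.orientation, dtype=float)
    ori = ori / np.linalg.norm(ori)
    # radial direction: perpendicular to both the run direction and the axis
    # when possible, else any perpendicular to the run direction
    radial = np.cross(ax, ori)
    if np.linalg.norm(radial) < 1e-6:
        radial = np.cross(ori, (1.0, 0.0, 0.0))
        if np.linalg.norm(radial) < 1e-6:
            radial = np.cross(ori, (0.0, 1.0, 0.0))
    radial = radial / np.linalg.norm(radial)
    anchor = centre + spec.offset_mm * radial
    t = np.linspace(-0.5, 0.5, n_pts)
    if spec.geometry == "straight":
        if spec.label == "pallidosubthalamic" or spec.length_mm < 10.0:
            # short bundle: one end terminates near the contacts
            start = anchor
            return start[None, :] + np.outer(
                (t + 0.5) * spec.length_mm, ori
            )
        return anchor[None, :] + np.outer(t * spec.length_mm, ori)
    if spec.geometry == "arc":
        # circular arc bowing away from the lead in the (ori, radial) plane
        radius = spec.length_mm
        half_angle = 0.5 * spec.length_mm / radius
        ang = t * 2.0 * half_angle
        return (
            anchor[None, :]
            + radius * np.outer(np.sin(ang), ori)
            + radius * np.outer(1.0 - np.cos(ang), radial)
        )
    # helix: gentle spiral advancing along ori
    turns = 1.0
    ang = t * 2.0 * np.pi * turns
    perp1 = radial
    perp2 = np.cross(ori, radial)
    wobble = 0.15 * spec.offset_mm
    return (
        anchor[None, :]
        + np.outer(t * spec.length_mm, ori)
        + wobble * np.outer(np.cos(ang) - np.cos(ang[0]), perp1)
        + wobble * np.outer(np.sin(ang) - np.sin(ang[0]), perp2)
    )


def make_synthetic_atlas(
    spec: SyntheticAtlasSpec,
    electrode: Optional[Electrode] = None,
    hemisphere: str = "right",
) -> PathwayAtlas:
    """Generate the labelled fibre bundles around a lead.

    Fibres are translated copies of each bundle's template: a systematic
    fan-out (``spread_mm``, moving fibres away from the lead) plus seeded
    isotropic jitter.  Fibres whose polyline enters the lead cylinder are
    flagged.  Output is byte-reproducible for a given spec.
    """
    electrode = electrode or make_electrode()
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(len(spec.bundles))
    fibers: List[Fiber] = []
    fid = 0
    for bundle, ss in zip(spec.bundles, streams):
        rng = np.random.default_rng(ss)
        template = _template_curve(bundle, electrode, spec.points_per_fiber)
        ori = np.asarray(bundle.orientation, dtype=float)
        ori = ori / np.linalg.norm(ori)
        ax = np.asarray(electrode.axis)
        radial = np.cross(ax, ori)
        if np.linalg.norm(radial) < 1e-6:
            radial = np.cross(ori, (1.0, 0.0, 0.0))
        radial = radial / np.linalg.norm(radial)
        for i in range(bundle.n_fibers):
            frac = i / max(bundle.n_fibers - 1, 1)
            shift = (frac * bundle.spread_mm) * radial
            shift = shift + rng.normal(0.0, bundle.jitter_sd_mm, size=3)
            pts = template + shift[None, :]
            fibers.append(
                Fiber(
                    fiber_id=fid,
                    points=pts,
                    pathway=bundle.label,
                    hemisphere=hemisphere,
                    flagged=electrode.intersects(pts),
                )
            )
            fid += 1
    return PathwayAtlas.from_fibers(fibers, space_tag="synthetic-RAS")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort generator settings.

    Outcomes are planted as
    ``baseline + effect_size * activated_fraction(effect_pathway) + noise``
    where the activated fraction uses the generator's reference metric
    (binary field magnitude >= 200 V/m, peak aggregation) in the stimulated
    hemisphere.  Defaults mirror the clinical cohort shape: 15 patients,
    bilateral bipolar settings, voltages 0.5–8.3 V, pulse widths 60–90 µs.
    """

    n_patients: int = 15
    effect_pathway: str = "motor_hyperdirect"
    effect_size: float = 40.0  # outcome % per unit activated fraction
    noise_sd: float = 5.0  # %
    baseline: float = 20.0  # %
    seed: int = 0
    voltage_range: Tuple[float, float] = (0.5, 8.3)
    pulse_widths_us: Tuple[float, ...] = (60.0, 70.0, 80.0, 90.0)
    frequency_hz: float = 130.0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortStimulation:
    """One generated stimulation: protocol plus bookkeeping."""

    patient_id: int
    hemisphere: str
    protocol: StimulationProtocol  # current-mode, resolved sources
    voltage: float
    signature: str
    active_contact_positions: np.ndarray  # (2, 3)


def _reference_activation(
    atlas: PathwayAtlas, field: PointSourceField, pathway: str
) -> float:
    """Fraction of a pathway's fibres activated under the reference metric."""
    cfg = MetricConfig(metric="magnitude", aggregator="peak")
    fibers = atlas.pathways[pathway]
    n_act = sum(
        1 for f in fibers if fiber_metric(f, field, cfg).binary
    )
    return n_act / len(fibers)


def make_cohort(
    spec: SyntheticCohortSpec,
    atlas: PathwayAtlas,
    electrode: Optional[Electrode] = None,
    sigma: float = DEFAULT_SIGMA,
) -> tuple[pd.DataFrame, List[CohortStimulation]]:
    """Generate bilateral bipolar stimulations and planted outcomes.

    ``atlas``/``electrode`` describe the right hemisphere; the left is
    their exact mirror.  Per patient and hemisphere: a random adjacent
    contact pair with random polarity order, a random voltage and pulse
    width, converted to a charge-balanced current-mode protocol.  Returns
    the cohort table (patient_id, hemisphere, outcome_percent, protocol
    descriptors, planted activated fraction) and the stimulation list.
    """
    electrode = electrode or make_electrode()
    if spec.effect_pathway not in atlas.pathways:
        raise ValueError(
            f"effect pathway {spec.effect_pathway!r} not in atlas"
        )
    atlas_by_hemi = {"right": atlas, "left": mirror_fibers(atlas)}
    electrode_by_hemi = {"right": electrode, "left": electrode.mirrored()}
    root = np.random.SeedSequence(spec.seed)
    proto_rng = np.random.default_rng(root.spawn(2)[0])
    noise_rng = np.random.default_rng(root.spawn(2)[1])

    rows = []
    stims: List[CohortStimulation] = []
    for pid in range(1, spec.n_patients + 1):
        for hemi in ("right", "left"):
            el = electrode_by_hemi[hemi]
            pair = int(proto_rng.integers(0, 3))  # adjacent contacts
            anode_first = bool(proto_rng.integers(0, 2))
            lo, hi = (pair, pair + 1) if anode_first else (pair + 1, pair)
            signature = f"{lo}+{hi}-"
            voltage = float(proto_rng.uniform(*spec.voltage_range))
            pw = float(proto_rng.choice(spec.pulse_widths_us))
            proto_v = StimulationProtocol(
                sources=(
                    ContactSource(tuple(el.contact_positions[lo]), 0.0),
                    ContactSource(tuple(el.contact_positions[hi]), 0.0),
                ),
                mode="voltage",
                set_amplitude=voltage,
                pulse_width_us=pw,
                frequency_hz=spec.frequency_hz,
                polarity_signature=signature,
            )
            proto_i = voltage_to_current(
                proto_v, sigma=sigma, contact_radius=el.radius_mm
            )
            field = PointSourceField.from_protocol(proto_i, sigma=sigma)
            frac = _reference_activation(
                atlas_by_hemi[hemi], field, spec.effect_pathway
            )
            outcome = (
                spec.baseline
                + spec.effect_size * frac
                + noise_rng.normal(0.0, spec.noise_sd)
            )
            active_pos = np.stack(
                [el.contact_positions[lo], el.contact_positions[hi]]
            )
            stims.append(
                CohortStimulation(
                    patient_id=pid, hemisphere=hemi, protocol=proto_i,
                    voltage=voltage, signature=signature,
                    active_contact_positions=active_pos,
                )
            )
            rows.append(
                dict(
                    patient_id=pid,
                    hemisphere=hemi,
                    contacts=signature,
                    voltage_v=voltage,
                    pulse_width_us=pw,
                    frequency_hz=spec.frequency_hz,
                    effect_fraction=frac,
                    outcome_percent=outcome,
                )
            )
    return pd.DataFrame(rows), stims
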