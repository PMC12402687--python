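"""End-to-end orchestration: cohort -> activation matrices -> statistics.

One stimulation means one hemisphere of one patient.  Left-hemisphere
stimulations are evaluated on the mirrored atlas and their fibre columns
folded back onto the right-hemisphere homologues, which doubles the number
of rows in every activation matrix (the 'mirroring' step of the group
analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .axon import PulseWaveform
from .field_metrics import MetricConfig, atlas_metrics
from .fibers import MIRROR_ID_OFFSET, PathwayAtlas, mirror_fibers
from .group_stats import (FiberFilter, compare_profiles_spearman,
                          fold_mirrored_matrix, pathway_profile)
from .pam import (PRUNE_DRIVE_PTP_MV, flagged_fiber_rule, pam_dataframe,
                  ppam_atlas)
from .synth import CohortStimulation
from .volume_conductor import PointSourceField

__all__ = [
    "MetricRun",
    "compute_metric_matrices",
    "compute_pam_matrices",
    "profile_correlations",
    "METRIC_COLUMNS",
]

#: activation-matrix variants produced per metric family
METRIC_COLUMNS = {
    "magnitude": ("binary", "probability"),
    "projection": ("binary", "probability"),
    "pam": ("p_A", "binary_full", "binary_any"),
}


@dataclass
class MetricRun:
    """Per-stimulation fibre tables plus folded activation matrices."""

    tables: List[pd.DataFrame]  # one per stimulation, atlas order
    matrices: Dict[str, pd.DataFrame]  # variant -> (n_stim x n_fibers)


def _fold_columns(ids: Sequence[int]) -> List[int]:
    return [i - MIRROR_ID_OFFSET if i >= MIRROR_ID_OFFSET else i for i in ids]


def compute_metric_matrices(
    atlas: PathwayAtlas,
    stims: Sequence[CohortStimulation],
    config: MetricConfig,
    sigma: float = 0.1,
) -> MetricRun:
    """Field-metric activation matrices for a cohort.

    Rows follow ``stims`` order; columns are right-hemisphere fiber_ids
    (left-hemisphere results folded onto homologues).
    """
    mirrored = mirror_fibers(atlas)
    per_hemi = {"right": atlas, "left": mirrored}
    tables = []
    bin_rows, prob_rows = [], []
    for stim in stims:
        a = per_hemi[stim.hemisphere]
        field = PointSourceField.from_protocol(stim.protocol, sigma=sigma)
        df = atlas_metrics(a, field, config)
        df["fiber_id"] = _fold_columns(df["fiber_id"].tolist())
        df = df.sort_values("fiber_id").reset_index(drop=True)
        tables.append(df)
        bin_rows.append(df.set_index("fiber_id")["binary"].astype(float))
        prob_rows.append(df.set_index("fiber_id")["probability"])
    return MetricRun(
        tables=tables,
        matrices={
            "binary": pd.DataFrame(bin_rows).reset_index(drop=True),
            "probability": pd.DataFrame(prob_rows).reset_index(drop=True),
        },
    )


def compute_pam_matrices(
    atlas: PathwayAtlas,
    stims: Sequence[CohortStimulation],
    waveform_amplitude: float = 1.0,
    sigma: float = 0.1,
    n_diameters: int = 10,
    dt_us: float = 5.0,
    prune_drive_ptp_mv: Optional[float] = PRUNE_DRIVE_PTP_MV,
) -> MetricRun:
    """Probabilistic-PAM activation matrices for a cohort.

    Per stimulation: batched pPAM over the hemisphere atlas (flagged fibres
    skipped), then the Euclidean flagged-fibre rule assigns verdicts using
    fibres with p(A) = 1 as the activated reference set.
    """
    mirrored = mirror_fibers(atlas)
    per_hemi = {"right": atlas, "left": mirrored}
    tables = []
    rows: Dict[str, list] = {k: [] for k in METRIC_COLUMNS["pam"]}
    for stim in stims:
        a = per_hemi[stim.hemisphere]
        field = PointSourceField.from_protocol(stim.protocol, sigma=sigma)
        waveform = PulseWaveform(
            amplitude_scale=waveform_amplitude,
            pulse_width_us=stim.protocol.pulse_width_us,
        )
        results, _excluded = ppam_atlas(
            a, field, waveform, n=n_diameters, dt_us=dt_us,
            prune_drive_ptp_mv=prune_drive_ptp_mv,
        )
        activated_ref = [
            a.get(fid) for fid, r in results.items() if r.probability == 1.0
        ]
        flagged = [f for f in a if f.flagged]
        verdicts = flagged_fiber_rule(
            flagged, activated_ref, stim.active_contact_positions
        )
        df = pam_dataframe(a, results, verdicts)
        df["fiber_id"] = _fold_columns(df["fiber_id"].tolist())
        df = df.sort_values("fiber_id").reset_index(drop=True)
        tables.append(df)
        idx = df.set_index("fiber_id")
        rows["p_A"].append(idx["p_A"])
        rows["binary_full"].append(idx["binary_full"].astype(float))
        rows["binary_any"].append(idx["binary_any"].astype(float))
    return MetricRun(
        tables=tables,
        matrices={
            k: pd.DataFrame(v).reset_index(drop=True)
            for k, v in rows.items()
        },
    )


def profile_correlations(
    atlas: PathwayAtlas,
    runs: Dict[str, MetricRun],
    variant_by_metric: Dict[str, str],
    prob_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Spearman correlation of pathway activation profiles per stimulation.

    For every pair of metrics and every stimulation, compute the two
    pathway profiles and their rank correlation; returns a long frame with
    columns (stim, metric_a, metric_b, rho, p).  Stimulations where a
    profile is constant (no variation to rank) are skipped.
    """
    names = list(runs)
    out = []
    first = runs[names[0]]
    n_stims = first.matrices[variant_by_metric[names[0]]].shape[0]
    for s in range(n_stims):
        profiles = {}
        for name in names:
            run = runs[name]
            variant = variant_by_metric[name]
            mat = run.matrices[variant]
            acts = dict(mat.iloc[s])
            profiles[name] = pathway_profile(
                atlas, {int(k): float(v) for k, v in acts.items()},
                prob_cutoff=prob_cutoff,
            )
        for i, na in enumerate(names):
            for nb in names[i + 1:]:
                try:
                    cmp_ = compare_profiles_spearman(profiles[na],
                                                     profiles[nb])
                except ValueError:
                    continue
                out.append(dict(stim=s, metric_a=na, metric_b=nb,
                                rho=cmp_.rho, p=cmp_.p_value))
    return pd.DataFrame(out)
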