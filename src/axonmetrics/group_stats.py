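"""Group-level fibre-filtering statistics linking activation to outcomes.

Given a cohort of stimulations (rows) and per-fibre activation values
(columns, binary or probabilistic), fibre filtering contrasts the clinical
outcome (e.g. % UPDRS-III improvement) between stimulations that do and do
not activate each fibre, via an unpaired two-sample t-test or its
probability-weighted analogue.  Pathway activation profiles (% of fibres
activated per pathway) and their Spearman comparisons quantify agreement
between activation metrics.

The modelling surface follows the statsmodels idiom: build a
:class:`FiberFilter` from the activation matrix and outcomes, call
:meth:`~FiberFilter.fit`, and read estimates off the returned
:class:`FiberFilterResults` (per-fibre T-values, top-k pathway distribution,
``summary()``).  The underlying operations are importable functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fibers import MIRROR_ID_OFFSET, PathwayAtlas

__all__ = [
    "ActivationProfile",
    "FiberStat",
    "ProfileComparison",
    "pathway_profile",
    "compare_profiles_spearman",
    "compare_correlation_sets",
    "prevalence_filter",
    "fiber_ttest",
    "weighted_fiber_ttest",
    "weighted_odds_ratio",
    "top_fiber_distribution",
    "fold_mirrored_matrix",
    "FiberFilter",
    "FiberFilterResults",
    "DEFAULT_PROB_CUTOFF",
    "DEFAULT_MIN_FRAC",
    "DEFAULT_TOP_K",
]

#: p(A) cutoff for binarizing probabilistic activations
DEFAULT_PROB_CUTOFF = 0.5
#: minimum fraction of stimulations in which a fibre must be activated
DEFAULT_MIN_FRAC = 0.2
#: number of highest-T fibres summarized per pathway
DEFAULT_TOP_K = 100


class StatsError(ValueError):
    """Data inconsistency in the group-level statistics."""


@dataclass(frozen=True)
class FiberStat:
    """Per-fibre outcome contrast."""

    fiber_id: int
    t_value: float
    n_act: float
    n_nonact: float
    included: bool
    defined: bool = True


@dataclass(frozen=True)
class ProfileComparison:
    """Spearman comparison of two pathway activation profiles."""

    rho: float
    p_value: float
    n_pathways: int


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def pathway_profile(
    atlas: PathwayAtlas,
    fiber_activations: Dict[int, float],
    prob_cutoff: float = DEFAULT_PROB_CUTOFF,
) -> Dict[str, float]:
    """Per-pathway percentage of activated fibres (0–100).

    ``fiber_activations`` maps fiber_id to a binary {0,1} or probabilistic
    [0,1] activation; probabilistic values are binarized at ``prob_cutoff``
    (>= convention).  Fibres absent from the map count as not activated;
    ids absent from the atlas raise.
    """
    known = set(atlas.fiber_ids)
    unknown = set(fiber_activations) - known
    if unknown:
        raise StatsError(f"activation for unknown fiber_ids {sorted(unknown)[:5]}")
    profile: Dict[str, float] = {}
    for pathway, fibers in atlas.pathways.items():
        n = len(fibers)
        n_act = sum(
            1 for f in fibers
            if fiber_activations.get(f.fiber_id, 0.0) >= prob_cutoff
        )
        profile[pathway] = 100.0 * n_act / n
    return profile


def compare_profiles_spearman(
    a: Dict[str, float], b: Dict[str, float]
) -> ProfileComparison:
    """Spearman rank correlation between two activation profiles.

    Pathway key sets must match and hold at least 3 entries; ties receive
    average ranks and the p-value uses the t-approximation.  Constant
    profiles have no defined rank correlation and raise.
    """
    if set(a) != set(b):
        raise StatsError("profiles cover different pathway sets")
    keys = sorted(a)
    if len(keys) < 3:
        raise StatsError("need >= 3 pathways")
    xa = np.array([a[k] for k in keys])
    xb = np.array([b[k] for k in keys])
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise StatsError("constant profile: correlation undefined")
    rho, p = sps.spearmanr(xa, xb)
    return ProfileComparison(rho=float(rho), p_value=float(p),
                             n_pathways=len(keys))


def compare_correlation_sets(
    rhos_a: Sequence[float],
    rhos_b: Sequence[float],
    clamp: bool = False,
) -> tuple[float, float]:
    """Paired two-tailed t-test on Fisher z-transformed correlations.

    Each correlation is mapped through ``z = atanh(rho)`` to stabilize the
    variance, then the two lists are compared with a paired t-test.
    ``|rho| = 1`` has infinite z; pass ``clamp=True`` to nudge such values
    inside the open interval instead of raising.
    """
    ra = np.asarray(rhos_a, dtype=float)
    rb = np.asarray(rhos_b, dtype=float)
    if ra.shape != rb.shape or ra.size < 3:
        raise StatsError("need two equal-length lists of >= 3 correlations")
    if np.any(np.abs(ra) >= 1) or np.any(np.abs(rb) >= 1):
        if not clamp:
            raise StatsError(
                "|rho| = 1 cannot be z-transformed (use clamp=True)"
            )
        eps = 1e-12
        ra = np.clip(ra, -1 + eps, 1 - eps)
        rb = np.clip(rb, -1 + eps, 1 - eps)
    za, zb = np.arctanh(ra), np.arctanh(rb)
    if np.allclose(za, zb):
        return 0.0, 1.0
    t, p = sps.ttest_rel(za, zb)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Fibre-wise tests
# ---------------------------------------------------------------------------

def prevalence_filter(
    matrix: pd.DataFrame,
    min_frac: float = DEFAULT_MIN_FRAC,
    prob_cutoff: float = DEFAULT_PROB_CUTOFF,
) -> List[int]:
    """Fibres eligible for the outcome contrast.

    ``matrix`` is stimulations x fibres (columns = fiber_ids) with entries
    in [0, 1].  A fibre is included iff it is activated (entry >=
    ``prob_cutoff``) in at least ``min_frac`` of stimulations *and* not
    activated in at least 2 — without a comparison group the t-statistic
    does not exist.
    """
    if matrix.empty:
        raise StatsError("empty activation matrix")
    binary = matrix.to_numpy(dtype=float) >= prob_cutoff
    n_stim = binary.shape[0]
    n_act = binary.sum(axis=0)
    keep = (n_act / n_stim >= min_frac) & (n_stim - n_act >= 2)
    return [int(c) for c, k in zip(matrix.columns, keep) if k]


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    """Student (pooled-variance) two-sample t; assumes len >= 2 each."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
        nx + ny - 2
    )
    if sp2 == 0:
        return np.nan
    return float((x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny)))


def fiber_ttest(
    matrix: pd.DataFrame,
    outcomes: Sequence[float],
    included: Optional[Sequence[int]] = None,
    welch: bool = False,
) -> List[FiberStat]:
    """Unpaired two-sample t-test per fibre on a *binary* matrix.

    For each fibre, outcomes of stimulations where it was activated are
    compared against those where it was not; T > 0 means the activated
    group improved more.  Pooled-variance Student t by default, Welch
    behind the flag.  No multiple-comparison correction is applied.
    """
    y = np.asarray(outcomes, dtype=float)
    if len(y) != matrix.shape[0]:
        raise StatsError("outcomes length does not match matrix rows")
    vals = matrix.to_numpy(dtype=float)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise StatsError("fiber_ttest needs a binary matrix")
    inc = set(matrix.columns if included is None else included)
    out: List[FiberStat] = []
    for j, fid in enumerate(matrix.columns):
        if fid not in inc:
            out.append(FiberStat(int(fid), np.nan, 0, 0, included=False,
                                 defined=False))
            continue
        mask = vals[:, j] == 1.0
        a, b = y[mask], y[~mask]
        if len(a) < 2 or len(b) < 2:
            out.append(FiberStat(int(fid), np.nan, len(a), len(b),
                                 included=True, defined=False))
            continue
        if welch:
            t = float(sps.ttest_ind(a, b, equal_var=False).statistic)
        else:
            t = _pooled_t(a, b)
        out.append(FiberStat(int(fid), t, len(a), len(b), included=True,
                             defined=np.isfinite(t)))
    return out


def weighted_fiber_ttest(
    matrix: pd.DataFrame,
    outcomes: Sequence[float],
    included: Optional[Sequence[int]] = None,
) -> List[FiberStat]:
    """Probability-weighted unpaired t-test per fibre.

    Stimulation i contributes to the activated group with weight
    ``w_i = p(A)_i`` and to the non-activated group with ``1 - w_i``.
    Group means and pooled variance use these weights, with Kish effective
    sample sizes ``n_eff = (sum w)^2 / sum w^2`` standing in for the group
    counts.  With all weights in {0, 1} this reduces exactly to
    :func:`fiber_ttest`.
    """
    y = np.asarray(outcomes, dtype=float)
    if len(y) != matrix.shape[0]:
        raise StatsError("outcomes length does not match matrix rows")
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise StatsError("weights must lie in [0, 1]")
    inc = set(matrix.columns if included is None else included)
    out: List[FiberStat] = []
    for j, fid in enumerate(matrix.columns):
        if fid not in inc:
            out.append(FiberStat(int(fid), np.nan, 0, 0, included=False,
                                 defined=False))
            continue
        w = vals[:, j]
        u = 1.0 - w
        sw, su = w.sum(), u.sum()
        if sw == 0 or su == 0:
            out.append(FiberStat(int(fid), np.nan, sw, su, included=True,
                                 defined=False))
            continue
        n_a = sw**2 / np.sum(w**2)
        n_b = su**2 / np.sum(u**2)
        mean_a = np.sum(w * y) / sw
        mean_b = np.sum(u * y) / su
        var_a = np.sum(w * (y - mean_a) ** 2) / sw * n_a / max(n_a - 1, 1e-12)
        var_b = np.sum(u * (y - mean_b) ** 2) / su * n_b / max(n_b - 1, 1e-12)
        if n_a <= 1 or n_b <= 1:
            out.append(FiberStat(int(fid), np.nan, n_a, n_b, included=True,
                                 defined=False))
            continue
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        if sp2 <= 0:
            out.append(FiberStat(int(fid), np.nan, n_a, n_b, included=True,
                                 defined=False))
            continue
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        out.append(FiberStat(int(fid), float(t), float(n_a), float(n_b),
                             included=True, defined=np.isfinite(t)))
    return out


def weighted_odds_ratio(
    weights: Sequence[float], binary_outcome: Sequence[int]
) -> tuple[float, tuple[float, float]]:
    """Probability-weighted odds ratio for a binary outcome.

    Builds a weighted 2x2 table (activation-side weight w vs 1-w, outcome
    1 vs 0), applies the Haldane–Anscombe +0.5 correction when any cell is
    empty, and returns the odds ratio with a 95% Wald CI on the log scale.
    """
    w = np.asarray(weights, dtype=float)
    yb = np.asarray(binary_outcome)
    if not np.all(np.isin(yb, (0, 1))):
        raise StatsError("outcome must be binary")
    if yb.min() == yb.max():
        raise StatsError("degenerate outcome vector")
    if np.any(w < 0) or np.any(w > 1):
        raise StatsError("weights must lie in [0, 1]")
    a = float(np.sum(w[yb == 1]))
    b = float(np.sum(w[yb == 0]))
    c = float(np.sum((1 - w)[yb == 1]))
    d = float(np.sum((1 - w)[yb == 0]))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return or_, (float(lo), float(hi))


def top_fiber_distribution(
    stats: Sequence[FiberStat],
    atlas: PathwayAtlas,
    k: int = DEFAULT_TOP_K,
) -> Dict[str, int]:
    """Pathway counts of the k fibres with the highest T-values.

    Only included fibres with defined T enter the ranking; ties at the
    boundary are broken by ascending fiber_id.  If fewer than k fibres are
    available, all are used.
    """
    pathway_of = {f.fiber_id: f.pathway for f in atlas}
    ranked = sorted(
        (s for s in stats if s.included and s.defined),
        key=lambda s: (-s.t_value, s.fiber_id),
    )
    counts = {p: 0 for p in atlas.pathways}
    for s in ranked[:k]:
        counts[pathway_of[s.fiber_id]] += 1
    return counts


def fold_mirrored_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map mirrored fibre columns onto their homologues.

    Columns whose fiber_id carries the mirroring offset are renamed to the
    original id so that stimulations of both hemispheres address one shared
    fibre set (the 'mirroring' that doubles the number of stimulations in
    the fibre-wise tests).
    """
    ren = {
        c: c - MIRROR_ID_OFFSET for c in matrix.columns
        if c >= MIRROR_ID_OFFSET
    }
    return matrix.rename(columns=ren)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class FiberFilter:
    """Fibre-filtering model: per-fibre outcome contrasts for one cohort.

    Parameters
    ----------
    matrix
        Stimulations x fibres activation matrix (columns = fiber_ids,
        entries binary or p(A) in [0, 1]); hemispheres should already be
        folded (see :func:`fold_mirrored_matrix`).
    outcomes
        One continuous outcome per stimulation (e.g. % UPDRS-III
        improvement).
    atlas
        Pathway atlas resolving fiber_ids to pathway labels.

    Examples
    --------
    >>> model = FiberFilter(matrix, outcomes, atlas)      # doctest: +SKIP
    >>> res = model.fit(weighted=True)                    # doctest: +SKIP
    >>> res.top_pathways()                                # doctest: +SKIP
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        outcomes: Sequence[float],
        atlas: PathwayAtlas,
        prob_cutoff: float = DEFAULT_PROB_CUTOFF,
        min_frac: float = DEFAULT_MIN_FRAC,
    ) -> None:
        if matrix.shape[0] != len(outcomes):
            raise StatsError("outcomes length does not match matrix rows")
        self.matrix = matrix
        self.outcomes = np.asarray(outcomes, dtype=float)
        self.atlas = atlas
        self.prob_cutoff = prob_cutoff
        self.min_frac = min_frac

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        atlas: PathwayAtlas,
        outcome_col: str = "outcome_percent",
        **kwargs,
    ) -> "FiberFilter":
        """Build from a tidy frame whose non-outcome columns are fibre ids."""
        fiber_cols = [c for c in df.columns if c != outcome_col]
        matrix = df[fiber_cols].copy()
        matrix.columns = [int(c) for c in fiber_cols]
        return cls(matrix, df[outcome_col].to_numpy(), atlas, **kwargs)

    def fit(self, weighted: bool = False, welch: bool = False
            ) -> "FiberFilterResults":
        """Run the prevalence filter and per-fibre t-tests.

        ``weighted=True`` runs the probability-weighted test on the raw
        [0, 1] entries; otherwise entries are binarized at ``prob_cutoff``
        first.
        """
        included = prevalence_filter(
            self.matrix, self.min_frac, self.prob_cutoff
        )
        if weighted:
            stats_list = weighted_fiber_ttest(
                self.matrix, self.outcomes, included
            )
        else:
            binary = (self.matrix >= self.prob_cutoff).astype(float)
            stats_list = fiber_ttest(
                binary, self.outcomes, included, welch=welch
            )
        return FiberFilterResults(self, stats_list, weighted=weighted)


@dataclass
class FiberFilterResults:
    """Fitted fibre-filtering contrasts."""

    model: FiberFilter
    fiber_stats: List[FiberStat]
    weighted: bool

    @property
    def n_included(self) -> int:
        return sum(1 for s in self.fiber_stats if s.included)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(fiber_id=s.fiber_id, t_value=s.t_value, n_act=s.n_act,
                     n_nonact=s.n_nonact, included=s.included,
                     defined=s.defined)
                for s in self.fiber_stats
            ]
        )

    def top_pathways(self, k: int = DEFAULT_TOP_K) -> Dict[str, int]:
        return top_fiber_distribution(self.fiber_stats, self.model.atlas, k)

    def summary(self, k: int = DEFAULT_TOP_K) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        dist = self.top_pathways(k)
        n_stim = self.model.matrix.shape[0]
        kind = "probability-weighted" if self.weighted else "binary pooled"
        lines = [
            "Fibre filtering results",
            "=" * 47,
            f"stimulations:        {n_stim}",
            f"fibres tested:       {self.model.matrix.shape[1]}",
            f"fibres included:     {self.n_included} "
            f"(prevalence >= {self.model.min_frac:.0%}, "
            f"p(A) cutoff {self.model.prob_cutoff})",
            f"t-test:              {kind} two-sample",
            f"top-{min(k, self.n_included)} fibres by T, per pathway:",
        ]
        for p, c in sorted(dist.items(), key=lambda kv: -kv[1]):
            lines.append(f"    {p:<28s} {c:4d}")
        return "\n".join(lines)
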