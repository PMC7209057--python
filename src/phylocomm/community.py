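"""Count-level manipulations and occurrence summaries.

Rarefaction to a common depth, binarization, genus-level aggregation,
shared/unique ASV intersection counts across areas, and the
generic-richness ANOVA with its normality/homoscedasticity gates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import UNASSIGNED, CommunityMatrix, ValidationError

__all__ = [
    "rarefy",
    "to_presence_absence",
    "drop_empty_taxa",
    "aggregate_by_rank",
    "IntersectionSummary",
    "intersection_summary",
    "richness_anova",
    "AnovaReport",
]


def rarefy(cm: CommunityMatrix, depth: int, seed) -> CommunityMatrix:
    """Subsample every sample, without replacement, to exactly ``depth`` reads.

    A single draw per sample (the analysis consumes one rarefied matrix,
    not an average over draws); fully reproducible given ``seed``.
    """
    depth = int(depth)
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(seed)
    counts = cm.counts.to_numpy()
    totals = counts.sum(axis=0)
    for j, tot in enumerate(totals):
        if tot < depth:
            raise ValidationError(
                f"sample {cm.sample_ids[j]!r} has only {tot} reads (< depth {depth})"
            )
    out = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        col = counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
            continue
        if depth == 0:
            continue
        # multivariate hypergeometric draw = sampling reads w/o replacement
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return replace(cm, counts=pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns))


def to_presence_absence(cm: CommunityMatrix) -> CommunityMatrix:
    """Binary view: 1 iff count > 0; idempotent on binary input."""
    return cm.presence_absence()


def drop_empty_taxa(cm: CommunityMatrix) -> tuple[CommunityMatrix, list[str]]:
    """Drop all-zero taxon rows (e.g. after rarefaction); returns dropped ids."""
    present = cm.counts.sum(axis=1) > 0
    dropped = list(cm.counts.index[~present])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} all-zero taxa", stacklevel=2)
        cm = cm.select_taxa(list(cm.counts.index[present]))
    return cm, dropped


def aggregate_by_rank(cm: CommunityMatrix, rank: str = "genus") -> CommunityMatrix:
    """Sum counts over taxa sharing a label at ``rank``.

    ASVs whose lineage stops above ``rank`` are pooled under the literal
    label ``Unassigned``; per-sample totals are conserved.
    """
    if cm.taxonomy is None:
        raise ValidationError("aggregate_by_rank requires taxonomy")
    labels = [cm.lineage_rank(t, rank) or UNASSIGNED for t in cm.taxon_ids]
    agg = cm.counts.groupby(pd.Index(labels, name="taxon_id"), sort=True).sum()
    return CommunityMatrix(agg)


@dataclass(frozen=True)
class IntersectionSummary:
    """Exclusive-subset (UpSet-style) occurrence counts across areas."""

    group_labels: tuple[str, ...]
    exclusive_counts: dict[frozenset, int]
    totals: dict[str, int]  # ASVs occurring in each area (non-exclusive)

    @property
    def n_taxa(self) -> int:
        return sum(self.exclusive_counts.values())

    def unique_fraction(self, area: str | None = None) -> float:
        """Fraction of ASVs confined to one area (overall or for ``area``)."""
        singletons = {
            next(iter(k)): v for k, v in self.exclusive_counts.items() if len(k) == 1
        }
        if area is None:
            return sum(singletons.values()) / self.n_taxa if self.n_taxa else 0.0
        return singletons.get(area, 0) / self.totals[area] if self.totals.get(area) else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "&".join(sorted(k)), "n_areas": len(k), "count": v}
            for k, v in sorted(
                self.exclusive_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["subset", "n_areas", "count"])


def intersection_summary(
    cm: CommunityMatrix, area_of_sample: dict[str, str]
) -> IntersectionSummary:
    """Assign each ASV to the exact set of areas where it occurs.

    Subsets partition the observed ASV pool: every ASV present somewhere
    lands in exactly one non-empty subset.
    """
    missing = [s for s in cm.sample_ids if s not in area_of_sample]
    if missing:
        raise ValidationError(f"samples without an area label: {missing}")
    areas = tuple(dict.fromkeys(area_of_sample[s] for s in cm.sample_ids))
    pa = cm.presence_absence().counts
    by_area = pa.T.groupby(pd.Index([area_of_sample[s] for s in cm.sample_ids])).max().T
    exclusive: dict[frozenset, int] = {}
    totals = {a: int((by_area[a] > 0).sum()) for a in areas}
    member = by_area > 0
    for t in member.index:
        subset = frozenset(member.columns[member.loc[t]])
        if subset:
            exclusive[subset] = exclusive.get(subset, 0) + 1
    return IntersectionSummary(areas, exclusive, totals)


@dataclass(frozen=True)
class AnovaReport:
    shapiro_p: dict[str, float | None]  # None when n < 3 (gate skipped)
    levene_p: float
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # Tukey HSD: group1, group2, diff, p_adj
    excluded_groups: tuple[str, ...]
    degenerate: bool = False  # all groups constant -> F undefined


def richness_anova(values_by_area: dict[str, np.ndarray]) -> AnovaReport:
    """One-way ANOVA across areas with Shapiro-Wilk and Levene gates.

    Normality is reported per group where n >= 3 (flagged None below
    that, as with under-replicated areas); groups with fewer than two
    observations are excluded with a warning. The post-hoc is Tukey HSD
    with family-wise adjusted p-values.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_area.items()}
    excluded = tuple(k for k, v in groups.items() if v.size < 2)
    if excluded:
        warnings.warn(f"excluding under-replicated groups: {excluded}", stacklevel=2)
        groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValidationError("need at least two groups with n >= 2")
    shapiro_p: dict[str, float | None] = {}
    for k, v in groups.items():
        if v.size >= 3 and np.ptp(v) > 0:
            shapiro_p[k] = float(stats.shapiro(v).pvalue)
        else:
            shapiro_p[k] = None
    vals = list(groups.values())
    if all(np.ptp(v) == 0 for v in vals) and len({v[0] for v in vals}) == 1:
        return AnovaReport(shapiro_p, np.nan, np.nan, np.nan,
                           pd.DataFrame(columns=["group1", "group2", "diff", "p_adj"]),
                           excluded, degenerate=True)
    levene = stats.levene(*vals)
    f, p = stats.f_oneway(*vals)
    degenerate = not np.isfinite(f)
    names = list(groups)
    tk = stats.tukey_hsd(*vals)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group1": names[i],
                "group2": names[j],
                "diff": float(np.mean(vals[i]) - np.mean(vals[j])),
                "p_adj": float(tk.pvalue[i, j]),
            }
        )
    return AnovaReport(
        shapiro_p,
        float(levene.pvalue),
        float(f),
        float(p),
        pd.DataFrame(rows),
        excluded,
        degenerate,
    )
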