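"""Checkerboard-pair and C-score co-occurrence tests under the sim2 null.

For a binary taxa x sites matrix, each unordered taxon pair (i, j)
contributes C_ij = (R_i - S)(R_j - S), where R_i, R_j are the row sums
(occurrence frequencies) and S the number of sites holding both taxa.
The C-score is the mean of C_ij over all pairs; a checkerboard pair is a
pair that never co-occurs (S = 0). High values indicate segregation,
low values aggregation.

The null ensemble is sim2: each row's presences are reshuffled across
sites equiprobably, preserving every taxon's occurrence frequency while
letting site richness vary. Departures are summarized by the
standardized effect size ses = (obs - mean(null)) / sd(null), a
tie-inclusive empirical p-value in each tail, and one-sample t-tests of
the null distribution against the observed value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CommunityMatrix, ValidationError

__all__ = [
    "CooccurrenceStats",
    "NullEnsembleResult",
    "c_score",
    "sim2_null",
    "cooccurrence_test",
    "pool_by_area",
    "run_scales",
]


@dataclass(frozen=True)
class CooccurrenceStats:
    c_score: float
    n_checkerboard_pairs: int
    n_pairs_evaluated: int


@dataclass(frozen=True)
class NullEnsembleResult:
    observed: float
    null_values: np.ndarray = field(repr=False)
    ses: float
    p_upper: float
    p_lower: float
    t_p_upper: float
    t_p_lower: float
    degenerate_null: bool = False

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))


def _as_binary_array(pa: CommunityMatrix | np.ndarray, drop_empty: bool = True) -> np.ndarray:
    m = pa.counts.to_numpy() if isinstance(pa, CommunityMatrix) else np.asarray(pa)
    if not np.isin(m, (0, 1)).all():
        raise ValidationError("co-occurrence statistics need a presence-absence matrix")
    m = m.astype(np.int64)
    if drop_empty:
        occupied = m.sum(axis=1) > 0
        if not occupied.all():
            warnings.warn(
                f"dropping {int((~occupied).sum())} all-zero taxon rows", stacklevel=3
            )
            m = m[occupied]
    return m


def _pair_stats(m: np.ndarray) -> tuple[float, int, int]:
    t = m.shape[0]
    shared = m @ m.T  # S for every pair
    r = m.sum(axis=1)
    iu = np.triu_indices(t, k=1)
    s = shared[iu]
    c = (r[iu[0]] - s) * (r[iu[1]] - s)
    return float(c.mean()), int((s == 0).sum()), len(s)


def c_score(pa: CommunityMatrix | np.ndarray, drop_empty: bool = True) -> CooccurrenceStats:
    """C-score and checkerboard-pair count over all unordered taxon pairs."""
    m = _as_binary_array(pa, drop_empty)
    if m.shape[0] < 2:
        raise ValidationError("need at least two occupied taxa")
    cs, cp, n = _pair_stats(m)
    return CooccurrenceStats(cs, cp, n)


def sim2_null(
    pa: CommunityMatrix | np.ndarray,
    n_reps: int = 10_000,
    seed=None,
    chunk: int = 2_000,
):
    """Yield sim2-randomized matrices: each row reshuffled equiprobably.

    Row sums are preserved exactly on every draw; within a row every
    arrangement of its ones across columns is equally likely; column
    sums vary freely. Matrices are streamed in chunks to bound memory.
    """
    m = _as_binary_array(pa, drop_empty=False)
    rng = np.random.default_rng(seed)
    t, s = m.shape
    rowsums = m.sum(axis=1)
    done = 0
    while done < n_reps:
        k = min(chunk, n_reps - done)
        # ranks of i.i.d. uniforms give an independent uniform permutation
        # of each row in each replicate
        u = rng.random((k, t, s))
        ranks = np.argsort(np.argsort(u, axis=2), axis=2)
        out = (ranks < rowsums[None, :, None]).astype(np.int64)
        yield from out
        done += k


def _empirical_p(null: np.ndarray, obs: float) -> tuple[float, float]:
    n = len(null)
    upper = (np.sum(null >= obs) + 1) / (n + 1)
    lower = (np.sum(null <= obs) + 1) / (n + 1)
    return float(upper), float(lower)


def cooccurrence_test(
    pa: CommunityMatrix | np.ndarray,
    statistic: str = "c_score",
    n_reps: int = 10_000,
    seed=None,
) -> NullEnsembleResult:
    """Observed statistic vs the sim2 ensemble.

    statistic: ``c_score`` or ``checker_pairs``. p_upper is the
    tie-inclusive (count+1)/(reps+1) upper-tail probability that the null
    meets or exceeds the observation; t_p_upper/t_p_lower are one-sample
    t-tests of the null sample against the observed constant
    (upper: alternative null mean < observed).
    """
    if statistic not in {"c_score", "checker_pairs"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    m = _as_binary_array(pa)
    if m.shape[0] < 2:
        raise ValidationError("need at least two occupied taxa")

    def stat(mat: np.ndarray) -> float:
        cs, cp, _ = _pair_stats(mat)
        return cs if statistic == "c_score" else float(cp)

    obs = stat(m)
    null = np.fromiter(
        (stat(x) for x in sim2_null(m, n_reps=n_reps, seed=seed)),
        dtype=float,
        count=n_reps,
    )
    sd = null.std(ddof=1)
    degenerate = not (sd > 0)
    ses = 0.0 if degenerate else float((obs - null.mean()) / sd)
    p_upper, p_lower = _empirical_p(null, obs)
    if degenerate:
        t_p_upper = t_p_lower = 1.0
    else:
        t_p_upper = float(stats.ttest_1samp(null, obs, alternative="less").pvalue)
        t_p_lower = float(stats.ttest_1samp(null, obs, alternative="greater").pvalue)
    return NullEnsembleResult(
        observed=obs,
        null_values=null,
        ses=ses,
        p_upper=p_upper,
        p_lower=p_lower,
        t_p_upper=t_p_upper,
        t_p_lower=t_p_lower,
        degenerate_null=degenerate,
    )


def pool_by_area(pa: CommunityMatrix, sample_to_area: dict[str, str]) -> CommunityMatrix:
    """Pool replicates by area with union-of-presences (logical OR)."""
    missing = [s for s in pa.sample_ids if s not in sample_to_area]
    if missing:
        raise ValidationError(f"samples without an area label: {missing}")
    b = pa.presence_absence().counts
    areas = list(dict.fromkeys(sample_to_area[s] for s in pa.sample_ids))
    pooled = (
        b.T.groupby(pd.Index([sample_to_area[s] for s in pa.sample_ids])).max().T[areas]
    )
    return CommunityMatrix(pooled, taxonomy=pa.taxonomy)


def run_scales(
    pa: CommunityMatrix,
    sample_to_area: dict[str, str],
    statistics: tuple[str, ...] = ("c_score", "checker_pairs"),
    n_reps: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Co-occurrence tests at the three spatial scales of the design.

    * ``regional_replicates`` — all samples, unpooled;
    * ``regional_areas`` — replicates pooled by area (one column per area);
    * ``local:<area>`` — each area's replicates alone (skipped with a
      warning below two replicates).

    Taxa absent at a given scale are dropped there. Returns a tidy table
    with observed value, null mean/sd, ses and all four p-values.
    """
    pa = pa.presence_absence()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    scopes: list[tuple[str, CommunityMatrix]] = [
        ("regional_replicates", pa),
        ("regional_areas", pool_by_area(pa, sample_to_area)),
    ]
    areas = list(dict.fromkeys(sample_to_area[s] for s in pa.sample_ids))
    for a in areas:
        cols = [s for s in pa.sample_ids if sample_to_area[s] == a]
        if len(cols) < 2:
            warnings.warn(f"skipping local scale for {a!r}: <2 replicates", stacklevel=2)
            continue
        scopes.append((f"local:{a}", pa.select_samples(cols)))
    rows = []
    child_seeds = ss.spawn(len(scopes) * len(statistics))
    k = 0
    for scope, mat in scopes:
        for statname in statistics:
            res = cooccurrence_test(mat, statname, n_reps=n_reps, seed=child_seeds[k])
            k += 1
            rows.append(
                {
                    "scope": scope,
                    "statistic": statname,
                    "n_samples": mat.shape[1],
                    "observed": res.observed,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "ses": res.ses,
                    "p_upper": res.p_upper,
                    "p_lower": res.p_lower,
                    "t_p_upper": res.t_p_upper,
                    "t_p_lower": res.t_p_lower,
                    "degenerate_null": res.degenerate_null,
                }
            )
    return pd.DataFrame(rows)
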