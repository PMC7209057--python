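"""Standardized effect sizes of PD/MPD/MNTD and the area-level tests.

For every sample, metric and null model the observed metric is compared
to its distribution over ``n_reps`` randomizations:

    ses = (observed - mean(null)) / sd(null)

Negative ses indicates phylogenetic clustering (co-occurring taxa more
related than chance), positive ses overdispersion. Per area, departure
of the ses values from zero is tested with a one-sample two-tailed
t-test when the Shapiro-Wilk gate accepts normality and the area has at
least three replicates, and with the Wilcoxon signed-rank test
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CommunityMatrix, ValidationError
from .nullmodels import MATRIX_MODELS, NULL_MODELS, permute_labels, randomize_membership
from .phylometrics import mpd_mntd_from_submatrix
from .tree import PhyloTree

__all__ = ["PhyloStructureResult", "ses_metrics", "area_tests"]

METRICS = ("PD", "MPD", "MNTD")


@dataclass
class PhyloStructureResult:
    observed: pd.DataFrame  # samples x metrics
    ses: dict[str, pd.DataFrame]  # model -> samples x metrics
    null_mean: dict[str, pd.DataFrame]
    null_sd: dict[str, pd.DataFrame]
    degenerate: dict[str, pd.DataFrame] = field(default_factory=dict)
    #: tie-inclusive empirical tail probabilities, (count+1)/(reps+1)
    p_upper: dict[str, pd.DataFrame] = field(default_factory=dict)
    p_lower: dict[str, pd.DataFrame] = field(default_factory=dict)

    def tidy(self) -> pd.DataFrame:
        rows = []
        for model, df in self.ses.items():
            for sample in df.index:
                for metric in df.columns:
                    rows.append(
                        {
                            "sample": sample,
                            "metric": metric,
                            "model": model,
                            "observed": self.observed.loc[sample, metric],
                            "null_mean": self.null_mean[model].loc[sample, metric],
                            "null_sd": self.null_sd[model].loc[sample, metric],
                            "ses": df.loc[sample, metric],
                        }
                    )
        return pd.DataFrame(rows)


def _metric_block(
    member: np.ndarray, dist: np.ndarray, et, metrics
) -> np.ndarray:
    """(n_samples x n_metrics) metric values for one membership matrix."""
    n_samples = member.shape[1]
    out = np.full((n_samples, len(metrics)), np.nan)
    if "PD" in metrics:
        out[:, metrics.index("PD")] = et.pd_values(member)
        empty = member.sum(axis=0) == 0
        out[empty, metrics.index("PD")] = np.nan
    need_pairs = [m for m in ("MPD", "MNTD") if m in metrics]
    if need_pairs:
        for j in range(n_samples):
            idx = np.flatnonzero(member[:, j])
            v_mpd, v_mntd = mpd_mntd_from_submatrix(dist[np.ix_(idx, idx)])
            if "MPD" in metrics:
                out[j, metrics.index("MPD")] = v_mpd
            if "MNTD" in metrics:
                out[j, metrics.index("MNTD")] = v_mntd
    return out


def _metric_batch(mats: np.ndarray, dist: np.ndarray, et, metrics) -> np.ndarray:
    """(n_reps x n_samples x n_metrics) metrics for a stack of memberships.

    PD and MPD are evaluated with batched matrix products; MNTD needs a
    per-community nearest-neighbour scan and falls back to a loop.
    """
    r, t, s = mats.shape
    out = np.full((r, s, len(metrics)), np.nan)
    a = mats.astype(np.float64)
    k = a.sum(axis=1)  # r x s community sizes
    if "PD" in metrics:
        flat = a.transpose(1, 0, 2).reshape(t, r * s)
        pd_flat = et.pd_values(flat > 0)
        vals = pd_flat.reshape(r, s)
        vals[k == 0] = np.nan
        out[:, :, metrics.index("PD")] = vals
    if "MPD" in metrics:
        # sum over ordered pairs = m^T D m (diagonal of D is zero)
        da = np.tensordot(dist, a, axes=([1], [1]))  # t x r x s
        quad = (a.transpose(1, 0, 2) * da).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(k >= 2, quad / (k * (k - 1)), np.nan)
        out[:, :, metrics.index("MPD")] = vals
    if "MNTD" in metrics:
        col = metrics.index("MNTD")
        for i in range(r):
            for j in range(s):
                idx = np.flatnonzero(mats[i, :, j])
                if len(idx) < 2:
                    continue
                d = dist[idx][:, idx].copy()
                np.fill_diagonal(d, np.inf)
                out[i, j, col] = d.min(axis=1).mean()
    return out


def ses_metrics(
    pa: CommunityMatrix,
    tree: PhyloTree,
    models=NULL_MODELS,
    n_reps: int = 999,
    seed=None,
    metrics=METRICS,
    burn_in: int | None = None,
    thin: int | None = None,
) -> PhyloStructureResult:
    """ses.PD / ses.MPD / ses.MNTD per sample under each null model.

    The taxon universe is the tree's tip set (so ``phylogeny.pool`` can
    draw tips never observed in the matrix); matrix taxa must be a
    subset of the tips. Samples with fewer than two taxa carry NaN for
    MPD/MNTD; a zero-variance null yields NaN ses with a degenerate
    flag. Each model's ensemble is seeded independently from ``seed``.
    """
    metrics = tuple(metrics)
    unknown_m = set(metrics) - set(METRICS)
    if unknown_m:
        raise ValueError(f"unknown metrics {sorted(unknown_m)}")
    unknown = set(models) - set(NULL_MODELS)
    if unknown:
        raise ValueError(f"unknown null models {sorted(unknown)}")
    b = pa.presence_absence()
    et = tree.edges
    stray = sorted(set(b.taxon_ids) - set(et.tip_names))
    if stray:
        raise ValidationError(f"matrix taxa missing from tree: {stray}")
    n_tips = len(et.tip_names)
    member = np.zeros((n_tips, b.shape[1]), dtype=np.int8)
    rows = np.array([et.tip_index[t] for t in b.taxon_ids])
    member[rows] = b.counts.to_numpy(dtype=np.int8)
    dist_df = tree.patristic_distances()
    dist = dist_df.loc[et.tip_names, et.tip_names].to_numpy()

    obs = _metric_block(member.astype(bool), dist, et, metrics)
    observed = pd.DataFrame(obs, index=b.sample_ids, columns=metrics)

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    seeds = dict(zip(NULL_MODELS, ss.spawn(len(NULL_MODELS))))
    ses_d, mean_d, sd_d, degen_d, p_up_d, p_lo_d = {}, {}, {}, {}, {}, {}
    for model in models:
        rng = np.random.default_rng(seeds[model])
        if model == "taxa.labels":
            mats = np.stack(
                [member[permute_labels(n_tips, rng)] for _ in range(n_reps)]
            )
        else:
            mats = np.stack(
                list(
                    randomize_membership(
                        member,
                        model,
                        rng,
                        n_reps,
                        pool=np.arange(n_tips) if model == "phylogeny.pool" else None,
                        burn_in=burn_in,
                        thin=thin,
                    )
                )
            )
        nulls = _metric_batch(mats, dist, et, metrics)
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(nulls, axis=0)
            sd = np.nanstd(nulls, axis=0, ddof=1)
            ses = np.where(sd > 0, (obs - mu) / sd, np.nan)
            valid = np.sum(np.isfinite(nulls), axis=0)
            p_up = (np.nansum(nulls >= obs[None], axis=0) + 1) / (valid + 1)
            p_lo = (np.nansum(nulls <= obs[None], axis=0) + 1) / (valid + 1)
            p_up = np.where(np.isfinite(obs) & (valid > 0), p_up, np.nan)
            p_lo = np.where(np.isfinite(obs) & (valid > 0), p_lo, np.nan)
        cols = pd.Index(metrics)
        ses_d[model] = pd.DataFrame(ses, index=b.sample_ids, columns=cols)
        mean_d[model] = pd.DataFrame(mu, index=b.sample_ids, columns=cols)
        sd_d[model] = pd.DataFrame(sd, index=b.sample_ids, columns=cols)
        degen_d[model] = pd.DataFrame(
            ~(sd > 0) & np.isfinite(obs), index=b.sample_ids, columns=cols
        )
        p_up_d[model] = pd.DataFrame(p_up, index=b.sample_ids, columns=cols)
        p_lo_d[model] = pd.DataFrame(p_lo, index=b.sample_ids, columns=cols)
    return PhyloStructureResult(
        observed, ses_d, mean_d, sd_d, degen_d, p_up_d, p_lo_d
    )


def area_tests(
    ses_result: PhyloStructureResult | pd.DataFrame,
    sample_to_area: dict[str, str],
    alpha: float = 0.05,
    shapiro_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per area x metric x model test of mean ses against zero.

    Protocol: Shapiro-Wilk on the area's ses values when n >= 3; a
    one-sample two-tailed t-test when normality is not rejected,
    otherwise (and always when n < 3) the Wilcoxon signed-rank test.
    Verdict at ``alpha``: 'clustered' (mean ses < 0), 'overdispersed'
    (mean ses > 0), or 'random'; n = 1 yields 'insufficient
    replication'. Note: a Wilcoxon with n = 2 cannot attain two-sided
    p < 0.5, flagged in the ``note`` column.
    """
    if isinstance(ses_result, PhyloStructureResult):
        frames = {m: df for m, df in ses_result.ses.items()}
    else:  # a single samples x metrics ses frame under one model
        frames = {"": ses_result}
    rows = []
    for model, df in frames.items():
        areas = dict.fromkeys(sample_to_area[s] for s in df.index)
        for area in areas:
            samples = [s for s in df.index if sample_to_area[s] == area]
            for metric in df.columns:
                v = df.loc[samples, metric].dropna().to_numpy()
                n = len(v)
                rec = {
                    "area": area,
                    "metric": metric,
                    "model": model,
                    "n": n,
                    "mean_ses": float(np.mean(v)) if n else np.nan,
                    "shapiro_p": np.nan,
                    "test": None,
                    "statistic": np.nan,
                    "p": np.nan,
                    "verdict": "insufficient replication",
                    "note": "",
                }
                if n >= 2:
                    use_t = False
                    if n >= 3:
                        if np.ptp(v) > 0:
                            rec["shapiro_p"] = float(stats.shapiro(v).pvalue)
                            use_t = rec["shapiro_p"] >= shapiro_alpha
                        else:
                            rec["note"] = "constant ses; normality untestable"
                    if use_t:
                        t = stats.ttest_1samp(v, 0.0)
                        rec.update(test="t", statistic=float(t.statistic),
                                   p=float(t.pvalue))
                    else:
                        if np.all(v == 0):
                            rec.update(test="wilcoxon", statistic=0.0, p=1.0)
                        else:
                            w = stats.wilcoxon(v)
                            rec.update(test="wilcoxon",
                                       statistic=float(w.statistic),
                                       p=float(w.pvalue))
                        if n == 2:
                            rec["note"] = (
                                "wilcoxon with n=2: minimum attainable "
                                "two-sided p is 0.5"
                            ).strip()
                    if np.isfinite(rec["p"]) and rec["p"] < alpha:
                        rec["verdict"] = (
                            "clustered" if rec["mean_ses"] < 0 else "overdispersed"
                        )
                    else:
                        rec["verdict"] = "random"
                rows.append(rec)
    return pd.DataFrame(rows)
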