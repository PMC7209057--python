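"""Alpha and beta phylogenetic diversity metrics.

Faith's PD (the branch length connecting a taxon set to the root), mean
pairwise distance (MPD), mean nearest-taxon distance (MNTD), the
unweighted UniFrac distance between presence-absence communities, and
classical (metric) principal coordinates analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .io import CommunityMatrix, ValidationError
from .tree import PhyloTree

__all__ = [
    "faith_pd",
    "mpd",
    "mntd",
    "mpd_mntd_from_submatrix",
    "unweighted_unifrac",
    "PCoAResult",
    "pcoa",
]


def faith_pd(tree: PhyloTree, taxon_set) -> float:
    """Sum of branch lengths joining ``taxon_set`` to the root.

    The root-to-tip path is included, so a singleton's PD is its depth.
    """
    taxa = list(taxon_set)
    if not taxa:
        raise ValidationError("faith_pd needs a non-empty taxon set")
    et = tree.edges
    unknown = sorted(set(taxa) - set(et.tip_names))
    if unknown:
        raise ValidationError(f"taxa not in tree: {unknown}")
    member = np.zeros((len(et.tip_names), 1), dtype=bool)
    member[[et.tip_index[t] for t in taxa], 0] = True
    return float(et.pd_values(member)[0])


def _subset_dist(dist: pd.DataFrame, taxa: list[str]) -> np.ndarray:
    unknown = sorted(set(taxa) - set(dist.index))
    if unknown:
        raise ValidationError(f"taxa not in distance matrix: {unknown}")
    return dist.loc[taxa, taxa].to_numpy()


def mpd(dist: pd.DataFrame, taxon_set) -> float:
    """Mean patristic distance over all unordered pairs; NaN for singletons."""
    taxa = list(taxon_set)
    if len(taxa) < 2:
        return float("nan")
    d = _subset_dist(dist, taxa)
    iu = np.triu_indices(len(taxa), k=1)
    return float(d[iu].mean())


def mntd(dist: pd.DataFrame, taxon_set) -> float:
    """Mean distance from each member to its nearest co-occurring member."""
    taxa = list(taxon_set)
    if len(taxa) < 2:
        return float("nan")
    d = _subset_dist(dist, taxa).astype(float)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def mpd_mntd_from_submatrix(d: np.ndarray) -> tuple[float, float]:
    """Both metrics from an already-subset square distance array."""
    k = d.shape[0]
    if k < 2:
        return float("nan"), float("nan")
    iu = np.triu_indices(k, k=1)
    mpd_v = float(d[iu].mean())
    dd = d.astype(float).copy()
    np.fill_diagonal(dd, np.inf)
    return mpd_v, float(dd.min(axis=1).mean())


def unweighted_unifrac(pa: CommunityMatrix, tree: PhyloTree) -> pd.DataFrame:
    """Pairwise unweighted UniFrac distances between samples.

    For samples a, b: the branch length leading exclusively to one of
    the two communities divided by the branch length leading to either;
    symmetric, zero diagonal, values in [0, 1]. Empty samples yield NaN
    against everything (flagged by the caller's report).
    """
    b = pa.presence_absence()
    et = tree.edges
    unknown = sorted(set(b.taxon_ids) - set(et.tip_names))
    if unknown:
        raise ValidationError(f"matrix taxa missing from tree: {unknown}")
    member = np.zeros((len(et.tip_names), b.shape[1]), dtype=bool)
    rows = [et.tip_index[t] for t in b.taxon_ids]
    member[rows] = b.counts.to_numpy(dtype=bool)
    pres = et.presence(member)  # edges x samples
    lengths = et.lengths
    # weighted edge overlap between samples
    shared = (lengths[:, None] * pres).T @ pres
    totals = lengths @ pres
    union = totals[:, None] + totals[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, 1.0 - shared / union, np.nan)
    d = np.clip(d, 0.0, 1.0)  # guard float round-off at the [0,1] edges
    np.fill_diagonal(d, 0.0)
    empty = b.counts.sum(axis=0).to_numpy() == 0
    d[empty, :] = np.nan
    d[:, empty] = np.nan
    return pd.DataFrame(d, index=b.sample_ids, columns=b.sample_ids)


@dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained axes (positive eigenvalues)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # relative to the sum of positive eigenvalues
    n_negative: int


def pcoa(dist: pd.DataFrame, eps: float = 1e-9) -> PCoAResult:
    """Principal coordinates from a symmetric distance matrix.

    Eigen-decomposition of the Gower-centred matrix -0.5 * J D^2 J.
    Axes belonging to negative eigenvalues are reported in the spectrum
    but suppressed from the coordinates (no Cailliez/Lingoes correction).
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("pcoa needs a symmetric square distance matrix")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValidationError("pcoa needs a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = scipy.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eps * max(1.0, abs(vals[0]))
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    pos_sum = vals[pos].sum()
    prop = np.where(pos, vals / pos_sum, 0.0) if pos_sum > 0 else np.zeros_like(vals)
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dist.index, columns=axes),
        eigenvalues=vals,
        proportion_explained=prop,
        n_negative=int((vals < -eps * max(1.0, abs(vals[0]))).sum()),
    )
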