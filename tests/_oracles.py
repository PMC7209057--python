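"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a statistic from first principles
(explicit loops over pairs, edges or paths) so the vectorized library
code can be checked against a second, independent route.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_c_score(m: np.ndarray) -> tuple[float, int]:
    """Mean (R_i - S)(R_j - S) over pairs and the checkerboard-pair count."""
    t = m.shape[0]
    scores, checkers = [], 0
    for i, j in itertools.combinations(range(t), 2):
        ri, rj = m[i].sum(), m[j].sum()
        s = int(np.sum((m[i] == 1) & (m[j] == 1)))
        scores.append((ri - s) * (rj - s))
        if s == 0:
            checkers += 1
    return float(np.mean(scores)), checkers


def _edge_sets(sk_root):
    """(length, set-of-descendant-tips) per edge of a scikit-bio tree."""
    out = []
    for node in sk_root.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        out.append((float(node.length or 0.0), tips))
    return out


def brute_faith_pd(tree, taxa) -> float:
    """Union of root-to-tip edge sets, summed edge by edge."""
    taxa = set(taxa)
    return sum(l for l, below in _edge_sets(tree.node) if below & taxa)


def brute_mpd_mntd(dist, taxa) -> tuple[float, float]:
    taxa = list(taxa)
    pair = [
        dist.loc[a, b] for a, b in itertools.combinations(taxa, 2)
    ]
    nearest = [
        min(dist.loc[a, b] for b in taxa if b != a) for a in taxa
    ]
    return float(np.mean(pair)), float(np.mean(nearest))


def brute_unifrac(tree, taxa_a, taxa_b) -> float:
    """Edge-classification definition of unweighted UniFrac."""
    a, b = set(taxa_a), set(taxa_b)
    unique = shared = 0.0
    for length, below in _edge_sets(tree.node):
        in_a, in_b = bool(below & a), bool(below & b)
        if in_a and in_b:
            shared += length
        elif in_a or in_b:
            unique += length
    total = unique + shared
    return unique / total if total > 0 else np.nan


def brute_tree_diameter(tree) -> float:
    """Longest tip-to-tip path via exhaustive all-pairs search."""
    d = tree.patristic_distances()
    return float(np.max(d.to_numpy()))


def enumerate_fixed_margin(row_sums, col_sums) -> list[bytes]:
    """All binary matrices with the given margins (tiny instances only)."""
    t, s = len(row_sums), len(col_sums)
    rows_by_sum = {
        r: [np.array(v) for v in itertools.product((0, 1), repeat=s) if sum(v) == r]
        for r in set(row_sums)
    }
    found = []
    for combo in itertools.product(*(rows_by_sum[r] for r in row_sums)):
        m = np.vstack(combo)
        if (m.sum(axis=0) == np.asarray(col_sums)).all():
            found.append(m.astype(np.int8).tobytes())
    return found


def random_binary(rng, t, s, p=0.5, nonempty_rows=False) -> np.ndarray:
    m = (rng.random((t, s)) < p).astype(np.int64)
    if nonempty_rows:
        for i in range(t):
            if m[i].sum() == 0:
                m[i, rng.integers(s)] = 1
    return m
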