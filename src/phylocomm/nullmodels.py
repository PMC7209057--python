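"""Community null models for phylogenetic structure analysis.

Seven randomization schemes, named as in the community-phylogenetics
literature (picante's vocabulary):

* ``taxa.labels`` — permute taxon identities on the distance matrix /
  tree; community membership untouched.
* ``richness`` — each sample redraws its observed number of taxa
  equiprobably from the matrix's taxon set.
* ``frequency`` — each taxon redraws its observed number of occurrences
  equiprobably across samples (column sums free).
* ``sample.pool`` — as richness, with the pool restricted to taxa
  occurring in at least one sample.
* ``phylogeny.pool`` — as richness, with the pool equal to all tree
  tips (taxa never observed in the matrix included).
* ``independentswap`` — a Markov chain of 2x2 checkerboard submatrix
  swaps preserving BOTH row and column sums; thinning counts successful
  swaps.
* ``trialswap`` — the same chain but one attempted swap per trial
  (failed trials count toward thinning), the classic trial-swap walk.

Swap chains use a burn-in and thinning so successive saved matrices are
approximately independent uniform draws from the fixed-margin set; the
uniformity of the stationary distribution is verified by enumeration on
small instances in the test suite rather than assumed.
"""

from __future__ import annotations

import warnings

import numpy as np

try:  # optional acceleration for the swap chains
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

__all__ = [
    "NULL_MODELS",
    "MATRIX_MODELS",
    "permute_labels",
    "randomize_membership",
    "swap_chain",
    "has_swappable_pair",
]

NULL_MODELS = (
    "taxa.labels",
    "richness",
    "frequency",
    "sample.pool",
    "phylogeny.pool",
    "independentswap",
    "trialswap",
)
#: models that produce a randomized membership matrix (vs a label permutation)
MATRIX_MODELS = tuple(m for m in NULL_MODELS if m != "taxa.labels")


def permute_labels(n_taxa: int, rng: np.random.Generator) -> np.ndarray:
    """Row-permutation implementing the ``taxa.labels`` relabeling."""
    return rng.permutation(n_taxa)


def _redraw_columns(m: np.ndarray, pool: np.ndarray, rng) -> np.ndarray:
    """Per-sample equiprobable redraw of each sample's richness from ``pool``."""
    out = np.zeros_like(m)
    richness = m.sum(axis=0)
    for j, k in enumerate(richness):
        if k > len(pool):
            raise ValueError(
                f"sample {j} richness {k} exceeds pool size {len(pool)}"
            )
        if k:
            out[rng.choice(pool, size=k, replace=False), j] = 1
    return out


def _redraw_rows(m: np.ndarray, rng) -> np.ndarray:
    """Per-taxon equiprobable redraw of occurrences across samples (sim2)."""
    out = np.zeros_like(m)
    s = m.shape[1]
    for i, r in enumerate(m.sum(axis=1)):
        if r:
            out[i, rng.choice(s, size=r, replace=False)] = 1
    return out


def has_swappable_pair(m: np.ndarray) -> bool:
    """True when some 2x2 submatrix is a checkerboard (swap possible)."""
    t = m.shape[0]
    for i in range(t):
        for j in range(i + 1, t):
            d = m[i] - m[j]
            if (d > 0).any() and (d < 0).any():
                return True
    return False


def _swap_kernel_py(m, out, burn_in, thin, count_trials, seed):
    rng = np.random.default_rng(seed)
    t, s = m.shape
    units, target, saved = 0, burn_in, 0
    n_saves = out.shape[0]
    batch = 16_384
    while saved < n_saves:
        rows = rng.integers(0, t, size=(batch, 2))
        cols = rng.integers(0, s, size=(batch, 2))
        for (r1, r2), (c1, c2) in zip(rows, cols):
            success = False
            if r1 != r2 and c1 != c2:
                a = m[r1, c1]
                b = m[r1, c2]
                if a == m[r2, c2] and b == m[r2, c1] and a != b:
                    m[r1, c1] = m[r2, c2] = b
                    m[r1, c2] = m[r2, c1] = a
                    success = True
            units += 1 if count_trials else int(success)
            if units >= target:
                out[saved] = m
                saved += 1
                # random parity step: success-counted chains can be
                # periodic (every swap flips a parity invariant on some
                # instances), so a fixed stride would sample one class
                target += thin + int(rng.integers(2))
                if saved >= n_saves:
                    return


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _swap_kernel_nb(m, out, burn_in, thin, count_trials, seed):  # pragma: no cover
        np.random.seed(seed)
        t, s = m.shape
        units, target, saved = 0, burn_in, 0
        n_saves = out.shape[0]
        while saved < n_saves:
            r1 = np.random.randint(0, t)
            r2 = np.random.randint(0, t)
            c1 = np.random.randint(0, s)
            c2 = np.random.randint(0, s)
            success = False
            if r1 != r2 and c1 != c2:
                a = m[r1, c1]
                b = m[r1, c2]
                if a == m[r2, c2] and b == m[r2, c1] and a != b:
                    m[r1, c1] = b
                    m[r2, c2] = b
                    m[r1, c2] = a
                    m[r2, c1] = a
                    success = True
            if count_trials or success:
                units += 1
            if units >= target:
                out[saved] = m
                saved += 1
                # random parity step; see the pure-python kernel
                target += thin + np.random.randint(0, 2)


def swap_chain(
    m: np.ndarray,
    rng: np.random.Generator,
    n_saves: int,
    burn_in: int | None = None,
    thin: int | None = None,
    count: str = "successes",
):
    """Yield ``n_saves`` matrices from the fixed-margin checkerboard-swap chain.

    count='successes' (independent swap): burn-in and thinning are counted
    in successful swaps. count='trials' (trial swap): every attempted 2x2
    draw counts, whether or not it hits a checkerboard.
    """
    m = np.ascontiguousarray(m, dtype=np.int8).copy()
    t, s = m.shape
    ones = int(m.sum())
    if burn_in is None:
        burn_in = 10_000
    if thin is None:
        thin = 10 * max(ones, 1)
    if t < 2 or s < 2 or not has_swappable_pair(m):
        warnings.warn("no swappable 2x2 submatrix; returning input unchanged",
                      stacklevel=2)
        for _ in range(n_saves):
            yield m.copy()
        return
    out = np.empty((n_saves, t, s), dtype=np.int8)
    seed = int(rng.integers(2**31 - 1))
    kernel = _swap_kernel_nb if _HAVE_NUMBA else _swap_kernel_py
    kernel(m, out, int(burn_in), int(thin), count == "trials", seed)
    yield from out


def randomize_membership(
    m: np.ndarray,
    model: str,
    rng: np.random.Generator,
    n_reps: int,
    pool: np.ndarray | None = None,
    burn_in: int | None = None,
    thin: int | None = None,
):
    """Yield ``n_reps`` randomized membership matrices under ``model``.

    ``m`` is binary taxa x samples. ``pool`` (row indices) is required
    for ``phylogeny.pool`` when the row universe exceeds the matrix; for
    ``richness`` it defaults to all rows and for ``sample.pool`` to the
    occupied rows.
    """
    if model not in MATRIX_MODELS:
        raise ValueError(f"unknown matrix null model {model!r}")
    m = np.asarray(m)
    if model == "frequency":
        for _ in range(n_reps):
            yield _redraw_rows(m, rng)
    elif model in {"richness", "sample.pool", "phylogeny.pool"}:
        if model == "richness":
            pool = np.arange(m.shape[0]) if pool is None else np.asarray(pool)
        elif model == "sample.pool":
            pool = np.flatnonzero(m.sum(axis=1) > 0)
        else:
            if pool is None:
                pool = np.arange(m.shape[0])
            pool = np.asarray(pool)
        for _ in range(n_reps):
            yield _redraw_columns(m, pool, rng)
    else:  # swap models
        yield from swap_chain(
            m,
            rng,
            n_saves=n_reps,
            burn_in=burn_in,
            thin=thin,
            count="trials" if model == "trialswap" else "successes",
        )
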