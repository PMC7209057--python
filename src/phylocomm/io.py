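"""Readers, writers and validated containers for all external artifacts.

Downstream modules never touch text: count tables, taxonomy, trees and
sample metadata enter the pipeline here, are validated once, and flow on
as :class:`CommunityMatrix`, :class:`PhyloTree` and :class:`EnvTable`.

File conventions
----------------
* count table: TSV, first column ``taxon_id``, remaining columns samples
  (or transposed, see ``orientation``); integer counts.
* taxonomy: TSV with columns ``taxon_id``, ``lineage`` (rank-separated
  lineage string, default separator ``;``).
* tree: newick with branch lengths.
* metadata: TSV with columns ``sample_id``, ``area`` and numeric
  environmental covariates (``TOC``, ``CPE``, ``Mud``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "CommunityMatrix",
    "EnvTable",
    "ValidationError",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "align_inputs",
]

UNASSIGNED = "Unassigned"
RANK_ORDER = ("phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """Input violates a container invariant."""


@dataclass(frozen=True)
class CommunityMatrix:
    """Taxa x samples table of non-negative integer counts.

    ``taxonomy`` optionally maps taxon ids to rank-separated lineage
    strings (phylum down to genus, possibly truncated).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = None
    rank_separator: str = ";"

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError(
                f"duplicate taxon ids: {sorted(c.index[c.index.duplicated()])}"
            )
        if c.columns.has_duplicates:
            raise ValidationError(
                f"duplicate sample ids: {sorted(c.columns[c.columns.duplicated()])}"
            )
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                raise ValidationError("counts must be integers")
            object.__setattr__(self, "counts", c.astype(np.int64))
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            r, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at taxon {c.index[r]!r}, sample {c.columns[s]!r}"
            )
        if self.taxonomy is not None:
            stray = set(self.taxonomy) - set(c.index)
            if stray:
                raise ValidationError(f"taxonomy keys not in matrix: {sorted(stray)}")

    # -- views -------------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def presence_absence(self) -> "CommunityMatrix":
        """Binary view: 1 iff count > 0. Idempotent."""
        return replace(self, counts=(self.counts > 0).astype(np.int64))

    @property
    def is_binary(self) -> bool:
        return bool(self.counts.isin([0, 1]).all().all())

    def select_taxa(self, taxa) -> "CommunityMatrix":
        taxa = list(taxa)
        tax = (
            {t: v for t, v in self.taxonomy.items() if t in set(taxa)}
            if self.taxonomy is not None
            else None
        )
        return replace(self, counts=self.counts.loc[taxa], taxonomy=tax)

    def select_samples(self, samples) -> "CommunityMatrix":
        return replace(self, counts=self.counts[list(samples)])

    def lineage_rank(self, taxon: str, rank: str) -> str | None:
        """Label of ``taxon`` at ``rank`` or None when the lineage stops short."""
        if self.taxonomy is None or taxon not in self.taxonomy:
            return None
        parts = [p.strip() for p in self.taxonomy[taxon].split(self.rank_separator)]
        try:
            i = RANK_ORDER.index(rank)
        except ValueError:
            raise ValidationError(f"unknown rank {rank!r}; use one of {RANK_ORDER}")
        if i >= len(parts) or not parts[i] or parts[i] == UNASSIGNED:
            return None
        return parts[i]


@dataclass(frozen=True)
class EnvTable:
    """Per-sample environmental covariates plus an area label.

    ``Mud`` is a percentage and must lie in [0, 100]; all covariates must
    be complete (no missing values survive validation).
    """

    data: pd.DataFrame  # index = sample_id; columns: area + numeric covariates

    def __post_init__(self):
        d = self.data
        if d.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        if "area" not in d.columns:
            raise ValidationError("metadata must contain an 'area' column")
        num = d.drop(columns=["area"])
        if num.isna().any().any():
            bad = num.columns[num.isna().any()].tolist()
            raise ValidationError(f"missing values in covariates: {bad}")
        if "Mud" in num.columns:
            mud = num["Mud"]
            if ((mud < 0) | (mud > 100)).any():
                raise ValidationError("Mud percentages must lie in [0, 100]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def area(self) -> pd.Series:
        return self.data["area"]

    @property
    def variables(self) -> pd.DataFrame:
        return self.data.drop(columns=["area"])

    def select_samples(self, samples) -> "EnvTable":
        return EnvTable(self.data.loc[list(samples)])


# -- count tables -----------------------------------------------------------

def read_count_table(
    path,
    orientation: str = "auto",
    taxonomy: dict[str, str] | None = None,
) -> CommunityMatrix:
    """Read a TSV count table into canonical taxa x samples orientation.

    orientation: ``taxa_rows`` (first column = taxon ids), ``samples_rows``
    (transposed), or ``auto`` — taxa on rows when the id column is not
    named ``sample_id``.
    """
    if orientation not in {"taxa_rows", "samples_rows", "auto"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
    if df.isna().any().any():
        raise ValidationError(f"missing cells in {path}")
    if orientation == "auto":
        orientation = (
            "samples_rows" if str(df.index.name).lower() == "sample_id" else "taxa_rows"
        )
    if orientation == "samples_rows":
        df = df.T
        df.columns.name = None
    df.index.name = "taxon_id"
    return CommunityMatrix(df, taxonomy=taxonomy)


def write_count_table(cm: CommunityMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path, rank_separator: str = ";") -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"taxon_id", "lineage"}.issubset(df.columns):
        raise ValidationError("taxonomy TSV needs columns taxon_id, lineage")
    if df["taxon_id"].duplicated().any():
        raise ValidationError("duplicate taxon_id in taxonomy")
    return dict(zip(df["taxon_id"], df["lineage"].fillna(UNASSIGNED)))


# -- trees ------------------------------------------------------------------

def write_taxonomy(taxonomy: dict[str, str], path) -> None:
    pd.DataFrame(
        {"taxon_id": list(taxonomy), "lineage": list(taxonomy.values())}
    ).to_csv(path, sep="\t", index=False)


def read_tree(path, fill_missing_lengths: bool = False) -> PhyloTree:
    return PhyloTree.read(path, fill_missing_lengths=fill_missing_lengths)


def write_tree(tree: PhyloTree, path) -> None:
    tree.write(path)


# -- metadata ---------------------------------------------------------------

def read_metadata(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("metadata TSV needs a sample_id column")
    df = df.set_index("sample_id")
    return EnvTable(df)


def write_metadata(env: EnvTable, path) -> None:
    out = env.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# -- alignment --------------------------------------------------------------

def align_inputs(
    cm: CommunityMatrix,
    tree: PhyloTree | None = None,
    env: EnvTable | None = None,
):
    """Restrict matrix/tree/env to their common taxa and samples.

    Returns ``(cm, tree, env, report)`` with deterministic (input-order)
    ordering; the report lists every dropped id. Idempotent. Raises
    ValidationError when an intersection is empty.
    """
    report: dict[str, list[str]] = {
        "taxa_dropped_from_matrix": [],
        "tips_dropped_from_tree": [],
        "samples_dropped_from_matrix": [],
        "samples_dropped_from_env": [],
    }
    if tree is not None:
        tips = set(tree.tip_names)
        keep_taxa = [t for t in cm.taxon_ids if t in tips]
        if not keep_taxa:
            raise ValidationError("matrix taxa and tree tips are disjoint")
        report["taxa_dropped_from_matrix"] = [
            t for t in cm.taxon_ids if t not in tips
        ]
        report["tips_dropped_from_tree"] = sorted(tips - set(cm.taxon_ids))
        if report["taxa_dropped_from_matrix"]:
            cm = cm.select_taxa(keep_taxa)
        if report["tips_dropped_from_tree"]:
            tree = tree.prune_to(keep_taxa)
    if env is not None:
        have = set(env.sample_ids)
        keep_samples = [s for s in cm.sample_ids if s in have]
        if not keep_samples:
            raise ValidationError("matrix samples and metadata samples are disjoint")
        report["samples_dropped_from_matrix"] = [
            s for s in cm.sample_ids if s not in have
        ]
        report["samples_dropped_from_env"] = [
            s for s in env.sample_ids if s not in set(cm.sample_ids)
        ]
        if report["samples_dropped_from_matrix"]:
            cm = cm.select_samples(keep_samples)
        if report["samples_dropped_from_env"]:
            env = env.select_samples(keep_samples)
    report["n_taxa"] = cm.shape[0]
    report["n_samples"] = cm.shape[1]
    return cm, tree, env, report
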