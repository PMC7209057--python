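"""Known-truth synthetic data with the structure the pipeline assumes.

The generator emulates an abyssal metabarcoding survey: several areas
with a handful of replicate cores each, a regional ASV pool on a Yule
phylogeny, a phylogenetically conserved (Brownian) trait that
environmental filtering acts on, a long lognormal abundance tail with
per-area endemics, and environmental gradients (TOC, CPE, Mud) that can
be tied to local richness. Four assembly scenarios provide the
alternatives the analysis distinguishes:

* ``neutral`` — members drawn uniformly; no structure.
* ``filtering`` — inclusion weight falls off with trait distance from
  the sample's optimum, producing phylogenetic clustering.
* ``limiting_similarity`` — members accepted only when far enough (in
  patristic distance) from everyone already accepted; overdispersion.
* ``habitat_blocks`` — taxa confined to one of two area-blocks;
  cross-block pairs are perfect checkerboards (segregation).

Every draw is reproducible from the scenario seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CommunityMatrix, EnvTable
from .tree import PhyloTree

__all__ = [
    "SynthScenario",
    "SynthDataset",
    "gen_tree",
    "evolve_trait",
    "gen_env",
    "assign_taxonomy",
    "assemble_communities",
    "generate_dataset",
    "linear_response",
    "PAPER_DESIGN",
]

#: the survey design emulated by default: area -> number of replicate cores
PAPER_DESIGN = {
    "BGR.PA": 5,
    "BGR.RA": 4,
    "IOM.C": 2,
    "GSR": 4,
    "IFREMER": 5,
    "APEI3": 3,
}

ASSEMBLIES = ("neutral", "filtering", "limiting_similarity", "habitat_blocks")


@dataclass(frozen=True)
class SynthScenario:
    """Generator parameters; the seed fully determines the output."""

    n_tips: int = 200
    birth_rate: float = 1.0
    areas: dict[str, int] = field(default_factory=lambda: dict(PAPER_DESIGN))
    assembly: str = "filtering"
    filter_sigma: float = 0.5  # trait-match bandwidth (trait units)
    trait_sigma2: float = 1.0  # Brownian rate per unit branch length
    richness_per_sample: int = 25
    env_effect: dict[str, float] = field(default_factory=dict)  # var -> slope on richness
    endemic_fraction: float = 0.65  # taxa confined to a single area
    abundance_sigma: float = 1.5  # lognormal sd of regional abundances
    depth_mean: int = 20_000  # expected reads per sample
    n_blocks: int = 2  # habitat_blocks: number of area blocks
    similarity_threshold: float | None = None  # limiting_similarity cutoff
    seed: int = 0

    def __post_init__(self):
        if self.assembly not in ASSEMBLIES:
            raise ValueError(f"unknown assembly {self.assembly!r}")
        if self.n_tips < 3 or self.birth_rate <= 0 or self.trait_sigma2 < 0:
            raise ValueError("n_tips >= 3 and positive rates required")
        if any(r < 1 for r in self.areas.values()):
            raise ValueError("every area needs at least one replicate")


@dataclass
class SynthDataset:
    community: CommunityMatrix
    tree: PhyloTree
    env: EnvTable
    traits: pd.Series
    truth: dict


# -- tree and trait ---------------------------------------------------------

def gen_tree(n_tips: int, birth_rate: float = 1.0, seed=None) -> PhyloTree:
    """Ultrametric pure-birth (Yule) tree with exponential waiting times.

    The root splits at time zero; each of the k extant lineages splits
    at total rate ``birth_rate * k``; after the last split the present
    is pushed one further exponential waiting time so no pendant edge
    has zero length.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)
    counter = iter(range(10 * n_tips))
    root = next(counter)
    a, b = next(counter), next(counter)
    children: dict[int, tuple[int, int]] = {root: (a, b)}
    split_time: dict[int, float] = {root: 0.0}
    born: dict[int, float] = {a: 0.0, b: 0.0}
    active = [a, b]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        kids = (next(counter), next(counter))
        children[node] = kids
        split_time[node] = t
        born[kids[0]] = born[kids[1]] = t
        active.extend(kids)
    present = t + rng.exponential(1.0 / (birth_rate * n_tips))
    labels = {lid: f"t{i + 1:04d}" for i, lid in enumerate(sorted(active))}

    def newick(node: int) -> str:
        if node in children:
            inner = ",".join(newick(c) for c in children[node])
            length = split_time[node] - born.get(node, 0.0)
            return f"({inner}):{length:.12f}"
        return f"{labels[node]}:{present - born[node]:.12f}"

    text = f"({newick(children[root][0])},{newick(children[root][1])});"
    return PhyloTree.from_newick(text)


def assign_taxonomy(
    tree: PhyloTree,
    cut_fraction: float = 0.7,
    unassigned_fraction: float = 0.5,
    seed=None,
) -> dict[str, str]:
    """Clade-based genus labels with a truncated-lineage fraction.

    The tree is cut at ``cut_fraction`` of its depth; tips descending
    from the same cut edge share a genus, so genera are monophyletic by
    construction (mirroring marker-gene taxonomy). A random
    ``unassigned_fraction`` of tips get a lineage truncated above genus
    — the ASVs a reference database cannot place.
    """
    rng = np.random.default_rng(seed)
    depth = max(t.accumulate_to_ancestor(tree.node) for t in tree.node.tips())
    cut = cut_fraction * depth
    genus_of: dict[str, int] = {}
    n_genera = 0
    for node in tree.node.preorder(include_self=False):
        top = node.accumulate_to_ancestor(tree.node) - (node.length or 0.0)
        bottom = top + (node.length or 0.0)
        if top <= cut < bottom:  # this edge crosses the cut line
            n_genera += 1
            for t in [node] if node.is_tip() else node.tips():
                genus_of[t.name] = n_genera
    lineages = {}
    for tip in tree.tip_names:
        g = genus_of.get(tip, 0)
        if g == 0 or rng.random() < unassigned_fraction:
            lineages[tip] = "Nematoda;Chromadorea;Unassigned"
        else:
            lineages[tip] = (
                f"Nematoda;Chromadorea;Order{(g - 1) // 6 + 1};"
                f"Family{(g - 1) // 2 + 1};Genus{g}"
            )
    return lineages


def evolve_trait(tree: PhyloTree, trait_sigma2: float = 1.0, seed=None) -> pd.Series:
    """Brownian trait along branches from a root value of zero.

    Tip variance equals ``trait_sigma2`` times root-to-tip depth; sister
    tips covary through their shared path, which is what makes the
    filtering scenario phylogenetically clustered.
    """
    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(trait_sigma2))
    values: dict[int, float] = {id(tree.node): 0.0}
    out = {}
    for node in tree.node.preorder(include_self=False):
        step = rng.normal(0.0, sd * np.sqrt(node.length or 0.0))
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out, name="trait").loc[tree.tip_names]


# -- environment ------------------------------------------------------------

def gen_env(
    areas: dict[str, int] | None = None,
    env_effect: dict[str, float] | None = None,
    seed=None,
    toc_range: tuple[float, float] = (0.25, 0.70),  # %TOC across the gradient
    cpe_range: tuple[float, float] = (0.10, 1.00),  # pigment equivalents
    noise: float = 0.05,  # relative within-area noise on TOC/CPE
    area_noise: float = 0.30,  # relative between-area noise on CPE
    mud_mean: float = 60.0,
    mud_sd: float = 8.0,
) -> EnvTable:
    """Sample metadata with TOC/CPE increasing along an area gradient.

    Areas sit at evenly spaced positions on a 0-1 productivity gradient
    (emulating the eastward organic-flux increase of the study region).
    TOC and CPE both track the gradient so they correlate, but CPE
    carries an independent between-area component (``area_noise``) so
    the correlation stays moderate rather than collinear (the regression
    screening assumes VIF well below 10). Mud is an independent
    percentage clipped to [0, 100]. ``env_effect`` is kept by the caller
    to tie richness to these covariates.
    """
    areas = dict(PAPER_DESIGN) if areas is None else areas
    rng = np.random.default_rng(seed)
    gradient = dict(zip(areas, np.linspace(0.0, 1.0, len(areas))))
    rows = []
    for area, n_rep in areas.items():
        g = gradient[area]
        toc_a = toc_range[0] + g * (toc_range[1] - toc_range[0])
        cpe_a = (cpe_range[0] + g * (cpe_range[1] - cpe_range[0])) * max(
            1 + rng.normal(0, area_noise), 0.05
        )
        for r in range(1, n_rep + 1):
            rows.append(
                {
                    "sample_id": f"{area}.{r}",
                    "area": area,
                    "TOC": max(toc_a * (1 + rng.normal(0, noise)), 1e-3),
                    "CPE": max(cpe_a * (1 + rng.normal(0, noise)), 1e-3),
                    "Mud": float(np.clip(rng.normal(mud_mean, mud_sd), 0, 100)),
                }
            )
    return EnvTable(pd.DataFrame(rows).set_index("sample_id"))


# -- community assembly -----------------------------------------------------

def _sample_richness(scenario: SynthScenario, env: EnvTable) -> pd.Series:
    """Per-sample target richness, optionally tied to covariates.

    Each slope in ``env_effect`` scales richness multiplicatively per
    standard deviation of the covariate, so positive TOC effects give
    richer (hence higher-PD) eastern samples.
    """
    base = float(scenario.richness_per_sample)
    mult = np.ones(len(env.sample_ids))
    for var, slope in scenario.env_effect.items():
        x = env.variables[var].to_numpy(dtype=float)
        z = (x - x.mean()) / (x.std() or 1.0)
        mult = mult * (1.0 + slope * z)
    k = np.clip(np.round(base * np.clip(mult, 0.1, None)), 2, None).astype(int)
    return pd.Series(k, index=env.sample_ids)


def assemble_communities(
    tree: PhyloTree,
    traits: pd.Series,
    scenario: SynthScenario,
    env: EnvTable | None = None,
    seed=None,
) -> tuple[CommunityMatrix, dict]:
    """Draw community membership and counts under the scenario's rules.

    Membership per sample follows the assembly process; the count layer
    puts a lognormal regional abundance on every taxon and draws each
    sample's reads multinomially at a Poisson depth (every member is
    guaranteed at least one read so presence is crisp). Returns the
    matrix plus truth labels describing the construction.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(scenario.seed).spawn(1)[0] if seed is None else seed
    )
    if env is None:
        env = gen_env(scenario.areas, scenario.env_effect, seed=rng.integers(2**31))
    taxa = list(tree.tip_names)
    n = len(taxa)
    trait = traits.loc[taxa].to_numpy()
    area_names = list(scenario.areas)
    area_of_sample = {s: env.area[s] for s in env.sample_ids}
    richness = _sample_richness(scenario, env)

    # endemics: a fraction of the pool usable in exactly one (home) area.
    # The neutral scenario skips the overlay: neutrality means every
    # sample is an exchangeable uniform draw from the whole pool, and a
    # hard pool restriction is itself a (non-neutral) assembly mechanism.
    endemic_fraction = (
        0.0 if scenario.assembly == "neutral" else scenario.endemic_fraction
    )
    n_endemic = int(round(endemic_fraction * n))
    endemic_idx = rng.choice(n, size=n_endemic, replace=False)
    home = np.full(n, -1)
    home[endemic_idx] = rng.integers(len(area_names), size=n_endemic)
    truth: dict = {
        "assembly": scenario.assembly,
        "endemic_home": {
            taxa[i]: area_names[home[i]] for i in endemic_idx
        },
    }

    dist = None
    if scenario.assembly == "limiting_similarity":
        dist = tree.patristic_distances().loc[taxa, taxa].to_numpy()
        threshold = (
            scenario.similarity_threshold
            if scenario.similarity_threshold is not None
            else float(np.quantile(dist[np.triu_indices(n, 1)], 0.25))
        )
        truth["similarity_threshold"] = threshold

    if scenario.assembly == "habitat_blocks":
        blocks = np.array_split(np.arange(len(area_names)), scenario.n_blocks)
        area_block = {}
        for bi, grp in enumerate(blocks):
            for ai in grp:
                area_block[area_names[ai]] = bi
        taxon_block = rng.integers(scenario.n_blocks, size=n)
        truth["area_block"] = dict(area_block)
        truth["taxon_block"] = dict(zip(taxa, (int(b) for b in taxon_block)))

    # filtering optima: trait quantile matched to the area's gradient position
    gradient = dict(zip(area_names, np.linspace(0.0, 1.0, len(area_names))))
    optimum = {
        a: float(np.quantile(trait, 0.15 + 0.7 * g)) for a, g in gradient.items()
    }
    if scenario.assembly == "filtering":
        truth["optima"] = optimum

    membership = np.zeros((n, len(env.sample_ids)), dtype=np.int64)
    for j, s in enumerate(env.sample_ids):
        area = area_of_sample[s]
        allowed = (home < 0) | (home == area_names.index(area))
        k = int(min(richness[s], allowed.sum()))
        if k < 2:
            raise ValueError(f"sample {s}: fewer than 2 admissible taxa")
        if scenario.assembly == "neutral":
            w = allowed.astype(float)
        elif scenario.assembly == "filtering":
            w = np.exp(-((trait - optimum[area]) ** 2) / (2 * scenario.filter_sigma**2))
            w = np.where(allowed, np.maximum(w, 1e-300), 0.0)
        elif scenario.assembly == "habitat_blocks":
            w = (allowed & (taxon_block == area_block[area])).astype(float)
            k = int(min(k, w.sum()))
            if k < 2:
                raise ValueError(f"sample {s}: block pool exhausted")
        else:  # limiting_similarity: sequential acceptance
            order = rng.permutation(np.flatnonzero(allowed))
            chosen: list[int] = []
            for i in order:
                if all(dist[i, c] > threshold for c in chosen):
                    chosen.append(i)
                if len(chosen) == k:
                    break
            if len(chosen) < 2:
                raise ValueError(f"sample {s}: similarity threshold too strict")
            membership[chosen, j] = 1
            continue
        idx = rng.choice(n, size=k, replace=False, p=w / w.sum())
        membership[idx, j] = 1

    abundance = rng.lognormal(0.0, scenario.abundance_sigma, size=n)
    counts = np.zeros_like(membership)
    for j in range(membership.shape[1]):
        members = np.flatnonzero(membership[:, j])
        depth = max(int(rng.poisson(scenario.depth_mean)), len(members))
        p = abundance[members] / abundance[members].sum()
        counts[members, j] = 1 + rng.multinomial(depth - len(members), p)
    cm = CommunityMatrix(
        pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"),
                     columns=list(env.sample_ids))
    )
    truth["richness"] = {s: int(richness[s]) for s in env.sample_ids}
    return cm, truth


def generate_dataset(scenario: SynthScenario) -> SynthDataset:
    """Tree, traits, environment and community from one scenario seed."""
    ss = np.random.SeedSequence(scenario.seed)
    s_tree, s_trait, s_env, s_comm, s_tax = ss.spawn(5)
    tree = gen_tree(scenario.n_tips, scenario.birth_rate, seed=s_tree)
    traits = evolve_trait(tree, scenario.trait_sigma2, seed=s_trait)
    env = gen_env(scenario.areas, scenario.env_effect, seed=s_env)
    cm, truth = assemble_communities(tree, traits, scenario, env=env, seed=s_comm)
    taxonomy = assign_taxonomy(tree, seed=s_tax)
    cm = CommunityMatrix(cm.counts, taxonomy=taxonomy)
    truth["scenario"] = {
        "n_tips": scenario.n_tips,
        "assembly": scenario.assembly,
        "seed": scenario.seed,
    }
    return SynthDataset(cm, tree, env, traits, truth)


def linear_response(
    env: EnvTable | pd.DataFrame,
    coeffs: dict[str, float],
    sigma: float = 1.0,
    intercept: float = 0.0,
    seed=None,
) -> pd.Series:
    """A response with known linear dependence on (transformed) covariates.

    ``coeffs`` keys may name raw covariates, ``Mud_sqrt`` or interaction
    terms joined with ``:``; used to exercise the regression protocol
    against known truth.
    """
    from .envmodel import transform_env

    x = transform_env(env)
    rng = np.random.default_rng(seed)
    y = np.full(len(x), float(intercept))
    for term, beta in coeffs.items():
        col = np.ones(len(x))
        for part in term.split(":"):
            col = col * x[part].to_numpy(dtype=float)
        y = y + beta * col
    y = y + rng.normal(0.0, sigma, size=len(x))
    return pd.Series(y, index=x.index, name="response")
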