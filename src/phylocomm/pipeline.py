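"""End-to-end orchestration: one config, one seed, one output directory.

``run_all`` executes the full analysis graph — (optionally) synthesize
inputs, align, rarefy, intersections and generic richness, co-occurrence
tests at all scales, phylogenetic structure (ses + area tests), UniFrac
and PCoA, and the PD ~ environment regression — writing every stage's
table under ``out_dir`` plus a JSON run manifest with versions, seeds
and input digests. Stages are cached: a re-run recomputes a stage only
when its parameters or any upstream stage changed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import community as comm
from . import cooccurrence as cooc
from . import envmodel, io, phylometrics, phylostructure, synthetic
from .nullmodels import NULL_MODELS

log = logging.getLogger("phylocomm")

__all__ = ["RunConfig", "run_all"]

#: fixed spawn order of the run-level seed (documented splitting scheme)
SEED_STAGES = ("synth", "rarefy", "cooccur", "phylostructure")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # either real input paths ...
    counts: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    metadata: str | None = None
    # ... or a synthetic scenario
    scenario: synthetic.SynthScenario | None = None
    rarefaction_depth: int | str = "auto"  # "auto" = minimum column sum
    cooccur_reps: int = 10_000
    phylo_reps: int = 999
    null_models: tuple[str, ...] = NULL_MODELS
    alpha: float = 0.05

    def validate(self) -> None:
        if self.counts is None and self.scenario is None:
            raise ValueError("config needs either input paths or a synth scenario")
        if self.cooccur_reps < 1 or self.phylo_reps < 1:
            raise ValueError("replicate counts must be positive")
        unknown = set(self.null_models) - set(NULL_MODELS)
        if unknown:
            raise ValueError(f"unknown null models: {sorted(unknown)}")
        if self.rarefaction_depth != "auto" and int(self.rarefaction_depth) < 0:
            raise ValueError("rarefaction depth must be 'auto' or >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "scenario" in raw and raw["scenario"] is not None:
            raw["scenario"] = synthetic.SynthScenario(**raw["scenario"])
        if "null_models" in raw:
            raw["null_models"] = tuple(raw["null_models"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scenario is not None:
            d["scenario"] = dataclasses.asdict(self.scenario)
        d["null_models"] = list(self.null_models)
        return d


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _param_hash(*parts) -> str:
    return hashlib.sha256(repr(parts).encode()).hexdigest()[:16]


class _Runner:
    """Stage bookkeeping: skip a stage when its hash chain is unchanged."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.state_path = out_dir / "stage_state.json"
        self.prev = (
            json.loads(self.state_path.read_text()) if self.state_path.exists() else {}
        )
        self.state: dict[str, str] = {}
        self.manifest_stages: dict[str, dict] = {}

    def should_run(self, stage: str, h: str, outputs: list[Path]) -> bool:
        cached = self.prev.get(stage) == h and all(p.exists() for p in outputs)
        self.state[stage] = h
        self.manifest_stages[stage] = {
            "hash": h,
            "cached": cached,
            "outputs": [p.name for p in outputs],
        }
        return not cached

    def save(self) -> None:
        self.state_path.write_text(json.dumps(self.state, indent=1))


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = _Runner(out)
    seeds = {
        name: seq
        for name, seq in zip(SEED_STAGES, np.random.SeedSequence(config.seed).spawn(len(SEED_STAGES)))
    }
    seed_report = {k: int(v.generate_state(1)[0]) for k, v in seeds.items()}
    manifest: dict = {
        "tool": "phylocomm",
        "version": __version__,
        "python": sys.version.split()[0],
        "config": config.to_jsonable(),
        "stage_seeds": seed_report,
        "inputs": {},
    }

    # -- stage: inputs ------------------------------------------------------
    paths = {
        "counts": out / "community.tsv",
        "tree": out / "tree.nwk",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
    }
    if config.scenario is not None and config.counts is None:
        h = _param_hash("synth", dataclasses.asdict(config.scenario))
        if runner.should_run("synth", h, list(paths.values())):
            log.info("stage synth: generating scenario %r", config.scenario.assembly)
            ds = synthetic.generate_dataset(config.scenario)
            io.write_count_table(ds.community, paths["counts"])
            io.write_tree(ds.tree, paths["tree"])
            io.write_metadata(ds.env, paths["metadata"])
            io.write_taxonomy(ds.community.taxonomy or {}, paths["taxonomy"])
            (out / "truth.json").write_text(json.dumps(ds.truth, indent=1, default=str))
    else:
        for key, src in (("counts", config.counts), ("tree", config.tree),
                         ("metadata", config.metadata),
                         ("taxonomy", config.taxonomy)):
            if src is not None:
                paths[key] = Path(src)
    for key, p in paths.items():
        if p.exists():
            manifest["inputs"][key] = {"path": str(p), "sha256": _digest(p)}

    taxonomy = (
        io.read_taxonomy(paths["taxonomy"]) if paths["taxonomy"].exists() else None
    )
    cm = io.read_count_table(paths["counts"], taxonomy=taxonomy)
    tree = io.read_tree(paths["tree"]) if paths["tree"].exists() else None
    env = io.read_metadata(paths["metadata"]) if paths["metadata"].exists() else None
    cm, tree, env, align_report = io.align_inputs(cm, tree, env)
    (out / "align_report.json").write_text(json.dumps(align_report, indent=1))

    # -- stage: rarefy ------------------------------------------------------
    depth = (
        int(cm.counts.sum(axis=0).min())
        if config.rarefaction_depth == "auto"
        else int(config.rarefaction_depth)
    )
    rare_path = out / "rarefied.tsv"
    h = _param_hash("rarefy", manifest["inputs"], depth, seed_report["rarefy"])
    if runner.should_run("rarefy", h, [rare_path]):
        log.info("stage rarefy: depth %d", depth)
        rare = comm.rarefy(cm, depth, seed=seeds["rarefy"])
        rare, dropped = comm.drop_empty_taxa(rare)
        io.write_count_table(rare, rare_path)
        (out / "rarefy_dropped.json").write_text(json.dumps(dropped, indent=1))
    rare = io.read_count_table(rare_path, taxonomy=None)
    if tree is not None:
        rare_t, tree_r, _, _ = io.align_inputs(rare, tree, None)
    else:
        rare_t, tree_r = rare, None
    pa = rare.presence_absence()
    area_of_sample = (
        {s: env.area[s] for s in rare.sample_ids} if env is not None else None
    )

    # -- stage: intersections & generic richness ----------------------------
    if area_of_sample is not None:
        inter = comm.intersection_summary(pa, area_of_sample)
        inter.to_frame().to_csv(out / "intersections.tsv", sep="\t", index=False)
        manifest["intersections"] = {
            "n_taxa": inter.n_taxa,
            "unique_fraction": inter.unique_fraction(),
        }
        if taxonomy is not None:
            rare_tax = dataclasses.replace(
                rare, taxonomy={t: taxonomy[t] for t in rare.taxon_ids if t in taxonomy}
            )
            genera = comm.aggregate_by_rank(rare_tax, "genus")
            assigned = genera.counts.drop(index="Unassigned", errors="ignore")
            richness = (assigned > 0).sum(axis=0)
            by_area: dict[str, list] = {}
            for s, r in richness.items():
                by_area.setdefault(area_of_sample[s], []).append(int(r))
            report = comm.richness_anova({k: np.array(v) for k, v in by_area.items()})
            (out / "richness_anova.json").write_text(json.dumps({
                "richness_by_area": by_area,
                "shapiro_p": report.shapiro_p,
                "levene_p": report.levene_p,
                "anova_f": report.anova_f,
                "anova_p": report.anova_p,
                "pairwise": report.pairwise.to_dict(orient="records"),
                "excluded_groups": list(report.excluded_groups),
            }, indent=1, default=str))

    # -- stage: co-occurrence -----------------------------------------------
    cooccur_path = out / "cooccurrence.tsv"
    h = _param_hash("cooccur", runner.state["rarefy"], config.cooccur_reps,
                    seed_report["cooccur"])
    if area_of_sample is not None and runner.should_run("cooccur", h, [cooccur_path]):
        log.info("stage cooccur: %d reps", config.cooccur_reps)
        table = cooc.run_scales(
            pa, area_of_sample, n_reps=config.cooccur_reps, seed=seeds["cooccur"]
        )
        table.to_csv(cooccur_path, sep="\t", index=False)

    # -- stage: phylogenetic structure --------------------------------------
    if tree_r is not None:
        rooted = tree_r.midpoint_root()
        h = _param_hash("phylostructure", runner.state["rarefy"], config.phylo_reps,
                        config.null_models, seed_report["phylostructure"])
        ses_path = out / "ses.tsv"
        tests_path = out / "area_tests.tsv"
        uf_path = out / "unifrac.tsv"
        pcoa_path = out / "pcoa.tsv"
        outs = [ses_path, uf_path, pcoa_path] + (
            [tests_path] if area_of_sample else []
        )
        if runner.should_run("phylostructure", h, outs):
            log.info("stage phylostructure: %d reps x %d models",
                     config.phylo_reps, len(config.null_models))
            pa_t = rare_t.presence_absence()
            res = phylostructure.ses_metrics(
                pa_t, rooted, models=config.null_models,
                n_reps=config.phylo_reps, seed=seeds["phylostructure"],
            )
            res.tidy().to_csv(ses_path, sep="\t", index=False)
            if area_of_sample:
                tests = phylostructure.area_tests(res, area_of_sample, config.alpha)
                tests.to_csv(tests_path, sep="\t", index=False)
            dm = phylometrics.unweighted_unifrac(pa_t, rooted)
            dm.to_csv(uf_path, sep="\t")
            ord_res = phylometrics.pcoa(dm)
            coords = ord_res.coordinates.copy()
            coords.to_csv(pcoa_path, sep="\t")
            (out / "pcoa_eigenvalues.json").write_text(json.dumps({
                "eigenvalues": ord_res.eigenvalues.tolist(),
                "proportion_explained": ord_res.proportion_explained.tolist(),
                "n_negative": ord_res.n_negative,
            }, indent=1))

        # -- stage: environment regression ----------------------------------
        if env is not None and {"TOC", "CPE", "Mud"}.issubset(env.variables.columns):
            pd_values = pd.Series(
                {
                    s: phylometrics.faith_pd(
                        rooted,
                        list(rare_t.counts.index[rare_t.counts[s] > 0]),
                    )
                    for s in rare_t.sample_ids
                },
                name="PD",
            )
            pd_values.rename_axis("sample_id").to_csv(out / "pd.tsv", sep="\t")
            screening = envmodel.screen_variables(env)
            report = envmodel.backward_eliminate(pd_values, env, alpha=config.alpha)
            (out / "regression.json").write_text(json.dumps({
                "screening": {
                    "levene_p": screening.levene_p,
                    "vif": screening.vif,
                    "pearson": screening.pearson.to_dict(),
                    "flagged": list(screening.flagged),
                },
                "trace": [list(t) for t in report.trace],
                "final_terms": list(report.final_terms),
                "coefficients": report.coefficients.to_dict(orient="records"),
                "r_squared": report.r_squared,
                "adj_r_squared": report.adj_r_squared,
                "outliers_removed": [list(o) for o in report.outliers_removed],
                "shapiro_residuals_p": report.shapiro_residuals_p,
                "significant": report.significant,
            }, indent=1))

    runner.save()
    manifest["stages"] = runner.manifest_stages
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
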