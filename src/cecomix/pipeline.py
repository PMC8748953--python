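"""Configuration-driven end-to-end driver.

Sequences the analysis stages — abundance → diversity → group statistics →
clustering → correlations → species consensus — over one set of input
files, skipping any stage whose optional input (tree, metabolites, species
tables) is absent.  Every stochastic stage receives a seed derived
deterministically from the master seed, and a JSON manifest records the
config, per-stage seeds, input checksums, and stage statuses, which is
enough to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import __version__
from .feature_table import (read_feature_table, read_sample_metadata,
                            aggregate_by_rank, relative_abundance,
                            observed_richness, fb_ratio)
from .diversity import alpha_diversity, bray_curtis, unifrac, pcoa, anosim
from .group_stats import run_feature_screen, screen_to_frame, posthoc_to_frame
from .clustering import kmeans_profile
from .decider import correlate_matrix, records_to_frame
from .consensus import (consensus_species, genus_level_consistency,
                        calls_to_frame)


@dataclass
class RunConfig:
    feature_table: str
    metadata: str
    tree: str | None = None
    metabolites: str | None = None
    species_best_hit: str | None = None
    species_bayes: str | None = None
    ranks: tuple[str, ...] = ("phylum", "genus")
    alpha: float = 0.05
    fdr: float = 0.05
    anosim_permutations: int = 999
    k: int | None = None
    k_range: tuple[int, int] = (1, 10)
    n_restarts: int = 50
    seed: int = 0
    outdir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        doc = yaml.safe_load(Path(path).read_text())
        if "ranks" in doc:
            doc["ranks"] = tuple(doc["ranks"])
        if "k_range" in doc:
            doc["k_range"] = tuple(doc["k_range"])
        return cls(**doc)


def derive_seeds(master: int, names: list[str]) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(master).spawn(len(names))
    return {name: int(ss.generate_state(1)[0] % (2 ** 31))
            for name, ss in zip(names, children)}


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage whose inputs are present; return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed, ["anosim", "kmeans"])
    stages: dict[str, str] = {}
    manifest = {
        "cecomix_version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds,
        "input_checksums": {},
        "stages": stages,
    }
    for key in ("feature_table", "metadata", "tree", "metabolites",
                "species_best_hit", "species_bayes"):
        p = getattr(config, key)
        if p:
            manifest["input_checksums"][key] = _checksum(p)

    table = read_feature_table(config.feature_table)
    meta = read_sample_metadata(config.metadata)
    meta = meta.reindex(table.sample_ids)
    tree = TreeNode.read(config.tree) if config.tree else None

    # --- abundance ---------------------------------------------------------
    relab_by_rank = {}
    for rank in config.ranks:
        agg = aggregate_by_rank(table, rank)
        relab = relative_abundance(agg, rank=rank)
        agg.to_csv(out / f"counts_{rank}.tsv", sep="\t")
        relab.values.to_csv(out / f"relative_abundance_{rank}.tsv", sep="\t")
        relab_by_rank[rank] = relab
    observed_richness(table).to_csv(out / "observed_richness.tsv", sep="\t")
    if "phylum" in relab_by_rank:
        try:
            fb_ratio(relab_by_rank["phylum"]).to_csv(
                out / "fb_ratio.tsv", sep="\t")
        except ValueError:
            pass  # phyla of interest absent; ratio not applicable
    stages["abundance"] = "ok"

    # --- diversity ---------------------------------------------------------
    alpha_df = alpha_diversity(table, tree=tree)
    alpha_df.to_csv(out / "alpha_diversity.tsv", sep="\t")
    asv_relab = relative_abundance(table.counts, rank="asv")
    dms = {"bray-curtis": bray_curtis(asv_relab)}
    if tree is not None:
        dms["unweighted-unifrac"] = unifrac(table, tree, weighted=False)
        dms["weighted-unifrac"] = unifrac(table, tree, weighted=True)
        stages["unifrac"] = "ok"
    else:
        stages["unifrac"] = "skipped (no tree)"
    anosim_rows = []
    for name, dm in dms.items():
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out / f"distance_{name}.tsv", sep="\t")
        ordination = pcoa(dm)
        ordination.coordinates.to_csv(out / f"pcoa_{name}.tsv", sep="\t")
        (out / f"pcoa_{name}_eigenvalues.json").write_text(json.dumps({
            "eigenvalues": ordination.eigenvalues.tolist(),
            "percent_explained": ordination.percent_explained.tolist()}))
        res = anosim(dm, meta, n_permutations=config.anosim_permutations,
                     seed=seeds["anosim"])
        anosim_rows.append({"metric": name, "R": res.R, "p": res.p,
                            "n_permutations": res.n_permutations})
    pd.DataFrame(anosim_rows).to_csv(out / "anosim.tsv", sep="\t", index=False)
    stages["diversity"] = "ok"

    # --- group statistics --------------------------------------------------
    for rank, relab in relab_by_rank.items():
        results = run_feature_screen(relab, meta, alpha=config.alpha,
                                     fdr=config.fdr)
        screen_to_frame(results).to_csv(out / f"screen_{rank}.tsv", sep="\t")
        posthoc_to_frame(results).to_csv(out / f"posthoc_{rank}.tsv",
                                         sep="\t", index=False)
    stages["group_stats"] = "ok"

    # --- clustering --------------------------------------------------------
    lo, hi = config.k_range
    cluster = kmeans_profile(asv_relab, meta, k=config.k,
                             k_range=range(lo, hi + 1),
                             n_restarts=config.n_restarts,
                             seed=seeds["kmeans"])
    cluster.assignments.to_csv(out / "cluster_assignments.tsv", sep="\t")
    pd.Series(cluster.sse_by_k, name="sse").rename_axis("k").to_csv(
        out / "cluster_sse.tsv", sep="\t")
    cluster.composition.to_csv(out / "cluster_composition.tsv", sep="\t")
    stages["clustering"] = "ok"

    # --- correlations ------------------------------------------------------
    if config.metabolites:
        metabolites = pd.read_csv(config.metabolites, sep="\t", index_col=0)
        records = correlate_matrix(relab_by_rank.get("genus", asv_relab),
                                   metabolites, alpha=config.alpha,
                                   fdr=config.fdr)
        records_to_frame(records).to_csv(out / "correlations.tsv", sep="\t",
                                         index=False)
        stages["correlations"] = "ok"
    else:
        stages["correlations"] = "skipped (no metabolites)"

    # --- species consensus -------------------------------------------------
    if config.species_best_hit and config.species_bayes:
        a = pd.read_csv(config.species_best_hit, sep="\t")
        b = pd.read_csv(config.species_bayes, sep="\t")
        calls, summary = consensus_species(a, b)
        calls_to_frame(calls).to_csv(out / "consensus_calls.tsv", sep="\t")
        genus_level_consistency(calls, table.taxonomy).to_csv(
            out / "genus_consistency.tsv", sep="\t")
        (out / "consensus_summary.json").write_text(json.dumps(summary))
        stages["consensus"] = "ok"
    else:
        stages["consensus"] = "skipped (no species tables)"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
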