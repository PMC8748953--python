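"""Synthetic microbiome–metabolome cohorts with known ground truth.

The generator emulates the statistical structure of a four-group mouse
cecal-microbiome study: ~25 retained samples in unbalanced treatment groups
(two diet controls, a diet-switch group, and a treated diet-switch group),
six phyla plus an unclassified bin, 59 classified genera plus an
unclassified bin, one heavily dominant genus, deep amplicon libraries
(~130k tags/sample), planted group effects on selected genera, and a
metabolite matrix with planted genus–metabolite rank correlations.

The noise model is Dirichlet-multinomial: per group, a mean composition is
built from base genus weights times group fold-changes (the dominant genus
mean is pinned directly per group); per sample a composition is drawn from
a Dirichlet with that mean and a total concentration controlling
overdispersion, and ASV counts are drawn multinomially at the sample's
library size.  Metabolites are lognormal with a Gaussian-copula link to
their planted genus, so the planted ``r`` is a rank (copula) correlation,
invariant to the monotone transforms involved.

Every planted truth is recorded in a JSON-serialisable ledger so tests can
score recovery.  All randomness flows from the config seed; the same config
yields bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from skbio import TreeNode

from .feature_table import (FeatureTable, RANKS, UNCLASSIFIED,
                            write_feature_table_tsv)


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Study design constants
# ---------------------------------------------------------------------------

GROUPS = ("LD/LD-V", "WD/WD-V", "WD/LD-V", "WD/LD-T")

#: Animals enrolled per group.
ENROLLED = {"LD/LD-V": 8, "WD/WD-V": 6, "WD/LD-V": 8, "WD/LD-T": 8}

#: Cecal samples lost per group (flushed ceca during early collection).
EXCLUDED = {"LD/LD-V": 2, "WD/WD-V": 1, "WD/LD-V": 1, "WD/LD-T": 1}


def retained_samples(enrolled: dict[str, int] | None = None,
                     excluded: dict[str, int] | None = None
                     ) -> tuple[dict[str, int], int]:
    """Sample accounting: per-group retained counts and their total."""
    enrolled = dict(ENROLLED if enrolled is None else enrolled)
    excluded = dict(EXCLUDED if excluded is None else excluded)
    retained = {g: enrolled[g] - excluded.get(g, 0) for g in enrolled}
    if any(v < 0 for v in retained.values()):
        raise SyntheticError("more exclusions than enrolled animals")
    return retained, sum(retained.values())


DOMINANT_GENUS = "Ileibacterium"

#: Group means of the dominant genus (proportion scale).
DOMINANT_MEANS = {"LD/LD-V": 0.51, "WD/WD-V": 0.68,
                  "WD/LD-V": 0.40, "WD/LD-T": 0.41}

#: Default planted genus-level group effects (fold change on the genus's
#: share of the non-dominant mass, relative to the LD control baseline).
PLANTED_EFFECTS: dict[str, dict[str, float]] = {
    "Parasutterella": {"WD/WD-V": 0.5, "WD/LD-V": 8.0, "WD/LD-T": 8.0},
    "Akkermansia": {"WD/WD-V": 0.5, "WD/LD-V": 8.0, "WD/LD-T": 2.0},
    "Erysipelatoclostridium": {"WD/WD-V": 0.5, "WD/LD-V": 6.0, "WD/LD-T": 0.5},
    "Lactobacillus": {"WD/WD-V": 0.5, "WD/LD-V": 0.7, "WD/LD-T": 25.0},
    "Acetatifactor": {"WD/LD-T": 6.0},
    "[Eubacterium] coprostanoligenes group": {"WD/LD-V": 4.0, "WD/LD-T": 4.0},
    "Family XIII UCG-001": {"WD/LD-V": 5.0, "WD/LD-T": 5.0},
    "Ruminiclostridium 6": {"WD/WD-V": 0.0, "WD/LD-V": 0.0, "WD/LD-T": 0.0},
    "Ruminococcaceae UCG-004": {"WD/LD-V": 0.0, "WD/LD-T": 0.0},
    "Ruminococcaceae UCG-009": {"WD/WD-V": 0.1, "WD/LD-V": 0.3},
    UNCLASSIFIED: {"WD/LD-V": 3.0, "WD/LD-T": 3.0},
}

#: Phylum-level fold adjustments applied to every genus of the phylum
#: (diet shifts the Firmicutes:Bacteroidetes balance and Actinobacteria).
PHYLUM_EFFECTS: dict[str, dict[str, float]] = {
    "Bacteroidetes": {"WD/WD-V": 0.4, "WD/LD-V": 1.2, "WD/LD-T": 1.3},
    "Actinobacteria": {"WD/WD-V": 3.0},
}


def _default_genus_table() -> pd.DataFrame:
    """59 classified genera (6 phyla) + the unclassified bin, with base
    weights for the LD-control composition."""
    rows: list[tuple[str, str, float]] = [(DOMINANT_GENUS, "Firmicutes", 0.0)]
    firmicutes = [
        ("Lactobacillus", 0.008), ("Erysipelatoclostridium", 0.004),
        ("Acetatifactor", 0.005),
        ("[Eubacterium] coprostanoligenes group", 0.010),
        ("Family XIII UCG-001", 0.004), ("Ruminiclostridium 6", 0.010),
        ("Ruminococcaceae UCG-004", 0.005), ("Ruminococcaceae UCG-009", 0.008),
        ("Romboutsia", 0.015), ("Lactococcus", 0.003),
        ("Staphylococcus", 0.002), ("UBA1819", 0.002), ("Dubosiella", 0.015),
        ("Turicibacter", 0.010), ("Faecalibaculum", 0.012),
    ]
    filler = ["Blautia", "Roseburia", "Oscillibacter", "Butyricicoccus",
              "Anaerotruncus", "Lachnoclostridium", "Ruminiclostridium 9",
              "Lachnospiraceae NK4A136 group", "Lachnospiraceae UCG-006",
              "Tyzzerella", "Enterococcus", "Streptococcus",
              "Clostridium sensu stricto 1", "Candidatus Arthromitus",
              "Anaerostipes", "Marvinbryantia", "Christensenellaceae R-7 group",
              "Intestinimonas", "Flavonifractor", "Harryflintia",
              "Papillibacter", "Ruminococcus 1", "Angelakisella",
              "GCA-900066575"]
    firmicutes += [(g, 0.012 * 0.85 ** i) for i, g in enumerate(filler)]
    rows += [(g, "Firmicutes", w) for g, w in firmicutes]
    bacteroidetes = [("Bacteroides", 0.025), ("Alistipes", 0.020),
                     ("Muribaculum", 0.015), ("Parabacteroides", 0.010),
                     ("Prevotellaceae UCG-001", 0.006), ("Odoribacter", 0.006),
                     ("Butyricimonas", 0.005), ("Rikenella", 0.005),
                     ("Alloprevotella", 0.004), ("Barnesiella", 0.004),
                     ("Coprobacter", 0.003), ("Duncaniella", 0.003)]
    rows += [(g, "Bacteroidetes", w) for g, w in bacteroidetes]
    rows += [("Parasutterella", "Proteobacteria", 0.003),
             ("Akkermansia", "Verrucomicrobia", 0.004),
             ("Bifidobacterium", "Actinobacteria", 0.004),
             ("Enterorhabdus", "Actinobacteria", 0.002),
             ("Adlercreutzia", "Actinobacteria", 0.002),
             ("Coriobacteriaceae UCG-002", "Actinobacteria", 0.002),
             ("Mucispirillum", "Deferribacteres", 0.005),
             (UNCLASSIFIED, UNCLASSIFIED, 0.050)]
    df = pd.DataFrame(rows, columns=["genus", "phylum", "base_weight"])
    return df.set_index("genus")


def _default_planted_correlations() -> list[tuple[str, str, float]]:
    pairs: list[tuple[str, str, float]] = []
    for i in range(1, 21):
        pairs.append(("Parasutterella", f"met_{i:03d}", 0.7))
    for i in range(21, 31):
        pairs.append(("Parasutterella", f"met_{i:03d}", -0.7))
    for i in range(31, 35):
        pairs.append(("Lactobacillus", f"met_{i:03d}", 0.7))
    for i in range(35, 39):
        pairs.append(("Erysipelatoclostridium", f"met_{i:03d}", -0.7))
    return pairs


@dataclass
class SyntheticConfig:
    """Full parameterisation of a synthetic cohort."""

    enrolled: dict[str, int] = field(default_factory=lambda: dict(ENROLLED))
    excluded: dict[str, int] = field(default_factory=lambda: dict(EXCLUDED))
    genus_table: pd.DataFrame = field(default_factory=_default_genus_table,
                                      repr=False)
    dominant_genus: str = DOMINANT_GENUS
    dominant_means: dict[str, float] = field(
        default_factory=lambda: dict(DOMINANT_MEANS))
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(f) for g, f in PLANTED_EFFECTS.items()})
    phylum_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(f) for p, f in PHYLUM_EFFECTS.items()})
    concentration: float = 20.0
    library_size_mean: float = 130_000.0
    library_size_sigma: float = 0.25
    n_metabolites: int = 170
    planted_correlations: list[tuple[str, str, float]] = field(
        default_factory=_default_planted_correlations)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.enrolled.items():
            if n - self.excluded.get(g, 0) < 2:
                raise SyntheticError(f"group {g!r} retains < 2 samples")
        for _, _, r in self.planted_correlations:
            if not -1 < r < 1:
                raise SyntheticError(f"target correlation {r} outside (-1, 1)")
        for folds in self.effects.values():
            for f in folds.values():
                if not np.isfinite(f) or f < 0:
                    raise SyntheticError("fold changes must be finite and >= 0")
        # Upfront feasibility: with independent genus latents a metabolite's
        # planted correlations must satisfy sum r^2 < 1.
        per_met: dict[str, float] = {}
        for _, met, r in self.planted_correlations:
            per_met[met] = per_met.get(met, 0.0) + r * r
        bad = [m for m, s in per_met.items() if s >= 1.0]
        if bad:
            raise SyntheticError(
                f"infeasible correlation structure for metabolite(s) {bad}")

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "SyntheticConfig":
        """A cohort with no planted effects or correlations: group labels
        are exchangeable by construction."""
        means = {g: 0.51 for g in GROUPS}
        return cls(effects={}, phylum_effects={}, dominant_means=means,
                   planted_correlations=[], seed=seed, **kwargs)

    def group_sizes(self) -> dict[str, int]:
        return retained_samples(self.enrolled, self.excluded)[0]


# ---------------------------------------------------------------------------
# Composition model
# ---------------------------------------------------------------------------

def expected_mean_composition(config: SyntheticConfig, group: str) -> pd.Series:
    """Expected genus-level mean composition (proportions) for one group.

    The dominant genus's mean is pinned to its configured target; every
    other genus receives base_weight × (genus fold) × (phylum fold), and the
    remaining mass 1 − m_dominant is distributed proportionally.
    """
    tab = config.genus_table
    m_dom = config.dominant_means.get(group, 0.51)
    weights = {}
    for genus, row in tab.iterrows():
        if genus == config.dominant_genus:
            continue
        w = float(row["base_weight"])
        w *= config.effects.get(genus, {}).get(group, 1.0)
        w *= config.phylum_effects.get(row["phylum"], {}).get(group, 1.0)
        weights[genus] = w
    total = sum(weights.values())
    if total <= 0:
        raise SyntheticError("non-dominant genus weights sum to zero")
    means = {g: w / total * (1.0 - m_dom) for g, w in weights.items()}
    means[config.dominant_genus] = m_dom
    return pd.Series(means).reindex(tab.index)


def _asvs_per_genus(config: SyntheticConfig) -> dict[str, int]:
    out = {}
    for genus, row in config.genus_table.iterrows():
        w = float(row["base_weight"])
        if genus == config.dominant_genus:
            out[genus] = 8
        elif genus == UNCLASSIFIED:
            out[genus] = 6
        elif w >= 0.015:
            out[genus] = 4
        elif w >= 0.008:
            out[genus] = 3
        elif w >= 0.004:
            out[genus] = 2
        else:
            out[genus] = 1
    return out


def _blom_scores(v: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal scores (Blom offsets)."""
    from scipy.stats import rankdata
    ranks = rankdata(v)
    return norm.ppf((ranks - 0.375) / (len(v) + 0.25))


def generate_cohort(config: SyntheticConfig
                    ) -> tuple[FeatureTable, pd.Series, pd.DataFrame, dict]:
    """Draw a cohort: feature table, metadata, metabolites, truth ledger."""
    rng = np.random.default_rng(config.seed)
    sizes = config.group_sizes()
    groups = [g for g in sizes for _ in range(sizes[g])]
    sample_ids = [f"m{i + 1:02d}" for i in range(len(groups))]
    meta = pd.Series(groups, index=sample_ids, name="group")

    tab = config.genus_table
    genera = list(tab.index)
    mean_by_group = {g: expected_mean_composition(config, g) for g in sizes}

    # ASV layout: fixed per cohort; within-genus weights drawn once so the
    # genus signal is shared by its ASVs (phylogenetic coherence).
    n_asv_map = _asvs_per_genus(config)
    asv_ids, asv_genus, asv_weight = [], [], []
    counter = 1
    for genus in genera:
        k = n_asv_map[genus]
        w = rng.dirichlet(np.full(k, 2.0)) if k > 1 else np.array([1.0])
        for j in range(k):
            asv_ids.append(f"ASV_{counter:04d}")
            asv_genus.append(genus)
            asv_weight.append(w[j])
            counter += 1
    asv_weight = np.array(asv_weight)
    genus_of_asv = pd.Series(asv_genus, index=asv_ids)

    libraries = rng.lognormal(
        mean=np.log(config.library_size_mean) - config.library_size_sigma ** 2 / 2,
        sigma=config.library_size_sigma, size=len(sample_ids))
    libraries = np.maximum(libraries.round().astype(np.int64), 1000)

    counts = np.zeros((len(asv_ids), len(sample_ids)), dtype=np.int64)
    genus_idx = {g: np.where(genus_of_asv.to_numpy() == g)[0] for g in genera}
    for s, (sid, grp) in enumerate(zip(sample_ids, groups)):
        alpha = mean_by_group[grp].to_numpy() * config.concentration
        gamma = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
        gamma[alpha <= 0] = 0.0
        p_genus = gamma / gamma.sum()
        p_asv = np.zeros(len(asv_ids))
        for gi, genus in enumerate(genera):
            idx = genus_idx[genus]
            p_asv[idx] = p_genus[gi] * asv_weight[idx]
        counts[:, s] = rng.multinomial(libraries[s], p_asv / p_asv.sum())

    # Taxonomy: genus + phylum from the genus table; 2 of the unclassified
    # bin's ASVs get a fully unclassified lineage (no phylum either).
    taxonomy = pd.DataFrame(index=asv_ids, columns=list(RANKS), data=UNCLASSIFIED)
    for asv, genus in genus_of_asv.items():
        taxonomy.loc[asv, "genus"] = genus
        taxonomy.loc[asv, "phylum"] = tab.loc[genus, "phylum"]
    uncl_asvs = genus_idx[UNCLASSIFIED]
    for j in uncl_asvs[:len(uncl_asvs) - 2]:
        taxonomy.iloc[j, taxonomy.columns.get_loc("phylum")] = "Firmicutes"

    table = FeatureTable(
        counts=pd.DataFrame(counts, index=asv_ids, columns=sample_ids),
        taxonomy=taxonomy)

    metabolites, planted = _generate_metabolites(config, rng, table, meta)

    truth = {
        "seed": config.seed,
        "group_sizes": sizes,
        "library_sizes": dict(zip(sample_ids, libraries.tolist())),
        "dominant_genus": config.dominant_genus,
        "dominant_means": dict(config.dominant_means),
        "planted_effects": {g: dict(f) for g, f in config.effects.items()},
        "phylum_effects": {p: dict(f) for p, f in config.phylum_effects.items()},
        "differential_taxa": sorted(
            set(config.effects)
            | ({config.dominant_genus}
               if len(set(config.dominant_means.values())) > 1 else set())),
        "planted_correlations": planted,
        "mean_composition": {g: mean_by_group[g].round(6).to_dict()
                             for g in sizes},
    }
    return table, meta, metabolites, truth


def _generate_metabolites(config: SyntheticConfig, rng: np.random.Generator,
                          table: FeatureTable, meta: pd.Series
                          ) -> tuple[pd.DataFrame, list]:
    n = len(meta)
    names = [f"met_{i + 1:03d}" for i in range(config.n_metabolites)]
    mus = rng.uniform(np.log(1e3), np.log(1e6), size=config.n_metabolites)
    sigmas = rng.uniform(0.3, 0.6, size=config.n_metabolites)
    eps = rng.standard_normal((config.n_metabolites, n))

    by_met: dict[str, list[tuple[str, float]]] = {}
    for genus, met, r in config.planted_correlations:
        by_met.setdefault(met, []).append((genus, r))

    genus_counts = table.counts.groupby(table.taxonomy["genus"]).sum()
    relab = genus_counts / genus_counts.sum(axis=0)

    zcache: dict[str, np.ndarray] = {}

    def _z(genus: str) -> np.ndarray:
        if genus not in zcache:
            if genus not in relab.index:
                raise SyntheticError(f"planted genus {genus!r} not in cohort")
            v = relab.loc[genus].to_numpy()
            if np.ptp(v) == 0:
                raise SyntheticError(
                    f"planted genus {genus!r} has zero variance")
            zcache[genus] = _blom_scores(v)
        return zcache[genus]

    values = np.empty((config.n_metabolites, n))
    planted = []
    for i, met in enumerate(names):
        if met in by_met:
            pairs = by_met[met]
            Z = np.column_stack([_z(g) for g, _ in pairs])
            r_vec = np.array([r for _, r in pairs])
            R = np.corrcoef(Z, rowvar=False) if Z.shape[1] > 1 else np.ones((1, 1))
            w = np.linalg.solve(R, r_vec)
            s2 = 1.0 - float(r_vec @ w)
            if s2 <= 1e-9:
                raise SyntheticError(
                    f"infeasible correlation structure for {met!r}")
            latent = Z @ w + np.sqrt(s2) * eps[i]
            planted += [{"genus": g, "metabolite": met, "target_r": r}
                        for g, r in pairs]
        else:
            latent = eps[i]
        values[i] = np.exp(mus[i] + sigmas[i] * latent)
    df = pd.DataFrame(values, index=names, columns=list(meta.index))
    return df, planted


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------

def generate_tree(asv_ids, taxonomy: pd.DataFrame | None = None,
                  seed: int = 0) -> TreeNode:
    """Random rooted coalescent-style tree over the ASVs.

    ASVs of the same genus are joined first with short branches, and genus
    subtrees are then joined with longer branches, so same-genus tips are
    systematically closer (genus-level monophyly) and UniFrac behaves
    sensibly.  All branch lengths are positive; the root carries a short
    edge of its own (whole-tree convention for Faith's PD).
    """
    asv_ids = list(asv_ids)
    if len(asv_ids) < 2:
        raise SyntheticError("need at least 2 ASVs for a tree")
    rng = np.random.default_rng(seed)
    if taxonomy is not None:
        genus_of = taxonomy["genus"].to_dict()
    else:
        genus_of = {a: "all" for a in asv_ids}

    def _coalesce(nodes: list[TreeNode], scale: float, base: float) -> TreeNode:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            for child in (a, b):
                if child.length is None:
                    child.length = float(base + rng.exponential(scale))
            parent = TreeNode(children=[a, b])
            nodes.append(parent)
        return nodes[0]

    genus_roots = []
    for genus in sorted({genus_of[a] for a in asv_ids}):
        tips = [TreeNode(name=a) for a in asv_ids if genus_of[a] == genus]
        if len(tips) == 1:
            genus_roots.append(tips[0])
        else:
            genus_roots.append(_coalesce(tips, scale=0.02, base=0.005))
    if len(genus_roots) == 1:
        root = genus_roots[0]
    else:
        root = _coalesce(genus_roots, scale=0.15, base=0.05)
    if root.length is None:
        root.length = 0.05
    return root


# ---------------------------------------------------------------------------
# Species-assignment stand-ins
# ---------------------------------------------------------------------------

#: Fixed species for selected genera (used by both methods when they agree).
_KNOWN_SPECIES = {
    "Erysipelatoclostridium": "[Clostridium] cocleatum",
    "Parasutterella": "Parasutterella excrementihominis",
    "Romboutsia": "Romboutsia ilealis",
    "Lactococcus": "Lactococcus lactis",
    "Staphylococcus": "Staphylococcus xylosus",
    "UBA1819": "Ruthenibacterium lactatiformans",
}


def generate_species_assignments(table: FeatureTable, seed: int = 0,
                                 n_agree: int = 60, n_disagree: int = 11,
                                 n_single: int = 20
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic stand-in for a pair of species-assignment tables.

    Emulates the outputs of a best-hit search (species, percent identity,
    e-value) and a Bayesian classifier (species, bootstrap confidence):
    ``n_agree`` ASVs get the same species from both methods, ``n_disagree``
    get conflicting congeneric species, and ``n_single`` extra ASVs are
    assigned by the best-hit method only (best-hit searches assign more
    liberally).  Genera with a fixed known species always agree, so
    genus-level consistency has positives to find.
    """
    rng = np.random.default_rng(seed)
    genus_of = table.taxonomy["genus"]
    known = [a for a in table.asv_ids if genus_of[a] in _KNOWN_SPECIES]
    others = [a for a in table.asv_ids if a not in set(known)]
    need = n_agree + n_disagree + n_single - len(known)
    if need > len(others):
        raise SyntheticError("table has too few ASVs for the requested split")
    chosen = list(rng.choice(others, size=max(need, 0), replace=False))
    agree = known + chosen[:max(n_agree - len(known), 0)]
    rest = chosen[max(n_agree - len(known), 0):]
    disagree, single = rest[:n_disagree], rest[n_disagree:]

    def _binomial(asv: str, tag: str) -> str:
        genus = genus_of[asv]
        if genus in _KNOWN_SPECIES:
            return _KNOWN_SPECIES[genus]
        stem = (genus.split()[0].lower() if genus != UNCLASSIFIED
                else "Dubosiella")
        return f"{stem.capitalize()} {tag}"

    rows_hit, rows_blca = [], []
    for asv in agree:
        sp = _binomial(asv, "concordans")
        # Exercise bracket normalisation: best-hit strips brackets.
        rows_hit.append((asv, sp.replace("[", "").replace("]", "")))
        rows_blca.append((asv, sp))
    for asv in disagree:
        rows_hit.append((asv, _binomial(asv, "alpha")))
        rows_blca.append((asv, _binomial(asv, "beta")))
    for asv in single:
        rows_hit.append((asv, _binomial(asv, "solum")))

    best_hit = pd.DataFrame(rows_hit, columns=["asv_id", "species"])
    best_hit["identity"] = rng.uniform(97, 100, len(best_hit)).round(2)
    best_hit["evalue"] = 10.0 ** rng.uniform(-140, -60, len(best_hit))
    blca = pd.DataFrame(rows_blca, columns=["asv_id", "species"])
    blca["confidence"] = rng.uniform(80, 100, len(blca)).round(2)
    return best_hit, blca


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_cohort(outdir: str | Path, table: FeatureTable, meta: pd.Series,
                 metabolites: pd.DataFrame, truth: dict,
                 tree: TreeNode | None = None,
                 species: tuple[pd.DataFrame, pd.DataFrame] | None = None
                 ) -> dict[str, Path]:
    """Write a cohort in the same formats the pipeline reads."""
    import json
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"feature_table": outdir / "feature_table.tsv",
             "metadata": outdir / "metadata.tsv",
             "metabolites": outdir / "metabolites.tsv",
             "truth": outdir / "truth.json"}
    write_feature_table_tsv(table, paths["feature_table"])
    meta.rename_axis("sample_id").to_frame().to_csv(paths["metadata"], sep="\t")
    metabolites.rename_axis("metabolite").to_csv(paths["metabolites"], sep="\t")
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    if tree is not None:
        paths["tree"] = outdir / "tree.nwk"
        tree.write(str(paths["tree"]))
    if species is not None:
        paths["species_best_hit"] = outdir / "species_best_hit.tsv"
        paths["species_bayes"] = outdir / "species_bayes.tsv"
        species[0].to_csv(paths["species_best_hit"], sep="\t", index=False)
        species[1].to_csv(paths["species_bayes"], sep="\t", index=False)
    return paths
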