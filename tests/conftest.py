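import numpy as np
import pandas as pd
import pytest

import cecomix as cx
from cecomix.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def study_cohort():
    """One default (study-emulating) synthetic cohort, shared read-only."""
    table, meta, metabolites, truth = cx.generate_cohort(SyntheticConfig(seed=1))
    return {"table": table, "meta": meta, "metabolites": metabolites,
            "truth": truth}


@pytest.fixture(scope="session")
def genus_relab(study_cohort):
    agg = cx.aggregate_by_rank(study_cohort["table"], "genus")
    return cx.relative_abundance(agg, rank="genus")


@pytest.fixture()
def tiny_table():
    """3 ASVs x 2 samples with mixed classification."""
    counts = pd.DataFrame([[3, 0], [4, 5], [2, 1]],
                          index=["ASV_1", "ASV_2", "ASV_3"],
                          columns=["s1", "s2"])
    taxonomy = pd.DataFrame(
        {"phylum": ["Firmicutes", "Firmicutes", "unclassified"],
         "genus": ["GenA", "GenA", "unclassified"]},
        index=counts.index)
    return cx.FeatureTable(counts=counts, taxonomy=taxonomy)


@pytest.fixture()
def four_groups():
    """Balanced 4-group metadata over 24 samples (6 per group)."""
    samples = [f"s{i:02d}" for i in range(24)]
    return pd.Series([f"G{i // 6}" for i in range(24)], index=samples,
                     name="group")


def random_counts(rng, n_asv=20, n_samples=6):
    counts = pd.DataFrame(rng.integers(0, 50, size=(n_asv, n_samples)),
                          index=[f"A{i}" for i in range(n_asv)],
                          columns=[f"s{i}" for i in range(n_samples)])
    genera = rng.choice(["g1", "g2", "g3", "unclassified"], size=n_asv)
    phyla = np.where(genera == "unclassified", "unclassified", "P1")
    taxonomy = pd.DataFrame({"phylum": phyla, "genus": genera},
                            index=counts.index)
    return cx.FeatureTable(counts=counts, taxonomy=taxonomy)
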