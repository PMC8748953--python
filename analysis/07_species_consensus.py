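"""Dual-method species consensus and genus-level consistency.

Cross-compares the best-hit and Bayesian-confidence species tables,
keeping only calls on which both methods agree, and reports which genera
are internally consistent. Writes results/consensus/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import cecomix as cx
from cecomix.consensus import calls_to_frame


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.results / "consensus"
    out.mkdir(parents=True, exist_ok=True)

    table = cx.read_feature_table(args.results / "cohort/feature_table.tsv")
    best = pd.read_csv(args.results / "cohort/species_best_hit.tsv", sep="\t")
    blca = pd.read_csv(args.results / "cohort/species_bayes.tsv", sep="\t")

    calls, summary = cx.consensus_species(best, blca)
    calls_to_frame(calls).to_csv(out / "consensus_calls.tsv", sep="\t")
    (out / "summary.json").write_text(json.dumps(summary))
    print(f"{summary['n_agree']} ASVs with identical species from both "
          f"methods (definitive), {summary['n_disagree']} mapped to "
          f"dissimilar species, {summary['n_single_method']} assigned by "
          f"one method only")

    consistency = cx.genus_level_consistency(calls, table.taxonomy)
    consistency.to_csv(out / "genus_consistency.tsv", sep="\t")
    counts = consistency["status"].value_counts().to_dict()
    print(f"genus-level consistency: {counts}")


if __name__ == "__main__":
    main()
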