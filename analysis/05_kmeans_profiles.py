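"""K-means profiling of per-animal ASV relative-abundance vectors.

Computes the SSE curve over k, clusters at k = 5 (the study's choice) with
50 seeded restarts, and reports cluster sizes and treatment-group
composition to results/clustering/.
"""

import argparse
from pathlib import Path

import pandas as pd

import cecomix as cx


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--k", type=int, default=5)
    ap.add_argument("--restarts", type=int, default=50)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.results / "clustering"
    out.mkdir(parents=True, exist_ok=True)

    table = cx.read_feature_table(args.results / "cohort/feature_table.tsv")
    meta = cx.read_sample_metadata(args.results / "cohort/metadata.tsv")
    relab = cx.relative_abundance(table.counts)

    res = cx.kmeans_profile(relab, meta, k=args.k, k_range=range(1, 11),
                            n_restarts=args.restarts, seed=args.seed)
    res.assignments.to_csv(out / "assignments.tsv", sep="\t")
    pd.Series(res.sse_by_k, name="sse").rename_axis("k").to_csv(
        out / "sse_curve.tsv", sep="\t")
    res.composition.to_csv(out / "composition.tsv", sep="\t")

    from cecomix.clustering import elbow_k
    print(f"SSE elbow suggests k = {elbow_k(res.sse_by_k)}; "
          f"clustering run at k = {res.k}")
    print(res.composition.to_string())
    excl = res.composition[res.composition["exclusive"]]
    for cluster, row in excl.iterrows():
        group = row.drop(["size", "exclusive"]).idxmax()
        print(f"cluster {cluster}: {int(row['size'])} animals, "
              f"exclusively {group}")


if __name__ == "__main__":
    main()
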