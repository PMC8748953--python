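"""Alpha diversity, beta-diversity matrices, PCoA, and ANOSIM.

Writes per-sample alpha metrics, Bray-Curtis and UniFrac distance
matrices, PCoA coordinates and the ANOSIM table to results/diversity/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd
from skbio import TreeNode

import cecomix as cx


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--permutations", type=int, default=999)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.results / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    table = cx.read_feature_table(args.results / "cohort/feature_table.tsv")
    meta = cx.read_sample_metadata(args.results / "cohort/metadata.tsv")
    tree = TreeNode.read(str(args.results / "cohort/tree.nwk"))

    alpha = cx.alpha_diversity(table, tree=tree)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    print("alpha diversity group means (Shannon H bits):")
    for g, vals in alpha["shannon_H"].groupby(meta.reindex(alpha.index)):
        print(f"  {g:10s} {vals.mean():.2f}")

    relab = cx.relative_abundance(table.counts)
    dms = {
        "bray-curtis": cx.bray_curtis(relab),
        "unweighted-unifrac": cx.unifrac(table, tree, weighted=False),
        "weighted-unifrac": cx.unifrac(table, tree, weighted=True),
    }
    rows = []
    for name, dm in dms.items():
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out / f"distance_{name}.tsv", sep="\t")
        ordination = cx.pcoa(dm)
        ordination.coordinates.to_csv(out / f"pcoa_{name}.tsv", sep="\t")
        (out / f"pcoa_{name}_eigenvalues.json").write_text(json.dumps(
            {"eigenvalues": ordination.eigenvalues.tolist(),
             "percent_explained": ordination.percent_explained.tolist()}))
        res = cx.anosim(dm, meta, n_permutations=args.permutations,
                        seed=args.seed)
        rows.append({"metric": name, "R": round(res.R, 4), "p": res.p})
        print(f"ANOSIM {name:19s} R = {res.R:6.3f}  p = {res.p:.4f}")
    pd.DataFrame(rows).to_csv(out / "anosim.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
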