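"""Phylum/genus relative abundances, dominant-genus means, F:B ratio.

Reads results/cohort/ and writes aggregated counts, relative abundances,
per-sample observed richness and Firmicutes:Bacteroidetes ratios to
results/taxonomy/.
"""

import argparse
from pathlib import Path

import numpy as np

import cecomix as cx

GROUPS = ["LD/LD-V", "WD/WD-V", "WD/LD-V", "WD/LD-T"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.results / "taxonomy"
    out.mkdir(parents=True, exist_ok=True)

    table = cx.read_feature_table(args.results / "cohort/feature_table.tsv")
    meta = cx.read_sample_metadata(args.results / "cohort/metadata.tsv")

    for rank in ("phylum", "genus"):
        agg = cx.aggregate_by_rank(table, rank)
        relab = cx.relative_abundance(agg, rank=rank)
        agg.to_csv(out / f"counts_{rank}.tsv", sep="\t")
        relab.values.to_csv(out / f"relative_abundance_{rank}.tsv", sep="\t")
        print(f"{rank}: {len(relab.taxa)} taxa "
              f"({len(set(relab.taxa) - {'unclassified'})} classified)")

    genus = cx.relative_abundance(cx.aggregate_by_rank(table, "genus"),
                                  "genus")
    dom = genus.values.loc["Ileibacterium"]
    means = {g: dom[meta == g].mean() for g in GROUPS}
    print("dominant genus (Ileibacterium) mean relative abundance by group:")
    for g, m in means.items():
        print(f"  {g:10s} {m:5.1f} %")

    phylum = cx.relative_abundance(cx.aggregate_by_rank(table, "phylum"),
                                   "phylum")
    fb = cx.fb_ratio(phylum)
    fb.to_csv(out / "fb_ratio.tsv", sep="\t")
    wd = np.nanmean(fb[meta == "WD/WD-V"])
    ld_end = np.nanmean([np.nanmean(fb[meta == g])
                         for g in GROUPS if g != "WD/WD-V"])
    print(f"F:B ratio, WD-control group mean = {wd:.1f}; LD-ending groups "
          f"mean = {ld_end:.1f} ({wd / ld_end:.1f}-fold higher on WD)")

    rich = cx.observed_richness(table)
    rich.to_csv(out / "observed_richness.tsv", sep="\t")
    print(f"observed richness: {rich.min()}-{rich.max()} classified "
          f"ASVs/sample")


if __name__ == "__main__":
    main()
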