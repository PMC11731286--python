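#!/usr/bin/env python
"""The temporal candidate cascade.

Regresses each gene's KPC/CRE log2 fold change on week, gates on R^2,
sustained FPKM expression, protein-coding biotype and secreted/cell-surface
annotation, then intersects the survivors with the final-week DEG list and
splits them by trend direction. With ground truth available, also reports
recovery of the planted trend genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from tempotrend.containers import read_counts
from tempotrend.de import deg_sets
from tempotrend.norm import compute_fpkm, compute_tmm_factors
from tempotrend.screen import (
    classify_direction,
    fit_linear_trend,
    intersect_with_week12_degs,
    screen_candidates,
    timecourse_log2fc,
)
from tempotrend.simulate import read_truth


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    d = args.datadir

    cm = read_counts(d / "counts.tsv", d / "samples.tsv", d / "genes.tsv")
    de_tables = {
        w: pd.read_csv(d / f"de_results_w{w}.tsv", sep="\t", index_col=0)
        for w in cm.weeks
    }
    factors = compute_tmm_factors(cm)
    fits = fit_linear_trend(timecourse_log2fc(de_tables))
    fits.rename_axis("gene_id").to_csv(d / "trend_fits.tsv", sep="\t")

    decisions = screen_candidates(fits, compute_fpkm(cm, factors), cm)
    final_week = cm.weeks[-1]
    degs = set.union(*deg_sets(de_tables[final_week]).values())
    decisions = intersect_with_week12_degs(decisions, degs)
    decisions.rename_axis("gene_id").to_csv(d / "screen_decisions.tsv", sep="\t")

    trend = sorted(decisions.index[decisions["candidate_trend"]])
    final = sorted(decisions.index[decisions["candidate_final"]])
    (d / "candidates_trend.txt").write_text("\n".join(trend) + "\n")
    (d / "candidates_final.txt").write_text("\n".join(final) + "\n")
    split = classify_direction(fits, final)
    print(f"{len(trend)} trend candidates pass all four gates")
    print(f"{len(final)} remain after intersecting week-{final_week} DEGs "
          f"({len(split['up'])} continuously up, {len(split['down'])} continuously down)")

    truth_path = d / "truth.tsv"
    if truth_path.exists():
        truth = read_truth(truth_path)
        planted = set(truth.planted_trend)
        tp = len(set(trend) & planted)
        print(f"recovery vs ground truth: sensitivity {tp / len(planted):.2f}, "
              f"precision {tp / len(trend):.2f}")


if __name__ == "__main__":
    main()
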