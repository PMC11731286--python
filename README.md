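# tempotrend

A tested, reusable pipeline for temporal two-genotype bulk RNA-seq
screening, motivated by time-course comparisons of pancreatic fibroblasts
from tumor-bearing (KPC) versus control (CRE) mice sampled at 4, 6, 8, 10
and 12 weeks of age. The scientific question it serves: when almost nothing
is differentially expressed at early timepoints, which genes nonetheless
change *steadily* with disease progression, and which pathways shift?

It is written for computational biologists who have a gene × sample count
matrix with a (genotype × timepoint × replicate) design and want the whole
screen — normalization, per-timepoint testing, temporal trend selection and
enrichment — as composable, seed-deterministic library calls, plus a
synthetic-data generator with planted ground truth so every stage can be
validated without real data.

## What it computes

1. **TMM normalization** (trimmed mean of M-values): per-sample scaling
   factors from doubly trimmed, precision-weighted log ratios against a
   reference sample; CPM and FPKM on the effective library sizes.
2. **Per-timepoint differential expression**: the conditional
   negative-binomial exact test between genotypes. With group sums
   $s_A, s_B$, $n$ replicates per group and common dispersion $\varphi$
   (variance $\mu + \varphi\mu^2$), the test conditions on $s = s_A + s_B$;
   $P(Y_A = y \mid s) \propto \mathrm{NB}(y;\, n_A/\varphi)\,
   \mathrm{NB}(s-y;\, n_B/\varphi)$ at equal per-sample means, and the
   two-sided p doubles the smaller tail. $\varphi$ is estimated by
   conditional maximum likelihood; BH correction within each timepoint;
   DEG = FDR < 0.05 and $|\log_2\mathrm{FC}| \ge 1$.
3. **Temporal trend screen**: per gene, OLS of $\log_2\mathrm{FC}$ on week.
   Candidates need $R^2 \ge 0.8$, mean FPKM $\ge 1$ in one genotype at
   every week, protein-coding biotype, and a secreted-or-cell-surface
   annotation; the surviving set is intersected with the final-week DEG
   list and split by slope sign.
4. **Unweighted preranked GSEA** (exponent 0): genes ranked by
   $\log_2\mathrm{FC}$; the enrichment score is the extreme of the
   running sum ($+1/N_{hit}$ on members, $-1/N_{miss}$ otherwise);
   significance from a random same-size gene-set null, NES by same-sign
   null-mean scaling, BH across each collection, and cross-timepoint
   consistency sets.

## Worked example

The numbered scripts under `analysis/` run the screen on the default
synthetic design (2000 genes, 20 trend-up + 20 trend-down + 50 late-effect
genes planted, NB dispersion 0.05, 3 replicates per genotype per week):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_trend_screen.py
python analysis/04_gsea.py
```

which prints (seed 1):

```
simulated 2000 genes x 30 samples (90 planted: 20 trend-up, 20 trend-down, 50 late-only)
common dispersion estimate: 0.0492
week  4: 1974 genes tested, 0 up / 0 down DEGs
week  6: 1969 genes tested, 6 up / 4 down DEGs
week  8: 1976 genes tested, 20 up / 16 down DEGs
week 10: 1976 genes tested, 19 up / 18 down DEGs
week 12: 1977 genes tested, 71 up / 19 down DEGs
40 trend candidates pass all four gates
35 remain after intersecting week-12 DEGs (19 continuously up, 16 continuously down)
recovery vs ground truth: sensitivity 0.88, precision 0.88
canonical: significant sets per week [0, 10, 10, 10, 10]; 0 significant at every week
hallmark: significant sets per week [0, 5, 5, 5, 6]; 0 significant at every week
```

Reading the output: planted trends are anchored at zero fold change at
week 4, so the first timepoint is null-like (0 DEGs, no enriched sets); the
DEG burst at week 12 combines trend genes (fold change has grown to
$2^{\pm 4}$) with the 50 late-effect genes; the dispersion estimate 0.0492
recovers the generating value 0.05; and the trend cascade recovers 35/40
planted trend genes with 5 false positives — the screen's operating point
at these conditions.

The same run is available as a single command with a JSON report:

```bash
tempotrend run --outdir results/run --seed 1
```

and the individual stages as `tempotrend simulate|de|screen|gsea`.

## Layout

- `src/tempotrend/` — the library: `simulate`, `norm`, `de`, `screen`,
  `gsea`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite with independent oracles (direct-formula TMM,
  exhaustive conditional-pmf enumeration, rational-arithmetic running sums,
  exhaustive permutation nulls).
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and limitations.
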