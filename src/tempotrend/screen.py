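"""The temporal candidate cascade.

A gene survives the screen when (a) its KPC/CRE log2 fold change regresses
linearly on week with R^2 at or above a minimum, (b) it stays expressed
(mean FPKM >= 1 for at least one genotype at every week), (c) it is
protein-coding, and (d) it is annotated secreted or cell-surface. The
surviving set is then intersected with the final-week DEG list, and
candidates are split by trend direction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError

log = logging.getLogger(__name__)


def timecourse_log2fc(de_tables: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Genes x weeks matrix of log2FC, NaN where the gene was not tested.

    Genes with an incomplete profile (NaN at any week) are ineligible for
    the trend regression; callers use ``.dropna()`` and may log the excluded
    genes with reason "incomplete profile".
    """
    weeks = sorted(de_tables)
    mat = pd.DataFrame(
        {w: de_tables[w]["log2FC"] for w in weeks}
    )
    mat.columns.name = "week"
    return mat


def fit_linear_trend(lfc_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene OLS of log2FC on week (with intercept), vectorized.

    Returns a frame with slope, intercept, r2 and direction per gene; genes
    with any NaN log2FC are excluded. A constant response (zero total sum of
    squares) gets r2 = 0 and direction "flat" by convention, so it can never
    pass the R^2 gate spuriously.
    """
    complete = lfc_matrix.dropna()
    weeks = np.asarray(complete.columns, dtype=float)
    if len(weeks) < 3:
        raise ValidationError("trend regression needs >= 3 timepoints")
    if len(np.unique(weeks)) != len(weeks):
        raise ValidationError("weeks must be distinct")
    y = complete.to_numpy(dtype=float)
    xc = weeks - weeks.mean()
    sxx = float(np.sum(xc**2))
    yc = y - y.mean(axis=1, keepdims=True)
    sxy = yc @ xc
    slope = sxy / sxx
    intercept = y.mean(axis=1) - slope * weeks.mean()
    sst = np.sum(yc**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, (sxy**2) / (sxx * sst), 0.0)
    direction = np.where(slope > 0, "up", np.where(slope < 0, "down", "flat"))
    direction = np.where(sst > 0, direction, "flat")
    out = pd.DataFrame(
        {"slope": slope, "intercept": intercept, "r2": r2, "direction": direction},
        index=complete.index,
    )
    return out


def expression_gate(
    fpkm: pd.DataFrame,
    cm: CountMatrix,
    threshold: float = 1.0,
    rule: str = "genotype-fixed",
) -> pd.Series:
    """Sustained-expression gate on replicate-mean FPKM.

    ``genotype-fixed`` (default): pass iff some single genotype has mean
    FPKM >= threshold at every week. ``per-week-either``: pass iff at every
    week at least one of the genotypes clears the threshold (the genotype
    may change between weeks).
    """
    weeks = cm.weeks
    means = {}
    for genotype in ("CRE", "KPC"):
        for w in weeks:
            ids = cm.samples_of(genotype, w)
            if len(ids) == 0:
                raise ValidationError(f"missing {genotype} samples at week {w}")
            means[(genotype, w)] = fpkm[ids].mean(axis=1)
    per_gt = {
        g: pd.concat([means[(g, w)] for w in weeks], axis=1).min(axis=1)
        for g in ("CRE", "KPC")
    }
    if rule == "genotype-fixed":
        return (per_gt["CRE"] >= threshold) | (per_gt["KPC"] >= threshold)
    if rule == "per-week-either":
        weekly_best = pd.concat(
            [pd.concat([means[("CRE", w)], means[("KPC", w)]], axis=1).max(axis=1)
             for w in weeks],
            axis=1,
        ).min(axis=1)
        return weekly_best >= threshold
    raise ValidationError(f"unknown expression rule {rule!r}")


def coding_gate(genes: pd.DataFrame, universe) -> pd.Series:
    """Protein-coding biotype gate."""
    return genes.reindex(universe)["biotype"].eq("protein_coding").fillna(False)


def localization_gate(genes: pd.DataFrame, universe) -> pd.Series:
    """Secreted-or-cell-surface gate. Genes absent from the annotation table
    fail with a warning."""
    sub = genes.reindex(universe)
    missing = sub.index[sub["secreted"].isna() | sub["cell_surface"].isna()]
    for g in missing:
        log.warning("gene %s missing from annotation; localization gate fails", g)
    sec = sub["secreted"].notna() & sub["secreted"].eq(True)
    surf = sub["cell_surface"].notna() & sub["cell_surface"].eq(True)
    return sec | surf


def screen_candidates(
    fits: pd.DataFrame,
    fpkm: pd.DataFrame,
    cm: CountMatrix,
    r2_min: float = 0.8,
    fpkm_min: float = 1.0,
    expression_rule: str = "genotype-fixed",
) -> pd.DataFrame:
    """Per-gene gate booleans over the full gene universe of ``cm``.

    Columns: r2_pass, expression_pass, coding_pass, localization_pass and
    their conjunction ``candidate_trend`` (the screen's "96-like" set).
    Genes without a complete trend fit fail r2_pass.
    """
    universe = cm.gene_ids
    r2_pass = fits["r2"].reindex(universe).ge(r2_min)  # NaN (no fit) fails
    expr = expression_gate(fpkm, cm, threshold=fpkm_min, rule=expression_rule)
    dec = pd.DataFrame(
        {
            "r2_pass": r2_pass.astype(bool),
            "expression_pass": expr.reindex(universe).fillna(False).astype(bool),
            "coding_pass": coding_gate(cm.genes, universe).astype(bool),
            "localization_pass": localization_gate(cm.genes, universe).astype(bool),
        },
        index=universe,
    )
    dec["candidate_trend"] = dec.all(axis=1)
    return dec


def intersect_with_week12_degs(
    decisions: pd.DataFrame, deg_ids: set[str]
) -> pd.DataFrame:
    """Add the final-week DEG gate and the intersected candidate set.

    ``candidate_final`` (the "26-like" set) is exactly
    ``candidate_trend AND deg_final_pass`` — plain set algebra.
    """
    out = decisions.copy()
    out["deg_final_pass"] = out.index.isin(sorted(deg_ids))
    out["candidate_final"] = out["candidate_trend"] & out["deg_final_pass"]
    return out


def classify_direction(
    fits: pd.DataFrame, candidates
) -> dict[str, list[str]]:
    """Split a candidate set into continuously up- and down-regulated genes
    by the sign of the fitted slope. After an R^2 gate at any positive
    threshold, a zero slope is impossible, so no "flat" bucket is needed."""
    ids = sorted(candidates)
    sub = fits.reindex(ids)
    return {
        "up": sorted(sub.index[sub["slope"] > 0]),
        "down": sorted(sub.index[sub["slope"] < 0]),
    }
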