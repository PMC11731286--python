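"""Negative-binomial differential expression between genotypes per timepoint.

The test is the classic conditional exact test for two groups of NB counts
with a common dispersion: conditioned on the total, the group-A sum follows
the ratio of two NB pmfs (a negative-hypergeometric-type law), evaluated by
direct summation over the full support. The common dispersion is a maximum
conditional-likelihood estimate on library-size-equalized counts, found by
bounded one-dimensional search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ValidationError
from .norm import NormFactors, compute_cpm

_PHI_LO, _PHI_HI = 1e-6, 10.0


@dataclass
class DispersionEstimate:
    phi: float
    method: str = "qCML-common"
    per_gene: pd.Series | None = None


def _equalized_counts(cm: CountMatrix, factors: NormFactors) -> np.ndarray:
    """Counts rescaled to the geometric mean of effective library sizes.

    This is an approximation to full quantile adjustment: the conditional
    test below assumes exchangeable per-sample means, which holds only after
    depth equalization.
    """
    eff = factors.eff_lib_size.loc[cm.sample_ids].to_numpy(dtype=float)
    geo = np.exp(np.mean(np.log(eff)))
    return cm.counts.to_numpy(dtype=float) * (geo / eff)


def _group_cond_ll(y: np.ndarray, phi: float) -> float:
    """Summed per-gene conditional log-likelihood of within-group counts
    given the group totals, for one replicate group (genes x reps)."""
    r = 1.0 / phi
    n = y.shape[1]
    z = y.sum(axis=1)
    ll = (
        np.sum(gammaln(y + r) - gammaln(y + 1.0), axis=1)
        - n * gammaln(r)
        - (gammaln(z + n * r) - gammaln(z + 1.0) - gammaln(n * r))
    )
    return float(ll.sum())


def estimate_common_dispersion(
    cm: CountMatrix, factors: NormFactors
) -> DispersionEstimate:
    """Common NB dispersion phi by conditional maximum likelihood.

    Groups are (genotype, week) cells with >= 2 replicates; counts are first
    equalized to a common effective library size. Optimized on log(phi) over
    [1e-6, 10]; an estimate at the lower bound is reported as 0.
    """
    eq = _equalized_counts(cm, factors)
    groups = []
    for (_, _), idx in cm.samples.groupby(["genotype", "week"]).groups.items():
        cols = [cm.counts.columns.get_loc(s) for s in idx]
        if len(cols) >= 2:
            groups.append(eq[:, cols])
    if not groups:
        raise ValidationError("dispersion unidentifiable: no group with >= 2 replicates")

    def neg_ll(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return -sum(_group_cond_ll(g, phi) for g in groups)

    res = minimize_scalar(
        neg_ll, bounds=(np.log(_PHI_LO), np.log(_PHI_HI)), method="bounded",
        options={"xatol": 1e-6},
    )
    phi = float(np.exp(res.x))
    if phi <= _PHI_LO * 1.5:
        phi = 0.0
    return DispersionEstimate(phi=phi)


def nb_exact_test(
    sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided exact p-value for a difference between two NB groups.

    Conditional on the total ``s = sum_a + sum_b`` the group-A sum has pmf
    proportional to ``NB(y; size n_a/phi) * NB(s - y; size n_b/phi)`` at equal
    per-sample means (the mean cancels). ``phi = 0`` degenerates to the
    binomial (Poisson) conditional. The p-value doubles the smaller tail and
    caps at 1; ``s = 0`` returns 1 by convention.
    """
    if phi < 0:
        raise ValidationError("dispersion must be >= 0")
    sum_a, sum_b = int(round(sum_a)), int(round(sum_b))
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    y = np.arange(s + 1)
    if phi == 0.0:
        pr = n_a / (n_a + n_b)
        logp = (
            gammaln(s + 1.0) - gammaln(y + 1.0) - gammaln(s - y + 1.0)
            + y * np.log(pr) + (s - y) * np.log1p(-pr)
        )
    else:
        ra = n_a / phi
        rb = n_b / phi
        logp = (
            gammaln(y + ra) - gammaln(y + 1.0)
            + gammaln(s - y + rb) - gammaln(s - y + 1.0)
        )
        logp -= logsumexp(logp)
    # tails in log space for numerical safety at extreme observations
    lower = np.exp(logsumexp(logp[: sum_a + 1]))
    upper = np.exp(logsumexp(logp[sum_a:]))
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up, preserving input order; NaNs are excluded
    from the number of tests and returned as NaN."""
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if ok.any() and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def differential_expression_at_timepoint(
    cm: CountMatrix,
    week: int,
    factors: NormFactors,
    dispersion: DispersionEstimate,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    cpm_filter: float | None = 1.0,
    min_samples: int = 2,
    prior: float = 0.25,
) -> pd.DataFrame:
    """KPC-vs-CRE exact-test results for one week.

    Genes below the expression filter (CPM > ``cpm_filter`` in fewer than
    ``min_samples`` of the week's samples; pass ``cpm_filter=None`` to
    disable) are kept in the table with ``tested = False`` and NaN
    statistics. log2FC is the ratio of prior-augmented group-mean CPM. BH
    adjustment is within the timepoint, over tested genes.
    """
    sub = cm.subset_week(week)
    cre = sub.samples_of("CRE")
    kpc = sub.samples_of("KPC")
    if len(cre) == 0 or len(kpc) == 0:
        raise ValidationError(f"week {week}: both genotypes required")

    cpm = compute_cpm(sub, factors, prior=prior)
    cpm_raw = compute_cpm(sub, factors, prior=0.0)
    if cpm_filter is None:
        tested = np.ones(len(sub.gene_ids), dtype=bool)
    else:
        tested = (cpm_raw.to_numpy() > cpm_filter).sum(axis=1) >= min_samples

    eq = _equalized_counts(sub, factors)
    cre_cols = [sub.counts.columns.get_loc(s) for s in cre]
    kpc_cols = [sub.counts.columns.get_loc(s) for s in kpc]
    sum_cre = np.rint(eq[:, cre_cols].sum(axis=1)).astype(np.int64)
    sum_kpc = np.rint(eq[:, kpc_cols].sum(axis=1)).astype(np.int64)

    mean_cpm_cre = cpm[cre].mean(axis=1).to_numpy()
    mean_cpm_kpc = cpm[kpc].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_cpm_kpc / mean_cpm_cre)

    pvals = np.full(len(sub.gene_ids), np.nan)
    phi = dispersion.phi
    for i in np.flatnonzero(tested):
        pvals[i] = nb_exact_test(
            sum_kpc[i], sum_cre[i], len(kpc), len(cre), phi
        )
    fdr = bh_adjust(pvals)

    out = pd.DataFrame(
        {
            "week": week,
            "log2FC": np.where(tested, log2fc, np.nan),
            "mean_cpm_CRE": mean_cpm_cre,
            "mean_cpm_KPC": mean_cpm_kpc,
            "pvalue": pvals,
            "fdr": fdr,
            "tested": tested,
        },
        index=sub.gene_ids,
    )
    out["deg_flag"] = (
        (out["fdr"] < fdr_threshold) & (out["log2FC"].abs() >= lfc_threshold)
    ).fillna(False)
    return out


def deg_sets(de_table: pd.DataFrame) -> dict[str, set[str]]:
    """Partition DEG-flagged genes by fold-change sign."""
    flagged = de_table[de_table["deg_flag"]]
    return {
        "up": set(flagged.index[flagged["log2FC"] > 0]),
        "down": set(flagged.index[flagged["log2FC"] < 0]),
    }
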