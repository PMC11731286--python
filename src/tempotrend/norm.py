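"""Between-sample normalization: TMM factors, CPM and FPKM.

TMM (trimmed mean of M-values) follows the published estimator: pick a
reference sample by upper-quartile similarity, compute gene-wise log ratios
(M) and average log abundances (A) against it over genes detected in both
samples, doubly trim by M and A, and average the surviving M-values with
inverse asymptotic-binomial-variance weights. Factors are recentred to
geometric mean 1 so effective library sizes stay on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, ValidationError


@dataclass
class NormFactors:
    """Per-sample library size, TMM factor and effective library size."""

    table: pd.DataFrame  # columns: lib_size, tmm_factor, eff_lib_size

    @property
    def eff_lib_size(self) -> pd.Series:
        return self.table["eff_lib_size"]

    @property
    def factors(self) -> pd.Series:
        return self.table["tmm_factor"]


def _pair_tmm(obs, ref, n_obs, n_ref, trim_m, trim_a):
    """TMM factor of one sample against the reference column."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return None
    o = obs[both] / n_obs
    r = ref[both] / n_ref
    m = np.log2(o / r)
    a = 0.5 * (np.log2(o) + np.log2(r))
    # inverse asymptotic binomial variance of M
    v = (n_obs - obs[both]) / (n_obs * obs[both]) + (n_ref - ref[both]) / (n_ref * ref[both])

    if np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def compute_tmm_factors(
    cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """TMM normalization factors for every sample of ``cm``.

    The reference is the sample whose upper quartile of nonzero CPM is
    closest to the across-sample mean upper quartile. Raises if a sample
    shares no detected gene with the reference.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")
    if (lib == 0).any():
        bad = cm.sample_ids[np.argmax(lib == 0)]
        raise ValidationError(f"sample {bad!r} has zero library size")

    uq = np.array(
        [
            np.quantile(counts[counts[:, j] > 0, j] / lib[j] * 1e6, 0.75)
            for j in range(counts.shape[1])
        ]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_idx]

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
            continue
        f = _pair_tmm(counts[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
        if f is None:
            raise ValidationError(
                f"sample {cm.sample_ids[j]!r} shares no detected gene with the reference"
            )
        factors[j] = f

    factors = factors / np.exp(np.mean(np.log(factors)))
    table = pd.DataFrame(
        {
            "lib_size": lib,
            "tmm_factor": factors,
            "eff_lib_size": lib * factors,
        },
        index=cm.sample_ids,
    )
    return NormFactors(table)


def compute_cpm(
    cm: CountMatrix, factors: NormFactors, prior: float = 0.25
) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes.

    The pseudo-count is scaled per sample in proportion to its effective
    library size: with L_j the effective size and L-bar their mean,
    ``cpm[g, j] = (count[g, j] + prior * L_j / L-bar) / L_j * 1e6``, so the
    same prior contributes the same CPM offset in every sample.
    """
    eff = factors.eff_lib_size.loc[cm.sample_ids].to_numpy(dtype=float)
    if (eff <= 0).any():
        raise ValidationError("zero effective library size")
    prior_j = prior * eff / eff.mean()
    return (cm.counts + prior_j) / eff * 1e6


def compute_fpkm(cm: CountMatrix, factors: NormFactors) -> pd.DataFrame:
    """Fragments per kilobase per million on TMM-effective library sizes:
    ``count / ((length_bp / 1e3) * (eff_lib_size / 1e6))``."""
    missing = cm.counts.index.difference(cm.genes.index)
    if len(missing):
        raise ValidationError(f"missing length for gene {missing[0]!r}")
    lengths = cm.genes.loc[cm.counts.index, "length_bp"].to_numpy(dtype=float)
    eff = factors.eff_lib_size.loc[cm.sample_ids].to_numpy(dtype=float)
    if (eff <= 0).any():
        raise ValidationError("zero effective library size")
    denom = np.outer(lengths / 1e3, eff / 1e6)
    return pd.DataFrame(
        cm.counts.to_numpy(dtype=float) / denom,
        index=cm.counts.index,
        columns=cm.counts.columns,
    )
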