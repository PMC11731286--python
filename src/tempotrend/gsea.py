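"""Unweighted (exponent-0) preranked gene-set enrichment.

Genes are ranked by log2 fold change; the enrichment score is the classic
Kolmogorov-Smirnov-style running sum where every set member adds ``1/Nhit``
and every non-member subtracts ``1/Nmiss`` — with exponent 0 the scores
influence only the ordering, never the increments. Significance comes from a
gene-label null: random same-size sets drawn without replacement from the
ranked universe. NES divides the observed score by the mean same-sign null
score magnitude.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, ValidationError
from .de import bh_adjust


# ---------------------------------------------------------------- GMT I/O

def read_gmt(path: str | Path, source: str = "user") -> GeneSetCollection:
    """Parse a GMT file (name, description, members per tab-separated line).

    Duplicate members within a set are dropped; empty sets are skipped with
    a warning comment in the collection's description.
    """
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: malformed GMT line (needs >= 3 fields)"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                continue
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            desc[name] = description
    return GeneSetCollection(sets, source=source, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            description = collection.descriptions.get(name, collection.source)
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------- ranking

def rank_by_log2fc(de_table: pd.DataFrame) -> pd.Series:
    """Ranked list for one timepoint: log2FC descending, ties broken by
    gene id (lexicographic) so the order is deterministic."""
    scores = de_table["log2FC"].dropna()
    if scores.empty:
        raise ValidationError("no ranked genes: empty or untested table")
    frame = scores.rename("score").rename_axis("gene_id").reset_index()
    frame = frame.sort_values(["score", "gene_id"], ascending=[False, True])
    return frame.set_index("gene_id")["score"]


# ---------------------------------------------------------------- ES

def enrichment_score_unweighted(ranked_ids, members) -> tuple[float, np.ndarray]:
    """ES and the full running-sum profile for one set.

    The ES is the running-sum value of maximal absolute deviation from zero
    (signed); on an exact magnitude tie between the positive peak and the
    negative trough the positive one is taken.
    """
    ids = list(ranked_ids)
    n = len(ids)
    hit = np.fromiter((g in members for g in ids), dtype=bool, count=n)
    n_hit = int(hit.sum())
    n_miss = n - n_hit
    if n_hit == 0 or n_miss == 0:
        raise ValidationError("set must be a proper non-empty subset of the universe")
    # integer-scaled running sum (x Nhit*Nmiss) keeps magnitude ties exact,
    # so the positive-preference tie-break is reproducible
    steps = np.where(hit, n_miss, -n_hit).astype(np.int64)
    scaled = np.cumsum(steps)
    peak = int(scaled.max())
    trough = int(scaled.min())
    es_scaled = peak if peak >= -trough else trough
    denom = n_hit * n_miss
    return es_scaled / denom, scaled / denom


def _es_from_positions(pos: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many hit-position vectors.

    ``pos`` is (m, k) of 0-based hit ranks, sorted ascending per row. Only
    the running-sum values just before and at each hit can be extreme, so
    the scan reduces to 2k candidates per row.
    """
    m, k = pos.shape
    pos = pos.astype(np.int64)
    j = np.arange(1, k + 1, dtype=np.int64)
    n_miss = n - k
    # same integer scaling (x k * n_miss) as the running-sum implementation
    after = j * n_miss - (pos + 1 - j) * k
    before = (j - 1) * n_miss - (pos - (j - 1)) * k
    peak = after.max(axis=1)
    trough = np.minimum(before.min(axis=1), 0)
    es_scaled = np.where(peak >= -trough, peak, trough)
    return es_scaled / (k * n_miss)


def _leading_edge_size(running: np.ndarray, es: float, hit_positions: np.ndarray) -> int:
    if es >= 0:
        cut = int(np.argmax(running))
        return int(np.sum(hit_positions <= cut))
    cut = int(np.argmin(running))
    return int(np.sum(hit_positions > cut))


# ---------------------------------------------------------------- null

def _null_es_samples(
    n: int, sizes: list[int], n_perm: int, rng: np.random.Generator,
    exhaustive_limit: int = 0,
) -> dict[int, np.ndarray]:
    """Null ES samples per set size on a universe of ``n`` ranks.

    One pool of random permutations is shared across sizes: the first k
    entries of a shuffled rank vector are a uniform without-replacement draw
    of k positions. If ``exhaustive_limit`` > 0 and C(n, k) is at most that
    limit, full enumeration replaces sampling for that size.
    """
    out: dict[int, np.ndarray] = {}
    need_sampled = []
    for k in sorted(set(sizes)):
        n_comb = _n_choose_k(n, k)
        if exhaustive_limit and n_comb <= exhaustive_limit:
            pos = np.array(list(combinations(range(n), k)), dtype=float)
            out[k] = _es_from_positions(pos, n)
        else:
            need_sampled.append(k)
    if need_sampled:
        kmax = max(need_sampled)
        # draw k-subsets via partial Fisher-Yates on the first kmax slots
        pool = np.tile(np.arange(n), (n_perm, 1))
        for slot in range(kmax):
            jidx = rng.integers(slot, n, size=n_perm)
            rows = np.arange(n_perm)
            tmp = pool[rows, slot].copy()
            pool[rows, slot] = pool[rows, jidx]
            pool[rows, jidx] = tmp
        for k in need_sampled:
            pos = np.sort(pool[:, :k], axis=1).astype(float)
            out[k] = _es_from_positions(pos, n)
    return out


def _n_choose_k(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def _p_and_nes(es: float, null_es: np.ndarray) -> tuple[float, float]:
    """One-sided permutation p in the direction of the observed ES (with the
    +1 correction) and the same-sign-mean NES."""
    if es > 0:
        same = null_es[null_es > 0]
    elif es < 0:
        same = null_es[null_es < 0]
    else:
        return 1.0, 0.0
    if same.size == 0:
        return 1.0, np.nan
    p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
    nes = es / np.mean(np.abs(same))
    return float(p), float(nes)


def normalize_es(es: float, null_es) -> float:
    """NES: the observed ES divided by the mean magnitude of same-sign null
    ES values (sign preserved). Returns 0 for ES = 0 and NaN when the null
    sample contains no same-sign values."""
    return _p_and_nes(float(es), np.asarray(null_es, dtype=float))[1]


def permutation_pvalues(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 10000,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.Series:
    """Nominal permutation p-value per set (no size filtering).

    With ``exhaustive=True`` the null enumerates every same-size subset of
    the universe instead of sampling, which is exact for small problems.
    """
    res = gsea_preranked(
        ranked, collection, n_perm=n_perm, seed=seed,
        min_size=1, max_size=None,
        exhaustive_limit=(10**9 if exhaustive else 0),
    )
    return res["pval"]


def gsea_preranked(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 10000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int | None = 500,
    exhaustive_limit: int = 0,
) -> pd.DataFrame:
    """Full preranked enrichment of a collection against one ranked list.

    Returns a frame indexed by set name with size, ES, NES, nominal p and
    BH-adjusted p (across the collection), and the leading-edge size.
    Deterministic given the seed.
    """
    if n_perm < 100 and not exhaustive_limit:
        raise ValidationError("n_perm must be >= 100")
    ids = list(ranked.index)
    if len(set(ids)) != len(ids):
        raise ValidationError("ranked list contains duplicate gene ids")
    n = len(ids)
    restricted = collection.restrict(ids, min_size=min_size, max_size=max_size)
    pos_of = {g: i for i, g in enumerate(ids)}

    names = sorted(restricted.sets)
    sizes = [len(restricted.sets[nm]) for nm in names]
    rng = np.random.default_rng(seed)
    null_by_size = _null_es_samples(
        n, sizes, n_perm, rng, exhaustive_limit=exhaustive_limit
    )

    rows = []
    for nm in names:
        members = restricted.sets[nm]
        hit_positions = np.sort([pos_of[g] for g in members])
        es, running = enrichment_score_unweighted(ids, members)
        p, nes = _p_and_nes(es, null_by_size[len(members)])
        rows.append(
            {
                "set": nm,
                "size": len(members),
                "ES": es,
                "NES": nes,
                "pval": p,
                "leading_edge_size": _leading_edge_size(running, es, hit_positions),
            }
        )
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "ES", "NES", "pval", "leading_edge_size"]
    )
    if len(out):
        out["padj"] = bh_adjust(out["pval"].to_numpy())
    else:
        out["padj"] = []
    return out


# ------------------------------------------------- cross-timepoint summaries

def consistent_sets_across_timepoints(
    results: dict[int, pd.DataFrame], alpha: float = 0.05
) -> tuple[list[str], dict[int, int]]:
    """Set names significant (padj < alpha) at every timepoint, plus the
    per-timepoint significant counts."""
    per_week_sig = {
        w: set(tbl.index[tbl["padj"] < alpha]) for w, tbl in results.items()
    }
    consistent = set.intersection(*per_week_sig.values()) if per_week_sig else set()
    counts = {w: len(s) for w, s in per_week_sig.items()}
    return sorted(consistent), counts


def top_k_sets(
    result: pd.DataFrame, k: int = 20, sign: str = "positive"
) -> list[str]:
    """Top-k set names by NES (descending for positive enrichment,
    ascending for negative), ties broken by name."""
    tbl = result.reset_index().rename(columns={"index": "set"})
    if sign == "positive":
        tbl = tbl[tbl["NES"] > 0].sort_values(["NES", "set"], ascending=[False, True])
    elif sign == "negative":
        tbl = tbl[tbl["NES"] < 0].sort_values(["NES", "set"], ascending=[True, True])
    else:
        raise ValidationError(f"sign must be positive/negative, got {sign!r}")
    return tbl["set"].head(k).tolist()


def nes_matrix(results: dict[int, pd.DataFrame], set_names) -> pd.DataFrame:
    """Sets x weeks matrix of NES for heatmap-style output."""
    return pd.DataFrame(
        {w: tbl["NES"].reindex(set_names) for w, tbl in sorted(results.items())}
    )
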