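"""Unweighted enrichment: step-through and exhaustive-null oracles,
antisymmetry, determinism, NES arithmetic, and the summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from tempotrend.containers import GeneSetCollection, ValidationError
from tempotrend.gsea import (
    _es_from_positions,
    normalize_es,
    consistent_sets_across_timepoints,
    enrichment_score_unweighted,
    gsea_preranked,
    nes_matrix,
    permutation_pvalues,
    rank_by_log2fc,
    read_gmt,
    top_k_sets,
    write_gmt,
)

from .oracles import bh_reference, es_step_oracle, exhaustive_null_p


def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"g{i:03d}" for i in range(n)]
    scores = np.sort(rng.normal(size=n))[::-1]
    return pd.Series(scores, index=pd.Index(ids, name="gene_id"), name="score")


# ------------------------------------------------------------------ GMT

def test_gmt_round_trip_and_dedup(tmp_path):
    path = tmp_path / "toy.gmt"
    path.write_text(
        "SET_A\tdesc\tg1\tg2\tg2\tg3\n"
        "SET_B\tdesc\tg4\tg5\n"
    )
    coll = read_gmt(path)
    assert len(coll) == 2
    assert coll.sets["SET_A"] == frozenset({"g1", "g2", "g3"})
    out = tmp_path / "rt.gmt"
    write_gmt(coll, out)
    again = read_gmt(out)
    assert again.sets == coll.sets


def test_malformed_gmt_line_raises(tmp_path):
    path = tmp_path / "bad.gmt"
    path.write_text("ONLY_NAME\tdesc\n")
    with pytest.raises(ValidationError, match="malformed"):
        read_gmt(path)


# ------------------------------------------------------------------ ranking

def test_ranking_descends_with_lexicographic_ties():
    tbl = pd.DataFrame(
        {"log2FC": [1.0, 3.0, 1.0, np.nan]},
        index=["gb", "gc", "ga", "gd"],
    )
    ranked = rank_by_log2fc(tbl)
    assert list(ranked.index) == ["gc", "ga", "gb"]
    # input order must not matter
    ranked2 = rank_by_log2fc(tbl.iloc[::-1])
    assert list(ranked2.index) == list(ranked.index)


# ------------------------------------------------------------------ ES

def test_singleton_extremes_give_unit_es():
    ranked = _ranked(20)
    top = {ranked.index[0]}
    bottom = {ranked.index[-1]}
    assert enrichment_score_unweighted(ranked.index, top)[0] == pytest.approx(1.0)
    assert enrichment_score_unweighted(ranked.index, bottom)[0] == pytest.approx(-1.0)


def test_es_matches_step_oracle_on_toy_list():
    ranked = _ranked(10)
    members = {ranked.index[r] for r in (2, 3, 7)}
    es, _ = enrichment_score_unweighted(ranked.index, members)
    assert es == pytest.approx(es_step_oracle(10, [2, 3, 7]), abs=1e-12)


@given(
    n=st.integers(6, 40),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_es_reversal_antisymmetry_and_position_formula(n, seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, n - 1))
    positions = np.sort(rng.choice(n, size=k, replace=False))
    ranked = _ranked(n)
    members = {ranked.index[p] for p in positions}
    es, running = enrichment_score_unweighted(ranked.index, members)
    # skip exact peak/trough magnitude ties, where the positive-preference
    # convention (not the statistic itself) decides the sign
    assume(abs(running.max() + running.min()) > 1e-9)
    # reversing the list negates the ES exactly
    es_rev, _ = enrichment_score_unweighted(ranked.index[::-1], members)
    assert es_rev == pytest.approx(-es, abs=1e-12)
    # the vectorized position formula agrees with the running sum
    es_fast = _es_from_positions(positions[None, :].astype(float), n)[0]
    assert es_fast == pytest.approx(es, abs=1e-12)
    assert abs(es) <= 1.0


def test_whole_universe_set_rejected():
    ranked = _ranked(5)
    with pytest.raises(ValidationError):
        enrichment_score_unweighted(ranked.index, set(ranked.index))


# ------------------------------------------------------------ permutations

def test_permutation_p_reproducible_and_exhaustive_oracle():
    ranked = _ranked(8)
    members = frozenset({ranked.index[r] for r in (0, 2, 5)})
    coll = GeneSetCollection({"S": members})
    p_ex = permutation_pvalues(ranked, coll, exhaustive=True, seed=1)["S"]
    assert p_ex == pytest.approx(exhaustive_null_p(8, [0, 2, 5]), abs=1e-15)
    p1 = permutation_pvalues(ranked, coll, n_perm=500, seed=7)
    p2 = permutation_pvalues(ranked, coll, n_perm=500, seed=7)
    assert p1.equals(p2)


def test_singleton_top_gene_p_near_one_over_n():
    n = 200
    ranked = _ranked(n)
    coll = GeneSetCollection({"TOP": frozenset({ranked.index[0]})})
    p = permutation_pvalues(ranked, coll, exhaustive=True)["TOP"]
    # a singleton at 0-based rank r has ES = 1 - r/(n-1) when positive, so
    # exactly the top 100 ranks give positive null ES and only rank 0 attains
    # |ES| = 1: with the +1 correction p = (1+1)/(1+100) ~ 2/n
    assert p == pytest.approx(2 / 101, abs=1e-12)
    assert p < 5.0 / n


def test_nes_arithmetic():
    null = np.array([0.4, 0.2, -0.3, -0.1])
    assert normalize_es(0.3, null) == pytest.approx(1.0)  # mean positive null = 0.3
    assert normalize_es(0.0, null) == 0.0
    assert normalize_es(-0.4, null) == pytest.approx(-2.0)  # mean |neg| = 0.2
    assert np.isnan(normalize_es(0.5, [-0.2, -0.1]))  # no same-sign null


def test_gsea_preranked_padj_is_bh_over_the_collection():
    ranked = _ranked(60, seed=3)
    rng = np.random.default_rng(5)
    sets = {
        f"S{i}": frozenset(rng.choice(ranked.index, size=8, replace=False))
        for i in range(6)
    }
    res = gsea_preranked(ranked, GeneSetCollection(sets), n_perm=300, seed=9,
                         min_size=1, max_size=None)
    assert np.allclose(res["padj"], bh_reference(res["pval"]))
    assert res["ES"].abs().max() <= 1.0
    assert np.all(np.sign(res["NES"].dropna()) == np.sign(res["ES"][res["NES"].notna()]))


# ------------------------------------------------------------ summaries

def _fake_results():
    weeks = [4, 6, 8, 10, 12]
    names = ["A", "B", "C"]
    out = {}
    for i, w in enumerate(weeks):
        padj = {"A": 0.01, "B": 0.01 if w != 8 else 0.2, "C": 0.8}
        nes = {"A": 2.0, "B": -1.5, "C": 0.5 + i * 0.1}
        out[w] = pd.DataFrame(
            {"padj": [padj[n] for n in names], "NES": [nes[n] for n in names]},
            index=pd.Index(names, name="set"),
        )
    return out


def test_consistency_requires_every_timepoint():
    consistent, counts = consistent_sets_across_timepoints(_fake_results())
    assert consistent == ["A"]  # B misses week 8, C never significant
    assert counts == {4: 2, 6: 2, 8: 1, 10: 2, 12: 2}


def test_top_k_ordering_and_overflow():
    res = _fake_results()[12]
    assert top_k_sets(res, k=20, sign="positive") == ["A", "C"]
    assert top_k_sets(res, k=1, sign="negative") == ["B"]
    mat = nes_matrix(_fake_results(), ["A", "B"])
    assert mat.shape == (2, 5)
    assert mat.loc["A", 12] == 2.0
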