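"""Trend regression and the gate cascade: OLS oracle, degenerate
conventions, both expression-rule readings, and set algebra."""

import numpy as np
import pandas as pd
import pytest

from tempotrend.containers import ValidationError
from tempotrend.de import (
    deg_sets,
    differential_expression_at_timepoint,
    estimate_common_dispersion,
)
from tempotrend.norm import compute_fpkm, compute_tmm_factors
from tempotrend.screen import (
    classify_direction,
    expression_gate,
    fit_linear_trend,
    intersect_with_week12_degs,
    localization_gate,
    screen_candidates,
    timecourse_log2fc,
)
from tempotrend.simulate import SimulationConfig, simulate_counts

from .conftest import make_count_matrix
from .oracles import ols_reference

WEEKS = [4, 6, 8, 10, 12]


def _lfc_frame(rows: dict):
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=WEEKS)
    mat.columns.name = "week"
    return mat


def test_exact_line_recovers_slope_with_unit_r2():
    fits = fit_linear_trend(_lfc_frame({"g": [0, 0.5, 1.0, 1.5, 2.0]}))
    assert fits.loc["g", "slope"] == pytest.approx(0.25)
    assert fits.loc["g", "r2"] == pytest.approx(1.0)
    assert fits.loc["g", "direction"] == "up"


def test_constant_profile_gets_zero_r2_flat_by_convention():
    fits = fit_linear_trend(_lfc_frame({"g": [0.7] * 5}))
    assert fits.loc["g", "slope"] == 0.0
    assert fits.loc["g", "r2"] == 0.0
    assert fits.loc["g", "direction"] == "flat"


def test_fit_matches_closed_form_ols_oracle():
    y = [0.1, 0.9, 1.6, 3.4, 3.9]
    fits = fit_linear_trend(_lfc_frame({"g": y}))
    slope, intercept, r2 = ols_reference(WEEKS, y)
    assert fits.loc["g", "slope"] == pytest.approx(slope, abs=1e-12)
    assert fits.loc["g", "intercept"] == pytest.approx(intercept, abs=1e-12)
    assert fits.loc["g", "r2"] == pytest.approx(r2, abs=1e-12)


def test_incomplete_profiles_are_excluded():
    mat = _lfc_frame({"full": [0, 1, 2, 3, 4], "holey": [0, 1, np.nan, 3, 4]})
    fits = fit_linear_trend(mat)
    assert list(fits.index) == ["full"]


def test_too_few_timepoints_raise():
    mat = pd.DataFrame({4: [0.0], 6: [1.0]}, index=["g"])
    with pytest.raises(ValidationError):
        fit_linear_trend(mat)


def _gate_fixture(cre_means, kpc_means):
    """One gene, 5 weeks x 2 genotypes x 1 replicate, FPKM set directly."""
    n = 10
    counts = np.ones((1, n), dtype=int)
    genotypes = ["CRE"] * 5 + ["KPC"] * 5
    weeks = WEEKS + WEEKS
    cm = make_count_matrix(counts, genotypes=genotypes, weeks=weeks)
    fpkm = pd.DataFrame(
        [list(cre_means) + list(kpc_means)], index=cm.gene_ids, columns=cm.sample_ids
    )
    return cm, fpkm


def test_expression_gate_genotype_fixed_passes_when_one_genotype_holds():
    cm, fpkm = _gate_fixture([1.2, 1.1, 1.5, 2.0, 3.1], [0.2] * 5)
    assert expression_gate(fpkm, cm).iloc[0]


def test_expression_gate_rules_disagree_on_alternating_profiles():
    cm, fpkm = _gate_fixture([1.2, 0.9, 1.5, 2.0, 3.1], [0.5, 1.2, 0.8, 1.4, 2.0])
    assert not expression_gate(fpkm, cm, rule="genotype-fixed").iloc[0]
    assert expression_gate(fpkm, cm, rule="per-week-either").iloc[0]


def test_all_zero_gene_fails_expression_gate():
    cm, fpkm = _gate_fixture([0.0] * 5, [0.0] * 5)
    assert not expression_gate(fpkm, cm).iloc[0]


def test_localization_gate_and_missing_annotation(caplog):
    genes = pd.DataFrame(
        {"secreted": [True, False], "cell_surface": [False, False]},
        index=["a", "b"],
    )
    out = localization_gate(genes, ["a", "b", "ghost"])
    assert out.loc["a"] and not out.loc["b"] and not out.loc["ghost"]


def test_candidate_conjunction_and_intersection_set_algebra(small_sim):
    _, cm, truth = small_sim
    f = compute_tmm_factors(cm)
    phi = estimate_common_dispersion(cm, f)
    de = {w: differential_expression_at_timepoint(cm, w, f, phi) for w in cm.weeks}
    fits = fit_linear_trend(timecourse_log2fc(de))
    dec = screen_candidates(fits, compute_fpkm(cm, f), cm)
    gates = dec[["r2_pass", "expression_pass", "coding_pass", "localization_pass"]]
    assert (dec["candidate_trend"] == gates.all(axis=1)).all()

    deg12 = set.union(*deg_sets(de[12]).values())
    dec = intersect_with_week12_degs(dec, deg12)
    cand96 = set(dec.index[dec["candidate_trend"]])
    cand26 = set(dec.index[dec["candidate_final"]])
    assert cand26 == cand96 & deg12
    assert cand26 <= cand96


def test_screen_recovers_planted_directions(small_sim):
    _, cm, truth = small_sim
    f = compute_tmm_factors(cm)
    phi = estimate_common_dispersion(cm, f)
    de = {w: differential_expression_at_timepoint(cm, w, f, phi) for w in cm.weeks}
    fits = fit_linear_trend(timecourse_log2fc(de))
    dec = screen_candidates(fits, compute_fpkm(cm, f), cm)
    selected = set(dec.index[dec["candidate_trend"]])
    split = classify_direction(fits, selected)
    up_true = set(truth.genes_of_class("trend_up"))
    down_true = set(truth.genes_of_class("trend_down"))
    # every selected planted gene lands in the bucket of its planted sign
    assert set(split["up"]) & up_true == selected & up_true
    assert set(split["down"]) & down_true == selected & down_true
    assert set(split["up"]) | set(split["down"]) == selected


def test_classify_direction_trivial_cases():
    fits = pd.DataFrame({"slope": [1.0, 2.0]}, index=["a", "b"])
    assert classify_direction(fits, ["a", "b"]) == {"up": ["a", "b"], "down": []}
    assert classify_direction(fits, []) == {"up": [], "down": []}


def test_gate_decisions_invariant_to_global_count_scaling():
    cfg = SimulationConfig(n_genes=300, n_trend_up=6, n_trend_down=6, n_late=0,
                           enrich_planted_annotation=True, seed=17)
    cm, _ = simulate_counts(cfg)
    from tempotrend.containers import CountMatrix

    doubled = CountMatrix(cm.counts * 2, cm.samples, cm.genes)

    def gates(matrix):
        f = compute_tmm_factors(matrix)
        phi = estimate_common_dispersion(matrix, f)
        de = {w: differential_expression_at_timepoint(matrix, w, f, phi)
              for w in matrix.weeks}
        fits = fit_linear_trend(timecourse_log2fc(de))
        dec = screen_candidates(fits, compute_fpkm(matrix, f), matrix)
        return dec[["r2_pass", "expression_pass", "coding_pass", "localization_pass"]]

    pd.testing.assert_frame_equal(gates(cm), gates(doubled))
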