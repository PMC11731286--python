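"""End-to-end orchestration: simulate/load -> normalize -> DE -> screen -> GSEA.

A single master seed drives a spawned seed hierarchy, so every stochastic
stage is independently reproducible and the whole run is byte-identical
under a fixed configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix, GeneSetCollection, ValidationError, read_counts, write_counts
from .de import (
    deg_sets,
    differential_expression_at_timepoint,
    estimate_common_dispersion,
)
from .gsea import (
    consistent_sets_across_timepoints,
    gsea_preranked,
    nes_matrix,
    rank_by_log2fc,
    read_gmt,
    top_k_sets,
    write_gmt,
)
from .norm import compute_cpm, compute_fpkm, compute_tmm_factors
from .screen import (
    classify_direction,
    fit_linear_trend,
    intersect_with_week12_degs,
    screen_candidates,
    timecourse_log2fc,
)
from .simulate import SimulationConfig, simulate_counts, simulate_gene_sets, write_truth

log = logging.getLogger(__name__)

_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Everything one run needs: either input paths or a simulation block,
    plus every screening threshold the analysis prints."""

    simulation: SimulationConfig | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    genes_path: str | None = None
    gmt_paths: dict[str, str] = field(default_factory=dict)
    fdr: float = 0.05
    lfc: float = 1.0
    r2_min: float = 0.8
    fpkm_min: float = 1.0
    alpha: float = 0.05
    cpm_filter: float | None = 1.0
    trim_m: float = 0.30
    trim_a: float = 0.05
    expression_rule: str = "genotype-fixed"
    n_perm: int = 10000
    min_set_size: int = 5
    max_set_size: int = 500
    top_k: int = 20
    seed: int = 0

    def validate(self) -> None:
        has_paths = self.counts_path is not None
        if has_paths == (self.simulation is not None):
            raise ValidationError(
                "exactly one of input paths or a simulation block must be set"
            )
        if has_paths and (self.samples_path is None or self.genes_path is None):
            raise ValidationError("counts_path requires samples_path and genes_path")
        for name, val in [
            ("fdr", self.fdr), ("alpha", self.alpha),
            ("trim_m", self.trim_m), ("trim_a", self.trim_a),
        ]:
            if not (0 < val < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.lfc < 0 or self.r2_min < 0 or self.r2_min > 1 or self.fpkm_min < 0:
            raise ValidationError("thresholds out of range")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            sim["weeks"] = tuple(sim.get("weeks", (4, 6, 8, 10, 12)))
            if "gene_length_range" in sim:
                sim["gene_length_range"] = tuple(sim["gene_length_range"])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_jsonable(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("simulation",)
        }
        d["simulation"] = self.simulation.to_dict() if self.simulation else None
        return d


def _child_seed(ss: np.random.SeedSequence) -> int:
    # keep spawned seeds in int32 range for portability of downstream APIs
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def venn_counts(named_sets: dict[str, set]) -> dict[str, int]:
    """Counts of every exclusive intersection region of >= 2 named sets.

    Region keys join the member names with ``&`` (sorted); every element is
    counted in exactly one region, so regions sum to the union size.
    """
    if len(named_sets) < 2:
        raise ValidationError("venn needs >= 2 sets")
    names = sorted(named_sets)
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for group in combinations(names, r):
            inside = set.intersection(*(named_sets[g] for g in group))
            outside = set.union(
                *(named_sets[g] for g in names if g not in group), set()
            )
            out["&".join(group)] = len(inside - outside)
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full screen and write every stage's artifacts.

    Returns the run report (also written to ``run_report.json``); every
    count in the report equals the cardinality of the corresponding emitted
    file. Idempotent given the seed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    ss_sim, ss_sets, ss_gsea = master.spawn(3)

    # ---- stage 1: data
    truth = None
    if config.simulation is not None:
        sim_cfg = config.simulation
        sim_cfg = SimulationConfig(**{**sim_cfg.__dict__, "seed": _child_seed(ss_sim)})
        cm, truth = simulate_counts(sim_cfg)
        write_counts(cm, outdir)
        write_truth(truth, outdir / "truth.tsv")
    else:
        cm = read_counts(config.counts_path, config.samples_path, config.genes_path)
    weeks = cm.weeks
    log.info("stage=data genes=%d samples=%d weeks=%s", len(cm.gene_ids), len(cm.sample_ids), weeks)

    # ---- stage 2: normalization
    factors = compute_tmm_factors(cm, trim_m=config.trim_m, trim_a=config.trim_a)
    factors.table.rename_axis("sample_id").to_csv(outdir / "norm_factors.tsv", sep="\t")
    dispersion = estimate_common_dispersion(cm, factors)
    log.info("stage=normalize phi=%.4f", dispersion.phi)

    # ---- stage 3: per-timepoint DE
    de_tables: dict[int, pd.DataFrame] = {}
    deg_by_week: dict[int, dict[str, set]] = {}
    for w in weeks:
        tbl = differential_expression_at_timepoint(
            cm, w, factors, dispersion,
            fdr_threshold=config.fdr, lfc_threshold=config.lfc,
            cpm_filter=config.cpm_filter,
        )
        de_tables[w] = tbl
        deg_by_week[w] = deg_sets(tbl)
        tbl.rename_axis("gene_id").to_csv(outdir / f"de_results_w{w}.tsv", sep="\t")
        log.info(
            "stage=de week=%d tested=%d up=%d down=%d",
            w, int(tbl["tested"].sum()), len(deg_by_week[w]["up"]), len(deg_by_week[w]["down"]),
        )

    # ---- stage 4: temporal screen
    lfc_mat = timecourse_log2fc(de_tables)
    fits = fit_linear_trend(lfc_mat)
    fits.rename_axis("gene_id").to_csv(outdir / "trend_fits.tsv", sep="\t")
    fpkm = compute_fpkm(cm, factors)
    decisions = screen_candidates(
        fits, fpkm, cm,
        r2_min=config.r2_min, fpkm_min=config.fpkm_min,
        expression_rule=config.expression_rule,
    )
    final_week = weeks[-1]
    deg12 = deg_by_week[final_week]["up"] | deg_by_week[final_week]["down"]
    decisions = intersect_with_week12_degs(decisions, deg12)
    decisions.rename_axis("gene_id").to_csv(outdir / "screen_decisions.tsv", sep="\t")
    cand_trend = sorted(decisions.index[decisions["candidate_trend"]])
    cand_final = sorted(decisions.index[decisions["candidate_final"]])
    (outdir / "candidates_trend.txt").write_text("\n".join(cand_trend) + ("\n" if cand_trend else ""))
    (outdir / "candidates_final.txt").write_text("\n".join(cand_final) + ("\n" if cand_final else ""))
    direction = classify_direction(fits, cand_final)
    log.info(
        "stage=screen trend_candidates=%d final_candidates=%d up=%d down=%d",
        len(cand_trend), len(cand_final), len(direction["up"]), len(direction["down"]),
    )

    # ---- stage 5: GSEA
    collections: dict[str, GeneSetCollection] = {}
    if config.gmt_paths:
        for name, path in sorted(config.gmt_paths.items()):
            collections[name] = read_gmt(path, source=name)
    elif config.simulation is not None:
        s1, s2 = ss_sets.spawn(2)
        collections["canonical"] = simulate_gene_sets(
            cm.gene_ids, truth, n_sets=100, n_planted=10,
            source="canonical", seed=_child_seed(s1),
        )
        collections["hallmark"] = simulate_gene_sets(
            cm.gene_ids, truth, n_sets=50, n_planted=5,
            planted_class="trend_down", source="hallmark", seed=_child_seed(s2),
        )
        for name, coll in collections.items():
            write_gmt(coll, outdir / f"{name}.gmt")

    gsea_report: dict[str, dict] = {}
    coll_seeds = dict(zip(sorted(collections), ss_gsea.spawn(max(1, len(collections)))))
    for name, coll in collections.items():
        results: dict[int, pd.DataFrame] = {}
        week_seeds = coll_seeds[name].spawn(len(weeks))
        for w, ss_w in zip(weeks, week_seeds):
            ranked = rank_by_log2fc(de_tables[w])
            res = gsea_preranked(
                ranked, coll, n_perm=config.n_perm, seed=_child_seed(ss_w),
                min_size=config.min_set_size, max_size=config.max_set_size,
            )
            res.rename_axis("set").to_csv(outdir / f"gsea_{name}_w{w}.tsv", sep="\t")
            results[w] = res
        consistent, per_week = consistent_sets_across_timepoints(results, alpha=config.alpha)
        (outdir / f"consistent_sets_{name}.txt").write_text(
            "\n".join(consistent) + ("\n" if consistent else "")
        )
        ref = results[final_week]
        top_pos = top_k_sets(ref, k=config.top_k, sign="positive")
        top_neg = top_k_sets(ref, k=config.top_k, sign="negative")
        nes_matrix(results, top_pos).rename_axis("set").to_csv(
            outdir / f"top{config.top_k}_pos_nes_{name}.tsv", sep="\t"
        )
        nes_matrix(results, top_neg).rename_axis("set").to_csv(
            outdir / f"top{config.top_k}_neg_nes_{name}.tsv", sep="\t"
        )
        gsea_report[name] = {
            "per_week_significant": {str(w): per_week[w] for w in weeks},
            "consistent_sets": len(consistent),
            "n_sets_tested": int(len(results[final_week])),
        }
        log.info(
            "stage=gsea collection=%s consistent=%d per_week=%s",
            name, len(consistent), per_week,
        )

    # ---- report
    report = {
        "version": _VERSION,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "weeks": weeks,
        "dispersion": dispersion.phi,
        "deg_counts": {
            str(w): {
                "up": len(deg_by_week[w]["up"]),
                "down": len(deg_by_week[w]["down"]),
                "total": len(deg_by_week[w]["up"]) + len(deg_by_week[w]["down"]),
            }
            for w in weeks
        },
        "deg_venn_mid_vs_final": venn_counts(
            {
                f"w{weeks[len(weeks) // 2 - 1]}": set.union(
                    *deg_by_week[weeks[len(weeks) // 2 - 1]].values()
                ),
                f"w{final_week}": deg12,
            }
        )
        if len(weeks) >= 2
        else {},
        "candidates_trend": len(cand_trend),
        "candidates_final": len(cand_final),
        "direction_split": {"up": len(direction["up"]), "down": len(direction["down"])},
        "gsea": gsea_report,
    }
    with open(outdir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
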