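"""Synthetic count-matrix generator with planted temporal ground truth.

The generator emulates a two-genotype (CRE control vs KPC) five-timepoint
bulk RNA-seq design. Counts are negative-binomial draws (gamma-Poisson
parameterization, variance = mu + phi * mu^2) around library-size-scaled
relative abundances. Three planted gene classes exist alongside a null
majority:

* ``trend_up`` / ``trend_down`` — the KPC/CRE log2 fold change moves
  linearly with age, anchored at 0 at the first week, so the earliest
  timepoint is null-like and trend recovery is nontrivial.
* ``late_only`` — a fixed log2 fold change at the final week only.

Gene annotation (biotype, secreted/cell-surface flags, length) is emitted
alongside, with an optional switch that enriches planted trend genes for the
coding + secreted/surface annotation needed to traverse the full candidate
cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, ValidationError

CLASSES = ("null", "trend_up", "trend_down", "late_only")


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the generator.

    Defaults describe a fibroblast-like detected transcriptome: a long-tailed
    log-normal abundance distribution, ~2M fragments per sample, three
    replicates per genotype per week, and a biological squared coefficient of
    variation of 0.05 typical of cultured cells from inbred animals.
    """

    n_genes: int = 2000
    weeks: tuple[int, ...] = (4, 6, 8, 10, 12)
    n_replicates: int = 3
    baseline_log_mean: float = 3.0   # natural-log scale of relative abundance
    baseline_log_sd: float = 2.0
    dispersion: float = 0.05         # NB phi, variance = mu + phi mu^2
    libsize_mean: float = 2.0e6
    libsize_cv: float = 0.3
    n_trend_up: int = 20
    n_trend_down: int = 20
    trend_slope: float = 0.5         # log2FC per week for planted trend genes
    n_late: int = 50
    late_log2fc: float = 3.0
    frac_coding: float = 0.70
    frac_secreted_or_surface: float = 0.12
    enrich_planted_annotation: bool = False
    per_gene_dispersion: bool = False
    per_gene_dispersion_log_sd: float = 0.5
    gene_length_range: tuple[int, int] = (200, 10000)
    seed: int = 0

    def validate(self) -> None:
        def bad(name, why):
            raise ValidationError(f"invalid config field {name!r}: {why}")

        if self.n_genes < 1:
            bad("n_genes", "must be >= 1")
        if self.n_trend_up < 0 or self.n_trend_down < 0 or self.n_late < 0:
            bad("n_trend_up/n_trend_down/n_late", "must be >= 0")
        if self.n_trend_up + self.n_trend_down + self.n_late > self.n_genes:
            bad("n_genes", "fewer genes than planted effects")
        if self.dispersion <= 0:
            bad("dispersion", "must be > 0")
        if len(self.weeks) < 2 or any(
            b <= a for a, b in zip(self.weeks, self.weeks[1:])
        ):
            bad("weeks", "must be strictly increasing with >= 2 values")
        if self.n_replicates < 1:
            bad("n_replicates", "must be >= 1")
        if self.libsize_mean <= 0 or self.libsize_cv < 0:
            bad("libsize_mean/libsize_cv", "must be positive / non-negative")
        if not (0 <= self.frac_coding <= 1):
            bad("frac_coding", "must be in [0, 1]")
        if not (0 <= self.frac_secreted_or_surface <= 1):
            bad("frac_secreted_or_surface", "must be in [0, 1]")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            bad("gene_length_range", "must satisfy 0 < lo <= hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weeks"] = list(self.weeks)
        d["gene_length_range"] = list(self.gene_length_range)
        return d


@dataclass
class GroundTruth:
    """Planted truth emitted next to the simulated counts.

    ``table`` has one row per gene: class, true slope (log2FC per week),
    the true log2FC at every week (columns ``lfc_w{week}``), and the
    annotation flags actually assigned.
    """

    table: pd.DataFrame
    weeks: tuple[int, ...]

    def genes_of_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["cls"] == cls]

    @property
    def planted_trend(self) -> pd.Index:
        return self.table.index[self.table["cls"].isin(["trend_up", "trend_down"])]


def _true_log2fc(cfg: SimulationConfig, classes: np.ndarray) -> np.ndarray:
    """Genes x weeks matrix of planted KPC/CRE log2 fold changes."""
    w = np.asarray(cfg.weeks, dtype=float)
    lfc = np.zeros((len(classes), len(w)))
    ramp = cfg.trend_slope * (w - w[0])
    lfc[classes == "trend_up"] = ramp
    lfc[classes == "trend_down"] = -ramp
    lfc[classes == "late_only", len(w) - 1] = cfg.late_log2fc
    return lfc


def simulate_counts(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a count matrix and its ground truth from ``cfg``.

    The per-sample mean for gene g is ``libsize * rel_abundance(g) *
    2^lfc(g, week)`` for KPC samples (CRE samples use lfc = 0), so the KPC
    group mean is exactly ``2^lfc`` times the CRE group mean at equal depth.
    Deterministic: the same config (including seed) reproduces the output
    byte for byte.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes

    classes = np.array(["null"] * n, dtype=object)
    planted = rng.permutation(n)[: cfg.n_trend_up + cfg.n_trend_down + cfg.n_late]
    classes[planted[: cfg.n_trend_up]] = "trend_up"
    classes[planted[cfg.n_trend_up : cfg.n_trend_up + cfg.n_trend_down]] = "trend_down"
    classes[planted[cfg.n_trend_up + cfg.n_trend_down :]] = "late_only"

    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")
    lfc = _true_log2fc(cfg, classes)

    # Relative abundances: log-normal, normalized on the CRE baseline so the
    # planted fold changes do not get re-absorbed by per-sample normalization.
    q = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)
    rel = q / q.sum()

    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n)
    coding = rng.random(n) < cfg.frac_coding
    # secreted vs cell-surface split of the localization flag is cosmetic;
    # the screen only uses their union.
    loc = rng.random(n) < cfg.frac_secreted_or_surface
    which_surface = rng.random(n) < 0.5
    secreted = loc & ~which_surface
    surface = loc & which_surface
    if cfg.enrich_planted_annotation:
        is_trend = (classes == "trend_up") | (classes == "trend_down")
        coding = coding | is_trend
        secreted = secreted | (is_trend & ~which_surface)
        surface = surface | (is_trend & which_surface)

    if cfg.per_gene_dispersion:
        phi = rng.lognormal(np.log(cfg.dispersion), cfg.per_gene_dispersion_log_sd, size=n)
    else:
        phi = np.full(n, cfg.dispersion)

    sigma2 = np.log1p(cfg.libsize_cv**2)
    mu_ls = np.log(cfg.libsize_mean) - sigma2 / 2

    sample_rows = []
    cols = {}
    for wi, week in enumerate(cfg.weeks):
        for genotype in ("CRE", "KPC"):
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{genotype}_w{week:02d}_r{rep}"
                libsize = float(rng.lognormal(mu_ls, np.sqrt(sigma2)))
                shift = 2.0 ** lfc[:, wi] if genotype == "KPC" else 1.0
                mu = libsize * rel * shift
                # gamma-Poisson draw == NB(mean mu, var mu + phi mu^2);
                # numerically safe for phi -> 0 unlike a direct NB size 1/phi.
                lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
                cols[sid] = rng.poisson(lam)
                sample_rows.append((sid, genotype, week, rep))

    counts = pd.DataFrame(cols, index=gene_ids).astype(np.int64)
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "genotype", "week", "replicate"]
    ).set_index("sample_id")
    genes = pd.DataFrame(
        {
            "length_bp": lengths,
            "biotype": np.where(coding, "protein_coding", "non_coding"),
            "secreted": secreted,
            "cell_surface": surface,
        },
        index=gene_ids,
    )

    truth = pd.DataFrame({"cls": classes}, index=gene_ids)
    truth["true_slope"] = 0.0
    truth.loc[classes == "trend_up", "true_slope"] = cfg.trend_slope
    truth.loc[classes == "trend_down", "true_slope"] = -cfg.trend_slope
    for wi, week in enumerate(cfg.weeks):
        truth[f"lfc_w{week}"] = lfc[:, wi]
    truth["coding"] = coding
    truth["secreted_or_surface"] = secreted | surface

    cm = CountMatrix(counts, samples, genes)
    cm.validate()
    return cm, GroundTruth(truth, cfg.weeks)


def simulate_gene_sets(
    gene_ids,
    truth: GroundTruth | None = None,
    n_sets: int = 100,
    size_range: tuple[int, int] = (10, 50),
    n_planted: int = 10,
    planted_frac: float = 0.7,
    planted_class: str = "trend_up",
    source: str = "canonical",
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene-set collection, optionally with sets enriched for a
    planted expression class.

    The first ``n_planted`` sets draw ``planted_frac`` of their members from
    genes of ``planted_class`` (cycling if the class is smaller than needed)
    and the rest at random; remaining sets are uniform draws. Used to give
    the enrichment stage something to find on synthetic data.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(list(gene_ids), dtype=object)
    planted_pool = (
        np.asarray(truth.genes_of_class(planted_class), dtype=object)
        if truth is not None
        else np.array([], dtype=object)
    )
    sets: dict[str, frozenset[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if i < n_planted and len(planted_pool):
            k = min(int(round(planted_frac * size)), len(planted_pool))
            hit = rng.choice(planted_pool, size=k, replace=False)
            rest = rng.choice(np.setdiff1d(ids, hit), size=size - k, replace=False)
            members = np.concatenate([hit, rest])
            name = f"{source.upper()}_PLANTED_{i:03d}"
        else:
            members = rng.choice(ids, size=size, replace=False)
            name = f"{source.upper()}_RANDOM_{i:03d}"
        sets[name] = frozenset(members.tolist())
    return GeneSetCollection(sets, source=source)


def write_truth(truth: GroundTruth, path) -> None:
    truth.table.rename_axis("gene_id").to_csv(path, sep="\t")


def read_truth(path, weeks=None) -> GroundTruth:
    # keep_default_na: the class label "null" must survive the round trip
    table = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, na_values=[""])
    if weeks is None:
        weeks = tuple(
            int(c[len("lfc_w"):]) for c in table.columns if c.startswith("lfc_w")
        )
    return GroundTruth(table, tuple(weeks))
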