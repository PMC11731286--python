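"""In-memory containers: the annotated count matrix and gene-set collections."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("CRE", "KPC")


class ValidationError(ValueError):
    """Raised when an input table violates the pipeline's schema contract."""


@dataclass
class CountMatrix:
    """A genes x samples integer count matrix with design and annotation.

    Attributes
    ----------
    counts : pd.DataFrame
        Non-negative integers, index = gene ids, columns = sample ids.
    samples : pd.DataFrame
        Indexed by sample id with columns ``genotype`` (CRE/KPC), ``week``
        (int) and ``replicate``.
    genes : pd.DataFrame
        Indexed by gene id with columns ``length_bp``, ``biotype``,
        ``secreted`` and ``cell_surface``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def weeks(self) -> list[int]:
        return sorted(self.samples["week"].unique().tolist())

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_week(self, week: int) -> "CountMatrix":
        keep = self.samples.index[self.samples["week"] == week]
        return CountMatrix(self.counts[keep], self.samples.loc[keep], self.genes)

    def samples_of(self, genotype: str, week: int | None = None) -> pd.Index:
        mask = self.samples["genotype"] == genotype
        if week is not None:
            mask &= self.samples["week"] == week
        return self.samples.index[mask]

    def validate(self) -> None:
        """Check schema invariants, raising :class:`ValidationError` with the
        offending gene/sample named."""
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count for gene {self.counts.index[bad[0]]!r} "
                    f"in sample {self.counts.columns[bad[1]]!r}"
                )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.counts.index[bad[0]]!r} "
                f"in sample {self.counts.columns[bad[1]]!r}"
            )
        missing = self.counts.columns.difference(self.samples.index)
        if len(missing):
            raise ValidationError(f"sample {missing[0]!r} missing from sample table")
        missing_g = self.counts.index.difference(self.genes.index)
        if len(missing_g):
            raise ValidationError(f"gene {missing_g[0]!r} missing from gene table")
        sub = self.samples.loc[self.counts.columns]
        if sub["genotype"].isna().any() or (~sub["genotype"].isin(GENOTYPES)).any():
            bad = sub.index[~sub["genotype"].isin(GENOTYPES)][0]
            raise ValidationError(f"sample {bad!r} has genotype outside {GENOTYPES}")
        if sub["week"].isna().any():
            bad = sub.index[sub["week"].isna()][0]
            raise ValidationError(f"sample {bad!r} has no week")
        lengths = self.genes.loc[self.counts.index, "length_bp"]
        if (lengths <= 0).any():
            bad = lengths.index[lengths <= 0][0]
            raise ValidationError(f"gene {bad!r} has non-positive length")


def write_counts(cm: CountMatrix, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write counts.tsv / samples.tsv / genes.tsv under ``outdir``.

    Returns the mapping of table name to written path. Round-trips exactly
    through :func:`read_counts`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}counts.tsv",
        "samples": outdir / f"{prefix}samples.tsv",
        "genes": outdir / f"{prefix}genes.tsv",
    }
    cm.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    cm.samples.rename_axis("sample_id").to_csv(paths["samples"], sep="\t")
    cm.genes.rename_axis("gene_id").to_csv(paths["genes"], sep="\t")
    return paths


def read_counts(
    counts_path: str | Path,
    samples_path: str | Path,
    genes_path: str | Path,
) -> CountMatrix:
    """Read the three TSV tables and validate the schema.

    The reader is schema-only: it checks ids, integer/non-negative counts and
    required columns, but does not enforce any particular week design (the
    pipeline validates the design separately).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    genes = pd.read_csv(genes_path, sep="\t", index_col=0)
    for col in ("secreted", "cell_surface"):
        if col in genes.columns:
            genes[col] = genes[col].astype(bool)
    cm = CountMatrix(counts, samples, genes)
    cm.validate()
    cm.counts = cm.counts.astype(np.int64)
    return cm


@dataclass
class GeneSetCollection:
    """Named gene sets with a source tag (e.g. ``canonical``, ``hallmark``)."""

    sets: dict[str, frozenset[str]]
    source: str = "user"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restrict(self, universe, min_size: int = 1, max_size: int | None = None) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and drop sets outside the
        size window. Set names keep their original order."""
        uni = frozenset(universe)
        out: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            hit = members & uni
            if len(hit) < max(1, min_size):
                continue
            if max_size is not None and len(hit) > max_size:
                continue
            out[name] = hit
        return GeneSetCollection(out, source=self.source, descriptions=self.descriptions)
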