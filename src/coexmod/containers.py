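"""Core data carriers shared by every pipeline stage.

The universal carrier is :class:`ExpressionDataset`: a genes × samples matrix
of log2 expression values plus a per-sample condition label drawn from
``{"REF", "TEST1", "TEST2"}`` (reference endometrium and the two disease
stages in the motivating study; any three labels work).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical condition labels: reference plus two test (disease-stage) sets.
CONDITIONS = ("REF", "TEST1", "TEST2")

#: Reserved label for genes not assigned to any module.
GREY = "grey"


class CoexmodError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CoexmodError):
    """A configuration value is invalid or inconsistent."""


class InputError(CoexmodError):
    """An input violates a documented precondition."""


@dataclass
class ExpressionDataset:
    """Log2 expression matrix with per-sample condition labels.

    Parameters
    ----------
    expr : pandas.DataFrame
        Rows are probes or genes (unique ids), columns are samples.
    conditions : pandas.Series
        Indexed by sample id, values are condition labels; every column of
        ``expr`` must be present.
    """

    expr: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            raise InputError("duplicate row ids in expression matrix")
        if self.expr.columns.has_duplicates:
            raise InputError("duplicate sample ids in expression matrix")
        self.conditions = pd.Series(self.conditions)
        missing = [s for s in self.expr.columns if s not in self.conditions.index]
        if missing:
            raise InputError(f"samples without a condition label: {missing[:5]}")
        self.conditions = self.conditions.loc[self.expr.columns]

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    def condition(self, label: str) -> pd.DataFrame:
        """Return the genes × samples submatrix of one condition."""
        cols = self.conditions.index[self.conditions == label]
        if len(cols) == 0:
            raise InputError(f"no samples with condition label {label!r}")
        return self.expr.loc[:, cols]

    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    def drop_samples(self, sample_ids) -> "ExpressionDataset":
        keep = [s for s in self.expr.columns if s not in set(sample_ids)]
        return ExpressionDataset(self.expr.loc[:, keep], self.conditions.loc[keep])

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        return ExpressionDataset(self.expr.loc[list(gene_ids)], self.conditions)

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, expr_path: str | Path, meta_path: str | Path) -> None:
        """Write the matrix (first column gene id) and the metadata table."""
        df = self.expr.copy()
        df.index.name = "gene"
        df.to_csv(expr_path, sep="\t")
        meta = pd.DataFrame(
            {"sample_id": self.conditions.index, "condition": self.conditions.values}
        )
        meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expr_path: str | Path, meta_path: str | Path) -> "ExpressionDataset":
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        cond = pd.Series(meta["condition"].values, index=meta["sample_id"].values)
        return cls(expr, cond)


@dataclass
class ModulePartition:
    """Gene → module-label map from the reference condition.

    Labels are size-ranked colour names (largest module = "turquoise");
    ``grey`` marks unassigned genes and is excluded from downstream analysis.
    """

    labels: pd.Series  # index = gene, value = module label

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if self.labels.index.has_duplicates:
            raise InputError("duplicate genes in partition")

    @property
    def module_names(self) -> list[str]:
        """Non-grey module labels, largest first."""
        sizes = self.sizes()
        return [m for m in sizes.index if m != GREY]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_of(self, module: str) -> list:
        return list(self.labels.index[self.labels == module])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"gene": self.labels.index, "module": self.labels.values})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ModulePartition":
        df = pd.read_csv(path, sep="\t")
        return cls(pd.Series(df["module"].values, index=df["gene"].values))


@dataclass
class EigengeneSet:
    """Module eigengenes: first principal component per module.

    ``scores`` is samples × modules with unit-norm columns, each sign-aligned
    so that it correlates non-negatively with the module's mean expression
    profile; ``var_explained`` is the proportion of module variance captured.
    """

    scores: pd.DataFrame
    var_explained: pd.Series = field(default_factory=pd.Series)

    def to_tsv(self, path: str | Path) -> None:
        df = self.scores.copy()
        df.index.name = "sample"
        df.to_csv(path, sep="\t")
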