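"""Core in-memory containers shared across the pipeline.

All tabular data is held in pandas objects; the thin dataclasses here exist
to bundle the pieces that always travel together (counts + gene lengths +
sample metadata, a gene set + its provenance) and to validate invariants at
construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionTable",
    "GeneSet",
    "EnrichmentResult",
    "RescueSummary",
]


class GliatrapError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GliatrapError):
    """Invalid configuration or parameter value."""


class DegenerateInputError(GliatrapError):
    """Input is structurally valid but statistically degenerate
    (zero variance, undefined fraction, too few genes)."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with gene lengths and sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id with one column per sample_id;
        non-negative integers.
    lengths
        Series of transcript lengths in bp, indexed by gene_id.
    samples
        DataFrame indexed by sample_id with at least a ``genotype`` column;
        ``region`` and ``stage`` columns are optional annotations.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ConfigError("duplicate gene_id in count matrix")
        if self.counts.columns.duplicated().any():
            raise ConfigError("duplicate sample_id in count matrix")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:5].tolist()
            raise ConfigError(f"genes without a length: {missing}")
        if (self.lengths <= 0).any():
            raise ConfigError("gene lengths must be positive")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ConfigError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ConfigError("counts must be integral")
        if "genotype" not in self.samples.columns:
            raise ConfigError("sample metadata requires a 'genotype' column")
        extra = set(self.counts.columns) - set(self.samples.index)
        if extra:
            raise ConfigError(f"samples missing from metadata: {sorted(extra)[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_for(self, genotype: str) -> list[str]:
        """Sample ids carrying the given genotype label."""
        hits = self.samples.index[self.samples["genotype"] == genotype]
        return [s for s in self.counts.columns if s in set(hits)]


@dataclass
class ExpressionTable:
    """FPKM per gene and sample, plus per-group means.

    ``fpkm`` is gene x sample; ``group_means`` is gene x genotype-group.
    """

    fpkm: pd.DataFrame
    group_means: pd.DataFrame

    def max_group_mean(self) -> pd.Series:
        return self.group_means.max(axis=1)

    def min_group_mean(self) -> pd.Series:
        return self.group_means.min(axis=1)


@dataclass
class GeneSet:
    """A named set of genes with a provenance record.

    Provenance always records where the set came from (thresholds, source
    contrast, rule); sets without provenance cannot be audited and are
    rejected.
    """

    name: str
    members: frozenset[str]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.provenance:
            raise ConfigError(f"gene set {self.name!r} lacks provenance")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def intersect(self, genes: Iterable[str], note: str) -> "GeneSet":
        prov = dict(self.provenance)
        prov["filtered_by"] = note
        return GeneSet(self.name, self.members & set(genes), prov)


@dataclass
class EnrichmentResult:
    """A 2x2 overlap table with odds-ratio fold enrichment, Woolf CI and
    two-sided Fisher exact p.

    Cells: ``a`` = query AND reference, ``b`` = query only, ``c`` = reference
    only, ``d`` = neither, all within the declared universe.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    fold_vs_expected: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigError("2x2 cells must be non-negative")
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ConfigError("CI must bracket the odds ratio")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class RescueSummary:
    """Paired per-gene fold changes across two genotype contrasts.

    ``table`` has one row per signature gene with columns
    ``log2fc_primary`` and ``log2fc_intervention``; the paired t statistics
    quantify whether the intervention attenuates the primary signature, and
    ``attenuation`` estimates the fraction of the primary log2 effect
    removed (1 = complete rescue).
    """

    table: pd.DataFrame
    t: float
    df: int
    p: float
    attenuation: float

    def __post_init__(self) -> None:
        if self.df != len(self.table) - 1:
            raise ConfigError("df must equal n_genes - 1")
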