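"""Rank-based derivation of stimulus-specific and pan-reactive astrocyte
gene sets from a two-stimulus fold-change table.

The procedure mirrors the expanded LPS / MCAO / pan-reactive set
construction: probe-level fold changes are collapsed to one value per
annotated gene, genes are ranked per stimulus by descending fold change
(rank 1 = strongest induction), and three disjoint sets are read off the
rank pairs:

* stimulus-specific: ranked in the top ``top_specific`` for one stimulus
  and at least ``separation`` rank places lower for the other;
* pan-reactive: ranked in the top ``top_pan`` for both stimuli with no more
  than ``separation`` rank places between them, and not already claimed by
  a specific set (specific sets take precedence at the boundary, which
  keeps the three sets disjoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigError, DegenerateInputError, ExpressionTable, GeneSet

__all__ = [
    "collapse_probes",
    "rank_genes",
    "classify_reactive",
    "ReactiveSets",
    "filter_expressed",
    "marker_upregulation_fraction",
]

_FC_COLS = ("fc_stimA", "fc_stimB")


@dataclass
class ReactiveSets:
    """The three disjoint reactive gene sets plus a per-gene audit table
    (ranks, assigned set, rule fired)."""

    stim_a_set: GeneSet
    stim_b_set: GeneSet
    pan_set: GeneSet
    audit: pd.DataFrame

    def __post_init__(self) -> None:
        a, b, p = self.stim_a_set.members, self.stim_b_set.members, self.pan_set.members
        if a & b or a & p or b & p:
            raise ConfigError("reactive sets must be pairwise disjoint")


def collapse_probes(table: pd.DataFrame, top_n: int = 250) -> pd.DataFrame:
    """Collapse a probe-level fold-change table to one row per gene.

    Probes without a gene symbol are dropped ("fully annotated genes"
    only).  For genes with multiple probes the arithmetic mean fold change
    per stimulus is taken as the gene's value — stated for genes featuring
    within the provisional top ``top_n`` probes of either stimulus, and
    applied uniformly to all multi-probe genes, which leaves the ranking of
    the top genes unchanged while giving every gene a single value.
    Single-probe genes pass through unchanged.
    """
    if table.empty:
        raise ConfigError("probe table is empty")
    annotated = table[table["gene_symbol"].notna() & (table["gene_symbol"] != "")]
    if annotated.empty:
        import warnings

        warnings.warn("all probes unannotated; collapsed table is empty", stacklevel=2)
        return pd.DataFrame(columns=["gene_symbol", *_FC_COLS])
    out = (annotated.groupby("gene_symbol", sort=False)[list(_FC_COLS)]
           .mean().reset_index())
    out.attrs["top_n"] = top_n
    return out


def rank_genes(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Rank genes per stimulus by descending fold change (rank 1 highest).

    Ties in fold change are broken lexicographically by gene symbol so the
    ranking is a total order.  Duplicate gene symbols are an error (the
    collapse step must have merged them).
    """
    if collapsed.empty:
        raise ConfigError("collapsed table has no genes")
    if collapsed["gene_symbol"].duplicated().any():
        dups = collapsed.loc[collapsed["gene_symbol"].duplicated(), "gene_symbol"]
        raise ConfigError(f"duplicate gene symbols after collapsing: {dups.tolist()[:5]}")
    out = collapsed.set_index("gene_symbol").copy()
    order = out.index.to_numpy()
    for col, rank_col in zip(_FC_COLS, ("rank_stimA", "rank_stimB")):
        idx = np.lexsort((order, -out[col].to_numpy()))
        ranks = np.empty(len(out), dtype=int)
        ranks[idx] = np.arange(1, len(out) + 1)
        out[rank_col] = ranks
    return out.reset_index()


def classify_reactive(ranked: pd.DataFrame, top_specific: int = 100,
                      top_pan: int = 250, separation: int = 50,
                      labels: tuple[str, str] = ("stimA", "stimB")) -> ReactiveSets:
    """Partition ranked genes into stimulus-specific and pan-reactive sets.

    A gene ranked 8 and 26 lands in the pan set (both within the top 250,
    18 places apart); a gene ranked 6 and 61 is specific to the first
    stimulus (top 100, 55 places lower for the other).  Both separation
    comparisons are inclusive; a gene satisfying both rules exactly at the
    boundary goes to the specific set.
    """
    if separation < 0:
        raise ConfigError("separation must be >= 0")
    ra = ranked["rank_stimA"].to_numpy()
    rb = ranked["rank_stimB"].to_numpy()
    is_a = (ra <= top_specific) & (rb - ra >= separation)
    is_b = (rb <= top_specific) & (ra - rb >= separation)
    is_pan = ((ra <= top_pan) & (rb <= top_pan)
              & (np.abs(ra - rb) <= separation) & ~is_a & ~is_b)

    assigned = np.where(is_a, f"{labels[0]}_specific",
                        np.where(is_b, f"{labels[1]}_specific",
                                 np.where(is_pan, "pan_reactive", "none")))
    rule = np.where(is_a, f"top{top_specific} {labels[0]}, >= {separation} lower in {labels[1]}",
                    np.where(is_b, f"top{top_specific} {labels[1]}, >= {separation} lower in {labels[0]}",
                             np.where(is_pan, f"both top{top_pan}, <= {separation} apart", "")))
    audit = ranked[["gene_symbol", "rank_stimA", "rank_stimB"]].copy()
    audit["assigned_set"] = assigned
    audit["rule"] = rule

    prov = {"top_specific": top_specific, "top_pan": top_pan, "separation": separation}
    genes = ranked["gene_symbol"].to_numpy()
    return ReactiveSets(
        stim_a_set=GeneSet(f"{labels[0]}_specific", frozenset(genes[is_a]), dict(prov)),
        stim_b_set=GeneSet(f"{labels[1]}_specific", frozenset(genes[is_b]), dict(prov)),
        pan_set=GeneSet("pan_reactive", frozenset(genes[is_pan]), dict(prov)),
        audit=audit,
    )


def filter_expressed(sets: ReactiveSets, expr: ExpressionTable,
                     min_fpkm: float = 1.0) -> ReactiveSets:
    """Restrict each reactive set to genes expressed above ``min_fpkm``
    (strictly) in every condition group of the interrogated dataset."""
    ok = expr.group_means.index[(expr.group_means > min_fpkm).all(axis=1)]
    note = f"FPKM > {min_fpkm} in all condition groups"
    keep = set(ok)
    return ReactiveSets(
        stim_a_set=sets.stim_a_set.intersect(keep, note),
        stim_b_set=sets.stim_b_set.intersect(keep, note),
        pan_set=sets.pan_set.intersect(keep, note),
        audit=sets.audit,
    )


def marker_upregulation_fraction(markers: GeneSet, de: pd.DataFrame,
                                 expr: ExpressionTable, min_fpkm: float = 1.0,
                                 max_padj: float = 0.05) -> tuple[int, int]:
    """Of the marker genes expressed above ``min_fpkm``, how many are
    significantly upregulated?

    Returns (k, m): m markers pass the expression filter (markers below it
    are discarded before testing), k of those have padj < ``max_padj`` and
    positive log2 fold change.  Raises if no marker passes the filter, since
    the fraction k/m is then undefined.
    """
    if not markers.members:
        raise ConfigError("marker set is empty")
    expressed = markers.members & set(
        expr.max_group_mean().index[expr.max_group_mean() > min_fpkm])
    m = len(expressed)
    if m == 0:
        raise DegenerateInputError(
            f"no marker in {markers.name!r} passes the {min_fpkm} FPKM filter; "
            "upregulated fraction is undefined")
    sub = de.loc[de.index.intersection(expressed)]
    k = int(((sub["padj"] < max_padj) & (sub["log2fc"] > 0)).sum())
    return k, m
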