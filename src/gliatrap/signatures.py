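"""Cross-model core signatures, cross-species comparison, early-vs-late
precocity testing, and inter-region concordance.

A "core" signature is the intersection of the genes significantly changed
in the same direction in two disease models, tested for overlap against
the jointly tested universe.  Cross-species comparison maps a human gene
set into mouse through strict 1:1 orthologs, applies an expression floor
(10 FPKM by default — single-nucleus data preferentially detects highly
expressed genes), and tallies per-gene significance in each model at both
raw and adjusted p.  Precocity asks whether genes strongly induced at a
late disease stage are already shifted at the early stage, by a ratio
paired t-test on per-gene log2 ratios of group-mean FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import (ConfigError, DegenerateInputError, EnrichmentResult,
                         ExpressionTable, GeneSet)
from .enrichment import fisher_enrichment

__all__ = [
    "core_overlap",
    "cross_species_compare",
    "CrossSpeciesResult",
    "precocity_test",
    "regional_concordance",
    "log2_ratio_of_means",
]

_PSEUDOCOUNT = 0.1  # added to both group-mean FPKMs before taking ratios


def log2_ratio_of_means(num: pd.Series, den: pd.Series,
                        pseudocount: float = _PSEUDOCOUNT) -> pd.Series:
    """log2((num + pc) / (den + pc)); the pseudocount guards zero means."""
    return np.log2((num + pseudocount) / (den + pseudocount))


def _significant(de: pd.DataFrame, direction: str, max_padj: float,
                 col: str = "padj") -> set[str]:
    sign_ok = de["log2fc"] > 0 if direction == "up" else de["log2fc"] < 0
    return set(de.index[(de[col] < max_padj) & sign_ok & (de["status"] == "tested")])


def core_overlap(de_a: pd.DataFrame, de_b: pd.DataFrame, direction: str = "up",
                 max_padj: float = 0.05) -> tuple[GeneSet, EnrichmentResult]:
    """Genes significantly changed in the stated direction in both models,
    with Fisher overlap significance on the jointly tested universe."""
    if direction not in ("up", "down"):
        raise ConfigError("direction must be 'up' or 'down'")
    uni = (set(de_a.index[de_a["status"] == "tested"])
           & set(de_b.index[de_b["status"] == "tested"]))
    if not uni:
        raise ConfigError("the two DE results share no tested genes")
    sig_a = _significant(de_a, direction, max_padj) & uni
    sig_b = _significant(de_b, direction, max_padj) & uni
    core = GeneSet(f"core_{direction}", frozenset(sig_a & sig_b),
                   {"direction": direction, "max_padj": max_padj,
                    "n_model_a": len(sig_a), "n_model_b": len(sig_b)})
    enr = fisher_enrichment(
        GeneSet("model_a_sig", frozenset(sig_a), {"model": "A"}),
        GeneSet("model_b_sig", frozenset(sig_b), {"model": "B"}),
        uni)
    return core, enr


@dataclass
class CrossSpeciesResult:
    """Per-gene cross-model table for a human-derived gene set mapped into
    mouse, plus enrichment of that set in each model and in the core."""

    table: pd.DataFrame  # log2fc per model + significance categories
    n_mapped: int
    n_raw_significant: int      # significant (raw p) in at least one model
    n_adj_significant: int      # significant (padj) in at least one model
    enrichment_model_a: EnrichmentResult
    enrichment_model_b: EnrichmentResult
    enrichment_core: EnrichmentResult


def _category(in_a: pd.Series, in_b: pd.Series) -> pd.Series:
    return pd.Series(
        np.where(in_a & in_b, "both",
                 np.where(in_a, "A_only", np.where(in_b, "B_only", "neither"))),
        index=in_a.index)


def cross_species_compare(human_set: GeneSet, orthologs: pd.DataFrame,
                          de_a: pd.DataFrame, de_b: pd.DataFrame,
                          expr_a: ExpressionTable, expr_b: ExpressionTable,
                          min_fpkm: float = 10.0) -> CrossSpeciesResult:
    """Map a human gene set into mouse (1:1 orthologs only), apply the
    expression floor, and compare against two mouse models.

    ``orthologs`` needs columns human_gene, mouse_gene, one_to_one (bool).
    Genes expressed above ``min_fpkm`` in either model's data survive the
    filter; each survivor is categorised as induced in both / A only /
    B only / neither at raw p < 0.05 (as plotted) and at padj < 0.05 (also
    tallied).  Enrichments use the union of both models' tested genes as
    the universe.
    """
    one2one = orthologs[orthologs["one_to_one"].astype(bool)]
    mapped = set(one2one.loc[one2one["human_gene"].isin(human_set.members),
                             "mouse_gene"])
    max_a = expr_a.max_group_mean()
    max_b = expr_b.max_group_mean()
    expressed = set(max_a.index[max_a > min_fpkm]) | set(max_b.index[max_b > min_fpkm])
    genes = sorted(mapped & expressed)
    if not genes:
        import warnings

        warnings.warn("no human gene survives ortholog mapping and the "
                      "expression filter", stacklevel=2)
    uni = (set(de_a.index[de_a["status"] == "tested"])
           | set(de_b.index[de_b["status"] == "tested"]))

    idx = pd.Index(genes)
    up_a_raw = idx.isin(_significant(de_a, "up", 0.05, "p"))
    up_b_raw = idx.isin(_significant(de_b, "up", 0.05, "p"))
    up_a_adj = idx.isin(_significant(de_a, "up", 0.05, "padj"))
    up_b_adj = idx.isin(_significant(de_b, "up", 0.05, "padj"))
    table = pd.DataFrame({
        "log2fc_modelA": de_a["log2fc"].reindex(idx),
        "log2fc_modelB": de_b["log2fc"].reindex(idx),
        "category_raw_p": _category(pd.Series(up_a_raw, idx), pd.Series(up_b_raw, idx)),
        "category_padj": _category(pd.Series(up_a_adj, idx), pd.Series(up_b_adj, idx)),
    })

    query = GeneSet(human_set.name + "_mouse", frozenset(g for g in genes if g in uni),
                    {"mapped_from": human_set.name, "min_fpkm": min_fpkm})
    sig_a = GeneSet("model_a_up", frozenset(_significant(de_a, "up", 0.05)), {"m": "A"})
    sig_b = GeneSet("model_b_up", frozenset(_significant(de_b, "up", 0.05)), {"m": "B"})
    core, _ = core_overlap(de_a, de_b, "up")
    return CrossSpeciesResult(
        table=table,
        n_mapped=len(genes),
        n_raw_significant=int((table["category_raw_p"] != "neither").sum()),
        n_adj_significant=int((table["category_padj"] != "neither").sum()),
        enrichment_model_a=fisher_enrichment(query, sig_a, uni),
        enrichment_model_b=fisher_enrichment(query, sig_b, uni),
        enrichment_core=fisher_enrichment(query, core, uni),
    )


def precocity_test(late_de: pd.DataFrame, early_expr: ExpressionTable,
                   contrast: tuple[str, str], fold_threshold: float = 2.0,
                   max_padj: float = 0.05) -> tuple[float, int, float, pd.Series]:
    """Are genes strongly induced at the late stage already shifted early?

    The gene set is the late-stage genes induced more than
    ``fold_threshold``-fold at padj < ``max_padj``; for each, the early
    log2 fold change is log2 of the ratio of early group-mean FPKMs
    (test vs reference, pseudocount 0.1), and a ratio paired t-test is a
    one-sample t of those log ratios against zero.  Returns
    (t, df, p, per-gene early log2FC) with df = n_genes - 1.
    """
    test, ref = contrast
    genes = late_de.index[(late_de["log2fc"] > np.log2(fold_threshold))
                          & (late_de["padj"] < max_padj)]
    genes = genes.intersection(early_expr.group_means.index)
    if len(genes) < 3:
        raise DegenerateInputError(
            f"only {len(genes)} late-induced genes available at early stage; "
            "need at least 3 for the ratio paired t-test")
    ratios = log2_ratio_of_means(early_expr.group_means.loc[genes, test],
                                 early_expr.group_means.loc[genes, ref])
    if np.allclose(ratios.var(ddof=1), 0.0):
        raise DegenerateInputError("early log ratios have zero variance")
    t, p = stats.ttest_1samp(ratios, 0.0)
    return float(t), len(genes) - 1, float(p), ratios


def regional_concordance(de_a: pd.DataFrame, de_b: pd.DataFrame,
                         expr_a: ExpressionTable | None = None,
                         expr_b: ExpressionTable | None = None,
                         min_fpkm: float = 1.0) -> tuple[float, float, tuple[float, float]]:
    """Pearson correlation and OLS slope of per-gene log2 fold changes
    between two regions (B regressed on A), with a normal-theory 95% CI on
    the slope.

    The shared universe is genes tested in both; when expression tables are
    supplied it is further restricted to genes above ``min_fpkm`` in both.
    """
    genes = (de_a.index[de_a["status"] == "tested"]
             .intersection(de_b.index[de_b["status"] == "tested"]))
    if expr_a is not None:
        genes = genes.intersection(
            expr_a.max_group_mean().index[expr_a.max_group_mean() >= min_fpkm])
    if expr_b is not None:
        genes = genes.intersection(
            expr_b.max_group_mean().index[expr_b.max_group_mean() >= min_fpkm])
    if len(genes) < 3:
        raise ConfigError("need at least 3 shared genes")
    x = de_a.loc[genes, "log2fc"].to_numpy()
    y = de_b.loc[genes, "log2fc"].to_numpy()
    if np.allclose(x.var(), 0) or np.allclose(y.var(), 0):
        raise DegenerateInputError("zero variance in a fold-change vector")
    r = float(np.corrcoef(x, y)[0, 1])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return r, float(fit.params[1]), (float(lo), float(hi))
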