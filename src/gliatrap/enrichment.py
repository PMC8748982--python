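"""Gene-set enrichment statistics: 2x2 Fisher tests with odds-ratio
confidence intervals, comparison of two enrichments, the multi-cutoff GWAS
risk sweep, and generic over-representation against GMT annotations.

Fold enrichment is reported as the sample odds ratio (a*d)/(b*c) with a 95%
Woolf (log-OR normal) interval, exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c +
1/d)).  When any cell is zero the OR and CI are computed after adding 0.5
to every cell (Haldane-Anscombe); the exact p is never corrected.  The
ratio of observed to expected overlap is also exposed
(``fold_vs_expected``) for users who prefer that reading of "fold
enrichment".
"""

from __future__ import annotations

import fnmatch
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, EnrichmentResult, ExpressionTable, GeneSet
from .expression import bh_adjust

__all__ = [
    "fisher_enrichment",
    "enrichment_from_table",
    "compare_enrichments",
    "risk_enrichment_sweep",
    "auto_cutoffs",
    "overrepresentation",
]

_Z95 = stats.norm.ppf(0.975)


def enrichment_from_table(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Enrichment statistics for an explicit 2x2 table.

    Two-sided Fisher exact p on the uncorrected table; odds ratio and Woolf
    CI with the +0.5 zero-cell rule applied only when needed.
    """
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    odds = (aa * dd) / (bb * cc)
    se = math.sqrt((1 / cells).sum())
    ci_low, ci_high = odds * math.exp(-_Z95 * se), odds * math.exp(_Z95 * se)
    n = a + b + c + d
    expected = (a + b) * (a + c) / n if n else float("nan")
    fold = a / expected if expected else float("nan")
    return EnrichmentResult(a=a, b=b, c=c, d=d, odds_ratio=odds,
                            ci_low=ci_low, ci_high=ci_high, p=p,
                            fold_vs_expected=fold)


def fisher_enrichment(query: GeneSet, reference: GeneSet,
                      universe: Iterable[str]) -> EnrichmentResult:
    """Is ``query`` over-represented in ``reference`` within ``universe``?

    The reference is silently intersected with the universe; the query must
    be contained in it.
    """
    uni = set(universe)
    if not uni:
        raise ConfigError("universe is empty")
    stray = query.members - uni
    if stray:
        raise ConfigError(f"query genes outside the universe: {sorted(stray)[:10]}")
    ref = reference.members & uni
    a = len(query.members & ref)
    b = len(query.members) - a
    c = len(ref) - a
    d = len(uni) - a - b - c
    return enrichment_from_table(a, b, c, d)


def compare_enrichments(e1: EnrichmentResult, e2: EnrichmentResult) -> tuple[float, float]:
    """Normal approximation to the difference in log odds ratios.

    z = (ln OR1 - ln OR2) / sqrt(SE1^2 + SE2^2), SE^2 = sum of reciprocal
    cells (after the zero-cell rule); returns (z, two-sided p).
    """
    def log_or_se(e: EnrichmentResult) -> tuple[float, float]:
        cells = np.array([e.a, e.b, e.c, e.d], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        return math.log(e.odds_ratio), float((1 / cells).sum())

    l1, v1 = log_or_se(e1)
    l2, v2 = log_or_se(e2)
    z = (l1 - l2) / math.sqrt(v1 + v2)
    return z, float(2 * stats.norm.sf(abs(z)))


def auto_cutoffs(universe_size: int) -> list[float]:
    """The sweep grid: a Bonferroni point 0.05/universe followed by
    sequentially relaxed sub-threshold cutoffs."""
    return [0.05 / universe_size, 5e-5, 5e-4, 5e-3, 5e-2]


def risk_enrichment_sweep(induced: GeneSet, gwas: pd.Series, expr: ExpressionTable,
                          cutoffs: Sequence[float] | str = "auto",
                          min_fpkm: float = 1.0) -> pd.DataFrame:
    """Enrichment of an induced gene set in GWAS risk genes at a sequence of
    relaxing gene-level p-value cutoffs.

    The universe is the set of genes expressed above ``min_fpkm`` (maximum
    genotype-group mean FPKM) for which a GWAS p value is available; at each
    cutoff the risk set is the universe genes with p below it.  With the
    default "auto" grid the first cutoff is Bonferroni, 0.05 / universe
    size.  Returns one row per cutoff with all four 2x2 cells exposed.
    """
    expressed = set(expr.max_group_mean().index[expr.max_group_mean() > min_fpkm])
    uni = expressed & set(gwas.index)
    if not uni:
        raise ConfigError("empty universe: no expressed gene has a GWAS p value")
    grid = auto_cutoffs(len(uni)) if isinstance(cutoffs, str) else list(cutoffs)
    query = induced.intersect(uni, "restricted to sweep universe")
    rows = []
    for cut in grid:
        risk = GeneSet(f"gwas_p<{cut:g}",
                       frozenset(g for g in uni if gwas[g] < cut),
                       {"cutoff": cut})
        e = fisher_enrichment(query, risk, uni)
        rows.append({"cutoff": cut, "a": e.a, "b": e.b, "c": e.c, "d": e.d,
                     "odds_ratio": e.odds_ratio, "ci_low": e.ci_low,
                     "ci_high": e.ci_high, "p": e.p, "n_risk": e.a + e.c,
                     "universe": len(uni)})
    return pd.DataFrame(rows)


def overrepresentation(query: GeneSet, annotation: Sequence[GeneSet],
                       universe: Iterable[str], min_genes: int = 5,
                       excluded_terms: Sequence[str] = (),
                       top: int = 10, max_padj: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each
    annotation term.

    Terms whose name matches any glob pattern in ``excluded_terms`` are
    dropped (e.g. disease pathways); terms overlapping the query in fewer
    than ``min_genes`` genes are dropped before testing, and terms are
    clipped to the universe.  BH adjustment runs across the tested terms
    only.  All tested terms are returned ranked by padj; the ``reported``
    column marks the display subset — the top ``top`` terms, unless fewer
    reach padj < ``max_padj``, in which case only those.
    """
    if not annotation:
        raise ConfigError("annotation collection is empty")
    uni = set(universe)
    q = query.members & uni
    rows = []
    for term in annotation:
        if any(fnmatch.fnmatch(term.name.lower(), pat.lower()) or
               pat.lower() in term.name.lower() for pat in excluded_terms):
            continue
        members = term.members & uni
        overlap = q & members
        if len(overlap) < min_genes:
            continue
        # P(X >= overlap) drawing |q| genes from the universe
        p = float(stats.hypergeom.sf(len(overlap) - 1, len(uni), len(members), len(q)))
        rows.append({"term_id": term.name, "term_size_in_universe": len(members),
                     "overlap": len(overlap), "p": p,
                     "members": ",".join(sorted(overlap))})
    out = pd.DataFrame(rows, columns=["term_id", "term_size_in_universe",
                                      "overlap", "p", "members"])
    if out.empty:
        out["padj"] = pd.Series(dtype=float)
        out["reported"] = pd.Series(dtype=bool)
        return out
    out["padj"] = bh_adjust(out["p"])
    out = out.sort_values(["padj", "p", "term_id"]).reset_index(drop=True)
    n_sig = int((out["padj"] < max_padj).sum())
    n_report = top if n_sig >= top else n_sig
    out["reported"] = np.arange(len(out)) < n_report
    return out
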