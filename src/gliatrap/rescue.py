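"""Transcriptomic-rescue quantification and two self-contained procedures:
allele-read fractions at a two-allele locus and horizontal-bar behavioural
scoring.

Rescue is quantified gene-wise: for a signature of perturbation-responsive
genes, the log2 fold change the perturbation causes on its own (primary
contrast, e.g. TG vs WT) is paired with the fold change it causes in the
intervention background (e.g. TGxNRF2 vs NRF2), and a ratio paired t-test
asks whether the intervention attenuates the signature.  The attenuation
estimate 1 - mean(intervention lfc)/mean(primary lfc) is 1 for a complete
rescue and 0 for none.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .containers import (ConfigError, DegenerateInputError, ExpressionTable,
                         GeneSet, RescueSummary)
from .signatures import log2_ratio_of_means

__all__ = [
    "rescue_fold_change_test",
    "baseline_shift_check",
    "allele_fraction",
    "bar_score",
    "bar_session_score",
]


def _signature_log2fc(signature: GeneSet, expr: ExpressionTable,
                      contrast: tuple[str, str]) -> pd.Series:
    test, ref = contrast
    missing = signature.members - set(expr.group_means.index)
    if missing:
        raise ConfigError(f"signature genes absent from expression table: "
                          f"{sorted(missing)[:5]}")
    for g in contrast:
        if g not in expr.group_means.columns:
            raise ConfigError(f"genotype {g!r} absent from expression table")
    genes = sorted(signature.members)
    return log2_ratio_of_means(expr.group_means.loc[genes, test],
                               expr.group_means.loc[genes, ref])


def rescue_fold_change_test(signature: GeneSet, expr: ExpressionTable,
                            primary_contrast: tuple[str, str],
                            intervention_contrast: tuple[str, str]) -> RescueSummary:
    """Ratio paired t-test of a signature's fold changes with and without
    the intervention.

    Per-gene log2 fold changes are computed from genotype-group mean FPKMs
    (pseudocount 0.1) for both contrasts, and the paired t-test runs on the
    per-gene differences.  df = n_genes - 1.
    """
    if len(signature) < 3:
        raise ConfigError("need at least 3 signature genes")
    lfc_primary = _signature_log2fc(signature, expr, primary_contrast)
    lfc_intervention = _signature_log2fc(signature, expr, intervention_contrast)
    diffs = lfc_primary - lfc_intervention
    if np.allclose(diffs.var(ddof=1), 0.0):
        raise DegenerateInputError(
            "primary and intervention fold changes differ by a constant; "
            "the paired t-test is degenerate")
    t, p = stats.ttest_rel(lfc_primary, lfc_intervention)
    mean_primary = lfc_primary.mean()
    atten = (1.0 - lfc_intervention.mean() / mean_primary
             if not np.isclose(mean_primary, 0.0) else float("nan"))
    table = pd.DataFrame({"log2fc_primary": lfc_primary,
                          "log2fc_intervention": lfc_intervention})
    return RescueSummary(table=table, t=float(t), df=len(table) - 1,
                         p=float(p), attenuation=float(atten))


def baseline_shift_check(signature: GeneSet, expr: ExpressionTable,
                         baseline_contrast: tuple[str, str]
                         ) -> tuple[pd.Series, float, float, float]:
    """Does the intervention alone move the signature's baseline expression?

    One-sample t of the per-gene baseline log2 fold changes (e.g. NRF2 vs
    WT) against zero; non-significance supports the control that rescue is
    not an artefact of a changed fold-change denominator.  Returns
    (per-gene log2FC, mean, t, p).
    """
    if not signature.members:
        raise ConfigError("signature is empty")
    if len(signature) < 3:
        raise ConfigError("need at least 3 signature genes")
    lfc = _signature_log2fc(signature, expr, baseline_contrast)
    if np.allclose(lfc.var(ddof=1), 0.0):
        raise DegenerateInputError("baseline log ratios have zero variance")
    t, p = stats.ttest_1samp(lfc, 0.0)
    return lfc, float(lfc.mean()), float(t), float(p)


def allele_fraction(reads: list[str], wt_motif: str, mut_motif: str
                    ) -> tuple[float, tuple[float, float], int, int, int]:
    """Score reads as wild type or mutant by exact motif match and return
    the percent mutant.

    Reads containing neither motif, or both, are counted as unscored.
    Returns (percent_mutant, Wilson 95% CI as percents, n_wt, n_mut,
    n_unscored).
    """
    if wt_motif == mut_motif:
        raise ConfigError("motifs must differ")
    n_wt = n_mut = n_unscored = 0
    for read in reads:
        has_wt, has_mut = wt_motif in read, mut_motif in read
        if has_wt and not has_mut:
            n_wt += 1
        elif has_mut and not has_wt:
            n_mut += 1
        else:
            n_unscored += 1
    scored = n_wt + n_mut
    if scored == 0:
        raise DegenerateInputError("no read matches either motif; "
                                   "allele fraction undefined")
    pct = 100.0 * n_mut / scored
    lo, hi = proportion_confint(n_mut, scored, alpha=0.05, method="wilson")
    return pct, (100.0 * lo, 100.0 * hi), n_wt, n_mut, n_unscored


# horizontal-bar scoring bands: (upper time bound in whole seconds, score)
_FELL_BANDS = [(5, 0), (10, 1), (20, 2), (40, 3), (59, 4), (60, 5)]
_REACHED_BANDS = [(5, 10), (10, 9), (20, 8), (30, 7), (59, 6), (60, 5)]


def bar_score(outcome: str, time_s: float) -> int:
    """Convert one horizontal-bar trial to a 0-10 score.

    ``outcome`` is "fell" or "reached_platform"; ``time_s`` is in [0, 60]
    (60 s is the cut-off).  Times are floored to whole seconds before the
    band lookup, since the scoring table is specified in whole seconds.
    Falling quickly scores low, reaching the platform quickly scores high,
    and lasting the full 60 s scores 5 under either outcome.
    """
    if not 0.0 <= time_s <= 60.0:
        raise ConfigError("time must be in [0, 60] seconds")
    bands = {"fell": _FELL_BANDS, "reached_platform": _REACHED_BANDS}.get(outcome)
    if bands is None:
        raise ConfigError("outcome must be 'fell' or 'reached_platform'")
    whole = math.floor(time_s)
    for upper, score in bands:
        if whole <= upper:
            return score
    raise AssertionError("unreachable")


def bar_session_score(trials: list[tuple[str, float]]) -> float:
    """Mean score over the (three) trials of one testing session."""
    if not trials:
        raise ConfigError("session has no trials")
    return float(np.mean([bar_score(o, t) for o, t in trials]))
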