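"""Fisher enrichment, Woolf CIs, log-OR comparison, the GWAS sweep and ORA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gliatrap.containers import ConfigError, GeneSet
from gliatrap.enrichment import (auto_cutoffs, compare_enrichments,
                                 enrichment_from_table, fisher_enrichment,
                                 overrepresentation, risk_enrichment_sweep)


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over tables with fixed
    margins, summing probabilities no larger than the observed table's
    (minimum-likelihood rule).  Independent of scipy."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def gs(name, members):
    return GeneSet(name, frozenset(members), {"source": "test"})


class TestFisherEnrichment:
    def test_exact_independence(self):
        e = enrichment_from_table(1, 9, 9, 81)
        assert e.odds_ratio == pytest.approx(1.0)
        assert e.p == pytest.approx(1.0)

    def test_known_odds_ratio(self):
        e = enrichment_from_table(8, 2, 12, 78)
        assert e.odds_ratio == pytest.approx(26.0)
        assert e.p == pytest.approx(fisher_two_sided_oracle(8, 2, 12, 78), rel=1e-9)

    def test_zero_cell_rule(self):
        """OR/CI from the +0.5-corrected table; exact p uncorrected."""
        e = enrichment_from_table(0, 10, 5, 85)
        # hand calculation on the corrected table
        odds = (0.5 * 85.5) / (10.5 * 5.5)
        se = math.sqrt(1 / 0.5 + 1 / 10.5 + 1 / 5.5 + 1 / 85.5)
        assert e.odds_ratio == pytest.approx(odds)
        assert e.ci_low == pytest.approx(odds * math.exp(-1.959963984540054 * se), rel=1e-6)
        assert e.p == pytest.approx(fisher_two_sided_oracle(0, 10, 5, 85), rel=1e-9)

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60),
           st.integers(0, 60))
    def test_p_equals_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        e = enrichment_from_table(a, b, c, d)
        assert e.p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-7)

    def test_query_reference_symmetry(self):
        universe = [f"g{i}" for i in range(60)]
        q = gs("q", universe[:20])
        r = gs("r", universe[10:35])
        e1 = fisher_enrichment(q, r, universe)
        e2 = fisher_enrichment(r, q, universe)
        assert e1.odds_ratio == pytest.approx(e2.odds_ratio)
        assert e1.p == pytest.approx(e2.p)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ConfigError, match="outside"):
            fisher_enrichment(gs("q", {"x"}), gs("r", {"a"}), ["a", "b"])
        with pytest.raises(ConfigError):
            fisher_enrichment(gs("q", set()), gs("r", {"a"}), [])

    def test_ci_brackets_or(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, 4)
            if (a + b) and (c + d) and (a + c) and (b + d):
                e = enrichment_from_table(int(a), int(b), int(c), int(d))
                assert e.ci_low <= e.odds_ratio <= e.ci_high

    def test_woolf_ci_null_coverage(self):
        """95% Woolf interval contains OR=1 for ~95% of null tables."""
        rng = np.random.default_rng(42)
        n1 = n2 = 60
        a = rng.binomial(n1, 0.3, 2000)
        c = rng.binomial(n2, 0.3, 2000)
        covered = 0
        for ai, ci in zip(a, c):
            e = enrichment_from_table(int(ai), n1 - int(ai), int(ci), n2 - int(ci))
            covered += e.ci_low <= 1.0 <= e.ci_high
        assert covered / 2000 == pytest.approx(0.95, abs=0.02)


class TestCompareEnrichments:
    def test_identical_tables_z_zero(self):
        e = enrichment_from_table(5, 5, 5, 5)
        z, p = compare_enrichments(e, e)
        assert z == 0.0 and p == 1.0

    def test_closed_form(self):
        e1 = enrichment_from_table(20, 80, 10, 890)
        e2 = enrichment_from_table(10, 90, 10, 890)
        z, p = compare_enrichments(e1, e2)
        # independent recomputation of the log-OR difference z
        lor1 = math.log(20 * 890 / (80 * 10))
        lor2 = math.log(10 * 890 / (90 * 10))
        se = math.sqrt(1/20 + 1/80 + 1/10 + 1/890 + 1/10 + 1/90 + 1/10 + 1/890)
        assert z == pytest.approx((lor1 - lor2) / se)
        assert z == pytest.approx(1.3227, abs=1e-3)

    def test_antisymmetry(self):
        e1 = enrichment_from_table(20, 80, 10, 890)
        e2 = enrichment_from_table(10, 90, 10, 890)
        z12, p12 = compare_enrichments(e1, e2)
        z21, p21 = compare_enrichments(e2, e1)
        assert z21 == pytest.approx(-z12)
        assert p21 == pytest.approx(p12)


class TestRiskSweep:
    @staticmethod
    def _setup(induced_bias, seed, n=4000):
        from gliatrap.expression import compute_fpkm, differential_expression, select_genes
        from gliatrap.sim import SimConfig, simulate_gwas_table, simulate_translatome

        cm, labels = simulate_translatome(
            SimConfig(n_genes=n, effect_log2fc=2.0, seed=seed))
        expr = compute_fpkm(cm)
        de = differential_expression(cm, ("TG", "WT"))
        induced = select_genes(de, expr, direction="up")
        gwas, _ = simulate_gwas_table(cm.gene_ids,
                                      labels.index[labels == "induced"],
                                      risk_fraction=0.02,
                                      induced_bias=induced_bias, seed=seed)
        return induced, gwas, expr

    def test_bonferroni_first_auto_cutoff(self):
        assert auto_cutoffs(9938)[0] == pytest.approx(5.03e-6, rel=1e-3)

    def test_null_bias_gives_unit_odds_ratios(self):
        """With no planted association the mean sweep OR is ~1."""
        log_ors = []
        for seed in range(20):
            induced, gwas, expr = self._setup(1.0, seed, n=2000)
            sweep = risk_enrichment_sweep(induced, gwas, expr)
            log_ors.append(np.log(sweep["odds_ratio"].iloc[-1]))  # densest cutoff
        mean = np.mean(log_ors)
        se = np.std(log_ors, ddof=1) / np.sqrt(len(log_ors))
        assert abs(mean) < max(2.5 * se, 0.1)

    def test_planted_bias_detected_at_bonferroni(self):
        induced, gwas, expr = self._setup(4.0, 7, n=10_000)
        sweep = risk_enrichment_sweep(induced, gwas, expr)
        first = sweep.iloc[0]
        assert first["odds_ratio"] > 1 and first["ci_low"] > 1

    def test_zero_risk_handled_by_zero_cell_rule(self):
        genes = [f"g{i}" for i in range(200)]
        gwas = pd.Series(np.linspace(0.2, 1.0, 200), index=genes)
        gm = pd.DataFrame({"WT": 5.0, "TG": 5.0}, index=pd.Index(genes))
        from gliatrap.containers import ExpressionTable
        expr = ExpressionTable(fpkm=gm.copy(), group_means=gm)
        sweep = risk_enrichment_sweep(gs("q", genes[:20]), gwas, expr,
                                      cutoffs=[1e-6])
        row = sweep.iloc[0]
        assert row["a"] == 0 and np.isfinite(row["odds_ratio"])

    def test_single_cutoff_matches_fisher(self):
        induced, gwas, expr = self._setup(2.0, 3, n=2000)
        sweep = risk_enrichment_sweep(induced, gwas, expr, cutoffs=[5e-2])
        expressed = expr.max_group_mean()
        uni = set(expressed.index[expressed > 1]) & set(gwas.index)
        risk = gs("risk", {g for g in uni if gwas[g] < 5e-2})
        e = fisher_enrichment(induced.intersect(uni, "u"), risk, uni)
        assert sweep["odds_ratio"].iloc[0] == pytest.approx(e.odds_ratio)
        assert sweep["p"].iloc[0] == pytest.approx(e.p)

    def test_overlap_monotone_along_sweep(self):
        induced, gwas, expr = self._setup(3.0, 5, n=3000)
        sweep = risk_enrichment_sweep(induced, gwas, expr)
        assert (sweep["cutoff"].diff().dropna() > 0).all()
        assert (sweep["a"].diff().dropna() >= 0).all()
        assert (sweep["n_risk"].diff().dropna() >= 0).all()


class TestOverrepresentation:
    def test_toy_hypergeometric_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        term = gs("term", universe[:10])
        query = gs("q", universe[5:15])  # overlap 5
        out = overrepresentation(query, [term], universe, min_genes=5)
        # enumeration: P(X >= 5), X hypergeom(N=100, K=10, n=10)
        def pmf(k):
            return (math.comb(10, k) * math.comb(90, 10 - k)) / math.comb(100, 10)
        expected = sum(pmf(k) for k in range(5, 11))
        assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_min_genes_rule(self):
        universe = [f"g{i}" for i in range(50)]
        term = gs("small", universe[:8])
        query = gs("q", universe[4:8])  # overlap 4 < 5
        out = overrepresentation(query, [term], universe, min_genes=5)
        assert out.empty

    def test_query_equals_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        out = overrepresentation(gs("q", universe), [gs("t", universe[:10])],
                                 universe, min_genes=5)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_excluded_terms_dropped(self):
        universe = [f"g{i}" for i in range(30)]
        terms = [gs("disease pathway X", universe[:10]),
                 gs("metabolic pathway", universe[:10])]
        out = overrepresentation(gs("q", universe[:10]), terms, universe,
                                 min_genes=5, excluded_terms=["disease"])
        assert out["term_id"].tolist() == ["metabolic pathway"]

    def test_truncation_rule(self):
        """Top ten shown, unless fewer reach padj < 0.05."""
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(400)]
        query = gs("q", universe[:40])
        strong = [gs(f"hit{i}", universe[:30]) for i in range(3)]
        weak = [gs(f"bg{i}", list(rng.choice(universe, 60, replace=False)))
                for i in range(12)]
        out = overrepresentation(query, strong + weak, universe, min_genes=3)
        n_sig = int((out["padj"] < 0.05).sum())
        assert out["reported"].sum() == (10 if n_sig >= 10 else n_sig)
        # the reported subset is the best-ranked rows
        assert out["reported"].tolist() == sorted(out["reported"], reverse=True)
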