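"""Synthetic data generators with planted ground truth.

Every input the analysis pipeline consumes can be simulated here: two-group
negative-binomial translatome counts, the four-genotype rescue factorial,
two-stimulus probe-level fold-change tables with planted stimulus-specific
and shared responders, gene-level GWAS p-value tables with planted risk
enrichment, and short reads spanning a two-allele locus.  All generators are
deterministic given their seed; per-generator sub-streams are derived from
the one seed so stages stay independent.

The count model is NB with mean mu and variance mu + alpha * mu**2 (alpha =
``dispersion``), the standard RNA-seq noise model and the same model the
differential-expression stage assumes.  Gene lengths are log-uniform in
[0.5 kb, 10 kb] and per-sample library-size factors log-normal, so FPKM
values span a realistic dynamic range without any external reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigError, CountMatrix

__all__ = [
    "SimConfig",
    "StimulusConfig",
    "simulate_translatome",
    "simulate_rescue_experiment",
    "simulate_stimulus_fc_table",
    "simulate_gwas_table",
    "simulate_locus_reads",
    "random_feasible_stimulus_config",
    "SWEDISH_WT_MOTIF",
    "SWEDISH_MUT_MOTIF",
]

# APP codons around the K/M -> N/L (Swedish) double substitution; the mutant
# differs from wild type at the two codons in the middle of the motif.
SWEDISH_WT_MOTIF = "GAAGTGAAGATGGATGCAGAA"
SWEDISH_MUT_MOTIF = "GAAGTGAATCTGGATGCAGAA"

# sub-stream indices: one per generator so adding a stage never perturbs
# the draws of another
_STREAMS = {"translatome": 0, "rescue": 1, "stimulus": 2, "gwas": 3, "reads": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-group (and four-genotype) count simulators.

    ``n_per_group`` defaults to 4 replicates per genotype, the design used
    throughout for the translatome comparisons.  ``rescue_factor`` is the
    fraction of the planted log2 effect removed in the intervention
    background (1 = complete rescue).  ``target_library_size`` sets the
    expected per-sample sequencing depth.
    """

    n_genes: int = 2000
    n_per_group: int = 4
    frac_induced: float = 0.05
    frac_repressed: float = 0.05
    effect_log2fc: float = 1.0
    dispersion: float = 0.05
    mean_log10_expr_range: tuple[float, float] = (0.5, 3.0)
    rescue_factor: float = 1.0
    target_library_size: float = 1.0e7
    library_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ConfigError("n_genes and n_per_group must be positive")
        for name in ("frac_induced", "frac_repressed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.frac_induced + self.frac_repressed > 1.0:
            raise ConfigError("frac_induced + frac_repressed must be <= 1")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if not 0.0 <= self.rescue_factor <= 1.0:
            raise ConfigError("rescue_factor must be in [0, 1]")
        lo, hi = self.mean_log10_expr_range
        if hi < lo:
            raise ConfigError("mean_log10_expr_range must be (low, high)")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance mu + alpha*mu^2 (size r = 1/alpha)."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _gene_layout(config: SimConfig, rng: np.random.Generator):
    """Gene ids, lengths, baseline means and induced/repressed labels."""
    n = config.n_genes
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene_id")
    lengths = np.round(10 ** rng.uniform(np.log10(500), np.log10(10_000), n)).astype(int)
    lo, hi = config.mean_log10_expr_range
    rel = 10 ** rng.uniform(lo, hi, n)
    base = rel * (config.target_library_size / rel.sum())

    n_ind = int(round(config.frac_induced * n))
    n_rep = int(round(config.frac_repressed * n))
    labels = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_ind]] = "induced"
    labels[order[n_ind:n_ind + n_rep]] = "repressed"
    sign = np.where(labels == "induced", 1.0, np.where(labels == "repressed", -1.0, 0.0))
    return gene_ids, lengths, base, pd.Series(labels, index=gene_ids, name="label"), sign


def _assemble(config: SimConfig, rng: np.random.Generator, gene_ids, lengths,
              base, sign, genotypes: list[str], shift_per_genotype: dict[str, float],
              region: str = "cortex", stage: str = "late") -> CountMatrix:
    cols, meta_rows, data = [], [], []
    for gt in genotypes:
        mult = 2.0 ** (sign * shift_per_genotype[gt])
        for rep in range(config.n_per_group):
            lib = rng.lognormal(mean=0.0, sigma=config.library_sigma)
            mu = base * mult * lib
            data.append(_nb_draw(rng, mu, config.dispersion))
            sid = f"{gt}_{rep + 1}"
            cols.append(sid)
            meta_rows.append({"sample_id": sid, "genotype": gt,
                              "region": region, "stage": stage})
    counts = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(counts=counts,
                       lengths=pd.Series(lengths, index=gene_ids, name="length_bp"),
                       samples=samples)


def simulate_translatome(config: SimConfig) -> tuple[CountMatrix, pd.Series]:
    """Two-group (WT vs TG) NB counts with a planted induced/repressed
    fraction.

    Returns the count matrix and a per-gene truth label in
    {induced, repressed, null}.  Induced genes have expected log2 fold
    change ``+effect_log2fc`` in TG relative to WT; repressed genes the
    negative; null genes zero.
    """
    rng = _rng(config.seed, "translatome")
    gene_ids, lengths, base, labels, sign = _gene_layout(config, rng)
    cm = _assemble(config, rng, gene_ids, lengths, base, sign, ["WT", "TG"],
                   {"WT": 0.0, "TG": config.effect_log2fc})
    return cm, labels


def simulate_rescue_experiment(config: SimConfig) -> tuple[CountMatrix, pd.Series]:
    """Four-genotype factorial (WT, NRF2, TG, TGxNRF2) with a tunable rescue.

    TG vs WT carries the planted signature at full strength; TGxNRF2 vs
    NRF2 carries it attenuated to ``(1 - rescue_factor)`` of the log2
    effect; NRF2 vs WT is null for signature genes, so the baseline
    'denominator' of the fold changes is unchanged by the intervention.
    """
    rng = _rng(config.seed, "rescue")
    gene_ids, lengths, base, labels, sign = _gene_layout(config, rng)
    e = config.effect_log2fc
    shifts = {"WT": 0.0, "NRF2": 0.0, "TG": e, "TGxNRF2": (1.0 - config.rescue_factor) * e}
    cm = _assemble(config, rng, gene_ids, lengths, base, sign,
                   ["WT", "NRF2", "TG", "TGxNRF2"], shifts)
    return cm, labels


# ---------------------------------------------------------------------------
# two-stimulus fold-change tables


@dataclass(frozen=True)
class StimulusConfig:
    """Planted composition of a two-stimulus probe-level fold-change table.

    Defaults mirror the scale of the acute LPS / MCAO derivation (70
    stimulus-specific genes each, 42 shared).  ``max_probes_per_gene``
    controls the probes-per-gene distribution (uniform on 1..max);
    ``n_unannotated`` adds probes with no gene symbol, which the collapse
    step must drop.

    Not every composition admits a table the rank classifier can recover
    exactly: the classification rules leave no room for unclassified genes
    in the top ``top_specific`` ranks of either stimulus, so when null genes
    are present the planted classes must jointly cover those ranks.  The
    generator verifies recoverability by running the classifier before
    emitting a table and raises ``ConfigError`` otherwise.
    """

    n_genes: int = 1000
    n_stim_a: int = 70
    n_stim_b: int = 70
    n_shared: int = 42
    max_probes_per_gene: int = 3
    n_unannotated: int = 10
    probe_jitter: float = 0.1
    top_specific: int = 100
    top_pan: int = 250
    separation: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_stim_a, self.n_stim_b, self.n_shared) < 0:
            raise ConfigError("set sizes must be non-negative")
        if self.n_stim_a + self.n_stim_b + self.n_shared > self.n_genes:
            raise ConfigError("planted set sizes exceed n_genes")
        if self.max_probes_per_gene < 1:
            raise ConfigError("max_probes_per_gene must be >= 1")

    @property
    def n_null(self) -> int:
        return self.n_genes - self.n_stim_a - self.n_stim_b - self.n_shared


def _stimulus_rank_targets(cfg: StimulusConfig) -> pd.DataFrame:
    """Target rank pairs per gene implementing the planted classes.

    Layout (per stimulus, rank 1 = strongest): own-specific genes first,
    then shared genes, then the other stimulus' specific genes (their
    separation equals n_other + n_shared), then null genes.  Null genes are
    reverse-paired between the two stimuli so that any null with both ranks
    inside the pan window is kept more than ``separation`` apart.
    """
    nA, nB, nS, nN = cfg.n_stim_a, cfg.n_stim_b, cfg.n_shared, cfg.n_null
    n = cfg.n_genes
    ids = [f"GsimA{i:03d}" for i in range(nA)] + [f"GsimB{i:03d}" for i in range(nB)] \
        + [f"Gshared{i:03d}" for i in range(nS)] + [f"Gnull{i:04d}" for i in range(nN)]
    truth = ["stimA_specific"] * nA + ["stimB_specific"] * nB + ["shared"] * nS + ["null"] * nN

    rank_a = np.empty(n, dtype=int)
    rank_b = np.empty(n, dtype=int)
    # stimulus A ranks
    rank_a[:nA] = np.arange(1, nA + 1)                              # A-specific
    rank_a[nA + nB:nA + nB + nS] = nA + np.arange(1, nS + 1)        # shared
    rank_a[nA:nA + nB] = nA + nS + np.arange(1, nB + 1)             # B-specific
    # stimulus B ranks (mirror image)
    rank_b[nA:nA + nB] = np.arange(1, nB + 1)
    rank_b[nA + nB:nA + nB + nS] = nB + np.arange(1, nS + 1)
    rank_b[:nA] = nB + nS + np.arange(1, nA + 1)
    # nulls: forward in A, reversed in B
    q = nA + nB + nS
    rank_a[q:] = q + 1 + np.arange(nN)
    rank_b[q:] = n - np.arange(nN)
    return pd.DataFrame({"gene_symbol": ids, "truth": truth,
                         "rank_a": rank_a, "rank_b": rank_b})


def simulate_stimulus_fc_table(cfg: StimulusConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Probe-level fold changes for two stimuli with planted class structure.

    Returns a ProbeFCTable (probe_id, gene_symbol, fc_stimA, fc_stimB) and
    per-gene truth labels in {stimA_specific, stimB_specific, shared, null}.
    The table is verified internally: the collapse -> rank -> classify chain
    must recover the planted labels exactly, else ``ConfigError`` is raised.
    """
    from .reactive import classify_reactive, collapse_probes, rank_genes

    rng = _rng(cfg.seed, "stimulus")
    targets = _stimulus_rank_targets(cfg)
    n = cfg.n_genes

    def value(rank: np.ndarray) -> np.ndarray:
        # strictly decreasing in rank, all > 1
        return 1.0 + (n - rank + 1) * (8.0 / n)

    fc_a = value(targets["rank_a"].to_numpy())
    fc_b = value(targets["rank_b"].to_numpy())

    rows = []
    n_probes = rng.integers(1, cfg.max_probes_per_gene + 1, size=n)
    for g in range(n):
        k = int(n_probes[g])
        if k == 1:
            eps = np.zeros(1)
        else:
            eps = rng.uniform(-cfg.probe_jitter, cfg.probe_jitter, k)
            eps -= eps.mean()  # probe mean is exactly the gene value
        for j in range(k):
            rows.append((f"probe_{g:05d}_{j}", targets["gene_symbol"].iat[g],
                         fc_a[g] * (1 + eps[j]), fc_b[g] * (1 + eps[j])))
    for u in range(cfg.n_unannotated):
        rows.append((f"probe_noname_{u:03d}", "",
                     float(rng.uniform(0.5, 9.0)), float(rng.uniform(0.5, 9.0))))
    table = pd.DataFrame(rows, columns=["probe_id", "gene_symbol", "fc_stimA", "fc_stimB"])
    table = table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)

    truth = pd.Series(targets["truth"].to_numpy(), index=targets["gene_symbol"], name="label")

    # internal verification: the table must be classifier-recoverable
    sets = classify_reactive(rank_genes(collapse_probes(table, top_n=cfg.top_pan)),
                             top_specific=cfg.top_specific, top_pan=cfg.top_pan,
                             separation=cfg.separation)
    recovered = {
        "stimA_specific": sets.stim_a_set.members,
        "stimB_specific": sets.stim_b_set.members,
        "shared": sets.pan_set.members,
    }
    for label, members in recovered.items():
        planted = set(truth.index[truth == label])
        if members != planted:
            raise ConfigError(
                f"planted composition is not classifier-recoverable: class {label!r} "
                f"planted {len(planted)} recovered {len(members)}; adjust set sizes "
                f"(classes must tile the top-{cfg.top_specific} ranks when nulls exist)")
    return table, truth


def random_feasible_stimulus_config(rng: np.random.Generator, seed: int) -> StimulusConfig:
    """Draw a random planted composition satisfying the recoverability
    constraints (used by property tests)."""
    while True:
        nA = int(rng.integers(5, 101))
        nB = int(rng.integers(max(5, nA - 49), min(101, nA + 50)))
        nS_low = max(0, 50 - min(nA, nB), 100 - nA - nB)
        nS = int(rng.integers(nS_low, 151))
        if nA + nS > 250 or nB + nS > 250:
            continue
        q = nA + nB + nS
        n = int(rng.integers(max(q, 500 - q, 300), 1200))
        return StimulusConfig(n_genes=n, n_stim_a=nA, n_stim_b=nB, n_shared=nS,
                              seed=seed)


# ---------------------------------------------------------------------------
# GWAS tables


def simulate_gwas_table(genes, induced_genes, risk_fraction: float,
                        induced_bias: float = 1.0, seed: int = 0
                        ) -> tuple[pd.Series, pd.Series]:
    """Gene-level association p values with planted risk enrichment.

    Each gene is a risk gene with base probability ``risk_fraction``;
    ``induced_bias`` >= 1 multiplies the *odds* of being a risk gene for
    genes in ``induced_genes``.  Risk genes get p values below 0.5 * 0.05/n
    (hence below any Bonferroni cutoff over a universe of at most n genes);
    non-risk genes get uniform p values.  With ``induced_bias`` == 1 the
    table carries no enrichment signal.

    Returns (p-value Series, truth Series in {risk, non_risk}).
    """
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise ConfigError("gene list must be non-empty")
    if not 0.0 <= risk_fraction <= 1.0:
        raise ConfigError("risk_fraction must be in [0, 1]")
    if induced_bias < 1.0:
        raise ConfigError("induced_bias must be >= 1")
    rng = _rng(seed, "gwas")
    induced = genes.isin(set(induced_genes))
    q = risk_fraction
    if q in (0.0, 1.0):
        p_risk_gene = np.full(len(genes), q)
    else:
        odds = q / (1.0 - q) * np.where(induced, induced_bias, 1.0)
        p_risk_gene = odds / (1.0 + odds)
    is_risk = rng.uniform(size=len(genes)) < p_risk_gene
    pvals = rng.uniform(size=len(genes))
    pvals[is_risk] = rng.uniform(0.0, 0.5 * 0.05 / len(genes), size=int(is_risk.sum()))
    truth = pd.Series(np.where(is_risk, "risk", "non_risk"), index=genes, name="label")
    return pd.Series(pvals, index=genes, name="gwas_p"), truth


# ---------------------------------------------------------------------------
# locus reads


def simulate_locus_reads(n_reads: int, mutant_fraction: float,
                         wt_motif: str = SWEDISH_WT_MOTIF,
                         mut_motif: str = SWEDISH_MUT_MOTIF,
                         seed: int = 0, flank: int = 40) -> tuple[list[str], float]:
    """Reads spanning a two-allele locus: each read is one motif embedded in
    i.i.d. random flanking sequence.

    Each read carries the mutant motif with probability ``mutant_fraction``
    (so the mutant count is Binomial(n_reads, mutant_fraction)).  Reads are
    rejection-sampled so each contains exactly one of the two motifs.
    Returns (reads, true mutant fraction).
    """
    if wt_motif == mut_motif:
        raise ConfigError("wild-type and mutant motifs must differ")
    if len(wt_motif) != len(mut_motif):
        raise ConfigError("motifs must have equal length")
    if not 0.0 <= mutant_fraction <= 1.0:
        raise ConfigError("mutant_fraction must be in [0, 1]")
    rng = _rng(seed, "reads")
    bases = np.array(list("ACGT"))
    reads: list[str] = []
    is_mut = rng.uniform(size=n_reads) < mutant_fraction
    for mut in is_mut:
        motif, other = (mut_motif, wt_motif) if mut else (wt_motif, mut_motif)
        while True:
            left = "".join(rng.choice(bases, flank))
            right = "".join(rng.choice(bases, flank))
            read = left + motif + right
            if other not in read and read.count(motif) == 1:
                reads.append(read)
                break
    return reads, float(mutant_fraction)
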