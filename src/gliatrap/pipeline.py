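"""End-to-end orchestration of the three analyses (model characterisation,
core signature, rescue) from a single YAML config.

Stages are skippable: the config lists only the inputs it has, optional
stages whose inputs are absent are skipped with a logged warning, and any
hard error aborts with the stage name and offending input.  Every
intermediate is written as TSV or GMT next to a machine-readable
provenance JSON recording inputs, thresholds, seed and package version.
"""

from __future__ import annotations

import json
import logging
import sys
from importlib import metadata, resources
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, expression, io, reactive, rescue, signatures
from .containers import ConfigError, GliatrapError

__all__ = ["run_pipeline", "load_config", "validate_provenance"]

log = logging.getLogger("gliatrap.pipeline")

_REQUIRED_PROVENANCE_KEYS = {
    "inputs": dict, "thresholds": dict, "seed": (int, type(None)),
    "version": str, "stages_run": list,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: pipeline config must be a mapping")
    for key in ("counts", "metadata", "contrast", "outdir"):
        if key not in cfg:
            raise ConfigError(f"{path}: missing required config key {key!r}")
    for key in ("counts", "metadata"):
        if not Path(cfg[key]).exists():
            raise ConfigError(f"{path}: input file does not exist: {cfg[key]}")
    return cfg


def validate_provenance(record: dict) -> None:
    """Check a provenance record against the shipped schema."""
    schema = json.loads(
        resources.files("gliatrap").joinpath("provenance_schema.json").read_text())
    for key, spec in schema["required"].items():
        if key not in record:
            raise ConfigError(f"provenance record missing key {key!r}")
        expected = {"object": dict, "array": list, "string": str,
                    "integer": (int, type(None))}[spec["type"]]
        if not isinstance(record[key], expected):
            raise ConfigError(f"provenance key {key!r} has wrong type")


def _thresholds(cfg: dict) -> dict:
    th = {"fold": 1.5, "padj": 0.05, "fpkm": 1.0}
    th.update(cfg.get("thresholds", {}))
    if any(v <= 0 for v in th.values()):
        raise ConfigError("thresholds must be positive")
    return th


def run_pipeline(config: dict | str | Path) -> Path:
    """Run the configured stages; returns the output directory.

    Always runs: DE on the primary contrast and up/down gene-set selection.
    Optional stages (each skipped with a warning when its inputs are not
    configured): reactive-set classification (``probe_fc``), GWAS risk
    sweep (``gwas``), second-model DE + core signature (``model_b``),
    cross-species comparison (``human_set`` + ``orthologs``), rescue
    statistics (``rescue``).
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    th = _thresholds(cfg)
    stages_run: list[str] = []

    def stage(name):
        log.info("stage %s", name)
        stages_run.append(name)

    # --- differential expression + selection -----------------------------
    stage("differential_expression")
    try:
        cm = io.read_counts(cfg["counts"], cfg["metadata"])
    except GliatrapError as exc:
        raise ConfigError(f"stage differential_expression: {exc}") from exc
    contrast = tuple(cfg["contrast"])
    expr = expression.compute_fpkm(cm)
    de = expression.differential_expression(cm, contrast)
    de.to_csv(outdir / "de_primary.tsv", sep="\t", index_label="gene_id")

    stage("gene_set_selection")
    sets = {}
    for direction in ("up", "down"):
        gs = expression.select_genes(de, expr, min_fold=th["fold"],
                                     max_padj=th["padj"], min_fpkm=th["fpkm"],
                                     direction=direction,
                                     name=f"primary_{direction}")
        sets[direction] = gs
    io.write_gmt(sets.values(), outdir / "primary_sets.gmt")

    # --- reactive sets ----------------------------------------------------
    if cfg.get("probe_fc"):
        stage("reactive_sets")
        try:
            probe_table = pd.read_csv(cfg["probe_fc"], sep="\t").fillna({"gene_symbol": ""})
            ranked = reactive.rank_genes(reactive.collapse_probes(probe_table))
            rsets = reactive.classify_reactive(ranked)
            io.write_gmt([rsets.stim_a_set, rsets.stim_b_set, rsets.pan_set],
                         outdir / "reactive_sets.gmt")
            rsets.audit.to_csv(outdir / "reactive_audit.tsv", sep="\t", index=False)
        except GliatrapError as exc:
            raise ConfigError(f"stage reactive_sets: {exc}") from exc
    else:
        log.warning("no probe_fc table configured; skipping reactive-set stage")

    # --- GWAS risk sweep --------------------------------------------------
    if cfg.get("gwas"):
        stage("risk_sweep")
        try:
            gwas = pd.read_csv(cfg["gwas"], sep="\t", index_col="gene_id")["gwas_p"]
            sweep = enrichment.risk_enrichment_sweep(sets["up"], gwas, expr,
                                                     cutoffs="auto",
                                                     min_fpkm=th["fpkm"])
            sweep.to_csv(outdir / "risk_sweep.tsv", sep="\t", index=False)
        except GliatrapError as exc:
            raise ConfigError(f"stage risk_sweep: {exc}") from exc
    else:
        log.warning("no GWAS table configured; skipping risk-sweep stage")

    # --- second model: core signature ------------------------------------
    de_b = expr_b = None
    if cfg.get("model_b"):
        stage("core_signature")
        mb = cfg["model_b"]
        try:
            cm_b = io.read_counts(mb["counts"], mb["metadata"])
            expr_b = expression.compute_fpkm(cm_b)
            de_b = expression.differential_expression(cm_b, tuple(mb["contrast"]))
            de_b.to_csv(outdir / "de_model_b.tsv", sep="\t", index_label="gene_id")
            core_rows = []
            core_sets = []
            for direction in ("up", "down"):
                core, enr = signatures.core_overlap(de, de_b, direction,
                                                    max_padj=th["padj"])
                core_sets.append(core)
                core_rows.append({"direction": direction, "n_core": len(core),
                                  "odds_ratio": enr.odds_ratio, "p": enr.p,
                                  "ci_low": enr.ci_low, "ci_high": enr.ci_high})
            io.write_gmt(core_sets, outdir / "core_sets.gmt")
            pd.DataFrame(core_rows).to_csv(outdir / "core_overlap.tsv",
                                           sep="\t", index=False)
        except GliatrapError as exc:
            raise ConfigError(f"stage core_signature: {exc}") from exc
    else:
        log.warning("no second model configured; skipping core-signature stage")

    # --- cross-species ----------------------------------------------------
    if cfg.get("human_set") and cfg.get("orthologs") and de_b is not None:
        stage("cross_species")
        try:
            human = io.read_gmt(cfg["human_set"])[0]
            orth = pd.read_csv(cfg["orthologs"], sep="\t")
            xs = signatures.cross_species_compare(human, orth, de, de_b,
                                                  expr, expr_b)
            xs.table.to_csv(outdir / "cross_species.tsv", sep="\t",
                            index_label="mouse_gene")
        except GliatrapError as exc:
            raise ConfigError(f"stage cross_species: {exc}") from exc
    elif cfg.get("human_set") or cfg.get("orthologs"):
        log.warning("cross-species stage needs human_set, orthologs and "
                    "model_b; skipping")

    # --- rescue -----------------------------------------------------------
    if cfg.get("rescue"):
        stage("rescue")
        rc = cfg["rescue"]
        try:
            cm_r = io.read_counts(rc["counts"], rc["metadata"])
            expr_r = expression.compute_fpkm(cm_r)
            de_r = expression.differential_expression(cm_r, tuple(rc["primary_contrast"]))
            sig = expression.select_genes(de_r, expr_r, min_fold=th["fold"],
                                          max_padj=th["padj"], min_fpkm=th["fpkm"],
                                          direction=rc.get("direction", "up"),
                                          name="rescue_signature")
            summary = rescue.rescue_fold_change_test(
                sig, expr_r, tuple(rc["primary_contrast"]),
                tuple(rc["intervention_contrast"]))
            summary.table.to_csv(outdir / "rescue_pairs.tsv", sep="\t",
                                 index_label="gene_id")
            res = {"t": summary.t, "df": summary.df, "p": summary.p,
                   "attenuation": summary.attenuation,
                   "n_signature": len(summary.table)}
            if rc.get("baseline_contrast"):
                _, mean_b, t_b, p_b = rescue.baseline_shift_check(
                    sig, expr_r, tuple(rc["baseline_contrast"]))
                res.update({"baseline_mean_log2fc": mean_b,
                            "baseline_t": t_b, "baseline_p": p_b})
            with open(outdir / "rescue_summary.json", "w") as fh:
                json.dump(res, fh, indent=2)
        except GliatrapError as exc:
            raise ConfigError(f"stage rescue: {exc}") from exc
    else:
        log.warning("no rescue experiment configured; skipping rescue stage")

    # --- provenance -------------------------------------------------------
    try:
        version = metadata.version("gliatrap")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    record = {
        "inputs": {k: str(cfg[k]) for k in
                   ("counts", "metadata", "probe_fc", "gwas", "human_set",
                    "orthologs") if cfg.get(k)},
        "thresholds": th,
        "seed": cfg.get("seed"),
        "version": version,
        "stages_run": stages_run,
    }
    validate_provenance(record)
    io.write_provenance(outdir / "provenance.json", record)
    return outdir


def _configure_logging() -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
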