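"""End-to-end orchestration: QC → batch → DE → signature → modules → TF networks.

``run_pipeline`` is a pure function of (inputs, config, seed): re-runs write
bit-identical tables (timestamps live only in the run log).  Every stage's
output lands as a TSV under the output directory; a failing stage aborts
with its name so partial outputs are identifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .batch import eb_batch_adjust
from .coexpression import (UNASSIGNED, build_network, detect_modules,
                           eigengenes_kme, module_overlap,
                           signature_module_enrichment, trait_correlation)
from .diffexpr import call_de, moderated_ttest
from .io import AnalysisConfig, ExpressionBundle, write_expression_matrix
from .qc import run_qc
from .signature import concordant_signature, signature_condition_profile
from .tfnet import (build_literature_network, build_sequence_network,
                    intersect_networks)

logger = logging.getLogger("duosig")


@dataclass
class PipelineResult:
    """In-memory handles to every stage's output."""

    qc_reports: dict
    de_tables: dict                       # cohort → called DE table (T2D vs ND)
    signature: object                     # SignatureTable
    condition_profile: pd.DataFrame | None
    condition_counts: pd.Series | None
    module_sets: dict                     # cohort → ModuleSet
    module_overlap: pd.DataFrame | None
    trait_corr: pd.DataFrame | None
    enrichment: object | None             # OverlapTest of signature in modules
    networks: dict = field(default_factory=dict)
    universe: set = field(default_factory=set)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(od: ExpressionBundle, ppp: ExpressionBundle,
                 config: AnalysisConfig | None = None,
                 motif_targets: dict[str, set[str]] | None = None,
                 causal_edges: pd.DataFrame | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full dual-cohort analysis; optionally write all tables.

    TF-network stages run only when their inputs (``motif_targets`` for the
    sequence channel, ``causal_edges`` for the literature channel) are given.
    """
    cfg = config or AnalysisConfig()
    bundles = {"OD": od, "PPP": ppp}

    # --- QC + batch adjustment per cohort ------------------------------
    qc_reports, clean = {}, {}
    for cohort, bundle in bundles.items():
        trimmed, report = _stage(f"qc[{cohort}]")(run_qc)(
            bundle, cfg.expression_quantile, cfg.expression_sample_fraction,
            cfg.fructosamine_max, cfg.glucose_max, cfg.insulin_sd)
        qc_reports[cohort] = report
        adjusted, _ = _stage(f"batch[{cohort}]")(eb_batch_adjust)(trimmed)
        clean[cohort] = adjusted

    universe = set(qc_reports["OD"].retained_genes) | set(qc_reports["PPP"].retained_genes)

    # --- differential expression & signature ---------------------------
    de_tables = {}
    for cohort, bundle in clean.items():
        res = _stage(f"dge[{cohort}]")(moderated_ttest)(bundle, ("T2D", "ND"))
        de_tables[cohort] = call_de(res, cfg.fdr, cfg.fold_change)
    sig = _stage("signature")(concordant_signature)(
        de_tables["OD"], de_tables["PPP"], universe_size=len(universe))
    concordant = set(sig.table.index[sig.table["concordant"]])

    # --- condition profile on the PPP contrasts ------------------------
    profile = counts = None
    ppp_groups = set(clean["PPP"].metadata["group"])
    conds = [g for g in ("T2D", "IGT", "T3cD") if g in ppp_groups]
    if concordant and conds:
        cond_tables = {}
        for g in conds:
            res = _stage(f"profile[{g}]")(moderated_ttest)(clean["PPP"], (g, "ND"))
            cond_tables[g] = res.table
        profile, counts = signature_condition_profile(
            sorted(concordant), cond_tables, cfg.reporting_fold_change)

    # --- co-expression modules on non-diabetic samples -----------------
    module_sets, assignments = {}, {}
    for cohort, bundle in clean.items():
        nd = bundle.subset(samples=bundle.metadata.index[
            bundle.metadata["group"] == "ND"])
        net = _stage(f"network[{cohort}]")(build_network)(nd.values, cfg.soft_power)
        assign = detect_modules(net, cfg.cut_height, cfg.min_module_size)
        assignments[cohort] = assign
        module_sets[cohort] = eigengenes_kme(bundle.values, assign, cfg.hub_top_k)

    overlap = _stage("module_overlap")(module_overlap)(
        assignments["OD"], assignments["PPP"], cfg.overlap_alpha)
    preserved_od = sorted(set(overlap.loc[overlap["preserved"], "module_a"])) \
        if not overlap.empty else []

    trait_cols = [c for c in clean["OD"].metadata.columns
                  if c not in ("cohort", "group", "batch")
                  and pd.api.types.is_numeric_dtype(clean["OD"].metadata[c])]
    traits = pd.concat([clean[c].metadata[trait_cols] for c in clean])
    eig_all = module_sets["OD"].eigengenes
    tc = trait_correlation(eig_all, traits.loc[eig_all.index.intersection(traits.index)]) \
        if not eig_all.empty else None

    enr = None
    if concordant and preserved_od:
        enr = _stage("enrichment")(signature_module_enrichment)(
            concordant, assignments["OD"], preserved_od, len(universe))

    # --- TF networks ----------------------------------------------------
    networks = {}
    assign_od = assignments["OD"]
    module_genes = {m: set(assign_od.index[assign_od == m])
                    for m in preserved_od}
    if motif_targets is not None and module_genes:
        networks["sequence"] = _stage("tfnet[sequence]")(build_sequence_network)(
            module_genes, motif_targets, universe & set(assign_od.index),
            cfg.enrichment_alpha)
    if causal_edges is not None:
        networks["literature"] = _stage("tfnet[literature]")(build_literature_network)(
            causal_edges, de_tables["OD"], assign_od, len(universe),
            cfg.z_threshold, cfg.enrichment_alpha)
    if "sequence" in networks and "literature" in networks:
        networks["intersection"] = intersect_networks(
            networks["literature"], networks["sequence"])

    result = PipelineResult(
        qc_reports=qc_reports, de_tables=de_tables, signature=sig,
        condition_profile=profile, condition_counts=counts,
        module_sets=module_sets, module_overlap=overlap, trait_corr=tc,
        enrichment=enr, networks=networks, universe=universe)
    if outdir is not None:
        write_results(result, clean, cfg, Path(outdir))
    return result


def write_results(result: PipelineResult, clean: dict,
                  cfg: AnalysisConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for cohort, report in result.qc_reports.items():
        report.excluded_samples.to_csv(
            outdir / f"qc_exclusions_{cohort}.tsv", sep="\t", index=False)
        pd.Series(sorted(report.retained_genes)).to_csv(
            outdir / f"retained_genes_{cohort}.txt", index=False, header=False)
    for cohort, bundle in clean.items():
        write_expression_matrix(bundle.values, outdir / f"adjusted_{cohort}.tsv")
    for cohort, table in result.de_tables.items():
        table.to_csv(outdir / f"dge_{cohort}.tsv", sep="\t", float_format="%.6g")
    result.signature.table.to_csv(outdir / "signature.tsv", sep="\t",
                                  float_format="%.6g")
    summary = {k: v for k, v in result.signature.summary.items()}
    with open(outdir / "signature_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    if result.condition_profile is not None:
        result.condition_profile.to_csv(outdir / "condition_profile.tsv",
                                        sep="\t", float_format="%.6g")
    for cohort, ms in result.module_sets.items():
        ms.assignment.to_csv(outdir / f"modules_{cohort}.tsv", sep="\t",
                             header=["module"])
        ms.eigengenes.to_csv(outdir / f"eigengenes_{cohort}.tsv", sep="\t",
                             float_format="%.6g")
        ms.kme.to_csv(outdir / f"kme_{cohort}.tsv", sep="\t", float_format="%.6g")
        pd.DataFrame([(m, g) for m, hub in ms.hubs.items() for g in hub],
                     columns=["module", "gene"]).to_csv(
            outdir / f"hubs_{cohort}.tsv", sep="\t", index=False)
    if result.module_overlap is not None:
        result.module_overlap.to_csv(outdir / "module_overlap.tsv", sep="\t",
                                     index=False, float_format="%.6g")
    if result.trait_corr is not None:
        result.trait_corr.to_csv(outdir / "trait_corr.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    for name, net in result.networks.items():
        net.edges.to_csv(outdir / f"{name}_network.tsv", sep="\t", index=False)
        net.scores.to_csv(outdir / f"{name}_scores.tsv", sep="\t", index=False,
                          float_format="%.6g")
        net.hive_table().to_csv(outdir / f"{name}_hive.tsv", sep="\t", index=False)
    log = {
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16],
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
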