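#!/usr/bin/env python
"""Co-expression modules, cross-cohort preservation and trait correlation.

Builds the weighted network (|cor|^6, topological overlap) on each cohort's
non-diabetic samples, cuts the average-linkage dendrogram statically,
tests module preservation across cohorts by hypergeometric overlap,
correlates module eigengenes with the simulated clinical traits, and tests
enrichment of the concordant signature inside the preserved modules.
Outputs under results/modules/.
"""

from pathlib import Path

import pandas as pd

from duosig.coexpression import (build_network, detect_modules, eigengenes_kme,
                                 module_overlap, signature_module_enrichment,
                                 trait_correlation)
from duosig.io import AnalysisConfig, read_bundle

QC = Path("results/qc")
SIG = Path("results/signature")
OUT = Path("results/modules")


def main() -> None:
    cfg = AnalysisConfig()
    OUT.mkdir(parents=True, exist_ok=True)
    assignments, bundles = {}, {}
    for cohort in ("OD", "PPP"):
        bundle = read_bundle(QC / f"{cohort}_adjusted_expression.tsv",
                             QC / f"{cohort}_adjusted_metadata.tsv")
        bundles[cohort] = bundle
        nd = bundle.subset(samples=bundle.metadata.index[
            bundle.metadata["group"] == "ND"])
        net = build_network(nd.values, cfg.soft_power)
        assign = detect_modules(net, cfg.cut_height, cfg.min_module_size)
        assignments[cohort] = assign
        assign.to_csv(OUT / f"modules_{cohort}.tsv", sep="\t", header=["module"])
        sizes = assign[assign != "unassigned"].value_counts().to_dict()
        print(f"{cohort}: modules {sizes} "
              f"({(assign == 'unassigned').sum()} genes unassigned)")

    overlap = module_overlap(assignments["OD"], assignments["PPP"],
                             cfg.overlap_alpha)
    overlap.to_csv(OUT / "module_overlap.tsv", sep="\t", index=False,
                   float_format="%.6g")
    preserved = sorted(set(overlap.loc[overlap["preserved"], "module_a"]))
    print(f"preserved OD modules (overlap q ≤ {cfg.overlap_alpha}): {preserved}")

    ms = eigengenes_kme(bundles["OD"].values, assignments["OD"], cfg.hub_top_k)
    ms.eigengenes.to_csv(OUT / "eigengenes_OD.tsv", sep="\t", float_format="%.6g")
    ms.kme.to_csv(OUT / "kme_OD.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame([(m, g) for m, hub in ms.hubs.items() for g in hub],
                 columns=["module", "gene"]).to_csv(OUT / "hubs_OD.tsv",
                                                    sep="\t", index=False)

    traits = bundles["OD"].metadata[["insulin_stim_index", "ogtt_2h_glucose"]]
    tc = trait_correlation(ms.eigengenes, traits)
    tc.to_csv(OUT / "trait_corr.tsv", sep="\t", index=False, float_format="%.6g")
    for row in tc.sort_values("p").groupby("trait").head(1).itertuples():
        print(f"trait {row.trait}: strongest module {row.module} "
              f"(r = {row.r:.2f}, p = {row.p:.2g})")

    sig_table = pd.read_csv(SIG / "signature.tsv", sep="\t", index_col=0)
    concordant = set(sig_table.index[sig_table["concordant"]])
    universe = set()
    for c in ("OD", "PPP"):
        universe |= set(pd.read_csv(QC / f"retained_genes_{c}.txt", header=None)[0])
    if preserved and concordant:
        enr = signature_module_enrichment(concordant, assignments["OD"],
                                          preserved, len(universe))
        print(f"signature-in-modules enrichment: k={enr.k} of n={enr.n} "
              f"inside K={enr.K} module genes (N={enr.N}), p = {enr.p:.3g}")


if __name__ == "__main__":
    main()
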