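#!/usr/bin/env python
"""Upstream regulator inference: literature and sequence channels, merged.

Scores every regulator's signed causal edges against the OD DE directions
(activation z-score), tests motif-target enrichment inside the preserved
modules (sequence channel), builds both networks and intersects them.
Compares the recovered regulators with the generator's planted truth.
Outputs under results/tfnet/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from duosig.io import AnalysisConfig, read_edge_list, read_gmt
from duosig.tfnet import (build_literature_network, build_sequence_network,
                          intersect_networks)

DATA = Path("results/data")
QC = Path("results/qc")
DGE = Path("results/dge")
MOD = Path("results/modules")
OUT = Path("results/tfnet")


def main() -> None:
    cfg = AnalysisConfig()
    OUT.mkdir(parents=True, exist_ok=True)

    de_od = pd.read_csv(DGE / "dge_OD_T2D_vs_ND.tsv", sep="\t", index_col=0)
    edges = read_edge_list(DATA / "causal_edges.tsv")
    motif = read_gmt(DATA / "motif_targets.gmt")
    assign = pd.read_csv(MOD / "modules_OD.tsv", sep="\t", index_col=0)["module"]
    overlap = pd.read_csv(MOD / "module_overlap.tsv", sep="\t")
    preserved = sorted(set(overlap.loc[overlap["preserved"], "module_a"]))
    module_genes = {m: set(assign.index[assign == m]) for m in preserved}
    universe = set()
    for c in ("OD", "PPP"):
        universe |= set(pd.read_csv(QC / f"retained_genes_{c}.txt", header=None)[0])

    lit = build_literature_network(edges, de_od, assign, len(universe),
                                   cfg.z_threshold, cfg.enrichment_alpha)
    seq = build_sequence_network(module_genes, motif,
                                 universe & set(assign.index),
                                 cfg.enrichment_alpha)
    inter = intersect_networks(lit, seq)
    for name, net in (("literature", lit), ("sequence", seq),
                      ("intersection", inter)):
        net.edges.to_csv(OUT / f"{name}_network.tsv", sep="\t", index=False)
        net.scores.to_csv(OUT / f"{name}_scores.tsv", sep="\t", index=False,
                          float_format="%.6g")
        net.hive_table().to_csv(OUT / f"{name}_hive.tsv", sep="\t", index=False)
        print(f"{name}: {len(net.tfs())} TFs, {len(net.edges)} edges")

    top = lit.scores.sort_values("z", key=np.abs, ascending=False).head(5)
    print("top regulators by |z|:")
    for row in top.itertuples():
        print(f"  {row.tf}: z = {row.z:+.2f} ({row.state}), "
              f"n = {row.n}, overlap p = {row.overlap_p:.2g}")

    truth = pd.read_csv(DATA / "truth_regulators.tsv", sep="\t")
    planted = set(truth["tf"])
    recovered = inter.tfs()
    print(f"planted active regulators: {sorted(planted)}; "
          f"recovered in intersection: {sorted(recovered)} "
          f"(precision {len(recovered & planted) / max(len(recovered), 1):.2f}, "
          f"recall {len(recovered & planted) / len(planted):.2f})")


if __name__ == "__main__":
    main()
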