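#!/usr/bin/env python
"""Moderated-t differential expression per cohort (T2D vs ND).

Per-gene two-group fits with empirical-Bayes variance moderation; genes are
called at BH-FDR ≤ 0.05 and linear fold change ≥ 1.5.  The PPP cohort's
IGT and T3cD contrasts against the same ND reference are computed for the
condition profile of the next stage.  Tables land under results/dge/.
"""

from pathlib import Path

from duosig.diffexpr import call_de, moderated_ttest
from duosig.io import AnalysisConfig, read_bundle

QC = Path("results/qc")
OUT = Path("results/dge")


def main() -> None:
    cfg = AnalysisConfig()
    OUT.mkdir(parents=True, exist_ok=True)
    for cohort in ("OD", "PPP"):
        bundle = read_bundle(QC / f"{cohort}_adjusted_expression.tsv",
                             QC / f"{cohort}_adjusted_metadata.tsv")
        groups = [g for g in ("T2D", "IGT", "T3cD")
                  if (bundle.metadata["group"] == g).sum() >= 2]
        for group in groups:
            res = moderated_ttest(bundle, (group, "ND"))
            table = call_de(res, cfg.fdr, cfg.fold_change)
            table.to_csv(OUT / f"dge_{cohort}_{group}_vs_ND.tsv", sep="\t",
                         float_format="%.6g")
            n_called = int(table["called"].sum())
            n_down = int((table["called"] & (table["direction"] == "down")).sum())
            print(f"{cohort} {group} vs ND: {n_called} called "
                  f"({n_down} down, {n_called - n_down} up); "
                  f"prior d0 = {res.d0:.2f}, s0² = {res.s02:.4f}")


if __name__ == "__main__":
    main()
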