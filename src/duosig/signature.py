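"""Cross-cohort concordant signature and hypergeometric overlap testing.

Genes called DE in both cohorts form the overlap; those whose linear-scale
ratios deviate from 1 in the same direction in both cohorts are the
concordant signature.  The chance of observing an overlap this large between
the two DE lists is an upper-tail hypergeometric probability against the
expressed-gene universe.  A condition-wise profile tabulates the signature
genes' fold changes across IGT / T3cD / T2D contrasts versus the shared ND
reference.

The published 23-gene worked example (per-cohort ratios and adjusted p of
the dual-cohort islet comparison) ships with the package and is loaded by
:func:`load_published_signature_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OverlapTest:
    """Upper-tail hypergeometric overlap: P(X ≥ k) drawing n from N with K marked."""

    k: int
    K: int
    n: int
    N: int
    p: float


@dataclass
class SignatureTable:
    table: pd.DataFrame     # per overlapping gene: ratios, q's, directions, concordant
    summary: dict           # n_overlap, n_concordant, n_down, n_up, n_discordant


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n), inclusive upper tail.

    k=0 returns exactly 1.  Computed via the survival function of the
    log-space-stable scipy implementation.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 ≤ k ≤ min(K, n), got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"need K, n ≤ N, got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def concordant_signature(de_od: pd.DataFrame, de_ppp: pd.DataFrame,
                         universe_size: int | None = None) -> SignatureTable:
    """Classify the genes called in both cohorts by direction concordance.

    Both inputs are called DE tables (indexed by gene, with ``called``,
    ``ratio`` and ``q`` columns) produced with identical thresholds.  A gene
    is concordant iff sign(ratio_od − 1) == sign(ratio_ppp − 1).  When
    ``universe_size`` is given, the overlap test of the two called lists
    against that background is included in the summary.
    """
    for name, t in (("OD", de_od), ("PPP", de_ppp)):
        if t.index.duplicated().any():
            raise ValueError(f"duplicate gene ids in {name} DE table after collapsing")
    called_od = de_od.index[de_od["called"]]
    called_ppp = de_ppp.index[de_ppp["called"]]
    overlap = called_od.intersection(called_ppp)

    rows = []
    for g in overlap:
        r_od = de_od.at[g, "ratio"]
        r_ppp = de_ppp.at[g, "ratio"]
        rows.append({
            "gene": g,
            "od_ratio": r_od, "ppp_ratio": r_ppp,
            "od_q": de_od.at[g, "q"], "ppp_q": de_ppp.at[g, "q"],
            "direction_od": "down" if r_od < 1 else "up",
            "direction_ppp": "down" if r_ppp < 1 else "up",
            "concordant": np.sign(r_od - 1) == np.sign(r_ppp - 1),
        })
    cols = ["gene", "od_ratio", "ppp_ratio", "od_q", "ppp_q",
            "direction_od", "direction_ppp", "concordant"]
    table = pd.DataFrame(rows, columns=cols).set_index("gene").sort_index()
    table["concordant"] = table["concordant"].astype(bool)

    conc = table[table["concordant"]]
    summary = {
        "n_overlap": len(table),
        "n_concordant": len(conc),
        "n_down": int((conc["direction_od"] == "down").sum()),
        "n_up": int((conc["direction_od"] == "up").sum()),
        "n_discordant": int((~table["concordant"]).sum()),
    }
    if universe_size is not None:
        summary["overlap_test"] = hypergeom_tail(
            len(table), len(called_od), len(called_ppp), universe_size)
    return SignatureTable(table=table, summary=summary)


def signature_condition_profile(signature_genes, de_tables: dict[str, pd.DataFrame],
                                reporting_fold_change: float = 1.2
                                ) -> tuple[pd.DataFrame, pd.Series]:
    """Fold-change matrix of the signature genes across conditions vs ND.

    ``de_tables`` maps condition name → DE table (any table with a ``ratio``
    column vs the shared ND reference).  Genes absent from a condition are
    recorded as missing, never imputed.  Also returns, per condition, the
    count of signature genes with max(r, 1/r) > ``reporting_fold_change``.
    """
    genes = list(signature_genes)
    profile = pd.DataFrame(index=pd.Index(genes, name="gene"),
                           columns=list(de_tables), dtype=float)
    for cond, t in de_tables.items():
        present = [g for g in genes if g in t.index]
        profile.loc[present, cond] = t.loc[present, "ratio"].to_numpy()
    with np.errstate(invalid="ignore"):
        above = np.maximum(profile, 1 / profile) > reporting_fold_change
    counts = above.sum(axis=0).astype(int)
    counts.name = f"n_abs_fc_gt_{reporting_fold_change:g}"
    return profile, counts


def load_published_signature_table() -> pd.DataFrame:
    """Load the packaged 23-gene dual-cohort worked-example table.

    Columns: entrez, symbol, per-cohort probe id, linear-scale ratio
    (T2D vs ND) and BH-adjusted p for the OD and PPP comparisons.
    """
    with resources.files("duosig.data").joinpath(
            "t2d_islet_signature.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def published_table_as_de_tables(table: pd.DataFrame | None = None
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recast the published table as a pair of minimal called DE tables.

    Every row was called in both cohorts at the published thresholds, so
    ``called`` is True throughout; this feeds :func:`concordant_signature`
    for the printed-table worked example.
    """
    if table is None:
        table = load_published_signature_table()
    de_od = pd.DataFrame({
        "gene": table["symbol"], "ratio": table["od_ratio"],
        "q": table["od_adj_p"], "called": True}).set_index("gene")
    de_ppp = pd.DataFrame({
        "gene": table["symbol"], "ratio": table["ppp_ratio"],
        "q": table["ppp_adj_p"], "called": True}).set_index("gene")
    return de_od, de_ppp
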