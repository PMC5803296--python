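"""Upstream-regulator inference from two evidence channels and their merge.

The *sequence* channel asks whether a regulator's motif-predicted target set
(promoter windows, TSS ± 5 kb by convention, consumed as a GMT annotation)
is over-represented in a co-expression module; enriched regulators
contribute edges to their targets inside the module.  The *literature*
channel scores each regulator's signed causal edges against the observed DE
directions with the sign-consistency activation statistic

    z = Σ_targets s_e · d_t / √n,      s_e, d_t ∈ {+1, −1},

where the sum runs over the regulator's DE-called targets; |z| ≥ 2 is the
conventional significance line and a hypergeometric overlap p guards
against trivially small target sets.  The *intersection* network keeps the
(tf, target) edges predicted by both channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import bh_adjust
from .signature import hypergeom_tail

EDGE_COLS = ["tf", "target", "channel", "module"]


@dataclass
class RegulatorScore:
    tf: str
    n: int              # DE-called matched targets
    z: float
    state: str          # activated | inhibited | none
    overlap_p: float


@dataclass
class TFNetwork:
    edges: pd.DataFrame                 # tf, target, channel, module
    scores: pd.DataFrame                # per-TF diagnostics for the channel
    channel: str

    def tfs(self) -> set[str]:
        return set(self.edges["tf"])

    def edge_set(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.edges[["tf", "target"]].itertuples(index=False)))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(channel=self.channel)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.tf, row.target, channel=row.channel, module=row.module)
        return g

    def hive_table(self) -> pd.DataFrame:
        """Long node table for hive-plot layouts: axis, node, degree, module."""
        g = self.to_networkx()
        tfs = self.tfs()
        rows = []
        for node in g:
            axis = "tf" if node in tfs else "target"
            modules = {d.get("module") for _, _, d in g.edges(node, data=True)}
            modules |= {d.get("module") for _, _, d in g.in_edges(node, data=True)}
            modules.discard(None)
            rows.append({"axis": axis, "node": node, "degree": g.degree(node),
                         "module": ";".join(sorted(str(m) for m in modules))})
        return pd.DataFrame(rows, columns=["axis", "node", "degree", "module"])


def ora(query, sets: dict[str, set[str]], universe, alpha: float = 0.05
        ) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set against ``universe``.

    Upper-tail hypergeometric p per set (set membership restricted to the
    universe), BH-adjusted across sets; ``significant`` flags q ≤ alpha.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    rows = []
    for name, members in sets.items():
        m = members & universe
        k = len(query & m)
        p = hypergeom_tail(k, len(m), len(query), len(universe))
        rows.append({"set": name, "k": k, "K": len(m), "n": len(query), "p": p})
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "p"])
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] <= alpha
    return out


def causal_activation_scores(edges: pd.DataFrame, de_table: pd.DataFrame,
                             universe_size: int, z_threshold: float = 2.0,
                             called_only: bool = True) -> pd.DataFrame:
    """Activation z-scores of signed causal regulons against DE directions.

    ``edges`` carries (tf, target, sign); ``de_table`` is a called DE table
    with ``called`` and ``direction`` columns.  By default only DE-called
    targets contribute (directions of non-significant genes are noise);
    ``called_only=False`` uses every measured target.  Regulators with no
    matched target are omitted.  ``overlap_p`` is the hypergeometric tail of
    the regulon's overlap with the called set against ``universe_size``.
    """
    if called_only:
        obs = de_table[de_table["called"]]
    else:
        obs = de_table
    directions = obs["direction"].map({"up": 1, "down": -1})
    n_called = int(de_table["called"].sum())
    rows = []
    for tf, sub in edges.groupby("tf", sort=True):
        measured = sub[sub["target"].isin(de_table.index)]
        matched = sub[sub["target"].isin(directions.index)]
        n = len(matched)
        if n == 0:
            continue
        z = float((matched["sign"].to_numpy()
                   * directions.loc[matched["target"]].to_numpy()).sum() / np.sqrt(n))
        state = "none"
        if z >= z_threshold:
            state = "activated"
        elif z <= -z_threshold:
            state = "inhibited"
        k = len(set(matched["target"]))
        K = len(set(measured["target"]))
        overlap_p = hypergeom_tail(min(k, n_called), K, n_called, universe_size)
        rows.append({"tf": tf, "n": n, "z": z, "state": state,
                     "overlap_p": overlap_p})
    return pd.DataFrame(rows, columns=["tf", "n", "z", "state", "overlap_p"])


def build_sequence_network(module_genes: dict[str, set[str]],
                           motif_targets: dict[str, set[str]],
                           universe, alpha: float = 0.05) -> TFNetwork:
    """Motif-target enrichment per module → TF→target edges (sequence channel).

    For each module, each regulator's motif-target set is tested for
    over-representation among the module genes; regulators with q ≤ alpha
    contribute edges to their targets inside that module.
    """
    universe = set(universe)
    edge_rows, score_rows = [], []
    for module, genes in module_genes.items():
        outside = set(genes) - universe
        if outside:
            raise ValueError(f"module {module!r} genes outside universe: "
                             f"{sorted(outside)[:5]}")
        res = ora(genes, motif_targets, universe, alpha)
        res.insert(0, "module", module)
        score_rows.append(res)
        for row in res[res.get("significant", pd.Series(dtype=bool))].itertuples():
            for target in sorted(motif_targets[row.set] & set(genes)):
                edge_rows.append({"tf": row.set, "target": target,
                                  "channel": "sequence", "module": module})
    edges = pd.DataFrame(edge_rows, columns=EDGE_COLS).drop_duplicates(["tf", "target"])
    scores = (pd.concat(score_rows, ignore_index=True)
              if score_rows else pd.DataFrame())
    return TFNetwork(edges=edges.reset_index(drop=True), scores=scores,
                     channel="sequence")


def build_literature_network(edges: pd.DataFrame, de_table: pd.DataFrame,
                             module_assignment: pd.Series | None,
                             universe_size: int, z_threshold: float = 2.0,
                             alpha: float = 0.05) -> TFNetwork:
    """Signed-causal channel: activated/inhibited regulators and their DE targets.

    Regulators need |z| ≥ ``z_threshold`` AND overlap_p ≤ ``alpha`` to enter;
    their DE-called matched targets become edges, labelled with the target's
    module when an assignment is given.
    """
    scores = causal_activation_scores(edges, de_table, universe_size, z_threshold)
    passing = set(scores.loc[(scores["z"].abs() >= z_threshold)
                             & (scores["overlap_p"] <= alpha), "tf"])
    called = set(de_table.index[de_table["called"]])
    rows = []
    for row in edges.itertuples(index=False):
        if row.tf in passing and row.target in called:
            module = None
            if module_assignment is not None and row.target in module_assignment.index:
                m = module_assignment[row.target]
                module = None if m == "unassigned" else m
            rows.append({"tf": row.tf, "target": row.target,
                         "channel": "literature", "module": module})
    out = pd.DataFrame(rows, columns=EDGE_COLS).drop_duplicates(["tf", "target"])
    return TFNetwork(edges=out.reset_index(drop=True), scores=scores,
                     channel="literature")


def intersect_networks(a: TFNetwork, b: TFNetwork) -> TFNetwork:
    """Exact (tf, target) intersection of two networks.

    Retained TFs are those with at least one surviving edge; per-TF scores
    from both parents are carried (suffixed by parent channel); module
    labels come from the first network where present, else the second.
    """
    common = a.edge_set() & b.edge_set()
    module_a = {(r.tf, r.target): r.module for r in a.edges.itertuples(index=False)}
    module_b = {(r.tf, r.target): r.module for r in b.edges.itertuples(index=False)}
    rows = [{"tf": tf, "target": tg, "channel": "intersection",
             "module": module_a.get((tf, tg)) or module_b.get((tf, tg))}
            for tf, tg in sorted(common)]
    edges = pd.DataFrame(rows, columns=EDGE_COLS)
    scores = _merge_scores(a, b, {r["tf"] for r in rows})
    return TFNetwork(edges=edges, scores=scores, channel="intersection")


def _merge_scores(a: TFNetwork, b: TFNetwork, tfs: set[str]) -> pd.DataFrame:
    def per_tf(net: TFNetwork) -> pd.DataFrame:
        s = net.scores
        if s.empty:
            return pd.DataFrame({"tf": sorted(tfs)})
        key = "tf" if "tf" in s.columns else "set"
        sub = s[s[key].isin(tfs)].rename(columns={key: "tf"})
        return sub.add_suffix(f"_{net.channel}").rename(
            columns={f"tf_{net.channel}": "tf"})
    left, right = per_tf(a), per_tf(b)
    if left.empty and right.empty:
        return pd.DataFrame({"tf": sorted(tfs)})
    return left.merge(right, on="tf", how="outer")
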