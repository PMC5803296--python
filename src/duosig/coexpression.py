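"""Weighted co-expression networks, modules, eigengenes and trait correlation.

Network construction follows standard weighted-network practice: unsigned
adjacency a_ij = |cor(x_i, x_j)|^β, topological overlap

    ω_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),   ω_ii = 1,

average-linkage hierarchical clustering of the dissimilarity 1 − ω with a
static cut, and modules summarised by their eigengene (first principal
component of the standardized module expression, sign-oriented so the mean
module membership kME is non-negative).  Modules are meant to be derived
from non-diabetic samples; cross-cohort module preservation and
signature-in-module enrichment are hypergeometric overlap tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust
from .signature import OverlapTest, hypergeom_tail

UNASSIGNED = "unassigned"


@dataclass
class CoexpressionNetwork:
    beta: float
    adjacency: pd.DataFrame       # genes × genes, |cor|^β, zero diagonal
    tom: pd.DataFrame             # topological overlap, unit diagonal
    connectivity: pd.Series       # k_i = Σ_{j≠i} a_ij


@dataclass
class ModuleSet:
    assignment: pd.Series         # gene → module label (UNASSIGNED allowed)
    eigengenes: pd.DataFrame      # samples × modules, unit variance scores
    kme: pd.DataFrame             # genes × modules, cor(x_g, eigengene)
    hubs: dict[str, list[str]]    # module → top-k genes by |kME|


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """TOM of a symmetric adjacency with zero diagonal (unit diagonal output)."""
    k = adj.sum(axis=1)
    tom = (adj @ adj + adj) / (np.minimum.outer(k, k) + 1.0 - adj)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2, 0.0, 1.0)


def build_network(values: pd.DataFrame, beta: float = 6.0) -> CoexpressionNetwork:
    """Unsigned weighted network from a genes × samples matrix.

    ``values`` should contain the samples the network is defined on (for the
    dual-cohort analysis: the non-diabetic samples of one cohort).
    Zero-variance genes cannot be correlated and raise.
    """
    if values.shape[1] < 4:
        raise ValueError("need at least 4 samples to estimate correlations")
    if beta < 1:
        raise ValueError("soft power beta must be ≥ 1")
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = list(values.index[sd == 0])
        raise ValueError(f"zero-variance genes must be removed first: {bad[:5]}")
    corr = np.corrcoef(values.to_numpy())
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    adj = np.clip((adj + adj.T) / 2, 0.0, 1.0)  # enforce symmetry at fp precision
    k = adj.sum(axis=1)
    tom = topological_overlap(adj)
    idx = values.index
    return CoexpressionNetwork(
        beta=beta,
        adjacency=pd.DataFrame(adj, index=idx, columns=idx),
        tom=pd.DataFrame(tom, index=idx, columns=idx),
        connectivity=pd.Series(k, index=idx, name="connectivity"),
    )


def pick_soft_power(values: pd.DataFrame, candidates=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12),
                    r2_target: float = 0.8, n_bins: int = 10) -> float:
    """Smallest β whose connectivity distribution fits a scale-free law.

    Fits log10 p(k) against log10 k over binned connectivities and returns
    the first candidate with model R² ≥ ``r2_target`` (falling back to the
    best-fitting candidate if none reaches it).
    """
    corr = np.abs(np.corrcoef(values.to_numpy()))
    np.fill_diagonal(corr, 0.0)
    best_beta, best_r2 = candidates[0], -np.inf
    for beta in candidates:
        k = (corr ** beta).sum(axis=1)
        k = k[k > 0]
        hist, edges = np.histogram(k, bins=n_bins)
        centers = (edges[:-1] + edges[1:]) / 2
        ok = (hist > 0) & (centers > 0)
        if ok.sum() < 3:
            continue
        r = np.corrcoef(np.log10(centers[ok]), np.log10(hist[ok]))[0, 1]
        r2 = r ** 2
        if r2 >= r2_target:
            return float(beta)
        if r2 > best_r2:
            best_beta, best_r2 = beta, r2
    return float(best_beta)


def detect_modules(network: CoexpressionNetwork, cut_height: float = 0.9,
                   min_size: int = 20) -> pd.Series:
    """Average-linkage clustering of 1 − TOM with a static cut.

    Clusters smaller than ``min_size`` become UNASSIGNED.  Labels are
    'M1', 'M2', … ordered by decreasing module size (ties broken by the
    first member's position), so the partition is deterministic and
    invariant to gene order up to renaming.
    """
    if not 0 < cut_height < 1:
        raise ValueError("cut_height must lie in (0, 1)")
    if min_size < 2:
        raise ValueError("min_size must be ≥ 2")
    genes = network.tom.index
    if len(genes) < min_size:
        return pd.Series(UNASSIGNED, index=genes, name="module")
    diss = 1.0 - network.tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_size]
    order = sorted(keep.index,
                   key=lambda c: (-keep[c], int(np.argmax(labels.to_numpy() == c))))
    mapping = {c: f"M{i + 1}" for i, c in enumerate(order)}
    return labels.map(lambda c: mapping.get(c, UNASSIGNED)).rename("module")


def eigengenes_kme(values: pd.DataFrame, assignment: pd.Series,
                   top_k: int = 10) -> ModuleSet:
    """Module eigengenes, all-gene kME and per-module hub lists.

    The eigengene is the first right singular vector of the standardized
    module expression, scaled to unit variance and sign-oriented so the mean
    kME of the module's own genes is ≥ 0.  kME is computed for every gene
    against every module eigengene; hubs are each module's own top-k genes
    by |kME|.  A singleton module's eigengene is its standardized gene.
    """
    assignment = assignment.reindex(values.index).fillna(UNASSIGNED)
    modules = sorted(set(assignment) - {UNASSIGNED})
    n_samples = values.shape[1]
    eig = {}
    for m in modules:
        sub = values.loc[assignment[assignment == m].index].to_numpy()
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        e = e / e.std(ddof=1)
        if np.corrcoef(z, e)[:-1, -1].mean() < 0:
            e = -e
        eig[m] = e
    eigengenes = pd.DataFrame(eig, index=values.columns)

    if modules:
        x = values.to_numpy()
        xz = x - x.mean(axis=1, keepdims=True)
        xsd = x.std(axis=1, ddof=1)
        e = eigengenes.to_numpy()
        ez = e - e.mean(axis=0)
        esd = np.std(e, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            kme = (xz @ ez) / ((n_samples - 1) * np.outer(xsd, esd))
        kme = pd.DataFrame(np.clip(kme, -1, 1), index=values.index, columns=modules)
    else:
        kme = pd.DataFrame(index=values.index)

    hubs = {}
    for m in modules:
        own = assignment[assignment == m].index
        ranked = kme.loc[own, m].abs().sort_values(ascending=False)
        hubs[m] = list(ranked.index[:top_k])
    return ModuleSet(assignment=assignment, eigengenes=eigengenes,
                     kme=kme, hubs=hubs)


def module_overlap(assign_a: pd.Series, assign_b: pd.Series,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric overlap of every module pair across two partitions.

    The background N is the shared gene universe of the two assignments.
    BH adjustment runs across all pairs; pairs with q ≤ alpha are flagged
    ``preserved``.
    """
    shared = assign_a.index.intersection(assign_b.index)
    if len(shared) == 0:
        raise ValueError("assignments share no genes")
    a = assign_a.loc[shared]
    b = assign_b.loc[shared]
    n_univ = len(shared)
    rows = []
    for ma in sorted(set(a) - {UNASSIGNED}):
        in_a = set(a.index[a == ma])
        for mb in sorted(set(b) - {UNASSIGNED}):
            in_b = set(b.index[b == mb])
            k = len(in_a & in_b)
            p = hypergeom_tail(k, len(in_a), len(in_b), n_univ)
            rows.append({"module_a": ma, "module_b": mb, "k": k,
                         "size_a": len(in_a), "size_b": len(in_b), "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["preserved"] = out["q"] <= alpha
    return out


def trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame
                      ) -> pd.DataFrame:
    """Pearson correlation of module eigengenes with per-sample traits.

    Missing trait values are pairwise-dropped; p comes from the exact
    t = r·√((n−2)/(1−r²)) reference on n−2 df, with |r| = 1 reported as
    p = 0 and flagged.  Constant traits are reported as missing with reason.
    """
    rows = []
    for m in eigengenes.columns:
        for tr in traits.columns:
            paired = pd.concat([eigengenes[m], traits[tr]], axis=1, join="inner").dropna()
            n = len(paired)
            row = {"module": m, "trait": tr, "n": n, "r": np.nan, "p": np.nan,
                   "flag": ""}
            if n < 4:
                row["flag"] = "too_few_observations"
            elif paired.iloc[:, 1].nunique() == 1 or paired.iloc[:, 0].nunique() == 1:
                row["flag"] = "constant_input"
            else:
                r = float(np.corrcoef(paired.iloc[:, 0], paired.iloc[:, 1])[0, 1])
                row["r"] = r
                if abs(r) >= 1.0 - 1e-12:
                    row["p"] = 0.0
                    row["flag"] = "perfect_correlation"
                else:
                    t = r * np.sqrt((n - 2) / (1 - r ** 2))
                    row["p"] = float(2 * stats.t.sf(abs(t), n - 2))
            rows.append(row)
    return pd.DataFrame(rows)


def signature_module_enrichment(signature_genes, assignment: pd.Series,
                                selected_modules, universe_size: int
                                ) -> OverlapTest:
    """Hypergeometric enrichment of the signature inside selected modules.

    K = genes assigned to the selected modules, n = signature size,
    k = signature genes inside those modules, N = ``universe_size``.
    """
    selected_modules = list(selected_modules)
    if not selected_modules:
        raise ValueError("no modules selected")
    in_mod = set(assignment.index[assignment.isin(selected_modules)])
    sig = set(signature_genes)
    k = len(sig & in_mod)
    p = hypergeom_tail(k, len(in_mod), len(sig), universe_size)
    return OverlapTest(k=k, K=len(in_mod), n=len(sig), N=universe_size, p=p)
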