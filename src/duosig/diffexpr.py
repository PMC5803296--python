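"""Two-group differential expression with empirical-Bayes moderated t-statistics.

Per gene, an ordinary two-group fit on log2 values gives the effect
(log2 mean difference), residual variance s² and df d = n1 + n2 − 2.  The
variances are shrunk towards a global prior via the scaled inverse-χ² model:
the prior df d0 and prior variance s0² are estimated by matching the moments
of log s² through digamma/trigamma closed forms (d0 by Newton inversion of
the trigamma function), and the posterior variance is

    s̃² = (d0·s0² + d·s²) / (d0 + d).

The moderated t = effect / (s̃·√(1/n1 + 1/n2)) is referred to a t
distribution on d0 + d df (standard normal when d0 = ∞).  Multiplicity is
controlled by Benjamini–Hochberg; genes are called when q ≤ fdr and the
linear-scale ratio 2^effect satisfies max(r, 1/r) ≥ the fold-change cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionBundle


@dataclass
class ModeratedResult:
    """Per-gene moderated statistics for one two-group contrast."""

    table: pd.DataFrame        # gene, effect, ratio, s2, df, s2_post, t, df_total, p, q
    d0: float                  # prior df (may be inf)
    s02: float                 # prior variance
    contrast: tuple[str, str]  # (test group, reference group)
    n: tuple[int, int]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration (tol 1e-8)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0²) of the scaled inverse-χ² prior from log s².

    Uses e = log s² − digamma(d/2) + log(d/2), for which E[e] = log s0² −
    digamma(d0/2) + log(d0/2) and Var[e] = trigamma(d/2) + trigamma(d0/2).
    A non-positive excess variance drives d0 → ∞ (all genes share s0²).
    Zero variances are excluded from the fit.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need ≥2 positive variances to fit the prior")
    e = np.log(s2[ok]) - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, df / 2)
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2 * trigamma_inverse(excess)
    s02 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s02)


def group_stats(bundle: ExpressionBundle, contrast: tuple[str, str],
                group_col: str = "group") -> pd.DataFrame:
    """Per-gene two-group OLS statistics (effect = mean test − mean reference)."""
    test, ref = contrast
    groups = bundle.metadata[group_col]
    a = bundle.values.loc[:, (groups == test).to_numpy()]
    b = bundle.values.loc[:, (groups == ref).to_numpy()]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need ≥2 samples per group, got {test}={n1}, {ref}={n2}")
    effect = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a.sub(a.mean(axis=1), axis=0) ** 2).sum(axis=1)
          + (b.sub(b.mean(axis=1), axis=0) ** 2).sum(axis=1))
    df = n1 + n2 - 2
    return pd.DataFrame({"effect": effect, "s2": ss / df,
                         "df": df, "n1": n1, "n2": n2})


def moderated_ttest(bundle: ExpressionBundle, contrast: tuple[str, str],
                    group_col: str = "group", d0_override: float | None = None,
                    ) -> ModeratedResult:
    """Empirical-Bayes moderated t-test of ``contrast`` on log2 values.

    ``d0_override`` forces the prior df (0 recovers the classical pooled t);
    by default (d0, s0²) are estimated from the data.  Zero-variance genes
    with an unshrunk posterior get t = ±inf, p = 0 and ``flag`` set.
    """
    gs = group_stats(bundle, contrast, group_col)
    n1, n2 = int(gs["n1"].iloc[0]), int(gs["n2"].iloc[0])
    df = float(gs["df"].iloc[0])
    s2 = gs["s2"].to_numpy()

    if d0_override is not None:
        d0 = float(d0_override)
        s02 = fit_variance_prior(s2, df)[1] if d0 > 0 else np.nan
    else:
        d0, s02 = fit_variance_prior(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    effect = gs["effect"].to_numpy()
    flag = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(flag, np.sign(effect) * np.inf, effect / np.where(flag, 1, se))
        t[flag & (effect == 0)] = 0.0
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    q = bh_adjust(p)

    table = pd.DataFrame({
        "gene": bundle.genes,
        "effect": effect,
        "ratio": np.exp2(effect),
        "s2": s2,
        "df": df,
        "s2_post": s2_post,
        "t": t,
        "df_total": df_total,
        "p": p,
        "q": q,
        "flag_zero_variance": flag,
    }).set_index("gene")
    return ModeratedResult(table=table, d0=d0, s02=float(s02),
                           contrast=contrast, n=(n1, n2))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(result: ModeratedResult, fdr: float = 0.05,
            fold_change: float = 1.5) -> pd.DataFrame:
    """Call DE at q ≤ fdr and max(ratio, 1/ratio) ≥ fold_change; sort by q.

    Adds ``called`` and ``direction`` (up/down by the sign of effect) columns.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    if fold_change <= 1:
        raise ValueError("fold_change must be > 1")
    t = result.table.copy()
    abs_fc = np.maximum(t["ratio"], 1 / t["ratio"])
    t["called"] = (t["q"] <= fdr) & (abs_fc >= fold_change)
    t["direction"] = np.where(t["ratio"] < 1, "down", "up")
    return t.sort_values("q")


def collapse_probes(de_table: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probe-level rows to gene level, keeping the smallest-q probe.

    ``probe_to_gene`` maps the table's index (probes) to gene symbols.  The
    returned table is indexed by gene and records the representative probe.
    """
    t = de_table.copy()
    t["probe"] = t.index
    t["gene_symbol"] = probe_to_gene.reindex(t.index)
    t = t.dropna(subset=["gene_symbol"])
    best = t.sort_values("q").groupby("gene_symbol", sort=True).head(1)
    return best.set_index("gene_symbol").sort_values("q")
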