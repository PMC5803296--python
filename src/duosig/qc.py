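"""Sample exclusion rules, expression filtering and PCA diagnostics.

QC runs in two stages, exclusions first: (1) samples are dropped for
metabolic evidence of undiagnosed dysglycaemia (fructosamine > 285 μmol/l or
glucose > 11.1 mmol/l in samples without a diabetes history) or for low
insulin secretion (below the within-(cohort, group) mean minus one SD);
(2) genes are kept only if expressed — intensity strictly above the pooled
per-cohort 75th-percentile intensity τ in at least 25% of the samples of at
least one diagnostic group.  Both readings of the ambiguous ">75%" criterion
hang off the τ hook: pass a different ``tau`` to change the interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import ExpressionBundle

logger = logging.getLogger("duosig")

#: diagnostic groups treated as having no previous history of diabetes
NO_DIABETES_HISTORY = ("ND", "IGT")


@dataclass
class QCReport:
    retained_genes: set[str]
    excluded_samples: pd.DataFrame      # columns: sample, reason
    tau: float


def filter_expressed(bundle: ExpressionBundle, quantile: float = 0.75,
                     sample_fraction: float = 0.25, group_col: str = "group",
                     tau: float | None = None) -> set[str]:
    """Return the genes expressed in at least one diagnostic group.

    A gene is retained iff, in some group, strictly more than
    ``sample_fraction`` − ε of that group's samples exceed τ, the pooled
    ``quantile`` of all intensities in the cohort (strict '>', so a constant
    matrix retains nothing).
    """
    if not 0 < quantile < 1 or not 0 < sample_fraction <= 1:
        raise ValueError("quantile and sample_fraction must lie in (0, 1]")
    groups = bundle.metadata[group_col]
    if groups.isna().any() or len(groups) == 0:
        raise ValueError("empty or missing group labels")
    if tau is None:
        tau = float(np.quantile(bundle.values.to_numpy(), quantile))
    retained: set[str] = set()
    for group, members in groups.groupby(groups).groups.items():
        sub = bundle.values[list(members)]
        frac = (sub.to_numpy() > tau).mean(axis=1)
        retained |= set(bundle.genes[frac >= sample_fraction])
    return retained


def exclude_samples(metadata: pd.DataFrame, fructosamine_max: float = 285.0,
                    glucose_max: float = 11.1, insulin_sd: float = 1.0,
                    ) -> pd.DataFrame:
    """Flag samples violating the metabolic / secretion exclusion rules.

    Returns a table (sample, reason) with reason ∈ {fructosamine, glucose,
    insulin}; a sample may appear once per violated rule.  Samples missing the
    field a rule needs are skipped for that rule with a logged warning.
    """
    rows: list[tuple[str, str]] = []
    if metadata.empty:
        return pd.DataFrame(columns=["sample", "reason"])

    history_free = metadata["group"].isin(NO_DIABETES_HISTORY)
    for col, cutoff, reason in (("fructosamine", fructosamine_max, "fructosamine"),
                                ("glucose", glucose_max, "glucose")):
        if col not in metadata:
            logger.warning("metadata lacks %r; %s rule skipped", col, reason)
            continue
        vals = metadata[col]
        n_missing = int((vals.isna() & history_free).sum())
        if n_missing:
            logger.warning("%d samples missing %r; skipped for that rule",
                           n_missing, col)
        bad = history_free & vals.notna() & (vals > cutoff)
        rows += [(s, reason) for s in metadata.index[bad]]

    if "insulin" not in metadata:
        logger.warning("metadata lacks 'insulin'; insulin rule skipped")
    else:
        strata = metadata.groupby(["cohort", "group"], sort=False, observed=True)
        for _, stratum in strata:
            ins = stratum["insulin"].dropna()
            n_missing = len(stratum) - len(ins)
            if n_missing:
                logger.warning("%d samples missing insulin in stratum %s; skipped",
                               n_missing, _)
            if len(ins) < 2:
                continue
            cutoff = ins.mean() - insulin_sd * ins.std(ddof=1)
            rows += [(s, "insulin") for s in ins.index[ins < cutoff]]

    out = pd.DataFrame(rows, columns=["sample", "reason"]).drop_duplicates()
    return out.sort_values(["sample", "reason"]).reset_index(drop=True)


def run_qc(bundle: ExpressionBundle, quantile: float = 0.75,
           sample_fraction: float = 0.25, fructosamine_max: float = 285.0,
           glucose_max: float = 11.1, insulin_sd: float = 1.0,
           ) -> tuple[ExpressionBundle, QCReport]:
    """Sample exclusions first, then the expression filter on the survivors."""
    excl = exclude_samples(bundle.metadata, fructosamine_max, glucose_max, insulin_sd)
    keep = [s for s in bundle.samples if s not in set(excl["sample"])]
    trimmed = bundle.subset(samples=keep)
    tau = float(np.quantile(trimmed.values.to_numpy(), quantile))
    genes = filter_expressed(trimmed, quantile, sample_fraction, tau=tau)
    report = QCReport(retained_genes=genes, excluded_samples=excl, tau=tau)
    return trimmed.subset(genes=genes), report


def contamination_check(bundle: ExpressionBundle, marker_sets: dict[str, set[str]],
                        compare_by: str = "cohort"
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score exocrine/ductal marker expression per sample and compare groups.

    The score for a marker set is the mean log2 expression of its members in
    that sample.  Returns (per-sample scores, per-set comparison) where the
    comparison reports group mean ± SD and, when ``compare_by`` has exactly
    two levels, a two-sided Welch t-test between them.
    """
    universe = set(bundle.genes)
    scores = {}
    for name, markers in marker_sets.items():
        present = sorted(markers & universe)
        if not present:
            raise ValueError(f"marker set {name!r} is disjoint from the genes")
        scores[name] = bundle.values.loc[present].mean(axis=0)
    scores_df = pd.DataFrame(scores)

    labels = bundle.metadata[compare_by]
    rows = []
    levels = list(pd.unique(labels))
    for name in scores_df:
        row: dict = {"marker_set": name}
        for lv in levels:
            vals = scores_df.loc[labels == lv, name]
            row[f"mean_{lv}"] = vals.mean()
            row[f"sd_{lv}"] = vals.std(ddof=1)
        if len(levels) == 2:
            a = scores_df.loc[labels == levels[0], name]
            b = scores_df.loc[labels == levels[1], name]
            t, p = stats.ttest_ind(a, b, equal_var=False)
            row["difference"] = a.mean() - b.mean()
            row["t"] = t
            row["p"] = p
        rows.append(row)
    return scores_df, pd.DataFrame(rows)


def pca_embed(values: pd.DataFrame, n_components: int | None = None
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on centred (unscaled) log2 values.

    Genes are variables, samples observations; genes are centred, matching
    the usual prcomp(center=TRUE, scale.=FALSE) convention.  Returns the
    sample coordinates and the per-component variance fractions (which sum to
    1 over all computed components).
    """
    if values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = values.to_numpy().T  # samples × genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=values.columns, columns=cols),
            pca.explained_variance_ratio_)
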