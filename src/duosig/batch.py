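"""Parametric empirical-Bayes location–scale batch adjustment.

Per-gene batch means and variances are estimated on data standardized
against a batch-free model (grand mean plus protected covariates such as
the diagnostic group), then shrunk across genes towards batch-level priors —
normal for the location, inverse-gamma for the scale — via the usual
iterative fixed point.  The adjusted matrix restores the protected model
after removing the shrunken batch location and rescaling by the shrunken
batch scale.  With a single batch the adjustment is exactly the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionBundle


@dataclass
class BatchModel:
    batches: list[str]
    gamma_hat: pd.DataFrame        # genes × batches, raw standardized locations
    delta2_hat: pd.DataFrame       # genes × batches, raw standardized scales
    gamma_star: pd.DataFrame       # shrunken locations
    delta2_star: pd.DataFrame      # shrunken scales
    gamma_bar: pd.Series           # per-batch location prior mean
    tau2: pd.Series                # per-batch location prior variance
    a_prior: pd.Series             # per-batch inverse-gamma shape
    b_prior: pd.Series             # per-batch inverse-gamma rate
    n_iter: dict[str, int]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "batch": self.batches,
            "gamma_bar": self.gamma_bar.values,
            "tau2": self.tau2.values,
            "a_prior": self.a_prior.values,
            "b_prior": self.b_prior.values,
            "iterations": [self.n_iter[b] for b in self.batches],
        })


def _dummy(series: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(series))
    mat = np.column_stack([(series == lv).to_numpy(float) for lv in levels])
    return mat, levels


def eb_batch_adjust(bundle: ExpressionBundle, batch_col: str = "batch",
                    covariate_cols: tuple[str, ...] = ("group",),
                    tol: float = 1e-4, max_iter: int = 100,
                    ) -> tuple[ExpressionBundle, BatchModel | None]:
    """Remove batch location/scale effects while protecting covariates.

    ``covariate_cols`` (categorical, e.g. the diagnostic group) enter the
    design so disease signal is not absorbed into batch estimates.  Aborts if
    any batch has fewer than 2 samples or a covariate is confounded with
    batch (rank-deficient combined design).
    """
    y = bundle.values.to_numpy(float)
    n_genes, n_samples = y.shape
    batch = bundle.metadata[batch_col]
    b_design, batches = _dummy(batch)
    n_per_batch = b_design.sum(axis=0)
    if len(batches) == 1:
        return bundle.subset(), None
    if (n_per_batch < 2).any():
        small = [b for b, n in zip(batches, n_per_batch) if n < 2]
        raise ValueError(f"batches of size 1 cannot be adjusted: {small}")

    cov_parts = []
    for col in covariate_cols:
        mat, levels = _dummy(bundle.metadata[col])
        cov_parts.append(mat[:, 1:])  # drop reference level; batch spans intercept
    x_cov = np.hstack(cov_parts) if cov_parts else np.empty((n_samples, 0))
    design = np.hstack([b_design, x_cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "covariates are confounded with batch (rank-deficient design); "
            "batch effects cannot be separated from the protected covariates")

    # per-gene OLS of the full design; grand mean = batch-size-weighted batch means
    b_hat, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    n_batch = len(batches)
    grand = (n_per_batch / n_samples) @ b_hat[:n_batch]          # per gene
    stand_mean = grand[:, None] + (x_cov @ b_hat[n_batch:]).T    # genes × samples
    resid = y - (design @ b_hat).T
    var_pooled = (resid ** 2).mean(axis=1)
    if (var_pooled <= 0).any():
        raise ValueError("zero pooled variance; constant genes must be removed first")
    z = (y - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.empty((n_genes, n_batch))
    delta2_hat = np.empty((n_genes, n_batch))
    for i, b in enumerate(batches):
        cols = b_design[:, i] == 1
        gamma_hat[:, i] = z[:, cols].mean(axis=1)
        delta2_hat[:, i] = z[:, cols].var(axis=1, ddof=1)

    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    m = delta2_hat.mean(axis=0)
    s2 = delta2_hat.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = np.where(s2 > 0, (2 * s2 + m ** 2) / s2, np.inf)
        b_prior = np.where(s2 > 0, (m * s2 + m ** 3) / s2, np.inf)

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    n_iter: dict[str, int] = {}
    z_adj = z.copy()
    for i, b in enumerate(batches):
        cols = b_design[:, i] == 1
        n_i = cols.sum()
        g_old = gamma_hat[:, i].copy()
        d_old = delta2_hat[:, i].copy()
        if not np.isfinite(a_prior[i]):
            # degenerate scale prior (identical per-gene scales): no shrinkage
            g_new = ((n_i * tau2[i] * gamma_hat[:, i] + d_old * gamma_bar[i])
                     / (n_i * tau2[i] + d_old))
            d_new, it = d_old, 0
        else:
            it = 0
            for it in range(1, max_iter + 1):
                g_new = ((n_i * tau2[i] * gamma_hat[:, i] + d_old * gamma_bar[i])
                         / (n_i * tau2[i] + d_old))
                ssr = ((z[:, cols] - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (b_prior[i] + 0.5 * ssr) / (n_i / 2 + a_prior[i] - 1)
                change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
                g_old, d_old = g_new, d_new
                if change < tol:
                    break
        gamma_star[:, i] = g_new
        delta2_star[:, i] = d_new
        n_iter[b] = it
        z_adj[:, cols] = (z[:, cols] - g_new[:, None]) / np.sqrt(d_new)[:, None]

    adjusted = z_adj * np.sqrt(var_pooled)[:, None] + stand_mean
    out = ExpressionBundle(
        pd.DataFrame(adjusted, index=bundle.genes, columns=bundle.samples),
        bundle.metadata.copy(),
    )
    gidx = bundle.genes
    model = BatchModel(
        batches=batches,
        gamma_hat=pd.DataFrame(gamma_hat, index=gidx, columns=batches),
        delta2_hat=pd.DataFrame(delta2_hat, index=gidx, columns=batches),
        gamma_star=pd.DataFrame(gamma_star, index=gidx, columns=batches),
        delta2_star=pd.DataFrame(delta2_star, index=gidx, columns=batches),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau2=pd.Series(tau2, index=batches),
        a_prior=pd.Series(a_prior, index=batches),
        b_prior=pd.Series(b_prior, index=batches),
        n_iter=n_iter,
    )
    return out, model
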