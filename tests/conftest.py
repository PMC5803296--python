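"""Shared fixtures: tiny constructed bundles and the default synthetic runs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from duosig.io import ExpressionBundle
from duosig.pipeline import run_pipeline
from duosig.simulate import SimConfig, generate_bundle, generate_networks

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_bundle(values: np.ndarray, groups, cohort="OD", batch=None,
                gene_prefix="g", **extra_cols) -> ExpressionBundle:
    """Wrap a raw matrix + group labels into a validated bundle."""
    n_genes, n_samples = values.shape
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(index=pd.Index(samples, name="sample"))
    meta["cohort"] = cohort
    meta["group"] = list(groups)
    meta["batch"] = list(batch) if batch is not None else "b1"
    for k, v in extra_cols.items():
        meta[k] = v
    vals = pd.DataFrame(values, index=[f"{gene_prefix}{i}" for i in range(n_genes)],
                        columns=samples)
    return ExpressionBundle(vals, meta)


@pytest.fixture(scope="session")
def default_runs():
    """Full pipeline on the default synthetic config for seeds 1–5.

    Returns a list of (truth, PipelineResult); shared across recovery tests
    to keep the suite fast.
    """
    runs = []
    for seed in range(1, 6):
        cfg = SimConfig()
        od, ppp, truth = generate_bundle(cfg, seed)
        motif, edges = generate_networks(cfg, seed)
        runs.append((truth, run_pipeline(od, ppp, None, motif, edges)))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
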