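"""Readers, writers and core containers for the dual-cohort islet pipeline.

Expression matrices travel as log2 intensities in a genes × samples table;
sample-level clinical annotation (cohort, diagnostic group, batch, fructosamine,
glucose, insulin secretion, optional functional traits) rides alongside in an
:class:`ExpressionBundle`.  Gene sets are exchanged in GMT, signed regulator →
target edges as three-column TSV.  All readers validate rather than coerce:
duplicate identifiers, non-numeric cells and malformed sign tokens raise.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("duosig")

COHORTS = ("OD", "PPP")
GROUPS = ("ND", "T2D", "IGT", "T3cD")

#: accepted spellings of edge signs, normalised to +1 / −1
_SIGN_TOKENS = {
    "+1": 1, "1": 1, "+": 1, "activation": 1, "activates": 1,
    "-1": -1, "-": -1, "repression": -1, "represses": -1,
}


@dataclass
class ExpressionBundle:
    """Log2 expression matrix plus aligned per-sample metadata for one cohort.

    Parameters
    ----------
    values
        genes × samples DataFrame of finite log2 intensities; the index is the
        gene universe, columns are sample ids.
    metadata
        per-sample DataFrame indexed by sample id, aligned to ``values``
        columns.  Expected columns: ``cohort``, ``group``, ``batch``, plus any
        of ``fructosamine`` (μmol/l), ``glucose`` (mmol/l), ``insulin``
        (secretion measure) and named numeric traits.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        if list(self.values.columns) != list(self.metadata.index):
            raise ValueError("sample ids of matrix and metadata are not aligned")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset(self, genes=None, samples=None) -> "ExpressionBundle":
        """Return a bundle restricted to the given genes and/or samples."""
        values = self.values
        meta = self.metadata
        if genes is not None:
            genes = [g for g in values.index if g in set(genes)]
            values = values.loc[genes]
        if samples is not None:
            samples = [s for s in values.columns if s in set(samples)]
            values = values[samples]
            meta = meta.loc[samples]
        return ExpressionBundle(values.copy(), meta.copy())


@dataclass
class AnalysisConfig:
    """Pipeline thresholds; defaults are the study's published cut-offs."""

    fdr: float = 0.05                      # BH-adjusted p cut-off for DE
    fold_change: float = 1.5               # linear-scale |FC| cut-off for DE
    tf_fold_change: float = 1.2            # relaxed FC cut-off for TF-focused DE
    expression_quantile: float = 0.75      # pooled intensity percentile τ
    expression_sample_fraction: float = 0.25
    fructosamine_max: float = 285.0        # μmol/l, no-diabetes-history samples
    glucose_max: float = 11.1              # mmol/l, no-diabetes-history samples
    insulin_sd: float = 1.0                # exclude insulin < mean − k·SD
    soft_power: float = 6.0                # co-expression adjacency exponent β
    cut_height: float = 0.9                # static cut on 1 − TOM dendrogram
    min_module_size: int = 20
    overlap_alpha: float = 0.05            # module preservation / ORA q cut-off
    hub_top_k: int = 10
    z_threshold: float = 2.0               # |activation z| significance line
    enrichment_alpha: float = 0.05
    reporting_fold_change: float = 1.2     # condition-profile reporting line
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr", "expression_quantile", "expression_sample_fraction",
                     "overlap_alpha", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("fold_change", "tf_fold_change", "reporting_fold_change"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        for name in ("fructosamine_max", "glucose_max", "insulin_sd",
                     "soft_power", "cut_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a YAML (or JSON — YAML superset) mapping of field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# expression matrices and metadata
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from exc
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.12g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in metadata {path}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample", float_format="%.12g")


def read_bundle(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionBundle:
    values = read_expression_matrix(matrix_path)
    meta = read_metadata(metadata_path)
    missing = set(values.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
    return ExpressionBundle(values, meta.loc[values.columns])


def write_bundle(bundle: ExpressionBundle, outdir: str | Path, prefix: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(bundle.values, outdir / f"{prefix}_expression.tsv")
    write_metadata(bundle.metadata, outdir / f"{prefix}_metadata.tsv")


# ---------------------------------------------------------------------------
# gene sets (GMT) and signed edge lists
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set name: member set}``.

    Lines carry name, description, then members, tab-separated.  Duplicate
    members collapse (set semantics); empty sets are dropped with a warning.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name, members = parts[0], {m for m in parts[2:] if m}
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                logger.warning("GMT set %r is empty; dropped", name)
                continue
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(sets[name])]) + "\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read signed regulator → target edges (tf, target, sign) from TSV.

    Sign tokens ``+1``/``-1`` or ``activation``/``repression`` are accepted.
    Duplicate (tf, target) pairs with conflicting signs raise; consistent
    duplicates collapse to one edge.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 3:
        raise ValueError(f"{path}: edge list must have exactly 3 columns")
    df.columns = ["tf", "target", "sign"]
    # tolerate an optional header row
    if str(df.iloc[0]["sign"]).lower() not in _SIGN_TOKENS:
        if str(df.iloc[0]["sign"]).lower() == "sign":
            df = df.iloc[1:].reset_index(drop=True)
    try:
        df["sign"] = [_SIGN_TOKENS[str(s).strip().lower()] for s in df["sign"]]
    except KeyError as exc:
        raise ValueError(f"{path}: invalid sign token {exc.args[0]!r}") from None
    df = df.drop_duplicates()
    conflicts = df[df.duplicated(["tf", "target"], keep=False)]
    if not conflicts.empty:
        pairs = conflicts[["tf", "target"]].drop_duplicates().values.tolist()
        raise ValueError(f"conflicting signs for edges: {pairs[:5]}")
    return df.reset_index(drop=True)


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges[["tf", "target", "sign"]].to_csv(path, sep="\t", header=False, index=False)
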