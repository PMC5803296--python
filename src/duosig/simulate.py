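"""Two-cohort synthetic islet expression generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes, at the
published cohort sizes (OD: 84 ND / 19 T2D; PPP: 32 ND / 36 T2D / 15 IGT /
20 T3cD):

* a per-gene Gaussian baseline on the log2 intensity scale, with planted
  signal genes placed in the expressed regime so they survive the expression
  filter the way real signature genes (expressed islet genes) do;
* latent-factor co-expression blocks — factors are standard normal per sample,
  loadings constant within a module, so the module eigengene approximates the
  factor;
* planted differential expression: concordant, OD-only and PPP-only genes
  with log2 effects drawn uniformly from a configurable range; IGT and T3cD
  samples receive attenuated effects (0.25 / 0.6 of the T2D effect,
  concordant genes only), mirroring the muted fold-change profile of those
  conditions;
* a dominant batch axis per cohort (per gene × batch Gaussian shifts);
* clinical traits driven linearly by a module's factor;
* TF regulons: active regulators' targets live inside one co-expression
  module and receive coherent concordant effects (direction = regulator state
  × edge sign); the regulons are observed through a noisy motif channel
  (false positives / negatives) and a noisy signed literature channel
  (sign flips);
* injected QC violations (high fructosamine/glucose in samples without a
  diabetes history, low insulin secretors) flagged in the truth table so QC
  recall is testable.  Insulin secretion is simulated for the OD cohort only;
  PPP samples carry a missing value, as for LCM material.

The model per gene *g*, sample *j* is::

    x_gj = mu_g + sum_m L_gm f_mj + delta_g * e(group_j) + gamma_g,batch(j) + eps_gj

with f, eps Gaussian and e() the per-group effect multiplier.  Identical
(config, seed) pairs give bit-identical output; independent sub-streams per
cohort / network are derived by spawning, so adding a cohort leaves the
other unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionBundle

DEFAULT_GROUP_SIZES = {
    "OD": {"ND": 84, "T2D": 19},
    "PPP": {"ND": 32, "T2D": 36, "IGT": 15, "T3cD": 20},
}

#: effect multiplier per diagnostic group (concordant genes; T2D effect = 1)
ATTENUATION = {"ND": 0.0, "T2D": 1.0, "IGT": 0.25, "T3cD": 0.6}


@dataclass(frozen=True)
class ModuleSpec:
    size: int
    loading: float


@dataclass(frozen=True)
class SignatureSpec:
    n_concordant: int = 30
    n_od_only: int = 40
    n_ppp_only: int = 30
    log2fc_range: tuple[float, float] = (math.log2(1.5), math.log2(3.0))


@dataclass(frozen=True)
class TraitSpec:
    name: str
    module: int          # index into SimConfig.modules
    slope: float
    noise_sd: float


@dataclass(frozen=True)
class TFSpec:
    n_regulators: int = 20
    regulon_size: int = 25
    motif_fp_rate: float = 0.1
    motif_fn_rate: float = 0.1
    literature_sign_error_rate: float = 0.05
    n_active: int = 3


@dataclass
class SimConfig:
    """Generator settings; defaults are the package's standard study conditions."""

    n_genes: int = 2000
    group_sizes: dict = field(default_factory=lambda: {
        c: dict(g) for c, g in DEFAULT_GROUP_SIZES.items()})
    n_batches_per_cohort: int = 2
    batch_shift_sd: float = 0.3            # log2 units
    baseline_mean: float = 7.0             # log2 units
    baseline_sd: float = 1.5
    signal_baseline_range: tuple[float, float] = (10.5, 12.0)
    noise_sd: float = 0.15
    modules: tuple[ModuleSpec, ...] = tuple(ModuleSpec(100, 0.3) for _ in range(4))
    signature: SignatureSpec = field(default_factory=SignatureSpec)
    traits: tuple[TraitSpec, ...] = (
        TraitSpec("insulin_stim_index", 0, 1.0, 0.5),
        TraitSpec("ogtt_2h_glucose", 1, -1.0, 0.5),
    )
    tf: TFSpec = field(default_factory=TFSpec)
    qc_violation_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for cohort, groups in self.group_sizes.items():
            for group, n in groups.items():
                if n <= 0:
                    raise ValueError(f"group size {cohort}/{group} must be positive")
        if self.n_batches_per_cohort < 1:
            raise ValueError("need at least one batch per cohort")
        mod_total = sum(m.size for m in self.modules)
        if mod_total > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        sig = self.signature
        for n in (sig.n_concordant, sig.n_od_only, sig.n_ppp_only):
            if n < 0:
                raise ValueError("signature counts must be ≥ 0")
        if sig.n_concordant + sig.n_od_only + sig.n_ppp_only > self.n_genes - mod_total:
            raise ValueError("planted signature does not fit outside the modules")
        if sig.n_concordant > 0 and sig.log2fc_range[0] <= 0:
            raise ValueError("log2fc_range lower bound must be > 0")
        for rate in (self.tf.motif_fp_rate, self.tf.motif_fn_rate,
                     self.tf.literature_sign_error_rate, self.qc_violation_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.tf.regulon_size > self.n_genes:
            raise ValueError("regulon_size exceeds n_genes")
        if self.tf.n_active > self.tf.n_regulators:
            raise ValueError("n_active exceeds n_regulators")
        if self.tf.n_active > 0 and not self.modules:
            raise ValueError("active regulators require at least one module")
        for t in self.traits:
            if not 0 <= t.module < max(len(self.modules), 1):
                raise ValueError(f"trait {t.name!r} references missing module")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset.

    signature_genes maps gene → (direction ∈ {up, down}, scope ∈ {concordant,
    od_only, ppp_only}); regulator-driven concordant genes are included.
    """

    signature_genes: dict[str, tuple[str, str]]
    module_assignment: dict[str, str]
    active_regulators: dict[str, str]          # tf → {activated, inhibited}
    regulons: dict[str, dict[str, int]]        # tf → {target: sign}
    trait_map: dict[str, str]                  # trait name → module label
    qc_flags: list[tuple[str, str]]            # (sample id, reason)

    def concordant_genes(self) -> set[str]:
        return {g for g, (_, scope) in self.signature_genes.items()
                if scope == "concordant"}


# ---------------------------------------------------------------------------
# deterministic layout shared by generate_bundle and generate_networks
# ---------------------------------------------------------------------------

def _streams(config: SimConfig, seed: int | None):
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    names = ("layout", "OD", "PPP", "networks", "qc")
    return dict(zip(names, (np.random.default_rng(s) for s in root.spawn(len(names)))))


def _layout(config: SimConfig, rng: np.random.Generator):
    """Draw gene placement, effects, regulons and signs (one shared stream)."""
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    order = rng.permutation(config.n_genes)

    pos = 0
    module_idx: list[np.ndarray] = []
    assignment: dict[str, str] = {}
    for m, spec in enumerate(config.modules):
        idx = order[pos:pos + spec.size]
        pos += spec.size
        module_idx.append(idx)
        for i in idx:
            assignment[genes[i]] = f"M{m + 1}"

    sig = config.signature
    free = order[pos:]
    conc = free[:sig.n_concordant]
    od_only = free[sig.n_concordant:sig.n_concordant + sig.n_od_only]
    ppp_only = free[sig.n_concordant + sig.n_od_only:
                    sig.n_concordant + sig.n_od_only + sig.n_ppp_only]

    lo, hi = sig.log2fc_range
    delta_conc = np.zeros(config.n_genes)       # same effect in both cohorts
    delta_od = np.zeros(config.n_genes)         # OD-specific
    delta_ppp = np.zeros(config.n_genes)        # PPP-specific
    signature: dict[str, tuple[str, str]] = {}

    def plant(idx, scope, vec):
        for i in idx:
            direction = rng.choice([-1, 1])
            vec[i] = direction * rng.uniform(lo, hi)
            signature[genes[i]] = ("up" if direction > 0 else "down", scope)

    plant(conc, "concordant", delta_conc)
    plant(od_only, "od_only", delta_od)
    plant(ppp_only, "ppp_only", delta_ppp)

    # regulons: active regulators sit on a module; their targets get coherent
    # concordant effects.  Inactive regulators draw targets uniformly.
    tf = config.tf
    regulators = [f"TF{r + 1:02d}" for r in range(tf.n_regulators)]
    active = {}
    regulons: dict[str, dict[str, int]] = {}
    used_per_module: dict[int, set[int]] = {m: set() for m in range(len(config.modules))}
    for r, name in enumerate(regulators):
        if r < tf.n_active:
            m = r % len(config.modules)
            pool = np.array([i for i in module_idx[m] if i not in used_per_module[m]])
            if len(pool) < tf.regulon_size:
                raise ValueError("module too small for disjoint active regulons")
            targets = rng.choice(pool, tf.regulon_size, replace=False)
            used_per_module[m].update(targets.tolist())
            state = 1 if r % 2 == 0 else -1
            active[name] = "activated" if state > 0 else "inhibited"
            signs = rng.choice([-1, 1], tf.regulon_size)
            for i, s in zip(targets, signs):
                d = state * s
                delta_conc[i] = d * rng.uniform(lo, hi)
                signature[genes[i]] = ("up" if d > 0 else "down", "concordant")
            regulons[name] = {genes[i]: int(s) for i, s in zip(targets, signs)}
        else:
            targets = rng.choice(config.n_genes, tf.regulon_size, replace=False)
            signs = rng.choice([-1, 1], tf.regulon_size)
            regulons[name] = {genes[i]: int(s) for i, s in zip(targets, signs)}

    # baselines: background Gaussian; planted signal genes in the expressed regime
    mu = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    signal = sorted({i for i in np.concatenate([conc, od_only, ppp_only])}
                    | {i for idx in module_idx for i in idx})
    if signal:
        mu[signal] = rng.uniform(*config.signal_baseline_range, len(signal))

    loadings = np.zeros((config.n_genes, len(config.modules)))
    for m, spec in enumerate(config.modules):
        loadings[module_idx[m], m] = spec.loading

    return {
        "genes": genes, "mu": mu, "loadings": loadings,
        "delta_conc": delta_conc, "delta_od": delta_od, "delta_ppp": delta_ppp,
        "signature": signature, "assignment": assignment,
        "active": active, "regulons": regulons,
    }


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _clinical(group: str, cohort: str, rng: np.random.Generator):
    """Fructosamine / glucose / insulin draws per diagnostic group."""
    fru = rng.normal(222, 40) if group in ("T2D", "T3cD") else rng.normal(180, 30)
    glu = rng.normal(9.0, 1.5) if group in ("T2D", "T3cD") else rng.normal(5.5, 0.9)
    if cohort == "OD":
        ins = rng.normal(1.2, 0.3) if group == "T2D" else rng.normal(2.0, 0.4)
    else:
        ins = np.nan  # not measured on LCM material
    return fru, glu, ins


def _simulate_cohort(cohort: str, config: SimConfig, lay: dict,
                     rng: np.random.Generator, rng_qc: np.random.Generator,
                     qc_flags: list[tuple[str, str]]) -> ExpressionBundle:
    groups = config.group_sizes[cohort]
    sample_ids, sample_group = [], []
    for group, n in groups.items():
        for i in range(n):
            sample_ids.append(f"{cohort}_{group}_{i + 1:03d}")
            sample_group.append(group)
    n_samples = len(sample_ids)
    sample_group = np.array(sample_group)

    # balanced batch assignment, then shuffled
    batches = np.tile(np.arange(config.n_batches_per_cohort),
                      n_samples // config.n_batches_per_cohort + 1)[:n_samples]
    batches = batches[rng.permutation(n_samples)]
    batch_labels = np.array([f"{cohort}_b{b + 1}" for b in batches])

    n_mod = len(config.modules)
    factors = rng.standard_normal((n_mod, n_samples)) if n_mod else np.zeros((0, n_samples))
    gamma = rng.normal(0.0, config.batch_shift_sd,
                       (config.n_genes, config.n_batches_per_cohort))
    eps = rng.normal(0.0, config.noise_sd, (config.n_genes, n_samples))

    # concordant effects scale with the condition (IGT/T3cD attenuated);
    # cohort-specific effects apply to the T2D contrast only
    atten = np.array([ATTENUATION[g] for g in sample_group])
    is_t2d = (sample_group == "T2D").astype(float)
    specific = lay["delta_od"] if cohort == "OD" else lay["delta_ppp"]

    x = (lay["mu"][:, None]
         + lay["loadings"] @ factors
         + np.outer(lay["delta_conc"], atten)
         + np.outer(specific, is_t2d)
         + gamma[:, batches]
         + eps)

    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample"))
    meta["cohort"] = cohort
    meta["group"] = sample_group
    meta["batch"] = batch_labels
    clinical = np.array([_clinical(g, cohort, rng) for g in sample_group])
    meta["fructosamine"] = clinical[:, 0]
    meta["glucose"] = clinical[:, 1]
    meta["insulin"] = clinical[:, 2]
    for t in config.traits:
        meta[t.name] = (t.slope * factors[t.module]
                        + rng.normal(0.0, t.noise_sd, n_samples))

    # inject QC violations, flagged in truth
    frac = config.qc_violation_fraction
    if frac > 0:
        nd_like = np.flatnonzero(np.isin(sample_group, ["ND", "IGT"]))
        n_bad = int(round(frac * len(nd_like)))
        for i in rng_qc.choice(nd_like, n_bad, replace=False):
            if rng_qc.random() < 0.5:
                meta.iloc[i, meta.columns.get_loc("fructosamine")] = rng_qc.uniform(290, 340)
                qc_flags.append((sample_ids[i], "fructosamine"))
            else:
                meta.iloc[i, meta.columns.get_loc("glucose")] = rng_qc.uniform(11.5, 15.0)
                qc_flags.append((sample_ids[i], "glucose"))
        if cohort == "OD":
            ok = np.flatnonzero(~np.isnan(clinical[:, 2]))
            n_low = int(round(frac * len(ok)))
            for i in rng_qc.choice(ok, n_low, replace=False):
                base = 1.2 if sample_group[i] == "T2D" else 2.0
                sd = 0.3 if sample_group[i] == "T2D" else 0.4
                meta.iloc[i, meta.columns.get_loc("insulin")] = base - 3.5 * sd
                qc_flags.append((sample_ids[i], "insulin"))

    values = pd.DataFrame(x, index=pd.Index(lay["genes"], name="gene"),
                          columns=sample_ids)
    return ExpressionBundle(values, meta)


def generate_bundle(config: SimConfig, seed: int | None = None
                    ) -> tuple[ExpressionBundle, ExpressionBundle, SyntheticTruth]:
    """Generate the OD and PPP cohort bundles plus ground truth."""
    config.validate()
    streams = _streams(config, seed)
    lay = _layout(config, streams["layout"])
    qc_flags: list[tuple[str, str]] = []
    od = _simulate_cohort("OD", config, lay, streams["OD"], streams["qc"], qc_flags)
    ppp = _simulate_cohort("PPP", config, lay, streams["PPP"], streams["qc"], qc_flags)
    truth = SyntheticTruth(
        signature_genes=lay["signature"],
        module_assignment=lay["assignment"],
        active_regulators=lay["active"],
        regulons=lay["regulons"],
        trait_map={t.name: f"M{t.module + 1}" for t in config.traits},
        qc_flags=qc_flags,
    )
    return od, ppp, truth


def generate_networks(config: SimConfig, seed: int | None = None
                      ) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Observe the true regulons through the motif and literature channels.

    Motif channel: each true target is dropped with probability
    ``motif_fn_rate``; ``Binomial(regulon_size, motif_fp_rate)`` spurious
    genes are drawn uniformly from the non-targets (spurious count scales
    with regulon size, not universe size).  Literature channel: every edge is
    kept with its sign flipped with probability ``literature_sign_error_rate``.

    Shares the layout seed stream with :func:`generate_bundle`, so the same
    (config, seed) pair describes the same underlying regulons.
    """
    config.validate()
    streams = _streams(config, seed)
    lay = _layout(config, streams["layout"])
    rng = streams["networks"]
    genes = lay["genes"]

    motif: dict[str, set[str]] = {}
    rows = []
    for tf_name, regulon in lay["regulons"].items():
        targets = list(regulon)
        keep = [t for t in targets if rng.random() >= config.tf.motif_fn_rate]
        non_targets = np.setdiff1d(genes, targets, assume_unique=False)
        n_fp = rng.binomial(len(targets), config.tf.motif_fp_rate)
        n_fp = min(n_fp, len(non_targets))
        fp = rng.choice(non_targets, n_fp, replace=False) if n_fp else []
        motif[tf_name] = set(keep) | set(fp)
        for t in targets:
            s = regulon[t]
            if rng.random() < config.tf.literature_sign_error_rate:
                s = -s
            rows.append((tf_name, t, s))

    edges = pd.DataFrame(rows, columns=["tf", "target", "sign"])
    return motif, edges


def write_truth(truth: SyntheticTruth, outdir) -> None:
    """Write the truth tables as TSV (signature, modules, regulators, QC flags)."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(g, d, s) for g, (d, s) in sorted(truth.signature_genes.items())],
        columns=["gene", "direction", "scope"],
    ).to_csv(outdir / "truth_signature.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.module_assignment.items()),
                 columns=["gene", "module"]
                 ).to_csv(outdir / "truth_modules.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.active_regulators.items()),
                 columns=["tf", "state"]
                 ).to_csv(outdir / "truth_regulators.tsv", sep="\t", index=False)
    pd.DataFrame(truth.qc_flags, columns=["sample", "reason"]
                 ).to_csv(outdir / "truth_qc_flags.tsv", sep="\t", index=False)
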