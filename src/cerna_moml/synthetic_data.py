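"""Synthetic multi-omics cohorts with planted ceRNA architecture.

The generator emulates the input bundle of a tumour/normal expression
cohort: negative-binomial RNA and miRNA counts with group effects for the
differential-expression stage, tumour-sample regulator matrices (gene-level
copy number and DNA-methylation beta values), candidate interaction wiring
(miRNA->mRNA, miRNA->lncRNA, TF->gene), expression-linked survival times,
and a ground-truth record of everything that was planted.

Continuous tumour expression is generated directly on the log (voom-like)
scale by the structural model

    mRNA_g   = b_cna * CNA_g + b_dm * DM_g + sum_m b_mir * miRNA_m
               + b_tf * TF_t + eps,          eps ~ N(0, noise_sd)
    lncRNA_l = sum_m b_mir * miRNA_m + eps

where planted ceRNA partners load on the same shared miRNAs with negative
coefficients (the sponge mechanism: both partners are repressed by the
common miRNA pool, hence positively correlated, and the correlation drops
once the pool is conditioned away).  Counts for the DE stage are drawn
independently of the continuous layer — mirroring a pipeline that calls DE
on raw counts but fits regulator models on normalized expression.

Decoy regulators (candidate edges with true coefficient zero) are wired in
for every gene to provide realistic false-positive pressure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    CountsMatrix,
    GeneValueMatrix,
    InteractionTable,
    RegulatorBundle,
    make_pair_key,
    write_matrix,
    write_interactions,
)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Effect sizes are on the log-expression scale; ``beta_mirna`` must be
    negative (miRNAs repress their targets).  ``nb_mean_log2fc`` is the
    planted tumour/normal log2 fold change of DE features in the count
    layer and ``nb_dispersion`` the negative-binomial dispersion (1/size).
    ``surv_log_hr`` is the log hazard ratio of high vs low expression of
    the prognostic gene; censoring is independent with probability
    ``censor_rate``.
    """

    seed: int = 0
    n_tumour: int = 100
    n_normal: int = 50
    n_mrna: int = 50
    n_lncrna: int = 10
    n_mirna: int = 30
    n_tf: int = 10
    n_cerna_pairs: int = 10
    mirnas_per_pair: int = 3
    beta_cna: float = 0.5
    beta_dm: float = -0.5
    beta_tf: float = 0.5
    beta_mirna: float = -0.5
    noise_sd: float = 0.2
    nb_dispersion: float = 0.2
    nb_mean_log2fc: float = 2.0
    surv_log_hr: float = 1.0
    censor_rate: float = 0.3
    decoy_mirnas_per_gene: int = 5
    decoy_tfs_per_gene: int = 1
    de_fraction: float = 0.3  # chance a non-planted feature is DE in the count layer

    def __post_init__(self) -> None:
        for name in ("n_tumour", "n_normal", "n_mrna", "n_lncrna", "n_mirna",
                     "n_tf", "n_cerna_pairs", "mirnas_per_pair"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.beta_mirna >= 0:
            raise ValueError("beta_mirna must be negative (miRNA repression)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.mirnas_per_pair > self.n_mirna:
            raise ValueError(
                f"mirnas_per_pair={self.mirnas_per_pair} exceeds n_mirna={self.n_mirna}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted, keyed the same way the pipeline reports."""

    planted_pairs: dict  # pair_key -> frozenset of shared miRNA ids
    planted_regulators: dict  # target_id -> {regulator_id: true coefficient}
    de_features: set  # features simulated with a tumour/normal group effect
    prognostic_genes: dict  # gene_id -> planted log hazard ratio


@dataclass
class SimulatedCohort:
    """Full output bundle of :func:`simulate_cohort`."""

    counts: CountsMatrix
    expression: pd.DataFrame  # continuous tumour expression, features x samples
    regulators: RegulatorBundle
    clinical: pd.DataFrame  # index sample_id, columns time, event
    truth: GroundTruth


def _feature_ids(cfg: SimulationConfig) -> tuple[list, list, list, list]:
    mrna = [f"ENSG{i:04d}" for i in range(1, cfg.n_mrna + 1)]
    lnc = [f"ENSL{i:04d}" for i in range(1, cfg.n_lncrna + 1)]
    mir = [f"MIR{i:03d}" for i in range(1, cfg.n_mirna + 1)]
    tf = [f"TF{i:03d}" for i in range(1, cfg.n_tf + 1)]
    return mrna, lnc, mir, tf


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort; identical config (incl. seed) gives identical output.

    One global seed feeds named sub-streams (wiring, expression/noise,
    counts, survival) so each stage's randomness is independent of the
    others' consumption order.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_wire, rng_expr, rng_counts, rng_surv = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    mrna_ids, lnc_ids, mir_ids, tf_ids = _feature_ids(cfg)
    tumour_samples = [f"T{i:04d}" for i in range(1, cfg.n_tumour + 1)]
    normal_samples = [f"N{i:04d}" for i in range(1, cfg.n_normal + 1)]

    # ---- wiring: planted pairs, shared miRNAs, true TFs, decoy edges ----
    pair_members: list[tuple[str, str]] = []
    mrna_cursor = 0
    lnc_cursor = 0
    for p in range(cfg.n_cerna_pairs):
        # every third pair is lncRNA-mRNA while lncRNAs remain; rest mRNA-mRNA
        use_lnc = (p % 3 == 2) and lnc_cursor < cfg.n_lncrna
        if use_lnc:
            if mrna_cursor >= cfg.n_mrna:
                raise ValueError("not enough mRNAs to plant the requested pairs")
            pair_members.append((mrna_ids[mrna_cursor], lnc_ids[lnc_cursor]))
            mrna_cursor += 1
            lnc_cursor += 1
        else:
            if mrna_cursor + 1 >= cfg.n_mrna + 1:
                raise ValueError("not enough mRNAs to plant the requested pairs")
            if mrna_cursor + 2 > cfg.n_mrna:
                raise ValueError("not enough mRNAs to plant the requested pairs")
            pair_members.append((mrna_ids[mrna_cursor], mrna_ids[mrna_cursor + 1]))
            mrna_cursor += 2

    # shared miRNA sets: disjoint while the pool lasts, then resampled
    shuffled_mirs = list(rng_wire.permutation(mir_ids))
    pair_mirnas: list[frozenset] = []
    cursor = 0
    for _ in range(cfg.n_cerna_pairs):
        if cursor + cfg.mirnas_per_pair <= len(shuffled_mirs):
            chosen = shuffled_mirs[cursor:cursor + cfg.mirnas_per_pair]
            cursor += cfg.mirnas_per_pair
        else:
            chosen = list(rng_wire.choice(mir_ids, size=cfg.mirnas_per_pair,
                                          replace=False))
        pair_mirnas.append(frozenset(chosen))

    planted_pairs = {
        make_pair_key(a, b): mirs
        for (a, b), mirs in zip(pair_members, pair_mirnas)
    }

    planted_regulators: dict = {}
    mirna_mrna_edges: set = set()
    mirna_lnc_edges: set = set()
    tf_gene_edges: set = set()

    paired_genes = {g for ab in pair_members for g in ab}
    gene_true_mirnas: dict = {}
    for (a, b), mirs in zip(pair_members, pair_mirnas):
        for g in (a, b):
            gene_true_mirnas.setdefault(g, set()).update(mirs)

    for g in mrna_ids + lnc_ids:
        is_mrna = g in set(mrna_ids)
        regs: dict = {}
        true_mirs = gene_true_mirnas.get(g, set())
        for m in true_mirs:
            regs[m] = cfg.beta_mirna
            (mirna_mrna_edges if is_mrna else mirna_lnc_edges).add((m, g))
        # decoy miRNA candidates, coefficient zero
        pool = [m for m in mir_ids if m not in true_mirs]
        n_decoy = min(cfg.decoy_mirnas_per_gene, len(pool))
        for m in rng_wire.choice(pool, size=n_decoy, replace=False):
            (mirna_mrna_edges if is_mrna else mirna_lnc_edges).add((m, g))
        if is_mrna:
            true_tf = tf_ids[int(rng_wire.integers(cfg.n_tf))]
            regs[true_tf] = cfg.beta_tf
            tf_gene_edges.add((true_tf, g))
            tf_pool = [t for t in tf_ids if t != true_tf]
            n_decoy_tf = min(cfg.decoy_tfs_per_gene, len(tf_pool))
            for t in rng_wire.choice(tf_pool, size=n_decoy_tf, replace=False):
                tf_gene_edges.add((t, g))
            regs["CNA"] = cfg.beta_cna
            regs["DM"] = cfg.beta_dm
        planted_regulators[g] = regs

    # ---- continuous tumour expression (log scale) ----
    nt = cfg.n_tumour
    mir_expr = pd.DataFrame(rng_expr.normal(size=(cfg.n_mirna, nt)),
                            index=mir_ids, columns=tumour_samples)
    tf_expr = pd.DataFrame(rng_expr.normal(size=(cfg.n_tf, nt)),
                           index=tf_ids, columns=tumour_samples)
    cna = pd.DataFrame(rng_expr.normal(size=(cfg.n_mrna, nt)),
                       index=mrna_ids, columns=tumour_samples)
    dm_latent = rng_expr.normal(size=(cfg.n_mrna, nt))
    dm = pd.DataFrame(1.0 / (1.0 + np.exp(-dm_latent)),
                      index=mrna_ids, columns=tumour_samples)

    expr_rows = {}
    for g in mrna_ids:
        y = np.zeros(nt)
        regs = planted_regulators[g]
        y += regs["CNA"] * cna.loc[g].to_numpy()
        y += regs["DM"] * dm.loc[g].to_numpy()
        for r, beta in regs.items():
            if r in ("CNA", "DM"):
                continue
            source = mir_expr if r.startswith("MIR") else tf_expr
            y += beta * source.loc[r].to_numpy()
        y += rng_expr.normal(scale=cfg.noise_sd, size=nt)
        expr_rows[g] = y
    for g in lnc_ids:
        y = np.zeros(nt)
        for r, beta in planted_regulators[g].items():
            y += beta * mir_expr.loc[r].to_numpy()
        y += rng_expr.normal(scale=cfg.noise_sd, size=nt)
        expr_rows[g] = y

    expression = pd.concat(
        [
            pd.DataFrame(expr_rows, index=tumour_samples).T,
            mir_expr,
            tf_expr,
        ]
    )
    expression = expression.loc[mrna_ids + lnc_ids + mir_ids + tf_ids]

    # ---- count layer for the DE stage ----
    all_feature_ids = mrna_ids + lnc_ids + tf_ids + mir_ids
    feature_class = pd.Series(
        ["mRNA"] * cfg.n_mrna + ["lncRNA"] * cfg.n_lncrna
        + ["mRNA"] * cfg.n_tf + ["miRNA"] * cfg.n_mirna,
        index=all_feature_ids,
    )
    essential = set(paired_genes)
    for mirs in pair_mirnas:
        essential.update(mirs)
    essential.update(s for s, _ in tf_gene_edges)  # TFs with any candidate edge
    de_features = set()
    for i, f in enumerate(all_feature_ids):
        if f in essential or rng_counts.uniform() < cfg.de_fraction:
            de_features.add(f)

    n_feat = len(all_feature_ids)
    base_mean = np.exp(rng_counts.normal(5.5, 1.0, size=n_feat))
    lfc = np.zeros(n_feat)
    sign = 1.0
    for i, f in enumerate(all_feature_ids):
        if f in de_features:
            lfc[i] = sign * cfg.nb_mean_log2fc
            sign = -sign
    mu_t = base_mean * 2.0 ** (lfc / 2.0)
    mu_n = base_mean * 2.0 ** (-lfc / 2.0)
    size = 1.0 / cfg.nb_dispersion

    def _nb(mu: np.ndarray, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        mu_mat = np.tile(mu[:, None], (1, n_samples))
        p = size / (size + mu_mat)
        return rng.negative_binomial(size, p)

    counts_values = np.hstack([
        _nb(mu_t, cfg.n_tumour, rng_counts),
        _nb(mu_n, cfg.n_normal, rng_counts),
    ])
    counts = CountsMatrix(
        pd.DataFrame(counts_values, index=all_feature_ids,
                     columns=tumour_samples + normal_samples),
        pd.Series(["tumour"] * cfg.n_tumour + ["normal"] * cfg.n_normal,
                  index=tumour_samples + normal_samples),
        feature_class,
    )

    # ---- survival linked to the first planted gene's expression ----
    prog_gene = pair_members[0][0]
    x = expression.loc[prog_gene].to_numpy()
    high = (x > np.median(x)).astype(float)
    base_rate = 0.1
    rate = base_rate * np.exp(cfg.surv_log_hr * high)
    t_event = rng_surv.exponential(1.0 / rate)
    censored = rng_surv.uniform(size=nt) < cfg.censor_rate
    time = np.where(censored, t_event * rng_surv.uniform(size=nt), t_event)
    clinical = pd.DataFrame(
        {"time": time, "event": (~censored).astype(int)},
        index=pd.Index(tumour_samples, name="sample_id"),
    )

    bundle = RegulatorBundle(
        cna=GeneValueMatrix(cna, "CNA"),
        dm=GeneValueMatrix(dm, "DM"),
        mirna_mrna=InteractionTable(frozenset(mirna_mrna_edges), "miRNA->mRNA"),
        mirna_lncrna=InteractionTable(frozenset(mirna_lnc_edges), "miRNA->lncRNA"),
        tf_gene=InteractionTable(frozenset(tf_gene_edges), "TF->gene"),
    )
    truth = GroundTruth(
        planted_pairs=planted_pairs,
        planted_regulators=planted_regulators,
        de_features=de_features,
        prognostic_genes={prog_gene: cfg.surv_log_hr},
    )
    return SimulatedCohort(counts, expression, bundle, clinical, truth)


def truth_recovery_report(called, truth: GroundTruth) -> dict:
    """Sensitivity and observed FDR of a called pair set against the truth.

    ``called`` may be a set of pair keys or any object with a
    ``passed_keys()`` method (a CeRNANetwork).
    """
    if hasattr(called, "passed_keys"):
        called_keys = set(called.passed_keys())
    else:
        called_keys = set(called)
    planted = set(truth.planted_pairs)
    tp = len(called_keys & planted)
    sensitivity = tp / len(planted) if planted else 0.0
    observed_fdr = len(called_keys - planted) / max(1, len(called_keys))
    return {"sensitivity": sensitivity, "observed_fdr": observed_fdr}


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict:
    """Write the full bundle as TSV files; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "classes": out / "classes.tsv",
        "groups": out / "groups.tsv",
        "expression": out / "expression.tsv",
        "cna": out / "cna.tsv",
        "dm": out / "dm.tsv",
        "mirna_mrna": out / "mirna_mrna.tsv",
        "mirna_lncrna": out / "mirna_lncrna.tsv",
        "tf_gene": out / "tf_gene.tsv",
        "clinical": out / "clinical.tsv",
        "truth_pairs": out / "truth_pairs.tsv",
        "truth_regulators": out / "truth_regulators.tsv",
    }
    write_matrix(cohort.counts.values, paths["counts"])
    cohort.counts.feature_class.rename("feature_class").to_csv(
        paths["classes"], sep="\t", header=False)
    cohort.counts.group.rename("group").to_csv(paths["groups"], sep="\t", header=False)
    write_matrix(cohort.expression, paths["expression"])
    write_matrix(cohort.regulators.cna.values, paths["cna"])
    write_matrix(cohort.regulators.dm.values, paths["dm"])
    write_interactions(cohort.regulators.mirna_mrna, paths["mirna_mrna"])
    write_interactions(cohort.regulators.mirna_lncrna, paths["mirna_lncrna"])
    write_interactions(cohort.regulators.tf_gene, paths["tf_gene"])
    cohort.clinical.to_csv(paths["clinical"], sep="\t")
    with open(paths["truth_pairs"], "w") as fh:
        fh.write("pair_key\tshared_mirnas\n")
        for key in sorted(cohort.truth.planted_pairs):
            mirs = ",".join(sorted(cohort.truth.planted_pairs[key]))
            fh.write(f"{key}\t{mirs}\n")
    with open(paths["truth_regulators"], "w") as fh:
        fh.write("target_id\tregulator_id\tcoefficient\n")
        for g in sorted(cohort.truth.planted_regulators):
            for r, b in sorted(cohort.truth.planted_regulators[g].items()):
                fh.write(f"{g}\t{r}\t{b}\n")
    return {k: str(v) for k, v in paths.items()}
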