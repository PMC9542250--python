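"""End-to-end orchestration: per-cohort DE -> regulator selection ->
ceRNA inference, then cross-cohort intersection and survival/enrichment
screening.

A single YAML config drives the run; every stage writes its outputs under
``output_dir/<cohort>/`` together with a provenance record (config hash,
seed, input hashes) so that re-running with the same config re-uses
cached stage outputs and produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cerna_inference, cross_cancer, diffexpr, regulator_selection as regsel
from . import survival_enrichment as surv
from .formats_io import (
    RegulatorBundle,
    read_clinical,
    read_counts,
    read_gene_values,
    read_gmt,
    read_interactions,
    write_network,
)

logger = logging.getLogger("cerna_moml.pipeline")

STAGES = ("diffexpr", "select-regulators", "infer-cerna", "intersect", "survival", "enrich")

DEFAULT_PARAMS = {
    "lfc": 1.0,
    "fdr": 0.01,
    "weights": "voom",
    "runs": 100,
    "sel_threshold": 75,
    "folds": 10,
    "boot": 1000,
    "ci_level": 0.95,
    "require_negative_mirna": True,
    "pearson": 0.40,
    "hyper_p": 0.05,
    "mscor_padj": 0.05,
    "n_perm": 1000,
    "survival_alpha": 0.05,
    "cutpoint": "median",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cohort: str | None, message: str):
        where = f"stage {stage!r}" + (f", cohort {cohort!r}" if cohort else "")
        super().__init__(f"{where}: {message}")
        self.stage = stage
        self.cohort = cohort


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "cohorts" not in cfg:
        raise ValueError("config must be a mapping with a 'cohorts' section")
    cfg.setdefault("seed", 0)
    cfg.setdefault("output_dir", "cerna_out")
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    cfg["params"] = params
    base = Path(path).parent
    for cohort, files in cfg["cohorts"].items():
        for key, p in files.items():
            files[key] = str((base / p) if not Path(p).is_absolute() else Path(p))
    if "gmt" in cfg and not Path(cfg["gmt"]).is_absolute():
        cfg["gmt"] = str(base / cfg["gmt"])
    return cfg


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _cache_key(params: dict, seed: int, inputs: list) -> str:
    return _hash_obj({"params": params, "seed": seed,
                      "inputs": [_hash_file(p) for p in inputs]})


def _cached(stage_dir: Path, key: str) -> bool:
    prov = stage_dir / "provenance.json"
    if not prov.exists():
        return False
    try:
        return json.loads(prov.read_text()).get("key") == key
    except json.JSONDecodeError:
        return False


def _stamp(stage_dir: Path, stage: str, key: str, seed: int) -> None:
    (stage_dir / "provenance.json").write_text(
        json.dumps({"stage": stage, "key": key, "seed": seed}, sort_keys=True))


def _cohort_seed(seed: int, cohort_idx: int, stage_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, cohort_idx, stage_idx]))


def _load_cohort_inputs(files: dict, stage: str, cohort: str):
    required = ("counts", "classes", "groups", "cna", "dm",
                "mirna_mrna", "mirna_lncrna", "tf_gene")
    for key in required:
        if key not in files:
            raise StageError(stage, cohort, f"missing input {key!r}")
        if not Path(files[key]).exists():
            raise StageError(stage, cohort, f"input file not found: {files[key]}")
    counts = read_counts(files["counts"], files["classes"], files["groups"])
    bundle = RegulatorBundle(
        cna=read_gene_values(files["cna"], "CNA"),
        dm=read_gene_values(files["dm"], "DM"),
        mirna_mrna=read_interactions(files["mirna_mrna"], "miRNA->mRNA"),
        mirna_lncrna=read_interactions(files["mirna_lncrna"], "miRNA->lncRNA"),
        tf_gene=read_interactions(files["tf_gene"], "TF->gene"),
    )
    return counts, bundle


def _tumour_expression(files: dict, counts, norm) -> pd.DataFrame:
    """Continuous tumour-sample expression for the model stages: the
    user-supplied matrix when given, else voom log-CPM of tumour samples."""
    if "expression" in files:
        return pd.read_csv(files["expression"], sep="\t", index_col=0)
    return norm.matrix.loc[:, counts.tumour_samples]


def run_all(config: dict, stages: tuple = STAGES) -> dict:
    """Run the requested stages for every cohort, with per-stage caching.

    Returns a dict with per-cohort networks, the shared table, and paths
    of everything written.
    """
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    seed = int(config.get("seed", 0))
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_ids = sorted(config["cohorts"])

    networks: dict = {}
    expr_by_cohort: dict = {}
    clin_by_cohort: dict = {}
    class_by_cohort: dict = {}

    for ci, cohort in enumerate(cohort_ids):
        files = config["cohorts"][cohort]
        cdir = outdir / cohort
        cdir.mkdir(parents=True, exist_ok=True)
        counts, bundle = _load_cohort_inputs(files, stages[0] if stages else "diffexpr", cohort)
        class_by_cohort[cohort] = counts.feature_class

        # --- differential expression ---
        de_dir = cdir / "diffexpr"
        de_dir.mkdir(exist_ok=True)
        de_inputs = [files["counts"], files["classes"], files["groups"]]
        de_key = _cache_key({k: params[k] for k in ("lfc", "fdr", "weights")}, seed, de_inputs)
        if "diffexpr" in stages and not _cached(de_dir, de_key):
            logger.info("[%s] differential expression", cohort)
            try:
                filtered = diffexpr.filter_low_expressed(counts)
                factors = diffexpr.tmm_factors(filtered)
                norm = diffexpr.voom_transform(filtered, factors,
                                               weight_mode=params["weights"])
                results = diffexpr.moderated_t(norm, filtered.group)
            except ValueError as e:
                raise StageError("diffexpr", cohort, str(e)) from e
            de_sets = diffexpr.select_de(results, filtered.feature_class,
                                         params["lfc"], params["fdr"])
            diffexpr.results_to_frame(results).to_csv(de_dir / "de_results.tsv", sep="\t")
            norm.matrix.to_csv(de_dir / "normalized.tsv", sep="\t")
            (de_dir / "de_sets.json").write_text(json.dumps(
                {k: sorted(v) for k, v in de_sets.items()}, sort_keys=True))
            _stamp(de_dir, "diffexpr", de_key, seed)
        else:
            if not (de_dir / "de_sets.json").exists():
                raise StageError("diffexpr", cohort, "no cached output to resume from")
            de_sets = {k: set(v) for k, v in
                       json.loads((de_dir / "de_sets.json").read_text()).items()}
            norm_matrix = pd.read_csv(de_dir / "normalized.tsv", sep="\t", index_col=0)
            norm = diffexpr.NormalizedExpression(
                norm_matrix, norm_matrix * 0 + 1.0,
                pd.Series(1.0, index=norm_matrix.columns))

        expression = _tumour_expression(files, counts, norm)
        expr_by_cohort[cohort] = expression

        # --- regulator selection ---
        sel_dir = cdir / "models"
        sel_dir.mkdir(exist_ok=True)
        sel_key = _cache_key(
            {k: params[k] for k in ("runs", "sel_threshold", "folds", "boot",
                                    "ci_level", "require_negative_mirna")},
            seed, de_inputs + [files["cna"], files["dm"], files["mirna_mrna"],
                               files["mirna_lncrna"], files["tf_gene"]])
        if "select-regulators" in stages and not _cached(sel_dir, sel_key):
            logger.info("[%s] regulator selection", cohort)
            rng = _cohort_seed(seed, ci, 1)
            models = select_regulators_for_cohort(
                expression, bundle, de_sets, params, rng)
            regsel.models_to_frame(models).to_csv(sel_dir / "models.tsv",
                                                  sep="\t", index=False)
            _stamp(sel_dir, "select-regulators", sel_key, seed)
            maps = regsel.build_mirna_maps(models)
        else:
            if not (sel_dir / "models.tsv").exists():
                raise StageError("select-regulators", cohort,
                                 "no cached models to resume from")
            mframe = pd.read_csv(sel_dir / "models.tsv", sep="\t")
            maps = regsel.mirna_maps_from_frame(mframe)

        # --- ceRNA inference ---
        net_dir = cdir / "network"
        net_dir.mkdir(exist_ok=True)
        net_key = _cache_key(
            {k: params[k] for k in ("pearson", "hyper_p", "mscor_padj", "n_perm")},
            seed, [sel_dir / "models.tsv"])
        if "infer-cerna" in stages and not _cached(net_dir, net_key):
            logger.info("[%s] ceRNA inference (%d targets with miRNA sets)",
                        cohort, len(maps))
            rng = _cohort_seed(seed, ci, 2)
            net = cerna_inference.infer_network(
                expression, maps, counts.feature_class,
                cerna_inference.Thresholds(params["pearson"], params["hyper_p"],
                                           params["mscor_padj"]),
                n_perm=params["n_perm"], cohort_id=cohort, rng=rng)
            write_network(net, net_dir / "network.tsv")
            _stamp(net_dir, "infer-cerna", net_key, seed)
            networks[cohort] = net
        else:
            if not (net_dir / "network.tsv").exists():
                raise StageError("infer-cerna", cohort, "no cached network to resume from")
            df = pd.read_csv(net_dir / "network.tsv", sep="\t")
            networks[cohort] = set(df["pair_key"]) if len(df) else set()

        if "clinical" in files:
            clin_by_cohort[cohort] = read_clinical(files["clinical"])

    result = {"networks": networks, "output_dir": str(outdir)}

    if "intersect" in stages and len(cohort_ids) >= 2:
        shared = cross_cancer.intersect_networks(networks)
        shared.membership.to_csv(outdir / "shared_pairs.tsv", sep="\t")
        shared.combination_summary().to_csv(outdir / "combination_summary.tsv",
                                            sep="\t", index=False)
        result["shared"] = shared

        if "survival" in stages and clin_by_cohort:
            screen = surv.screen_shared_genes(
                shared, expr_by_cohort, clin_by_cohort,
                alpha=params["survival_alpha"], cutpoint=params["cutpoint"])
            screen.to_csv(outdir / "survival_screen.tsv", sep="\t", index=False)
            result["survival"] = screen

        if "enrich" in stages and config.get("gmt"):
            gmt = read_gmt(config["gmt"])
            genes: set = set()
            for r in range(2, len(shared.cohorts) + 1):
                from itertools import combinations
                for subset in combinations(shared.cohorts, r):
                    genes |= shared.genes_in_exactly(subset)
            universe = set()
            for expr in expr_by_cohort.values():
                universe |= set(expr.index)
            universe |= genes
            if genes:
                enrich = surv.geneset_enrichment(genes, gmt, universe)
                enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
                result["enrichment"] = enrich

    return result


def select_regulators_for_cohort(expression: pd.DataFrame,
                                 bundle: RegulatorBundle, de_sets: dict,
                                 params: dict,
                                 rng: np.random.Generator) -> list:
    """Fit one stability-selection model per DE mRNA/lncRNA target.

    Candidate miRNA columns are restricted to DE miRNAs; TF candidates
    are taken from the TF->gene table regardless of the TF's own DE
    status.
    """
    models = []
    targets = [(t, "mRNA") for t in sorted(de_sets.get("mRNA", set()))]
    targets += [(t, "lncRNA") for t in sorted(de_sets.get("lncRNA", set()))]
    de_mirnas = de_sets.get("miRNA", set())
    for target, cls in targets:
        design = regsel.build_design(target, cls, expression, bundle,
                                     allowed_mirnas=de_mirnas)
        if design is None or len(design.y) < params["folds"]:
            continue
        model = regsel.fit_regulator_model(
            design, runs=params["runs"], threshold=params["sel_threshold"],
            folds=params["folds"], B=params["boot"], level=params["ci_level"],
            require_negative_mirna=params["require_negative_mirna"], rng=rng)
        models.append(model)
    return models
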