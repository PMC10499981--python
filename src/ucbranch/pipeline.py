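"""End-to-end orchestration of the progression analysis.

Stages run in dependency order: cohort input (synthetic or files) ->
label-free quantification -> pathway/DDR scoring -> mutational signatures
-> copy-number burden -> differential panel -> origin classifier ->
derived-group comparisons (metastasis Fisher test, pathway Wilcoxon,
Kaplan-Meier/log-rank/Cox).  In synthetic mode a truth-vs-estimate
recovery table is emitted.  A single top-level seed deterministically
derives per-stage substreams; all outputs are TSV/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import cna as _cna
from . import enrich as _enrich
from . import mutsig as _mutsig
from . import quant as _quant
from . import stats as _stats
from . import survival as _survival
from . import synthetic as _synthetic

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "compare_derived_groups"]

logger = logging.getLogger("ucbranch")

__version__ = "0.1.0"


class StageError(RuntimeError):
    """Pipeline stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" or "files"
    cohort: _synthetic.CohortConfig = field(default_factory=_synthetic.CohortConfig)
    paths: dict = field(default_factory=dict)  # files mode inputs
    enrichment: dict = field(default_factory=dict)  # EnrichmentParams overrides
    alpha: float = 0.05
    fold_bounds: tuple = (2.0, 0.5)
    lam: float = 1.0
    cv_folds: int = 10
    train_fraction: float = 0.8
    panel_size: int = _classify.DEFAULT_PANEL_SIZE
    signature_threshold: float = _mutsig.WEIGHT_THRESHOLD
    cna_cutoff: float = _cna.CALL_CUTOFF
    minprop: float = 0.1
    outdir: str = "ucbranch_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in {"synthetic", "files"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1 or not 0 < self.train_fraction < 1:
            raise ValueError("alpha and train_fraction must lie in (0, 1)")
        if not 0 < self.signature_threshold < 1:
            raise ValueError("signature_threshold must lie in (0, 1)")
        if self.mode == "files":
            required = ["peptides", "fasta", "phospho", "clinical", "mutations",
                        "segments", "arms", "signatures", "gene_sets"]
            for key in required:
                if key not in self.paths:
                    raise ValueError(f"files mode requires path {key!r}")
                if not Path(self.paths[key]).exists():
                    raise ValueError(f"input path does not exist: {self.paths[key]}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if cohort_raw:
            cfg.cohort = _synthetic.CohortConfig(**cohort_raw)
        if isinstance(cfg.fold_bounds, list):
            cfg.fold_bounds = tuple(cfg.fold_bounds)
        return cfg

    def canonical_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["cohort"] = dataclasses.asdict(self.cohort)
        # where results land and how much is logged do not alter them
        payload.pop("outdir", None)
        payload.pop("log_level", None)
        return json.dumps(payload, sort_keys=True, default=str)


@dataclass
class ReportBundle:
    outdir: Path
    protein_matrix: _quant.AbundanceMatrix
    phospho_matrix: _quant.AbundanceMatrix
    pathway_scores: pd.DataFrame
    ddr: _enrich.DdrScore
    exposures: list
    signature_labels: pd.Series
    arm_burden: pd.DataFrame
    arm_calls: pd.DataFrame
    panel: _stats.PanelDefinition
    model: _classify.ClassifierModel
    cv_report: _classify.EvalReport
    test_report: _classify.EvalReport
    origin_calls: list
    derived_comparison: dict
    recovery: dict | None
    provenance: dict


def _derive_seed(seed_seq: np.random.SeedSequence, index: int) -> int:
    return int(seed_seq.spawn(index + 1)[index].generate_state(1)[0] % (2**31))


def _load_inputs(config: PipelineConfig):
    if config.mode == "synthetic":
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        bundle = _synthetic.generate_cohort(cohort_cfg)
        return bundle
    p = config.paths
    import types

    bundle = types.SimpleNamespace()
    bundle.cohort = _survival.read_clinical_tsv(p["clinical"])
    bundle.peptides = _quant.read_peptides_tsv(p["peptides"])
    bundle.sequences = _quant.read_fasta(p["fasta"])
    bundle.phospho = _quant.read_matrix_tsv(p["phospho"])
    bundle.mutations = _mutsig.read_maf_tsv(p["mutations"])
    bundle.segments = _cna.read_seg_tsv(p["segments"])
    bundle.arms = _cna.read_arms_tsv(p["arms"])
    bundle.signatures = _mutsig.read_signatures_tsv(p["signatures"])
    bundle.gene_sets = _enrich.read_gmt(p["gene_sets"])
    bundle.truth = None
    return bundle


def compare_derived_groups(
    origin_calls: list,
    clinical: pd.DataFrame,
    pathway_scores: pd.DataFrame,
) -> dict:
    """Compare PUC-derived vs CIS-derived invasive samples.

    Fisher's exact test on metastasis, Wilcoxon with BH across pathway
    scores, and Kaplan-Meier/log-rank/univariate Cox on the derived
    label.  Returns a JSON-serializable report section; skipped with a
    warning if only one derived group is present.
    """
    labels = pd.Series({c.sample: c.label for c in origin_calls})
    if labels.nunique() < 2 or labels.value_counts().min() < 2:
        logger.warning("derived-group comparison skipped: need two groups with >= 2 samples")
        return {"skipped": True}
    clin = clinical.loc[labels.index]
    is_cis = labels == "CIS-derived"

    met = clin["metastasis"].astype(int)
    table = [
        [int((met[is_cis] == 1).sum()), int((met[is_cis] == 0).sum())],
        [int((met[~is_cis] == 1).sum()), int((met[~is_cis] == 0).sum())],
    ]
    fisher = _stats.fisher_exact_2x2(table)

    pathway_rows = []
    scores = pathway_scores.reindex(labels.index).dropna(how="all")
    for name in scores.columns:
        a = scores.loc[is_cis.reindex(scores.index, fill_value=False), name].dropna()
        b = scores.loc[(~is_cis).reindex(scores.index, fill_value=False), name].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        res = _stats.wilcoxon_rank_sum(a.to_numpy(), b.to_numpy())
        pathway_rows.append({"pathway": name, "p": res.p_value})
    if pathway_rows:
        ptab = pd.DataFrame(pathway_rows)
        ptab["q"] = _stats.bh_adjust(ptab["p"].to_numpy())
        pathway_section = ptab.to_dict(orient="records")
    else:
        pathway_section = []

    time = clin["survival_time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy()
    lr = _survival.logrank_test(time, event, labels.to_numpy())
    cox = _survival.cox_univariate(time, event, is_cis.to_numpy(dtype=float))
    km = {
        label: _survival.km_estimate(time[labels == label], event[labels == label]).to_dict(
            orient="list"
        )
        for label in ["PUC-derived", "CIS-derived"]
    }
    return {
        "skipped": False,
        "metastasis_fisher": {"table": table, "odds_ratio": fisher.effect,
                              "p": fisher.p_value},
        "pathway_wilcoxon": pathway_section,
        "logrank": {"statistic": lr.statistic, "p": lr.p_value},
        "cox": dataclasses.asdict(cox),
        "km": km,
    }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(f"not serializable: {type(o)}")


def _dump_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage on the configured cohort; deterministic by seed."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed_root = np.random.SeedSequence(config.seed)
    stage_seeds = {name: _derive_seed(seed_root, i) for i, name in enumerate(
        ["enrich", "split", "cv", "cutpoint"]
    )}

    logger.info("stage: input (%s mode)", config.mode)
    bundle = _load_inputs(config)
    cohort = bundle.cohort
    cohort.to_csv(out / "cohort.tsv", sep="\t")

    # --- quantification -----------------------------------------------------
    logger.info("stage: quant")
    try:
        n_obs = {pid: _quant.count_observable_peptides(seq)
                 for pid, seq in bundle.sequences.items()}
        ibaq, _excluded = _quant.ibaq_matrix(bundle.peptides, n_obs)
        fot = _quant.fot_matrix(ibaq)
        protein = _quant.filter_and_impute(fot)
        protein.values = protein.values.reindex(cohort.index)
        protein.mask = protein.mask.reindex(cohort.index).fillna(True)
        protein.values = protein.values.fillna(np.log2(_quant.FOT_FLOOR))
    except Exception as exc:  # noqa: BLE001
        raise StageError("quant", str(exc)) from exc
    phospho = _quant.filter_and_impute(bundle.phospho)
    _quant.write_matrix_tsv(protein, out / "protein_matrix.tsv")
    _quant.write_matrix_tsv(phospho, out / "phospho_matrix.tsv")

    # --- enrichment ---------------------------------------------------------
    logger.info("stage: enrich")
    params = _enrich.EnrichmentParams(seed=stage_seeds["enrich"],
                                      **config.enrichment)
    scores, skipped = _enrich.score_matrix(protein, bundle.gene_sets, params)
    scores.to_csv(out / "pathway_scores.tsv", sep="\t")
    if skipped:
        logger.info("skipped gene sets: %s", skipped)
    ddr_markers = (bundle.truth.ddr_marker_ids if bundle.truth is not None
                   else [f for f in phospho.features if f.startswith("DDR")])
    try:
        ddr = _enrich.ddr_score(phospho, ddr_markers)
    except ValueError as exc:
        raise StageError("enrich", str(exc)) from exc
    ddr.scores.rename("ddr_score").to_csv(out / "ddr_scores.tsv", sep="\t")

    # --- mutational signatures ----------------------------------------------
    logger.info("stage: mutsig")
    catalog, n_skipped = _mutsig.build_catalog(bundle.mutations)
    if n_skipped:
        logger.info("skipped %d mutation records", n_skipped)
    catalog = catalog.reindex(cohort.index, fill_value=0)
    exposures = []
    for s in catalog.index:
        counts = catalog.loc[s].to_numpy()
        if counts.sum() == 0:
            exposures.append(_mutsig.ExposureResult(sample=str(s), weights={},
                                                    residual=float("nan"),
                                                    dominant=None, unassigned=True))
        else:
            exposures.append(_mutsig.refit_signatures(
                counts, bundle.signatures, config.signature_threshold, sample=str(s)))
    sig_labels, sig_crosstab = _mutsig.assign_signature_groups(
        exposures, cohort["histology_class"])
    _mutsig.write_exposures_tsv(exposures, out / "signature_exposures.tsv")
    sig_labels.to_csv(out / "signature_groups.tsv", sep="\t")
    if sig_crosstab is not None:
        sig_crosstab.to_csv(out / "signature_stage_crosstab.tsv", sep="\t")

    # --- copy number ----------------------------------------------------------
    logger.info("stage: cna")
    burden = _cna.arm_burden(bundle.segments, bundle.arms).reindex(cohort.index)
    calls = _cna.call_matrix(burden, cutoff=config.cna_cutoff)
    burden.to_csv(out / "arm_burden.tsv", sep="\t")
    calls.to_csv(out / "arm_calls.tsv", sep="\t")
    invasive_mask = cohort["histology_class"] == "Invasive"
    met_freq = None
    if invasive_mask.sum() >= 4 and cohort.loc[invasive_mask, "metastasis"].nunique() == 2:
        met_freq = _cna.group_freq_test(
            calls.loc[invasive_mask],
            cohort.loc[invasive_mask, "metastasis"].map({0: "non-met", 1: "met"}),
        )
        met_freq.to_csv(out / "metastasis_arm_fisher.tsv", sep="\t")

    # --- differential panel ----------------------------------------------------
    logger.info("stage: panel")
    puc_mask = cohort["histology_class"].isin(["LGPC", "HGPC"])
    cis_mask = cohort["histology_class"] == "CIS"
    if puc_mask.sum() < 3 or cis_mask.sum() < 3:
        raise StageError("panel", "need >= 3 PUC (LGPC/HGPC) and >= 3 CIS samples")
    sub = protein.values.loc[puc_mask | cis_mask]
    group = pd.Series(np.where(cis_mask.loc[sub.index], "CIS", "PUC"), index=sub.index)
    panel = _stats.differential_panel(sub, group, "CIS", "PUC",
                                      alpha=config.alpha, fold_bounds=config.fold_bounds)
    _stats.write_results_tsv(panel.table, out / "differential_panel.tsv")
    ranked = panel.table.loc[panel.table["direction"] != "ns"].sort_values(
        ["q", "p", "fold_change"], kind="mergesort")
    panel_features = ranked.index.tolist()[: config.panel_size]
    if len(panel_features) < 2:
        raise StageError("panel", "fewer than 2 panel features selected")

    # --- classifier -------------------------------------------------------------
    logger.info("stage: classify")
    labels = group
    X_all = sub[panel_features]
    y_all = (labels == "CIS").astype(int)
    train_idx, test_idx = _classify.split_train_test(
        labels, config.train_fraction, seed=stage_seeds["split"])
    model = _classify.fit_margin_logistic(
        X_all.loc[train_idx].to_numpy(), y_all.loc[train_idx].to_numpy(),
        lam=config.lam, features=panel_features, positive_label="cis")
    cv_report = _classify.cross_validate(
        X_all.loc[train_idx].to_numpy(), y_all.loc[train_idx].to_numpy(),
        k=config.cv_folds, seed=stage_seeds["cv"], lam=config.lam)
    test_report = _classify.evaluate(
        model, X_all.loc[test_idx].to_numpy(), y_all.loc[test_idx].to_numpy())
    model.to_json(out / "origin_model.json")
    _dump_json({"cv": dataclasses.asdict(cv_report),
                "test": dataclasses.asdict(test_report)}, out / "classifier_eval.json")

    invasive = protein.values.loc[invasive_mask, panel_features]
    origin_calls = _classify.assign_origin(model, invasive)
    pd.DataFrame(
        [{"sample": c.sample, "label": c.label, "prob_cis": c.probability,
          "tie": int(c.tie)} for c in origin_calls]
    ).to_csv(out / "origin_calls.tsv", sep="\t", index=False)

    # --- derived-group comparisons ----------------------------------------------
    logger.info("stage: derived groups")
    derived = compare_derived_groups(origin_calls, cohort, scores)
    _dump_json(derived, out / "derived_comparison.json")

    # --- recovery vs truth (synthetic mode) --------------------------------------
    recovery = None
    if bundle.truth is not None:
        truth = bundle.truth
        truth_panel = set(truth.panel_up_papillary) | set(truth.panel_up_cis)
        found = set(panel.up_in_a) | set(panel.up_in_b)
        call_map = {c.sample: c.label for c in origin_calls}
        true_label = cohort.loc[invasive_mask, "derived_label"]
        acc = float(np.mean([
            call_map[s] == true_label[s] for s in true_label.index
        ])) if len(true_label) else float("nan")
        exp_err = []
        for r in exposures:
            true_w = truth.exposures.get(r.sample, {})
            sigs = set(true_w) | set(r.weights)
            if true_w:
                exp_err.append(np.mean([
                    abs(r.weights.get(s, 0.0) - true_w.get(s, 0.0)) for s in sigs
                ]))
        cox = derived.get("cox") if not derived.get("skipped") else None
        recovery = {
            "panel_recall": len(truth_panel & found) / len(truth_panel),
            "exposure_mean_abs_error": float(np.mean(exp_err)) if exp_err else None,
            "origin_label_accuracy": acc,
            "true_hr": truth.true_hr,
            "estimated_hr": cox["hazard_ratio"] if cox else None,
        }
        _dump_json(recovery, out / "recovery.json")

    provenance = {
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    _dump_json(provenance, out / "provenance.json")
    logger.info("pipeline complete: %s", out)
    return ReportBundle(
        outdir=out,
        protein_matrix=protein,
        phospho_matrix=phospho,
        pathway_scores=scores,
        ddr=ddr,
        exposures=exposures,
        signature_labels=sig_labels,
        arm_burden=burden,
        arm_calls=calls,
        panel=panel,
        model=model,
        cv_report=cv_report,
        test_report=test_report,
        origin_calls=origin_calls,
        derived_comparison=derived,
        recovery=recovery,
        provenance=provenance,
    )
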