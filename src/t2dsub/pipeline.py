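"""End-to-end orchestration of the subtyping analysis.

A YAML/dict config drives: synthesize (or load) the cohort -> classify
status -> train/test split -> cluster the training T2D cases (k vote, k=4
fit, subtype labels, bootstrap Jaccard) -> sensitivity checks (fasting
correction, sex-specific re-clustering, center transfer to the test half)
-> case-control omics association -> subtype signature selection ->
medication enrichment.  Every stage writes TSV/JSON outputs under the run
directory, a machine-readable summary collects the headline quantities, and
per-stage child seeds are derived deterministically from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, clustering, medications, signatures, synthetic
from .cohort import CLUSTER_FEATURES, classify_table, split_cohort

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger("t2dsub.pipeline")


@dataclass
class PipelineConfig:
    out_dir: str = "t2dsub_run"
    seed: int = 0
    alpha: float = 0.05
    k_min: int = 2
    k_max: int = 15
    n_restarts: int = 100
    n_stability_reruns: int = 500
    fasting_reference_minutes: float = 480.0
    train_fraction: float = 0.5
    protein_covariates: list = field(
        default_factory=lambda: ["age", "sex_male", "lysis_proxy", "collection_week",
                                 "fasting_minutes", "tube_number"]
    )
    metabolite_covariates: list = field(
        default_factory=lambda: ["age", "sex_male", "bmi", "lysis_proxy",
                                 "collection_week", "fasting_minutes", "tube_number"]
    )
    # synthetic preset overrides (None -> SimulationParams defaults)
    synthetic: dict = field(default_factory=dict)
    # optional input paths (subjects/proteins/metabolites/medications TSVs);
    # when empty, the synthetic preset is generated instead
    paths: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_config(source) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a config mapping or YAML file; report *all* violations.

    Returns (config, []) on success or (None, violations) on failure.
    """
    if isinstance(source, (str, Path)):
        try:
            raw = yaml.safe_load(Path(source).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            return None, [f"unreadable config file: {exc}"]
    else:
        raw = dict(source)
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if not 0.0 < cfg.alpha < 1.0:
        errors.append(f"alpha must be in (0, 1), got {cfg.alpha}")
    if not 0.0 < cfg.train_fraction < 1.0:
        errors.append(f"train_fraction must be in (0, 1), got {cfg.train_fraction}")
    if not (2 <= cfg.k_min <= cfg.k_max <= 15):
        errors.append(f"k range [{cfg.k_min}, {cfg.k_max}] must lie within [2, 15]")
    if cfg.n_restarts < 1:
        errors.append("n_restarts must be >= 1")
    if cfg.n_stability_reruns < 1:
        errors.append("n_stability_reruns must be >= 1")
    if cfg.fasting_reference_minutes < 0:
        errors.append("fasting_reference_minutes must be >= 0")
    for key, path in cfg.paths.items():
        if not Path(path).exists():
            errors.append(f"paths.{key} does not exist: {path}")
    if cfg.synthetic:
        try:
            _synthetic_params(cfg).validate()
        except (TypeError, ValueError) as exc:
            errors.append(f"synthetic preset invalid: {exc}")
    return (None, errors) if errors else (cfg, [])


def _synthetic_params(cfg: PipelineConfig) -> synthetic.SimulationParams:
    overrides = dict(cfg.synthetic)
    overrides.setdefault("seed", _child_seed(cfg.seed, "synthesize"))
    return synthetic.SimulationParams(**overrides)


def _child_seed(master: int, stage: str) -> int:
    h = np.random.SeedSequence(
        [int(master), abs(hash(stage)) % (2**31 - 1)]
    ).generate_state(1)[0]
    return int(h % (2**31 - 1))


def _covariate_frame(table: pd.DataFrame, omics: association.OmicsMatrix,
                     names: list[str]) -> pd.DataFrame:
    base = pd.DataFrame(index=omics.sample_ids)
    base["age"] = table["age"].reindex(base.index)
    base["sex_male"] = (table["sex"].reindex(base.index) == "male").astype(float)
    base["bmi"] = table["bmi"].reindex(base.index)
    if omics.covariates is not None:
        for c in omics.covariates.columns:
            base[c] = omics.covariates[c]
    return base[names]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to JSON).

    Any stage error aborts with :class:`PipelineError` naming the stage;
    outputs of completed stages are preserved in the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "stage_seeds": {}}

    def stage(name):
        seed = _child_seed(config.seed, name)
        summary["stage_seeds"][name] = seed
        log.info("stage %s (seed %d)", name, seed)
        return seed

    try:
        # ---- data -------------------------------------------------------
        name = "synthesize"
        seed = stage(name)
        if config.paths:
            table = pd.read_csv(config.paths["subjects"], sep="\t")
            table = table.set_index("subject_id", drop=False)
            table.index.name = None
            truth = None
            proteins = association.OmicsMatrix(
                pd.read_csv(config.paths["proteins"], sep="\t", index_col=0),
                "protein",
            )
            metabolites = association.OmicsMatrix(
                pd.read_csv(config.paths["metabolites"], sep="\t", index_col=0),
                "metabolite",
            )
            meds_raw = pd.read_csv(config.paths["medications"], sep="\t")
        else:
            params = _synthetic_params(config)
            table, truth = synthetic.generate_cohort(params)
            proteins = synthetic.generate_omics(truth, params, "protein")
            metabolites = synthetic.generate_omics(truth, params, "metabolite")
            meds_raw = synthetic.generate_medications(truth, params)
            (out / "truth.json").write_text(truth.to_json())
        table.to_csv(out / "subjects.tsv", sep="\t", index=False)

        name = "classify"
        stage(name)
        table["status"] = classify_table(table)
        status_counts = table["status"].value_counts().to_dict()
        summary["status_counts"] = status_counts
        table.to_csv(out / "subjects_classified.tsv", sep="\t", index=False)

        name = "split"
        seed = stage(name)
        train_ids, test_ids = split_cohort(table, config.train_fraction, seed)
        summary["n_train"] = len(train_ids)
        summary["n_test"] = len(test_ids)
        pd.DataFrame(
            {"subject_id": train_ids + test_ids,
             "split": ["train"] * len(train_ids) + ["test"] * len(test_ids)}
        ).to_csv(out / "split.tsv", sep="\t", index=False)

        # ---- clustering -------------------------------------------------
        name = "cluster"
        seed = stage(name)
        t2d_train = [i for i in train_ids if table.loc[i, "status"] == "T2D"]
        t2d_all = table.index[table["status"] == "T2D"]
        X_std, std_params = clustering.standardize(
            table.loc[t2d_all], fit_ids=t2d_train
        )
        chosen_k, votes = clustering.select_k(
            X_std.loc[t2d_train], range(config.k_min, config.k_max + 1), seed=seed
        )
        votes.to_csv(out / "k_votes.tsv", sep="\t")
        summary["k_selected"] = chosen_k
        summary["k_votes"] = votes.attrs["votes"]

        model = clustering.fit_cluster_model(
            X_std.loc[t2d_train], k=4, restarts=config.n_restarts, seed=seed,
            standardization=std_params,
        )
        model.save(out / "model.json")
        assignments = clustering.assign_by_centers(X_std, model)
        assignments.to_csv(out / "assignments.tsv", sep="\t", index_label="subject_id")
        subtype = assignments["subtype"]
        summary["cluster_sizes"] = subtype.value_counts().to_dict()

        stability = clustering.jaccard_stability(
            X_std.loc[t2d_train], model, n_reruns=config.n_stability_reruns,
            seed=seed,
        )
        summary["jaccard"] = {
            model.label_map[i]: float(j)
            for i, j in enumerate(stability.per_cluster_jaccard)
        }
        summary["jaccard_min"] = stability.min_jaccard

        # ---- sensitivity ------------------------------------------------
        name = "sensitivity"
        seed = stage(name)
        corrected = clustering.correct_for_fasting(
            table.loc[t2d_all], config.fasting_reference_minutes
        )
        Xc_std, _ = clustering.standardize(corrected, fit_ids=t2d_train)
        corr_assign = clustering.assign_by_centers(
            Xc_std, clustering.fit_cluster_model(
                Xc_std.loc[t2d_train], 4, config.n_restarts, seed, std_params)
        )
        agree_fast, _ = clustering.compare_partitions(
            subtype.astype(str), corr_assign["subtype"].astype(str)
        )
        summary["fasting_correction_agreement_percent"] = agree_fast

        sex_agree = {}
        for s in ("male", "female"):
            ids = [i for i in t2d_all if table.loc[i, "sex"] == s]
            if len(ids) < 8:
                continue
            m = clustering.fit_cluster_model(
                X_std.loc[ids], 4, config.n_restarts, seed
            )
            part = clustering.assign_by_centers(X_std.loc[ids], m)["subtype"]
            sex_agree[s], _ = clustering.compare_partitions(
                subtype.loc[ids].astype(str), part.astype(str)
            )
        summary["sex_specific_agreement_percent"] = sex_agree

        t2d_test = [i for i in test_ids if table.loc[i, "status"] == "T2D"]
        transfer = clustering.transfer_centers(
            table.loc[t2d_test], model.centers, std_params,
            label_maps=model.label_map,
        )
        denovo = clustering.fit_cluster_model(
            X_std.loc[t2d_test], 4, config.n_restarts, seed, std_params
        )
        denovo_part = clustering.assign_by_centers(X_std.loc[t2d_test], denovo)
        agree_transfer, _ = clustering.compare_partitions(
            transfer["subtype"].astype(str), denovo_part["subtype"].astype(str)
        )
        summary["train_to_test_transfer_agreement_percent"] = agree_transfer

        # ---- omics case-control ----------------------------------------
        name = "omics_case_control"
        stage(name)
        status = table["status"]
        assoc_counts = {}
        processed = {}
        for omics, covs in (
            (proteins, config.protein_covariates),
            (metabolites, config.metabolite_covariates),
        ):
            proc, excl = association.preprocess_features(omics)
            processed[omics.platform] = proc
            excl.to_csv(out / f"{omics.platform}_exclusions.tsv", sep="\t", index=False)
            cov = _covariate_frame(table, omics, covs)
            recs = association.associate_case_control(proc, status, covariates=cov)
            recs.to_csv(out / f"{omics.platform}_case_control.tsv", sep="\t",
                        index=False)
            thr = association.bonferroni_threshold(config.alpha, len(recs))
            assoc_counts[omics.platform] = int((recs["p"] < thr).sum())
        summary["case_control_significant"] = assoc_counts

        # ---- subtype signatures ----------------------------------------
        name = "signatures"
        stage(name)
        sig_counts = {}
        specific_ids = {}
        for platform, proc in processed.items():
            sig = signatures.cluster_specific_features(
                proc, subtype, alpha=config.alpha
            )
            sig.to_csv(out / f"{platform}_signatures.tsv", sep="\t", index=False)
            spec = sig[sig["specific"]]
            sig_counts[platform] = int(len(spec))
            specific_ids[platform] = spec["feature"].unique().tolist()
            groups = pd.concat(
                [subtype.astype(str),
                 status[status.isin(["CONTROL", "SAID"])].replace(
                     {"CONTROL": "control"})]
            )
            if len(spec):
                profiles = signatures.normalized_cluster_profiles(
                    proc, groups, reference_cluster="MARD",
                    features=specific_ids[platform],
                )
                profiles.to_csv(out / f"{platform}_profiles.tsv", sep="\t",
                                index=False)
            pcs = signatures.pc_variance_explained(proc, subtype)
            pcs.to_csv(out / f"{platform}_pc_r2.tsv", sep="\t", index=False)
        summary["subtype_specific_features"] = sig_counts
        if specific_ids.get("protein") and specific_ids.get("metabolite"):
            corr = signatures.correlate_signature_features(
                processed["protein"], processed["metabolite"],
                specific_ids["protein"], specific_ids["metabolite"],
                sample_ids=subtype.index,
            )
            corr.to_csv(out / "signature_correlations.tsv", sep="\t", index=False)

        # ---- medications -----------------------------------------------
        name = "medications"
        stage(name)
        med_table = medications.annotate_medications(meds_raw)
        med_table.records.to_csv(out / "medications_annotated.tsv", sep="\t",
                                 index=False)
        cc_groups = status[status.isin(["CONTROL", "T2D"])]
        scan_cc = medications.enrichment_scan(med_table, cc_groups, "ATC-2",
                                              alpha=config.alpha)
        scan_cc.to_csv(out / "medication_enrichment_case_control.tsv", sep="\t",
                       index=False)
        scan_cluster = medications.enrichment_scan(med_table, subtype, "molecule",
                                                   alpha=config.alpha)
        scan_cluster.to_csv(out / "medication_enrichment_clusters.tsv", sep="\t",
                            index=False)
        summary["medication_enriched_case_control"] = int(
            scan_cc.get("bonferroni_significant", pd.Series(dtype=bool)).sum()
        )
        summary["medication_cluster_nominal"] = int((scan_cluster["p"] < 0.05).sum())
    except Exception as exc:  # noqa: BLE001 - stage name matters more than type
        log.error("stage %s failed:\n%s", name, traceback.format_exc())
        raise PipelineError(name, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
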