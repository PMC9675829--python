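"""Synthetic cohort generator for the subtyping pipeline.

Emulates the statistical structure the analysis assumes: T2D cases drawn
from a 4-component Gaussian mixture over the five standardized clustering
variables (age at diagnosis, BMI, HbA1c, HOMA2-B, HOMA2-IR) whose center
sign patterns follow the four clinical subtypes; controls satisfying all
four control rules; a SAID stratum (low C-peptide on insulin treatment);
log-normal omics matrices with subtype-specific and case-control planted
shifts plus technical covariates and missing-at-random entries; and
free-text medication lists with group-differential usage probabilities.
Ground truth (memberships, planted effects) is emitted for
parameter-recovery tests.

Default preset conditions
-------------------------
Subtype fractions (0.25, 0.05, 0.23, 0.47) mirror the reported relative
cluster sizes (SIRD is the small cluster); the SAID fraction is 109/1160 of
all diabetes rows; subtype centers are separated by >= 6 within-cluster SDs
pairwise, emulating well-separated clinical subtypes; physical-unit
back-transforms use documented affine constants patterned on typical
biobank magnitudes (they are preset constants, not cohort claims).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .association import OmicsMatrix
from .cohort import CLUSTER_FEATURES, SUBTYPE_NAMES

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "DEFAULT_SUBTYPE_CENTERS",
    "PHYSICAL_MEANS",
    "PHYSICAL_SDS",
    "generate_cohort",
    "generate_omics",
    "generate_medications",
    "write_synthetic_dataset",
]

#: Subtype centers in standardized units, rows ordered SIDD, SIRD, MOD, MARD,
#: columns ordered as CLUSTER_FEATURES.  Sign pattern: SIDD high HbA1c / low
#: HOMA2-B; SIRD high HOMA2-IR / high BMI; MOD high BMI / low age; MARD
#: highest age, small elsewhere.
DEFAULT_SUBTYPE_CENTERS = np.array(
    [
        #  aad   bmi  hba1c  h2b   h2ir
        [-0.8, -0.8, 2.0, -2.0, 0.0],  # SIDD
        [0.5, 1.0, 0.0, 0.5, 2.0],  # SIRD
        [-2.0, 2.0, -0.5, 0.5, -0.5],  # MOD
        [1.5, -0.5, -0.5, 0.0, -0.5],  # MARD
    ]
)

#: Affine back-transform to physical units (means / SDs per clustering variable).
PHYSICAL_MEANS = {
    "age_at_diagnosis": 45.0,
    "bmi": 32.0,
    "hba1c": 7.5,
    "homa2_b": 76.0,
    "homa2_ir": 2.8,
}
PHYSICAL_SDS = {
    "age_at_diagnosis": 8.0,
    "bmi": 4.5,
    "hba1c": 1.2,
    "homa2_b": 30.0,
    "homa2_ir": 1.2,
}

#: Lower clamps keeping back-transformed physical values clinically plausible.
_PHYSICAL_FLOOR = {
    "age_at_diagnosis": 18.0,
    "bmi": 15.0,
    "hba1c": 4.0,
    "homa2_b": 2.0,
    "homa2_ir": 0.05,
}

#: Default medication usage probabilities (drug -> group -> probability).
#: Groups resolve most-specific first: subtype name, then "t2d"/"said"/"control".
DEFAULT_MED_USAGE_PROBS: dict[str, dict[str, float]] = {
    "metformin": {"t2d": 0.60, "said": 0.30, "control": 0.02},
    "insulin human": {"SIDD": 0.45, "t2d": 0.12, "said": 0.95, "control": 0.0},
    "glibenclamide": {"SIDD": 0.30, "t2d": 0.08, "control": 0.0},
    "sitagliptin": {"SIDD": 0.20, "t2d": 0.06, "control": 0.0},
    "atorvastatin": {"t2d": 0.40, "said": 0.30, "control": 0.08},
    "lisinopril": {"MOD": 0.30, "t2d": 0.10, "control": 0.04},
    "losartan": {"SIRD": 0.30, "t2d": 0.08, "control": 0.04},
    "acetylsalicylic acid": {"t2d": 0.30, "said": 0.20, "control": 0.05},
    "paracetamol": {"t2d": 0.20, "said": 0.20, "control": 0.20},
    "ibuprofen": {"t2d": 0.10, "said": 0.10, "control": 0.12},
}

#: Planted enrichment truth implied by the default probabilities.
_DEFAULT_DRUG_TRUTH = {
    "metformin": "t2d",
    "insulin human": "SIDD",
    "glibenclamide": "SIDD",
    "sitagliptin": "SIDD",
    "atorvastatin": "t2d",
    "lisinopril": "MOD",
    "losartan": "SIRD",
    "acetylsalicylic acid": "t2d",
}


@dataclass
class SimulationParams:
    """Study conditions for one synthetic dataset (defaults are the preset)."""

    n_cases: int = 1000
    n_controls: int = 1735
    subtype_fractions: tuple[float, float, float, float] = (0.25, 0.05, 0.23, 0.47)
    subtype_centers: np.ndarray = field(
        default_factory=lambda: DEFAULT_SUBTYPE_CENTERS.copy()
    )
    within_cluster_sd: np.ndarray = field(default_factory=lambda: np.full(5, 0.5))
    said_fraction: float = 109.0 / 1160.0
    n_proteins: int = 200
    n_metabolites: int = 150
    n_specific_per_subtype: int = 5
    n_case_control: int = 20
    effect_size: float = 2.0
    case_control_effect: float = 0.8
    missing_rate: float = 0.05
    log_sd: float = 0.5
    med_usage_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            drug: dict(groups) for drug, groups in DEFAULT_MED_USAGE_PROBS.items()
        }
    )
    seed: int = 0

    def validate(self) -> None:
        fr = np.asarray(self.subtype_fractions, dtype=float)
        if fr.shape != (4,) or abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any():
            raise ValueError("subtype_fractions must be 4 proportions summing to 1")
        for name in ("n_cases", "n_controls", "n_proteins", "n_metabolites",
                     "n_specific_per_subtype", "n_case_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        centers = np.asarray(self.subtype_centers, dtype=float)
        if centers.shape != (4, 5) or not np.isfinite(centers).all():
            raise ValueError("subtype_centers must be a finite 4x5 matrix")
        sds = np.asarray(self.within_cluster_sd, dtype=float)
        if sds.shape != (5,) or (sds <= 0).any():
            raise ValueError("within_cluster_sd must be 5 positive reals")
        if not np.isfinite([self.effect_size, self.case_control_effect]).all():
            raise ValueError("effect sizes must be finite")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.said_fraction < 1.0:
            raise ValueError("said_fraction must be in [0, 1)")
        for drug, groups in self.med_usage_probs.items():
            for group, p in groups.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"med usage probability out of [0,1] for {drug}/{group}"
                    )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the generated tables."""

    group: dict[str, str]  # subject -> control / T2D / SAID
    subtype: dict[str, int]  # T2D subject -> subtype index 0..3
    features: dict[str, tuple[str | None, float]]  # feature -> (target, shift)
    drugs: dict[str, str]  # drug -> planted enrichment group
    clinical_means: dict[str, float] = field(default_factory=lambda: dict(PHYSICAL_MEANS))
    clinical_sds: dict[str, float] = field(default_factory=lambda: dict(PHYSICAL_SDS))

    def subtype_name(self, subject_id: str) -> str:
        return SUBTYPE_NAMES[self.subtype[subject_id]]

    def to_json(self) -> str:
        d = asdict(self)
        d["features"] = {k: list(v) for k, v in self.features.items()}
        return json.dumps(d, indent=1, sort_keys=True)


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_cohort(params: SimulationParams) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the subject table and its ground truth.

    T2D cases are drawn from the subtype mixture in standardized space and
    mapped back to physical units by the documented affine transform;
    HOMA2-B/IR are emitted directly so downstream stages do not depend on
    the HOMA2 estimator's absolute calibration.  Controls satisfy all four
    control rules by construction; SAID rows satisfy the SAID rule.
    """
    params.validate()
    rng = _child_rng(params.seed, 0)
    n_said = int(round(params.n_cases * params.said_fraction / (1.0 - params.said_fraction)))

    rows: list[dict] = []
    truth_group: dict[str, str] = {}
    truth_subtype: dict[str, int] = {}

    centers = np.asarray(params.subtype_centers, dtype=float)
    sds = np.asarray(params.within_cluster_sd, dtype=float)
    means_vec = np.array([PHYSICAL_MEANS[f] for f in CLUSTER_FEATURES])
    sds_vec = np.array([PHYSICAL_SDS[f] for f in CLUSTER_FEATURES])
    floor_vec = np.array([_PHYSICAL_FLOOR[f] for f in CLUSTER_FEATURES])

    subtypes = rng.choice(4, size=params.n_cases, p=np.asarray(params.subtype_fractions))
    z = centers[subtypes] + rng.standard_normal((params.n_cases, 5)) * sds
    physical = np.maximum(means_vec + z * sds_vec, floor_vec)

    for i in range(params.n_cases):
        sid = f"S{i + 1:05d}"
        aad, bmi, hba1c, h2b, h2ir = physical[i]
        time_since_dx = float(rng.gamma(2.0, 2.5))
        rows.append(
            {
                "subject_id": sid,
                "sex": "male" if rng.random() < 0.45 else "female",
                "age": aad + time_since_dx,
                "age_at_diagnosis": aad,
                "bmi": bmi,
                "hba1c": hba1c,
                "random_glucose": float(np.clip(rng.normal(160.0, 50.0), 60.0, 500.0)),
                "c_peptide": float(np.clip(rng.normal(1.0, 0.3), 0.55, 3.5)),
                "insulin": float(np.clip(rng.normal(130.0, 60.0), 10.0, 1000.0)),
                "fasting_minutes": float(np.clip(rng.gamma(2.0, 240.0), 0.0, 2000.0)),
                "time_since_diagnosis": time_since_dx,
                "flag_physician_diagnosis": True,
                "flag_diabetes_medication": bool(rng.random() < 0.7),
                "flag_insulin_treatment": False,
                "flag_self_report_t1d": False,
                "flag_gestational": False,
                "homa2_b": h2b,
                "homa2_ir": h2ir,
            }
        )
        truth_group[sid] = "T2D"
        truth_subtype[sid] = int(subtypes[i])

    for j in range(n_said):
        sid = f"A{j + 1:05d}"
        aad = float(np.clip(rng.normal(35.0, 10.0), 18.0, 80.0))
        rows.append(
            {
                "subject_id": sid,
                "sex": "male" if rng.random() < 0.5 else "female",
                "age": aad + float(rng.gamma(2.0, 3.0)),
                "age_at_diagnosis": aad,
                "bmi": float(np.clip(rng.normal(26.0, 4.5), 15.0, 60.0)),
                "hba1c": float(np.clip(rng.normal(8.2, 1.5), 4.0, 16.0)),
                "random_glucose": float(np.clip(rng.normal(180.0, 60.0), 60.0, 500.0)),
                "c_peptide": float(rng.uniform(0.05, 0.45)),
                "insulin": float(np.clip(rng.normal(80.0, 40.0), 5.0, 500.0)),
                "fasting_minutes": float(np.clip(rng.gamma(2.0, 240.0), 0.0, 2000.0)),
                "time_since_diagnosis": float(rng.gamma(2.0, 4.0)),
                "flag_physician_diagnosis": True,
                "flag_diabetes_medication": True,
                "flag_insulin_treatment": True,
                "flag_self_report_t1d": bool(rng.random() < 0.5),
                "flag_gestational": False,
                "homa2_b": float(np.clip(rng.normal(30.0, 10.0), 2.0, 100.0)),
                "homa2_ir": float(np.clip(rng.normal(1.0, 0.5), 0.05, 5.0)),
            }
        )
        truth_group[sid] = "SAID"

    for j in range(params.n_controls):
        sid = f"C{j + 1:05d}"
        rows.append(
            {
                "subject_id": sid,
                "sex": "male" if rng.random() < 0.35 else "female",
                "age": float(np.clip(rng.normal(35.0, 10.0), 18.0, 85.0)),
                "age_at_diagnosis": np.nan,
                "bmi": float(np.clip(rng.normal(28.0, 5.5), 15.0, 60.0)),
                "hba1c": float(np.clip(rng.normal(5.2, 0.2), 4.0, 5.69)),
                "random_glucose": float(np.clip(rng.normal(90.0, 10.0), 50.0, 199.0)),
                "c_peptide": float(np.clip(rng.normal(0.8, 0.3), 0.2, 3.0)),
                "insulin": float(np.clip(rng.normal(85.0, 40.0), 5.0, 500.0)),
                "fasting_minutes": float(np.clip(rng.gamma(2.0, 240.0), 0.0, 2000.0)),
                "time_since_diagnosis": np.nan,
                "flag_physician_diagnosis": False,
                "flag_diabetes_medication": False,
                "flag_insulin_treatment": False,
                "flag_self_report_t1d": False,
                "flag_gestational": False,
                "homa2_b": float(np.clip(rng.normal(105.0, 35.0), 10.0, 300.0)),
                "homa2_ir": float(np.clip(rng.normal(1.2, 0.6), 0.05, 6.0)),
            }
        )
        truth_group[sid] = "control"

    table = pd.DataFrame(rows).set_index("subject_id", drop=False)
    table.index.name = None
    truth = SyntheticTruth(
        group=truth_group,
        subtype=truth_subtype,
        features={},
        drugs=dict(_DEFAULT_DRUG_TRUTH),
    )
    return table, truth


def generate_omics(
    truth: SyntheticTruth, params: SimulationParams, platform: str
) -> OmicsMatrix:
    """Generate a positive relative-abundance matrix with planted effects.

    Log-normal baseline per feature; the first ``4 * n_specific_per_subtype``
    features are shifted by ``effect_size`` log-SDs in their target subtype
    only (disjoint across subtypes); the next ``n_case_control`` features are
    shifted by ``case_control_effect`` in all T2D cases; entries are masked
    missing-at-random at ``missing_rate``.  Technical covariates (lysis
    proxy, collection week, fasting minutes, tube number) are attached.
    Feature truth is recorded into ``truth.features``.
    """
    params.validate()
    if platform == "protein":
        n_features, prefix, stream = params.n_proteins, "P", 1
    elif platform == "metabolite":
        n_features, prefix, stream = params.n_metabolites, "M", 2
    else:
        raise ValueError(f"unknown platform tag {platform!r}")

    rng = _child_rng(params.seed, stream)
    sample_ids = sorted(truth.group)
    n = len(sample_ids)
    feature_ids = [f"{prefix}{k + 1:05d}" for k in range(n_features)]

    subtype_idx = np.array(
        [truth.subtype.get(s, -1) for s in sample_ids]
    )  # -1 for controls / SAID
    is_case = np.array([truth.group[s] == "T2D" for s in sample_ids])

    mu = rng.normal(5.0, 1.0, size=n_features)
    sigma = params.log_sd
    log_values = mu[None, :] + sigma * rng.standard_normal((n, n_features))

    n_spec = params.n_specific_per_subtype
    for k, feat in enumerate(feature_ids):
        if k < 4 * n_spec and n_spec > 0:
            target = k // n_spec
            shift = params.effect_size * sigma
            log_values[subtype_idx == target, k] += shift
            truth.features[feat] = (SUBTYPE_NAMES[target], params.effect_size)
        elif k < 4 * n_spec + params.n_case_control:
            shift = params.case_control_effect * sigma
            log_values[is_case, k] += shift
            truth.features[feat] = ("t2d", params.case_control_effect)
        else:
            truth.features[feat] = (None, 0.0)

    values = pd.DataFrame(np.exp(log_values), index=sample_ids, columns=feature_ids)
    if params.missing_rate > 0:
        mask = rng.random(values.shape) < params.missing_rate
        values = values.mask(mask)

    covariates = pd.DataFrame(
        {
            "lysis_proxy": rng.standard_normal(n),
            "collection_week": rng.integers(1, 21, size=n).astype(float),
            "fasting_minutes": rng.gamma(2.0, 240.0, size=n),
            "tube_number": rng.integers(1, 9, size=n).astype(float),
        },
        index=sample_ids,
    )
    return OmicsMatrix(values, platform, covariates=covariates)


def _decorate_entry(drug: str, synonyms: list[str], rng: np.random.Generator) -> str:
    """Render a free-text questionnaire entry for a drug."""
    base = synonyms[rng.integers(len(synonyms))] if synonyms else drug
    style = rng.integers(4)
    if style == 1:
        base = base.upper()
    elif style == 2:
        base = base.title()
    elif style == 3:
        base = base.capitalize() + f" {int(rng.choice([5, 10, 20, 40, 50, 100, 500]))}mg"
    if rng.random() < 0.15:
        base = base + "."
    return base


def generate_medications(
    truth: SyntheticTruth,
    params: SimulationParams,
    synonyms: Mapping[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Generate free-text medication entries (one row per subject x entry).

    Each drug is used by a subject with the most specific matching group
    probability (subtype name for T2D cases, else t2d / said / control).
    Entries are randomized case/punctuation variants of dictionary synonyms.
    """
    params.validate()
    if synonyms is None:
        from .medications import load_dictionary

        dictionary = load_dictionary()
        synonyms = {
            mol: grp["synonym"].tolist()
            for mol, grp in dictionary.groupby("molecule")
        }
    rng = _child_rng(params.seed, 3)
    rows = []
    for sid in sorted(truth.group):
        group = truth.group[sid]
        for drug in sorted(params.med_usage_probs):
            probs = params.med_usage_probs[drug]
            if group == "T2D":
                name = SUBTYPE_NAMES[truth.subtype[sid]]
                p = probs.get(name, probs.get("t2d", 0.0))
            elif group == "SAID":
                p = probs.get("said", 0.0)
            else:
                p = probs.get("control", 0.0)
            if rng.random() < p:
                rows.append(
                    {
                        "subject_id": sid,
                        "entry": _decorate_entry(drug, list(synonyms.get(drug, [drug])), rng),
                    }
                )
    return pd.DataFrame(rows, columns=["subject_id", "entry"])


def write_synthetic_dataset(params: SimulationParams, out_dir) -> None:
    """Generate the full dataset (clinical, omics, medications, truth) to TSV/JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = generate_cohort(params)
    proteins = generate_omics(truth, params, "protein")
    metabolites = generate_omics(truth, params, "metabolite")
    meds = generate_medications(truth, params)
    table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    proteins.values.to_csv(out / "proteins.tsv", sep="\t", index_label="sample_id")
    proteins.covariates.to_csv(
        out / "technical_covariates.tsv", sep="\t", index_label="sample_id"
    )
    metabolites.values.to_csv(out / "metabolites.tsv", sep="\t", index_label="sample_id")
    meds.to_csv(out / "medications.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(truth.to_json())
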