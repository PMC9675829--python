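"""Cohort status rules and construction of the clinical clustering variables.

Subjects are labelled by a fixed rule set: a subject is diabetic if any of
four conditions holds (physician diagnosis, diabetes medication, HbA1c above
6.5%, or random glucose above 200 mg/dL); diabetic subjects with self-reported
type 1 diabetes or with C-peptide below 0.5 nmol/L while on insulin treatment
are labelled SAID (severe autoimmune diabetes) and all others T2D.
Non-diabetic subjects with HbA1c in the prediabetic band 5.7-6.4% are
excluded, and controls must satisfy all four control conditions (no
diagnosis, no diabetes medication, HbA1c below 5.7%, glucose below
200 mg/dL).  Missing required fields yield an exclusion label rather than an
exception.

The module also houses a pluggable HOMA2 estimator (beta-cell function as a
percentage and insulin resistance as a dimensionless ratio, both from fasting
glucose and C-peptide) and a stratified, seed-deterministic train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StatusLabel",
    "REQUIRED_FIELDS",
    "CLUSTER_FEATURES",
    "SUBTYPE_NAMES",
    "MGDL_PER_MMOL",
    "classify_status",
    "classify_table",
    "Homa2Estimator",
    "ParametricHoma2",
    "PassthroughHoma2",
    "get_homa2_estimator",
    "compute_homa2",
    "split_cohort",
]

#: Glucose unit conversion at the HOMA2 boundary; clinical tables keep mg/dL.
MGDL_PER_MMOL = 18.016

#: Ordered clustering variables of the subtype model.
CLUSTER_FEATURES = ("age_at_diagnosis", "bmi", "hba1c", "homa2_b", "homa2_ir")

#: The four data-driven T2D subtypes.
SUBTYPE_NAMES = ("SIDD", "SIRD", "MOD", "MARD")


class StatusLabel(str, Enum):
    CONTROL = "CONTROL"
    T2D = "T2D"
    SAID = "SAID"
    EXCLUDED_PREDIABETES = "EXCLUDED_PREDIABETES"
    EXCLUDED_GESTATIONAL = "EXCLUDED_GESTATIONAL"
    EXCLUDED_INCOMPLETE = "EXCLUDED_INCOMPLETE"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


#: Fields that must be present and non-missing for a subject to be classifiable.
REQUIRED_FIELDS = (
    "hba1c",
    "random_glucose",
    "c_peptide",
    "flag_physician_diagnosis",
    "flag_diabetes_medication",
    "flag_insulin_treatment",
    "flag_self_report_t1d",
    "flag_gestational",
)


def _missing(value) -> bool:
    if value is None:
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def classify_status(record: Mapping) -> StatusLabel:
    """Assign one status label to a single subject record.

    Evaluation order: incomplete -> gestational -> diabetes (any of the four
    diabetes conditions) -> SAID vs T2D within diabetes -> prediabetes
    exclusion -> control.  Missingness is a label, never an exception.
    """
    for field in REQUIRED_FIELDS:
        if field not in record or _missing(record[field]):
            return StatusLabel.EXCLUDED_INCOMPLETE

    if bool(record["flag_gestational"]):
        return StatusLabel.EXCLUDED_GESTATIONAL

    diabetic = (
        bool(record["flag_physician_diagnosis"])
        or bool(record["flag_diabetes_medication"])
        or record["hba1c"] > 6.5
        or record["random_glucose"] > 200.0
    )
    if diabetic:
        said = bool(record["flag_self_report_t1d"]) or (
            record["c_peptide"] < 0.5 and bool(record["flag_insulin_treatment"])
        )
        return StatusLabel.SAID if said else StatusLabel.T2D

    if 5.7 <= record["hba1c"] <= 6.4:
        return StatusLabel.EXCLUDED_PREDIABETES

    control = (
        not bool(record["flag_physician_diagnosis"])
        and not bool(record["flag_diabetes_medication"])
        and record["hba1c"] < 5.7
        and record["random_glucose"] < 200.0
    )
    if control:
        return StatusLabel.CONTROL
    # Unreachable for finite inputs: the four control conditions are the
    # complement of the diabetes conditions below the prediabetic band.
    return StatusLabel.EXCLUDED_INCOMPLETE


def classify_table(table: pd.DataFrame) -> pd.Series:
    """Vector version of :func:`classify_status`; row order has no effect."""
    labels = [classify_status(row) for row in table.to_dict("records")]
    return pd.Series([str(l) for l in labels], index=table.index, name="status")


# ---------------------------------------------------------------------------
# HOMA2
# ---------------------------------------------------------------------------


class Homa2Estimator(Protocol):
    """Estimator interface: glucose in mmol/L, C-peptide in nmol/L."""

    glucose_range: tuple[float, float]
    c_peptide_range: tuple[float, float]

    def compute(self, glucose: float, c_peptide: float) -> tuple[float, float]:
        """Return ``(homa2_b percent, homa2_ir dimensionless)``."""
        ...


@dataclass(frozen=True)
class ParametricHoma2:
    """Monotone parametric approximation of the HOMA2 computer model.

    Beta-cell function rises with C-peptide and falls with glucose; insulin
    resistance rises with both.  The model is calibrated so that the
    reference input (glucose 5.4 mmol/L, C-peptide 0.55 nmol/L) maps to
    exactly (100 %, 1.0).  Absolute calibration away from the reference is
    approximate and no downstream stage depends on it; externally computed
    indices can be supplied verbatim through :class:`PassthroughHoma2`.
    """

    reference_glucose: float = 5.4
    reference_c_peptide: float = 0.55
    glucose_offset: float = 3.0
    glucose_range: tuple[float, float] = (3.5, 25.0)
    c_peptide_range: tuple[float, float] = (0.2, 3.5)

    def compute(self, glucose: float, c_peptide: float) -> tuple[float, float]:
        g0, c0 = self.reference_glucose, self.reference_c_peptide
        homa2_b = 100.0 * (c_peptide / c0) * (g0 - self.glucose_offset) / (
            glucose - self.glucose_offset
        )
        homa2_ir = (c_peptide / c0) * (glucose / g0)
        return homa2_b, homa2_ir


@dataclass(frozen=True)
class PassthroughHoma2:
    """Accepts externally computed (HOMA2-B, HOMA2-IR) pairs verbatim."""

    glucose_range: tuple[float, float] = (0.0, np.inf)
    c_peptide_range: tuple[float, float] = (0.0, np.inf)

    def compute(self, homa2_b: float, homa2_ir: float) -> tuple[float, float]:
        return homa2_b, homa2_ir


_ESTIMATORS = {"parametric": ParametricHoma2, "passthrough": PassthroughHoma2}


def get_homa2_estimator(name: str) -> Homa2Estimator:
    try:
        return _ESTIMATORS[name]()
    except KeyError:
        raise ValueError(
            f"unknown homa2 estimator {name!r}; known: {sorted(_ESTIMATORS)}"
        ) from None


def compute_homa2(
    glucose: float,
    c_peptide: float,
    estimator: Homa2Estimator | None = None,
) -> tuple[float, float]:
    """Compute (HOMA2-B %, HOMA2-IR) from glucose (mmol/L) and C-peptide (nmol/L).

    Inputs outside the estimator's declared valid range are clamped to the
    range boundary with a warning.
    """
    if estimator is None:
        estimator = ParametricHoma2()
    if not np.isfinite(glucose) or not np.isfinite(c_peptide):
        raise ValueError("glucose and c_peptide must be finite")
    if glucose <= 0 or c_peptide <= 0:
        raise ValueError("glucose and c_peptide must be positive")
    g_lo, g_hi = estimator.glucose_range
    c_lo, c_hi = estimator.c_peptide_range
    g = float(np.clip(glucose, g_lo, g_hi))
    c = float(np.clip(c_peptide, c_lo, c_hi))
    if g != glucose or c != c_peptide:
        warnings.warn(
            f"HOMA2 input clamped to valid range: glucose {glucose}->{g}, "
            f"c_peptide {c_peptide}->{c}",
            stacklevel=2,
        )
    return estimator.compute(g, c)


# ---------------------------------------------------------------------------
# Train / test split
# ---------------------------------------------------------------------------


def split_cohort(
    table: pd.DataFrame,
    fraction: float,
    seed: int,
    stratify_by: str | Sequence[str] = "status",
) -> tuple[list, list]:
    """Disjoint, exhaustive, seed-deterministic split of subject ids.

    Stratified by status label: within each stratum the training share is
    ``round(fraction * n)``, so prevalence matches across the halves to
    within one subject per stratum.  Returns (training ids, testing ids).
    """
    if table.empty:
        raise ValueError("cannot split an empty table")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if isinstance(stratify_by, str):
        strata = table[stratify_by].astype(str)
    else:
        strata = table[list(stratify_by)].astype(str).agg("|".join, axis=1)
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for _, idx in sorted(strata.groupby(strata).groups.items()):
        ids = np.asarray(sorted(idx))
        perm = rng.permutation(len(ids))
        n_train = int(round(fraction * len(ids)))
        train_ids.extend(ids[perm[:n_train]].tolist())
        test_ids.extend(ids[perm[n_train:]].tolist())
    return sorted(train_ids), sorted(test_ids)
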