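"""Omics preprocessing and case-control association models.

Relative-abundance matrices (samples x features, positive values, missing
allowed) are filtered for excess missingness, log-transformed, z-scored per
feature, and winsorized at +/- 5 standard deviations.  Case-control
association then runs one model per feature: logistic regression of disease
status on the feature (protein convention) or linear regression of the
feature on status (metabolite convention), both with covariates, reporting
two-sided Wald p-values with Bonferroni control and a replication
concordance summary across cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "OmicsMatrix",
    "ReplicationSummary",
    "preprocess_features",
    "associate_case_control",
    "bonferroni_threshold",
    "replication_concordance",
]


@dataclass
class OmicsMatrix:
    """Samples x features relative abundances with optional technical covariates.

    Missing entries are NaN in ``values``; ``platform`` is ``"protein"`` or
    ``"metabolite"``; ``covariates`` (if given) is indexed like ``values``.
    """

    values: pd.DataFrame
    platform: str
    covariates: pd.DataFrame | None = None
    processed: bool = False

    def __post_init__(self) -> None:
        if self.platform not in ("protein", "metabolite"):
            raise ValueError(f"unknown platform tag {self.platform!r}")
        if self.covariates is not None and not self.covariates.index.equals(
            self.values.index
        ):
            raise ValueError("covariates index must match sample ids")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns


def preprocess_features(
    matrix: OmicsMatrix,
    max_missing: float = 0.9,
    winsor_sd: float = 5.0,
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Filter, log-transform, z-score, and winsorize an omics matrix.

    Features missing in more than ``max_missing`` of samples are dropped and
    named in the exclusion log.  Non-positive observed values cannot be
    log-transformed and are demoted to missing with a warning.  Remaining
    values are natural-log transformed, z-scored per feature over observed
    entries, and clipped to ``[-winsor_sd, +winsor_sd]``; missing entries
    stay missing.  Returns the processed matrix and the exclusion log
    (columns: feature, reason, missing_fraction).
    """
    values = matrix.values.astype(float).copy()

    nonpos = (values <= 0).to_numpy()
    if nonpos.any():
        bad = values.columns[nonpos.any(axis=0)].tolist()
        warnings.warn(
            f"{int(nonpos.sum())} non-positive observed values treated as "
            f"missing (features: {bad[:5]}{'...' if len(bad) > 5 else ''})",
            stacklevel=2,
        )
        values = values.where(~nonpos)

    missing_frac = values.isna().mean(axis=0)
    excluded = missing_frac[missing_frac > max_missing]
    log = pd.DataFrame(
        {
            "feature": excluded.index,
            "reason": f"missingness > {max_missing:.0%}",
            "missing_fraction": excluded.to_numpy(),
        }
    ).reset_index(drop=True)
    values = values.drop(columns=excluded.index)

    logged = np.log(values)
    z = (logged - logged.mean(axis=0)) / logged.std(axis=0, ddof=1)
    z = z.clip(lower=-winsor_sd, upper=winsor_sd)
    return (
        OmicsMatrix(z, matrix.platform, covariates=matrix.covariates, processed=True),
        log,
    )


def _fit_one(
    y: np.ndarray, X: np.ndarray, model_kind: str, coef_index: int
) -> tuple[float, float, float]:
    """Return (estimate, se, p) for one design column; NaNs on failure."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if model_kind == "logistic":
                res = sm.Logit(y, X).fit(disp=False, maxiter=200)
                if not res.mle_retvals.get("converged", True):
                    return np.nan, np.nan, np.nan
            else:
                res = sm.OLS(y, X).fit()
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return np.nan, np.nan, np.nan
    est = float(res.params[coef_index])
    se = float(res.bse[coef_index])
    p = float(res.pvalues[coef_index])
    if not np.isfinite(est) or not np.isfinite(se) or se > 1e6:
        return np.nan, np.nan, np.nan
    return est, se, p


def associate_case_control(
    matrix: OmicsMatrix,
    status: pd.Series,
    covariates: pd.DataFrame | None = None,
    model_kind: str | None = None,
) -> pd.DataFrame:
    """Per-feature case-control association records.

    ``status`` maps sample id to ``CONTROL``/``T2D`` (other labels are
    dropped).  ``model_kind`` defaults by platform: ``logistic``
    (status ~ feature + covariates) for proteins, ``linear``
    (feature ~ status + covariates) for metabolites.  Rows with a missing
    feature value are excluded per feature (complete case).  Returns a
    DataFrame with columns feature, model, estimate, se, p, n, covariates.
    """
    if model_kind is None:
        model_kind = "logistic" if matrix.platform == "protein" else "linear"
    if model_kind not in ("logistic", "linear"):
        raise ValueError(f"unknown model kind {model_kind!r}")

    status = status.reindex(matrix.sample_ids)
    keep = status.isin(["CONTROL", "T2D"])
    status = status[keep]
    if status.nunique() < 2:
        raise ValueError("status has no contrast (need both CONTROL and T2D)")
    y_status = (status == "T2D").astype(float)

    values = matrix.values.loc[status.index]
    if covariates is None and matrix.covariates is not None:
        covariates = matrix.covariates
    if covariates is not None:
        covariates = covariates.loc[status.index].astype(float)
        if covariates.isna().any().any():
            raise ValueError("covariate columns must be complete for used rows")
        cov_names = list(covariates.columns)
        C = covariates.to_numpy()
    else:
        cov_names = []
        C = np.empty((len(status), 0))

    records = []
    ones = np.ones((len(status), 1))
    for feat in values.columns:
        x = values[feat].to_numpy(dtype=float)
        ok = np.isfinite(x)
        n = int(ok.sum())
        if n < 3 or np.nanstd(x[ok]) == 0:
            est = se = p = np.nan
        elif model_kind == "logistic":
            X = np.column_stack([ones[ok], x[ok], C[ok]])
            est, se, p = _fit_one(y_status.to_numpy()[ok], X, "logistic", 1)
        else:
            X = np.column_stack([ones[ok], y_status.to_numpy()[ok], C[ok]])
            est, se, p = _fit_one(x[ok], X, "linear", 1)
        records.append(
            {
                "feature": feat,
                "model": model_kind,
                "estimate": est,
                "se": se,
                "p": p,
                "n": n,
                "covariates": ",".join(cov_names),
            }
        )
    return pd.DataFrame.from_records(records)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive count")
    return alpha / m


@dataclass
class ReplicationSummary:
    n_tested: int
    n_passing: int
    n_concordant: int
    threshold: float
    table: pd.DataFrame = field(repr=False, default=None)


def replication_concordance(
    primary: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
    primary_threshold: float | None = None,
) -> ReplicationSummary:
    """Replication counting with directional concordance.

    Features significant in the primary cohort (at ``primary_threshold``,
    default Bonferroni over the primary records) and also tested in the
    replication cohort are assessed at ``alpha / n_shared_tested``; effects
    with matching sign count as directionally concordant.
    """
    shared = set(primary["feature"]) & set(replication["feature"])
    if not shared:
        raise ValueError("no shared features between primary and replication")
    if primary_threshold is None:
        primary_threshold = bonferroni_threshold(alpha, len(primary))
    prim = primary.set_index("feature")
    repl = replication.set_index("feature")
    significant = [
        f
        for f in prim.index
        if f in shared and np.isfinite(prim.loc[f, "p"]) and prim.loc[f, "p"] < primary_threshold
    ]
    n_tested = len(significant)
    if n_tested == 0:
        return ReplicationSummary(0, 0, 0, np.nan, pd.DataFrame())
    threshold = bonferroni_threshold(alpha, n_tested)
    rows = []
    for f in significant:
        p_rep = repl.loc[f, "p"]
        concordant = bool(
            np.sign(prim.loc[f, "estimate"]) == np.sign(repl.loc[f, "estimate"])
        )
        rows.append(
            {
                "feature": f,
                "p_primary": prim.loc[f, "p"],
                "p_replication": p_rep,
                "replicated": bool(np.isfinite(p_rep) and p_rep < threshold),
                "concordant": concordant,
            }
        )
    table = pd.DataFrame(rows)
    return ReplicationSummary(
        n_tested=n_tested,
        n_passing=int(table["replicated"].sum()),
        n_concordant=int(table["concordant"].sum()),
        threshold=threshold,
        table=table,
    )
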