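"""Cluster-specific omics signatures.

A feature is declared specific to a subtype iff (1) its mean in that
subtype differs from all other subtypes combined at the Bonferroni level
(0.05 divided by the number of features on the platform) and (2) it differs
from each other subtype in pairwise comparisons at nominal p < 0.05.  All
tests are two-group linear models without covariates over T2D cases only;
SAID and control groups appear in the normalized profile summaries for
reference but enter no test.  The module also computes the variance of
principal components explained by cluster membership and cross-platform
correlations among signature features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .association import OmicsMatrix, bonferroni_threshold
from .cohort import SUBTYPE_NAMES

__all__ = [
    "cluster_specific_features",
    "normalized_cluster_profiles",
    "pc_variance_explained",
    "correlate_signature_features",
]


def _two_group_lm(y: np.ndarray, group: np.ndarray) -> float:
    """Two-sided Wald p for the group coefficient of y ~ 1 + group.

    With a single binary predictor this is the equal-variance two-sample
    t-test; computed in closed form from the OLS normal equations.
    """
    ok = np.isfinite(y)
    y, group = y[ok], group[ok]
    n = len(y)
    n1 = int(group.sum())
    n0 = n - n1
    if n0 < 2 or n1 < 2:
        return np.nan
    X = np.column_stack([np.ones(n), group])
    beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    if sigma2 == 0:
        return np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se
    return float(2.0 * stats.t.sf(abs(t), dof))


def cluster_specific_features(
    matrix: OmicsMatrix,
    assignments: pd.Series,
    alpha: float = 0.05,
    m: int | None = None,
) -> pd.DataFrame:
    """Two-criteria subtype-specific feature selection over T2D cases.

    ``assignments`` maps T2D sample ids to subtype names; samples absent
    from it are ignored.  ``m`` defaults to the number of features on the
    platform.  Returns one record per feature x cluster with the
    one-vs-rest p, the pairwise p against each other cluster, per-cluster
    means, the direction, and the ``specific`` verdict; clusters with fewer
    than two members have their tests flagged missing.
    """
    ids = assignments.index.intersection(matrix.sample_ids)
    assignments = assignments.loc[ids]
    values = matrix.values.loc[ids]
    clusters = [c for c in SUBTYPE_NAMES if c in set(assignments)]
    if m is None:
        m = matrix.values.shape[1]
    threshold = bonferroni_threshold(alpha, m)

    membership = {c: (assignments == c).to_numpy() for c in clusters}
    records = []
    for feat in values.columns:
        y = values[feat].to_numpy(dtype=float)
        for c in clusters:
            in_c = membership[c]
            p_ovr = _two_group_lm(y, in_c.astype(float))
            pairwise = {}
            for other in clusters:
                if other == c:
                    continue
                sel = in_c | membership[other]
                pairwise[other] = _two_group_lm(
                    y[sel], in_c[sel].astype(float)
                )
            mean_c = float(np.nanmean(y[in_c])) if in_c.sum() else np.nan
            mean_rest = float(np.nanmean(y[~in_c])) if (~in_c).sum() else np.nan
            pair_ps = list(pairwise.values())
            specific = bool(
                np.isfinite(p_ovr)
                and p_ovr < threshold
                and all(np.isfinite(p) and p < 0.05 for p in pair_ps)
            )
            rec = {
                "feature": feat,
                "cluster": c,
                "p_one_vs_rest": p_ovr,
                "mean_cluster": mean_c,
                "mean_rest": mean_rest,
                "direction": "up" if mean_c > mean_rest else "down",
                "specific": specific,
            }
            for other in clusters:
                rec[f"p_vs_{other}"] = pairwise.get(other, np.nan)
            records.append(rec)
    out = pd.DataFrame.from_records(records)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["m"] = m
    return out


def normalized_cluster_profiles(
    matrix: OmicsMatrix,
    groups: pd.Series,
    reference_cluster: str,
    features=None,
) -> pd.DataFrame:
    """Group means normalized by the reference subtype's mean, with 95% CIs.

    ``groups`` maps sample id to a group label (the four subtypes plus SAID
    and control reference groups).  For each feature and group the mean and
    the normal-approximation CI (mean +/- 1.96 SE) are divided by the
    reference cluster's mean, so the reference group's normalized mean is
    exactly 1.
    """
    ids = groups.index.intersection(matrix.sample_ids)
    groups = groups.loc[ids]
    values = matrix.values.loc[ids]
    if features is not None:
        values = values.loc[:, list(features)]
    if reference_cluster not in set(groups):
        raise ValueError(f"reference cluster {reference_cluster!r} is empty")
    rows = []
    for feat in values.columns:
        y = values[feat]
        ref = y[groups == reference_cluster].dropna()
        ref_mean = float(ref.mean())
        if ref_mean == 0:
            raise ValueError(f"reference mean is zero for feature {feat!r}")
        for g in groups.unique():
            obs = y[groups == g].dropna()
            mean = float(obs.mean()) if len(obs) else np.nan
            se = float(obs.std(ddof=1) / np.sqrt(len(obs))) if len(obs) > 1 else 0.0
            rows.append(
                {
                    "feature": feat,
                    "group": g,
                    "n": len(obs),
                    "normalized_mean": mean / ref_mean,
                    "ci_low": (mean - 1.96 * se) / ref_mean,
                    "ci_high": (mean + 1.96 * se) / ref_mean,
                    "reference": reference_cluster,
                }
            )
    return pd.DataFrame(rows)


def pc_variance_explained(
    matrix: OmicsMatrix,
    assignments: pd.Series,
    n_components: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Variance of each principal component explained by cluster membership.

    PCA over T2D cases (missing entries mean-filled for the decomposition
    only); each component's scores are regressed on cluster-membership
    indicators and the R-squared is reported.
    """
    ids = assignments.index.intersection(matrix.sample_ids)
    assignments = assignments.loc[ids]
    values = matrix.values.loc[ids]
    filled = values.fillna(values.mean(axis=0)).to_numpy()
    rank = min(filled.shape)
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds rank {rank}")
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(filled)
    dummies = pd.get_dummies(assignments, dtype=float).to_numpy()
    X = np.column_stack([np.ones(len(ids)), dummies[:, 1:]])
    r2 = []
    for j in range(n_components):
        y = scores[:, j]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        r2.append(1.0 - float(resid @ resid) / tss if tss > 0 else 0.0)
    return pd.DataFrame(
        {
            "component": np.arange(1, n_components + 1),
            "r_squared": r2,
            "explained_variance_ratio": pca.explained_variance_ratio_,
        }
    )


def correlate_signature_features(
    proteins: OmicsMatrix,
    metabolites: OmicsMatrix,
    protein_ids,
    metabolite_ids,
    sample_ids=None,
) -> pd.DataFrame:
    """Pearson correlations between cluster-specific proteins and metabolites.

    Computed over the shared (typically T2D-case) samples; each pair gets a
    correlation coefficient and a two-sided p-value over pairwise-complete
    observations.
    """
    shared = proteins.sample_ids.intersection(metabolites.sample_ids)
    if sample_ids is not None:
        shared = shared.intersection(pd.Index(sample_ids))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    P = proteins.values.loc[shared, list(protein_ids)]
    M = metabolites.values.loc[shared, list(metabolite_ids)]
    rows = []
    for p in P.columns:
        for m in M.columns:
            pair = pd.concat([P[p], M[m]], axis=1).dropna()
            if len(pair) < 3:
                r, pv = np.nan, np.nan
            else:
                r, pv = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append(
                {"protein": p, "metabolite": m, "r": float(r), "p": float(pv),
                 "n": len(pair)}
            )
    return pd.DataFrame(rows)
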