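"""Four-cluster subtype model: fit, select, label, stabilize, transfer.

k-means on the five standardized clinical variables (age at diagnosis, BMI,
HbA1c, HOMA2-B, HOMA2-IR) yields the SIDD/SIRD/MOD/MARD subtype model.  The
module covers the number-of-clusters vote (Gaussian-mixture BIC plus a panel
of cluster-validity indices), clusterwise bootstrap Jaccard stability,
nearest-center transfer classification across cohorts and sexes, fasting-time
correction of the HOMA2 indices, partition comparison after optimal label
matching, and confounder sensitivity re-clustering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.mixture import GaussianMixture

from .cohort import CLUSTER_FEATURES, SUBTYPE_NAMES

__all__ = [
    "StandardizationParams",
    "ClusterModel",
    "StabilityResult",
    "SUBTYPE_PROTOTYPES",
    "standardize",
    "apply_standardization",
    "fit_cluster_model",
    "select_k",
    "assign_by_centers",
    "label_clusters",
    "jaccard_stability",
    "correct_for_fasting",
    "transfer_centers",
    "compare_partitions",
    "confounder_sensitivity",
]


@dataclass(frozen=True)
class StandardizationParams:
    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray


@dataclass
class ClusterModel:
    """A fitted k-means subtype model in standardized 5-variable space."""

    feature_names: tuple[str, ...]
    standardization: StandardizationParams
    centers: np.ndarray
    k: int
    label_map: dict[int, str] = field(default_factory=dict)
    fit_meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "standardization": {
                    "means": self.standardization.means.tolist(),
                    "sds": self.standardization.sds.tolist(),
                },
                "centers": self.centers.tolist(),
                "k": self.k,
                "label_map": {str(i): v for i, v in self.label_map.items()},
                "fit_meta": self.fit_meta,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        d = json.loads(text)
        names = tuple(d["feature_names"])
        return cls(
            feature_names=names,
            standardization=StandardizationParams(
                names,
                np.asarray(d["standardization"]["means"], dtype=float),
                np.asarray(d["standardization"]["sds"], dtype=float),
            ),
            centers=np.asarray(d["centers"], dtype=float),
            k=int(d["k"]),
            label_map={int(i): v for i, v in d["label_map"].items()},
            fit_meta=d.get("fit_meta", {}),
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "ClusterModel":
        return cls.from_json(Path(path).read_text())


@dataclass
class StabilityResult:
    per_cluster_jaccard: np.ndarray
    n_reruns: int
    scheme: str = "bootstrap"

    @property
    def min_jaccard(self) -> float:
        return float(np.min(self.per_cluster_jaccard))


def standardize(
    table: pd.DataFrame,
    fit_ids=None,
    features: tuple[str, ...] = CLUSTER_FEATURES,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Center to mean 0, SD 1 on the fit subset; params kept for reuse.

    Returns the standardized matrix over *all* rows of ``table`` together
    with the fit-subset moments, so held-out subjects can be mapped into the
    same space.
    """
    if fit_ids is None:
        fit_ids = table.index
    fit_ids = list(fit_ids)
    if not fit_ids:
        raise ValueError("fit_ids must be nonempty")
    X = table.loc[:, list(features)].astype(float)
    fit = X.loc[fit_ids]
    means = fit.mean(axis=0).to_numpy()
    sds = fit.std(axis=0, ddof=0).to_numpy()
    zero = np.asarray(features)[sds == 0]
    if zero.size:
        raise ValueError(f"zero-variance column(s): {', '.join(zero)}")
    params = StandardizationParams(tuple(features), means, sds)
    return apply_standardization(X, params), params


def apply_standardization(
    table: pd.DataFrame, params: StandardizationParams
) -> pd.DataFrame:
    X = table.loc[:, list(params.feature_names)].astype(float)
    return (X - params.means) / params.sds


def fit_cluster_model(
    X_std: pd.DataFrame,
    k: int = 4,
    restarts: int = 100,
    seed: int = 0,
    standardization: StandardizationParams | None = None,
) -> ClusterModel:
    """Best-inertia k-means over ``restarts`` seeded initializations.

    ``X_std`` must already be standardized (SAID rows excluded upstream).
    When ``k`` is 4 the clusters are labelled with the subtype names.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(X_std) < k:
        raise ValueError(f"need at least k={k} rows, got {len(X_std)}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(
        X_std.to_numpy()
    )
    if standardization is None:
        standardization = StandardizationParams(
            tuple(X_std.columns), np.zeros(X_std.shape[1]), np.ones(X_std.shape[1])
        )
    model = ClusterModel(
        feature_names=tuple(X_std.columns),
        standardization=standardization,
        centers=km.cluster_centers_.copy(),
        k=k,
        fit_meta={"restarts": restarts, "seed": seed, "inertia": float(km.inertia_)},
    )
    if k == 4:
        model.label_map = label_clusters(model)
    return model


# ---------------------------------------------------------------------------
# Number-of-clusters vote
# ---------------------------------------------------------------------------


def _elbow_k(ks: list[int], inertias: list[float]) -> int:
    """Within-SS elbow: the interior k with maximal discrete curvature."""
    if len(ks) < 3:
        return ks[0]
    w = np.asarray(inertias, dtype=float)
    curvature = w[:-2] - 2 * w[1:-1] + w[2:]
    return ks[1 + int(np.argmax(curvature))]


def select_k(
    X_std: pd.DataFrame,
    k_range=range(2, 16),
    seed: int = 0,
    restarts: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Majority vote over BIC and cluster-validity indices; ties to smaller k.

    Panel: BIC of full-covariance Gaussian-mixture fits (lowest wins),
    silhouette (highest), Calinski-Harabasz (highest), Davies-Bouldin
    (lowest), and the within-SS elbow.  Returns the winning k and the full
    per-criterion table.
    """
    ks = sorted(k_range)
    if not ks or ks[0] < 2 or ks[-1] > 15:
        raise ValueError("k_range must lie within [2, 15]")
    X = X_std.to_numpy()
    if len(X) <= ks[-1]:
        raise ValueError("too few rows for the requested k range")

    rows = []
    inertias = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        labels = km.labels_
        inertias.append(float(km.inertia_))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=2,
                random_state=seed,
                reg_covar=1e-5,
            ).fit(X)
        rows.append(
            {
                "k": k,
                "bic": float(gm.bic(X)),
                "silhouette": float(silhouette_score(X, labels)),
                "calinski_harabasz": float(calinski_harabasz_score(X, labels)),
                "davies_bouldin": float(davies_bouldin_score(X, labels)),
                "inertia": inertias[-1],
            }
        )
    table = pd.DataFrame(rows).set_index("k")

    votes = {
        "bic": int(table["bic"].idxmin()),
        "silhouette": int(table["silhouette"].idxmax()),
        "calinski_harabasz": int(table["calinski_harabasz"].idxmax()),
        "davies_bouldin": int(table["davies_bouldin"].idxmin()),
        "elbow": _elbow_k(ks, inertias),
    }
    counts = pd.Series(list(votes.values())).value_counts()
    best = counts.max()
    chosen = min(int(k) for k, c in counts.items() if c == best)
    table["vote"] = [sum(1 for v in votes.values() if v == k) for k in table.index]
    table.attrs["votes"] = votes
    return chosen, table


# ---------------------------------------------------------------------------
# Assignment and labelling
# ---------------------------------------------------------------------------


def assign_by_centers(X_std: pd.DataFrame, model: ClusterModel) -> pd.DataFrame:
    """Nearest-center assignment; ties broken by lowest cluster index.

    Returns a table with cluster index, subtype label, own-center distance,
    and the distance to every center.
    """
    X = X_std.to_numpy(dtype=float)
    if X.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {X.shape[1]} columns, "
            f"centers have {model.centers.shape[1]}"
        )
    d = np.linalg.norm(X[:, None, :] - model.centers[None, :, :], axis=2)
    cluster = d.argmin(axis=1)  # argmin takes the lowest index on ties
    out = pd.DataFrame(index=X_std.index)
    out["cluster"] = cluster
    out["subtype"] = [model.label_map.get(int(c), str(c)) for c in cluster]
    out["distance"] = d[np.arange(len(X)), cluster]
    for j in range(model.k):
        out[f"dist_{j}"] = d[:, j]
    return out


#: Prototype center sign patterns used to name the four clusters, in the
#: CLUSTER_FEATURES order (age at diagnosis, BMI, HbA1c, HOMA2-B, HOMA2-IR).
SUBTYPE_PROTOTYPES = pd.DataFrame(
    [
        [-0.5, -0.5, 1.0, -1.0, 0.0],  # SIDD: poor control, low beta-cell function
        [0.0, 0.5, 0.0, 0.0, 1.0],  # SIRD: insulin resistant, high BMI
        [-1.0, 1.0, 0.0, 0.0, 0.0],  # MOD: obese, young onset
        [1.0, 0.0, -0.5, 0.0, -0.5],  # MARD: late onset, mild
    ],
    index=list(SUBTYPE_NAMES),
    columns=list(CLUSTER_FEATURES),
)


def label_clusters(model: ClusterModel) -> dict[int, str]:
    """Bijectively name the 4 clusters by optimal match to prototype patterns.

    The total inner product between center coordinates and prototype sign
    patterns is maximized over one-to-one matchings (Hungarian algorithm),
    making the naming equivariant under center permutations.
    """
    if model.k != 4:
        raise ValueError("subtype labelling requires k = 4")
    proto = SUBTYPE_PROTOTYPES.loc[:, list(model.feature_names)].to_numpy()
    score = model.centers @ proto.T  # clusters x prototypes
    rows, cols = linear_sum_assignment(-score)
    return {int(r): SUBTYPE_NAMES[int(c)] for r, c in zip(rows, cols)}


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------


def jaccard_stability(
    X_std: pd.DataFrame,
    model: ClusterModel,
    n_reruns: int = 500,
    seed: int = 0,
    restarts: int = 10,
) -> StabilityResult:
    """Clusterwise bootstrap Jaccard stability of a k-means solution.

    Each re-run resamples rows with replacement, refits k-means, and records
    for each original cluster the maximum Jaccard similarity over the new
    clusters; similarities are computed over subject-id sets restricted to
    the resampled ids.  Per-cluster means over re-runs are reported.
    """
    if n_reruns < 1:
        raise ValueError("n_reruns must be >= 1")
    rng = np.random.default_rng(seed)
    X = X_std.to_numpy()
    base = assign_by_centers(X_std, model)["cluster"].to_numpy()
    n = len(X)
    sums = np.zeros(model.k)
    for r in range(n_reruns):
        idx = rng.integers(0, n, size=n)
        uniq = np.unique(idx)
        km = KMeans(
            n_clusters=model.k,
            n_init=restarts,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X[idx])
        new = km.predict(X[uniq])
        orig = base[uniq]
        for c in range(model.k):
            a = orig == c
            if not a.any():
                sums[c] += 0.0
                continue
            best = 0.0
            for c2 in range(model.k):
                b = new == c2
                inter = np.count_nonzero(a & b)
                union = np.count_nonzero(a | b)
                if union and inter / union > best:
                    best = inter / union
            sums[c] += best
    return StabilityResult(sums / n_reruns, n_reruns)


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------


def correct_for_fasting(
    table: pd.DataFrame,
    reference_minutes: float = 480.0,
    columns: tuple[str, ...] = ("homa2_b", "homa2_ir"),
    fasting_col: str = "fasting_minutes",
) -> pd.DataFrame:
    """Project HOMA2 indices to a common fasting time by linear regression.

    Each column is regressed on fasting minutes over the given rows and
    replaced by residual + prediction at ``reference_minutes`` (480 min, the
    8-hour fasting convention).  A constant fasting column leaves the data
    unchanged with a warning.
    """
    out = table.copy()
    t = table[fasting_col].astype(float)
    if np.ptp(t.to_numpy()) == 0:
        warnings.warn(
            "fasting_minutes is constant; fasting correction is a no-op",
            stacklevel=2,
        )
        return out
    for col in columns:
        y = table[col].astype(float)
        res = stats.linregress(t, y)
        out[col] = y - (res.intercept + res.slope * t) + (
            res.intercept + res.slope * reference_minutes
        )
    return out


def transfer_centers(
    table: pd.DataFrame,
    external_centers,
    standardization: StandardizationParams,
    sex: pd.Series | None = None,
    label_maps=None,
) -> pd.DataFrame:
    """Classify subjects with externally supplied cluster centers.

    ``external_centers`` is either a single k x 5 array (sex-pooled) or a
    mapping sex -> k x 5 array.  The receiving cohort's standardization
    params are applied before nearest-center assignment.
    """
    X_std = apply_standardization(table, standardization)
    if isinstance(external_centers, dict):
        if sex is None:
            raise ValueError("sex column required with sex-specific centers")
        parts = []
        for s, centers in external_centers.items():
            ids = sex.index[sex == s].intersection(X_std.index)
            if ids.empty:
                continue
            model = ClusterModel(
                feature_names=standardization.feature_names,
                standardization=standardization,
                centers=np.asarray(centers, dtype=float),
                k=len(centers),
                label_map=(label_maps or {}).get(s, {}),
            )
            parts.append(assign_by_centers(X_std.loc[ids], model))
        missing = X_std.index.difference(
            pd.Index(np.concatenate([p.index for p in parts])) if parts else pd.Index([])
        )
        if len(missing):
            raise ValueError(f"{len(missing)} subjects have no matching sex centers")
        return pd.concat(parts).loc[X_std.index]
    model = ClusterModel(
        feature_names=standardization.feature_names,
        standardization=standardization,
        centers=np.asarray(external_centers, dtype=float),
        k=len(external_centers),
        label_map=label_maps or {},
    )
    return assign_by_centers(X_std, model)


def compare_partitions(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    """(percent agreement after optimal label matching, adjusted Rand index).

    Percent agreement is maximized over one-to-one matchings of b's labels
    onto a's via the contingency table; both partitions must cover the same
    subject ids.
    """
    if set(a.index) != set(b.index):
        raise ValueError("partitions must cover the same subject ids")
    b = b.reindex(a.index)
    ct = pd.crosstab(a, b)
    # pad to square for one-to-one matching
    n_rows, n_cols = ct.shape
    m = max(n_rows, n_cols)
    padded = np.zeros((m, m))
    padded[:n_rows, :n_cols] = ct.to_numpy()
    rows, cols = linear_sum_assignment(-padded)
    agreement = 100.0 * padded[rows, cols].sum() / len(a)
    ari = float(adjusted_rand_score(a.to_numpy().astype(str), b.to_numpy().astype(str)))
    return float(agreement), ari


def confounder_sensitivity(
    table: pd.DataFrame,
    assignments: pd.Series,
    confounders: dict[str, str],
    alpha: float = 0.05,
    features: tuple[str, ...] = CLUSTER_FEATURES,
    seed: int = 0,
    restarts: int = 100,
) -> dict:
    """Test confounder association with clusters and re-cluster after correction.

    ``confounders`` maps column name -> 'categorical' | 'continuous'.  Each
    confounder is tested against cluster membership (chi-square or one-way
    ANOVA); the five clustering variables are residualized on the
    significant confounders, re-standardized and re-clustered; the result
    reports per-confounder p-values, assignment agreement with the original
    partition, and the post-correction across-cluster ANOVA p of each
    clustering variable.
    """
    sub = table.loc[assignments.index]
    assoc_p: dict[str, float] = {}
    for col, kind in confounders.items():
        x = sub[col]
        if kind == "categorical":
            if x.nunique() < 2:
                raise ValueError(f"confounder {col!r} has a single level")
            ct = pd.crosstab(x, assignments)
            assoc_p[col] = float(stats.chi2_contingency(ct)[1])
        elif kind == "continuous":
            groups = [x[assignments == c].astype(float) for c in assignments.unique()]
            assoc_p[col] = float(stats.f_oneway(*groups)[1])
        else:
            raise ValueError(f"unknown confounder kind {kind!r}")

    significant = [c for c, p in assoc_p.items() if p < alpha]
    corrected = sub.loc[:, list(features)].astype(float).copy()
    if significant:
        design = pd.get_dummies(
            sub[significant], drop_first=True, dtype=float
        )
        design.insert(0, "const", 1.0)
        D = design.to_numpy()
        for f in features:
            y = corrected[f].to_numpy()
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            corrected[f] = y - D @ beta + y.mean()

    X_std, params = standardize(corrected)
    model = fit_cluster_model(X_std, k=4, restarts=restarts, seed=seed,
                              standardization=params)
    new = assign_by_centers(X_std, model)["cluster"]
    agreement, ari = compare_partitions(assignments.astype(str), new.astype(str))

    post_p = {}
    for f in features:
        groups = [
            corrected[f][new == c].to_numpy() for c in sorted(new.unique())
        ]
        post_p[f] = float(stats.f_oneway(*groups)[1])
    return {
        "association_p": assoc_p,
        "significant_confounders": significant,
        "agreement_percent": agreement,
        "ari": ari,
        "post_correction_anova_p": post_p,
    }
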