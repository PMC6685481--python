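"""Mapping objective measures to perceptual ratings.

Implements the statistical battery relating a sounds x measures table to
per-sound perceptual ratings (Complexity, Pleasantness, Familiarity on
7-point scales; Accuracy of Naming as a proportion):

* percept inter-correlation with a redundancy flag (a percept highly
  correlated with two or more others carries little independent
  variance and is recommended for exclusion, as Familiarity typically is);
* simple and within-domain multiple OLS regressions of percepts on
  salient measures;
* one-way ANOVAs across sound-source categories with Brown-Forsythe
  heteroskedasticity checks and Tukey HSD post-hoc pairs, plus a tally of
  significant pairs across ANOVAs;
* PCA of the measure table (standardized, deterministic sign convention);
* agglomerative hierarchical clustering (Euclidean distance, Ward
  linkage) cut at several levels, with percept ANOVAs across clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
import statsmodels.api as sm

from .salience import CorrelationMatrix, FeatureTable, pearson_matrix

__all__ = [
    "PERCEPTS",
    "RatingsTable",
    "RegressionResult",
    "AnovaResult",
    "PCAResult",
    "ClusterAssignment",
    "CollinearPredictorsError",
    "percept_intercorrelation",
    "simple_regressions",
    "multiple_regression",
    "category_anova",
    "homogeneity_tally",
    "pca",
    "ahc_ward",
    "cluster_percept_comparison",
]

PERCEPTS = ("complexity", "pleasantness", "familiarity", "accuracy")
#: Percepts retained after the familiarity-redundancy exclusion.
CORE_PERCEPTS = ("complexity", "pleasantness", "accuracy")


class CollinearPredictorsError(ValueError):
    """Predictor matrix is ill-conditioned beyond the tolerance."""


@dataclass
class RatingsTable:
    """Per-sound mean ratings: Likert means in [1,7], accuracy in [0,1]."""

    data: pd.DataFrame

    def validate(self) -> None:
        for col in ("complexity", "pleasantness", "familiarity"):
            if col in self.data:
                v = self.data[col].dropna()
                if ((v < 1) | (v > 7)).any():
                    raise ValueError(f"{col} means outside [1, 7]")
        if "accuracy" in self.data:
            v = self.data["accuracy"].dropna()
            if ((v < 0) | (v > 1)).any():
                raise ValueError("accuracy outside [0, 1]")

    def to_csv(self, path_or_buf) -> None:
        self.data.to_csv(path_or_buf, index_label="sound_id")

    @classmethod
    def from_csv(cls, path_or_buf) -> "RatingsTable":
        df = pd.read_csv(path_or_buf, index_col="sound_id")
        df.index = df.index.astype(str)
        return cls(df)


@dataclass
class RegressionResult:
    response: str
    predictors: list[str]
    r: float | None  # simple regressions only
    r_squared: float
    p: float
    coefficients: dict[str, float]  # includes "intercept"
    n: int
    coef_se: dict[str, float] | None = None


@dataclass
class AnovaResult:
    """One-way ANOVA with Brown-Forsythe check and Tukey HSD pairs."""

    grouping: str
    response: str
    f: float
    p: float
    brown_forsythe_p: float
    tukey: pd.DataFrame  # columns: group_a, group_b, diff, p_adj, significant
    significant_pairs: int
    alpha: float
    groups_used: list[str]
    dropped_groups: list[str] = field(default_factory=list)
    unreliable: bool = False  # Brown-Forsythe rejected at alpha


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # measures x components, orthonormal columns
    scores: pd.DataFrame  # sounds x components
    explained: np.ndarray  # variance fractions, nonincreasing


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sound_id -> 1..k
    k: int
    linkage_matrix: np.ndarray
    feature_space: str  # e.g. "raw:spectral" or "pca:temporal"
    method: str = "ward"
    metric: str = "euclidean"


def percept_intercorrelation(ratings: RatingsTable,
                             redundancy_r: float = 0.7
                             ) -> tuple[CorrelationMatrix, list[str]]:
    """Pearson matrix over the percept columns plus drop recommendations.

    A percept correlated at |r| >= ``redundancy_r`` with two or more other
    percepts is flagged as redundant (it contributes the least independent
    variation).
    """
    cols = [c for c in PERCEPTS if c in ratings.data.columns]
    if len(ratings.data) < 3:
        raise ValueError("need at least 3 sounds")
    corr = pearson_matrix(ratings.data[cols])
    flags = []
    for c in cols:
        partners = [o for o in cols if o != c
                    and abs(corr.r.loc[c, o]) >= redundancy_r]
        if len(partners) >= 2:
            flags.append(c)
    return corr, flags


def _join(features: pd.DataFrame, ratings: pd.DataFrame) -> pd.DataFrame:
    joined = features.join(ratings, how="inner")
    if joined.empty:
        raise ValueError("no sounds shared between features and ratings")
    return joined


def simple_regressions(features: FeatureTable | pd.DataFrame,
                       ratings: RatingsTable,
                       measures: list[str] | None = None,
                       percepts: tuple = CORE_PERCEPTS) -> pd.DataFrame:
    """Per-(measure, percept) Pearson r and p, long-format table.

    One row per pair with columns measure, domain, percept, r, p, n;
    pivot on (measure, percept) to obtain the familiar correlation-matrix
    layout of measures against percepts.
    """
    fdf = features.data if isinstance(features, FeatureTable) else features
    domains = features.domains if isinstance(features, FeatureTable) else {}
    if measures is None:
        measures = list(fdf.columns)
    rows = []
    for m in measures:
        for pct in percepts:
            pair = _join(fdf[[m]], ratings.data[[pct]]).dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 joined rows for {m}/{pct}")
            res = stats.linregress(pair[m], pair[pct])
            rows.append({"measure": m, "domain": domains.get(m, ""),
                         "percept": pct, "r": res.rvalue,
                         "p": res.pvalue, "slope": res.slope,
                         "intercept": res.intercept, "n": len(pair)})
    return pd.DataFrame(rows)


def multiple_regression(features: FeatureTable | pd.DataFrame,
                        predictors: list[str], ratings: RatingsTable,
                        percept: str, enforce_same_domain: bool = True,
                        cond_threshold: float = 1e8) -> RegressionResult:
    """OLS of one percept on a set of measures (with intercept).

    Predictors must share a domain unless ``enforce_same_domain`` is off
    (temporal and spectral information are analyzed separately).  An
    ill-conditioned standardized design raises
    :class:`CollinearPredictorsError`.
    """
    fdf = features.data if isinstance(features, FeatureTable) else features
    if isinstance(features, FeatureTable) and enforce_same_domain:
        doms = {features.domains[p] for p in predictors}
        if len(doms) > 1:
            raise ValueError(
                f"predictors span domains {sorted(doms)}; pass "
                "enforce_same_domain=False to combine them")
    joined = _join(fdf[predictors], ratings.data[[percept]]).dropna()
    if len(joined) <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    x = joined[predictors].to_numpy()
    xs = (x - x.mean(0)) / x.std(0)
    if np.linalg.cond(xs) > cond_threshold:
        raise CollinearPredictorsError(
            f"predictors {predictors} are collinear")
    model = sm.OLS(joined[percept].to_numpy(), sm.add_constant(x)).fit()
    coefs = {"intercept": float(model.params[0])}
    coefs.update({p: float(b) for p, b in zip(predictors, model.params[1:])})
    ses = {"intercept": float(model.bse[0])}
    ses.update({p: float(s) for p, s in zip(predictors, model.bse[1:])})
    return RegressionResult(
        response=percept, predictors=list(predictors), r=None,
        r_squared=float(model.rsquared), p=float(model.f_pvalue),
        coefficients=coefs, n=len(joined), coef_se=ses)


def _anova_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA robust to the all-identical degenerate case."""
    grand = np.concatenate(groups)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ss_between <= 1e-300:
        return 0.0, 1.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def category_anova(values: pd.Series, categories: pd.Series,
                   alpha: float = 0.05,
                   response_name: str = "value",
                   grouping_name: str = "category") -> AnovaResult:
    """One-way ANOVA across categories with Tukey HSD post-hoc pairs.

    Categories with fewer than 2 members are dropped with a warning;
    heteroskedasticity is checked with the Brown-Forsythe (median-centred
    Levene) test and, when it rejects at ``alpha``, the result is stamped
    unreliable but still reported.
    """
    df = pd.DataFrame({"value": values, "group": categories}).dropna()
    sizes = df.groupby("group", observed=True).size()
    dropped = sorted(sizes[sizes < 2].index.astype(str))
    if dropped:
        warnings.warn(f"dropping undersized group(s): {dropped}",
                      stacklevel=2)
    usable = sorted(sizes[sizes >= 2].index.astype(str))
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable groups")
    groups = [df.loc[df["group"].astype(str) == g, "value"].to_numpy()
              for g in usable]
    f, p = _anova_f(groups)
    if all(np.ptp(g) == 0 for g in groups):
        bf_p = 1.0  # no within-group spread anywhere: variances equal
    else:
        bf_p = float(stats.levene(*groups, center="median").pvalue)
    pair_index = list(combinations(range(len(usable)), 2))
    means = [g.mean() for g in groups]
    diffs = [means[j] - means[i] for i, j in pair_index]
    if all(np.ptp(g) == 0 for g in groups) and f == 0.0:
        p_adj = [1.0] * len(pair_index)
    else:
        # Tukey-Kramer: studentized range of pairwise means over the
        # pooled within-group error; p via the fast table approximation
        from statsmodels.stats.libqsturng import psturng

        n_tot = sum(len(g) for g in groups)
        df_err = n_tot - len(groups)
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_err
        p_adj = []
        for (i, j), d in zip(pair_index, diffs):
            se = np.sqrt(mse / 2 * (1 / len(groups[i]) + 1 / len(groups[j])))
            if se == 0:
                p_adj.append(0.0 if d != 0 else 1.0)
                continue
            q = abs(d) / se
            p = psturng(q, len(groups), df_err)
            p_adj.append(float(np.atleast_1d(p)[0]))
    rows = []
    for (i, j), d, padj in zip(pair_index, diffs, p_adj):
        rows.append({"group_a": usable[i], "group_b": usable[j],
                     "diff": d, "p_adj": padj,
                     "significant": bool(padj < alpha)})
    tukey = pd.DataFrame(rows,
                         columns=["group_a", "group_b", "diff", "p_adj",
                                  "significant"])
    return AnovaResult(
        grouping=grouping_name, response=response_name, f=f, p=p,
        brown_forsythe_p=bf_p, tukey=tukey,
        significant_pairs=int(tukey["significant"].sum()), alpha=alpha,
        groups_used=usable, dropped_groups=dropped,
        unreliable=bool(bf_p < alpha))


def homogeneity_tally(results: list[AnovaResult], k: int) -> dict:
    """Sum significant Tukey pairs across ANOVAs sharing k groups.

    Reports observed and possible pair counts and their ratio — a
    descriptive summary of whether the groups differ more than they
    agree (a ratio near or above one half would mean mostly differences).
    """
    observed = sum(r.significant_pairs for r in results)
    possible = len(results) * k * (k - 1) // 2
    return {"observed": observed, "possible": possible,
            "ratio": observed / possible if possible else 0.0}


def pca(features: FeatureTable | pd.DataFrame,
        domain: str | None = None, standardize: bool = True,
        n_components: int | None = None) -> PCAResult:
    """PCA of the measure table with a deterministic sign convention.

    With ``standardize`` (default) the correlation matrix is decomposed;
    otherwise the covariance matrix.  Each loading vector is flipped so
    its largest-magnitude element is positive, making biplots
    reproducible.
    """
    if isinstance(features, FeatureTable):
        cols = (features.columns_in_domain(domain) if domain
                else list(features.data.columns))
        df = features.data[cols]
    else:
        df = features
    df = df.dropna()
    if df.shape[1] < 2:
        raise ValueError("need at least 2 measures")
    if df.shape[0] <= df.shape[1]:
        raise ValueError("need more sounds than measures")
    x = df.to_numpy(dtype=float)
    x = x - x.mean(0)
    sd = x.std(0, ddof=1)
    if np.any(sd == 0):
        bad = df.columns[sd == 0].tolist()
        raise ValueError(f"constant column(s): {bad}")
    if standardize:
        x = x / sd
    from sklearn.decomposition import PCA as _PCA

    k = n_components or df.shape[1]
    fit = _PCA(n_components=k, svd_solver="full").fit(x)
    loadings = fit.components_.T.copy()  # measures x components
    scores = fit.transform(x)
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=df.columns,
                              columns=comp_names),
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        explained=fit.explained_variance_ratio_.copy())


def ahc_ward(data: pd.DataFrame, k: int,
             standardize: bool = True,
             feature_space: str = "raw") -> ClusterAssignment:
    """Ward minimum-variance clustering on Euclidean distances, cut at k.

    Measures are standardized before distance computation by default
    (they live on wildly different scales).
    """
    df = data.dropna()
    n = len(df)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, n={n}]")
    x = df.to_numpy(dtype=float)
    if standardize:
        sd = x.std(0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(0)) / sd
    z = linkage(x, method="ward", metric="euclidean")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=df.index, name="cluster"),
        k=k, linkage_matrix=z, feature_space=feature_space)


def cluster_percept_comparison(features: FeatureTable, ratings: RatingsTable,
                               domain: str, levels: list[int],
                               use_pca: bool = False,
                               percepts: tuple = CORE_PERCEPTS,
                               alpha: float = 0.05,
                               min_cluster_size: int = 3,
                               force_include_small: bool = False) -> dict:
    """Cluster on one domain's measures and test percepts across clusters.

    For each level k the sounds are Ward-clustered on the domain's raw
    measures (or their first two PC scores when ``use_pca``), then each
    percept is compared across clusters by one-way ANOVA with Tukey pairs.
    Clusters smaller than ``min_cluster_size`` are excluded from the
    ANOVAs (reported in the result) unless ``force_include_small``; a
    level where fewer than 2 clusters remain is reported with a warning
    and no ANOVA.
    """
    cols = features.columns_in_domain(domain)
    if not cols:
        raise ValueError(f"no measures in domain {domain!r}")
    base = features.data[cols].dropna()
    joined_ids = base.index.intersection(ratings.data.index)
    if joined_ids.empty:
        raise ValueError("no sounds shared between features and ratings")
    base = base.loc[joined_ids]
    if use_pca:
        res = pca(base)
        space = res.scores[["PC1", "PC2"]]
        space_name = f"pca:{domain}"
    else:
        space = base
        space_name = f"raw:{domain}"
    out = {}
    for k in levels:
        if k > len(space):
            warnings.warn(f"level k={k} exceeds n={len(space)}; skipped",
                          stacklevel=2)
            continue
        assign = ahc_ward(space, k, feature_space=space_name)
        sizes = assign.labels.value_counts()
        small = sorted(sizes[sizes < min_cluster_size].index)
        use = assign.labels if force_include_small else \
            assign.labels[~assign.labels.isin(small)]
        entry = {"assignment": assign, "small_clusters": small,
                 "anova": {}}
        if use.nunique() < 2:
            warnings.warn(
                f"level k={k}: fewer than 2 usable clusters; ANOVA skipped",
                stacklevel=2)
            out[k] = entry
            continue
        for pct in percepts:
            vals = ratings.data.loc[use.index, pct]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                entry["anova"][pct] = category_anova(
                    vals, use.astype(str), alpha=alpha, response_name=pct,
                    grouping_name=f"cluster@{k}")
        out[k] = entry
    return out
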