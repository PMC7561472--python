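"""Unsupervised analyses of blastomere records: the high/low N/C YAP
threshold, hierarchical clustering into inside-like / outside-like /
undefined states, Spearman correlation matrices and gated group tests.

Conventions follow standard practice for this kind of morphometric data:
variables are z-scored before any Euclidean distance is computed, cluster
count comes from a minimum-cluster-size (dynamic-tree-cut style) cut of the
Ward dendrogram with a deterministic fallback to k = 3, and omnibus group
comparisons are gated per group by Shapiro-Wilk normality (ANOVA + Tukey HSD
when every group passes, Kruskal-Wallis + Dunn otherwise).
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CLUSTER_VARIABLES = ("nc_yap", "prop_exposed")
CLUSTER_NAMES = ("inside-like", "outside-like", "undefined")

#: Descriptor panel used for correlation matrices.
DESCRIPTOR_PANEL = (
    "nc_yap",
    "prop_exposed",
    "prop_contact",
    "prop_junctional",
    "aj_ratio",
    "sphericity",
    "oblateness",
    "prolateness",
    "volume",
    "total_area",
    "exposed_area",
    "contact_area",
)


# ---------------------------------------------------------------------------
# high/low YAP threshold
# ---------------------------------------------------------------------------
def yap_threshold(values: Sequence[float], seed: int = 0) -> Tuple[float, np.ndarray]:
    """Split N/C YAP ratios into low/high by 1-D k-means (k = 2).

    Values are standardised, clustered by Euclidean k-means with 10
    restarts, and the threshold is reported on the original scale as the
    midpoint between the maximum of the low cluster and the minimum of the
    high cluster. A cell is "high" iff its value exceeds the threshold
    (strictly), matching the published decision rule. Standardisation makes
    the split invariant under affine rescaling of the input.

    Returns ``(threshold, is_high)``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError(f"need at least 4 finite values, got {x.size}")
    sd = x.std()
    if sd == 0:
        raise ValueError("all values identical: no high/low structure to threshold")
    z = ((x - x.mean()) / sd).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z)
    centroids = km.cluster_centers_.ravel()
    low_cluster = int(np.argmin(centroids))  # ties broken by lowest centroid
    low = x[km.labels_ == low_cluster]
    high = x[km.labels_ != low_cluster]
    threshold = float((low.max() + high.min()) / 2.0)
    is_high = np.asarray(values, dtype=float) > threshold
    return threshold, is_high


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------
@dataclass
class ClusterModel:
    """Ward clustering of blastomere records in descriptor space."""

    labels: np.ndarray  # cluster id per record, 0..k-1
    k: int
    centroids: pd.DataFrame  # per-cluster mean of each variable (raw scale)
    names: Optional[Dict[int, str]]  # cluster id -> fate-like name, or None
    variables: Tuple[str, ...]
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    linkage_method: str = "ward"

    def named_labels(self) -> np.ndarray:
        if self.names is None:
            raise ValueError("cluster names are unset (ambiguous centroid ordering)")
        return np.array([self.names[int(l)] for l in self.labels])


def _min_size_tree_cut(
    Z: np.ndarray, n: int, min_size: int, k_max: int = 6, min_gap_ratio: float = 1.4
) -> int:
    """Dynamic-tree-cut style choice of cluster count on a dendrogram.

    Candidate cuts are the k in [2, k_max] whose flat partition keeps at
    least ``min_size`` members per cluster; among them the k whose cut falls
    in the widest relative merge-height gap wins (the dendrogram splits
    there most decisively). Returns 1 when no candidate shows a gap ratio
    of at least ``min_gap_ratio`` - i.e. the data look unimodal.
    """
    heights = Z[:, 2]
    best_k, best_ratio = 1, 0.0
    for k in range(2, min(k_max, n - 1) + 1):
        sizes = np.bincount(fcluster(Z, t=k, criterion="maxclust"))[1:]
        if len(sizes) != k or sizes.min() < min_size:
            continue
        below = heights[n - 1 - k]  # merge closing the k-cluster partition
        above = heights[n - k]
        ratio = above / below if below > 0 else np.inf
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    return best_k if best_ratio >= min_gap_ratio else 1


def hier_cluster(
    records: pd.DataFrame,
    variables: Sequence[str] = CLUSTER_VARIABLES,
    min_cluster_frac: float = 0.06,
    k: Optional[int] = None,
) -> ClusterModel:
    """Ward hierarchical clustering on z-scored descriptors.

    The cluster count is chosen by a minimum-cluster-size cut of the Ward
    dendrogram; if that yields k outside [2, 6] the model falls back to
    k = 3, the canonical inside-like / outside-like / undefined split.
    Cluster names derive from centroid ordering rules:

    * inside-like  - lowest ``prop_exposed`` and lowest ``nc_yap``;
    * outside-like - highest ``nc_yap`` with intermediate ``prop_exposed``;
    * undefined    - highest ``prop_exposed`` with intermediate ``nc_yap``.

    If the centroid ordering is ambiguous (for example one cluster is
    extreme in both variables) names are left unset with a warning rather
    than guessed.
    """
    variables = tuple(variables)
    X = records.loc[:, variables].to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1)
    if not ok.all():
        raise ValueError(
            f"{np.count_nonzero(~ok)} records have non-finite values in {variables}"
        )
    n = len(X)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xz = (X - mean) / sd
    Z = linkage(Xz, method="ward", metric="euclidean")
    if k is None:
        min_size = max(3, int(np.ceil(min_cluster_frac * n)))
        k_cut = _min_size_tree_cut(Z, n, min_size)
        if not 2 <= k_cut <= 6:
            log.warning("tree cut returned k=%d; falling back to k=3", k_cut)
            k_cut = 3
    else:
        k_cut = k
    if n < 3 * k_cut:
        raise ValueError(f"need at least {3 * k_cut} records for k={k_cut}, got {n}")
    labels = fcluster(Z, t=k_cut, criterion="maxclust") - 1
    centroids = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in range(k_cut)], columns=list(variables)
    )
    names = _name_clusters(centroids) if set(CLUSTER_VARIABLES) <= set(variables) else None
    return ClusterModel(
        labels=labels,
        k=k_cut,
        centroids=centroids,
        names=names,
        variables=variables,
        scale_mean=mean,
        scale_sd=sd,
    )


def _name_clusters(centroids: pd.DataFrame) -> Optional[Dict[int, str]]:
    """Apply the centroid-ordering naming rules; None when ambiguous."""
    if len(centroids) != 3:
        warnings.warn(
            f"naming rules need 3 clusters, got {len(centroids)}; names unset",
            stacklevel=2,
        )
        return None
    yap = centroids["nc_yap"].to_numpy()
    exp = centroids["prop_exposed"].to_numpy()
    inside = int(np.argmin(yap))
    outside = int(np.argmax(yap))
    undefined = ({0, 1, 2} - {inside, outside}).pop()
    consistent = (
        inside != outside
        and np.argmin(exp) == inside  # inside-like lowest in both
        and np.argmax(exp) == undefined  # undefined most exposed
    )
    if not consistent:
        warnings.warn(
            "cluster centroids do not follow the inside/outside/undefined "
            "ordering; names unset",
            stacklevel=2,
        )
        return None
    return {inside: "inside-like", outside: "outside-like", undefined: "undefined"}


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------
@dataclass
class CorrelationReport:
    rho: pd.DataFrame
    p: pd.DataFrame
    n: int


def correlate(
    records: pd.DataFrame,
    variables: Sequence[str] = DESCRIPTOR_PANEL,
    stages: Optional[Sequence[int]] = None,
) -> CorrelationReport:
    """Pairwise Spearman correlation matrix over the descriptor panel.

    ``stages`` restricts to a stage subset (e.g. ``range(16, 65)`` for the
    16- to 64-cell analysis). Pairs are correlated on their mutually finite
    records; constant columns yield NaN rather than an error. The matrix is
    symmetric with unit diagonal.
    """
    df = records
    if stages is not None:
        df = df[df["stage"].isin(list(stages))]
    variables = [v for v in variables if v in df.columns]
    if len(df) < 5:
        raise ValueError(f"need at least 5 records, got {len(df)}")
    m = len(variables)
    rho = np.eye(m)
    pval = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        x = df[variables[i]].to_numpy(dtype=float)
        y = df[variables[j]].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 5 or x[ok].std() == 0 or y[ok].std() == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.spearmanr(x[ok], y[ok])
        rho[i, j] = rho[j, i] = r
        pval[i, j] = pval[j, i] = p
    idx = pd.Index(variables)
    return CorrelationReport(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(pval, index=idx, columns=idx),
        n=len(df),
    )


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------
@dataclass
class GroupTestResult:
    variable: str
    groups: List
    normality_p: Dict
    test: str  # "anova" or "kruskal", or "skipped"
    statistic: float
    p_value: float
    posthoc: Optional[pd.DataFrame] = None
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "variable": self.variable,
            "groups": [str(g) for g in self.groups],
            "normality_p": {str(k): v for k, v in self.normality_p.items()},
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "warnings": self.warnings,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def dunn_test(groups: Dict, p_adjust: str = "holm") -> pd.DataFrame:
    """Dunn's post-hoc test of mean ranks after Kruskal-Wallis.

    Pairwise z statistics on mean ranks of the pooled sample with the usual
    tie correction; two-sided p-values reported raw and Holm-adjusted.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(data)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(((counts**3 - counts).sum()) / (12.0 * (N - 1)))
    splits = np.cumsum([len(d) for d in data])[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        na, nb = len(data[i]), len(data[j])
        se = np.sqrt((N * (N + 1) / 12.0 - ties) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=p_adjust)[1]
    return out


def group_tests(
    records: pd.DataFrame,
    group_col: str,
    variable: str,
    alpha_normality: float = 0.05,
) -> GroupTestResult:
    """Omnibus comparison of one variable across groups with a normality gate.

    Shapiro-Wilk is run per group at ``alpha_normality``; if every group
    looks normal the comparison is one-way ANOVA followed by Tukey's HSD,
    otherwise Kruskal-Wallis followed by Dunn's test (raw and Holm-adjusted
    p-values). Groups with fewer than 3 observations cause the omnibus test
    to be skipped with a warning rather than an error.
    """
    df = records[[group_col, variable]].dropna()
    names = list(pd.unique(df[group_col]))
    if len(names) < 2:
        raise ValueError(f"need at least 2 groups in {group_col!r}, got {len(names)}")
    groups = {g: df.loc[df[group_col] == g, variable].to_numpy(dtype=float) for g in names}
    warn: List[str] = []
    small = [g for g, v in groups.items() if len(v) < 3]
    if small:
        msg = f"groups {small} have < 3 observations; omnibus test skipped"
        warn.append(msg)
        log.warning(msg)
        return GroupTestResult(variable, names, {}, "skipped", np.nan, np.nan, None, warn)

    normality = {}
    for g, v in groups.items():
        if len(v) < 3 or np.ptp(v) == 0:
            normality[g] = 0.0  # degenerate: treat as non-normal
        else:
            normality[g] = float(stats.shapiro(v).pvalue)
    all_normal = all(p > alpha_normality for p in normality.values())

    values = [groups[g] for g in names]
    if all_normal:
        stat, p = stats.f_oneway(*values)
        if not np.isfinite(p):  # F rounds slightly negative for identical groups
            stat = max(float(stat), 0.0)
            dfn, dfd = len(names) - 1, sum(len(v) for v in values) - len(names)
            p = float(stats.f.sf(stat, dfn, dfd))
        posthoc = _tukey(groups)
        test = "anova"
    else:
        stat, p = stats.kruskal(*values)
        posthoc = dunn_test(groups)
        test = "kruskal"
    return GroupTestResult(variable, names, normality, test, float(stat), float(p), posthoc, warn)


def _tukey(groups: Dict) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([np.asarray(v, float) for v in groups.values()])
    labels = np.concatenate([[str(g)] * len(v) for g, v in groups.items()])
    res = pairwise_tukeyhsd(values, labels)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return frame.rename(
        columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_adj"}
    )


def fisher_test(table) -> Tuple[float, float]:
    """Fisher's exact test for a 2x2 count table (odds ratio, p)."""
    odds, p = stats.fisher_exact(np.asarray(table))
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# confinement comparison
# ---------------------------------------------------------------------------
def confinement_compare(
    control: pd.DataFrame,
    confined: pd.DataFrame,
    variables: Sequence[str] = CLUSTER_VARIABLES,
    labels: Tuple[str, str] = ("control", "confined"),
) -> dict:
    """Compare a confined cohort against spherical controls.

    Reports per-variable medians and shift tests, plus a joint Ward
    clustering of the pooled cohorts with per-cluster composition
    percentages (how each cluster splits between arms).
    """
    if len(control) == 0 or len(confined) == 0:
        raise ValueError("both cohorts must be non-empty")
    pooled = pd.concat(
        [control.assign(arm=labels[0]), confined.assign(arm=labels[1])],
        ignore_index=True,
    )
    out: dict = {"medians": {}, "tests": {}, "n": {labels[0]: len(control), labels[1]: len(confined)}}
    for v in variables:
        out["medians"][v] = {
            labels[0]: float(control[v].median()),
            labels[1]: float(confined[v].median()),
        }
        out["tests"][v] = group_tests(pooled, "arm", v)
    ok = np.isfinite(pooled.loc[:, variables].to_numpy(dtype=float)).all(axis=1)
    model = hier_cluster(pooled[ok], variables=variables)
    comp = (
        pd.crosstab(model.labels, pooled.loc[ok, "arm"], normalize="index") * 100.0
    )
    if model.names is not None:
        comp.index = [model.names[int(i)] for i in comp.index]
    out["cluster_model"] = model
    out["cluster_composition_pct"] = comp
    return out
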