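"""Clustering, annotation-term enrichment, PCA and reproducibility QC.

Significantly different proteins are clustered on group-median z-scores:
each protein row is z-scored across all samples, the median is taken
within every (fiber, time) group, and the resulting profiles are grouped
by agglomerative hierarchical clustering (Euclidean distance, average
linkage).  Clusters, or any other protein set, are then tested for
annotation-term enrichment or depletion against the full quantified
matrix with a two-sided Fisher exact test and Benjamini-Hochberg
adjustment within each annotation namespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import AnnotationMap
from .preprocess import LogMatrix


# ---------------------------------------------------------------------------
# Group-median z-scores + hierarchical clustering
# ---------------------------------------------------------------------------


def group_median_zscores(m: LogMatrix, proteins: Iterable[str]) -> pd.DataFrame:
    """Median within-group z-score profile per protein.

    Rows are z-scored across all samples (mean 0, SD 1, population SD);
    proteins with zero spread are dropped with a warning.
    """
    proteins = [p for p in m.values.index if p in set(proteins)]
    sub = m.values.loc[proteins]
    if sub.isna().any().any():
        raise ValueError("z-scoring requires a complete (imputed) matrix")
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} constant protein row(s) from clustering",
            stacklevel=2,
        )
        sub, mu, sd = sub[~flat], mu[~flat], sd[~flat]
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    out = {}
    for f, t in m.design.groups:
        out[f"{f}_{t}"] = z[m.design.samples_in(f, t)].median(axis=1)
    return pd.DataFrame(out, index=z.index)


@dataclass
class ClusterAssignment:
    """Cluster labels (contiguous from 1) with the tree that produced them."""

    labels: pd.Series
    z_matrix: pd.DataFrame
    linkage: np.ndarray
    n_clusters: int

    def members(self, cluster_id: int) -> set[str]:
        return set(self.labels.index[self.labels == cluster_id])


def hierarchical_cluster(z: pd.DataFrame, n_clusters: int = 2) -> ClusterAssignment:
    """Agglomerative clustering of z-profiles (Euclidean, average linkage)."""
    if len(z) < n_clusters:
        raise ValueError(f"{len(z)} rows cannot form {n_clusters} clusters")
    link = hierarchy.linkage(z.to_numpy(), method="average", metric="euclidean")
    raw = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    # Relabel in order of first appearance so ids are deterministic and
    # contiguous from 1 regardless of scipy's internal numbering.
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    return ClusterAssignment(
        pd.Series(labels, index=z.index, name="cluster"), z, link, n_clusters
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    annotation: AnnotationMap,
    namespaces: Sequence[str] | None = None,
    fdr_threshold: float = 0.05,
    accession_lists: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of annotation terms in a query set.

    The background is the full quantified matrix ("whole matrix"
    convention, which reduces noise relative to a genome-wide universe);
    the query must be a subset of it.  For each term the 2x2 table is

        [[k, m - k], [K - k, N - m - K + k]]

    with k annotated in the query, m the query size, K annotated in the
    background and N the background size.  Direction is labelled enriched
    or depleted by the odds ratio; q is BH-adjusted within each namespace
    (terms from different ontologies are not exchangeable hypotheses).
    Terms absent from the background are not tested.
    """
    query, background = set(query), set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N, m = len(background), len(query)
    acc = accession_lists or {}

    def term_groups(ns: str, term: str) -> set[str]:
        members = annotation.members(ns, term)
        hit = set()
        for pid in background:
            if pid in members or members.intersection(acc.get(pid, ())):
                hit.add(pid)
        return hit

    rows = []
    for ns, term in annotation.terms():
        if namespaces is not None and ns not in namespaces:
            continue
        in_bg = term_groups(ns, term)
        K = len(in_bg)
        if K == 0:
            continue
        k = len(in_bg & query)
        table = [[k, m - k], [K - k, N - m - K + k]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        direction = "enriched" if (k * (N - m - K + k)) > ((m - k) * (K - k)) else "depleted"
        rows.append((ns, term, k, m, K, N, odds, p, direction))
    res = pd.DataFrame(
        rows,
        columns=["namespace", "term", "k", "m", "K", "N", "odds_ratio", "p", "direction"],
    )
    res["q"] = np.nan
    for ns in res["namespace"].unique():
        sel = res["namespace"] == ns
        res.loc[sel, "q"] = bh_fdr(res.loc[sel, "p"].to_numpy())
    res["significant"] = res["q"] <= fdr_threshold
    return res.sort_values(["namespace", "p", "term"]).reset_index(drop=True)


def annotate_fraction(
    protein_set: Iterable[str],
    annotation: AnnotationMap,
    namespace: str,
    term: str,
    accession_lists: Mapping[str, Iterable[str]] | None = None,
) -> tuple[float, bool]:
    """Fraction of a protein set carrying a term; (0.0, True) flags empty."""
    pset = set(protein_set)
    if not pset:
        return 0.0, True
    members = annotation.members(namespace, term)
    acc = accession_lists or {}
    k = sum(
        1 for pid in pset
        if pid in members or members.intersection(acc.get(pid, ()))
    )
    return k / len(pset), False


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # proteins x components
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(m: LogMatrix) -> PcaResult:
    """PCA of samples in protein space on the imputed log2 matrix.

    Each protein is centred across samples (no scaling); components come
    from the SVD of the centred samples-by-proteins matrix, and variance
    explained is the squared-singular-value share.
    """
    if m.values.isna().any().any():
        raise ValueError("PCA requires a complete matrix; run imputation first")
    x = m.values.to_numpy(dtype=float)
    xc = (x - x.mean(axis=1, keepdims=True)).T  # samples x proteins
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / np.sum(s**2)
    comps = [f"PC{i+1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=m.values.columns, columns=comps)
    loadings = pd.DataFrame(vt.T, index=m.values.index, columns=comps)
    return PcaResult(scores, loadings, var)


# ---------------------------------------------------------------------------
# Reproducibility
# ---------------------------------------------------------------------------


@dataclass
class ReproducibilityResult:
    """Pairwise Pearson correlations of samples on observed log2 values."""

    r_matrix: pd.DataFrame
    median_within_group: pd.Series
    median_overall: float


def reproducibility_correlation(
    m: LogMatrix, min_shared: int = 3
) -> ReproducibilityResult:
    """Within-group sample correlations on pairwise-complete observed values.

    Uses only observed (non-imputed) cells; pairs sharing fewer than
    ``min_shared`` proteins get NaN.  The headline number is the median
    Pearson r over within-group sample pairs.
    """
    obs = m.values.where(m.observed)
    r = obs.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(r.values, 1.0)
    medians = {}
    all_within = []
    for f, t in m.design.groups:
        cols = m.design.samples_in(f, t)
        if len(cols) < 2:
            raise ValueError(f"group {(f, t)} has fewer than 2 samples")
        pair_r = [r.at[a, b] for i, a in enumerate(cols) for b in cols[i + 1:]]
        medians[f"{f}_{t}"] = _nanmedian(pair_r)
        all_within += pair_r
    return ReproducibilityResult(r, pd.Series(medians), _nanmedian(all_within))


def _nanmedian(vals) -> float:
    arr = np.asarray(vals, dtype=float)
    arr = arr[~np.isnan(arr)]
    return float(np.median(arr)) if arr.size else float("nan")
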