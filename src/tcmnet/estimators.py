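"""scikit-learn style estimators implementing the package's core computations.

Three estimators cover the three algorithmic stages of the herb-ingredient
network analysis:

``BipartiteProjection``
    A transformer mapping a binary biadjacency (incidence) matrix to the
    weighted adjacency of the unipartite projection on its rows: two rows are
    linked with weight equal to the number of columns (opposite-side
    neighbours) they share.

``FastGreedyCommunities``
    A clusterer running Clauset-Newman-Moore greedy agglomerative modularity
    optimisation on a (possibly weighted) adjacency matrix.  Deterministic:
    delta-Q ties are broken by the lexicographically smallest community-label
    pair, and the merged community keeps the smaller label.

``CoherenceValidator``
    Tests whether entities grouped in the same cluster have more similar
    annotations than expected under a size-preserving random regrouping,
    using a two-sided Wilcoxon rank-sum comparison of per-cluster mean
    pairwise similarities against a pooled permutation null.

The graph-level functions in :mod:`tcmnet.bigraph`, :mod:`tcmnet.community`
and :mod:`tcmnet.validation` are thin wrappers around these classes.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import NoEdgesError, ValidationError

__all__ = [
    "BipartiteProjection",
    "FastGreedyCommunities",
    "CoherenceValidator",
    "pairwise_similarity_matrix",
]


class BipartiteProjection(TransformerMixin, BaseEstimator):
    """Project a bipartite incidence matrix onto its row node set.

    Given a binary biadjacency matrix ``X`` with shape
    ``(n_row_nodes, n_col_nodes)``, :meth:`transform` returns the
    ``(n_row_nodes, n_row_nodes)`` adjacency of the unipartite projection:
    entry ``(u, v)`` is the number of shared column-side neighbours of rows
    ``u`` and ``v`` (the shared-ingredient count for two herbs), with a zero
    diagonal.  To project onto the column set, transform ``X.T``.

    Parameters
    ----------
    weighted : bool, default=True
        If False, the output adjacency is binarised: 1 whenever the two rows
        share at least one neighbour.

    Attributes
    ----------
    n_features_in_ : int
        Number of column-side nodes seen during :meth:`fit`.
    """

    def __init__(self, weighted: bool = True):
        self.weighted = weighted

    def fit(self, X, y=None):
        X = self._validate_input(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = self._validate_input(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        B = sp.csr_matrix((X > 0).astype(np.int64))
        A = (B @ B.T).tolil()
        A.setdiag(0)
        A = A.tocsr()
        A.eliminate_zeros()
        if not self.weighted:
            A = sp.csr_matrix((A > 0).astype(np.int64))
        return A

    @staticmethod
    def _validate_input(X):
        if sp.issparse(X):
            return X.tocsr()
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("expected a 2d biadjacency matrix")
        return sp.csr_matrix(X)


def _modularity_from_labels(A: sp.csr_matrix, labels: np.ndarray) -> float:
    """Newman-Girvan weighted modularity Q = sum_c [w_c/W - (s_c/2W)^2].

    ``w_c`` is the total intra-community edge weight, ``s_c`` the summed
    (weighted) degree of the community's nodes, ``W`` the total edge weight.
    """
    strengths = np.asarray(A.sum(axis=1)).ravel()
    two_w = strengths.sum()
    if two_w <= 0:
        raise NoEdgesError("modularity undefined on an edgeless graph")
    q = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        sub = A[idx][:, idx]
        w_c = sub.sum() / 2.0
        s_c = strengths[idx].sum()
        q += w_c / (two_w / 2.0) - (s_c / two_w) ** 2
    return q


class FastGreedyCommunities(ClusterMixin, BaseEstimator):
    """Greedy agglomerative modularity clustering (Clauset-Newman-Moore).

    Starts with every node in its own community and repeatedly merges the
    pair of connected communities yielding the largest modularity gain
    delta-Q, while any gain is positive.  The partition at the maximum Q
    encountered is returned.  Determinism: candidate pairs are scanned in
    lexicographic label order and a strictly larger gain is required to
    displace the incumbent, so delta-Q ties resolve to the smallest
    ``(label, label)`` pair; the merged community keeps the smaller label.

    Parameters
    ----------
    weighted : bool, default=True
        If False, all edge weights are treated as 1.

    Attributes
    ----------
    labels_ : ndarray of shape (n_nodes,)
        Community labels, contiguous integers starting at 0, ordered by each
        community's smallest member index.
    modularity_ : float
        Newman-Girvan Q of ``labels_``, recomputed from the final partition.
    n_communities_ : int
    """

    def __init__(self, weighted: bool = True):
        self.weighted = weighted

    def fit(self, X, y=None):
        A = self._as_adjacency(X)
        n = A.shape[0]
        if A.nnz == 0:
            raise NoEdgesError("fast greedy requires a graph with at least one edge")

        strengths = np.asarray(A.sum(axis=1)).ravel()
        two_w = strengths.sum()  # 2W
        w = two_w / 2.0

        # community state: intra weight, strength, and inter-community weights
        intra = {i: 0.0 for i in range(n)}
        strength = {i: float(strengths[i]) for i in range(n)}
        coo = A.tocoo()
        between: dict[int, dict[int, float]] = {i: {} for i in range(n)}
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if i < j:
                between[i][j] = between[i].get(j, 0.0) + float(v)
                between[j][i] = between[j].get(i, 0.0) + float(v)

        members = {i: [i] for i in range(n)}
        while len(members) > 1:
            best_pair = None
            best_dq = 0.0
            for c in sorted(between):
                for d in sorted(between[c]):
                    if d <= c:
                        continue
                    dq = between[c][d] / w - 2.0 * (
                        strength[c] / two_w
                    ) * (strength[d] / two_w)
                    if dq > best_dq:
                        best_dq = dq
                        best_pair = (c, d)
            if best_pair is None:
                break
            c, d = best_pair
            intra[c] += intra[d] + between[c][d]
            strength[c] += strength[d]
            members[c].extend(members[d])
            del between[c][d], between[d][c]
            for e, v in between[d].items():
                between[c][e] = between[c].get(e, 0.0) + v
                nbr = between[e]
                nbr[c] = nbr.get(c, 0.0) + v
                del nbr[d]
            del between[d], members[d], intra[d], strength[d]

        labels = np.empty(n, dtype=np.int64)
        for new_lab, root in enumerate(sorted(members, key=lambda r: min(members[r]))):
            labels[members[root]] = new_lab
        self.labels_ = labels
        self.n_communities_ = int(labels.max()) + 1
        self.modularity_ = _modularity_from_labels(A, labels)
        self.n_features_in_ = n
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def _as_adjacency(self, X) -> sp.csr_matrix:
        A = X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X, dtype=float))
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if abs(A - A.T).sum() > 1e-9:
            raise ValueError("adjacency matrix must be symmetric")
        A = A.copy().tolil()
        A.setdiag(0)
        A = A.tocsr()
        A.eliminate_zeros()
        if not self.weighted:
            A = sp.csr_matrix((A > 0).astype(float))
        return A.astype(float)


def pairwise_similarity_matrix(X, metric: str) -> np.ndarray:
    """Dense pairwise similarity of binary token-indicator rows.

    ``X`` is an ``(n_entities, n_tokens)`` 0/1 matrix where row ``i`` marks
    the tokens (labels, target ids, string bigrams) annotating entity ``i``.
    Supported metrics: ``overlap`` |A&B|/min(|A|,|B|), ``jaccard``
    |A&B|/|A|B|union, ``dice`` 2|A&B|/(|A|+|B|).  Every row must be non-empty.
    """
    X = np.asarray(X, dtype=float)
    X = (X > 0).astype(float)
    sizes = X.sum(axis=1)
    if np.any(sizes == 0):
        raise ValidationError("every entity must carry at least one annotation token")
    inter = X @ X.T
    if metric == "overlap":
        denom = np.minimum.outer(sizes, sizes)
    elif metric == "jaccard":
        denom = sizes[:, None] + sizes[None, :] - inter
    elif metric == "dice":
        return 2.0 * inter / (sizes[:, None] + sizes[None, :])
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    return inter / denom


def _cluster_means(S: np.ndarray, order: np.ndarray, sizes: list[int]) -> np.ndarray:
    """Mean off-diagonal similarity within consecutive blocks of ``order``.

    ``order`` lists entity indices; clusters occupy consecutive runs with the
    given sizes.  Only blocks of size >= 2 produce a value.
    """
    means = []
    start = 0
    for m in sizes:
        idx = order[start : start + m]
        start += m
        if m < 2:
            continue
        sub = S[np.ix_(idx, idx)]
        means.append((sub.sum() - np.trace(sub)) / (m * (m - 1)))
    return np.asarray(means)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact p by enumeration when the pooled sample has at most 12 values and
    no ties; otherwise the normal approximation with tie and continuity
    correction.  Returns ``(U statistic, p value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


class CoherenceValidator(BaseEstimator):
    """Cluster annotation-coherence test against a random-grouping null.

    Fits on a binary token-indicator matrix ``X`` (entities x annotation
    tokens) and cluster labels ``y``.  Observed statistic: for every cluster
    with at least two annotated members, the mean pairwise similarity of its
    members.  Null: ``n_replicates`` uniform permutations of the entity ->
    cluster assignment preserving the multiset of cluster sizes; per-cluster
    means are pooled over replicates.  The two distributions are compared
    with a two-sided Wilcoxon rank-sum test.

    Parameters
    ----------
    metric : {"overlap", "jaccard", "dice"}, default="overlap"
        Pairwise similarity of token sets.
    n_replicates : int, default=100
        Number of random regroupings forming the null.
    random_state : int or numpy Generator, optional
        Seeds the permutations; fits are reproducible given a seed.

    Attributes
    ----------
    observed_ : ndarray
        Per-cluster mean pairwise similarity (evaluable clusters only).
    cluster_ids_, cluster_sizes_ : lists
        Labels and annotated-member counts of the evaluable clusters.
    null_values_ : ndarray of length n_replicates * n_evaluable_clusters
    observed_median_, null_median_ : float
    statistic_, p_value_ : float
        Rank-sum U and its two-sided p-value.
    """

    def __init__(
        self,
        metric: str = "overlap",
        n_replicates: int = 100,
        random_state=None,
    ):
        self.metric = metric
        self.n_replicates = n_replicates
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        X = np.asarray(X)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have one row/label per entity")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        S = pairwise_similarity_matrix(X, self.metric)

        uniq, counts = np.unique(y, return_counts=True)
        evaluable = counts >= 2
        if not np.any(evaluable):
            raise ValidationError(
                "no cluster has two or more annotated members; nothing to validate"
            )
        # consecutive-block layout: sort entities by cluster once, then the
        # null only permutes which entity occupies which slot
        order = np.argsort(y, kind="stable")
        sizes = counts.tolist()
        self.cluster_ids_ = uniq[evaluable].tolist()
        self.cluster_sizes_ = counts[evaluable].tolist()
        self.observed_ = _cluster_means(S, order, sizes)

        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        n = y.shape[0]
        null = [
            _cluster_means(S, rng.permutation(n), sizes)
            for _ in range(self.n_replicates)
        ]
        self.null_values_ = np.concatenate(null)
        self.observed_median_ = float(np.median(self.observed_))
        self.null_median_ = float(np.median(self.null_values_))
        self.statistic_, self.p_value_ = rank_sum_test(
            self.observed_, self.null_values_
        )
        self.n_features_in_ = X.shape[1]
        return self
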