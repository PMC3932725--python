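"""Mining the n x p metric table: rank replacement, Spearman correlation,
PCA of the rank structure, candidate ranking, and metric-consistency
diagnostics.

Replacing each column's values by their within-column ranks removes all
scaling/monotone-transform concerns, so principal component analysis of the
Spearman rank correlation matrix (a nonparametric, outlier-resistant "robust
PCA") extracts the latent quality ordering the metrics agree on.  Candidates
are ranked by their oriented first-principal-component score; clustering the
correlation matrix exposes metrics that disagree with the consensus.

Everything here is deterministic: ties are broken by explicit conventions,
never randomly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .metrics import MetricTable

logger = logging.getLogger(__name__)

__all__ = [
    "RankTable",
    "PCAResult",
    "Ranking",
    "rank_transform",
    "spearman_matrix",
    "robust_pca",
    "orient_and_rank",
    "cluster_metrics",
    "consistency_report",
    "RankPCARanker",
    "CONSISTENT_METRICS",
]

#: The consensus subset: all battery metrics except the two historically
#: discordant ones (difference-entropy and the Woods criterion).
CONSISTENT_METRICS: Tuple[str, ...] = (
    "msd", "adi", "mif", "nmi", "ncc", "cor", "red", "uni", "aum",
)


def _as_frame(m: Union[MetricTable, pd.DataFrame]) -> pd.DataFrame:
    return m.scores if isinstance(m, MetricTable) else m


@dataclass
class RankTable:
    """Column-wise rank replacement of a metric table (1 = smallest score,
    average ranks on ties)."""

    ranks: pd.DataFrame
    dropped_rows: List[str]

    @property
    def n(self) -> int:
        return len(self.ranks)

    @property
    def p(self) -> int:
        return self.ranks.shape[1]


def rank_transform(
    m: Union[MetricTable, pd.DataFrame],
    missing_policy: str = "drop_row",
) -> RankTable:
    """Replace each column by within-column ascending ranks (ties averaged).

    Missing cells: ``drop_row`` removes candidates with any missing value
    before ranking; ``column_mean_rank`` ranks complete cells then imputes
    the column's mean rank into the holes.
    """
    df = _as_frame(m)
    if len(df) < 2:
        raise ValueError("rank transform needs at least 2 rows")
    all_missing = df.columns[df.isna().all()]
    if len(all_missing):
        raise ValueError(f"all-missing metric column(s): {list(all_missing)}")
    dropped: List[str] = []
    if missing_policy == "drop_row":
        keep = df.notna().all(axis=1)
        dropped = list(df.index[~keep])
        df = df.loc[keep]
        if len(df) < 2:
            raise ValueError("fewer than 2 complete rows after dropping missing")
        ranks = df.apply(lambda col: rankdata(col.to_numpy(), method="average"))
    elif missing_policy == "column_mean_rank":
        ranks = df.apply(
            lambda col: pd.Series(
                rankdata(col.to_numpy(), method="average", nan_policy="omit"),
                index=col.index,
            )
        )
        ranks = ranks.apply(lambda col: col.fillna(col.mean()))
    else:
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    return RankTable(ranks=ranks, dropped_rows=dropped)


def spearman_matrix(m: Union[MetricTable, pd.DataFrame, RankTable]) -> pd.DataFrame:
    """p x p Spearman rank correlation matrix of the metric columns.

    Equals the Pearson correlation of the rank-transformed columns.  Constant
    columns (zero rank variance) yield NaN correlations, flagged to the caller
    by their presence.
    """
    if isinstance(m, RankTable):
        ranks = m.ranks
    else:
        df = _as_frame(m)
        if len(df) < 3:
            raise ValueError("Spearman correlation needs n >= 3 rows")
        ranks = rank_transform(df).ranks
    x = ranks.to_numpy(dtype=np.float64)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (x.T @ x) / len(x) / np.outer(sd, sd)
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(c, index=ranks.columns, columns=ranks.columns)


@dataclass
class PCAResult:
    """Eigen-decomposition of the Spearman correlation of the rank table."""

    eigenvalues: np.ndarray           # descending
    loadings: pd.DataFrame            # p x p, columns PC1..PCp, unit-norm
    scores: pd.DataFrame              # n x p candidate scores on each PC
    oriented: List[bool]              # per-PC: sign flipped during orientation?


def robust_pca(r: Union[RankTable, MetricTable, pd.DataFrame]) -> PCAResult:
    """PCA of the Spearman rank correlation matrix.

    Candidate scores are the centered rank rows projected onto the unit-norm
    eigenvectors.  Eigenvector signs are fixed deterministically (largest-
    magnitude loading positive); orientation against the consensus happens in
    :func:`orient_and_rank`.
    """
    rank_table = r if isinstance(r, RankTable) else rank_transform(_as_frame(r))
    ranks = rank_table.ranks
    if len(ranks) < 3:
        raise ValueError("robust PCA needs n >= 3 candidates")
    corr = spearman_matrix(rank_table)
    if corr.isna().any().any():
        bad = corr.columns[corr.isna().any()].tolist()
        raise ValueError(f"undefined correlations (constant rank column?): {bad}")
    evals, evecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] <= 1e-12:
        raise ValueError("degenerate correlation matrix (rank 0)")
    # deterministic sign: largest-|loading| entry of each PC made positive
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    pcs = [f"PC{j + 1}" for j in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=ranks.columns, columns=pcs)
    centered = ranks.to_numpy(dtype=np.float64) - ranks.to_numpy().mean(axis=0)
    scores = pd.DataFrame(centered @ evecs, index=ranks.index, columns=pcs)
    return PCAResult(
        eigenvalues=np.maximum(evals, 0.0),
        loadings=loadings,
        scores=scores,
        oriented=[False] * len(pcs),
    )


@dataclass
class Ranking:
    """Final candidate ordering: rank 1 = best along oriented PC1."""

    table: pd.DataFrame  # index run_id; columns rank, pc1, pc2, row_mean_rank

    @property
    def order(self) -> List[str]:
        return list(self.table.sort_values("rank").index)

    def top(self) -> str:
        return self.order[0]

    def to_csv(self, path) -> None:
        self.table.sort_values("rank").to_csv(path, index_label="run_id")


def orient_and_rank(
    p: PCAResult, r: Union[RankTable, pd.DataFrame]
) -> Ranking:
    """Orient PC1 against the consensus and rank candidates along it.

    PC1's sign is flipped if its candidate scores correlate negatively with
    the row-mean rank (the across-metric consensus: since every score column
    ranks ascending with quality, a higher mean rank means a better
    candidate).  Candidates are then sorted descending by oriented PC1; ties
    break by row-mean rank (descending), then run_id.
    """
    ranks = r.ranks if isinstance(r, RankTable) else r
    ranks = ranks.loc[p.scores.index]
    row_mean = ranks.mean(axis=1)
    pc1 = p.scores["PC1"].to_numpy().copy()
    flipped = False
    if np.std(pc1) > 0 and np.std(row_mean.to_numpy()) > 0:
        c = np.corrcoef(pc1, row_mean.to_numpy())[0, 1]
        if c < 0:
            flipped = True
            pc1 = -pc1
    p.oriented[0] = flipped
    pc2 = p.scores["PC2"].to_numpy() if "PC2" in p.scores.columns else np.zeros_like(pc1)
    table = pd.DataFrame(
        {"pc1": pc1, "pc2": pc2, "row_mean_rank": row_mean.to_numpy()},
        index=p.scores.index,
    )
    ordered = table.sort_values(
        by=["pc1", "row_mean_rank"], ascending=[False, False], kind="mergesort"
    )
    # final deterministic tie-break on run_id
    ordered = ordered.loc[
        sorted(
            ordered.index,
            key=lambda rid: (
                -ordered.loc[rid, "pc1"],
                -ordered.loc[rid, "row_mean_rank"],
                str(rid),
            ),
        )
    ]
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    return Ranking(table=ordered[["rank", "pc1", "pc2", "row_mean_rank"]])


@dataclass
class MetricDendrogram:
    linkage_matrix: np.ndarray
    labels: List[str]
    leaf_order: List[str]

    def to_newick(self) -> str:
        """Nested-parenthesis text of the merge tree with merge heights."""
        n = len(self.labels)
        nodes: Dict[int, str] = {i: self.labels[i] for i in range(n)}
        for k, (a, b, dist, _cnt) in enumerate(self.linkage_matrix):
            nodes[n + k] = f"({nodes[int(a)]},{nodes[int(b)]}):{dist:.6f}"
        return nodes[n + len(self.linkage_matrix) - 1] + ";"


def cluster_metrics(c: pd.DataFrame) -> MetricDendrogram:
    """Agglomerative (average-linkage) clustering of metrics at distance
    1 - correlation; deterministic leaf order from scipy's dendrogram."""
    if c.isna().any().any():
        bad = c.columns[c.isna().any()].tolist()
        raise ValueError(f"undefined correlation entries for metrics: {bad}")
    dist = 1.0 - c.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    condensed = squareform(dist, checks=False)
    link = linkage(condensed, method="average")
    order = [c.columns[i] for i in leaves_list(link)]
    return MetricDendrogram(linkage_matrix=link, labels=list(c.columns), leaf_order=order)


@dataclass
class ConsistencyReport:
    subset: List[str]
    min_pairwise_correlation: Optional[float]   # None when subset has < 2 metrics
    flagged: List[str]                          # metrics discordant with the subset
    mean_correlation_with_subset: Dict[str, float]


def consistency_report(
    c: pd.DataFrame,
    subset: Optional[Sequence[str]] = None,
    threshold: float = 0.0,
) -> ConsistencyReport:
    """Summarize metric agreement.

    Reports the minimum pairwise Spearman correlation within the consensus
    ``subset`` (default: all columns except edi and woo that are present) and
    flags metrics whose mean correlation with that subset falls below
    ``threshold`` (default 0: anticorrelated with the consensus).
    """
    if subset is None:
        subset = [m for m in c.columns if m in CONSISTENT_METRICS] or list(c.columns)
    subset = [m for m in subset if m in c.columns]
    if len(subset) >= 2:
        block = c.loc[subset, subset].to_numpy()
        iu = np.triu_indices(len(subset), k=1)
        min_pair = float(np.min(block[iu]))
    else:
        min_pair = None
    mean_corr: Dict[str, float] = {}
    flagged: List[str] = []
    for m in c.columns:
        others = [x for x in subset if x != m]
        if not others:
            continue
        mc = float(c.loc[m, others].mean())
        mean_corr[m] = mc
        if mc < threshold:
            flagged.append(m)
    return ConsistencyReport(
        subset=list(subset),
        min_pairwise_correlation=min_pair,
        flagged=flagged,
        mean_correlation_with_subset=mean_corr,
    )


class RankPCARanker(BaseEstimator):
    """Scikit-learn style estimator wrapping the full mining pipeline.

    ``fit(X)`` takes an (n, p) metric score table (DataFrame or MetricTable)
    and computes rank replacement, the Spearman correlation matrix, its PCA
    and the oriented-PC1 candidate ranking.

    Fitted attributes
    -----------------
    rank_table_ : RankTable
    spearman_ : DataFrame (p x p)
    eigenvalues_ : ndarray, descending
    loadings_ : DataFrame (p x p)
    scores_ : DataFrame (n x p) candidate PC scores (PC1 oriented)
    ranking_ : Ranking
    dendrogram_ : MetricDendrogram
    consistency_ : ConsistencyReport
    """

    def __init__(self, missing_policy: str = "drop_row", flag_threshold: float = 0.0):
        self.missing_policy = missing_policy
        self.flag_threshold = flag_threshold

    def fit(self, X: Union[MetricTable, pd.DataFrame], y=None) -> "RankPCARanker":
        df = _as_frame(X)
        # a constant score column carries no ranking information and has an
        # undefined Spearman correlation; exclude it from the mining, loudly
        constant = [c for c in df.columns if df[c].nunique(dropna=True) <= 1]
        self.dropped_metrics_ = constant
        if constant:
            logger.warning("dropping constant metric column(s): %s", constant)
            df = df.drop(columns=constant)
        if df.shape[1] < 2:
            raise ValueError("fewer than 2 informative metric columns")
        self.rank_table_ = rank_transform(df, missing_policy=self.missing_policy)
        self.spearman_ = spearman_matrix(self.rank_table_)
        pca = robust_pca(self.rank_table_)
        self.ranking_ = orient_and_rank(pca, self.rank_table_)
        if pca.oriented[0]:
            pca.loadings["PC1"] = -pca.loadings["PC1"]
            pca.scores["PC1"] = -pca.scores["PC1"]
        self.pca_ = pca
        self.eigenvalues_ = pca.eigenvalues
        self.loadings_ = pca.loadings
        self.scores_ = pca.scores
        self.dendrogram_ = cluster_metrics(self.spearman_)
        self.consistency_ = consistency_report(
            self.spearman_, threshold=self.flag_threshold
        )
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Candidate PC-score coordinates from the fit (X is ignored; the
        decomposition is tied to the fitted table)."""
        if not hasattr(self, "scores_"):
            raise RuntimeError("RankPCARanker is not fitted")
        return self.scores_

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform()
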