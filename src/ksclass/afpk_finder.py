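"""Embedding-based KS classification (the AFPK-Finder procedure).

A panel of profile HMMs turns every sequence into a vector of bit
scores; per-profile z-scoring makes models of different lengths
comparable; t-SNE (or deterministic PCA) maps the score matrix to 2D;
density clustering reads off groups; and the adjusted Rand index (ARI)
against reference clade labels measures cluster-clade congruence. Panels
are chosen by scoring random candidate subsets on labeled training
sequences and keeping the most congruent one. Queries are classified by
a k-nearest-neighbor vote among reference points in the embedding.

Even profiles a sequence barely aligns to contribute signal here: the
pattern of weak scores across the panel is itself discriminative, which
is why the score matrix, not any single threshold, is the input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_array, check_is_fitted

from .classify import score_panel
from .errors import (
    InputSizeError,
    InsufficientOverlapError,
    ParameterError,
    UnknownIdError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Embedding2D:
    """2D coordinates of embedded sequences."""

    seq_ids: tuple
    coords: np.ndarray  # (n, 2)
    method: str
    perplexity: float | None
    seed: int

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(self.seq_ids), 2):
            raise ParameterError("coords must have shape (n_ids, 2)")
        if not np.all(np.isfinite(coords)):
            raise ParameterError("embedding coordinates must be finite")


@dataclass(frozen=True)
class ClusterAssignment:
    """Integer cluster ids per sequence; -1 marks noise."""

    seq_ids: tuple
    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (len(self.seq_ids),):
            raise ParameterError("labels must parallel seq_ids")


@dataclass(frozen=True)
class ReferenceSet:
    """Sequences with known clade labels (e.g. mo-clade 1-4, FAS, PKS)."""

    seq_ids: tuple
    labels: tuple

    def __post_init__(self):
        if len(self.seq_ids) != len(self.labels):
            raise ParameterError("seq_ids and labels must parallel")
        if any(not l for l in self.labels):
            raise ParameterError("clade labels must be nonempty strings")

    @classmethod
    def from_mapping(cls, mapping) -> "ReferenceSet":
        items = list(mapping.items())
        return cls(tuple(k for k, _ in items), tuple(str(v) for _, v in items))

    def as_dict(self) -> dict:
        return dict(zip(self.seq_ids, self.labels))


def normalize_scores(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-score with population standard deviation; constant
    columns map to all-zero. Shape-preserving and idempotent."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise InputSizeError("cannot normalize an empty score matrix")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population (ddof=0)
    centered = values - mean
    out = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def embed_2d(matrix: pd.DataFrame, method: str = "tsne", perplexity: float = 30.0,
             seed: int = 0) -> Embedding2D:
    """Embed a (normalized) score matrix in 2D.

    t-SNE is the default; a perplexity at or above (rows - 1) / 3 is
    shrunk with a warning. PCA mode is fully deterministic: the top two
    principal components with each component's sign fixed so that its
    largest-magnitude loading is positive.
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 4:
        raise InputSizeError(f"embedding needs at least 4 rows, got {n}")
    ids = tuple(matrix.index)
    if method == "pca":
        centered = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        components = vt[:2]
        for j in range(components.shape[0]):
            i_max = int(np.argmax(np.abs(components[j])))
            if components[j, i_max] < 0:
                components[j] = -components[j]
        coords = centered @ components.T
        if coords.shape[1] < 2:  # rank/feature deficiency: pad with zeros
            coords = np.hstack([coords, np.zeros((n, 2 - coords.shape[1]))])
        return Embedding2D(ids, coords, "pca", None, seed)
    if method != "tsne":
        raise ParameterError(f"unknown embedding method {method!r}")
    limit = (n - 1) / 3.0
    if perplexity >= limit:
        new_p = max(1.0, limit - 1e-3)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} rows; shrunk to {new_p:.3f}",
            stacklevel=2,
        )
        perplexity = new_p
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(X)
    return Embedding2D(ids, np.asarray(coords, dtype=float), "tsne", perplexity, seed)


def default_eps(coords: np.ndarray) -> float:
    """3x the median 4th-nearest-neighbor distance (floored to stay positive)."""
    n = coords.shape[0]
    k = min(5, n)  # self + up to 4 neighbors
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    dist, _ = nn.kneighbors(coords)
    eps = 3.0 * float(np.median(dist[:, k - 1]))
    return max(eps, 1e-9)


def cluster_embedding(emb: Embedding2D, eps: float | None = None,
                      min_pts: int = 5) -> ClusterAssignment:
    """Density-based clustering of the embedding (DBSCAN semantics: a
    core point has >= min_pts points, itself included, within eps)."""
    if eps is not None and eps <= 0:
        raise ParameterError("eps must be positive")
    if min_pts < 1:
        raise ParameterError("min_pts must be >= 1")
    coords = emb.coords
    if eps is None:
        eps = default_eps(coords)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords)
    return ClusterAssignment(emb.seq_ids, labels)


def congruence(clusters: ClusterAssignment, reference: ReferenceSet) -> float:
    """Adjusted Rand index between the cluster partition and the clade
    partition over shared ids; noise points count as singleton groups."""
    ref = reference.as_dict()
    shared = [i for i, sid in enumerate(clusters.seq_ids) if sid in ref]
    if len(shared) < 2:
        raise InsufficientOverlapError(
            f"only {len(shared)} ids shared between clusters and reference"
        )
    clade_labels = [ref[clusters.seq_ids[i]] for i in shared]
    raw = clusters.labels[shared].astype(object)
    singleton = -2
    cluster_labels = []
    for lab in raw:
        if lab == -1:
            cluster_labels.append(singleton)
            singleton -= 1
        else:
            cluster_labels.append(int(lab))
    return float(adjusted_rand_score(clade_labels, cluster_labels))


def run_pipeline(matrix: pd.DataFrame, method: str = "tsne", perplexity: float = 30.0,
                 seed: int = 0, eps: float | None = None, min_pts: int = 5):
    """normalize -> embed -> cluster; returns (embedding, clusters)."""
    emb = embed_2d(normalize_scores(matrix), method=method, perplexity=perplexity, seed=seed)
    return emb, cluster_embedding(emb, eps=eps, min_pts=min_pts)


def select_panel(candidates, training_seqs, reference: ReferenceSet,
                 panel_size: int = 30, trials: int = 10, seed: int = 0,
                 method: str = "tsne", perplexity: float = 30.0,
                 min_pts: int = 5, return_trials: bool = False):
    """Choose the profile subset whose embedding best matches the clades.

    Draws ``trials`` seeded random subsets of size ``panel_size``, runs
    the full pipeline on the training sequences for each, and returns
    the subset with the highest ARI (ties: first drawn). The per-trial
    ARI table is logged, and returned as well when ``return_trials``.
    """
    candidates = list(candidates)
    if panel_size > len(candidates):
        raise ParameterError("panel_size exceeds number of candidate profiles")
    if trials < 1:
        raise ParameterError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    rows = []
    for trial in range(trials):
        picked = sorted(rng.choice(len(candidates), size=panel_size, replace=False))
        panel = [candidates[i] for i in picked]
        matrix = score_panel(training_seqs, panel)
        _, clusters = run_pipeline(
            matrix, method=method, perplexity=perplexity,
            seed=int(rng.integers(0, 2**31 - 1)), min_pts=min_pts,
        )
        ari = congruence(clusters, reference)
        rows.append({"trial": trial, "ari": ari,
                     "panel": ",".join(h.name for h in panel)})
        logger.info("panel trial %d: ARI=%.4f (%d profiles)", trial, ari, panel_size)
        if best is None or ari > best[0]:
            best = (ari, panel)
    table = pd.DataFrame(rows)
    logger.info("selected panel with ARI=%.4f", best[0])
    if return_trials:
        return best[1], table
    return best[1]


def classify_by_reference(emb: Embedding2D, reference: ReferenceSet,
                          query_ids, k: int = 5) -> pd.DataFrame:
    """Label queries by majority vote of their k nearest reference
    points in the embedding (Euclidean); confidence is the vote
    fraction, ties broken by the single nearest neighbor."""
    pos = {sid: i for i, sid in enumerate(emb.seq_ids)}
    ref_ids = [sid for sid in reference.seq_ids if sid in pos]
    if not ref_ids:
        raise UnknownIdError("no reference ids present in the embedding")
    if k < 1 or k > len(ref_ids):
        raise ParameterError(f"k must lie in [1, {len(ref_ids)}]")
    ref_dict = reference.as_dict()
    ref_coords = emb.coords[[pos[sid] for sid in ref_ids]]
    ref_labels = np.array([ref_dict[sid] for sid in ref_ids], dtype=object)
    missing = [q for q in query_ids if q not in pos]
    if missing:
        raise UnknownIdError(f"query ids absent from embedding: {missing[:5]}")
    q_coords = emb.coords[[pos[q] for q in query_ids]]
    nn = NearestNeighbors(n_neighbors=k).fit(ref_coords)
    dist, idx = nn.kneighbors(q_coords)
    out = []
    for qi, q in enumerate(query_ids):
        votes = ref_labels[idx[qi]]
        uniq, counts = np.unique(votes, return_counts=True)
        top = counts.max()
        winners = set(uniq[counts == top])
        if len(winners) > 1:  # tie: nearest single neighbor decides
            label = next(v for v in votes if v in winners)
        else:
            label = uniq[np.argmax(counts)]
        out.append({"seq_id": q, "label": label, "confidence": top / k})
    return pd.DataFrame(out).set_index("seq_id")


class AFPKFinder(ClassifierMixin, BaseEstimator):
    """Reference-guided embedding classifier over score matrices.

    ``fit`` stores reference score vectors with their clade labels;
    ``predict`` embeds reference and query rows jointly (normalize ->
    t-SNE/PCA) and labels each query by a k-NN vote among references.
    Because t-SNE has no out-of-sample transform, every predict call
    re-embeds; with ``method="pca"`` the pipeline is fully deterministic.

    Parameters
    ----------
    method : "tsne" | "pca"
    perplexity : float, t-SNE neighborhood size.
    n_neighbors : int, size of the reference vote.
    eps, min_pts : DBSCAN parameters for :meth:`cluster`.
    random_state : int seed for the embedding.
    """

    def __init__(self, method: str = "tsne", perplexity: float = 30.0,
                 n_neighbors: int = 5, eps: float | None = None,
                 min_pts: int = 5, random_state: int = 0):
        self.method = method
        self.perplexity = perplexity
        self.n_neighbors = n_neighbors
        self.eps = eps
        self.min_pts = min_pts
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if y.shape[0] != X.shape[0]:
            raise ParameterError("X and y must have the same number of rows")
        self.X_reference_ = X.copy()
        self.y_reference_ = y.copy()
        self.classes_ = np.unique(y.astype(str))
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_embedding(self, X_query: np.ndarray | None):
        n_ref = self.X_reference_.shape[0]
        ref_ids = [f"ref{i}" for i in range(n_ref)]
        if X_query is None:
            all_X, ids, query_ids = self.X_reference_, ref_ids, []
        else:
            query_ids = [f"query{i}" for i in range(X_query.shape[0])]
            all_X = np.vstack([self.X_reference_, X_query])
            ids = ref_ids + query_ids
        frame = pd.DataFrame(all_X, index=ids)
        frame.columns = [str(c) for c in frame.columns]
        emb = embed_2d(
            normalize_scores(frame), method=self.method,
            perplexity=self.perplexity, seed=self.random_state,
        )
        ref = ReferenceSet(tuple(ref_ids), tuple(str(v) for v in self.y_reference_))
        return emb, ref, query_ids

    def predict(self, X):
        return self.predict_with_confidence(X)["label"].to_numpy()

    def predict_with_confidence(self, X) -> pd.DataFrame:
        check_is_fitted(self, "X_reference_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ParameterError("query feature count differs from reference")
        emb, ref, query_ids = self._joint_embedding(X)
        return classify_by_reference(emb, ref, query_ids, k=self.n_neighbors)

    def cluster(self, X=None) -> ClusterAssignment:
        """Cluster the joint embedding of reference (and optional query) rows."""
        check_is_fitted(self, "X_reference_")
        if X is not None:
            X = check_array(X, dtype=float)
        emb, _, _ = self._joint_embedding(X)
        return cluster_embedding(emb, eps=self.eps, min_pts=self.min_pts)
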