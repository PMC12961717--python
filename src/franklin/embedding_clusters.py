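"""Diagnosis-code embeddings from co-occurrence, clusters, and max-similarity features.

The feature pipeline has three stages:

1. count how often pairs of codes co-occur within a beneficiary's one-year
   diagnosis set (profiles are unordered sets — no windowing);
2. embed each code as a dense d-dimensional vector (default d=50) via a
   positive pointwise-mutual-information transform of the co-occurrence
   matrix followed by rank-d truncated SVD, rows scaled by singular
   values**alpha.  PPMI+SVD is deterministic given a seed and is the
   classical count-based route to word-vector-quality embeddings;
3. group the embeddings into k clusters (default k=250) with spherical
   k-means (k-means on length-normalized vectors).

A beneficiary's feature vector has one entry per cluster: the maximum
cosine similarity between any of their code embeddings and the cluster
center.  A single code can therefore contribute to several clusters, and
beneficiaries with no in-vocabulary codes get the zero vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.utils.extmath import randomized_svd

from .claims_io import Cohort

__all__ = [
    "CooccurrenceMatrix",
    "EmbeddingModel",
    "ClusterModel",
    "build_cooccurrence",
    "train_embeddings",
    "fit_clusters",
    "cluster_stability",
    "compute_cluster_features",
    "cluster_feature_matrix",
]

DEFAULT_DIM = 50
DEFAULT_K = 250
DEFAULT_MIN_COUNT = 5


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric within-profile co-occurrence counts over a code vocabulary."""

    vocab: tuple[str, ...]
    counts: sp.csr_matrix  # (V, V), symmetric, zero diagonal
    marginals: np.ndarray  # profiles containing each code
    n_profiles: int

    @property
    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.vocab)}


@dataclass(frozen=True)
class EmbeddingModel:
    """Dense code -> vector map of dimension d."""

    vocab: tuple[str, ...]
    vectors: np.ndarray  # (V, d)
    d: int
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.vocab), self.d):
            raise ValueError("vectors shape must be (len(vocab), d)")

    @property
    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.vocab)}

    def vector(self, code: str) -> np.ndarray | None:
        i = self.index.get(code)
        return None if i is None else self.vectors[i]


@dataclass(frozen=True)
class ClusterModel:
    """k cluster centers over embedding space plus a code assignment."""

    centers: np.ndarray  # (k, d)
    assignments: np.ndarray  # (V,) cluster index per vocabulary code
    inertia: float
    seed: int

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def build_cooccurrence(
    cohort: Cohort, min_count: int = DEFAULT_MIN_COUNT
) -> CooccurrenceMatrix:
    """Count unordered within-profile code pairs over a cohort.

    The vocabulary is restricted to codes appearing in at least
    ``min_count`` profiles; each profile increments every unordered pair of
    its distinct in-vocabulary codes by one.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty; cannot build co-occurrence counts")
    profile_counts: dict[str, int] = {}
    for codes in cohort.dx:
        for c in codes:
            profile_counts[c] = profile_counts.get(c, 0) + 1
    vocab = tuple(sorted(c for c, n in profile_counts.items() if n >= min_count))
    if not vocab:
        raise ValueError(
            f"no code appears in >= {min_count} profiles; vocabulary is empty"
        )
    index = {c: i for i, c in enumerate(vocab)}

    rows: list[int] = []
    cols: list[int] = []
    for codes in cohort.dx:
        idx = sorted(index[c] for c in codes if c in index)
        for a_pos, a in enumerate(idx):
            for b in idx[a_pos + 1 :]:
                rows.append(a)
                cols.append(b)
    v = len(vocab)
    data = np.ones(len(rows))
    upper = sp.coo_matrix((data, (rows, cols)), shape=(v, v)).tocsr()
    counts = (upper + upper.T).tocsr()
    marginals = np.array([profile_counts[c] for c in vocab], dtype=float)
    return CooccurrenceMatrix(
        vocab=vocab, counts=counts, marginals=marginals, n_profiles=len(cohort)
    )


def _ppmi(counts) -> np.ndarray:
    """Positive pointwise mutual information of a symmetric count matrix."""
    c = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    total = c.sum()
    if total == 0:
        return np.zeros_like(c)
    row = c.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(c * total / (row @ row.T))
    pmi[~np.isfinite(pmi)] = 0.0
    return np.maximum(pmi, 0.0)


def _svd_factors(
    m: np.ndarray, d: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-d randomized SVD factors (u, s, vt) of a dense matrix."""
    return randomized_svd(m, n_components=d, random_state=seed)


def train_embeddings(
    cooc: CooccurrenceMatrix,
    d: int = DEFAULT_DIM,
    alpha: float = 0.5,
    seed: int = 0,
) -> EmbeddingModel:
    """PPMI + truncated SVD embeddings; rows scaled by singular_values**alpha.

    The embedding of a code is the sum of its "word" and "context" factor
    rows, u_i * s**alpha + v_i * s**alpha.  For the symmetric PPMI matrix
    this cancels the negative-eigenvalue directions, so codes that directly
    co-occur — not just codes with shared neighbors — come out similar.
    If the vocabulary has fewer than d+1 codes, d is clipped to
    ``len(vocab) - 1`` with a warning.
    """
    v = len(cooc.vocab)
    if v == 0:
        raise ValueError("empty vocabulary")
    if d >= v:
        warnings.warn(f"embedding dim {d} >= vocabulary {v}; clipping to {v - 1}")
        d = v - 1
    if d < 1:
        raise ValueError("vocabulary too small to embed (need >= 2 codes)")
    m = _ppmi(cooc.counts)
    u, s, vt = _svd_factors(m, d, seed)
    scale = s**alpha
    vectors = u * scale + vt.T * scale
    meta = {
        "n_profiles": cooc.n_profiles,
        "seed": seed,
        "alpha": alpha,
        "method": "ppmi_svd_wc",
    }
    return EmbeddingModel(vocab=cooc.vocab, vectors=vectors, d=d, meta=meta)


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return x / safe


def fit_clusters(
    emb: EmbeddingModel, k: int = DEFAULT_K, seed: int = 0, n_init: int = 10
) -> ClusterModel:
    """Spherical k-means over the code embeddings (best of ``n_init`` restarts)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    v = len(emb.vocab)
    if k > v:
        warnings.warn(f"k={k} exceeds vocabulary {v}; clipping to {v}")
        k = v
    unit = _normalize_rows(emb.vectors)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(unit)
    return ClusterModel(
        centers=km.cluster_centers_,
        assignments=labels,
        inertia=float(km.inertia_),
        seed=seed,
    )


def compute_cluster_features(
    dx_codes: Iterable[str], emb: EmbeddingModel, clusters: ClusterModel
) -> np.ndarray:
    """Max cosine similarity of any profile code to each cluster center.

    Out-of-vocabulary codes are ignored; an empty (or fully
    out-of-vocabulary) profile maps to the zero vector.
    """
    index = emb.index
    idx = [index[c] for c in dx_codes if c in index]
    if not idx:
        return np.zeros(clusters.k)
    code_unit = _normalize_rows(emb.vectors[idx])
    center_unit = _normalize_rows(clusters.centers)
    sims = code_unit @ center_unit.T  # (n_codes, k)
    return sims.max(axis=0)


def cluster_feature_matrix(
    cohort: Cohort, emb: EmbeddingModel, clusters: ClusterModel
) -> np.ndarray:
    """Stack per-beneficiary cluster features into an (n, k) matrix."""
    index = emb.index
    code_unit = _normalize_rows(emb.vectors)
    center_unit = _normalize_rows(clusters.centers)
    sims = code_unit @ center_unit.T  # (V, k)
    out = np.zeros((len(cohort), clusters.k))
    for i, codes in enumerate(cohort.dx):
        idx = [index[c] for c in codes if c in index]
        if idx:
            out[i] = sims[idx].max(axis=0)
    return out


def cluster_stability(
    cohort: Cohort,
    d: int = DEFAULT_DIM,
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_COUNT,
    n_boot: int = 5,
    seed: int = 0,
    resample_seeds: Sequence[int] | None = None,
) -> dict:
    """Bootstrap stability of the code partition.

    Refits embeddings+clusters on ``n_boot`` bootstrap resamples of the
    cohort and reports the mean pairwise adjusted Rand index between code
    partitions, computed over the codes common to each pair of vocabularies.
    ``resample_seeds`` pins the per-bootstrap resampling seed (identical
    seeds give identical resamples, hence agreement exactly 1).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if resample_seeds is None:
        resample_seeds = [seed + b + 1 for b in range(n_boot)]
    if len(resample_seeds) != n_boot:
        raise ValueError("resample_seeds length must equal n_boot")
    partitions: list[dict[str, int]] = []
    for rs in resample_seeds:
        rng = np.random.default_rng(rs)
        idx = rng.integers(0, len(cohort), size=len(cohort))
        # bootstrap with replacement: build an index-resampled cohort
        table = cohort.table.iloc[idx].copy()
        table["id"] = [f"{bid}_r{j}" for j, bid in enumerate(table["id"])]
        boot = Cohort(table, [cohort.dx[i] for i in idx])
        cooc = build_cooccurrence(boot, min_count=min_count)
        emb = train_embeddings(cooc, d=d, seed=rs)
        clus = fit_clusters(emb, k=k, seed=rs)
        partitions.append(dict(zip(emb.vocab, clus.assignments)))
    scores = []
    for a in range(n_boot):
        for b in range(a + 1, n_boot):
            common = sorted(set(partitions[a]) & set(partitions[b]))
            if len(common) < 2:
                continue
            la = [partitions[a][c] for c in common]
            lb = [partitions[b][c] for c in common]
            scores.append(adjusted_rand_score(la, lb))
    return {
        "mean_adjusted_agreement": float(np.mean(scores)) if scores else float("nan"),
        "pairwise_scores": scores,
        "n_boot": n_boot,
    }
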