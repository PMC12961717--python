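import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from franklin.claims_io import Cohort
from franklin.embedding_clusters import (
    ClusterModel,
    EmbeddingModel,
    build_cooccurrence,
    cluster_feature_matrix,
    cluster_stability,
    compute_cluster_features,
    fit_clusters,
    train_embeddings,
)
from franklin.synthetic_cohort import GeneratorConfig, generate_cohort


def _cohort_from_profiles(profiles):
    table = pd.DataFrame(
        {
            "id": [f"B{i}" for i in range(len(profiles))],
            "age": 70,
            "sex": "F",
            "observed_cost": 100.0,
        }
    )
    return Cohort(table, [frozenset(p) for p in profiles])


def test_cooccurrence_enumerates_unordered_pairs():
    cohort = _cohort_from_profiles([{"A01", "B02", "C03"}] * 5)
    cooc = build_cooccurrence(cohort, min_count=1)
    idx = cooc.index
    m = cooc.counts.toarray()
    for a, b in (("A01", "B02"), ("A01", "C03"), ("B02", "C03")):
        assert m[idx[a], idx[b]] == 5
        assert m[idx[b], idx[a]] == 5
    assert np.all(np.diag(m) == 0)
    assert np.array_equal(m, m.T)


def test_single_code_profiles_have_zero_pair_counts():
    cohort = _cohort_from_profiles([{"A01"}, {"B02"}, {"A01"}, {"B02"}, {"A01"}, {"B02"}])
    cooc = build_cooccurrence(cohort, min_count=1)
    assert cooc.counts.nnz == 0
    assert cooc.n_profiles == 6


def test_min_count_filters_rare_codes():
    cohort = _cohort_from_profiles([{"A01", "B02"}] * 5 + [{"Z99", "A01"}])
    cooc = build_cooccurrence(cohort, min_count=5)
    assert "Z99" not in cooc.vocab
    assert set(cooc.vocab) == {"A01", "B02"}


def test_empty_split_raises():
    cohort = _cohort_from_profiles([])
    with pytest.raises(ValueError):
        build_cooccurrence(cohort)


def test_within_condition_pairs_outnumber_cross_condition_pairs(small_cohort):
    """Mean within-condition pair count exceeds the cross-condition mean."""
    cohort, truth = small_cohort
    cooc = build_cooccurrence(cohort, min_count=1)
    idx = cooc.index
    m = cooc.counts.toarray()
    within, cross = [], []
    conds = {c: sorted(truth.condition_codes(c) & set(cooc.vocab))
             for c in range(truth.config.n_latent_conditions)}
    for c, codes in conds.items():
        for i, a in enumerate(codes):
            for b in codes[i + 1 :]:
                within.append(m[idx[a], idx[b]])
        for c2, codes2 in conds.items():
            if c2 <= c:
                continue
            for a in codes[:4]:
                for b in codes2[:4]:
                    cross.append(m[idx[a], idx[b]])
    assert np.mean(within) > np.mean(cross)


def test_exclusive_pair_has_highest_embedding_similarity():
    """Two codes that only co-occur with each other end up most similar.

    Four-code toy: {A01, B02} profiles and {C03, D04} profiles never mix,
    so within-pair cosine must beat every cross-pair cosine.
    """
    profiles = [{"A01", "B02"}] * 20 + [{"C03", "D04"}] * 20
    cohort = _cohort_from_profiles(profiles)
    cooc = build_cooccurrence(cohort, min_count=1)
    emb = train_embeddings(cooc, d=3, seed=0)

    def cos(a, b):
        va, vb = emb.vector(a), emb.vector(b)
        return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

    assert cos("A01", "B02") > cos("A01", "C03") + 0.5
    assert cos("A01", "B02") > cos("A01", "D04") + 0.5
    assert cos("C03", "D04") > cos("B02", "D04") + 0.5


def test_full_rank_svd_factors_reconstruct_ppmi():
    profiles = [{"A01", "B02"}] * 8 + [{"B02", "C03"}] * 8 + [{"A01", "C03", "D04"}] * 8
    cohort = _cohort_from_profiles(profiles)
    cooc = build_cooccurrence(cohort, min_count=1)
    from franklin.embedding_clusters import _ppmi, _svd_factors

    target = _ppmi(cooc.counts.toarray() if hasattr(cooc.counts, "toarray") else cooc.counts)
    u, s, vt = _svd_factors(target, d=len(cooc.vocab), seed=0)
    recon = (u * s) @ vt
    assert np.allclose(recon, target, atol=1e-8)


def test_embeddings_deterministic_for_seed(small_cohort):
    cohort, _ = small_cohort
    cooc = build_cooccurrence(cohort, min_count=2)
    a = train_embeddings(cooc, d=10, seed=3)
    b = train_embeddings(cooc, d=10, seed=3)
    assert np.array_equal(a.vectors, b.vectors)


def test_two_block_data_recovers_partition_with_k2():
    rng = np.random.default_rng(0)
    profiles = []
    block_a = [f"A{i:02d}" for i in range(5)]
    block_b = [f"B{i:02d}" for i in range(5)]
    for _ in range(150):
        block = block_a if rng.random() < 0.5 else block_b
        profiles.append({c for c in block if rng.random() < 0.8})
    cohort = _cohort_from_profiles([p for p in profiles if len(p) >= 2])
    cooc = build_cooccurrence(cohort, min_count=1)
    emb = train_embeddings(cooc, d=4, seed=0)
    clus = fit_clusters(emb, k=2, seed=0)
    truth_labels = [0 if c.startswith("A") else 1 for c in emb.vocab]
    assert adjusted_rand_score(truth_labels, clus.assignments) == 1.0


def test_k_equal_vocab_gives_zero_inertia(small_cohort):
    cohort, _ = small_cohort
    cooc = build_cooccurrence(cohort, min_count=10)
    emb = train_embeddings(cooc, d=8, seed=0)
    clus = fit_clusters(emb, k=len(emb.vocab), seed=0, n_init=2)
    assert clus.inertia == pytest.approx(0.0, abs=1e-9)


def test_clusters_deterministic_and_k_validation(small_cohort):
    cohort, _ = small_cohort
    cooc = build_cooccurrence(cohort, min_count=5)
    emb = train_embeddings(cooc, d=8, seed=0)
    a = fit_clusters(emb, k=4, seed=2)
    b = fit_clusters(emb, k=4, seed=2)
    assert np.array_equal(a.centers, b.centers)
    with pytest.raises(ValueError):
        fit_clusters(emb, k=1)
    with pytest.warns(UserWarning, match="clipping"):
        clipped = fit_clusters(emb, k=len(emb.vocab) + 50, seed=0, n_init=1)
    assert clipped.k == len(emb.vocab)


def test_features_match_hand_computed_cosines():
    emb = EmbeddingModel(
        vocab=("A01", "B02"),
        vectors=np.array([[1.0, 0.0], [1.0, 1.0]]),
        d=2,
    )
    clusters = ClusterModel(
        centers=np.array([[2.0, 0.0], [0.0, 3.0]]),
        assignments=np.array([0, 1]),
        inertia=0.0,
        seed=0,
    )
    f = compute_cluster_features({"A01", "B02"}, emb, clusters)
    # cluster 0: max(cos(A,c0)=1, cos(B,c0)=1/sqrt2); cluster 1: max(0, 1/sqrt2)
    assert f == pytest.approx([1.0, 1.0 / np.sqrt(2)])

    single = compute_cluster_features({"A01"}, emb, clusters)
    assert single == pytest.approx([1.0, 0.0])


def test_code_at_center_scores_one_and_empty_profile_zero():
    emb = EmbeddingModel(vocab=("A01",), vectors=np.array([[0.0, 2.0]]), d=2)
    clusters = ClusterModel(
        centers=np.array([[1.0, 0.0], [0.0, 0.5]]),
        assignments=np.array([1]),
        inertia=0.0,
        seed=0,
    )
    f = compute_cluster_features({"A01"}, emb, clusters)
    assert f[1] == pytest.approx(1.0)
    assert np.array_equal(compute_cluster_features(set(), emb, clusters), np.zeros(2))
    # out-of-vocabulary codes are ignored
    assert np.array_equal(compute_cluster_features({"Z99"}, emb, clusters), np.zeros(2))


def test_adding_codes_never_decreases_features(small_cohort):
    cohort, _ = small_cohort
    cooc = build_cooccurrence(cohort, min_count=2)
    emb = train_embeddings(cooc, d=8, seed=0)
    clus = fit_clusters(emb, k=5, seed=0)
    rng = np.random.default_rng(1)
    vocab = list(emb.vocab)
    for _ in range(20):
        base = set(rng.choice(vocab, size=3, replace=False))
        extra = base | set(rng.choice(vocab, size=2, replace=False))
        f_base = compute_cluster_features(base, emb, clus)
        f_extra = compute_cluster_features(extra, emb, clus)
        assert np.all(f_extra >= f_base - 1e-12)


def test_feature_matrix_agrees_with_per_profile_computation(small_cohort):
    cohort, _ = small_cohort
    sub = cohort.subset(np.arange(len(cohort)) < 40)
    cooc = build_cooccurrence(cohort, min_count=2)
    emb = train_embeddings(cooc, d=8, seed=0)
    clus = fit_clusters(emb, k=5, seed=0)
    mat = cluster_feature_matrix(sub, emb, clus)
    for i in range(len(sub)):
        assert mat[i] == pytest.approx(compute_cluster_features(sub.dx[i], emb, clus))
    assert np.all(mat >= -1 - 1e-12) and np.all(mat <= 1 + 1e-12)


def test_features_maximal_at_own_condition_cluster(blocked_cohort):
    """With k = K well-separated conditions, a single-condition beneficiary's
    largest feature sits at that condition's cluster."""
    cohort, truth = blocked_cohort
    cooc = build_cooccurrence(cohort, min_count=5)
    emb = train_embeddings(cooc, d=20, seed=0)
    clus = fit_clusters(emb, k=truth.config.n_latent_conditions, seed=0)
    # map each condition to the modal cluster of its codes
    idx = emb.index
    cond_cluster = {}
    for c in range(truth.config.n_latent_conditions):
        codes = [idx[x] for x in truth.condition_codes(c) if x in idx]
        labels = clus.assignments[codes]
        cond_cluster[c] = np.bincount(labels).argmax()
    z = truth.condition_indicators
    single = np.flatnonzero((z.sum(axis=1) == 1))
    checked = 0
    for i in single[:100]:
        if len(cohort.dx[i]) < 2:
            continue
        c = int(np.flatnonzero(z[i])[0])
        f = compute_cluster_features(cohort.dx[i], emb, clus)
        if f.max() > 0:
            assert f.argmax() == cond_cluster[c]
            checked += 1
    assert checked > 20


def test_stability_identical_resamples_agree_exactly(small_cohort):
    cohort, _ = small_cohort
    emb_half = cohort.subset(np.arange(len(cohort)) < 300)
    rec = cluster_stability(
        emb_half, d=6, k=4, min_count=3, n_boot=2, resample_seeds=(5, 5)
    )
    assert rec["mean_adjusted_agreement"] == pytest.approx(1.0)


def test_stability_blocked_exceeds_noise():
    blocked_cfg = GeneratorConfig(
        n_beneficiaries=1500, n_latent_conditions=5, vocab_size=40,
        codes_per_condition=8, code_emission_prob=0.9, noise_code_rate=0.0,
        zero_dx_fraction=0.0, seed=3,
    )
    noise_cfg = GeneratorConfig(
        n_beneficiaries=1500, n_latent_conditions=5, vocab_size=40,
        codes_per_condition=8, code_emission_prob=0.0, noise_code_rate=6.0,
        zero_dx_fraction=0.0, seed=3,
    )
    blocked, _ = generate_cohort(blocked_cfg)
    noise, _ = generate_cohort(noise_cfg)
    rb = cluster_stability(blocked, d=6, k=5, min_count=5, n_boot=3, seed=0)
    rn = cluster_stability(noise, d=6, k=5, min_count=5, n_boot=3, seed=0)
    assert rb["mean_adjusted_agreement"] >= 0.95
    assert rn["mean_adjusted_agreement"] < rb["mean_adjusted_agreement"]
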