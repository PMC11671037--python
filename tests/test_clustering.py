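import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score, silhouette_score

from turnmap.clustering import (
    NOISE,
    angular_distance,
    angular_distance_matrix,
    assign_to_reference,
    choose_k,
    dbscan,
    hybrid_bb_cluster,
    pam_kmedoids,
    read_reference_medoids,
    split_cluster,
    ClusterResult,
)
from turnmap.turn_detection import CLASSICAL_IDEALS


# ---------------------------------------------------------------------------
# metric
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "u,v,expected",
    [
        ((180, 0), (-180, 0), 0.0),
        ((170, 0), (-170, 0), 20.0),
        ((0, 0, 0, 0), (30, 40, 0, 0), 50.0),
    ],
)
def test_angular_distance_wraparound(u, v, expected):
    assert angular_distance(u, v) == pytest.approx(expected)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(-180, 180), min_size=4, max_size=4),
       st.lists(st.floats(-180, 180), min_size=4, max_size=4))
def test_angular_distance_is_a_metric_sample(u, v):
    assert angular_distance(u, u) == 0.0
    d = angular_distance(u, v)
    assert d == pytest.approx(angular_distance(v, u))
    assert 0 <= d <= np.sqrt(4 * 180.0 ** 2)


def test_angular_distance_length_mismatch():
    with pytest.raises(ValueError):
        angular_distance((0, 0), (0, 0, 0))


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def brute_force_pam(D, k):
    """Exhaustive optimum over medoid subsets; ties to the lexicographically
    smallest subset."""
    n = D.shape[0]
    best = None
    for subset in itertools.combinations(range(n), k):
        cost = D[:, subset].min(axis=1).sum()
        if best is None or cost < best[0] - 1e-12:
            best = (cost, subset)
    return best


def test_pam_two_pairs():
    x = np.array([0.0, 1.0, 10.0, 11.0])
    D = np.abs(x[:, None] - x[None, :])
    res = pam_kmedoids(D, 2)
    assert res.labels == [0, 0, 1, 1]
    cost = sum(D[i, res.medoid_index[l]] for i, l in enumerate(res.labels))
    assert cost == pytest.approx(brute_force_pam(D, 2)[0])


def test_pam_k1_is_row_sum_argmin(rng):
    pts = rng.normal(size=12)
    D = np.abs(pts[:, None] - pts[None, :])
    res = pam_kmedoids(D, 1)
    assert res.medoid_index[0] == int(D.sum(axis=1).argmin())


def test_pam_kn_zero_cost(rng):
    pts = rng.normal(size=6)
    D = np.abs(pts[:, None] - pts[None, :])
    res = pam_kmedoids(D, 6)
    assert sorted(res.medoid_index.values()) == list(range(6))
    assert all(res.sizes[l] == 1 for l in range(6))


def test_pam_matches_brute_force_on_planted_instances(rng):
    """100 planted instances (n <= 10, k <= 3): PAM attains the exhaustive
    optimum cost."""
    for trial in range(100):
        k = int(rng.integers(1, 4))
        n = int(rng.integers(k + 1, 11))
        centers = rng.uniform(-50, 50, size=k)
        pts = np.sort(
            np.concatenate(
                [rng.normal(c, 1.0, size=max(1, n // k)) for c in centers]
            )[:n]
        )
        if len(pts) < n:
            pts = np.concatenate([pts, rng.uniform(-50, 50, size=n - len(pts))])
        D = np.abs(pts[:, None] - pts[None, :])
        res = pam_kmedoids(D, k)
        cost = sum(D[i, res.medoid_index[l]] for i, l in enumerate(res.labels))
        assert cost == pytest.approx(brute_force_pam(D, k)[0], abs=1e-9)


def test_pam_rejects_bad_k():
    D = np.zeros((3, 3))
    with pytest.raises(ValueError):
        pam_kmedoids(D, 4)


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------

def test_dbscan_separated_pairs_and_noise():
    x = np.array([0.0, 1.0, 10.0, 11.0])
    D = np.abs(x[:, None] - x[None, :])
    assert dbscan(D, 2.0, 2) == [0, 0, 1, 1]
    x5 = np.array([0.0, 1.0, 10.0, 11.0, 100.0])
    D5 = np.abs(x5[:, None] - x5[None, :])
    assert dbscan(D5, 2.0, 2) == [0, 0, 1, 1, NOISE]
    assert dbscan(D5, 1000.0, 2) == [0, 0, 0, 0, 0]


def test_dbscan_permutation_invariant(rng):
    pts = np.concatenate([rng.normal(0, 1, 40), rng.normal(30, 1, 40), [200.0]])
    D = np.abs(pts[:, None] - pts[None, :])
    base = dbscan(D, 3.0, 4)
    for _ in range(5):
        perm = rng.permutation(len(pts))
        Dp = D[np.ix_(perm, perm)]
        permuted = dbscan(Dp, 3.0, 4)
        # noise set identical; clusters identical up to relabeling
        base_p = [base[i] for i in perm]
        assert [l == NOISE for l in permuted] == [l == NOISE for l in base_p]
        keep = [i for i, l in enumerate(permuted) if l != NOISE]
        assert adjusted_rand_score(
            [permuted[i] for i in keep], [base_p[i] for i in keep]
        ) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def test_choose_k_two_blobs(rng):
    pts = np.r_[rng.normal(0, 1, (30, 3)), rng.normal(25, 1, (30, 3))]
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    assert choose_k(D, 6) == 2


def test_choose_k_three_rotamer_groups(rng):
    centers = np.array([[-60.0], [60.0], [180.0]])
    pts = np.concatenate([c + rng.normal(0, 5, (30, 1)) for c in centers])
    D = angular_distance_matrix(pts)
    assert choose_k(D, 6) == 3


def test_choose_k_single_diffuse_blob_matches_direct_evaluation(rng):
    """A featureless high-dimensional blob: the directly evaluated silhouette
    stays below the acceptance threshold for every k, so one cluster."""
    pts = rng.normal(0, 1, (50, 8))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    best = max(
        silhouette_score(D, pam_kmedoids(D, k).labels, metric="precomputed")
        for k in range(2, 7)
    )
    assert best < 0.25
    assert choose_k(D, 6) == 1


def test_choose_k_degenerate_inputs():
    assert choose_k(np.zeros((1, 1)), 5) == 1
    assert choose_k(np.zeros((10, 10)), 5) == 1  # identical items


# ---------------------------------------------------------------------------
# hybrid backbone clustering
# ---------------------------------------------------------------------------

def _planted_vectors(rng, names=("I", "II", "I'"), n_each=200, sd=10.0):
    vecs, truth = [], []
    for ci, name in enumerate(names):
        ideal = np.array(CLASSICAL_IDEALS[name][0])
        vecs.extend(ideal + rng.normal(0, sd, size=(n_each, 4)))
        truth.extend([ci] * n_each)
    return np.array(vecs), truth


def test_hybrid_recovers_planted_types(rng):
    vecs, truth = _planted_vectors(rng)
    res = hybrid_bb_cluster(vecs)
    assert len(res.sizes) == 3
    assert adjusted_rand_score(truth, res.labels) >= 0.95
    assert sum(res.sizes.values()) == len(vecs)  # noise folded back in


def test_hybrid_single_component_and_determinism(rng):
    vecs, _ = _planted_vectors(rng, names=("I",), n_each=120)
    res = hybrid_bb_cluster(vecs)
    assert len(res.sizes) == 1
    res2 = hybrid_bb_cluster(vecs)
    assert res.labels == res2.labels and res.medoid_index == res2.medoid_index


def test_hybrid_zero_core_fallback(rng):
    vecs = rng.uniform(-180, 180, size=(12, 4))
    res = hybrid_bb_cluster(vecs, eps=1.0, min_pts=10)
    assert len(res.sizes) == 1 and res.sizes[0] == 12


# ---------------------------------------------------------------------------
# reference assignment and the AD-style split
# ---------------------------------------------------------------------------

def _reference_scheme(rng, n_labels=18, per=12):
    """Synthetic labeled clustering standing in for a published reference
    backbone scheme."""
    rng2 = np.random.default_rng(7)
    centers = rng2.uniform(-170, 170, size=(n_labels, 4))
    vecs = np.concatenate([c + rng2.normal(0, 2, (per, 4)) for c in centers])
    labels = [f"BB{chr(65 + i)}" for i in range(n_labels) for _ in range(per)]
    sizes = {f"BB{chr(65 + i)}": per for i in range(n_labels)}
    medoids = {f"BB{chr(65 + i)}": i * per for i in range(n_labels)}
    return ClusterResult(labels=labels, medoid_index=medoids, sizes=sizes), vecs


def test_split_cluster_grows_label_set_and_conserves(rng):
    result, vecs = _reference_scheme(rng)
    # make one cluster clearly the largest and internally structured
    target = "BBA"
    extra = np.concatenate(
        [vecs[result.labels.index(target)] + off + rng.normal(0, 1, (10, 4))
         for off in (0.0, 25.0, -25.0)]
    )
    vecs = np.concatenate([vecs, extra])
    labels = result.labels + [target] * 30
    sizes = dict(result.sizes)
    sizes[target] += 30
    result = ClusterResult(labels=labels, medoid_index=result.medoid_index, sizes=sizes)

    D = angular_distance_matrix(vecs)
    n_before = len(set(result.labels))
    assert n_before == 18
    split = split_cluster(result, D, target, 3)
    after = set(split.labels)
    assert len(after) == 20  # 18 - 1 + 3
    assert {f"{target}_1", f"{target}_2", f"{target}_3"} <= after
    # conservation and ordering by size
    sub_sizes = [split.sizes[f"{target}_{i}"] for i in (1, 2, 3)]
    assert sum(sub_sizes) == sizes[target]
    assert sub_sizes == sorted(sub_sizes, reverse=True)
    # untouched clusters retain members
    assert split.sizes["BBB"] == result.sizes["BBB"]


def test_split_cluster_identity_and_errors(rng):
    result, vecs = _reference_scheme(rng, n_labels=3)
    D = angular_distance_matrix(vecs)
    same = split_cluster(result, D, "BBA", 1)
    assert same.labels == result.labels
    with pytest.raises(ValueError):
        split_cluster(result, D, "BBA", 100)


def test_assign_to_reference_nearest_and_ties():
    ref = {"B": [0.0, 0, 0, 0], "A": [10.0, 0, 0, 0], "C": [170.0, 0, 0, 0]}
    assert assign_to_reference([1.0, 0, 0, 0], ref) == "B"
    assert assign_to_reference([5.0, 0, 0, 0], ref) == "A"  # tie -> alphabetical
    assert assign_to_reference([-175.0, 0, 0, 0], ref) == "C"  # wraparound
    with pytest.raises(ValueError):
        assign_to_reference([0, 0, 0, 0], {})


def test_reference_medoids_tsv_round_trip(tmp_path):
    p = tmp_path / "medoids.tsv"
    p.write_text("# label phi2 psi2 phi3 psi3\nAA1\t-64\t-27\t-90\t-7\nBB2 -60 120 80 5\n")
    ref = read_reference_medoids(p)
    assert set(ref) == {"AA1", "BB2"}
    assert ref["AA1"] == [-64.0, -27.0, -90.0, -7.0]
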