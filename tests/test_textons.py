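import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from droptex.filterbank import apply_filter_bank
from droptex.textons import (
    TextonDictionary,
    TextonMap,
    build_dictionary,
    chi2_distance,
    cluster_image_textons,
    dp_means,
    dp_means_objective,
    label_pixels,
    texton_histogram,
    ward_cluster,
)

# ---------------------------------------------------------------- vb-gmm


def test_vbgmm_single_mode_gives_one_centre(rng):
    X = rng.normal(0.0, 0.1, (2000, 8))
    centres = cluster_image_textons(X, seed=0)
    assert centres.shape == (1, 8)
    assert np.allclose(centres[0], 0.0, atol=0.02)


def test_vbgmm_recovers_two_separated_modes(rng):
    mu = np.zeros(8)
    mu[0] = 1.0  # 10 sigma apart at sigma = 0.1
    X = np.vstack(
        [rng.normal(0, 0.1, (1000, 8)), mu + rng.normal(0, 0.1, (1000, 8))]
    )
    centres = cluster_image_textons(X, seed=0)
    assert centres.shape[0] == 2
    # each true mean recovered within 3 sigma / sqrt(n)
    tol = 3 * 0.1 / np.sqrt(1000)
    for true in (np.zeros(8), mu):
        d = np.linalg.norm(centres - true, axis=1).min()
        assert d < 8 * tol  # L2 over 8 coordinates


def test_vbgmm_degenerate_input_rejected():
    X = np.tile([1.0] * 8, (10, 1))
    with pytest.raises(ValueError):
        cluster_image_textons(X)


# ---------------------------------------------------------------- dp-means


def test_dp_means_single_cluster_when_all_close():
    X = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [0.05, 0.05]])
    centres, z = dp_means(X, lam=1.0)
    assert centres.shape[0] == 1
    assert np.allclose(centres[0], X.mean(axis=0))


def test_dp_means_two_far_points_become_their_own_clusters():
    X = np.array([[0.0, 0.0], [5.0, 5.0]])
    centres, z = dp_means(X, lam=1.0)
    assert centres.shape[0] == 2
    assert sorted(map(tuple, centres)) == sorted(map(tuple, X))


def test_dp_means_input_validation():
    with pytest.raises(ValueError):
        dp_means(np.empty((0, 2)), 1.0)
    with pytest.raises(ValueError):
        dp_means(np.ones((3, 2)), 0.0)


def _all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1 :]
        yield [[first]] + part


def brute_force_dp_objective(X, lam):
    """Exhaustive minimum of the DP-means objective over all partitions."""
    best = np.inf
    for part in _all_partitions(list(range(len(X)))):
        obj = lam ** 2 * len(part)
        for block in part:
            B = X[np.asarray(block)]
            obj += ((B - B.mean(axis=0)) ** 2).sum()
        best = min(best, obj)
    return best


@pytest.mark.parametrize("case", range(40))
def test_dp_means_matches_exhaustive_minimum(case):
    r = np.random.default_rng(case)
    n = int(r.integers(2, 9))
    X = r.uniform(0, 2, (n, 3))
    lam = float(r.uniform(0.3, 1.5))
    centres, z = dp_means(X, lam, seed=case)
    obj = dp_means_objective(X, centres, z, lam)
    assert obj == pytest.approx(brute_force_dp_objective(X, lam), abs=1e-9)


# ---------------------------------------------------------------- dictionary


def _blob_responses(rng, means, n=40, sigma=0.05):
    return np.vstack([m + rng.normal(0, sigma, (n, 8)) for m in means])


def test_build_dictionary_basic_structure(rng):
    means = rng.uniform(-1, 1, (4, 8))
    cmeans = rng.uniform(2, 3, (2, 8))
    precip = [_blob_responses(rng, means) for _ in range(3)]
    crystal, in_mask = [], []
    for _ in range(2):
        resp = _blob_responses(rng, np.vstack([means[:2], cmeans]))
        crystal.append(resp)
        # the last two blobs (80 pts) lie inside the crystal mask
        m = np.zeros(resp.shape[0], dtype=bool)
        m[-80:] = True
        in_mask.append(m)
    d = build_dictionary(precip, crystal, in_mask, lam=0.5, seed=0)
    assert len(d) >= 4
    assert set(d.source) == {"precipitate", "crystal"}
    # ordering invariant: distance to entry 0 non-decreasing
    dist = np.linalg.norm(d.entries - d.entries[0], axis=1)
    assert np.all(np.diff(dist) >= -1e-12)


def test_build_dictionary_duplicate_images_add_nothing(rng):
    means = rng.uniform(-1, 1, (5, 8))
    precip = [_blob_responses(rng, means)]
    crystal = [_blob_responses(rng, means + 3.0)]
    in_mask = [np.ones(crystal[0].shape[0], dtype=bool)]
    d1 = build_dictionary(precip, crystal, in_mask, lam=0.5, seed=0)
    d2 = build_dictionary(
        precip * 3, crystal * 3, in_mask * 3, lam=0.5, seed=0
    )
    assert len(d1) == len(d2)


def test_build_dictionary_target_size_calibration(rng):
    means = rng.uniform(-2, 2, (30, 8))
    precip = [_blob_responses(rng, means, n=10) for _ in range(4)]
    crystal = [_blob_responses(rng, means[:10] + 4.0, n=10)]
    in_mask = [np.ones(crystal[0].shape[0], dtype=bool)]
    for target in (12, 20):
        d = build_dictionary(
            precip, crystal, in_mask, target_size=target, seed=0
        )
        assert len(d) == target


def test_build_dictionary_seed_reproducible(rng):
    means = rng.uniform(-1, 1, (6, 8))
    precip = [_blob_responses(rng, means) for _ in range(2)]
    crystal = [_blob_responses(rng, means + 2.0)]
    in_mask = [np.ones(crystal[0].shape[0], dtype=bool)]
    d1 = build_dictionary(precip, crystal, in_mask, seed=7)
    d2 = build_dictionary(precip, crystal, in_mask, seed=7)
    assert np.array_equal(d1.entries, d2.entries)
    assert np.array_equal(d1.source, d2.source)


def test_build_dictionary_warns_without_crystal_centres(rng):
    means = rng.uniform(-1, 1, (4, 8))
    precip = [_blob_responses(rng, means)]
    crystal = [_blob_responses(rng, means)]
    in_mask = [np.zeros(crystal[0].shape[0], dtype=bool)]  # nothing selected
    with pytest.warns(UserWarning):
        d = build_dictionary(precip, crystal, in_mask, lam=0.5, seed=0)
    assert set(d.source) == {"precipitate"}


def test_dictionary_csv_round_trip(tmp_path, rng):
    entries = rng.normal(0, 1, (10, 8))
    src = np.array(["precipitate"] * 6 + ["crystal"] * 4)
    d = TextonDictionary(entries, src)
    path = tmp_path / "dict.csv"
    d.to_csv(path)
    back = TextonDictionary.from_csv(path)
    assert np.allclose(back.entries, entries)
    assert np.array_equal(back.source, src)


# ---------------------------------------------------------------- labelling


def test_label_exact_match_and_mask(rng, bank):
    entries = rng.normal(0, 1, (20, 8))
    d = TextonDictionary(entries, np.array(["precipitate"] * 20))
    img = rng.uniform(0, 255, (40, 40))
    resp = apply_filter_bank(img, bank)
    # plant an exact dictionary vector at a valid pixel
    resp.responses[20, 20] = entries[7]
    mask = np.ones((40, 40), dtype=bool)
    mask[30:, :] = False
    tmap = label_pixels(resp, d, mask)
    assert tmap.labels[20, 20] == 7
    assert (tmap.labels[30:, :] == -1).all()
    half = bank.support // 2
    assert (tmap.labels[:half, :] == -1).all()


def test_label_matches_brute_force(rng, bank):
    entries = rng.normal(0, 0.5, (30, 8))
    d = TextonDictionary(entries, np.array(["precipitate"] * 30))
    img = rng.uniform(0, 255, (32, 32))
    resp = apply_filter_bank(img, bank)
    tmap = label_pixels(resp, d)
    for i in range(32):
        for j in range(32):
            if not resp.valid[i, j]:
                assert tmap.labels[i, j] == -1
                continue
            dists = np.linalg.norm(entries - resp.responses[i, j], axis=1)
            assert tmap.labels[i, j] == int(np.argmin(dists))


def test_histogram_conservation(rng):
    labels = rng.integers(-1, 12, (30, 30))
    h = texton_histogram(TextonMap(labels), 12)
    assert h.counts.sum() == h.n_pixels == (labels >= 0).sum()
    assert len(h.counts) == 12


def test_histogram_edge_cases():
    empty = texton_histogram(TextonMap(-np.ones((5, 5), dtype=int)), 10)
    assert empty.n_pixels == 0
    assert not empty.counts.any()
    uniform = texton_histogram(TextonMap(np.full((10, 10), 3)), 10)
    assert uniform.counts[3] == 100
    with pytest.raises(ValueError):
        texton_histogram(TextonMap(np.full((2, 2), 99)), 10)


# ---------------------------------------------------------------- chi2/ward


def test_chi2_known_values():
    assert chi2_distance(np.array([1, 0]), np.array([1, 0])) == 0.0
    assert chi2_distance(np.array([1, 0]), np.array([0, 1])) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        chi2_distance(np.ones(3), np.ones(4))


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_chi2_symmetry_and_nonnegativity(seed):
    r = np.random.default_rng(seed)
    x = r.integers(0, 50, 20).astype(float)
    y = r.integers(0, 50, 20).astype(float)
    d = chi2_distance(x, y)
    assert d >= 0
    assert d == pytest.approx(chi2_distance(y, x))
    assert chi2_distance(x, x) == 0.0


def test_ward_separates_two_texture_groups(rng):
    a = [rng.multinomial(500, [0.6, 0.3, 0.05, 0.05]) for _ in range(8)]
    b = [rng.multinomial(500, [0.05, 0.05, 0.3, 0.6]) for _ in range(8)]
    labels = ward_cluster(a + b, 2)
    assert len(set(labels[:8])) == 1
    assert len(set(labels[8:])) == 1
    assert labels[0] != labels[8]


def test_ward_trivial_and_permutation_invariant(rng):
    hists = [rng.multinomial(200, np.ones(10) / 10) for _ in range(6)]
    assert len(set(ward_cluster(hists, 6))) == 6
    perm = [2, 0, 5, 1, 4, 3]
    base = ward_cluster(hists, 3)
    shuffled = ward_cluster([hists[i] for i in perm], 3)
    # same partition up to label renaming
    for i in range(6):
        for j in range(6):
            same_base = base[perm[i]] == base[perm[j]]
            same_shuf = shuffled[i] == shuffled[j]
            assert same_base == same_shuf
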