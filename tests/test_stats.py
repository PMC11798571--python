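import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import freqtag as ft
from freqtag.errors import ConfigurationError, DataError


# --------------------------------------------------------------------------
# paired contrasts and d_z
# --------------------------------------------------------------------------

def test_paired_contrast_hand_computed():
    # diffs [1, 1, 2]: mean 4/3, sd 1/sqrt(3) => t = 4.0, d_z = 4/sqrt(3)
    res = ft.paired_contrast([1.0, 2.0, 4.0], [0.0, 1.0, 2.0])
    assert res.t == pytest.approx(4.0, rel=1e-12)
    assert res.d == pytest.approx(4.0 / np.sqrt(3.0), rel=1e-12)
    assert res.df == 2
    assert res.mean_diff == pytest.approx(4.0 / 3.0)
    assert res.p == pytest.approx(2 * sps.t.sf(4.0, 2), rel=1e-12)


def test_paired_contrast_zero_variance_rejected():
    with pytest.raises(DataError):
        ft.paired_contrast([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
    with pytest.raises(DataError):
        ft.paired_contrast([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


@given(st.lists(st.floats(-10, 10), min_size=4, max_size=30),
       st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_dz_equals_t_over_sqrt_n(vals, seed):
    a = np.asarray(vals)
    b = a + np.random.default_rng(seed).normal(0.5, 1.0, a.size)
    if np.std(a - b, ddof=1) == 0:
        return
    res = ft.paired_contrast(a, b)
    assert res.d == pytest.approx(res.t / np.sqrt(a.size), abs=1e-9)
    assert np.sign(res.d) == np.sign(res.t)


def test_dz_matches_agreement_of_published_pairs():
    # any (t, n) pair maps to d_z = t / sqrt(n); e.g. t=4.664, n=24 -> 0.952
    for t, d in [(4.664, 0.952), (3.028, 0.618), (3.240, 0.661), (5.132, 1.048)]:
        assert t / np.sqrt(24) == pytest.approx(d, abs=5e-4)


# --------------------------------------------------------------------------
# additive-model classification
# --------------------------------------------------------------------------

def test_exact_additivity_is_zero_variance_error():
    a = np.array([0.1, 0.2, 0.3, 0.4])
    v = np.array([0.2, 0.1, 0.3, 0.2])
    with pytest.raises(DataError):
        ft.additive_classification(a + v, a, v)


def test_near_additive_labeled_additive(rng):
    a = rng.uniform(0.1, 0.3, 20)
    v = rng.uniform(0.1, 0.3, 20)
    av = a + v + rng.normal(0.0, 1e-3, 20)
    assert ft.additive_classification(av, a, v).label == "additive"


def test_superadditive_and_subadditive_labels(rng):
    a = rng.uniform(0.1, 0.3, 20)
    v = rng.uniform(0.1, 0.3, 20)
    noise = rng.normal(0.0, 0.01, 20)
    assert ft.additive_classification(1.5 * (a + v) + noise, a, v).label == "super-additive"
    assert ft.additive_classification(0.5 * (a + v) + noise, a, v).label == "sub-additive"


# --------------------------------------------------------------------------
# congruency effect
# --------------------------------------------------------------------------

def test_congruency_effect_zero_for_identical(rng):
    x = rng.standard_normal((5, 8))
    np.testing.assert_array_equal(ft.congruency_effect(x, [x]), np.zeros_like(x))


def test_congruency_effect_averages_runs(rng):
    c = rng.standard_normal((5, 8))
    x, y = rng.standard_normal((2, 5, 8))
    np.testing.assert_allclose(ft.congruency_effect(c, [x, y]), c - (x + y) / 2,
                               atol=1e-12)


def test_congruency_effect_shape_mismatch():
    with pytest.raises(DataError):
        ft.congruency_effect(np.zeros((5, 8)), [np.zeros((5, 7))])


def test_congruency_boost_recovered(montage16, rng):
    up, _ = ft.simulate_effect_matrices(300, montage16, ["CPZ", "CP2"], boost=0.2,
                                        noise_sd=0.1, seed=8)
    base = np.zeros_like(up)
    eff = ft.congruency_effect(up, [base, base])
    assert eff[:, montage16.index("CPZ")].mean() == pytest.approx(0.2, abs=0.02)
    assert eff[:, montage16.index("FCZ")].mean() == pytest.approx(0.0, abs=0.02)


# --------------------------------------------------------------------------
# FDR peak test
# --------------------------------------------------------------------------

def test_peak_test_all_zero_data():
    vals = np.zeros((10, 20))
    freqs = np.arange(20) / 12.0
    res = ft.peak_ttest_fdr(vals, freqs)
    assert not res.q_significant.any()
    assert res.df == 9


def test_peak_test_flags_signal_bin(rng):
    # the signal bin is always recovered; BH controls the FDR (not the
    # family-wise rate), so occasional extra null-bin discoveries are the
    # expected price and stay rare
    signal_found, exact = 0, 0
    for i in range(60):
        vals = rng.standard_normal((24, 40))
        vals[:, 17] += 1.5
        freqs = np.arange(40) / 12.0
        res = ft.peak_ttest_fdr(vals, freqs)
        flagged = set(np.flatnonzero(res.q_significant))
        signal_found += 17 in flagged
        exact += flagged == {17}
    assert signal_found == 60
    assert exact / 60 >= 0.75


def test_peak_test_range_restriction(rng):
    vals = rng.standard_normal((12, 80)) + 3.0  # all bins strongly positive
    freqs = np.arange(80) / 12.0
    res = ft.peak_ttest_fdr(vals, freqs, f_max=5.33)
    assert res.q_significant[freqs < 5.33].all()
    assert not res.q_significant[freqs >= 5.33].any()


def test_peak_test_respects_valid_mask(rng):
    vals = np.abs(rng.standard_normal((12, 30))) + 3.0
    freqs = np.arange(30) / 12.0
    valid = np.ones(30, bool)
    valid[:2] = valid[-2:] = False
    res = ft.peak_ttest_fdr(vals, freqs, valid=valid)
    assert not res.q_significant[~valid].any()


def test_fdr_monotonicity(rng):
    # adding a strongly significant bin never demotes an existing discovery
    vals = rng.standard_normal((16, 30))
    vals[:, 5] += 1.2
    freqs = np.arange(30) / 12.0
    base = ft.peak_ttest_fdr(vals, freqs)
    boosted = vals.copy()
    boosted[:, 20] += 10.0
    res = ft.peak_ttest_fdr(boosted, freqs)
    assert (res.q_significant | ~base.q_significant).all()


def test_peak_test_too_few_subjects():
    with pytest.raises(DataError):
        ft.peak_ttest_fdr(np.zeros((2, 10)), np.arange(10) / 12.0)


# --------------------------------------------------------------------------
# cluster permutation test
# --------------------------------------------------------------------------

def exhaustive_cluster_p(up, inv, montage, cluster_alpha=0.05, min_neighbors=2):
    """Brute-force oracle: exhaustive sign-flip null via networkx components."""
    import itertools
    import networkx as nx

    d = up - inv
    n, n_e = d.shape
    t_crit = sps.t.ppf(1 - cluster_alpha / 2, n - 1)
    graph = nx.from_numpy_array(montage.adjacency)

    def clusters(tv):
        out = []
        for sign in (1, -1):
            mask = sign * tv > t_crit
            keep = [i for i in range(n_e)
                    if mask[i] and sum(mask[j] for j in graph[i]) >= min_neighbors]
            sub = graph.subgraph(keep)
            for comp in nx.connected_components(sub):
                out.append((frozenset(comp), float(tv[list(comp)].sum())))
        return out

    def tstat(dd):
        m, s = dd.mean(0), dd.std(0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s > 0, m / (s / np.sqrt(n)), 0.0)

    obs = clusters(tstat(d))
    null = []
    for signs in itertools.product((1.0, -1.0), repeat=n):
        tv = tstat(np.asarray(signs)[:, None] * d)
        cs = clusters(tv)
        null.append(max((abs(s) for _, s in cs), default=0.0))
    null = np.asarray(null)
    return {members: (1 + np.count_nonzero(null >= abs(stat))) / (1 + null.size)
            for members, stat in obs}


def test_no_difference_yields_no_clusters(montage16, rng):
    x = rng.standard_normal((10, 16))
    res = ft.cluster_permutation_interaction(x, x.copy() + 0.0, montage16,
                                             n_perm=200, seed=0)
    # upright == inverted: t undefined/zero everywhere, nothing supra-threshold
    assert res.clusters == []


def test_monte_carlo_matches_exhaustive_enumeration(montage16):
    """With n=8 subjects the 2^8 = 256 sign flips can be enumerated; the
    Monte-Carlo p must agree within 3 binomial SEs."""
    rng = np.random.default_rng(99)
    up, inv = ft.simulate_effect_matrices(8, montage16, ["C1", "CZ", "CPZ", "CP1"],
                                          boost=0.28, noise_sd=0.25, seed=42)
    oracle = exhaustive_cluster_p(up, inv, montage16)
    assert oracle, "fixture must produce at least one observed cluster"
    n_perm = 2000
    res = ft.cluster_permutation_interaction(up, inv, montage16, n_perm=n_perm,
                                             seed=7)
    assert len(res.clusters) == len(oracle)
    for c in res.clusters:
        members = frozenset(montage16.index(l) for l in c.electrodes)
        p_ex = oracle[members]
        se = np.sqrt(p_ex * (1 - p_ex) / n_perm)
        assert abs(c.p - p_ex) <= 3 * se + 1.0 / n_perm


def test_seeded_cluster_recovered(montage60):
    targets = ["C2", "CPZ", "CP2", "CP4", "CP6", "PZ", "P2", "P4", "P6"]
    up, inv = ft.simulate_effect_matrices(24, montage60, targets, boost=0.25,
                                          noise_sd=0.25, seed=5)
    res = ft.cluster_permutation_interaction(up, inv, montage60, n_perm=500, seed=6)
    sig = res.significant(0.05)
    assert sig
    assert len(set(targets) & set(sig[0].electrodes)) >= 5
    assert sig[0].polarity == "positive"


def test_cluster_determinism(montage16):
    up, inv = ft.simulate_effect_matrices(10, montage16, ["CPZ"], 0.3, 0.3, seed=1)
    a = ft.cluster_permutation_interaction(up, inv, montage16, n_perm=300, seed=11)
    b = ft.cluster_permutation_interaction(up, inv, montage16, n_perm=300, seed=11)
    assert [(c.electrodes, c.stat, c.p) for c in a.clusters] == \
           [(c.electrodes, c.stat, c.p) for c in b.clusters]


def test_low_n_perm_flagged(montage16, rng):
    up = rng.standard_normal((8, 16))
    inv = rng.standard_normal((8, 16))
    res = ft.cluster_permutation_interaction(up, inv, montage16, n_perm=50, seed=1)
    assert res.low_n_perm


def test_disconnected_montage_rejected(montage60, rng):
    two_islands = montage60.subset(["FP1", "FPZ", "FP2", "O1", "OZ", "O2"])
    with pytest.raises(ConfigurationError):
        ft.cluster_permutation_interaction(rng.standard_normal((8, 6)),
                                           rng.standard_normal((8, 6)),
                                           two_islands, n_perm=100, seed=0)


# --------------------------------------------------------------------------
# trait correlation and median split
# --------------------------------------------------------------------------

def test_pearson_perfect_linear():
    x = np.arange(10.0)
    res = ft.pearson_outlier_removed(x, -2.0 * x + 1.0)
    assert res.r == pytest.approx(-1.0)
    assert res.n_removed_outliers == 0


def test_single_pass_outlier_rule_hand_computed():
    # y = [2, 4, 6, 8, 1000]: mean 204, sd ~445; the extreme point deviates
    # 796 < 3*sd, so the single-pass rule removes nothing (sd is inflated
    # by the outlier itself) -- documented single-pass behavior
    x = np.arange(1.0, 6.0)
    y = np.array([2.0, 4.0, 6.0, 8.0, 1000.0])
    assert abs(y[-1] - y.mean()) < 3 * y.std(ddof=1)
    res = ft.pearson_outlier_removed(x, y, sd_thresh=3.0)
    assert res.n_removed_outliers == 0
    assert res.n_used == 5


def test_outlier_actually_removed(rng):
    x = rng.standard_normal(30)
    y = 0.1 * rng.standard_normal(30)
    y[0] = 50.0
    res = ft.pearson_outlier_removed(x, y, sd_thresh=3.0)
    assert res.n_removed_outliers == 1
    assert res.n_used == 29


def test_simulated_rho_sampling_distribution(rng):
    # mean sample r over many n=24 cohorts should sit near the target -0.5
    rs = []
    for _ in range(300):
        e = rng.standard_normal(24)
        aq = -0.5 * e + np.sqrt(1 - 0.25) * rng.standard_normal(24)
        rs.append(ft.pearson_outlier_removed(aq, e, sd_thresh=np.inf).r)
    assert -0.6 < np.mean(rs) < -0.4


def test_pearson_too_few_after_removal():
    with pytest.raises(DataError):
        ft.pearson_outlier_removed([1, 2, 3], [1, 2, 3])


def test_median_split_monotone_map(rng):
    aq = rng.integers(5, 40, 20).astype(float)
    res = ft.median_split_compare(aq, -aq)
    assert res.mean_low > res.mean_high
    assert res.t > 0


def test_median_split_tie_rule():
    aq = np.array([10.0, 10.0, 10.0, 20.0, 30.0, 40.0])
    res = ft.median_split_compare(aq, np.arange(6.0))
    # median 15: ties at/below go to the low group
    assert res.n_low == 3 and res.n_high == 3


def test_median_split_degenerate_rejected():
    with pytest.raises(DataError):
        ft.median_split_compare(np.full(8, 20.0), np.arange(8.0))


def test_median_split_null_behavior(rng):
    ps = []
    for _ in range(200):
        aq = rng.integers(0, 50, 24).astype(float)
        eff = rng.standard_normal(24)
        try:
            ps.append(ft.median_split_compare(aq, eff).p)
        except DataError:
            continue
    # under the null p-values are roughly uniform: mean near 0.5
    assert 0.4 < np.mean(ps) < 0.6
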