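"""Statistical core: every bespoke test against an independent oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from glytrome import stats


# ------------------------------------------------------------- Mann-Whitney

def _mw_enumeration_oracle(x, y):
    """Exact two-sided p by full enumeration of the U1 null distribution:
    doubled smaller tail, capped at 1."""
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(pooled)

    def u1_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u1_obs = u1_of(range(n1))
    u1s = np.array([u1_of(c) for c in
                    itertools.combinations(range(len(pooled)), n1)])
    p_low = np.mean(u1s <= u1_obs)
    p_high = np.mean(u1s >= u1_obs)
    return (min(u1_obs, n1 * n2 - u1_obs),
            min(1.0, 2.0 * min(p_low, p_high)))


@pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 3, 1), (5, 5, 2),
                                        (4, 6, 3), (2, 7, 4)])
def test_mann_whitney_matches_enumeration(n1, n2, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n1)
    y = rng.normal(0.5, size=n2)
    res = stats.mann_whitney_exact(x, y)
    u_ref, p_ref = _mw_enumeration_oracle(x, y)
    assert res.statistic == pytest.approx(u_ref)
    assert res.p_two_sided == pytest.approx(p_ref)


def test_mann_whitney_complete_separation_u_zero():
    # 9 values all above 8 others: U = 0
    res = stats.mann_whitney_exact(np.arange(10, 19), np.arange(1, 9))
    assert res.statistic == 0.0
    assert res.p_two_sided < 0.0001


def test_mann_whitney_7v8_separation_p():
    # complete separation at n=7 vs 8: two-sided p = 2/C(15,7) = 2/6435
    res = stats.mann_whitney_exact(np.arange(20, 27), np.arange(1, 9))
    assert res.statistic == 0.0
    assert res.p_two_sided == pytest.approx(2 / 6435)
    assert round(res.p_two_sided, 4) == 0.0003


def test_mann_whitney_identical_multisets_u_half():
    x = [1.0, 2.0, 3.0, 4.0]
    res = stats.mann_whitney_exact(x, x)
    assert res.statistic == pytest.approx(len(x) ** 2 / 2)
    assert res.p_two_sided == pytest.approx(1.0)


def test_mann_whitney_empty_sample_raises():
    with pytest.raises(ValueError):
        stats.mann_whitney_exact([], [1.0])


def test_mann_whitney_large_samples_use_normal_approximation():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=30), rng.normal(size=30)
    res = stats.mann_whitney_exact(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.method.startswith("mann-whitney-normal")
    assert res.p_two_sided == pytest.approx(ref.pvalue, rel=0.05)


# ------------------------------------------------------------------ BKY FDR

def test_bky_trivial_cases():
    assert np.allclose(stats.bky_adjust([1.0, 1.0, 1.0]), 1.0)
    assert stats.bky_adjust([0.3])[0] == pytest.approx(0.3)


def test_bky_hand_executed_vector():
    # stage 1: BH adjusted = (.005,.025,.0333,.625,.9); r1 at q/(1+q)=0.047619
    # is 3, so m0 = 2; stage 2 step-up with m0=2 gives p*2/rank, monotone.
    out = stats.bky_adjust([0.001, 0.01, 0.02, 0.5, 0.9])
    assert np.allclose(out, [0.002, 0.01, 2 * 0.02 / 3, 0.25, 0.36])


def test_bky_rejections_match_statsmodels_two_stage():
    import statsmodels.stats.multitest as mt
    rng = np.random.default_rng(5)
    for _ in range(20):
        p = rng.uniform(size=40)
        p[:5] = rng.uniform(0, 1e-3, size=5)
        ours = stats.bky_adjust(p) <= 0.05
        theirs = mt.multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
        assert (ours == theirs).all()


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=30))
def test_bky_never_exceeds_bh_and_is_monotone(pvals):
    p = np.asarray(pvals)
    bky = stats.bky_adjust(p)
    bh = stats._bh_adjust(p)
    assert (bky <= bh + 1e-12).all()
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(bky[order]) >= -1e-12).all()


def test_bky_rejects_out_of_range():
    with pytest.raises(ValueError):
        stats.bky_adjust([0.5, 1.5])


# ------------------------------------------------------------------- Grubbs

def test_grubbs_hand_computed_statistic():
    # x = (1,1,1,10): mean 3.25, sd 4.5, G = 6.75/4.5 = 1.5
    res = stats.grubbs_test([1, 1, 1, 10], alpha=0.05)
    assert res.statistic == pytest.approx(1.5)
    assert res.outlier_index == 3


def test_grubbs_symmetric_sample_no_outlier():
    # published critical value for n=5, alpha=0.05 is 1.715; G here is
    # 2/sqrt(2.5) = 1.265
    res = stats.grubbs_test([1.0, 2.0, 3.0, 4.0, 5.0], alpha=0.05)
    assert res.statistic == pytest.approx(2.0 / math.sqrt(2.5))
    assert res.outlier_index is None


def test_grubbs_constant_sample_raises():
    with pytest.raises(ValueError):
        stats.grubbs_test([2.0, 2.0, 2.0, 2.0])


# ------------------------------------------------------------ hypergeometric

def test_hypergeometric_matches_enumeration():
    N, K, n, k = 20, 5, 5, 3
    hits = sum(1 for c in itertools.combinations(range(N), n)
               if sum(i < K for i in c) >= k)
    assert stats.hypergeometric_tail(k, K, n, N) == pytest.approx(
        hits / math.comb(N, n))


def test_hypergeometric_forced_tails():
    assert stats.hypergeometric_tail(0, 5, 5, 20) == pytest.approx(1.0)
    assert stats.hypergeometric_tail(5, 20, 5, 20) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        stats.hypergeometric_tail(6, 5, 5, 20)


# ------------------------------------------------- mutual information + perm

def test_mi_perfect_association_equals_membership_entropy():
    rng = np.random.default_rng(0)
    values = rng.normal(size=500)
    bins = stats.equal_frequency_bins(values, 5)
    membership = (bins == 4).astype(int)
    res = stats.mutual_information_perm(values, membership, n_bins=5,
                                        n_perm=300, rng_seed=1)
    h = -(0.2 * math.log2(0.2) + 0.8 * math.log2(0.8))
    assert res.mi == pytest.approx(h, rel=1e-6)
    assert res.z > 10
    assert res.p_perm == pytest.approx(1 / 301)
    top = res.per_bin[4]
    assert top[3] == "enriched" and top[2] < 0.05


def test_mi_null_z_centred_near_zero():
    rng = np.random.default_rng(7)
    zs = []
    for i in range(400):
        values = rng.normal(size=200)
        membership = np.zeros(200, dtype=int)
        membership[rng.choice(200, size=50, replace=False)] = 1
        res = stats.mutual_information_perm(values, membership, n_bins=5,
                                            n_perm=150, rng_seed=i)
        zs.append(res.z)
    assert abs(np.mean(zs)) < 0.1


def test_mi_invariant_to_monotone_transform():
    rng = np.random.default_rng(3)
    values = rng.normal(size=300)
    membership = (values + rng.normal(0, 1, 300) > 0.5).astype(int)
    a = stats.mutual_information_perm(values, membership, n_perm=200,
                                      rng_seed=9)
    b = stats.mutual_information_perm(np.exp(3 * values), membership,
                                      n_perm=200, rng_seed=9)
    assert a.mi == pytest.approx(b.mi)
    assert a.z == pytest.approx(b.z)


def test_mi_contract_violations():
    with pytest.raises(ValueError):
        stats.mutual_information_perm([1.0, 2.0], [1, 1], n_perm=200)
    with pytest.warns(UserWarning):
        stats.mutual_information_perm(np.arange(20.0),
                                      np.tile([0, 1], 10), n_perm=50,
                                      rng_seed=0)


# ------------------------------------------------------------- NB exact test

def test_nb_exact_symmetric_split_p_one():
    res = stats.nb_exact_test([5, 5, 5], [5, 5, 5], dispersion=0.1)
    assert res.p_two_sided == pytest.approx(1.0)


def test_nb_exact_poisson_limit_matches_binomial_conditional():
    # dispersion -> 0: conditional distribution is Binomial(t, n1/(n1+n2))
    for counts_a, counts_b in [([8, 5, 7], [2, 1, 3]), ([10, 12], [9, 11]),
                               ([20, 15], [5, 2])]:
        t = sum(counts_a) + sum(counts_b)
        assert t <= 50
        s = sum(counts_a)
        n1, n2 = len(counts_a), len(counts_b)
        pmf = sps.binom.pmf(np.arange(t + 1), t, n1 / (n1 + n2))
        p_ref = min(1.0, 2 * min(pmf[:s + 1].sum(), pmf[s:].sum()))
        res = stats.nb_exact_test(counts_a, counts_b, dispersion=0.0)
        assert res.p_two_sided == pytest.approx(p_ref, rel=1e-9)
        res_small = stats.nb_exact_test(counts_a, counts_b, dispersion=1e-8)
        assert res_small.p_two_sided == pytest.approx(p_ref, rel=1e-4)


def test_nb_exact_strong_depletion_significant():
    res = stats.nb_exact_test([100, 95, 108], [10, 12, 9], dispersion=0.1)
    assert res.p_two_sided < 0.01


def test_nb_exact_negative_counts_raise():
    with pytest.raises(ValueError):
        stats.nb_exact_test([1, -2], [3, 4], dispersion=0.1)


def test_nb_detection_power_for_2p5x_depletion():
    # 2.5x depletion, n=3/group, dispersion 0.1, mean count 200:
    # raw p<0.05 detection rate must exceed 0.9 (estimated at 500 seeds;
    # the true rate is ~0.92)
    rng = np.random.default_rng(123)
    r = 1 / 0.1
    hits = 0
    n = 500
    for _ in range(n):
        a = rng.negative_binomial(r, r / (r + 200.0), 3)
        b = rng.negative_binomial(r, r / (r + 80.0), 3)
        if stats.nb_exact_test(a, b, 0.1).p_two_sided < 0.05:
            hits += 1
    assert hits / n > 0.9


def test_dispersion_mom_recovers_truth():
    rng = np.random.default_rng(1)
    r = 1 / 0.1
    mu = rng.lognormal(np.log(300), 1.0, size=400)
    counts = rng.negative_binomial(r, r / (r + mu[:, None]), (400, 6))
    est = stats.estimate_dispersion_mom(counts, (3, 3))
    assert est == pytest.approx(0.1, rel=0.4)


# --------------------------------------------------------------------- loess

def test_loess_constant_and_linear_exact():
    x = np.arange(50.0)
    assert np.allclose(stats.loess_fit(x, np.full(50, 7.0), span=0.5), 7.0)
    y = 2.0 * x + 1.0
    assert np.allclose(stats.loess_fit(x, y, span=1.0), y, atol=1e-6)


def test_loess_spike_suppressed():
    x = np.arange(100.0)
    y = np.full(100, 10.0)
    y[50] = 200.0
    fitted = stats.loess_fit(x, y, span=0.3)
    assert y[50] / fitted[50] > 2.0      # observed far exceeds prediction
    assert fitted[10] == pytest.approx(10.0, rel=0.1)


def test_loess_contract_violations():
    with pytest.raises(ValueError):
        stats.loess_fit(np.arange(5.0), np.arange(5.0))
    with pytest.raises(ValueError):
        stats.loess_fit(np.arange(20.0), np.arange(20.0), span=1.5)
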