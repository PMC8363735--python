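"""Shared statistical machinery.

Implements the tests the analysis stages depend on where a specific
variant is required -- the exact Mann-Whitney U test (with full null
enumeration at small n), the two-stage Benjamini-Krieger-Yekutieli FDR
step-up, the single-outlier Grubbs test, the conditional negative-
binomial exact test used for isodecoder differential expression, and
mutual-information gene-set enrichment with a permutation null.
Standard primitives (hypergeometric tail, loess smoothing) are thin
wrappers over scipy/statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "TestResult", "EnrichmentResult",
    "mann_whitney_exact", "bky_adjust", "grubbs_test",
    "hypergeometric_tail", "mutual_information_perm",
    "nb_exact_test", "estimate_dispersion_mom", "loess_fit",
]


@dataclass
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    n1: int
    n2: int
    outlier_index: int | None = None  # Grubbs only

    def __post_init__(self):
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError(f"p outside [0,1]: {self.p_two_sided}")


@dataclass
class EnrichmentResult:
    mi: float            # bits
    z: float
    p_perm: float
    per_bin: list = field(default_factory=list)
    # per_bin entries: (bin index, hypergeometric p, Bonferroni p, direction)


# ---------------------------------------------------------------- Mann-Whitney

def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments giving each U value, for samples n1/n2.

    counts[u] = #{subsets} with U1 = u, u in 0..n1*n2.  Classic recursion
    N(u; n, m) = N(u - m; n-1, m) + N(u; n, m-1).
    """
    max_u = n1 * n2
    # dp over number of x's included, using generating-function convolution
    counts = np.zeros(max_u + 1, dtype=float)
    counts[0] = 1.0
    # Gaussian binomial coefficient expansion: product over i of
    # (1 - q^(n2+i)) / (1 - q^i) for i=1..n1, done as polynomial ops.
    for i in range(1, n1 + 1):
        # multiply by (1 - q^(n2+i)), divide by (1 - q^i)
        new = counts.copy()
        if n2 + i <= max_u:
            new[n2 + i:] -= counts[:max_u + 1 - (n2 + i)]
        # divide by (1 - q^i): cumulative sum with stride i
        for u in range(i, max_u + 1):
            new[u] += new[u - i]
        counts = new
    return counts


def mann_whitney_exact(x, y) -> TestResult:
    """Two-sample Mann-Whitney U test, exact at n1+n2 <= 20.

    U = min(U1, U2).  Exact two-sided p enumerates the full null
    distribution of U over rank assignments (no ties).  Ties fall back to
    the normal approximation with tie correction, flagged in ``method``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 + n2 <= 20:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        k = int(round(u))
        p_low = counts[: k + 1].sum() / total
        p = min(1.0, 2.0 * p_low)
        method = "mann-whitney-exact"
    else:
        # normal approximation with tie correction
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum()
        mu = n1 * n2 / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (u - mu + 0.5) / math.sqrt(sigma2)  # continuity-corrected
            p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "mann-whitney-normal-ties" if has_ties else "mann-whitney-normal"
    return TestResult(statistic=float(u), p_two_sided=float(p),
                      method=method, n1=n1, n2=n2)


# ------------------------------------------------------------------- BKY FDR

def _bh_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Linear step-up adjusted values with denominator m (defaults len(p))."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if m is None:
        m = n
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def bky_adjust(p_values, q: float = 0.05) -> np.ndarray:
    """Two-stage linear step-up FDR adjustment (Benjamini-Krieger-Yekutieli).

    Stage 1 runs the linear step-up at level q/(1+q) and estimates the
    number of true nulls as m0 = m - r1 (at least 1); stage 2 re-runs the
    step-up with m0 in place of m.  Returned values are monotone and can be
    compared to q.  Never exceeds the plain Benjamini-Hochberg adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0,1]")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _bh_adjust(p)
    r1 = int((stage1 <= q1).sum())
    m0 = max(m - r1, 1)
    return _bh_adjust(p, m=m0)


# -------------------------------------------------------------------- Grubbs

def grubbs_test(x, alpha: float = 0.05) -> TestResult:
    """Two-sided single-outlier Grubbs test.

    G = max|x_i - mean| / sd, compared to the t-based critical value at
    ``alpha``.  ``outlier_index`` is set iff G exceeds the critical value.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("constant sample: Grubbs statistic undefined")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / s
    # critical value at two-sided alpha
    t_crit = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t_crit**2 / (n - 2 + t_crit**2))
    # approximate p-value by inverting G -> t
    denom = (n - 1) ** 2 / n - g**2
    if denom <= 0:
        p = 0.0
    else:
        t_stat = math.sqrt((n - 2) * g**2 / denom)
        p = min(1.0, 2.0 * n * sps.t.sf(t_stat, n - 2))
    return TestResult(statistic=float(g), p_two_sided=float(p),
                      method="grubbs", n1=n, n2=0,
                      outlier_index=idx if g > g_crit else None)


# ------------------------------------------------------------ hypergeometric

def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) drawing n from N with K successes."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


# -------------------------------------------------- mutual information + perm

def _mi_bits(bin_ids: np.ndarray, membership: np.ndarray, n_bins: int) -> float:
    n = bin_ids.size
    mi = 0.0
    p_m = membership.mean()
    for b in range(n_bins):
        sel = bin_ids == b
        p_b = sel.mean()
        if p_b == 0:
            continue
        for m_val, p_mv in ((1, p_m), (0, 1.0 - p_m)):
            if p_mv == 0:
                continue
            p_joint = (sel & (membership == m_val)).sum() / n
            if p_joint > 0:
                mi += p_joint * math.log2(p_joint / (p_b * p_mv))
    return mi


def equal_frequency_bins(values, n_bins: int) -> np.ndarray:
    """Assign values to n_bins equal-frequency bins (0..n_bins-1) by rank."""
    values = np.asarray(values, dtype=float)
    order = sps.rankdata(values, method="ordinal") - 1
    return (order * n_bins // values.size).astype(int)


def mutual_information_perm(values, membership, n_bins: int = 5,
                            n_perm: int = 10_000, rng_seed: int = 0,
                            ) -> EnrichmentResult:
    """MI between equal-frequency value bins and a binary gene set.

    The null distribution comes from ``n_perm`` shuffles of the membership
    vector; z = (MI - mean_null)/sd_null and the permutation p uses the +1
    correction.  Per value-bin, two-tailed hypergeometric enrichment and
    depletion p-values are Bonferroni-adjusted over bins.
    """
    values = np.asarray(values, dtype=float)
    membership = np.asarray(membership).astype(int)
    if membership.min() == membership.max():
        raise ValueError("membership must not be constant")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    import warnings
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a poorly resolved permutation null")

    bins = equal_frequency_bins(values, n_bins)
    mi = _mi_bits(bins, membership, n_bins)

    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_perm)
    shuffled = membership.copy()
    for i in range(n_perm):
        rng.shuffle(shuffled)
        null[i] = _mi_bits(bins, shuffled, n_bins)
    sd = null.std()
    z = (mi - null.mean()) / sd if sd > 0 else np.inf
    p_perm = (1.0 + (null >= mi).sum()) / (1.0 + n_perm)

    N = values.size
    K = int(membership.sum())
    per_bin = []
    for b in range(n_bins):
        sel = bins == b
        n_b = int(sel.sum())
        k = int((membership[sel] == 1).sum())
        p_enr = hypergeometric_tail(k, K, n_b, N)
        p_dep = float(sps.hypergeom.cdf(k, N, K, n_b))
        if p_enr <= p_dep:
            p, direction = p_enr, "enriched"
        else:
            p, direction = p_dep, "depleted"
        per_bin.append((b, p, min(1.0, p * n_bins), direction))
    return EnrichmentResult(mi=float(mi), z=float(z), p_perm=float(p_perm),
                            per_bin=per_bin)


# ------------------------------------------------------------- NB exact test

def estimate_dispersion_mom(counts: np.ndarray, group_sizes: tuple[int, int],
                            ) -> float:
    """Common NB dispersion by method of moments across features.

    ``counts``: features x samples array already scaled to a common library
    size; groups are the first/last ``group_sizes`` columns.  Per feature,
    phi_f = (pooled within-group variance - mean)/mean^2; the common value
    is the median over features (clipped at 0).
    """
    counts = np.asarray(counts, dtype=float)
    n1, n2 = group_sizes
    a, b = counts[:, :n1], counts[:, n1:n1 + n2]
    mu = counts.mean(axis=1)
    var = ((a - a.mean(axis=1, keepdims=True))**2).sum(axis=1)
    var = var + ((b - b.mean(axis=1, keepdims=True))**2).sum(axis=1)
    var = var / max(n1 + n2 - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var - mu) / mu**2
    phi = phi[np.isfinite(phi) & (mu > 0)]
    if phi.size == 0:
        return 0.0
    return float(max(0.0, np.median(phi)))


def nb_exact_test(counts_a, counts_b, dispersion: float) -> TestResult:
    """Conditional exact test for NB counts with a common dispersion.

    Conditions on the feature total: with per-sample dispersion phi, the
    group sums are NB with sizes n_i/phi and a shared success probability
    that cancels, so P(S_a = s | S_a + S_b = t) is proportional to
    C(s + r1 - 1, s) * C(t - s + r2 - 1, t - s).  The two-sided p doubles
    the smaller tail (capped at 1).  dispersion -> 0 reduces to the exact
    binomial conditional (Poisson limit).  Inputs must already be scaled
    to equal library sizes.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    n1, n2 = a.size, b.size
    s_obs = int(round(a.sum()))
    t = s_obs + int(round(b.sum()))
    if t == 0:
        return TestResult(0.0, 1.0, "nb-exact", n1, n2)
    s = np.arange(t + 1)
    if dispersion <= 0:
        # Poisson limit: binomial conditional with p = n1/(n1+n2)
        logw = (gammaln(t + 1) - gammaln(s + 1) - gammaln(t - s + 1)
                + s * math.log(n1 / (n1 + n2))
                + (t - s) * math.log(n2 / (n1 + n2)))
        method = "binomial-exact"
    else:
        r1, r2 = n1 / dispersion, n2 / dispersion
        logw = (gammaln(s + r1) - gammaln(s + 1)
                + gammaln(t - s + r2) - gammaln(t - s + 1))
        method = "nb-exact"
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    p_low = w[: s_obs + 1].sum()
    p_high = w[s_obs:].sum()
    p = min(1.0, 2.0 * min(p_low, p_high))
    return TestResult(float(s_obs), float(p), method, n1, n2)


# --------------------------------------------------------------------- loess

def _loess_pass(x: np.ndarray, y: np.ndarray, k: int,
                robust_w: np.ndarray) -> np.ndarray:
    fitted = np.empty_like(y)
    for i in range(x.size):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = np.average(y[idx], weights=robust_w[idx])
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None) * robust_w[idx]
        if w.sum() <= 0:
            fitted[i] = y[idx].mean()
            continue
        xw, yw = x[idx], y[idx]
        xbar = np.average(xw, weights=w)
        ybar = np.average(yw, weights=w)
        sxx = np.sum(w * (xw - xbar) ** 2)
        if sxx > 0:
            slope = np.sum(w * (xw - xbar) * (yw - ybar)) / sxx
        else:
            slope = 0.0
        fitted[i] = ybar + slope * (x[i] - xbar)
    return fitted


def loess_fit(x, y, span: float = 0.3, floor: float = 1e-6,
              robustness_iters: int = 2) -> np.ndarray:
    """Locally weighted linear regression with tricube weights.

    Each point is fitted from its nearest ceil(span*n) neighbours by
    weighted linear regression; two bisquare robustness passes downweight
    outlying observations (residuals beyond six median absolute
    deviations get zero weight), so isolated spikes do not drag the
    local fit.  Returns fitted values at the input x, floored at
    ``floor``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("loess_fit needs >= 10 points")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0,1]")
    k = max(2, int(math.ceil(span * x.size)))
    robust_w = np.ones_like(y)
    fitted = _loess_pass(x, y, k, robust_w)
    for _ in range(robustness_iters):
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        robust_w = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
        fitted = _loess_pass(x, y, k, robust_w)
    return np.maximum(fitted, floor)
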