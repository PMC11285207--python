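"""Independent brute-force oracles used by the test suite and the
acceptance report.  These deliberately avoid the code paths they check:
alignment scores come from exhaustive path enumeration (no dynamic
programming), tail probabilities from direct pmf summation, p-values from
explicit permutation, decoding from nearest-codeword search.
"""

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11
GAP_EXTEND = 1


def brute_force_global_score(a, b, gap_open=GAP_OPEN, gap_extend=GAP_EXTEND):
    """Best global alignment score by exhaustive enumeration of all
    alignment paths (match/insert/delete sequences), scoring gap runs as
    -(open + (L - 1) * extend).  Exponential; only for short sequences."""
    best = [-np.inf]

    def recurse(i, j, score, last):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1,
                    score + _BLOSUM62[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if last == "D" else gap_open
            recurse(i + 1, j, score - cost, "D")
        if j < len(b):
            cost = gap_extend if last == "I" else gap_open
            recurse(i, j + 1, score - cost, "I")

    recurse(0, 0, 0.0, "")
    return best[0]


def gp_upper_tail(k, theta, lam):
    """P(X >= k) for the generalized Poisson by direct log-pmf summation."""
    from scipy.special import gammaln

    if k <= 0:
        return 1.0
    j = np.arange(k, dtype=float)
    with np.errstate(divide="ignore"):
        logpmf = (np.log(theta) + (j - 1) * np.log(theta + j * lam)
                  - theta - j * lam - gammaln(j + 1))
    return float(1.0 - np.exp(logpmf).sum())


def nearest_codeword(read, codewords):
    """(codeword, distance, ambiguous) by exhaustive search."""
    dists = [(sum(c1 != c2 for c1, c2 in zip(read, w)), w) for w in codewords]
    dists.sort()
    best_d, best_w = dists[0]
    ambiguous = len(dists) > 1 and dists[1][0] == best_d
    return best_w, best_d, ambiguous


def exact_mann_whitney_p(x, y):
    """Two-sided exact Mann-Whitney p by enumeration of all group
    assignments of the pooled sample (no ties supported)."""
    pooled = list(x) + list(y)
    n_x = len(x)

    def u_of(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi)

    u_obs = u_of(x, y)
    mean_u = n_x * len(y) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_of(xs, ys) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


def friedman_permutation_p(blocks, n_perm=5000, seed=0):
    """Monte-Carlo permutation p for the Friedman statistic: permute
    treatments independently within every block."""
    from scipy.stats import rankdata

    blocks = np.asarray(blocks, dtype=float)
    n, k = blocks.shape
    rng = np.random.default_rng(seed)

    def statistic(mat):
        ranks = np.apply_along_axis(rankdata, 1, mat)
        rank_sums = ranks.sum(axis=0)
        tie = 0.0
        for row in mat:
            _, counts = np.unique(row, return_counts=True)
            tie += np.sum(counts ** 3 - counts)
        denom = n * k * (k + 1) - tie * k / (k - 1)
        if denom <= 0:
            return 0.0
        return 12.0 * np.sum((rank_sums - n * (k + 1) / 2.0) ** 2) / denom

    obs = statistic(blocks)
    count = 0
    for _ in range(n_perm):
        permuted = np.array([rng.permutation(row) for row in blocks])
        if statistic(permuted) >= obs - 1e-12:
            count += 1
    return count / n_perm, obs


def kruskal_permutation_p(groups, n_perm=5000, seed=0):
    """Monte-Carlo permutation p for the Kruskal-Wallis H statistic."""
    from scipy.stats import rankdata

    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    rng = np.random.default_rng(seed)

    def statistic(values):
        ranks = rankdata(values)
        N = len(values)
        h = 0.0
        off = 0
        for s in sizes:
            h += ranks[off:off + s].sum() ** 2 / s
            off += s
        h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
        _, counts = np.unique(values, return_counts=True)
        corr = 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
        return h / corr if corr > 0 else 0.0

    obs = statistic(pooled)
    count = 0
    for _ in range(n_perm):
        if statistic(rng.permutation(pooled)) >= obs - 1e-12:
            count += 1
    return count / n_perm, obs
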