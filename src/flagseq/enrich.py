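"""PhIP-Seq pre-processing and enrichment calling.

The post-IP read count of a peptide, conditional on its pre-IP (input) read
level, is modelled with the two-parameter generalized Poisson distribution

    P(k) = theta * (theta + k*lam)^(k-1) * exp(-theta - k*lam) / k!

with rate ``theta > 0`` and dispersion ``lam`` in ``[0, 1)`` (the Poisson
limit is ``lam = 0``).  Peptides are grouped into logarithmic input-level
bins, (theta, lam) is fitted per bin by maximum likelihood, and the fitted
parameters are interpolated across input levels so that every peptide is
scored against a null matched to its own input count.  Seropositivity is a
Bonferroni-adjusted upper-tail p-value <= alpha; fold changes are reported
only for seropositive peptides with at least 25 input reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .errors import FitError, ParameterError

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_INPUT = 25
DEFAULT_CAP = 1_250_000
DEFAULT_FLOOR = 750_000
DEFAULT_MIN_ENRICHED = 200


@dataclass(frozen=True)
class GPParams:
    """Generalized Poisson parameters (rate theta, dispersion lam)."""

    theta: float
    lam: float

    def __post_init__(self):
        if not (self.theta > 0):
            raise ParameterError(f"theta must be > 0, got {self.theta}")
        if not (0 <= self.lam < 1):
            raise ParameterError(f"lam must be in [0, 1), got {self.lam}")

    @property
    def mean(self):
        return self.theta / (1.0 - self.lam)


def gp_logpmf(k, theta, lam):
    """Vectorized log pmf of the generalized Poisson distribution."""
    k = np.asarray(k, dtype=float)
    theta = np.asarray(theta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(theta <= 0) or np.any(lam < 0) or np.any(lam >= 1):
        raise ParameterError("require theta > 0 and 0 <= lam < 1")
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ParameterError("k must be a non-negative integer")
    with np.errstate(divide="ignore"):
        out = (np.log(theta) + (k - 1) * np.log(theta + k * lam)
               - theta - k * lam - gammaln(k + 1))
    return out


def gp_pmf(k, params):
    """Probability mass at count ``k`` under ``params``."""
    return np.exp(gp_logpmf(k, params.theta, params.lam))


def gp_sf_at(k, theta, lam):
    """Upper-tail probability P(X >= k) by direct summation of the pmf."""
    k = int(k)
    if k <= 0:
        return 1.0
    j = np.arange(k)
    cdf = np.exp(gp_logpmf(j, theta, lam)).sum()
    return float(max(min(1.0, 1.0 - cdf), 1e-300))


def gp_rvs(theta, lam, rng):
    """Sample generalized Poisson variates via the branching-process
    representation (Poisson(theta) ancestors, Poisson(lam) offspring each);
    ``theta`` may be an array, ``lam`` is scalar.  Cells with theta == 0
    return 0."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ParameterError("theta must be >= 0")
    if not (0 <= lam < 1):
        raise ParameterError("lam must be in [0, 1)")
    total = rng.poisson(theta)
    generation = total.copy()
    while np.any(generation > 0):
        generation = rng.poisson(lam * generation)
        total = total + generation
    return total


# ---------------------------------------------------------------------------
# Read normalization
# ---------------------------------------------------------------------------

def normalize_reads(sample_counts, cap=DEFAULT_CAP, floor=DEFAULT_FLOOR,
                    seed=0):
    """Normalize a peptide -> count map to at most ``cap`` total reads.

    Totals above ``cap`` are subsampled without replacement (multivariate
    hypergeometric, deterministic per seed) to exactly ``cap``; totals in
    ``[floor, cap]`` pass unchanged; totals below ``floor`` mark the sample
    excluded.  Returns ``(counts, excluded)``.
    """
    counts = pd.Series(sample_counts)
    arr = counts.to_numpy()
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ParameterError("counts must be non-negative integers")
    total = int(arr.sum())
    if total < floor:
        return counts, True
    if total <= cap:
        return counts, False
    rng = np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(arr, cap)
    return pd.Series(sub, index=counts.index), False


# ---------------------------------------------------------------------------
# Null-model fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinFit:
    input_lo: float
    input_hi: float
    params: GPParams
    n_observations: int
    degenerate: bool = False


@dataclass(frozen=True)
class NullModel:
    """Per-input-level generalized Poisson null.

    ``bins`` holds the per-bin fits; ``params_at`` interpolates theta
    (log-log, monotone non-decreasing in input) and lam (linear, clipped)
    between bin centers, clamping queries outside the fitted range to the
    nearest bin.
    """

    bins: tuple
    log_centers: np.ndarray = field(repr=False)
    thetas: np.ndarray = field(repr=False)
    lams: np.ndarray = field(repr=False)

    def params_at(self, input_counts):
        x = np.log1p(np.asarray(input_counts, dtype=float))
        lo, hi = self.log_centers[0], self.log_centers[-1]
        if np.any(x < lo - 1e-12):
            warnings.warn("input level below interpolation range; "
                          "clamped to lowest bin", stacklevel=2)
        log_thetas = np.log(self.thetas)
        log_theta = np.interp(x, self.log_centers, log_thetas)
        # Above the top bin center theta keeps growing with input
        # (approximately proportionally); clamping there would understate
        # the null mean for the most abundant peptides.
        above = x > hi
        if np.any(above):
            # theta grows proportionally with input beyond the fitted range.
            log_theta = np.where(above, log_thetas[-1] + (x - hi), log_theta)
        lam = np.interp(x, self.log_centers, self.lams)
        return np.exp(log_theta), np.clip(lam, 0.0, 1.0 - 1e-9)


def _fit_gp_mle(counts):
    """Maximum-likelihood (theta, lam) for an i.i.d. GP sample."""
    counts = np.asarray(counts, dtype=float)
    mean = counts.mean()
    var = counts.var()
    if mean == 0:
        return GPParams(1e-8, 0.0), True
    if var == 0:
        # Degenerate: zero spread; clamp lam at its lower bound.
        return GPParams(max(mean, 1e-8), 0.0), True
    lam0 = float(np.clip(1.0 - np.sqrt(mean / var), 0.0, 0.9))
    theta0 = max(mean * (1.0 - lam0), 1e-6)
    ks, weights = np.unique(counts, return_counts=True)

    def nll(p):
        log_theta, lam = p
        return -float(np.dot(weights,
                             gp_logpmf(ks, np.exp(log_theta), lam)))

    res = minimize(nll, x0=[np.log(theta0), lam0], method="L-BFGS-B",
                   bounds=[(-20.0, 20.0), (0.0, 0.97)])
    theta = float(np.exp(res.x[0]))
    lam = float(res.x[1])
    return GPParams(theta, lam), False


def fit_null_model(input_counts, output_counts, min_bin_obs=200, max_bins=20,
                   trim_frac=0.0):
    """Fit the per-input-level GP null for one sample.

    Peptides with input >= 1 are split into logarithmic input-level bins
    (quantile edges, at least ``min_bin_obs`` observations each); (theta, lam)
    is fitted per bin by MLE and interpolated across bin centers.
    ``trim_frac`` drops that fraction of the largest outputs in each bin
    before fitting (used for a contamination-robust initial fit).
    """
    inp = np.asarray(input_counts, dtype=float)
    out = np.asarray(output_counts, dtype=float)
    if inp.shape != out.shape:
        raise ParameterError("input and output vectors must share length")
    mask = inp >= 1
    if mask.sum() < min_bin_obs:
        raise FitError(
            f"only {int(mask.sum())} peptides with input >= 1; need at least "
            f"{min_bin_obs} for a stable fit")
    x = np.log1p(inp[mask])
    y = out[mask]
    n_bins = int(np.clip(mask.sum() // min_bin_obs, 1, max_bins))
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    # Quantile bins leave a single fat bin over the abundance tail, where the
    # null mean varies several-fold within the bin; split wide bins while each
    # half keeps enough observations for a usable fit.
    max_log_width, min_split_obs = 0.5, 25
    changed = True
    while changed:
        changed = False
        for b in range(len(edges) - 1):
            if edges[b + 1] - edges[b] <= max_log_width:
                continue
            mid = 0.5 * (edges[b] + edges[b + 1])
            in_bin = (x >= edges[b]) & (x <= edges[b + 1])
            n_left = int(np.sum(x[in_bin] < mid))
            n_right = int(in_bin.sum()) - n_left
            if min(n_left, n_right) >= min_split_obs:
                edges = np.insert(edges, b + 1, mid)
                changed = True
                break
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                  len(edges) - 2)

    bins = []
    centers, thetas, lams = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() == 0:
            continue
        y_bin = y[sel]
        if trim_frac > 0 and len(y_bin) > 10:
            n_keep = len(y_bin) - int(np.ceil(trim_frac * len(y_bin)))
            y_bin = np.sort(y_bin)[:n_keep]
        params, degenerate = _fit_gp_mle(y_bin)
        bins.append(BinFit(float(np.expm1(edges[b])),
                           float(np.expm1(edges[b + 1])),
                           params, int(sel.sum()), degenerate))
        centers.append(float(x[sel].mean()))
        thetas.append(params.theta)
        lams.append(params.lam)
    if not bins:
        raise FitError("no usable input-level bins")
    order = np.argsort(centers)
    centers = np.asarray(centers)[order]
    # Enforce the model invariant: theta non-decreasing in input level.
    thetas = np.maximum.accumulate(np.asarray(thetas)[order])
    lams = np.asarray(lams)[order]
    return NullModel(tuple(bins), centers, thetas, lams)


# ---------------------------------------------------------------------------
# Scoring and calling
# ---------------------------------------------------------------------------

def score_peptides(input_counts, output_counts, model):
    """Upper-tail p-value P(X >= output | GP at the peptide's input level)
    for every peptide; p = 1 at output 0."""
    inp = np.asarray(input_counts, dtype=float)
    out = np.asarray(output_counts)
    if inp.shape != out.shape:
        raise ParameterError("input and output vectors must share length")
    theta, lam = model.params_at(inp)
    k = out.astype(np.int64)
    p = np.ones(len(k), dtype=float)
    pos = k > 0
    if pos.any():
        kp = k[pos]
        # Flat evaluation of the pmf over j = 0..k-1 per cell, then
        # segment sums; total work is sum(k), not max(k) * n.
        j = np.concatenate([np.arange(v) for v in kp])
        th = np.repeat(theta[pos], kp)
        lm = np.repeat(lam[pos], kp)
        pmf = np.exp(gp_logpmf(j, th, lm))
        starts = np.concatenate([[0], np.cumsum(kp)[:-1]])
        cdf = np.add.reduceat(pmf, starts)
        p[pos] = np.clip(1.0 - cdf, 1e-300, 1.0)
    return p


def call_seropositive(p, m, alpha=DEFAULT_ALPHA):
    """Bonferroni adjustment over ``m`` tests and the seropositivity flag."""
    p = np.asarray(p, dtype=float)
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if m < len(p):
        raise ParameterError("m must be at least the number of p-values")
    p_adj = np.minimum(1.0, p * m)
    return p_adj, p_adj <= alpha


def compute_fold_change(input_counts, output_counts, seropositive,
                        min_input=DEFAULT_MIN_INPUT):
    """Post-IP / pre-IP read ratio for seropositive peptides with at least
    ``min_input`` input reads; all remaining peptides are set to zero."""
    inp = np.asarray(input_counts, dtype=float)
    out = np.asarray(output_counts, dtype=float)
    flags = np.asarray(seropositive, dtype=bool)
    eligible = flags & (inp >= min_input)
    return np.where(eligible, out / np.where(inp > 0, inp, 1.0), 0.0)


def qc_samples(seropositive_counts, min_enriched=DEFAULT_MIN_ENRICHED):
    """Retain samples with at least ``min_enriched`` seropositive peptides."""
    return [s for s, n in seropositive_counts.items() if n >= min_enriched]


def score_sample(input_counts, output_counts, m, alpha=DEFAULT_ALPHA,
                 min_bin_obs=200, refit_rounds=2):
    """Fit the null and score one sample, with robust refitting.

    Antibody-driven enrichment contaminates the null fit (a strongly bound
    peptide inflates its bin's dispersion), so after an initial fit the
    provisionally seropositive cells are excluded and the null is refitted,
    up to ``refit_rounds`` times.  Returns ``(p, model)`` for all peptides.
    """
    inp = np.asarray(input_counts, dtype=float)
    out = np.asarray(output_counts, dtype=float)
    # Initial fit trims the right tail of each bin so strong antibody-driven
    # enrichment cannot inflate the null dispersion; subsequent rounds refit
    # on untrimmed data with provisionally seropositive cells excluded.
    model = fit_null_model(inp, out, min_bin_obs=min_bin_obs, trim_frac=0.15)
    p = score_peptides(inp, out, model)
    # Exclusion threshold well below alpha: genuinely bound cells sit orders
    # of magnitude lower still, while borderline null cells stay in the fit.
    exclude_alpha = min(alpha, 1e-3)
    for _ in range(refit_rounds):
        _, flags = call_seropositive(p, m, alpha=exclude_alpha)
        if flags.mean() > 0.5:
            break
        model = fit_null_model(inp[~flags], out[~flags],
                               min_bin_obs=min(min_bin_obs,
                                               max(50, (~flags).sum() // 20)))
        p = score_peptides(inp, out, model)
    return p, model


def score_matrix(input_df, output_df, alpha=DEFAULT_ALPHA,
                 min_input=DEFAULT_MIN_INPUT, cap=DEFAULT_CAP,
                 floor=DEFAULT_FLOOR, min_enriched=DEFAULT_MIN_ENRICHED,
                 min_bin_obs=200, seed=0, refit_rounds=2):
    """Run the full calling pipeline on peptide x sample count matrices.

    ``input_df`` may have one column (shared library input) or the same
    columns as ``output_df``.  Returns ``(calls, qc)``: a long-format calls
    DataFrame and a per-sample QC table.  The Bonferroni ``m`` is the number
    of library peptides scored (library-wide correction).
    """
    if not input_df.index.equals(output_df.index):
        raise ParameterError("input and output matrices must share peptides")
    m = len(output_df.index)
    shared_input = input_df.shape[1] == 1
    calls_parts = []
    qc_rows = []
    for i, sample in enumerate(output_df.columns):
        inp = input_df.iloc[:, 0] if shared_input else input_df[sample]
        out, excluded = normalize_reads(output_df[sample], cap=cap,
                                        floor=floor, seed=seed + i)
        if excluded:
            qc_rows.append({"sample_id": sample, "total_reads": int(out.sum()),
                            "n_seropositive": 0, "retained": False,
                            "reason": "below read floor"})
            continue
        p, _model = score_sample(inp.to_numpy(), out.to_numpy(), m,
                                 alpha=alpha, min_bin_obs=min_bin_obs,
                                 refit_rounds=refit_rounds)
        p_adj, flags = call_seropositive(p, m, alpha=alpha)
        fc = compute_fold_change(inp.to_numpy(), out.to_numpy(), flags,
                                 min_input=min_input)
        calls_parts.append(pd.DataFrame({
            "peptide_id": output_df.index,
            "sample_id": sample,
            "input": inp.to_numpy(),
            "output": out.to_numpy(),
            "p": p,
            "p_adj": p_adj,
            "seropositive": flags,
            "fold_change": fc,
        }))
        n_sero = int(flags.sum())
        qc_rows.append({"sample_id": sample, "total_reads": int(out.sum()),
                        "n_seropositive": n_sero,
                        "retained": n_sero >= min_enriched,
                        "reason": "" if n_sero >= min_enriched
                        else "below min enriched"})
    qc = pd.DataFrame(qc_rows)
    retained = set(qc.loc[qc["retained"], "sample_id"]) if len(qc) else set()
    if calls_parts:
        calls = pd.concat(calls_parts, ignore_index=True)
        calls = calls[calls["sample_id"].isin(retained)].reset_index(drop=True)
    else:
        calls = pd.DataFrame(columns=["peptide_id", "sample_id", "input",
                                      "output", "p", "p_adj", "seropositive",
                                      "fold_change"])
    return calls, qc
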