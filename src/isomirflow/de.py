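"""Count-based differential expression for miRNA and mRNA matrices.

The engine implements the classical count-DE stack from first principles:

* CPM scaling and the two expression filters (mRNA: keep genes with CPM >= 1
  in at least one sample; miRNA: keep features with raw count >= 5 in at
  least ceil(n/3) of the samples across the two compared groups).
* TMM (trimmed mean of M-values) between-sample normalisation: the reference
  sample is the one whose upper-quartile CPM is closest to the mean
  upper-quartile; per sample, a precision-weighted mean of log2 count ratios
  (M-values) is taken after trimming 30% of the M tails and 5% of the A
  tails, over features positive in both sample and reference; the factors
  are rescaled to geometric mean 1.
* A common negative-binomial dispersion by quantile-adjusted conditional
  maximum likelihood (qCML): library sizes are equalised by mapping counts
  quantile-to-quantile to a common library size, and the conditional NB
  log-likelihood given the per-group totals is maximised by bounded 1-D
  search.
* The NB exact test: conditional on a feature's total pseudo-count, the
  probability of group-sum splits as or more extreme than the observed one,
  two-sided by summing the probabilities of all splits whose probability is
  at most that of the observed split (no doubling).
* Benjamini-Hochberg step-up FDR adjustment.

Call rules: miRNA features are differentially expressed iff FDR <= 0.15 and
linear |FC| > 1.5 (strict); mRNA genes iff FDR < 0.05 (strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .io import CountMatrix

logger = logging.getLogger(__name__)

MIRNA_RULE = "mirna"
MRNA_RULE = "mrna"

PRIOR_COUNT = 0.125  # per-sample prior added when computing log fold changes


# ---------------------------------------------------------------------------
# CPM and expression filters


def cpm(counts: pd.DataFrame | CountMatrix,
        lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: count x 1e6 / library size (column sum by default)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if lib_sizes is None:
        lib_sizes = df.sum(axis=0)
    zero = lib_sizes[lib_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s) {list(zero.index)}")
    return df * 1e6 / lib_sizes


def filter_low_expression_mrna(matrix: CountMatrix) -> CountMatrix:
    """Keep genes with CPM >= 1 in at least one sample.

    Genes below 1 CPM everywhere are treated as no/low expression and
    omitted from further analysis.
    """
    keep = (cpm(matrix) >= 1.0).any(axis=1)
    return matrix.subset_features(keep[keep].index)


def filter_low_count_mirna(matrix: CountMatrix, min_count: int = 5,
                           fraction: float = 1 / 3) -> CountMatrix:
    """Keep features with raw count >= min_count in at least ceil(n * fraction)
    of the n samples across the compared groups."""
    n = matrix.counts.shape[1]
    need = math.ceil(n * fraction)
    keep = (matrix.counts >= min_count).sum(axis=1) >= need
    return matrix.subset_features(keep[keep].index)


# ---------------------------------------------------------------------------
# TMM normalisation


def _upper_quartile(df: pd.DataFrame, lib_sizes: pd.Series) -> pd.Series:
    return (df / lib_sizes).quantile(0.75, axis=0)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0:
        return np.nan
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = ((rank_m >= lo_l) & (rank_m <= hi_l)
            & (rank_a >= lo_s) & (rank_a <= hi_s))
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(matrix: CountMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors, geometric mean 1."""
    df = matrix.counts
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = df.sum(axis=0).astype(float)
    uq = _upper_quartile(df, lib)
    ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = df[ref_sample].to_numpy(dtype=float)
    factors = {}
    for s in df.columns:
        f = _tmm_pair(df[s].to_numpy(dtype=float), ref, lib[s],
                      lib[ref_sample], trim_m, trim_a)
        if np.isnan(f):
            logger.warning("sample %s shares no positive features with the "
                           "reference; factor set to 1", s)
            f = 1.0
        factors[s] = f
    out = pd.Series(factors, name="tmm_factor").reindex(df.columns)
    out /= np.exp(np.log(out).mean())
    return out


# ---------------------------------------------------------------------------
# quantile adjustment (pseudo-counts at a common library size)


def _q2q_nbinom(x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray,
                dispersion: float) -> np.ndarray:
    """Quantile-to-quantile map of counts from NB(input_mean, phi) to
    NB(output_mean, phi), averaging normal and gamma approximations and using
    the numerically favourable tail."""
    input_mean = np.where(input_mean < 1e-14, input_mean + 0.25, input_mean)
    output_mean = np.where(output_mean < 1e-14, output_mean + 0.25, output_mean)
    ri = 1.0 + dispersion * input_mean
    ro = 1.0 + dispersion * output_mean
    vi = input_mean * ri
    vo = output_mean * ro
    out = np.empty_like(x, dtype=float)
    upper = x >= input_mean
    for mask, lower_tail in ((~upper, True), (upper, False)):
        if not mask.any():
            continue
        xm, im, om = x[mask], input_mean[mask], output_mean[mask]
        rim, rom = ri[mask], ro[mask]
        sdi, sdo = np.sqrt(vi[mask]), np.sqrt(vo[mask])
        if lower_tail:
            p_norm = stats.norm.logcdf(xm, loc=im, scale=sdi)
            q_norm = stats.norm.ppf(np.exp(p_norm), loc=om, scale=sdo)
            p_gam = stats.gamma.logcdf(xm, a=im / rim, scale=rim)
            q_gam = stats.gamma.ppf(np.exp(p_gam), a=om / rom, scale=rom)
        else:
            p_norm = stats.norm.logsf(xm, loc=im, scale=sdi)
            q_norm = stats.norm.isf(np.exp(p_norm), loc=om, scale=sdo)
            p_gam = stats.gamma.logsf(xm, a=im / rim, scale=rim)
            q_gam = stats.gamma.isf(np.exp(p_gam), a=om / rom, scale=rom)
        out[mask] = (q_norm + q_gam) / 2.0
    return np.clip(out, 0.0, None)


def _one_group_nb_log_mean(y: np.ndarray, offsets: np.ndarray,
                           dispersion: float, iters: int = 50) -> np.ndarray:
    """Per-feature intercept of a one-group NB log-linear fit with offsets.

    Solves sum_s (y - mu) / (1 + phi * mu) = 0 for beta with
    mu_s = exp(beta + offset_s), by Newton iteration.
    """
    tot = y.sum(axis=1)
    beta = np.log(np.maximum(tot, 0.5)) - np.log(np.exp(offsets).sum())
    for _ in range(iters):
        mu = np.exp(beta[:, None] + offsets[None, :])
        denom = 1.0 + dispersion * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def equalize_library_sizes(
    matrix: CountMatrix, factors: pd.Series, dispersion: float
) -> tuple[pd.DataFrame, float]:
    """Pseudo-counts mapped to a common (geometric-mean) effective library size."""
    df = matrix.counts
    eff_lib = (df.sum(axis=0) * factors.reindex(df.columns)).to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(eff_lib))))
    y = df.to_numpy(dtype=float)
    beta = _one_group_nb_log_mean(y, np.log(eff_lib), dispersion)
    input_mean = np.exp(beta[:, None] + np.log(eff_lib)[None, :])
    output_mean = np.exp(beta[:, None]) * common * np.ones_like(input_mean)
    pseudo = _q2q_nbinom(y, input_mean, output_mean, dispersion)
    return pd.DataFrame(pseudo, index=df.index, columns=df.columns), common


# ---------------------------------------------------------------------------
# common dispersion (qCML)


@dataclass(frozen=True)
class Dispersion:
    common_dispersion: float


def _conditional_loglik(pseudo: np.ndarray, group_idx: list[np.ndarray],
                        phi: float) -> float:
    """Conditional NB log-likelihood given per-group totals, equal libraries."""
    r = 1.0 / phi
    total = 0.0
    for idx in group_idx:
        y = pseudo[:, idx]
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) - n * pseudo.shape[0] * gammaln(r)
            + np.sum(gammaln(n * r) - gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    tol: float = 1e-6,
    outer_iterations: int = 2,
) -> Dispersion:
    """qCML common-dispersion estimate.

    Counts are quantile-adjusted to a common effective library size at the
    current dispersion guess, then the conditional log-likelihood given the
    per-group totals is maximised over delta = phi / (1 + phi) by bounded
    search; the adjust/maximise cycle is iterated twice, as the estimate
    feeds back into the quantile adjustment.
    """
    if factors is None:
        factors = pd.Series(1.0, index=matrix.counts.columns)
    groups = matrix.groups
    sizes = groups.value_counts()
    if (sizes < 2).sum() == len(sizes):
        raise ValueError("need at least one group with >= 2 samples")
    if (matrix.counts.nunique(axis=1) == 1).all() and \
            (matrix.counts.std(axis=1) == 0).all():
        logger.warning("all features constant; dispersion set to 0")
        return Dispersion(0.0)
    cols = list(matrix.counts.columns)
    group_idx = [np.array([cols.index(s) for s in groups[groups == g].index])
                 for g in sizes.index]
    disp = 0.01
    for _ in range(outer_iterations):
        pseudo_df, _ = equalize_library_sizes(matrix, factors, disp)
        pseudo = pseudo_df.to_numpy()
        keep = pseudo.sum(axis=1) > 0
        pseudo = pseudo[keep]

        def neg_ll(delta: float) -> float:
            phi = delta / (1.0 - delta)
            return -_conditional_loglik(pseudo, group_idx, phi)

        res = optimize.minimize_scalar(
            neg_ll, bounds=(1e-6, 100.0 / 101.0), method="bounded",
            options={"xatol": tol})
        disp = res.x / (1.0 - res.x)
    return Dispersion(float(disp))


# ---------------------------------------------------------------------------
# exact test


def _exact_split_pvalue(z: int, n1: int, n2: int, mu: float, phi: float,
                        obs: int) -> float:
    """Two-sided conditional p-value for the split (obs, z - obs) of total z.

    Group sums are NB: Y1 ~ NB(n1*mu, phi/n1), Y2 ~ NB(n2*mu, phi/n2); the
    p-value sums, over the conditional distribution of Y1 given Y1+Y2=z, the
    probabilities of all splits at most as probable as the observed one
    (factor 1+1e-7 guards ties against round-off).
    """
    if z == 0:
        return 1.0
    if phi <= 1e-12:
        # Poisson limit: conditional distribution is binomial
        k = np.arange(z + 1)
        logp = stats.binom.logpmf(k, z, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / phi, n2 / phi
        p1 = r1 / (r1 + n1 * mu)
        p2 = r2 / (r2 + n2 * mu)
        # restrict the enumeration to where mass is non-negligible
        if z > 10000:
            m1 = z * n1 / (n1 + n2)
            sd = math.sqrt(max(z, 1.0)) * 2.0 * math.sqrt(1 + phi * mu)
            lo = max(0, int(m1 - 50 * sd))
            hi = min(z, int(m1 + 50 * sd))
            lo = min(lo, obs)
            hi = max(hi, obs)
            k = np.arange(lo, hi + 1)
        else:
            k = np.arange(z + 1)
        logp = (stats.nbinom.logpmf(k, r1, p1)
                + stats.nbinom.logpmf(z - k, r2, p2))
    log_tot = logsumexp(logp)
    cond = logp - log_tot
    obs_idx = int(obs - k[0])
    thresh = cond[obs_idx] + math.log1p(1e-7)
    return float(min(1.0, math.exp(logsumexp(cond[cond <= thresh]))))


def nb_exact_test(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    dispersion: float | Dispersion | None = None,
    pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Exact NB test between two groups on a filtered count matrix.

    Returns a DataFrame indexed by feature with columns log2fc (second group
    of ``pair`` over the first), pvalue and mean_cpm.  Counts are first
    quantile-adjusted to a common library size; log2 fold changes use a
    0.125 prior count per sample.
    """
    if factors is None:
        factors = pd.Series(1.0, index=matrix.counts.columns)
    groups = matrix.groups
    if pair is None:
        seen: list[str] = []
        for g in groups:
            if g not in seen:
                seen.append(g)
        if len(seen) != 2:
            raise ValueError(f"expected exactly 2 groups, found {seen}")
        pair = (seen[0], seen[1])
    g1, g2 = pair
    idx1 = groups[groups == g1].index
    idx2 = groups[groups == g2].index
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError("both groups must have at least one sample")
    if isinstance(dispersion, Dispersion):
        dispersion = dispersion.common_dispersion
    if dispersion is None:
        dispersion = estimate_common_dispersion(matrix, factors).common_dispersion

    pseudo, _ = equalize_library_sizes(matrix, factors, max(dispersion, 1e-8))
    n1, n2 = len(idx1), len(idx2)
    s1 = pseudo[idx1].sum(axis=1).round().astype(int).clip(lower=0)
    s2 = pseudo[idx2].sum(axis=1).round().astype(int).clip(lower=0)

    pvals = np.empty(len(pseudo))
    for i, (a, b) in enumerate(zip(s1.to_numpy(), s2.to_numpy())):
        z = int(a + b)
        mu = z / (n1 + n2)
        pvals[i] = _exact_split_pvalue(z, n1, n2, mu, dispersion, int(a))

    m1 = (s1 + PRIOR_COUNT * n1) / n1
    m2 = (s2 + PRIOR_COUNT * n2) / n2
    log2fc = np.log2(m2 / m1)
    mean_cpm = cpm(matrix).mean(axis=1)
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "mean_cpm": mean_cpm},
        index=matrix.counts.index,
    )


# ---------------------------------------------------------------------------
# multiple testing and call rules


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_de(results: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Add FDR and the is_de flag under the named call rule.

    mirna: is_de iff FDR <= 0.15 and linear |FC| > 1.5 (strict).
    mrna:  is_de iff FDR < 0.05 (strict).
    """
    out = results.copy()
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    if rule == MIRNA_RULE:
        # |FC| > 1.5 evaluated on the log2 scale (exact at the boundary)
        out["is_de"] = (out["fdr"] <= 0.15) & (np.abs(out["log2fc"]) > np.log2(1.5))
    elif rule == MRNA_RULE:
        out["is_de"] = out["fdr"] < 0.05
    else:
        raise ValueError(f"unknown call rule {rule!r}")
    return out


def de_analysis(
    matrix: CountMatrix,
    rule: str,
    pair: tuple[str, str] | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Filter, normalise, test and call: the full two-group DE pipeline."""
    if rule == MIRNA_RULE:
        filtered = filter_low_count_mirna(matrix)
    elif rule == MRNA_RULE:
        filtered = filter_low_expression_mrna(matrix)
    else:
        raise ValueError(f"unknown call rule {rule!r}")
    factors = tmm_factors(filtered)
    if dispersion is None:
        dispersion = estimate_common_dispersion(
            filtered, factors).common_dispersion
    results = nb_exact_test(filtered, factors, dispersion, pair)
    return call_de(results, rule)
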