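"""Two-group negative-binomial Wald differential expression.

A deliberately small DE engine for the 2 x 2 (genotype x replicate) design:
median-of-ratios size factors, per-species NB dispersion by adjusted profile
maximum likelihood (group means profiled out, Cox-Reid adjustment), Wald
log2 fold-changes with standard errors from observed Fisher information, and
two-sided normal p-values.  Downstream classification consumes only
(log2fc, se, p), and externally produced tables in the same schema are
accepted in place of this engine.

Also provides the standard-error-based comparison of two fold-changes (the
guide-vs-passenger test) and ratio statistics with first-order (delta-method)
error propagation used for arm- and isoform-ratio displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from tdmdscan.quantify import CountTable

DISPERSION_FLOOR = 1e-8
PSEUDO_LEVEL = 0.5  # pseudo normalized level for a group with mean zero

DE_COLUMNS = ["species_id", "tissue", "baseMean", "log2fc", "se", "p", "padj"]


class DiffexpError(ValueError):
    pass


@dataclass(frozen=True)
class DeRecord:
    """Per-species differential-expression summary (ko vs het)."""

    species_id: str
    tissue: str
    log2fc: float
    se: float
    p_two_sided: float
    mean_expr: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.se) or self.se <= 0:
            raise DiffexpError(f"{self.species_id}: se must be finite and positive")


@dataclass(frozen=True)
class RatioStat:
    """Ratio of two mean abundances with delta-method error on the log2 scale."""

    numerator_id: str
    denominator_id: str
    ratio: float
    log2_ratio: float
    se_log2: float


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over species (positive in all libraries) of
    count_ij / geometric-mean_i, rescaled to geometric mean 1.  Falls back to
    library-total ratios (with a warning) when no species is all-positive.
    """
    mat = counts.to_numpy(dtype=float)
    pos = (mat > 0).all(axis=1)
    if pos.any():
        logs = np.log(mat[pos])
        log_geo = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - log_geo, axis=0))
    else:
        import warnings

        warnings.warn("no species positive in all libraries; using library-total size factors")
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise DiffexpError("cannot compute size factors: empty library")
        factors = totals / np.exp(np.mean(np.log(totals)))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def _nb_loglik(k, mu, alpha):
    """NB log-likelihood, size 1/alpha, broadcasting over leading axes."""
    inv = 1.0 / alpha
    return (
        gammaln(k + inv)
        - gammaln(inv)
        - gammaln(k + 1.0)
        + k * np.log(alpha * mu / (1.0 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    )


def _dispersion_trend(alpha_mle: np.ndarray, base_mean: np.ndarray) -> np.ndarray:
    """Parametric mean-dispersion trend alpha(mu) = a0 + a1/mu.

    Fitted by least squares on the per-species estimates with one round of
    trimming (estimates > 4x or < 1/4 the fit are dropped), positivity
    enforced; falls back to the median dispersion when the fit degenerates.
    """
    x = 1.0 / np.maximum(base_mean, 1e-8)
    y = np.maximum(alpha_mle, 1e-8)
    keep = np.ones(len(y), dtype=bool)
    coef = None
    for _ in range(2):
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        coef, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
        fit = np.maximum(coef[0] + coef[1] * x, 1e-8)
        keep = (y < 4 * fit) & (y > fit / 4)
        if keep.sum() < 10:
            break
    if coef is None or coef[0] <= 0:
        return np.full_like(y, max(np.median(y), 1e-8))
    trend = coef[0] + max(coef[1], 0.0) * x
    return np.maximum(trend, 1e-8)


def _profile_group_means(k, s, alpha, n_iter=4):
    """Solve the NB score equation for the group mean q given dispersion.

    q satisfies sum_j (k_j - s_j q) / (1 + alpha s_j q) = 0; fixed-point
    iterations from the normalized-count mean.  Shapes: k,s (..., n_lib),
    alpha (...,) broadcastable.
    """
    q = np.maximum((k / s).mean(axis=-1), 1e-12)
    a = np.asarray(alpha)[..., None]  # (..., 1) against the library axis
    for _ in range(n_iter):
        w = s / (1.0 + a * s * q[..., None])
        q = np.maximum((w * (k / s)).sum(axis=-1) / np.maximum(w.sum(axis=-1), 1e-300), 1e-12)
    return q


def wald_de(
    table: CountTable,
    tissue: str,
    species: set[str] | None = None,
    factors: pd.Series | None = None,
    n_grid: int = 48,
    shrink_dispersion: bool = True,
    prior_dispersion: float | None = None,
) -> pd.DataFrame:
    """NB Wald DE for one tissue (ko vs het), vectorised over species.

    Per species: the dispersion point estimate maximises the
    Cox-Reid-adjusted profile likelihood on a log-spaced grid (with
    parabolic refinement), floored at 1e-8.  With few replicates that
    estimate is far too noisy for calibrated Wald tests, so by default it is
    moderated across species: a mean-dispersion trend a0 + a1/mean is fitted
    to the per-species estimates and the final dispersion maximises the
    penalised likelihood with a log-normal prior centred on the trend
    (empirical-Bayes MAP, the standard moderation for small-replicate
    RNA-seq designs).  log2fc = log2(q_ko / q_het) with a 0.5 pseudo-level
    for a zero group mean; SE from observed Fisher information of the two
    group log-means; p two-sided Wald.

    ``prior_dispersion`` supplies an external trend value (used for e.g.
    pooled-strand records computed on tiny tables, where no cross-species
    trend is estimable).  Returns a DataFrame with DE_COLUMNS plus a
    ``dispersion`` column (padj filled with NaN here).
    """
    sub = table.subset(tissue)
    counts = sub.counts.loc[sub.mirna_index()]
    if species is not None:
        counts = counts.loc[sorted(set(species) & set(counts.index))]
    counts = counts.loc[(counts.sum(axis=1) > 0)]
    if counts.empty:
        return pd.DataFrame(columns=DE_COLUMNS)
    if factors is None:
        factors = size_factors(sub.counts.loc[sub.mirna_index()])
    libs = list(counts.columns)
    geno = np.array([sub.libraries[l].genotype for l in libs])
    if not ((geno == "het").any() and (geno == "ko").any()):
        raise DiffexpError(f"tissue {tissue}: both genotypes required")

    k = counts.to_numpy(dtype=float)  # (n_species, n_lib)
    s = factors.loc[libs].to_numpy(dtype=float)[None, :]
    het = geno == "het"
    ko = geno == "ko"

    alphas = np.exp(np.linspace(np.log(1e-6), np.log(10.0), n_grid))  # (G,)

    def cr_profile_ll(alpha_vec):
        """Cox-Reid adjusted profile loglik, shape (n_species, len(alpha_vec))."""
        a = alpha_vec[None, :, None]  # (1, G, 1)
        ll = np.zeros((k.shape[0], alpha_vec.size))
        for mask in (het, ko):
            kg = k[:, None, mask]
            sg = s[:, None, mask]
            q = _profile_group_means(kg, sg, np.broadcast_to(alpha_vec[None, :], (k.shape[0], alpha_vec.size)))
            mu = sg * q[..., None]
            mu = np.maximum(mu, 1e-12)
            ll += _nb_loglik(kg, mu, a).sum(axis=-1)
            w = mu / (1.0 + a * mu)  # (n, G, n_g)
            ll -= 0.5 * np.log(np.maximum(w.sum(axis=-1), 1e-300))
        return ll

    ll = cr_profile_ll(alphas)
    log_alphas = np.log(alphas)
    base_mean = (k / s).mean(axis=1)

    def argmax_refined(obj):
        """Grid argmax with parabolic refinement in log-alpha."""
        best = np.argmax(obj, axis=1)
        i0 = np.clip(best, 1, n_grid - 2)
        rows = np.arange(obj.shape[0])
        y0, y1, y2 = obj[rows, i0 - 1], obj[rows, i0], obj[rows, i0 + 1]
        denom = y0 - 2 * y1 + y2
        step = log_alphas[1] - log_alphas[0]
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        a_hat = np.exp(log_alphas[i0] + shift * step)
        a_hat = np.where(best == 0, alphas[0], np.where(best == n_grid - 1, alphas[-1], a_hat))
        return np.maximum(a_hat, DISPERSION_FLOOR)

    alpha_mle = argmax_refined(ll)

    if shrink_dispersion and (prior_dispersion is not None or len(alpha_mle) >= 50):
        if prior_dispersion is not None:
            trend = np.full_like(alpha_mle, max(prior_dispersion, DISPERSION_FLOOR))
        else:
            trend = _dispersion_trend(alpha_mle, base_mean)
        log_resid = np.log(np.maximum(alpha_mle, 1e-8)) - np.log(trend)
        # sampling variance of a log-dispersion estimate with 2 residual df
        sampling_var = 1.645
        mad = np.median(np.abs(log_resid - np.median(log_resid)))
        prior_var = max((1.4826 * mad) ** 2 - sampling_var, 0.25)
        penalty = (log_alphas[None, :] - np.log(trend)[:, None]) ** 2 / (2.0 * prior_var)
        alpha_hat = argmax_refined(ll - penalty)
        # dispersion outliers (far above the prior) keep their own estimate;
        # shrinking them would understate their variance and inflate Wald z
        outlier = log_resid > 2.0 * np.sqrt(prior_var + sampling_var)
        alpha_hat = np.where(outlier, alpha_mle, alpha_hat)
    else:
        alpha_hat = alpha_mle

    # final group means at alpha_hat
    q_het = _profile_group_means(k[:, het], s[:, het], alpha_hat)
    q_ko = _profile_group_means(k[:, ko], s[:, ko], alpha_hat)

    zero_het = counts.to_numpy()[:, het].sum(axis=1) == 0
    q_het_fc = np.where(zero_het, PSEUDO_LEVEL, q_het)
    zero_ko = counts.to_numpy()[:, ko].sum(axis=1) == 0
    q_ko_fc = np.where(zero_ko, PSEUDO_LEVEL, q_ko)
    log2fc = np.log2(q_ko_fc / q_het_fc)

    def info_logmean(sq, q):
        mu = np.maximum(sq * q[:, None], 1e-12)
        a = alpha_hat[:, None]
        return (mu / (1.0 + a * mu)).sum(axis=1)

    var_log = 1.0 / np.maximum(info_logmean(s[:, het], q_het_fc), 1e-12) + 1.0 / np.maximum(
        info_logmean(s[:, ko], q_ko_fc), 1e-12
    )
    se = np.sqrt(var_log) / np.log(2.0)
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "species_id": counts.index,
            "tissue": tissue,
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": np.nan,
            "dispersion": alpha_hat,
        }
    ).reset_index(drop=True)


def de_record(row) -> DeRecord:
    """Convert a DE-table row (namedtuple or Series) to a DeRecord."""
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    return DeRecord(
        species_id=get("species_id"),
        tissue=get("tissue"),
        log2fc=float(get("log2fc")),
        se=float(get("se")),
        p_two_sided=float(get("p")),
        mean_expr=float(get("baseMean")),
    )


def lfc_diff_test(a: DeRecord, b: DeRecord) -> tuple[float, float, float, float]:
    """One-sided comparison of two log2 fold-changes via their standard errors.

    Returns (diff, se_diff, z, p_one_sided) for H1: lfc_a > lfc_b.
    """
    if a.tissue != b.tissue:
        raise DiffexpError("lfc_diff_test requires records from the same tissue")
    diff = a.log2fc - b.log2fc
    se_diff = float(np.hypot(a.se, b.se))
    z = diff / se_diff
    p = float(stats.norm.sf(z))
    return diff, se_diff, z, p


def strand_ratio(
    numerator_id: str,
    denominator_id: str,
    mean_num: float,
    se_num: float,
    mean_den: float,
    se_den: float,
) -> RatioStat:
    """Ratio of two mean levels with delta-method SE on the log2 scale."""
    if mean_den <= 0 or mean_num <= 0:
        raise DiffexpError("strand_ratio requires positive means")
    ratio = mean_num / mean_den
    se_log2 = float(
        np.sqrt((se_num / mean_num) ** 2 + (se_den / mean_den) ** 2) / np.log(2.0)
    )
    return RatioStat(numerator_id, denominator_id, ratio, float(np.log2(ratio)), se_log2)


def read_de_table(path) -> pd.DataFrame:
    """Read an externally produced DE table in the documented schema."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise DiffexpError(f"DE table missing columns {sorted(missing)}")
    return df[DE_COLUMNS]
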