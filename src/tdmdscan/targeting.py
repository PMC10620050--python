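"""Target-repression analysis with UTR-length-matched no-site resampling.

For a miRNA family, predicted-target cohorts of increasing stringency (all
canonical-site targets, conserved targets, and the top decile by cumulative
weighted context++ score) are compared against no-site cohorts sampled 5:1
from 3'-UTR-length-matched bins.  Repression is the median log2 fold-change
of the target cohort minus that of the no-site cohort; the sampling is
repeated (default 21 times, seed + index per repetition) to yield a mean,
standard error, and median Mann-Whitney p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tdmdscan.annotations import TargetPrediction

DEFAULT_N_BINS = 20
DEFAULT_RATIO = 5
DEFAULT_N_RESAMPLES = 21
DEFAULT_TPM_MIN = 10.0

COHORTS = ("top", "conserved", "all")


class TargetingError(ValueError):
    pass


@dataclass(frozen=True)
class RepressionResult:
    """Resampled fold-repression statistic for one family/tissue/cohort."""

    family_id: str
    tissue: str
    cohort: str
    fold_repression_mean: float
    fold_repression_se: float
    p_median: float
    n_targets: int
    n_no_site: int
    n_resamples: int


def expressed_transcripts(tpm: pd.DataFrame, tpm_min: float = DEFAULT_TPM_MIN) -> set[str]:
    """Transcripts above tpm_min in every library of the tissue's table.

    ``tpm`` is indexed by transcript_id with one column per library.
    """
    keep = (tpm > tpm_min).all(axis=1)
    return set(tpm.index[keep])


def bin_utr_lengths(utr_lengths: pd.Series, n_bins: int = DEFAULT_N_BINS) -> pd.Series:
    """Partition transcripts into n_bins equally populated 3'-UTR-length bins.

    Computed over the full annotation (before any expression filtering).
    Transcripts are ordered by (length, transcript_id) — the stable id
    tie-break — and split into contiguous equal-population bins, so bin
    boundaries are non-decreasing in length.  Returns a Series of bin indices
    (0..n_bins-1) indexed by transcript_id.
    """
    if len(utr_lengths) < n_bins:
        raise TargetingError(
            f"need at least {n_bins} transcripts to form {n_bins} bins, got {len(utr_lengths)}"
        )
    if (utr_lengths <= 0).any():
        raise TargetingError("utr lengths must be positive")
    order = utr_lengths.sort_index().sort_values(kind="stable")
    chunks = np.array_split(np.arange(len(order)), n_bins)
    bins = np.empty(len(order), dtype=int)
    for b, idx in enumerate(chunks):
        bins[idx] = b
    out = pd.Series(bins, index=order.index)
    if utr_lengths.nunique() == 1:
        warnings.warn("all UTR lengths identical; bins are arbitrary splits of ties")
    return out.loc[utr_lengths.index]


def build_cohorts(
    predictions: list[TargetPrediction],
    family_id: str,
    expressed: set[str],
    top_decile_within_expressed: bool = False,
) -> dict[str, list[str]]:
    """Build the three target cohorts and the no-site pool for one family.

    ``all``: expressed transcripts with any canonical 7-8-nt site;
    ``conserved``: expressed with a conserved site; ``top``: the top decile
    of the family's full annotated target list by most-negative context++
    score, intersected with the expressed set (set
    ``top_decile_within_expressed`` to rank within the expressed targets
    instead); ``no_site_pool``: expressed transcripts in the prediction table
    with no site for this family.
    """
    fam = [p for p in predictions if p.family_id == family_id]
    if not any(p.has_site for p in fam):
        raise TargetingError(f"family {family_id} has no predicted targets")
    targets = [p for p in fam if p.has_site]
    all_cohort = sorted(p.transcript_id for p in targets if p.transcript_id in expressed)
    conserved = sorted(
        p.transcript_id for p in targets if p.conserved and p.transcript_id in expressed
    )
    if not conserved:
        warnings.warn(f"family {family_id}: conserved cohort is empty")
    rank_pool = (
        [p for p in targets if p.transcript_id in expressed]
        if top_decile_within_expressed
        else targets
    )
    n_top = max(1, len(rank_pool) // 10)
    ranked = sorted(rank_pool, key=lambda p: (p.context_score, p.transcript_id))
    top_ids = {p.transcript_id for p in ranked[:n_top]}
    top = sorted(t for t in top_ids if t in expressed)
    no_site = sorted(
        p.transcript_id
        for p in fam
        if not p.has_site and p.transcript_id in expressed
    )
    return {"top": top, "conserved": conserved, "all": all_cohort, "no_site_pool": no_site}


def sample_no_site_cohort(
    target_cohort: list[str],
    no_site_pool: list[str],
    bins: pd.Series,
    ratio: int = DEFAULT_RATIO,
    seed: int | None = None,
) -> list[str]:
    """Draw a length-matched no-site cohort: ``ratio`` pool transcripts per target.

    Draws are without replacement within one cohort (disjoint across targets);
    for each target the draws come from its own UTR-length bin.  Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    targets_by_bin: dict[int, int] = {}
    for t in target_cohort:
        b = int(bins.loc[t])
        targets_by_bin[b] = targets_by_bin.get(b, 0) + 1
    pool_by_bin: dict[int, list[str]] = {}
    for t in no_site_pool:
        pool_by_bin.setdefault(int(bins.loc[t]), []).append(t)
    cohort: list[str] = []
    for b in sorted(targets_by_bin):
        need = ratio * targets_by_bin[b]
        pool = sorted(pool_by_bin.get(b, []))
        if len(pool) < need:
            raise TargetingError(
                f"bin {b}: no-site pool of {len(pool)} cannot supply {need} transcripts"
            )
        picked = rng.choice(len(pool), size=need, replace=False)
        cohort.extend(pool[i] for i in picked)
    return cohort


def repression_stats(
    lfc: pd.Series,
    target_cohort: list[str],
    no_site_pool: list[str],
    bins: pd.Series,
    family_id: str = "",
    tissue: str = "",
    cohort_name: str = "all",
    ratio: int = DEFAULT_RATIO,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    return_resamples: bool = False,
):
    """Resampled fold-repression of a target cohort vs length-matched no-site cohorts.

    Per repetition i (seeded seed + i): fold_repression_i = median lfc of the
    (fixed) target cohort minus median lfc of a freshly sampled no-site
    cohort; p_i is the two-sided Mann-Whitney U p-value between the two lfc
    distributions.  Returns mean, SE (SD/sqrt(n)), and median p over
    repetitions.
    """
    if len(target_cohort) < 2:
        raise TargetingError("target cohort must contain at least 2 transcripts")
    target_lfc = lfc.loc[target_cohort].to_numpy(dtype=float)
    target_median = float(np.median(target_lfc))
    reps = np.empty(n_resamples)
    pvals = np.empty(n_resamples)
    last_n_no_site = 0
    for i in range(n_resamples):
        cohort = sample_no_site_cohort(target_cohort, no_site_pool, bins, ratio, seed + i)
        ns_lfc = lfc.loc[cohort].to_numpy(dtype=float)
        last_n_no_site = len(cohort)
        reps[i] = target_median - float(np.median(ns_lfc))
        if np.ptp(np.concatenate([target_lfc, ns_lfc])) == 0.0:
            pvals[i] = 1.0  # constant fold-changes carry no rank information
        else:
            pvals[i] = stats.mannwhitneyu(target_lfc, ns_lfc, alternative="two-sided").pvalue
    result = RepressionResult(
        family_id=family_id,
        tissue=tissue,
        cohort=cohort_name,
        fold_repression_mean=float(reps.mean()),
        fold_repression_se=float(reps.std(ddof=1) / np.sqrt(n_resamples)),
        p_median=float(np.median(pvals)),
        n_targets=len(target_cohort),
        n_no_site=last_n_no_site,
        n_resamples=n_resamples,
    )
    if return_resamples:
        return result, pd.DataFrame({"resample": np.arange(n_resamples), "fold_repression": reps, "p": pvals})
    return result
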