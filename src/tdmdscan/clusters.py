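"""Genomic miRNA cluster calling and enrichment of sensitive loci in clusters.

A cluster is a maximal chain of >= 2 hairpin loci on the same chromosome and
strand in which the gap between consecutive loci (start of the next minus end
of the previous, floored at 0 for overlaps) is at most the window (default
10 kb).  Enrichment of a query locus set among clustered loci is assessed by
an exact upper-tail hypergeometric test, accompanied by a Monte-Carlo
random-cohort simulation (draws of the same size without replacement) that
reproduces the mean and SD background expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from tdmdscan.annotations import HairpinLocus

DEFAULT_WINDOW = 10_000
DEFAULT_N_COHORTS = 10_000


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterSet:
    """Partition of loci into ordered clusters (size >= 2) and singletons."""

    clusters: tuple[tuple[str, ...], ...]
    singletons: tuple[str, ...]

    @property
    def clustered_loci(self) -> frozenset:
        return frozenset(l for c in self.clusters for l in c)

    def is_clustered(self, locus_id: str) -> bool:
        return locus_id in self.clustered_loci


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric + Monte-Carlo enrichment of a query set in clusters."""

    N: int  # total loci
    K: int  # clustered loci
    n: int  # query loci
    k: int  # clustered query loci
    observed_frac: float
    background_frac: float
    p_hypergeom: float
    mc_mean: float
    mc_sd: float
    n_cohorts: int


def call_clusters(
    loci: list[HairpinLocus],
    window: int = DEFAULT_WINDOW,
    start_to_start: bool = False,
) -> ClusterSet:
    """Chain loci into clusters under the gap rule.

    Per (chromosome, strand), loci sorted by start are chained while the gap
    to the previous locus is <= window; maximal chains of >= 2 form clusters.
    ``start_to_start=True`` switches the distance to start-to-start.
    """
    seen: dict[str, HairpinLocus] = {}
    for locus in loci:
        if locus.locus_id in seen:
            raise ClusterError(f"duplicate locus id {locus.locus_id}")
        seen[locus.locus_id] = locus

    groups: dict[tuple[str, str], list[HairpinLocus]] = {}
    for locus in loci:
        groups.setdefault((locus.chromosome, locus.strand), []).append(locus)

    clusters: list[tuple[str, ...]] = []
    singletons: list[str] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda l: (l.start, l.end, l.locus_id))
        chain: list[HairpinLocus] = []
        for locus in members:
            if chain:
                prev = chain[-1]
                dist = locus.start - prev.start if start_to_start else max(0, locus.start - prev.end)
                if dist <= window:
                    chain.append(locus)
                    continue
                _flush(chain, clusters, singletons)
            chain = [locus]
        _flush(chain, clusters, singletons)
    return ClusterSet(tuple(clusters), tuple(singletons))


def _flush(chain, clusters, singletons) -> None:
    if len(chain) >= 2:
        clusters.append(tuple(l.locus_id for l in chain))
    elif chain:
        singletons.append(chain[0].locus_id)


def cluster_enrichment(
    query_loci,
    all_loci,
    clusterset: ClusterSet,
    n_cohorts: int = DEFAULT_N_COHORTS,
    seed: int | None = None,
) -> EnrichmentResult:
    """Enrichment of query loci among clustered loci.

    Membership is evaluated against the full-set ClusterSet (clusters are not
    re-called on the subset).  Exact p = P(X >= k) under Hypergeometric(N, K,
    n); the Monte-Carlo cohorts draw n loci without replacement n_cohorts
    times and summarise the clustered fraction.
    """
    all_ids = [l.locus_id if isinstance(l, HairpinLocus) else l for l in all_loci]
    query_ids = [l.locus_id if isinstance(l, HairpinLocus) else l for l in query_loci]
    if not query_ids:
        raise ClusterError("query locus set is empty")
    missing = set(query_ids) - set(all_ids)
    if missing:
        raise ClusterError(f"query loci not in the full set: {sorted(missing)}")
    clustered = clusterset.clustered_loci
    N = len(all_ids)
    K = sum(1 for l in all_ids if l in clustered)
    n = len(query_ids)
    k = sum(1 for l in query_ids if l in clustered)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))

    rng = np.random.default_rng(seed)
    flags = np.fromiter((l in clustered for l in all_ids), dtype=bool, count=N)
    draws = np.empty(n_cohorts)
    for i in range(n_cohorts):
        idx = rng.choice(N, size=n, replace=False)
        draws[i] = flags[idx].mean()
    return EnrichmentResult(
        N=N,
        K=K,
        n=n,
        k=k,
        observed_frac=k / n,
        background_frac=K / N,
        p_hypergeom=min(p, 1.0),
        mc_mean=float(draws.mean()),
        mc_sd=float(draws.std(ddof=1)),
        n_cohorts=n_cohorts,
    )


def write_cluster_tables(clusterset: ClusterSet, loci: list[HairpinLocus], tsv_path, bed_path) -> None:
    """Export clusters as a TSV (cluster_id, members, span) and a BED file."""
    by_id = {l.locus_id: l for l in loci}
    rows = []
    bed_lines = []
    for i, members in enumerate(clusterset.clusters, start=1):
        locs = [by_id[m] for m in members]
        start = min(l.start for l in locs)
        end = max(l.end for l in locs)
        cid = f"cluster_{i:04d}"
        rows.append(
            "\t".join([cid, locs[0].chromosome, locs[0].strand, str(start), str(end), ",".join(members)])
        )
        bed_lines.append(
            "\t".join([locs[0].chromosome, str(start), str(end), cid, str(len(members)), locs[0].strand])
        )
    with open(tsv_path, "w") as fh:
        fh.write("cluster_id\tchromosome\tstrand\tstart\tend\tmembers\n")
        fh.write("\n".join(rows) + ("\n" if rows else ""))
    with open(bed_path, "w") as fh:
        fh.write("\n".join(bed_lines) + ("\n" if bed_lines else ""))
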