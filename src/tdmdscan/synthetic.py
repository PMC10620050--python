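"""Synthetic datasets with known ground truth emulating the tissue survey design.

The generator emits, from a config and a seed, everything the pipeline
consumes: a miRBase-style annotation (hairpins with 5p/3p matures, family
table), a species-by-library count table for 12 tissues x 2 genotypes
(*Zswim8*+/- "het" vs *Zswim8*-/- "ko") x 2 replicates with spike-ins, and
matched mRNA prediction/expression tables with implanted target repression —
plus a truth object sufficient to score every classifier output.

Count model: negative binomial with log-normal species abundances,
log-normal library depth multipliers, and a configurable dispersion
(default 0.05).  Knockout effects multiply the ko-library means by
2**effect for sensitive strands only; secondary (transcriptional) effects
multiply both strands of a hairpin; spike-in means are genotype-independent.
The default scale (1,000 hairpin loci = 2,000 mature species, 10,000
transcripts, 12 tissues) runs end-to-end in minutes on one CPU.

Everything here is synthetic stand-in data; no real sequences or published
per-miRNA measurements are reproduced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tdmdscan.annotations import (
    HairpinLocus,
    MatureSpecies,
    TargetPrediction,
    write_mirbase_gff,
    write_target_predictions,
)
from tdmdscan.clusters import ClusterSet
from tdmdscan.quantify import CountTable, LibraryMeta, isoform_species_id, library_id_for

#: the 12 embryonic tissues of the survey design
DEFAULT_TISSUES = (
    "forebrain",
    "hindbrain",
    "eye",
    "heart",
    "lung",
    "liver",
    "stomach",
    "kidney",
    "intestine",
    "skin",
    "muscle",
    "placenta",
)

_NT = np.array(list("ACGU"))


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults are the study conditions."""

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = 2

    # annotation geometry
    n_loci: int = 1000
    n_clusters: int = 100
    n_clustered: int = 460  # ~46% of loci in clusters, the genomic background rate
    include_polycistron: bool = True  # one Mirg-like 38-hairpin polycistron
    include_paralog_trio: bool = True  # three 6-hairpin clusters sharing one guide
    hairpin_length: int = 90
    mature_length: int = 22
    cluster_gap_max: int = 8000  # intra-cluster gaps <= this (< 10-kb window)
    intercluster_gap: int = 50_000

    # implanted effects
    n_sensitive: int = 60
    sensitive_tissue_range: tuple[int, int] = (4, 10)
    sensitive_effect_range: tuple[float, float] = (0.5, 2.5)
    frac_sensitive_passenger: float = 0.15
    n_sensitive_clustered: int | None = None  # force k of the sensitive loci clustered
    n_secondary: int = 20
    secondary_n_tissues: int = 3
    secondary_effect_range: tuple[float, float] = (0.5, 2.0)
    n_broad_weak: int = 5
    broad_effect: float = 0.35
    arm_switch_tissues: tuple[str, ...] = ("forebrain", "hindbrain", "eye")
    arm_switch_effect: float = 2.5
    isoform_plus1_effect: float = 2.0

    # count model
    depth: float = 3e6
    depth_sigma: float = 0.2
    abundance_sigma: float = 1.5
    tissue_sigma: float = 0.5
    #: per (locus, tissue) probability that the locus is essentially silent
    #: there (tissue-restricted expression, as in the survey's detection map)
    tissue_silent_prob: float = 0.3
    silent_scale: float = 0.002
    dispersion: float = 0.05
    n_spikeins: int = 10
    spikein_total_frac: float = 0.02

    # mRNA model
    n_transcripts: int = 10_000
    n_targets_per_family: int = 250
    n_target_families: int = 3
    target_delta: float = 0.2
    target_sigma: float = 0.15
    conserved_rate: float = 0.4
    tpm_mu_log: float = np.log(60.0)
    tpm_sigma: float = 1.0
    utr_mu_log: float = np.log(1000.0)
    utr_sigma: float = 0.7

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tissues"] = list(self.tissues)
        d["arm_switch_tissues"] = list(self.arm_switch_tissues)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset."""

    sensitive_effects: dict[str, dict[str, float]]  # species -> tissue -> log2 effect
    secondary_effects: dict[str, dict[str, float]]
    broad_weak: dict[str, float]  # species -> effect applied in every tissue
    arm_switch_species: str | None
    arm_switch_tissues: tuple[str, ...]
    isoform_switch_species: str | None  # the shift-0 species whose +1 isoform is sensitive
    cluster_layout: ClusterSet
    sensitive_loci: tuple[str, ...]
    target_deltas: dict[str, dict[str, float]]  # family -> tissue -> delta
    locus_expressed: dict[str, list[str]]  # locus -> tissues where it is expressed
    seed: int

    @property
    def sensitive_species(self) -> set[str]:
        return set(self.sensitive_effects) | set(self.broad_weak)

    def to_json(self) -> str:
        d = {
            "sensitive_effects": self.sensitive_effects,
            "secondary_effects": self.secondary_effects,
            "broad_weak": self.broad_weak,
            "arm_switch_species": self.arm_switch_species,
            "arm_switch_tissues": list(self.arm_switch_tissues),
            "isoform_switch_species": self.isoform_switch_species,
            "clusters": [list(c) for c in self.cluster_layout.clusters],
            "singletons": list(self.cluster_layout.singletons),
            "sensitive_loci": list(self.sensitive_loci),
            "target_deltas": self.target_deltas,
            "locus_expressed": {k: list(v) for k, v in self.locus_expressed.items()},
            "seed": self.seed,
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            sensitive_effects=d["sensitive_effects"],
            secondary_effects=d["secondary_effects"],
            broad_weak=d["broad_weak"],
            arm_switch_species=d["arm_switch_species"],
            arm_switch_tissues=tuple(d["arm_switch_tissues"]),
            isoform_switch_species=d["isoform_switch_species"],
            cluster_layout=ClusterSet(
                tuple(tuple(c) for c in d["clusters"]), tuple(d["singletons"])
            ),
            sensitive_loci=tuple(d["sensitive_loci"]),
            target_deltas=d["target_deltas"],
            locus_expressed={k: list(v) for k, v in d["locus_expressed"].items()},
            seed=d["seed"],
        )


def _random_seq(rng, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _cluster_sizes(rng, config: SyntheticConfig) -> list[int]:
    """Cluster sizes summing to n_clustered over n_clusters groups (each >= 2)."""
    special: list[int] = []
    if config.include_polycistron:
        special.append(38)
    if config.include_paralog_trio:
        special.extend([6, 6, 6])
    n_rest = config.n_clusters - len(special)
    remaining = config.n_clustered - sum(special)
    if n_rest < 0 or remaining < 2 * n_rest or (n_rest == 0 and remaining != 0):
        raise SyntheticError("infeasible cluster geometry: not enough clustered loci")
    sizes = [2] * n_rest
    for _ in range(remaining - 2 * n_rest):
        sizes[rng.integers(0, n_rest)] += 1
    return special + sizes


def simulate_annotation(
    config: SyntheticConfig, seed: int
) -> tuple[list[HairpinLocus], list[MatureSpecies], ClusterSet]:
    """Random hairpin annotation with a known cluster partition.

    Clusters are placed with intra-cluster gaps <= cluster_gap_max (within
    the 10-kb chaining window) and separated from each other and from
    singletons by intercluster_gap, so the true partition is recoverable by
    the cluster caller.  When enabled, a Mirg-like 38-hairpin polycistron and
    a trio of 6-hairpin paralogous clusters (two of which produce a
    sequence-identical guide, exercising the species-merge rule) are
    included.
    """
    rng = np.random.default_rng(seed)
    if config.n_clusters > 0:
        sizes = _cluster_sizes(rng, config)
    else:
        sizes = []
    n_singletons = config.n_loci - sum(sizes)
    if n_singletons < 0:
        raise SyntheticError("infeasible geometry: clustered loci exceed n_loci")

    chroms = [f"chr{i}" for i in range(1, 20)] + ["chrX"]
    loci: list[HairpinLocus] = []
    species_raw: list[dict] = []
    clusters: list[tuple[str, ...]] = []
    singles: list[str] = []

    paralog_guide_seq = _random_seq(rng, config.mature_length) if config.include_paralog_trio else None
    paralog_cluster_ids: list[int] = [1, 2] if config.include_paralog_trio else []
    # cluster indices of the paralog trio within `sizes` (after the polycistron)
    if config.include_paralog_trio:
        base = 1 if config.include_polycistron else 0
        paralog_cluster_ids = [base, base + 1, base + 2]

    locus_counter = 0
    chrom_cursor: dict[tuple[str, str], int] = {}

    def place(chrom: str, strand: str, length: int, gap: int) -> tuple[int, int]:
        key = (chrom, strand)
        start = chrom_cursor.get(key, 10_000) + gap
        chrom_cursor[key] = start + length
        return start, start + length

    def add_hairpin(chrom, strand, gap, shared_guide_seq=None, paralog_member_idx=None):
        nonlocal locus_counter
        locus_counter += 1
        lid = f"hp{locus_counter:05d}"
        L = config.hairpin_length
        ml = config.mature_length
        off5 = 4
        off3 = L - ml - 4
        seq = _random_seq(rng, L)
        if shared_guide_seq is not None:
            # identical guide (5p) across paralogous loci -> merged species
            seq = seq[:off5] + shared_guide_seq + seq[off5 + ml :]
        start, end = place(chrom, strand, L, gap)
        guide_arm = "5p" if rng.random() < 0.5 else "3p"
        if shared_guide_seq is not None:
            guide_arm = "5p"
        for arm, off in (("5p", off5), ("3p", off3)):
            if shared_guide_seq is not None and arm == "5p":
                name = "mir-shared-5p"
                fam = "fam-shared"
            else:
                name = f"mir-{locus_counter:05d}-{arm}"
                fam = f"fam-{locus_counter:05d}-{arm}"
            species_raw.append(
                {
                    "name": name,
                    "parent": lid,
                    "arm": arm,
                    "offset": off,
                    "sequence": seq[off : off + ml],
                    "role": "guide" if arm == guide_arm else "passenger",
                    "family": fam,
                }
            )
        loci.append(
            HairpinLocus(
                locus_id=lid,
                chromosome=chrom,
                strand=strand,
                start=start,
                end=end,
                sequence=seq,
                mature_ids=(),
                family_confident=True,
            )
        )
        return lid

    ci = 0
    for size in sizes:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        members = []
        is_paralog = ci in paralog_cluster_ids[:2] if config.include_paralog_trio else False
        for j in range(size):
            gap = (
                config.intercluster_gap
                if j == 0
                else int(rng.integers(200, config.cluster_gap_max))
            )
            shared = paralog_guide_seq if (is_paralog and j == 0) else None
            members.append(add_hairpin(chrom, strand, gap, shared_guide_seq=shared))
        clusters.append(tuple(members))
        ci += 1
    for _ in range(n_singletons):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        singles.append(add_hairpin(chrom, strand, config.intercluster_gap))

    # merge sequence-identical matures into species (multiple parents)
    by_seq: dict[tuple[str, str], dict] = {}
    for s in species_raw:
        key = (s["sequence"], s["arm"])
        if key in by_seq:
            by_seq[key]["parents"].append(s["parent"])
        else:
            by_seq[key] = {**s, "parents": [s["parent"]]}
    species = [
        MatureSpecies(
            species_id=s["name"],
            parent_locus_ids=tuple(sorted(set(s["parents"]))),
            arm=s["arm"],
            offset_in_hairpin=s["offset"],
            sequence=s["sequence"],
            annotated_role=s["role"],
            family_id=s["family"],
        )
        for s in by_seq.values()
    ]
    species.sort(key=lambda sp: sp.species_id)

    # attach mature ids to loci
    locus_matures: dict[str, list[str]] = {}
    for sp in species:
        for pid in sp.parent_locus_ids:
            locus_matures.setdefault(pid, []).append(sp.species_id)
    loci = [
        dataclasses.replace(l, mature_ids=tuple(sorted(locus_matures.get(l.locus_id, ()))))
        for l in loci
    ]
    return loci, species, ClusterSet(tuple(clusters), tuple(singles))


def _draw_truth(
    config: SyntheticConfig,
    species: list[MatureSpecies],
    layout: ClusterSet,
    rng,
    seed: int,
) -> SyntheticTruth:
    tissues = list(config.tissues)
    by_id = {sp.species_id: sp for sp in species}
    shift0 = [sp for sp in species if sp.isoform_shift == 0]
    guides = [sp.species_id for sp in shift0 if sp.annotated_role == "guide"]
    passengers = [sp.species_id for sp in shift0 if sp.annotated_role == "passenger"]
    clustered = layout.clustered_loci

    # tissue-restricted expression: each locus is silent in a random subset of
    # tissues (at least two tissues stay expressed per locus)
    all_loci = sorted({pid for sp in shift0 for pid in sp.parent_locus_ids})
    locus_expressed: dict[str, list[str]] = {}
    for lid in all_loci:
        on = rng.random(len(tissues)) >= config.tissue_silent_prob
        if on.sum() < 2:
            on[rng.choice(len(tissues), size=2, replace=False)] = True
        locus_expressed[lid] = [t for t, flag in zip(tissues, on) if flag]

    def expressed_tissues_of(sp_id: str) -> list[str]:
        out: set[str] = set()
        for pid in by_id[sp_id].parent_locus_ids:
            out.update(locus_expressed[pid])
        return [t for t in tissues if t in out]

    def _capped(requested: int, pool_size: int, what: str) -> int:
        if requested > pool_size:
            import warnings

            warnings.warn(f"{what}: requested {requested} but only {pool_size} available")
            return pool_size
        return requested

    n_pass = int(round(config.n_sensitive * config.frac_sensitive_passenger))
    n_guides = config.n_sensitive - n_pass
    n_guides = _capped(n_guides, max(len(guides) - 10, 1), "sensitive guide strands")
    n_pass = _capped(n_pass, len(passengers), "sensitive passenger strands")

    if config.n_sensitive_clustered is not None:
        # force an exact clustered/unclustered split of sensitive loci
        cl_pool = sorted({s for s in guides if any(p in clustered for p in by_id[s].parent_locus_ids)})
        un_pool = sorted({s for s in guides if not any(p in clustered for p in by_id[s].parent_locus_ids)})
        k = config.n_sensitive_clustered
        chosen = list(rng.choice(cl_pool, size=k, replace=False)) + list(
            rng.choice(un_pool, size=config.n_sensitive - k, replace=False)
        )
    else:
        chosen = list(rng.choice(sorted(guides), size=n_guides, replace=False))
        chosen += list(rng.choice(sorted(passengers), size=n_pass, replace=False))

    lo_t, hi_t = config.sensitive_tissue_range
    lo_e, hi_e = config.sensitive_effect_range
    sensitive: dict[str, dict[str, float]] = {}
    for sp in chosen:
        n_t = int(rng.integers(lo_t, hi_t + 1))
        avail = expressed_tissues_of(sp)
        picked = rng.choice(avail, size=min(n_t, len(avail)), replace=False)
        sensitive[str(sp)] = {str(t): float(rng.uniform(lo_e, hi_e)) for t in sorted(picked)}

    # arm-switch case: pick one sensitive guide, give it strong effects in the
    # designated tissues; counts assign it the lower-abundance arm
    arm_switch_sp = None
    if config.arm_switch_tissues:
        arm_switch_sp = sorted(sensitive)[0]
        sensitive[arm_switch_sp] = {
            t: config.arm_switch_effect for t in config.arm_switch_tissues
        }
        for pid in by_id[arm_switch_sp].parent_locus_ids:
            locus_expressed[pid] = list(tissues)

    taken = set(sensitive)
    taken_loci = {pid for s in taken for pid in by_id[s].parent_locus_ids}
    hairpin_pool = sorted(
        {
            by_id[s].parent_locus_ids[0]
            for s in guides
            if s not in taken
            and len(by_id[s].parent_locus_ids) == 1
            and by_id[s].parent_locus_ids[0] not in taken_loci
        }
    )
    n_sec = _capped(config.n_secondary, len(hairpin_pool), "secondary loci")
    sec_loci = list(rng.choice(hairpin_pool, size=n_sec, replace=False))
    lo_s, hi_s = config.secondary_effect_range
    secondary: dict[str, dict[str, float]] = {}
    locus_species: dict[str, list[str]] = {}
    for sp in shift0:
        for pid in sp.parent_locus_ids:
            locus_species.setdefault(pid, []).append(sp.species_id)
    for lid in sec_loci:
        avail = locus_expressed[lid]
        picked = rng.choice(avail, size=min(config.secondary_n_tissues, len(avail)), replace=False)
        eff = {str(t): float(rng.uniform(lo_s, hi_s)) for t in sorted(picked)}
        for sid in locus_species[lid]:
            secondary[sid] = dict(eff)
        taken.update(locus_species[lid])

    broad_pool = sorted(s for s in guides if s not in taken)
    n_broad = _capped(config.n_broad_weak, len(broad_pool), "broad-weak strands")
    broad = {
        str(s): config.broad_effect
        for s in rng.choice(broad_pool, size=n_broad, replace=False)
    }
    taken.update(broad)
    for s in broad:  # broad-weak species must be assessable across all tissues
        for pid in by_id[s].parent_locus_ids:
            locus_expressed[pid] = list(tissues)

    iso_sp = None
    iso_pool = sorted(
        s for s in guides
        if s not in taken and len(by_id[s].parent_locus_ids) == 1 and by_id[s].arm == "3p"
    )
    if iso_pool:
        iso_sp = iso_pool[0]
        locus_expressed[by_id[iso_sp].parent_locus_ids[0]] = list(tissues)

    sensitive_loci = sorted(
        {
            pid
            for s in (set(sensitive) | set(broad))
            for pid in by_id[s].parent_locus_ids
        }
    )

    # implant target repression for the families of the strongest sensitive species
    strength = {
        s: sum(e.values()) for s, e in sensitive.items()
    }
    top_species = sorted(strength, key=lambda s: (-strength[s], s))[: config.n_target_families]
    deltas: dict[str, dict[str, float]] = {}
    for s in top_species:
        fam = by_id[s].family_id
        deltas[fam] = {t: config.target_delta for t in sensitive[s]}

    return SyntheticTruth(
        sensitive_effects=sensitive,
        secondary_effects=secondary,
        broad_weak=broad,
        arm_switch_species=arm_switch_sp,
        arm_switch_tissues=tuple(config.arm_switch_tissues),
        isoform_switch_species=iso_sp,
        cluster_layout=layout,
        sensitive_loci=tuple(sensitive_loci),
        target_deltas=deltas,
        locus_expressed=locus_expressed,
        seed=seed,
    )


#: 5' isoform fractions of the isoform-case arm (shift -> fraction of arm total)
ISOFORM_FRACTIONS = {-2: 0.05, -1: 0.10, 0: 0.50, 1: 0.25, 2: 0.05}


def simulate_counts(
    loci: list[HairpinLocus],
    species: list[MatureSpecies],
    truth: SyntheticTruth,
    config: SyntheticConfig,
    seed: int,
) -> tuple[CountTable, list[MatureSpecies]]:
    """NB counts for all tissues/libraries, plus the isoform species emitted.

    Returns the count table (including spike-in rows and 5' isoform rows for
    the isoform-switch case) and the full species list with isoform species
    appended.
    """
    rng = np.random.default_rng(seed)
    tissues = list(config.tissues)
    shift0 = sorted((sp for sp in species if sp.isoform_shift == 0), key=lambda s: s.species_id)
    by_id = {sp.species_id: sp for sp in shift0}

    # expand the isoform case into extra species rows
    iso_species: list[MatureSpecies] = []
    iso_fraction: dict[str, float] = {}
    if truth.isoform_switch_species is not None:
        base = by_id[truth.isoform_switch_species]
        locus = next(l for l in loci if l.locus_id == base.parent_locus_ids[0])
        from tdmdscan.quantify import enumerate_5p_isoforms

        iso_species = enumerate_5p_isoforms(locus, base)
        for sp in iso_species:
            iso_fraction[sp.species_id] = ISOFORM_FRACTIONS[sp.isoform_shift]
        iso_fraction[base.species_id] = ISOFORM_FRACTIONS[0]

    all_species = shift0 + sorted(iso_species, key=lambda s: s.species_id)
    ids = [sp.species_id for sp in all_species]
    n = len(ids)

    base_w = np.exp(rng.normal(0.0, config.abundance_sigma, size=n))
    # isoform rows share the annotated arm's abundance, split by fraction
    for i, sp in enumerate(all_species):
        if sp.species_id in iso_fraction and sp.isoform_shift != 0:
            base_idx = ids.index(isoform_species_id(sp.species_id.split(".iso")[0], 0))
            base_w[i] = base_w[base_idx] * iso_fraction[sp.species_id] / ISOFORM_FRACTIONS[0]
    # make the arm-switch case passenger-heavy: sensitive strand at 1/3 of cognate
    if truth.arm_switch_species is not None:
        s_idx = ids.index(truth.arm_switch_species)
        for cog in (
            sp.species_id
            for sp in shift0
            if truth.arm_switch_species != sp.species_id
            and set(sp.parent_locus_ids) & set(by_id[truth.arm_switch_species].parent_locus_ids)
        ):
            base_w[s_idx] = base_w[ids.index(cog)] / 3.0

    # tissue-to-tissue expression variation acts at the locus level (the two
    # arms and 5' isoforms are co-transcribed), keeping arm ratios stable;
    # loci marked silent in a tissue are scaled to near zero there
    locus_ids = sorted({l.locus_id for l in loci})
    locus_noise = {
        lid: np.exp(rng.normal(0.0, config.tissue_sigma, size=len(tissues)))
        for lid in locus_ids
    }
    for lid in locus_ids:
        on_tissues = set(truth.locus_expressed.get(lid, tissues))
        off = np.array([t not in on_tissues for t in tissues])
        locus_noise[lid][off] *= config.silent_scale
    tissue_w = np.empty((n, len(tissues)))
    for i, sp in enumerate(all_species):
        tissue_w[i] = base_w[i] * locus_noise[sp.parent_locus_ids[0]]

    effect = np.zeros((n, len(tissues)))
    t_index = {t: j for j, t in enumerate(tissues)}

    def add_effect(sp_id, eff_by_tissue):
        if sp_id not in ids:
            return
        i = ids.index(sp_id)
        for t, e in eff_by_tissue.items():
            effect[i, t_index[t]] += e

    for sp_id, eff in truth.sensitive_effects.items():
        add_effect(sp_id, eff)
    for sp_id, eff in truth.secondary_effects.items():
        add_effect(sp_id, eff)
    for sp_id, e in truth.broad_weak.items():
        add_effect(sp_id, {t: e for t in tissues})
    if truth.isoform_switch_species is not None:
        plus1 = isoform_species_id(truth.isoform_switch_species, 1)
        add_effect(plus1, {t: config.isoform_plus1_effect for t in tissues})

    spike_ids = [f"spikein_{i:02d}" for i in range(1, config.n_spikeins + 1)]
    spike_w = np.full(config.n_spikeins, config.spikein_total_frac / max(config.n_spikeins, 1))

    libraries: dict[str, LibraryMeta] = {}
    columns: dict[str, np.ndarray] = {}
    inv_disp = 1.0 / config.dispersion
    for tj, tissue in enumerate(tissues):
        w = tissue_w[:, tj]
        rel = w / w.sum()
        for genotype in ("het", "ko"):
            mult = np.exp2(effect[:, tj]) if genotype == "ko" else 1.0
            rel_g = rel * mult
            for rep in range(1, config.n_replicates + 1):
                lid = library_id_for(tissue, genotype, rep)
                libraries[lid] = LibraryMeta(lid, tissue, genotype, rep)
                depth = config.depth * np.exp(rng.normal(0.0, config.depth_sigma))
                mu = np.concatenate([rel_g * depth, spike_w * depth])
                counts = rng.negative_binomial(inv_disp, inv_disp / (inv_disp + mu))
                columns[lid] = counts.astype(np.int64)

    df = pd.DataFrame(columns, index=ids + spike_ids)
    table = CountTable(df, libraries, frozenset(spike_ids))
    return table, all_species


def simulate_mrna(
    species: list[MatureSpecies],
    truth: SyntheticTruth,
    config: SyntheticConfig,
    seed: int,
) -> tuple[list[TargetPrediction], dict[str, pd.DataFrame]]:
    """Predictions and per-tissue expression/fold-change tables.

    Transcripts get log-normal 3'-UTR lengths and TPMs.  For each family in
    ``truth.target_deltas`` a fixed target set is drawn; target fold-changes
    in tissues with implanted delta are shifted by -delta * w(score), where
    w = |score| / median(|score| over targets), capped at 2 — a monotone
    weighting so stronger-scoring targets are repressed more and the median
    target shift equals delta.  Conservation flags are assigned to the
    strongest-scoring fraction of each family's targets.
    """
    rng = np.random.default_rng(seed)
    tids = [f"tx{i:06d}" for i in range(1, config.n_transcripts + 1)]
    utr = np.maximum(
        50, np.exp(rng.normal(config.utr_mu_log, config.utr_sigma, size=config.n_transcripts))
    ).astype(int)

    predictions: list[TargetPrediction] = []
    target_weight: dict[str, dict[str, float]] = {}  # family -> transcript -> w
    families = sorted(truth.target_deltas)
    for fam in families:
        idx = rng.choice(config.n_transcripts, size=config.n_targets_per_family, replace=False)
        scores = -np.abs(rng.normal(0.35, 0.15, size=idx.size))
        order = np.argsort(scores)  # most negative first
        n_cons = int(round(config.conserved_rate * idx.size))
        conserved_pos = set(order[:n_cons])
        med = np.median(np.abs(scores))
        weights = np.minimum(np.abs(scores) / med, 2.0)
        target_weight[fam] = {}
        target_set = set()
        for j, (i, sc) in enumerate(zip(idx, scores)):
            predictions.append(
                TargetPrediction(
                    transcript_id=tids[i],
                    family_id=fam,
                    has_site=True,
                    conserved=j in conserved_pos,
                    context_score=float(sc),
                    utr_length=int(utr[i]),
                )
            )
            target_weight[fam][tids[i]] = float(weights[j])
            target_set.add(i)
        for i in range(config.n_transcripts):
            if i not in target_set:
                predictions.append(
                    TargetPrediction(
                        transcript_id=tids[i],
                        family_id=fam,
                        has_site=False,
                        conserved=False,
                        context_score=0.0,
                        utr_length=int(utr[i]),
                    )
                )

    expression: dict[str, pd.DataFrame] = {}
    n_lib = 2 * config.n_replicates
    for tissue in config.tissues:
        tpm_base = np.exp(rng.normal(config.tpm_mu_log, config.tpm_sigma, size=config.n_transcripts))
        tpm = tpm_base[:, None] * np.exp(rng.normal(0.0, 0.05, size=(config.n_transcripts, n_lib)))
        lfc = rng.normal(0.0, config.target_sigma, size=config.n_transcripts)
        for fam in families:
            delta = truth.target_deltas[fam].get(tissue)
            if delta is None:
                continue
            for tid, w in target_weight[fam].items():
                lfc[int(tid[2:]) - 1] -= delta * w
        cols = {
            f"tpm_{g}_rep{r}": tpm[:, i]
            for i, (g, r) in enumerate(
                (g, r) for g in ("het", "ko") for r in range(1, config.n_replicates + 1)
            )
        }
        df = pd.DataFrame({"transcript_id": tids, "utr_length": utr, **cols, "log2fc": lfc})
        expression[tissue] = df
    return predictions, expression


def simulate_dataset(config: SyntheticConfig, seed: int, outdir) -> SyntheticTruth:
    """Generate a complete dataset on disk; returns the truth (also written).

    Files: annotation.gff3, hairpins.fa, families.tsv, counts.tsv,
    spikeins.txt, predictions.tsv, expression.<tissue>.tsv, truth.json,
    config.json.  Deterministic: identical (config, seed) give byte-identical
    outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    loci, species, layout = simulate_annotation(config, int(rng.integers(2**31)))
    truth = _draw_truth(config, species, layout, rng, seed)
    table, all_species = simulate_counts(loci, species, truth, config, int(rng.integers(2**31)))
    predictions, expression = simulate_mrna(species, truth, config, int(rng.integers(2**31)))

    write_mirbase_gff(
        loci, species, outdir / "annotation.gff3", outdir / "hairpins.fa", outdir / "families.tsv"
    )
    table.write_tsv(outdir / "counts.tsv")
    spike_rng = np.random.default_rng(int(rng.integers(2**31)))
    with open(outdir / "spikeins.txt", "w") as fh:
        for sid in sorted(table.spikein_ids):
            fh.write(f"{sid}\t{_random_seq(spike_rng, 22)}\n")
    write_target_predictions(predictions, outdir / "predictions.tsv")
    for tissue, df in expression.items():
        df.to_csv(outdir / f"expression.{tissue}.tsv", sep="\t", index=False, float_format="%.10g")
    (outdir / "truth.json").write_text(truth.to_json())
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))
    return truth
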