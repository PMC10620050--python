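"""Read counting by 19-nt 5' prefix matching, expression filters, and CPM.

Small-RNA reads are assigned to mature species by exact matching of their
first *k* (default 19) nucleotides against a dictionary built from the mature
sequences, the scheme used for the tissue survey this package reimplements.
Counting is therefore 5'-anchored: 5'-shifted isoforms are separate species
while 3' heterogeneity is invisible.  Species whose k-prefixes collide are
pooled into a single species (mirroring the pooling of sequence-identical
matures) and reported.

Normalisation is counts-per-million over miRNA-matching reads after removing
spike-in counts.  Two CPM modes are provided: per-library CPM (used for the
5-CPM detection threshold) and tissue/genotype-level CPM in which replicate
counts are averaged before normalising to the summed mean counts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tdmdscan.annotations import HairpinLocus, MatureSpecies

DEFAULT_PREFIX_K = 19
DEFAULT_MIN_COUNT = 5
DEFAULT_DETECTION_CPM = 5.0

_VALID_READ = re.compile(r"^[ACGUT]+$")


class QuantifyError(ValueError):
    """Raised for invalid counting inputs."""


@dataclass(frozen=True)
class LibraryMeta:
    """Identity of one sequencing library within the 2-genotype design."""

    library_id: str
    tissue: str
    genotype: str  # 'het' or 'ko'
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in ("het", "ko"):
            raise QuantifyError(f"library {self.library_id}: genotype must be 'het' or 'ko'")
        if self.replicate < 1:
            raise QuantifyError(f"library {self.library_id}: replicate must be >= 1")


def library_id_for(tissue: str, genotype: str, replicate: int) -> str:
    return f"{tissue}.{genotype}.rep{replicate}"


def parse_library_id(library_id: str) -> LibraryMeta:
    m = re.match(r"^(.+)\.(het|ko)\.rep(\d+)$", library_id)
    if not m:
        raise QuantifyError(f"library id {library_id!r} not in '<tissue>.<genotype>.rep<i>' form")
    return LibraryMeta(library_id, m.group(1), m.group(2), int(m.group(3)))


@dataclass
class CountTable:
    """Species-by-library integer counts with library metadata and spike-in flags."""

    counts: pd.DataFrame  # rows: species_id, columns: library_id, integer >= 0
    libraries: dict[str, LibraryMeta]
    spikein_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and ((vals < 0).any() or not np.issubdtype(vals.dtype, np.integer)):
            raise QuantifyError("counts must be non-negative integers")
        unknown = self.spikein_ids - set(self.counts.index)
        if unknown:
            raise QuantifyError(f"spike-in ids absent from count table: {sorted(unknown)}")
        missing_meta = set(self.counts.columns) - set(self.libraries)
        if missing_meta:
            raise QuantifyError(f"libraries without metadata: {sorted(missing_meta)}")

    @property
    def tissues(self) -> list[str]:
        return sorted({m.tissue for m in self.libraries.values()})

    def tissue_libraries(self, tissue: str, genotype: str | None = None) -> list[str]:
        libs = [
            lid
            for lid, m in self.libraries.items()
            if m.tissue == tissue and (genotype is None or m.genotype == genotype)
        ]
        if not libs:
            raise QuantifyError(f"no libraries for tissue {tissue!r}")
        return sorted(libs, key=lambda l: (self.libraries[l].genotype, self.libraries[l].replicate))

    def mirna_index(self) -> pd.Index:
        """Row ids excluding spike-ins."""
        return self.counts.index[~self.counts.index.isin(self.spikein_ids)]

    def subset(self, tissue: str) -> "CountTable":
        libs = self.tissue_libraries(tissue)
        return CountTable(
            self.counts[libs].copy(),
            {l: self.libraries[l] for l in libs},
            self.spikein_ids,
        )

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "spikein", out.index.isin(self.spikein_ids).astype(int))
        out.to_csv(path, sep="\t", index_label="species_id")

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="species_id")
        spike = frozenset(df.index[df["spikein"] == 1])
        df = df.drop(columns=["spikein"]).astype(np.int64)
        libs = {c: parse_library_id(c) for c in df.columns}
        return cls(df, libs, spike)


@dataclass
class PrefixIndex:
    """k-prefix -> species dictionary with a pooled-collision audit trail.

    ``collisions`` maps each pooled species id to the ids it absorbed.
    """

    k: int
    prefix_to_species: dict[str, str]
    collisions: dict[str, tuple[str, ...]] = field(default_factory=dict)
    species_ids: tuple[str, ...] = ()

    def assign(self, read: str) -> str | None:
        if len(read) < self.k:
            return None
        return self.prefix_to_species.get(read[: self.k].upper().replace("T", "U"))


def build_prefix_index(matures: list[MatureSpecies] | list[tuple[str, str]], k: int = DEFAULT_PREFIX_K) -> PrefixIndex:
    """Build the k-prefix dictionary over mature species (and/or spike-ins).

    Accepts MatureSpecies or plain ``(species_id, sequence)`` pairs.  Species
    sharing a k-prefix are pooled into a species named by joining their ids
    with '&', and recorded in the collision report.
    """
    entries: list[tuple[str, str]] = []
    for m in matures:
        if isinstance(m, MatureSpecies):
            entries.append((m.species_id, m.sequence))
        else:
            entries.append((m[0], m[1]))
    by_prefix: dict[str, list[str]] = {}
    for sid, seq in entries:
        if len(seq) < k:
            raise QuantifyError(f"species {sid}: sequence shorter than k={k}")
        by_prefix.setdefault(seq[:k], []).append(sid)
    prefix_to_species: dict[str, str] = {}
    collisions: dict[str, tuple[str, ...]] = {}
    species_ids: set[str] = set()
    for prefix, sids in by_prefix.items():
        sids = sorted(set(sids))
        if len(sids) == 1:
            target = sids[0]
        else:
            target = "&".join(sids)
            collisions[target] = tuple(sids)
        prefix_to_species[prefix] = target
        species_ids.add(target)
    return PrefixIndex(k, prefix_to_species, collisions, tuple(sorted(species_ids)))


def count_reads(reads, index: PrefixIndex) -> tuple[pd.Series, int]:
    """Count reads into species by k-prefix; returns (counts, n_unassigned).

    Every read increments exactly one species or the unassigned tally, so
    assigned + unassigned equals the number of input reads.  Reads shorter
    than k or containing non-ACGU(T) characters are unassigned (the latter
    with a warning).
    """
    tallies: dict[str, int] = dict.fromkeys(index.species_ids, 0)
    unassigned = 0
    bad_chars = 0
    for read in reads:
        read = str(read).upper()
        if not _VALID_READ.match(read):
            bad_chars += 1
            unassigned += 1
            continue
        sid = index.assign(read)
        if sid is None:
            unassigned += 1
        else:
            tallies[sid] += 1
    if bad_chars:
        warnings.warn(f"{bad_chars} reads contained non-ACGU(T) characters; counted unassigned")
    return pd.Series(tallies, dtype=np.int64).sort_index(), unassigned


def isoform_species_id(species_id: str, shift: int) -> str:
    return species_id if shift == 0 else f"{species_id}.iso{shift:+d}"


def enumerate_5p_isoforms(
    hairpin: HairpinLocus,
    mature: MatureSpecies,
    shifts: tuple[int, ...] = (-2, -1, 1, 2),
) -> list[MatureSpecies]:
    """Enumerate templated 5'-shifted isoforms of an annotated mature.

    A +s extension starts ``s`` nt earlier in the hairpin; a -s truncation
    starts ``s`` nt later.  Sequences are templated from the hairpin and kept
    at the annotated mature length (counting is 5'-anchored, so only the new
    start matters).  Extensions running past the hairpin 5' end are omitted
    with a warning.
    """
    if mature.isoform_shift != 0:
        raise QuantifyError("isoforms are enumerated from the annotated (shift-0) species")
    out: list[MatureSpecies] = []
    length = len(mature.sequence)
    for s in shifts:
        if s == 0:
            continue
        start = mature.offset_in_hairpin - s
        if start < 0:
            warnings.warn(
                f"{mature.species_id}: +{s} extension runs past hairpin 5' end; omitted"
            )
            continue
        if start + length > len(hairpin.sequence):
            warnings.warn(
                f"{mature.species_id}: {s:+d} isoform runs past hairpin 3' end; omitted"
            )
            continue
        seq = hairpin.sequence[start : start + length]
        out.append(
            MatureSpecies(
                species_id=isoform_species_id(mature.species_id, s),
                parent_locus_ids=(hairpin.locus_id,),
                arm=mature.arm,
                offset_in_hairpin=start,
                sequence=seq,
                annotated_role=mature.annotated_role,
                family_id=mature.family_id,
                isoform_shift=s,
            )
        )
    return out


def filter_expressed(table: CountTable, tissue: str, min_count: int = DEFAULT_MIN_COUNT) -> set[str]:
    """Species with >= min_count reads in every library of the tissue (spike-ins excluded)."""
    libs = table.tissue_libraries(tissue)
    sub = table.counts.loc[table.mirna_index(), libs]
    keep = (sub >= min_count).all(axis=1)
    return set(sub.index[keep])


def normalize_cpm(table: CountTable) -> pd.DataFrame:
    """Per-library CPM over non-spike-in miRNA counts.

    Spike-in rows are retained in the output (scaled by the same miRNA
    denominator, for reference) but never contribute to it.
    """
    mirna = table.mirna_index()
    totals = table.counts.loc[mirna].sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise QuantifyError(f"zero miRNA-matching total in libraries {bad}")
    return table.counts.div(totals, axis=1) * 1e6


def genotype_mean_cpm(table: CountTable, tissue: str) -> pd.DataFrame:
    """Tissue-level CPM per genotype: mean replicate counts, then normalise.

    Returns a DataFrame with a two-level column index
    (genotype, {'cpm','se'}).  The SE is the standard error of the mean of the
    per-replicate CPMs (sd/sqrt(n_replicates)).
    """
    out: dict[tuple[str, str], pd.Series] = {}
    mirna = table.mirna_index()
    for genotype in ("het", "ko"):
        libs = table.tissue_libraries(tissue, genotype)
        mean_counts = table.counts[libs].mean(axis=1)
        denom = mean_counts.loc[mirna].sum()
        if denom <= 0:
            raise QuantifyError(f"zero mean miRNA total for {tissue}/{genotype}")
        out[(genotype, "cpm")] = mean_counts / denom * 1e6
        # replicate-level CPM spread for error bars
        rep_totals = table.counts.loc[mirna, libs].sum(axis=0).astype(float)
        rep_cpm = table.counts[libs].div(rep_totals, axis=1) * 1e6
        out[(genotype, "se")] = rep_cpm.std(axis=1, ddof=1) / np.sqrt(len(libs))
    return pd.DataFrame(out)


def detected_species(
    table: CountTable, tissue: str, detection_cpm: float = DEFAULT_DETECTION_CPM
) -> set[str]:
    """Species above the display detection threshold: > detection_cpm in each library."""
    libs = table.tissue_libraries(tissue)
    cpm = normalize_cpm(table)[libs].loc[table.mirna_index()]
    keep = (cpm > detection_cpm).all(axis=1)
    return set(cpm.index[keep])
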