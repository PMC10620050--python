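import numpy as np
import pandas as pd
import pytest

from tdmdscan.annotations import HairpinLocus, MatureSpecies
from tdmdscan.quantify import CountTable, LibraryMeta, library_id_for


def make_hairpin(locus_id="hpA", chrom="chr1", strand="+", start=1000, seq=None, length=90):
    if seq is None:
        rng = np.random.default_rng(abs(hash(locus_id)) % 2**31)
        seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])
    return HairpinLocus(
        locus_id=locus_id,
        chromosome=chrom,
        strand=strand,
        start=start,
        end=start + len(seq),
        sequence=seq,
        family_confident=True,
    )


def make_mature(hairpin, species_id, arm="5p", offset=4, length=22, role="guide", family=None, shift=0):
    return MatureSpecies(
        species_id=species_id,
        parent_locus_ids=(hairpin.locus_id,),
        arm=arm,
        offset_in_hairpin=offset,
        sequence=hairpin.sequence[offset : offset + length],
        annotated_role=role,
        family_id=family or f"fam-{species_id}",
        isoform_shift=shift,
    )


def make_count_table(rows: dict, tissue="liver", spikeins=()):
    """rows: species_id -> (het1, het2, ko1, ko2) counts."""
    libs = {}
    cols = {}
    for genotype in ("het", "ko"):
        for rep in (1, 2):
            lid = library_id_for(tissue, genotype, rep)
            libs[lid] = LibraryMeta(lid, tissue, genotype, rep)
    lib_ids = sorted(libs, key=lambda l: (libs[l].genotype, libs[l].replicate))
    for j, lid in enumerate(lib_ids):
        cols[lid] = [rows[sp][j] for sp in rows]
    df = pd.DataFrame(cols, index=list(rows), dtype=np.int64)
    return CountTable(df, libs, frozenset(spikeins))


@pytest.fixture
def hairpin():
    return make_hairpin()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
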