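"""miRNA genomic annotation: hairpin loci, mature strands, and target predictions.

Hairpin loci come from a miRBase-style GFF3 (``miRNA_primary_transcript``
features with ``miRNA`` children linked by ``Derives_from``) together with a
hairpin FASTA; family membership and annotation confidence come from a
TargetScan-style family table.  Internally all genomic intervals are 0-based
half-open; the GFF3 boundary (1-based inclusive) is converted on read/write.

Mature strands with identical sequence arising from paralogous loci are merged
into a single counting species with several parent loci, because 5'-anchored
prefix counting cannot distinguish them; locus-level analyses expand back
through ``parent_locus_ids``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: TargetScan family-confidence categories that qualify a locus as confidently
#: annotated (matched case-insensitively).
CONFIDENT_FAMILY_CATEGORIES = frozenset(
    {
        "broadly conserved",
        "conserved",
        "poorly conserved but confidently annotated",
    }
)


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation inputs."""


@dataclass(frozen=True)
class HairpinLocus:
    """A miRNA hairpin (primary-transcript) locus.

    ``start``/``end`` are 0-based half-open genomic coordinates.  ``sequence``
    is the hairpin RNA sequence (A/C/G/U), 5'->3' on the annotated strand.
    """

    locus_id: str
    chromosome: str
    strand: str  # '+' or '-'
    start: int
    end: int
    sequence: str
    mature_ids: tuple[str, ...] = ()
    family_confident: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"locus {self.locus_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise AnnotationError(f"locus {self.locus_id}: empty or inverted interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MatureSpecies:
    """A mature miRNA counting species (possibly pooled across paralogous loci).

    ``offset_in_hairpin`` locates the 5' end of the mature within the hairpin
    sequence of each parent (all parents must place it identically, which the
    merge rule guarantees for sequence-identical matures).  ``isoform_shift``
    is 0 for the annotated isoform; -1/-2 are 1- and 2-nt 5' truncations and
    +1/+2 are templated 5' extensions.
    """

    species_id: str
    parent_locus_ids: tuple[str, ...]
    arm: str  # '5p' or '3p'
    offset_in_hairpin: int
    sequence: str
    annotated_role: str  # 'guide' or 'passenger'
    family_id: str
    isoform_shift: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise AnnotationError(f"species {self.species_id}: arm must be '5p' or '3p'")
        if self.annotated_role not in ("guide", "passenger"):
            raise AnnotationError(f"species {self.species_id}: role must be 'guide' or 'passenger'")
        if self.isoform_shift not in (-2, -1, 0, 1, 2):
            raise AnnotationError(f"species {self.species_id}: isoform_shift must be in -2..+2")
        if not self.parent_locus_ids:
            raise AnnotationError(f"species {self.species_id}: needs at least one parent locus")
        if self.offset_in_hairpin < 0:
            raise AnnotationError(f"species {self.species_id}: negative hairpin offset")


@dataclass(frozen=True)
class TargetPrediction:
    """One transcript-family target prediction.

    ``context_score`` is a cumulative weighted context++ score (more negative
    means stronger predicted repression); ``utr_length`` is the annotated
    3'-UTR length in nucleotides.
    """

    transcript_id: str
    family_id: str
    has_site: bool
    conserved: bool
    context_score: float
    utr_length: int

    def __post_init__(self) -> None:
        if self.conserved and not self.has_site:
            raise AnnotationError(
                f"prediction {self.transcript_id}/{self.family_id}: conserved implies has_site"
            )
        if self.utr_length <= 0:
            raise AnnotationError(
                f"prediction {self.transcript_id}/{self.family_id}: utr_length must be positive"
            )


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def load_family_table(family_table_path) -> dict[str, tuple[str, str]]:
    """Read a TargetScan-style family table.

    Expects tab-separated columns ``family_id``, ``species_id``,
    ``confidence`` (header row required).  Returns a mapping
    species_id -> (family_id, confidence category).
    """
    df = pd.read_csv(family_table_path, sep="\t", dtype=str)
    required = {"family_id", "species_id", "confidence"}
    if not required.issubset(df.columns):
        raise AnnotationError(
            f"family table missing columns {sorted(required - set(df.columns))}"
        )
    return {
        row.species_id: (row.family_id, row.confidence)
        for row in df.itertuples(index=False)
    }


def load_mirbase_gff(
    gff3_path,
    hairpin_fasta_path,
    family_table_path=None,
) -> tuple[list[HairpinLocus], list[MatureSpecies]]:
    """Load hairpin loci and mature species from miRBase-dialect annotation.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Mature features must carry a ``Derives_from`` attribute naming their
    hairpin; their sequence is located within the hairpin sequence to derive
    the hairpin offset.  Matures with identical sequence across loci are merged
    into one counting species with multiple parents.  ``family_confident`` is
    set from family-table membership in the confident categories; species
    missing from the table get ``family_id='NA'`` with a warning.
    """
    hairpin_seqs = {
        rec.id: _rna(str(rec.seq)) for rec in SeqIO.parse(str(hairpin_fasta_path), "fasta")
    }
    families = load_family_table(family_table_path) if family_table_path else {}

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    def attr1(feat, key, default=None):
        vals = feat.attributes.get(key)
        return vals[0] if vals else default

    primaries: dict[str, dict] = {}
    matures_raw: list[dict] = []
    for feat in db.features_of_type("miRNA_primary_transcript"):
        fid = attr1(feat, "ID") or attr1(feat, "Name")
        primaries[fid] = {
            "locus_id": fid,
            "chromosome": feat.seqid,
            "strand": feat.strand,
            "start": feat.start - 1,  # GFF3 is 1-based inclusive
            "end": feat.end,
        }
    for feat in db.features_of_type("miRNA"):
        fid = attr1(feat, "ID") or attr1(feat, "Name")
        parent = attr1(feat, "Derives_from")
        if parent is None:
            raise AnnotationError(f"mature feature {fid} lacks Derives_from")
        matures_raw.append(
            {
                "id": fid,
                "name": attr1(feat, "Name", fid),
                "parent": parent,
                "chromosome": feat.seqid,
                "strand": feat.strand,
                "start": feat.start - 1,
                "end": feat.end,
                "arm": attr1(feat, "arm"),
                "role": attr1(feat, "role", "guide"),
            }
        )

    for m in matures_raw:
        if m["parent"] not in primaries:
            raise AnnotationError(
                f"mature {m['id']}: Derives_from names unknown primary transcript {m['parent']!r}"
            )

    # Derive per-locus mature placements, then merge sequence-identical matures.
    placements: list[dict] = []
    for m in matures_raw:
        prim = primaries[m["parent"]]
        hp_seq = hairpin_seqs.get(m["parent"])
        if hp_seq is None:
            raise AnnotationError(f"hairpin sequence for {m['parent']} absent from FASTA")
        if prim["strand"] == "+":
            offset = m["start"] - prim["start"]
        else:
            offset = prim["end"] - m["end"]
        length = m["end"] - m["start"]
        if offset < 0 or offset + length > len(hp_seq):
            raise AnnotationError(
                f"mature {m['id']} does not fit inside hairpin {m['parent']}"
            )
        seq = hp_seq[offset : offset + length]
        arm = m["arm"]
        if arm not in ("5p", "3p"):
            # Fall back to naming convention, then to position within hairpin.
            name = m["name"]
            if name.endswith("-5p"):
                arm = "5p"
            elif name.endswith("-3p"):
                arm = "3p"
            else:
                arm = "5p" if offset + length / 2 <= len(hp_seq) / 2 else "3p"
        placements.append(
            {
                "name": m["name"],
                "parent": m["parent"],
                "arm": arm,
                "offset": offset,
                "sequence": seq,
                "role": m["role"],
            }
        )

    by_seq: dict[str, list[dict]] = {}
    for p in placements:
        by_seq.setdefault(p["sequence"], []).append(p)

    species: list[MatureSpecies] = []
    locus_matures: dict[str, list[str]] = {lid: [] for lid in primaries}
    for seq, group in by_seq.items():
        first = sorted(group, key=lambda p: p["name"])[0]
        sid = first["name"]
        parents = tuple(sorted({p["parent"] for p in group}))
        fam, _conf = families.get(sid, (None, None))
        if fam is None:
            if families:
                warnings.warn(f"species {sid} missing from family table; family set to 'NA'")
            fam = "NA"
        species.append(
            MatureSpecies(
                species_id=sid,
                parent_locus_ids=parents,
                arm=first["arm"],
                offset_in_hairpin=first["offset"],
                sequence=seq,
                annotated_role=first["role"],
                family_id=fam,
            )
        )
        for parent in parents:
            locus_matures[parent].append(sid)

    loci: list[HairpinLocus] = []
    for lid, prim in primaries.items():
        mat_ids = tuple(sorted(locus_matures[lid]))
        confident = False
        for sid in mat_ids:
            _fam, conf = families.get(sid, (None, None))
            if conf is not None and conf.strip().lower() in CONFIDENT_FAMILY_CATEGORIES:
                confident = True
        loci.append(
            HairpinLocus(
                locus_id=lid,
                chromosome=prim["chromosome"],
                strand=prim["strand"],
                start=prim["start"],
                end=prim["end"],
                sequence=hairpin_seqs[lid],
                mature_ids=mat_ids,
                family_confident=confident,
            )
        )

    _verify_placements(loci, species)
    return loci, species


def _verify_placements(loci: list[HairpinLocus], species: list[MatureSpecies]) -> None:
    """Assert every mature sequence matches its parent hairpin at the offset."""
    by_id = {l.locus_id: l for l in loci}
    for sp in species:
        for pid in sp.parent_locus_ids:
            locus = by_id.get(pid)
            if locus is None:
                raise AnnotationError(f"species {sp.species_id}: unknown parent locus {pid}")
            sub = locus.sequence[sp.offset_in_hairpin : sp.offset_in_hairpin + len(sp.sequence)]
            if sub != sp.sequence:
                raise AnnotationError(
                    f"species {sp.species_id}: sequence mismatch in hairpin {pid} at offset "
                    f"{sp.offset_in_hairpin}"
                )


def write_mirbase_gff(
    loci: list[HairpinLocus],
    species: list[MatureSpecies],
    gff3_path,
    hairpin_fasta_path,
    family_table_path=None,
    family_confidence: dict[str, str] | None = None,
) -> None:
    """Write annotation back out in the formats ``load_mirbase_gff`` reads.

    Round-trips all fields.  ``family_confidence`` optionally maps species_id
    to a confidence category; species of family-confident loci default to
    'conserved' and all others to 'not confident'.
    """
    by_locus: dict[str, HairpinLocus] = {l.locus_id: l for l in loci}
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            fh.write(
                "\t".join(
                    [
                        locus.chromosome,
                        "tdmdscan",
                        "miRNA_primary_transcript",
                        str(locus.start + 1),
                        str(locus.end),
                        ".",
                        locus.strand,
                        ".",
                        f"ID={locus.locus_id};Name={locus.locus_id}",
                    ]
                )
                + "\n"
            )
        for sp in sorted(species, key=lambda s: s.species_id):
            if sp.isoform_shift != 0:
                continue  # isoform species are derived, not annotated
            for pid in sp.parent_locus_ids:
                locus = by_locus[pid]
                if locus.strand == "+":
                    start0 = locus.start + sp.offset_in_hairpin
                    end0 = start0 + len(sp.sequence)
                else:
                    end0 = locus.end - sp.offset_in_hairpin
                    start0 = end0 - len(sp.sequence)
                fh.write(
                    "\t".join(
                        [
                            locus.chromosome,
                            "tdmdscan",
                            "miRNA",
                            str(start0 + 1),
                            str(end0),
                            ".",
                            locus.strand,
                            ".",
                            f"ID={sp.species_id}@{pid};Name={sp.species_id};"
                            f"Derives_from={pid};arm={sp.arm};role={sp.annotated_role}",
                        ]
                    )
                    + "\n"
                )

    records = [
        SeqRecord(Seq(l.sequence), id=l.locus_id, description="") for l in loci
    ]
    SeqIO.write(records, str(hairpin_fasta_path), "fasta")

    if family_table_path is not None:
        confident_loci = {l.locus_id for l in loci if l.family_confident}
        rows = []
        for sp in sorted(species, key=lambda s: s.species_id):
            if sp.isoform_shift != 0:
                continue
            if family_confidence and sp.species_id in family_confidence:
                conf = family_confidence[sp.species_id]
            elif any(p in confident_loci for p in sp.parent_locus_ids):
                conf = "conserved"
            else:
                conf = "not confident"
            rows.append((sp.family_id, sp.species_id, conf))
        pd.DataFrame(rows, columns=["family_id", "species_id", "confidence"]).to_csv(
            family_table_path, sep="\t", index=False
        )


_PREDICTION_COLUMNS = [
    "transcript_id",
    "family_id",
    "has_site",
    "conserved",
    "context_score",
    "utr_length",
]


def load_target_predictions(tsv_path) -> list[TargetPrediction]:
    """Read a TargetScan-style prediction table (one row per transcript-family pair).

    Duplicate transcript-family pairs and non-numeric scores/lengths are
    rejected with the offending row number.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = set(_PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"prediction table missing columns {sorted(missing)}")
    preds: list[TargetPrediction] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based incl. header
        key = (row.transcript_id, row.family_id)
        if key in seen:
            raise AnnotationError(f"row {i}: duplicate transcript-family pair {key}")
        seen.add(key)
        try:
            score = float(row.context_score)
            utr = int(row.utr_length)
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"row {i}: non-numeric score or UTR length") from exc
        preds.append(
            TargetPrediction(
                transcript_id=row.transcript_id,
                family_id=row.family_id,
                has_site=str(row.has_site).strip().lower() in ("1", "true", "yes"),
                conserved=str(row.conserved).strip().lower() in ("1", "true", "yes"),
                context_score=score,
                utr_length=utr,
            )
        )
    return preds


def write_target_predictions(predictions: list[TargetPrediction], tsv_path) -> None:
    df = pd.DataFrame(
        [
            (p.transcript_id, p.family_id, p.has_site, p.conserved, repr(p.context_score), p.utr_length)
            for p in predictions
        ],
        columns=_PREDICTION_COLUMNS,
    )
    df.to_csv(tsv_path, sep="\t", index=False)


def cognate_map(species: list[MatureSpecies]) -> dict[str, tuple[str, ...]]:
    """Map each annotated (shift-0) species to its cognate strand(s).

    The cognate of a strand is the shift-0 species processed from the other
    arm of the same hairpin; a multi-locus species can have several cognates
    (one per parent locus), which downstream tests pool.
    """
    by_locus_arm: dict[tuple[str, str], str] = {}
    for sp in species:
        if sp.isoform_shift != 0:
            continue
        for pid in sp.parent_locus_ids:
            by_locus_arm[(pid, sp.arm)] = sp.species_id
    out: dict[str, tuple[str, ...]] = {}
    for sp in species:
        if sp.isoform_shift != 0:
            continue
        other = "3p" if sp.arm == "5p" else "5p"
        cogs = sorted(
            {
                by_locus_arm[(pid, other)]
                for pid in sp.parent_locus_ids
                if (pid, other) in by_locus_arm
            }
        )
        out[sp.species_id] = tuple(cogs)
    return out
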