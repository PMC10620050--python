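"""Per-tissue classification of ZSWIM8-sensitive miRNAs and derived analyses.

The decision procedure, per tissue: a miRNA passing the BBUM up-regulation
call (FDR-adjusted p < 0.05) is *sensitive* if its log2 fold-change upon
*Zswim8* loss is significantly greater than that of its passenger (cognate)
strand, or if the passenger is not detected above the count cutoff; a caller
that fails the passenger test is, together with its passenger, *secondarily*
sensitive (attributed to transcription/processing).  Species missed
per-tissue can be rescued by a broad weak-effect rule (increases in >= 11 of
12 tissues with median log2fc > 0.2, likewise for the margin over the
cognate), and species sensitive in another context (tissue or an external
reference list such as published MEF/iNeuron calls) that beat their passenger
in the tissue at hand are *marginally* sensitive there.  Both arms are
evaluated symmetrically, so annotated passenger strands can be called
sensitive (reported as a role swap; annotation is never mutated).

Also here: manual cross-context exclusions, genotype-dependent arm-switch and
5'-isoform-dominance detection, and ranking of the most-affected families by
absolute change in the miRNA pool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from tdmdscan.annotations import MatureSpecies
from tdmdscan.diffexp import DeRecord, RatioStat, de_record, lfc_diff_test, strand_ratio
from tdmdscan.quantify import isoform_species_id

PADJ_ALPHA = 0.05
PASSENGER_ALPHA = 0.05
BROAD_QUOTA = 11
BROAD_N_TISSUES = 12
BROAD_MEDIAN_MIN = 0.2

LABELS = ("sensitive", "secondary", "marginal", "not_called")
REASONS = (
    "bbum+passenger_test",
    "passenger_undetected",
    "broad_rescue",
    "cross_context_marginal",
    "excluded_manual",
    "none",
)


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class SensitivityCall:
    species_id: str
    tissue: str
    label: str
    reason: str
    padj: float = math.nan
    passenger_p: float = math.nan

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ClassifyError(f"unknown label {self.label!r}")
        if self.reason not in REASONS:
            raise ClassifyError(f"unknown reason {self.reason!r}")
        if self.label == "sensitive" and self.reason not in (
            "bbum+passenger_test",
            "passenger_undetected",
            "broad_rescue",
        ):
            raise ClassifyError(f"sensitive call with reason {self.reason!r}")


@dataclass(frozen=True)
class ArmSwitchEvent:
    """Genotype-dependent change in which hairpin arm is the more abundant."""

    group_id: str
    tissue: str
    dominant_het: str
    dominant_ko: str
    ratio_het: RatioStat
    ratio_ko: RatioStat


class DeStore:
    """Per-tissue DE results with cognate lookup and pooled-passenger records.

    ``de`` maps tissue -> DE DataFrame (species_id, log2fc, se, p, padj, ...);
    ``expressed`` maps tissue -> species passing the count filter;
    ``pooled`` maps (tissue, guide species) -> DeRecord of the summed-count
    cognate strand for guides whose parent loci contribute different
    passengers.
    """

    def __init__(
        self,
        de: dict[str, pd.DataFrame],
        expressed: dict[str, set],
        cognate_map: dict[str, tuple[str, ...]],
        pooled: dict[tuple[str, str], DeRecord] | None = None,
    ):
        self.de = {t: df.set_index("species_id", drop=False) for t, df in de.items()}
        self.expressed = expressed
        self.cognate_map = cognate_map
        self.pooled = pooled or {}

    @property
    def tissues(self) -> list[str]:
        return sorted(self.de)

    def record(self, tissue: str, species_id: str) -> DeRecord | None:
        df = self.de.get(tissue)
        if df is None or species_id not in df.index:
            return None
        return de_record(df.loc[species_id])

    def expressed_cognates(self, tissue: str, species_id: str) -> tuple[str, ...]:
        cogs = self.cognate_map.get(species_id, ())
        return tuple(c for c in cogs if c in self.expressed.get(tissue, set()))

    def passenger_record(self, tissue: str, species_id: str) -> DeRecord | None:
        """DE record of the (pooled) passenger strand, or None if undetected."""
        cogs = self.expressed_cognates(tissue, species_id)
        if not cogs:
            return None
        if len(cogs) == 1:
            return self.record(tissue, cogs[0])
        rec = self.pooled.get((tissue, species_id))
        if rec is None:
            raise ClassifyError(
                f"{species_id}/{tissue}: pooled cognate DE record required for "
                f"multi-locus passenger set {cogs}"
            )
        return rec

    def passenger_test(self, tissue: str, species_id: str) -> float | None:
        """One-sided p for lfc(species) > lfc(passenger), None if untestable."""
        rec = self.record(tissue, species_id)
        pas = self.passenger_record(tissue, species_id)
        if rec is None or pas is None:
            return None
        return lfc_diff_test(rec, pas)[3]


def classify_tissue(
    store: DeStore,
    tissue: str,
    padj_alpha: float = PADJ_ALPHA,
    passenger_alpha: float = PASSENGER_ALPHA,
) -> list[SensitivityCall]:
    """Apply the per-tissue sensitive/secondary decision rules.

    Evaluates every species with padj < padj_alpha in the tissue.  Secondary
    labels are emitted for both the caller and its passenger strand(s).
    """
    df = store.de.get(tissue)
    if df is None:
        raise ClassifyError(f"no DE results for tissue {tissue!r}")
    calls: dict[str, SensitivityCall] = {}
    up = df[df["padj"] < padj_alpha]
    for row in up.itertuples(index=False):
        sp = row.species_id
        rec = store.record(tissue, sp)
        if rec is None:  # cannot happen from the same table; guards ext. padj sets
            raise ClassifyError(f"{sp}: padj present but DE record missing in {tissue}")
        pas = store.passenger_record(tissue, sp)
        if pas is None:
            calls[sp] = SensitivityCall(sp, tissue, "sensitive", "passenger_undetected", row.padj)
            continue
        p_pass = lfc_diff_test(rec, pas)[3]
        if p_pass < passenger_alpha:
            calls[sp] = SensitivityCall(
                sp, tissue, "sensitive", "bbum+passenger_test", row.padj, p_pass
            )
        else:
            calls[sp] = SensitivityCall(sp, tissue, "secondary", "none", row.padj, p_pass)
            for cog in store.expressed_cognates(tissue, sp):
                if cog not in calls or calls[cog].label not in ("sensitive",):
                    calls[cog] = SensitivityCall(cog, tissue, "secondary", "none", math.nan, p_pass)
    return list(calls.values())


def _sensitive_anywhere(calls: list[SensitivityCall]) -> set[str]:
    return {c.species_id for c in calls if c.label == "sensitive"}


def rescue_broad(
    store: DeStore,
    calls: list[SensitivityCall],
    quota: int = BROAD_QUOTA,
    n_tissues: int = BROAD_N_TISSUES,
    median_min: float = BROAD_MEDIAN_MIN,
    scale_quota: bool = False,
) -> list[SensitivityCall]:
    """Rescue broadly, weakly up-regulated miRNAs missed by per-tissue calls.

    A species not sensitive in any tissue is rescued iff (i) its log2fc is
    positive in at least ``quota`` of the ``n_tissues`` tissues, (ii) its
    median log2fc over detected tissues exceeds median_min, and (iii, iv) the
    same two conditions hold for the margin over its (pooled) passenger
    strand.  A tissue where the species is undetected cannot count as an
    increase, so the default absolute quota effectively requires
    near-complete detection; ``scale_quota=True`` instead scales the quota to
    ceil(quota/n_tissues * n_detected), evaluating sparsely detected species
    over their detected tissues only (this loosens the rule enough that
    chance alone rescues a few of the many sparsely-detected null miRNAs, so
    it is not the default).  A species without a detectable passenger in any
    tissue satisfies (iii, iv) vacuously, mirroring the per-tissue
    passenger-undetected rule.  Rescued species are labelled
    sensitive(broad_rescue) in every tissue where they are detected.
    """
    already = _sensitive_anywhere(calls)
    new_calls: list[SensitivityCall] = []
    species_ids = sorted({sp for t in store.tissues for sp in store.de[t]["species_id"]})
    for sp in species_ids:
        if sp in already:
            continue
        det_tissues = [
            t for t in store.tissues
            if sp in store.expressed.get(t, set()) and store.record(t, sp) is not None
        ]
        if not det_tissues:
            continue
        lfcs = np.array([store.record(t, sp).log2fc for t in det_tissues])
        q = math.ceil(quota / n_tissues * len(det_tissues)) if scale_quota else quota
        if (lfcs > 0).sum() < q or np.median(lfcs) <= median_min:
            continue
        diffs = []
        for t in det_tissues:
            pas = store.passenger_record(t, sp)
            if pas is not None:
                diffs.append(store.record(t, sp).log2fc - pas.log2fc)
        if diffs:
            diffs = np.array(diffs)
            qd = math.ceil(quota / n_tissues * len(diffs)) if scale_quota else quota
            if (diffs > 0).sum() < qd or np.median(diffs) <= median_min:
                continue
        for t in det_tissues:
            new_calls.append(SensitivityCall(sp, t, "sensitive", "broad_rescue"))
    return new_calls


def mark_marginal(
    store: DeStore,
    calls: list[SensitivityCall],
    reference_sensitive: set[str] | None = None,
    passenger_alpha: float = PASSENGER_ALPHA,
) -> list[SensitivityCall]:
    """Marginal calls: sensitive elsewhere + passenger test passes here.

    A species sensitive in at least one other context (another tissue, or the
    external reference list of previously published sensitive miRNAs) becomes
    marginal in a tissue where it is detected, not already called, and its
    fold-change significantly exceeds its passenger's.  An undetectable
    passenger leaves the test unevaluable, so no marginal call is made.
    """
    reference_sensitive = reference_sensitive or set()
    labelled = {(c.species_id, c.tissue): c.label for c in calls}
    candidates = _sensitive_anywhere(calls) | set(reference_sensitive)
    out: list[SensitivityCall] = []
    for sp in sorted(candidates):
        for tissue in store.tissues:
            if labelled.get((sp, tissue)) in ("sensitive", "secondary", "marginal"):
                continue
            if sp not in store.expressed.get(tissue, set()):
                continue
            sensitive_elsewhere = sp in reference_sensitive or any(
                c.species_id == sp and c.label == "sensitive" and c.tissue != tissue
                for c in calls
            )
            if not sensitive_elsewhere:
                continue
            p_pass = store.passenger_test(tissue, sp)
            if p_pass is not None and p_pass < passenger_alpha:
                out.append(
                    SensitivityCall(sp, tissue, "marginal", "cross_context_marginal", math.nan, p_pass)
                )
    return out


def apply_exclusions(
    calls: list[SensitivityCall],
    exclusions: list[tuple[str, str]],
) -> tuple[list[SensitivityCall], list[SensitivityCall]]:
    """Remove suspected false positives named in the manual exclusion list.

    ``exclusions`` holds (species_id, tissue-or-'ALL') pairs.  Matching
    sensitive calls become not_called(excluded_manual); the removed originals
    are returned as the audit trail.
    """
    known = {c.species_id for c in calls}
    for sp, _scope in exclusions:
        if sp not in known:
            warnings.warn(f"exclusion names unknown species {sp!r}; ignored")
    excluded_all = {sp for sp, scope in exclusions if scope == "ALL"}
    excluded_pairs = {(sp, scope) for sp, scope in exclusions if scope != "ALL"}
    out: list[SensitivityCall] = []
    audit: list[SensitivityCall] = []
    for c in calls:
        if c.label == "sensitive" and (
            c.species_id in excluded_all or (c.species_id, c.tissue) in excluded_pairs
        ):
            audit.append(c)
            out.append(replace(c, label="not_called", reason="excluded_manual"))
        else:
            out.append(c)
    return out, audit


def merge_calls(*call_lists: list[SensitivityCall]) -> list[SensitivityCall]:
    """Combine call lists keeping one label per (species, tissue).

    Precedence: sensitive > secondary > marginal > not_called; earlier lists
    win ties.
    """
    rank = {"sensitive": 0, "secondary": 1, "marginal": 2, "not_called": 3}
    best: dict[tuple[str, str], SensitivityCall] = {}
    for calls in call_lists:
        for c in calls:
            key = (c.species_id, c.tissue)
            if key not in best or rank[c.label] < rank[best[key].label]:
                best[key] = c
    return sorted(best.values(), key=lambda c: (c.tissue, c.species_id))


def union_sensitive_sets(embryo_sensitive: set[str], reference_sensitive: set[str]) -> set[str]:
    """Union of tissue-identified sensitive miRNAs with a published reference set."""
    return set(embryo_sensitive) | set(reference_sensitive)


def detect_arm_switch(
    cpm_by_tissue: dict[str, pd.DataFrame],
    sensitive_species: set[str],
    species: list[MatureSpecies],
    cognate_map: dict[str, tuple[str, ...]],
) -> list[ArmSwitchEvent]:
    """Genotype-dependent dominance switches between the two hairpin arms.

    For each sensitive species and tissue, the passenger strands from all its
    parent loci are pooled (CPMs summed, SEs added in quadrature) and the
    more abundant strand is determined per genotype from the tissue-level
    mean CPMs; an event is emitted when the dominant arm depends on genotype.
    Exact ties yield no event.
    """
    arms = {sp.species_id: sp.arm for sp in species}
    events: list[ArmSwitchEvent] = []
    for tissue in sorted(cpm_by_tissue):
        cpm = cpm_by_tissue[tissue]
        for sp_id in sorted(sensitive_species):
            cogs = [c for c in cognate_map.get(sp_id, ()) if c in cpm.index]
            if sp_id not in cpm.index or not cogs:
                continue
            dominant: dict[str, str] = {}
            ratios: dict[str, RatioStat] = {}
            tie = False
            for geno in ("het", "ko"):
                own = float(cpm.loc[sp_id, (geno, "cpm")])
                own_se = float(cpm.loc[sp_id, (geno, "se")])
                pas = float(cpm.loc[cogs, (geno, "cpm")].sum())
                pas_se = float(np.sqrt((cpm.loc[cogs, (geno, "se")] ** 2).sum()))
                if own == pas:
                    tie = True
                    break
                own_arm = arms[sp_id]
                pas_arm = "3p" if own_arm == "5p" else "5p"
                dominant[geno] = own_arm if own > pas else pas_arm
                five, five_se, three, three_se = (
                    (own, own_se, pas, pas_se) if own_arm == "5p" else (pas, pas_se, own, own_se)
                )
                if five > 0 and three > 0:
                    ratios[geno] = strand_ratio(f"{sp_id}:5p", f"{sp_id}:3p", five, five_se, three, three_se)
            if tie:
                warnings.warn(f"{sp_id}/{tissue}: exact tie in arm abundances; no event")
                continue
            if dominant.get("het") != dominant.get("ko") and len(ratios) == 2:
                events.append(
                    ArmSwitchEvent(sp_id, tissue, dominant["het"], dominant["ko"], ratios["het"], ratios["ko"])
                )
    return events


@dataclass(frozen=True)
class IsoformSwitchEvent:
    """Genotype-dependent change in the dominant 5' isoform of an arm."""

    species_id: str
    tissue: str
    dominant_het: int
    dominant_ko: int
    nonannotated_exceeds_guides: bool
    annotated_over_plus1: RatioStat | None


def detect_isoform_switch(
    cpm_by_tissue: dict[str, pd.DataFrame],
    species_id: str,
    cognate_id: str | None = None,
    shifts: tuple[int, ...] = (-2, -1, 0, 1, 2),
    detection_cpm: float = 5.0,
) -> list[IsoformSwitchEvent]:
    """Dominance analysis over the 5' isoform set {-2..+2} of one arm.

    Per tissue, the dominant isoform is determined per genotype among
    isoforms above ``detection_cpm``; an event is emitted when the dominant
    isoform differs between genotypes, or when a non-annotated isoform in the
    knockout exceeds both annotated strands (the arm's annotated isoform and
    its cognate strand).  The annotated/+1 CPM ratio with propagated SE is
    attached when both are quantified.
    """
    events: list[IsoformSwitchEvent] = []
    for tissue in sorted(cpm_by_tissue):
        cpm = cpm_by_tissue[tissue]
        iso_ids = {s: isoform_species_id(species_id, s) for s in shifts}
        present = {s: i for s, i in iso_ids.items() if i in cpm.index}
        if 0 not in present or len(present) < 2:
            continue
        dominant: dict[str, int] = {}
        for geno in ("het", "ko"):
            levels = {
                s: float(cpm.loc[i, (geno, "cpm")])
                for s, i in present.items()
                if float(cpm.loc[i, (geno, "cpm")]) > detection_cpm
            }
            if not levels:
                continue
            top = max(sorted(levels), key=lambda s: levels[s])
            if sum(1 for v in levels.values() if v == levels[top]) > 1:
                continue  # tie: conservative, no dominance assigned
            dominant[geno] = top
        exceeds = False
        for s, iso in present.items():
            if s == 0:
                continue
            iso_ko = float(cpm.loc[iso, ("ko", "cpm")])
            ann_ko = float(cpm.loc[present[0], ("ko", "cpm")])
            cog_ko = (
                float(cpm.loc[cognate_id, ("ko", "cpm")])
                if cognate_id is not None and cognate_id in cpm.index
                else -np.inf
            )
            if iso_ko > ann_ko and iso_ko > cog_ko:
                exceeds = True
        ratio = None
        if 1 in present:
            ann, plus1 = present[0], present[1]
            a_cpm = float(cpm.loc[ann, ("ko", "cpm")])
            p_cpm = float(cpm.loc[plus1, ("ko", "cpm")])
            if a_cpm > 0 and p_cpm > 0:
                ratio = strand_ratio(
                    ann,
                    plus1,
                    a_cpm,
                    float(cpm.loc[ann, ("ko", "se")]),
                    p_cpm,
                    float(cpm.loc[plus1, ("ko", "se")]),
                )
        switched = (
            "het" in dominant and "ko" in dominant and dominant["het"] != dominant["ko"]
        )
        if switched or exceeds:
            events.append(
                IsoformSwitchEvent(
                    species_id,
                    tissue,
                    dominant.get("het", 0),
                    dominant.get("ko", 0),
                    exceeds,
                    ratio,
                )
            )
    return events


def rank_families(
    cpm: pd.DataFrame,
    calls: list[SensitivityCall],
    species: list[MatureSpecies],
    tissue: str,
    families_with_conserved_targets: set[str] | None = None,
) -> pd.DataFrame:
    """Rank miRNA families by absolute increase of the tissue miRNA pool.

    For each family with at least one sensitive or marginal member in the
    tissue, Delta_F sums (CPM_ko - CPM_het) over member guide strands (a
    sensitive annotated passenger counts as a guide: the sensitive strand is
    considered the miRNA).  pool_share_pct = Delta_F / 1e6 * 100.  Families
    lacking confidently predicted conserved targets are flagged so the
    targeting stage can skip them.
    """
    called_here = {
        c.species_id for c in calls if c.tissue == tissue and c.label in ("sensitive", "marginal")
    }
    fam_of = {sp.species_id: sp.family_id for sp in species if sp.isoform_shift == 0}
    role_of = {sp.species_id: sp.annotated_role for sp in species if sp.isoform_shift == 0}
    fams = sorted({fam_of[s] for s in called_here if s in fam_of})
    rows = []
    for fam in fams:
        members = [
            s
            for s, f in fam_of.items()
            if f == fam and (role_of[s] == "guide" or s in called_here) and s in cpm.index
        ]
        delta = float(
            (cpm.loc[members, ("ko", "cpm")] - cpm.loc[members, ("het", "cpm")]).sum()
        )
        rows.append(
            {
                "family_id": fam,
                "tissue": tissue,
                "delta_cpm": delta,
                "pool_share_pct": delta / 1e6 * 100.0,
                "n_members": len(members),
                "has_conserved_targets": (
                    fam in families_with_conserved_targets
                    if families_with_conserved_targets is not None
                    else True
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "family_id", "tissue", "delta_cpm", "pool_share_pct", "n_members", "has_conserved_targets",
        ],
    )
    return df.sort_values("delta_cpm", ascending=False, kind="stable").reset_index(drop=True)


def calls_to_frame(calls: list[SensitivityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": c.species_id,
                "tissue": c.tissue,
                "label": c.label,
                "reason": c.reason,
                "padj": c.padj,
                "passenger_p": c.passenger_p,
            }
            for c in calls
        ],
        columns=["species_id", "tissue", "label", "reason", "padj", "passenger_p"],
    )
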