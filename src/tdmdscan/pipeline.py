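"""End-to-end pipeline orchestration with a config file and run manifest.

Stages run in method order: quantify -> diffexp -> bbum -> classify ->
clusters -> targeting.  Every threshold has the survey's default (BBUM padj
0.05, passenger test one-sided 0.05, count filter 5 reads/library, detection
5 CPM, mRNA expression 10 TPM, 10-kb cluster window, 20 UTR bins, 5:1
no-site ratio, 21 resamples, 10,000 random cohorts, broad-rescue 11-of-12
with 0.2 medians).  A JSON manifest records the effective config, its hash,
the seed, and per-stage row counts; reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tdmdscan import __version__ as _pkg_version
from tdmdscan.annotations import cognate_map as build_cognate_map
from tdmdscan.annotations import load_mirbase_gff, load_target_predictions
from tdmdscan.bbum import fit_bbum, bbum_fdr
from tdmdscan.classify import (
    DeStore,
    apply_exclusions,
    calls_to_frame,
    classify_tissue,
    detect_arm_switch,
    detect_isoform_switch,
    mark_marginal,
    merge_calls,
    rank_families,
    rescue_broad,
)
from tdmdscan.clusters import call_clusters, cluster_enrichment, write_cluster_tables
from tdmdscan.diffexp import DE_COLUMNS, de_record, size_factors, wald_de
from tdmdscan.quantify import (
    CountTable,
    detected_species,
    filter_expressed,
    genotype_mean_cpm,
)
from tdmdscan.targeting import (
    bin_utr_lengths,
    build_cohorts,
    expressed_transcripts,
    repression_stats,
)

logger = logging.getLogger(__name__)

STAGES = ("quantify", "diffexp", "bbum", "classify", "clusters", "targeting")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds, and seed for one pipeline run."""

    # inputs
    annotation_gff3: str = ""
    hairpin_fasta: str = ""
    family_table: str = ""
    counts: str = ""
    predictions: str = ""
    expression_dir: str = ""  # expression.<tissue>.tsv files
    exclusion_list: str = ""  # TSV/text: species_id <tab> tissue-or-ALL
    reference_sensitive: str = ""  # text: one species per line (e.g. MEF/iNeuron calls)
    outdir: str = "tdmdscan_out"

    # thresholds (survey defaults)
    padj_alpha: float = 0.05
    passenger_alpha: float = 0.05
    min_count: int = 5
    detection_cpm: float = 5.0
    tpm_min: float = 10.0
    cluster_window: int = 10_000
    n_bins: int = 20
    no_site_ratio: int = 5
    n_resamples: int = 21
    n_cohorts: int = 10_000
    broad_quota: int = 11
    broad_n_tissues: int = 12
    broad_median_min: float = 0.2
    top_families: int = 3

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "padj_alpha", "passenger_alpha", "min_count", "detection_cpm", "tpm_min",
            "cluster_window", "n_bins", "no_site_ratio", "n_resamples", "n_cohorts",
            "broad_quota", "broad_n_tissues", "broad_median_min", "top_families",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _read_list(path) -> list[str]:
    if not path:
        return []
    return [
        line.strip().split("\t")[0]
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def _read_exclusions(path) -> list[tuple[str, str]]:
    if not path:
        return []
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        out.append((parts[0], parts[1] if len(parts) > 1 else "ALL"))
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    On stage failure a PipelineError is raised after the manifest (noting the
    failed stage) and any partial outputs are written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": _pkg_version,
        "stages": {},
        "completed": [],
        "failed": None,
    }
    state: dict = {}
    try:
        for stage in STAGES:
            logger.info("running stage %s", stage)
            rows = _STAGE_FUNCS[stage](config, state, outdir)
            manifest["stages"][stage] = rows
            manifest["completed"].append(stage)
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        manifest["failed"] = {"stage": stage, "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise PipelineError(stage, str(exc)) from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def _stage_quantify(config: RunConfig, state: dict, outdir: Path) -> dict:
    loci, species = load_mirbase_gff(
        config.annotation_gff3, config.hairpin_fasta, config.family_table or None
    )
    table = CountTable.read_tsv(config.counts)
    state["loci"] = loci
    state["species"] = species
    state["table"] = table
    state["cognates"] = build_cognate_map(species)
    state["expressed"] = {
        t: filter_expressed(table, t, config.min_count) for t in table.tissues
    }
    state["detected"] = {
        t: detected_species(table, t, config.detection_cpm) for t in table.tissues
    }
    state["cpm"] = {t: genotype_mean_cpm(table, t) for t in table.tissues}
    cpm_flat = pd.concat(
        {t: df for t, df in state["cpm"].items()}, axis=1
    )
    cpm_flat.columns = [".".join(c) for c in cpm_flat.columns]
    cpm_flat.to_csv(outdir / "cpm.tsv", sep="\t", index_label="species_id", float_format="%.6g")
    return {
        "n_species": int(len(table.counts)),
        "n_libraries": int(len(table.counts.columns)),
        "n_tissues": len(table.tissues),
        "min_count": config.min_count,
        "detection_cpm": config.detection_cpm,
    }


def _is_isoform(species_id: str) -> bool:
    return ".iso" in species_id


def _stage_diffexp(config: RunConfig, state: dict, outdir: Path) -> dict:
    table: CountTable = state["table"]
    de: dict[str, pd.DataFrame] = {}
    pooled: dict[tuple[str, str], object] = {}
    for tissue in table.tissues:
        expressed = state["expressed"][tissue]
        df = wald_de(table, tissue, species=expressed)
        de[tissue] = df
        # pooled cognate records for guides whose loci contribute >1 passenger
        sub = table.subset(tissue)
        factors = size_factors(sub.counts.loc[sub.mirna_index()])
        for sp, cogs in state["cognates"].items():
            cogs_x = [c for c in cogs if c in expressed]
            if len(cogs_x) > 1:
                pool_counts = sub.counts.loc[cogs_x].sum(axis=0).to_frame().T
                pool_counts.index = [f"{sp}|pooled_cognate"]
                pool_tab = CountTable(pool_counts, sub.libraries, frozenset())
                rec_df = wald_de(pool_tab, tissue, factors=factors)
                if not rec_df.empty:
                    pooled[(tissue, sp)] = de_record(rec_df.iloc[0])
    state["de"] = de
    all_de = pd.concat(de.values(), ignore_index=True) if de else pd.DataFrame(columns=DE_COLUMNS)
    state["pooled"] = pooled
    all_de.to_csv(outdir / "de.tsv", sep="\t", index=False, float_format="%.6g")
    return {"n_records": int(len(all_de)), "n_pooled_cognates": len(pooled)}


def _stage_bbum(config: RunConfig, state: dict, outdir: Path) -> dict:
    de = state["de"]
    reports = {}
    for tissue, df in de.items():
        mature = df[~df["species_id"].map(_is_isoform)]
        up = mature["log2fc"] > 0
        if up.sum() == 0 or (~up).sum() == 0:
            raise ValueError(f"tissue {tissue}: a fold-change direction is empty")
        params = fit_bbum(mature.loc[up, "p"].to_numpy(), mature.loc[~up, "p"].to_numpy())
        df = df.copy()
        df["padj"] = 1.0
        df.loc[mature.index[up], "padj"] = bbum_fdr(mature.loc[up, "p"].to_numpy(), params)
        df.loc[df["species_id"].map(_is_isoform), "padj"] = np.nan
        de[tissue] = df
        reports[tissue] = {
            "lambda": params.lam,
            "a": params.a,
            "theta": params.theta,
            "r": params.r,
            "loglik": params.loglik,
            "n_signal": params.n_signal,
            "n_background": params.n_background,
            "boundary": params.boundary,
        }
    (outdir / "bbum.json").write_text(json.dumps(reports, indent=1, sort_keys=True))
    pd.concat(de.values(), ignore_index=True).to_csv(
        outdir / "de.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return {"n_tissues": len(reports)}


def _stage_classify(config: RunConfig, state: dict, outdir: Path) -> dict:
    if config.predictions and "families_with_conserved_targets" not in state:
        preds = load_target_predictions(config.predictions)
        state["families_with_conserved_targets"] = {p.family_id for p in preds if p.conserved}
        state["predictions"] = preds
    de = {t: df[~df["species_id"].map(_is_isoform)] for t, df in state["de"].items()}
    store = DeStore(de, state["expressed"], state["cognates"], state["pooled"])
    per_tissue = []
    for tissue in store.tissues:
        per_tissue.extend(
            classify_tissue(store, tissue, config.padj_alpha, config.passenger_alpha)
        )
    rescued = rescue_broad(
        store, per_tissue, config.broad_quota, config.broad_n_tissues, config.broad_median_min
    )
    calls = merge_calls(per_tissue, rescued)
    reference = set(_read_list(config.reference_sensitive))
    marginal = mark_marginal(store, calls, reference, config.passenger_alpha)
    calls = merge_calls(calls, marginal)
    calls, audit = apply_exclusions(calls, _read_exclusions(config.exclusion_list))
    state["calls"] = calls
    calls_to_frame(calls).to_csv(outdir / "calls.tsv", sep="\t", index=False, float_format="%.6g")
    if audit:
        calls_to_frame(audit).to_csv(outdir / "calls_excluded_audit.tsv", sep="\t", index=False)

    sensitive = {c.species_id for c in calls if c.label == "sensitive"}
    state["sensitive"] = sensitive
    events = detect_arm_switch(state["cpm"], sensitive, state["species"], state["cognates"])
    pd.DataFrame(
        [
            {
                "group_id": e.group_id,
                "tissue": e.tissue,
                "dominant_het": e.dominant_het,
                "dominant_ko": e.dominant_ko,
                "ratio_het": e.ratio_het.ratio,
                "ratio_ko": e.ratio_ko.ratio,
                "se_log2_het": e.ratio_het.se_log2,
                "se_log2_ko": e.ratio_ko.se_log2,
            }
            for e in events
        ],
        columns=[
            "group_id", "tissue", "dominant_het", "dominant_ko",
            "ratio_het", "ratio_ko", "se_log2_het", "se_log2_ko",
        ],
    ).to_csv(outdir / "arm_switch.tsv", sep="\t", index=False, float_format="%.6g")
    state["arm_switch_events"] = events

    iso_bases = sorted(
        {s.split(".iso")[0] for df in state["de"].values() for s in df["species_id"] if _is_isoform(s)}
    )
    iso_events = []
    for base in iso_bases:
        cogs = state["cognates"].get(base, ())
        iso_events.extend(
            detect_isoform_switch(
                state["cpm"], base, cogs[0] if cogs else None, detection_cpm=config.detection_cpm
            )
        )
    pd.DataFrame(
        [
            {
                "species_id": e.species_id,
                "tissue": e.tissue,
                "dominant_het": e.dominant_het,
                "dominant_ko": e.dominant_ko,
                "nonannotated_exceeds_guides": e.nonannotated_exceeds_guides,
            }
            for e in iso_events
        ],
        columns=["species_id", "tissue", "dominant_het", "dominant_ko", "nonannotated_exceeds_guides"],
    ).to_csv(outdir / "isoform_switch.tsv", sep="\t", index=False)
    state["isoform_events"] = iso_events

    conserved_fams = state.get("families_with_conserved_targets")
    fam_frames = [
        df
        for tissue in store.tissues
        if not (df := rank_families(state["cpm"][tissue], calls, state["species"], tissue, conserved_fams)).empty
    ]
    families = (
        pd.concat(fam_frames, ignore_index=True)
        if fam_frames
        else rank_families(state["cpm"][store.tissues[0]], [], state["species"], store.tissues[0])
    )
    state["families"] = families
    families.to_csv(outdir / "families.tsv", sep="\t", index=False, float_format="%.6g")
    return {
        "n_calls": len(calls),
        "n_sensitive_species": len(sensitive),
        "n_arm_switch_events": len(events),
        "n_isoform_events": len(iso_events),
    }


def _stage_clusters(config: RunConfig, state: dict, outdir: Path) -> dict:
    loci = [l for l in state["loci"] if l.family_confident]
    clusterset = call_clusters(loci, config.cluster_window)
    by_species = {sp.species_id: sp for sp in state["species"]}
    sensitive_loci = sorted(
        {
            pid
            for sp_id in state["sensitive"]
            if sp_id in by_species
            for pid in by_species[sp_id].parent_locus_ids
        }
    )
    write_cluster_tables(clusterset, loci, outdir / "clusters.tsv", outdir / "clusters.bed")
    result = None
    if sensitive_loci:
        result = cluster_enrichment(
            sensitive_loci, loci, clusterset, config.n_cohorts, seed=config.seed
        )
        (outdir / "enrichment.json").write_text(
            json.dumps(dataclasses.asdict(result), indent=1, sort_keys=True)
        )
    state["clusterset"] = clusterset
    state["enrichment"] = result
    return {
        "n_loci": len(loci),
        "n_clusters": len(clusterset.clusters),
        "n_clustered_loci": len(clusterset.clustered_loci),
        "n_sensitive_loci": len(sensitive_loci),
    }


def _stage_targeting(config: RunConfig, state: dict, outdir: Path) -> dict:
    if not config.predictions or not config.expression_dir:
        state["repression"] = pd.DataFrame()
        return {"skipped": "no predictions/expression inputs"}
    predictions = state.get("predictions") or load_target_predictions(config.predictions)
    utr = (
        pd.DataFrame(
            {"transcript_id": [p.transcript_id for p in predictions],
             "utr_length": [p.utr_length for p in predictions]}
        )
        .drop_duplicates("transcript_id")
        .set_index("transcript_id")["utr_length"]
    )
    bins = bin_utr_lengths(utr, config.n_bins)
    fams_with_conserved = {p.family_id for p in predictions if p.conserved}
    state["families_with_conserved_targets"] = fams_with_conserved

    families: pd.DataFrame = state["families"]
    results = []
    for tissue in sorted(state["de"]):
        expr_path = Path(config.expression_dir) / f"expression.{tissue}.tsv"
        if not expr_path.exists():
            continue
        expr = pd.read_csv(expr_path, sep="\t").set_index("transcript_id")
        tpm_cols = [c for c in expr.columns if c.startswith("tpm_")]
        expressed = expressed_transcripts(expr[tpm_cols], config.tpm_min)
        lfc = expr["log2fc"]
        fam_rows = families[
            (families["tissue"] == tissue) & families["has_conserved_targets"]
        ].head(config.top_families)
        for fam in fam_rows["family_id"]:
            if fam not in fams_with_conserved:
                continue
            try:
                cohorts = build_cohorts(predictions, fam, expressed)
            except Exception:
                continue
            for cohort_name in ("top", "conserved", "all"):
                cohort = cohorts[cohort_name]
                if len(cohort) < 2:
                    continue
                res = repression_stats(
                    lfc,
                    cohort,
                    cohorts["no_site_pool"],
                    bins,
                    family_id=fam,
                    tissue=tissue,
                    cohort_name=cohort_name,
                    ratio=config.no_site_ratio,
                    n_resamples=config.n_resamples,
                    seed=config.seed,
                )
                results.append(dataclasses.asdict(res))
    rep = pd.DataFrame(
        results,
        columns=[
            "family_id", "tissue", "cohort", "fold_repression_mean", "fold_repression_se",
            "p_median", "n_targets", "n_no_site", "n_resamples",
        ],
    )
    state["repression"] = rep
    rep.to_csv(outdir / "repression.tsv", sep="\t", index=False, float_format="%.6g")
    return {"n_results": len(rep)}


def run_synthetic_screen(config=None, seed: int = 0, with_rescue: bool = True):
    """Simulate one dataset and run the classification stages in memory.

    Convenience wrapper used for recovery evaluation: returns a dict with the
    truth object, the count table, the per-tissue DE tables (padj filled),
    the DeStore, and the merged sensitivity calls (per-tissue rules plus
    broad rescue; no marginal/exclusion stages, which need external inputs).
    """
    from tdmdscan.classify import classify_tissue, merge_calls, rescue_broad
    from tdmdscan.synthetic import SyntheticConfig, _draw_truth, simulate_annotation, simulate_counts

    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    loci, species, layout = simulate_annotation(config, int(rng.integers(2**31)))
    truth = _draw_truth(config, species, layout, rng, seed)
    table, all_species = simulate_counts(loci, species, truth, config, int(rng.integers(2**31)))
    cognates = build_cognate_map(species)

    de: dict[str, pd.DataFrame] = {}
    expressed: dict[str, set] = {}
    pooled: dict[tuple[str, str], object] = {}
    for tissue in table.tissues:
        exp = filter_expressed(table, tissue)
        expressed[tissue] = exp
        df = wald_de(table, tissue, species=exp)
        mature = df[~df["species_id"].map(_is_isoform)].copy()
        up = mature["log2fc"] > 0
        params = fit_bbum(mature.loc[up, "p"].to_numpy(), mature.loc[~up, "p"].to_numpy())
        mature["padj"] = 1.0
        mature.loc[mature.index[up], "padj"] = bbum_fdr(mature.loc[up, "p"].to_numpy(), params)
        de[tissue] = mature.reset_index(drop=True)
        sub = table.subset(tissue)
        factors = size_factors(sub.counts.loc[sub.mirna_index()])
        med_disp = float(mature["dispersion"].median())
        for sp, cogs in cognates.items():
            cogs_x = [c for c in cogs if c in exp]
            if len(cogs_x) > 1:
                pool_counts = sub.counts.loc[cogs_x].sum(axis=0).to_frame().T
                pool_counts.index = [f"{sp}|pooled_cognate"]
                rec_df = wald_de(
                    CountTable(pool_counts, sub.libraries, frozenset()),
                    tissue,
                    factors=factors,
                    prior_dispersion=med_disp,
                )
                if not rec_df.empty:
                    pooled[(tissue, sp)] = de_record(rec_df.iloc[0])

    from tdmdscan.classify import DeStore

    store = DeStore(de, expressed, cognates, pooled)
    calls = []
    for tissue in store.tissues:
        calls.extend(classify_tissue(store, tissue))
    per_tissue_calls = list(calls)
    if with_rescue:
        calls = merge_calls(calls, rescue_broad(store, calls))
    else:
        calls = merge_calls(calls)
    return {
        "truth": truth,
        "loci": loci,
        "species": species,
        "all_species": all_species,
        "table": table,
        "de": de,
        "store": store,
        "per_tissue_calls": per_tissue_calls,
        "calls": calls,
        "config": config,
    }


_STAGE_FUNCS = {
    "quantify": _stage_quantify,
    "diffexp": _stage_diffexp,
    "bbum": _stage_bbum,
    "classify": _stage_classify,
    "clusters": _stage_clusters,
    "targeting": _stage_targeting,
}
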