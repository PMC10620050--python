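"""Synthetic-data generator: determinism, construction oracles, round-trips."""

import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from tdmdscan.annotations import load_mirbase_gff, load_target_predictions
from tdmdscan.clusters import call_clusters
from tdmdscan.quantify import CountTable, filter_expressed, isoform_species_id
from tdmdscan.synthetic import (
    SyntheticConfig,
    SyntheticError,
    SyntheticTruth,
    _draw_truth,
    simulate_annotation,
    simulate_counts,
    simulate_dataset,
    simulate_mrna,
)

SMALL = dict(
    n_loci=80,
    n_clusters=6,
    n_clustered=30,
    include_polycistron=False,
    include_paralog_trio=True,
    n_sensitive=8,
    n_secondary=3,
    n_broad_weak=2,
    n_transcripts=600,
    n_targets_per_family=25,
)


def small_config(**over):
    return SyntheticConfig(**{**SMALL, **over})


def _simulate(seed=0, **over):
    cfg = small_config(**over)
    rng = np.random.default_rng(seed)
    loci, species, layout = simulate_annotation(cfg, int(rng.integers(2**31)))
    truth = _draw_truth(cfg, species, layout, rng, seed)
    return cfg, loci, species, layout, truth


class TestAnnotationGeometry:
    def test_cluster_caller_recovers_constructed_partition(self):
        _cfg, loci, _sp, layout, _t = _simulate()
        called = call_clusters(loci, 10000)
        assert set(map(frozenset, called.clusters)) == set(map(frozenset, layout.clusters))
        assert set(called.singletons) == set(layout.singletons)

    def test_requested_totals(self):
        _cfg, loci, _sp, layout, _t = _simulate()
        assert len(loci) == 80
        assert len(layout.clusters) == 6
        assert len(layout.clustered_loci) == 30

    def test_zero_clusters_all_singletons(self):
        cfg = small_config(n_clusters=0, n_clustered=0, include_paralog_trio=False)
        loci, _sp, layout = simulate_annotation(cfg, 1)
        assert layout.clusters == ()
        assert len(layout.singletons) == len(loci)
        assert call_clusters(loci, 10000).clusters == ()

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(SyntheticError):
            simulate_annotation(small_config(n_clustered=200), 0)

    def test_paralog_guide_shared_across_two_loci(self):
        _cfg, _loci, species, _lay, _t = _simulate()
        shared = [s for s in species if len(s.parent_locus_ids) == 2]
        assert len(shared) == 1
        assert shared[0].species_id == "mir-shared-5p"

    def test_different_seeds_differ(self):
        a = simulate_annotation(small_config(), 1)[0]
        b = simulate_annotation(small_config(), 2)[0]
        assert any(x.sequence != y.sequence for x, y in zip(a, b))


class TestCounts:
    def test_implanted_effect_recovered_in_mean_lfc(self):
        """A +1 effect in one tissue shows up as ~+1 mean log2 ratio of ko to
        het normalized counts over repeated simulations.  A single affected
        species is implanted so CPM renormalisation does not absorb the
        effect."""
        cfg, loci, species, layout, truth = _simulate(
            3, n_sensitive=1, n_secondary=0, n_broad_weak=0, arm_switch_tissues=()
        )
        assert len(truth.sensitive_effects) == 1
        sp = next(iter(truth.sensitive_effects))
        tissue, eff = sorted(truth.sensitive_effects[sp].items())[0]
        truth.sensitive_effects[sp] = {tissue: 1.0}
        lfcs = []
        for rep in range(30):
            table, _ = simulate_counts(loci, species, truth, cfg, 1000 + rep)
            libs_het = table.tissue_libraries(tissue, "het")
            libs_ko = table.tissue_libraries(tissue, "ko")
            tot_h = table.counts.loc[table.mirna_index(), libs_het].sum()
            tot_k = table.counts.loc[table.mirna_index(), libs_ko].sum()
            cpm_h = (table.counts.loc[sp, libs_het] / tot_h).mean()
            cpm_k = (table.counts.loc[sp, libs_ko] / tot_k).mean()
            lfcs.append(np.log2(cpm_k / cpm_h))
        assert np.mean(lfcs) == pytest.approx(1.0, abs=0.15)

    def test_spikeins_unaffected_by_genotype(self):
        cfg, loci, species, layout, truth = _simulate(4)
        lfcs = []
        for rep in range(20):
            table, _ = simulate_counts(loci, species, truth, cfg, 2000 + rep)
            for tissue in cfg.tissues[:3]:
                h = table.counts.loc[sorted(table.spikein_ids), table.tissue_libraries(tissue, "het")].sum(axis=1)
                k = table.counts.loc[sorted(table.spikein_ids), table.tissue_libraries(tissue, "ko")].sum(axis=1)
                lfcs.append(np.log2((k.sum() + 1) / (h.sum() + 1)))
        assert abs(np.mean(lfcs)) < 0.1

    def test_isoform_rows_emitted_for_switch_case(self):
        cfg, loci, species, layout, truth = _simulate(5)
        table, all_species = simulate_counts(loci, species, truth, cfg, 9)
        plus1 = isoform_species_id(truth.isoform_switch_species, 1)
        assert plus1 in table.counts.index
        assert len(all_species) == len(species) + 4

    def test_silenced_locus_fails_expression_filter(self):
        cfg, loci, species, layout, truth = _simulate(6)
        silenced = [
            (lid, t)
            for lid, tissues in truth.locus_expressed.items()
            for t in cfg.tissues
            if t not in tissues
        ]
        assert silenced, "default config should silence some locus/tissue pairs"
        table, _ = simulate_counts(loci, species, truth, cfg, 10)
        by_locus = {l.locus_id: l for l in loci}
        lid, tissue = silenced[0]
        expressed = filter_expressed(table, tissue)
        members = {s.species_id for s in species if lid in s.parent_locus_ids and len(s.parent_locus_ids) == 1}
        assert not (members & expressed)


class TestMrna:
    def test_repression_recovery_via_pipeline_stats(self):
        from tdmdscan.targeting import bin_utr_lengths, build_cohorts, expressed_transcripts, repression_stats

        cfg, loci, species, layout, truth = _simulate(7, n_transcripts=3000, n_targets_per_family=150)
        preds, expr = simulate_mrna(species, truth, cfg, 11)
        fam = sorted(truth.target_deltas)[0]
        tissue = sorted(truth.target_deltas[fam])[0]
        utr = pd.Series({p.transcript_id: p.utr_length for p in preds})
        utr = utr[~utr.index.duplicated()]
        bins = bin_utr_lengths(utr, 20)
        e = expr[tissue].set_index("transcript_id")
        tpm_cols = [c for c in e.columns if c.startswith("tpm_")]
        cohorts = build_cohorts(preds, fam, expressed_transcripts(e[tpm_cols], 10.0))
        res = repression_stats(e["log2fc"], cohorts["all"], cohorts["no_site_pool"], bins, seed=5)
        assert res.fold_repression_mean == pytest.approx(-cfg.target_delta, abs=0.03)

    def test_zero_delta_centered_at_zero(self):
        from tdmdscan.targeting import bin_utr_lengths, build_cohorts, expressed_transcripts, repression_stats

        cfg, loci, species, layout, truth = _simulate(8, n_transcripts=3000, n_targets_per_family=150, target_delta=0.0)
        truth.target_deltas = {f: {t: 0.0 for t in d} for f, d in truth.target_deltas.items()}
        preds, expr = simulate_mrna(species, truth, cfg, 12)
        fam = sorted(truth.target_deltas)[0]
        tissue = sorted(truth.target_deltas[fam])[0]
        utr = pd.Series({p.transcript_id: p.utr_length for p in preds})
        utr = utr[~utr.index.duplicated()]
        bins = bin_utr_lengths(utr, 20)
        e = expr[tissue].set_index("transcript_id")
        tpm_cols = [c for c in e.columns if c.startswith("tpm_")]
        cohorts = build_cohorts(preds, fam, expressed_transcripts(e[tpm_cols], 10.0))
        res = repression_stats(e["log2fc"], cohorts["all"], cohorts["no_site_pool"], bins, seed=5)
        assert abs(res.fold_repression_mean) < 0.04


class TestDatasetOnDisk:
    def test_byte_identical_under_same_seed(self, tmp_path):
        simulate_dataset(small_config(), 21, tmp_path / "a")
        simulate_dataset(small_config(), 21, tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", files, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seed_different_bytes(self, tmp_path):
        simulate_dataset(small_config(), 21, tmp_path / "a")
        simulate_dataset(small_config(), 22, tmp_path / "c")
        assert (tmp_path / "a" / "counts.tsv").read_text() != (tmp_path / "c" / "counts.tsv").read_text()

    def test_emitted_files_readable_by_every_reader(self, tmp_path):
        truth = simulate_dataset(small_config(), 30, tmp_path / "d")
        loci, species = load_mirbase_gff(
            tmp_path / "d" / "annotation.gff3", tmp_path / "d" / "hairpins.fa", tmp_path / "d" / "families.tsv"
        )
        assert len(loci) == 80
        table = CountTable.read_tsv(tmp_path / "d" / "counts.tsv")
        assert table.spikein_ids
        preds = load_target_predictions(tmp_path / "d" / "predictions.tsv")
        assert preds
        truth2 = SyntheticTruth.from_json((tmp_path / "d" / "truth.json").read_text())
        assert truth2.sensitive_effects == truth.sensitive_effects
        assert truth2.cluster_layout == truth.cluster_layout
        cfg = json.loads((tmp_path / "d" / "config.json").read_text())
        assert cfg["n_loci"] == 80
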