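"""Generator contracts: determinism, injected effects, ground truth."""

import numpy as np
import pandas as pd
import pytest

from ucbranch.mutsig import build_catalog, refit_signatures
from ucbranch.survival import cox_univariate
from ucbranch.synthetic import (
    CLASSES,
    CohortConfig,
    _make_cohort_table,
    generate_cohort,
    generate_mutation_table,
    synthetic_signature_set,
)

SMALL = dict(n_proteins=40, n_phospho=30, n_ddr_markers=6)


class TestDeterminism:
    def test_identical_seeds_identical_bundles(self):
        b1 = generate_cohort(CohortConfig(seed=7, n_per_class=4, **SMALL))
        b2 = generate_cohort(CohortConfig(seed=7, n_per_class=4, **SMALL))
        pd.testing.assert_frame_equal(b1.cohort, b2.cohort)
        pd.testing.assert_frame_equal(b1.peptides, b2.peptides)
        pd.testing.assert_frame_equal(b1.protein_truth, b2.protein_truth)
        pd.testing.assert_frame_equal(b1.phospho.values, b2.phospho.values)
        pd.testing.assert_frame_equal(b1.mutations, b2.mutations)
        pd.testing.assert_frame_equal(b1.segments, b2.segments)
        assert b1.sequences == b2.sequences
        assert b1.truth == b2.truth

    def test_different_seeds_differ(self):
        b1 = generate_cohort(CohortConfig(seed=1, n_per_class=4, **SMALL))
        b2 = generate_cohort(CohortConfig(seed=2, n_per_class=4, **SMALL))
        assert not b1.protein_truth.equals(b2.protein_truth)

    def test_written_bundle_round_trips(self, tmp_path):
        b = generate_cohort(CohortConfig(seed=3, n_per_class=4, **SMALL))
        b.write(tmp_path)
        for name in ["clinical.tsv", "peptides.tsv", "phospho.tsv",
                     "mutations.maf.tsv", "segments.seg.tsv", "truth.json",
                     "gene_sets.gmt", "proteins.fasta", "signatures.tsv"]:
            assert (tmp_path / name).exists()


class TestEffectInjection:
    def test_null_effect_when_effect_zero(self):
        cfg = CohortConfig(seed=11, n_per_class=30, effect_log2=0.0, **SMALL)
        b = generate_cohort(cfg)
        branch = b.cohort["latent_branch"]
        panel = b.truth.panel_up_papillary + b.truth.panel_up_cis
        diff = (
            b.protein_truth.loc[branch == "papillary", panel].mean()
            - b.protein_truth.loc[branch == "cis", panel].mean()
        )
        assert np.all(np.abs(diff) < 0.5)  # within noise at n ~ 100/branch

    def test_standardized_mean_difference_matches_config(self):
        cfg = CohortConfig(seed=12, n_per_class=40, **SMALL)
        b = generate_cohort(cfg)
        branch = b.cohort["latent_branch"]
        pap = b.protein_truth.loc[branch == "papillary", b.truth.panel_up_papillary]
        cis = b.protein_truth.loc[branch == "cis", b.truth.panel_up_papillary]
        pooled_sd = np.sqrt((pap.var(ddof=1) + cis.var(ddof=1)) / 2)
        smd = (pap.mean() - cis.mean()) / pooled_sd
        assert smd.mean() == pytest.approx(1.5, abs=0.25)

    def test_ddr_markers_elevated_in_cis_and_invasive(self):
        b = generate_cohort(CohortConfig(seed=13, n_per_class=25, **SMALL))
        log_phos = np.log2(b.phospho.values)
        elevated = b.cohort["histology_class"].isin(["CIS", "Invasive"])
        markers = b.truth.ddr_marker_ids
        diff = (log_phos.loc[elevated, markers].mean()
                - log_phos.loc[~elevated, markers].mean())
        assert diff.mean() > 0.6


class TestMissingness:
    def test_dropout_monotone_in_abundance(self):
        cfg = CohortConfig(seed=14, n_per_class=12, **SMALL)
        b = generate_cohort(cfg)
        observed = set(zip(b.peptides["run_id"], b.peptides["protein"]))
        truth = b.protein_truth
        abund = []
        missing = []
        for s in truth.index:
            for p in truth.columns:
                abund.append(truth.loc[s, p])
                missing.append((s, p) not in observed)
        abund = np.asarray(abund)
        missing = np.asarray(missing, dtype=float)
        bins = np.quantile(abund, [0, 0.25, 0.5, 0.75, 1.0])
        rates = [
            missing[(abund >= lo) & (abund < hi)].mean()
            for lo, hi in zip(bins[:-1], bins[1:])
        ]
        assert all(a >= b - 0.02 for a, b in zip(rates[:-1], rates[1:]))


class TestMutations:
    def test_hras_hotspot_fraction_in_binomial_interval(self):
        cfg = CohortConfig(seed=15, n_per_class={"Papilloma": 1000},
                           n_proteins=40, n_phospho=10, n_ddr_markers=2)
        b = generate_cohort(cfg)
        frac = len(b.truth.hras_carriers) / 1000
        half_width = 2.576 * np.sqrt(0.83 * 0.17 / 1000)
        assert abs(frac - 0.83) <= half_width
        hras = b.mutations[b.mutations["gene"] == "HRAS"]
        q61r_frac = (hras["protein_change"] == "Q61R").mean()
        assert q61r_frac == pytest.approx(0.8, abs=0.05)

    def test_zero_mutation_rate_empty_catalog(self):
        cfg = CohortConfig(seed=16, n_per_class={"Normal": 4, "CIS": 4},
                           mutation_rate=0.0, n_proteins=40, n_phospho=10,
                           n_ddr_markers=2)
        b = generate_cohort(cfg)
        assert len(b.mutations) == 0
        cat, _ = build_catalog(b.mutations)
        assert cat.to_numpy().sum() == 0

    def test_pure_signature_recovered_end_to_end(self):
        sigs = synthetic_signature_set()
        cfg = CohortConfig(
            seed=17,
            n_per_class={"Normal": 6},
            mutation_rate=3000.0,
            exposure_profiles={"Normal": {"SIG_C": 1.0}},
            n_proteins=10, n_phospho=10, n_ddr_markers=2,
        )
        cohort = _make_cohort_table(cfg, np.random.default_rng(0))
        table = generate_mutation_table(cohort, sigs, cfg, np.random.default_rng(1))
        cat, _ = build_catalog(table)
        for s in cat.index:
            res = refit_signatures(cat.loc[s].to_numpy(), sigs)
            assert res.weights.get("SIG_C", 0.0) >= 0.95

    def test_context_frequencies_match_mixture(self):
        sigs = synthetic_signature_set()
        cfg = CohortConfig(
            seed=18, n_per_class={"Normal": 3}, mutation_rate=2000.0,
            exposure_profiles={"Normal": {"SIG_A": 0.6, "SIG_B": 0.4}},
            n_proteins=10, n_phospho=10, n_ddr_markers=2,
        )
        cohort = _make_cohort_table(cfg, np.random.default_rng(2))
        table = generate_mutation_table(cohort, sigs, cfg, np.random.default_rng(3))
        cat, _ = build_catalog(table)
        mix = 0.6 * sigs["SIG_A"] + 0.4 * sigs["SIG_B"]
        for s in cat.index:
            counts = cat.loc[s]
            n = counts.sum()
            freq = counts / n
            # 99.9% multinomial envelope per category
            se = np.sqrt(mix * (1 - mix) / n)
            assert np.all(np.abs(freq - mix) <= 3.3 * se + 1e-3)

    def test_unknown_signature_in_profile_rejected(self):
        cfg = CohortConfig(
            seed=19, n_per_class={"Normal": 3},
            exposure_profiles={"Normal": {"NOPE": 1.0}},
        )
        with pytest.raises(ValueError, match="unknown"):
            cfg.validate()


class TestSurvivalGenerator:
    def test_cox_recovers_true_hazard_ratio(self):
        cfg = CohortConfig(seed=20, n_per_class={"HGPC": 2000, "CIS": 2000},
                           **SMALL)
        cohort = _make_cohort_table(cfg, np.random.default_rng(7))
        x = (cohort["latent_branch"] == "cis").to_numpy(dtype=float)
        fit = cox_univariate(cohort["survival_time"].to_numpy(),
                             cohort["event"].to_numpy(), x)
        assert 0.85 * 2.0 <= fit.hazard_ratio <= 1.18 * 2.0


class TestInvariants:
    def test_cross_references_resolve(self, small_bundle):
        truth = small_bundle.truth
        proteins = set(small_bundle.protein_truth.columns)
        assert set(truth.panel_up_papillary) <= proteins
        assert set(truth.panel_up_cis) <= proteins
        assert truth.cis_effect_gene in proteins
        assert set(truth.ddr_marker_ids) <= set(small_bundle.phospho.features)
        assert set(truth.exposures) == set(small_bundle.cohort.index)
        for members in small_bundle.gene_sets.sets.values():
            assert set(members) <= proteins

    def test_derived_label_iff_invasive(self, small_bundle):
        coh = small_bundle.cohort
        invasive = coh["histology_class"] == "Invasive"
        assert (coh.loc[invasive, "derived_label"] != "").all()
        assert (coh.loc[~invasive, "derived_label"] == "").all()
        assert (coh["survival_time"] > 0).all()

    def test_del8p12_enriched_in_metastatic_invasive(self):
        b = generate_cohort(CohortConfig(seed=21, n_per_class=40, **SMALL))
        coh = b.cohort
        dels = pd.Series(b.truth.del8p12)
        inv_met = (coh["histology_class"] == "Invasive") & (coh["metastasis"] == 1)
        assert dels[inv_met[inv_met].index].mean() > dels[coh.index[~inv_met]].mean()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_class=1).validate()
        with pytest.raises(ValueError):
            CohortConfig(effect_log2=-1.0).validate()
        with pytest.raises(ValueError):
            CohortConfig(hras_papilloma_prob=1.5).validate()
        bad = CohortConfig()
        bad.exposure_profiles["CIS"] = {"SIG_A": 0.7, "SIG_B": 0.7}
        with pytest.raises(ValueError):
            bad.validate()

    def test_classes_cover_progression_spectrum(self):
        assert CLASSES == ("Normal", "Hyperplasia", "UPUMP", "Papilloma",
                           "LGPC", "HGPC", "CIS", "Invasive")
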