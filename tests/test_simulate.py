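"""Synthetic-data generators and the in-silico spike-in / LOD harness."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from panelcnv import (
    SimulationConfig,
    SpikeInSpec,
    estimate_tumor_fraction,
    generate_fragments,
    generate_normals,
    generate_panel,
    generate_tumor_profile,
    log2_ratio_from_abcn,
    run_lod_experiment,
    spike_in,
)
from panelcnv.errors import ValidationError
from panelcnv.normalize import (
    apply_bias_model,
    build_pon,
    fit_bias_model,
    median_normalize,
    normalize_sample,
)
from panelcnv.simulate import (
    analytic_lod_fraction,
    expected_short_fraction,
    injected_bias,
)


class TestGeneratePanel:
    def test_structure_and_determinism(self, sim_config):
        p1 = generate_panel(sim_config)
        p2 = generate_panel(sim_config)
        assert len(p1) == sim_config.n_genes * sim_config.probes_per_gene
        assert len(p1.genes) == sim_config.n_genes
        assert p1.checksum == p2.checksum

    def test_seed_changes_covariates_not_structure(self, sim_config):
        import dataclasses

        other = dataclasses.replace(sim_config, seed=sim_config.seed + 1)
        p1, p2 = generate_panel(sim_config), generate_panel(other)
        assert len(p1) == len(p2)
        assert p1.probe_ids == p2.probe_ids
        assert p1.checksum != p2.checksum  # covariates differ

    def test_gene_blocks_contiguous(self, sim_panel):
        for gene, idx in sim_panel.genes.items():
            assert list(idx) == list(range(idx[0], idx[-1] + 1))

    def test_named_genes_present(self, sim_panel):
        assert {"ERBB2", "EGFR", "MET"} <= set(sim_panel.genes)

    def test_more_names_than_genes_rejected(self):
        config = SimulationConfig(n_genes=2)
        with pytest.raises(ValidationError):
            generate_panel(config, gene_names=["A", "B", "C"])


class TestGenerateNormals:
    def test_noiseless_flat_bias_constant_depth(self):
        config = SimulationConfig(
            seed=3, n_genes=10, probes_per_gene=4, n_chromosomes=5,
            noise_sigma=0.0, gc_bias_amplitude=0.0, mappability_bias_slope=0.0,
        )
        panel = generate_panel(config)
        normals = generate_normals(config, panel, n=3)
        for p in normals:
            np.testing.assert_allclose(p.depths, config.target_depth)

    def test_independent_noise_across_samples(self, sim_config, sim_panel):
        normals = generate_normals(sim_config, sim_panel, n=10)
        assert len(normals) == 10
        depths = np.vstack([p.depths for p in normals])
        assert np.all(np.std(depths, axis=0) > 0)

    def test_depth_tracks_injected_bias(self, sim_config, sim_panel):
        normals = generate_normals(sim_config, sim_panel)
        med = np.median([p.depths for p in normals], axis=0)
        bias = injected_bias(sim_config, sim_panel)
        r = np.corrcoef(med, bias)[0, 1]
        assert r > 0.8

    def test_replicate_sets_are_independent(self, sim_config, sim_panel):
        a = generate_normals(sim_config, sim_panel, n=2, set_id=1)
        b = generate_normals(sim_config, sim_panel, n=2, set_id=2)
        assert not np.allclose(a[0].depths, b[0].depths)


class TestSpikeIn:
    def test_null_mixture_matches_background(self, sim_config, sim_panel):
        normals = generate_normals(sim_config, sim_panel, n=2)
        tumor = generate_tumor_profile(sim_config, sim_panel, {"ERBB2": 60.0})
        mixed = spike_in(tumor, normals[0], 0.0, seed=5)
        # same distribution as the background up to Poisson resampling
        stat, pvalue = sps.ks_2samp(mixed.depths, normals[0].depths)
        assert pvalue > 0.01

    def test_full_fraction_recovers_tumor(self, sim_config, sim_panel):
        normals = generate_normals(sim_config, sim_panel, n=1)
        tumor = generate_tumor_profile(sim_config, sim_panel, {"ERBB2": 60.0})
        mixed = spike_in(tumor, normals[0], 1.0, seed=5,
                         target_depth=sim_config.target_depth)
        idx = list(sim_panel.genes["ERBB2"])
        rel = mixed.depths / np.median(mixed.depths)
        tum_rel = tumor.depths / np.median(tumor.depths)
        np.testing.assert_allclose(rel[idx], tum_rel[idx], rtol=0.2)

    def test_expected_gene_log2_ratio_at_one_percent(self, sim_config, sim_panel,
                                                     fitted_reference):
        """Mean ERBB2 log2 ratio across replicates matches the mixture model."""
        model, pon = fitted_reference
        tumor = generate_tumor_profile(sim_config, sim_panel, {"ERBB2": 60.0})
        background = generate_normals(sim_config, sim_panel, n=1, set_id=50)[0]
        idx = np.array(sim_panel.genes["ERBB2"])
        expected = log2_ratio_from_abcn(60.0, 0.01)  # ~0.368
        observed = []
        for rep in range(50):
            mixed = spike_in(tumor, background, 0.01, seed=1000 + rep,
                             target_depth=sim_config.target_depth)
            lr = normalize_sample(mixed, model, pon, sim_panel)
            observed.append(np.mean(lr.log2_ratios[idx]))
        observed = np.asarray(observed)
        se = observed.std(ddof=1) / np.sqrt(len(observed))
        # the background sample's own noise adds a fixed offset; allow 3 SE
        # plus the per-probe background noise budget
        budget = 3 * se + 0.05
        assert abs(observed.mean() - expected) < budget

    def test_monotone_in_fraction(self, sim_config, sim_panel, fitted_reference):
        """Expected spiked-gene log2 ratio never decreases with fraction."""
        model, pon = fitted_reference
        tumor = generate_tumor_profile(sim_config, sim_panel, {"ERBB2": 60.0})
        background = generate_normals(sim_config, sim_panel, n=1, set_id=51)[0]
        idx = np.array(sim_panel.genes["ERBB2"])
        means = []
        for fraction in (0.003, 0.01, 0.03, 0.05):
            reps = []
            for rep in range(20):
                mixed = spike_in(tumor, background, fraction, seed=2000 + rep,
                                 target_depth=sim_config.target_depth)
                lr = normalize_sample(mixed, model, pon, sim_panel)
                reps.append(np.mean(lr.log2_ratios[idx]))
            means.append(np.mean(reps))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_depth_conservation(self, sim_config, sim_panel):
        normals = generate_normals(sim_config, sim_panel, n=1)
        tumor = generate_tumor_profile(sim_config, sim_panel, {"ERBB2": 60.0})
        mixed = spike_in(tumor, normals[0], 0.05, seed=9,
                         target_depth=sim_config.target_depth)
        # Poisson resampling conserves the expected total depth
        expected_total = sim_config.target_depth * len(sim_panel)
        assert mixed.depths.sum() == pytest.approx(expected_total, rel=0.05)

    def test_panel_mismatch_rejected(self, sim_config, sim_panel, small_panel):
        from panelcnv import DepthProfile

        tumor = generate_tumor_profile(sim_config, sim_panel, {"ERBB2": 60.0})
        bg = DepthProfile("bg", np.ones(len(small_panel)) * 100)
        with pytest.raises(Exception):
            spike_in(tumor, bg, 0.05, seed=1)


class TestGenerateFragments:
    def test_zero_tumor_fraction_with_long_mode_above_threshold(self):
        config = SimulationConfig(
            seed=4, normal_frag_mean=185.0, normal_frag_sd=5.0, frag_min=150
        )
        dist, ledger = generate_fragments(config, 0.0, 2000)
        assert ledger == {"n_tumor": 0, "n_normal": 2000}
        assert estimate_tumor_fraction(dist).p == 0.0

    def test_separated_modes_recover_weight(self):
        # modes fully separated around 150 bp
        config = SimulationConfig(
            seed=8, tumor_frag_mean=120.0, tumor_frag_sd=5.0,
            normal_frag_mean=185.0, normal_frag_sd=5.0,
        )
        n = 10_000
        dist, ledger = generate_fragments(config, 0.2, n)
        tf = estimate_tumor_fraction(dist)
        # within the binomial 95% CI of the generating weight
        ci = 1.96 * np.sqrt(0.2 * 0.8 / n)
        assert abs(tf.p - 0.2) < ci + abs(ledger["n_tumor"] / n - 0.2)

    def test_overlapping_modes_match_closed_form_mass(self):
        config = SimulationConfig(seed=15)  # defaults overlap the 150 bp cut
        n = 20_000
        weight = 0.3
        dist, _ = generate_fragments(config, weight, n)
        tf = estimate_tumor_fraction(dist)
        expected = expected_short_fraction(config, weight)
        # the estimator is biased off the generating weight by the overlap;
        # the bias is exactly the mixture mass below the cut
        assert expected != pytest.approx(weight, abs=0.05)
        ci = 3 * np.sqrt(expected * (1 - expected) / n)
        assert tf.p == pytest.approx(expected, abs=ci + 0.01)

    def test_total_count_conserved(self, sim_config):
        dist, ledger = generate_fragments(sim_config, 0.1, 500)
        assert dist.total == 500
        assert ledger["n_tumor"] + ledger["n_normal"] == 500

    def test_invalid_n_rejected(self, sim_config):
        with pytest.raises(ValidationError):
            generate_fragments(sim_config, 0.1, 0)


class TestLodExperiment:
    def test_noiseless_detects_every_detectable_fraction(self):
        """With no noise and very deep coverage, the LOD is exactly the
        smallest ladder fraction whose expected log2 ratio clears the
        threshold floor."""
        config = SimulationConfig(
            seed=21, n_genes=150, probes_per_gene=4, n_chromosomes=22,
            n_normals=4, noise_sigma=0.0, target_depth=20_000.0,
        )
        panel = generate_panel(config, gene_names=["ERBB2"])
        spec = SpikeInSpec(
            abcn_by_gene={"ERBB2": 60.0},
            fractions=(0.01, 0.006, 0.003),
            n_pon_sets=2,
        )
        results = run_lod_experiment(spec, config, panel=panel, n_permutations=200)
        assert len(results) == 1
        r = results[0]
        assert r.detections.all()
        assert r.lod_fraction == 0.003
        assert r.lod_effective_copies == pytest.approx(2.174)

    def test_neutral_gene_never_detected(self):
        config = SimulationConfig(
            seed=22, n_genes=150, probes_per_gene=4, n_chromosomes=22,
            n_normals=4, noise_sigma=0.0, target_depth=20_000.0,
        )
        panel = generate_panel(config, gene_names=["ERBB2"])
        # the diploid control sits on a different chromosome than ERBB2
        spec = SpikeInSpec(
            abcn_by_gene={"ERBB2": 60.0, "G075": 2.0},
            fractions=(0.05, 0.01),
            n_pon_sets=2,
        )
        results = {r.gene: r for r in
                   run_lod_experiment(spec, config, panel=panel, n_permutations=200)}
        assert not results["G075"].detections.any()
        assert results["G075"].lod_fraction is None
        assert results["G075"].lod_effective_copies is None
        assert results["ERBB2"].detections.all()

    def test_analytic_lod_fraction_helper(self):
        fractions = (0.05, 0.03, 0.01, 0.003)
        # ERBB2=60 crosses a 0.1 threshold just below 0.3%
        assert analytic_lod_fraction(60.0, 0.1, fractions) == 0.003
        # EGFR=20 crosses between 0.3% and 1%
        assert analytic_lod_fraction(20.0, 0.1, fractions) == 0.01
        assert analytic_lod_fraction(2.0, 0.1, fractions) is None

    def test_detection_matrix_shape_and_determinism(self, sim_config):
        spec = SpikeInSpec(
            abcn_by_gene={"ERBB2": 60.0},
            fractions=(0.05, 0.02),
            n_pon_sets=2,
        )
        panel = generate_panel(sim_config, gene_names=["ERBB2", "EGFR", "MET"])
        r1 = run_lod_experiment(spec, sim_config, panel=panel, n_permutations=200)[0]
        r2 = run_lod_experiment(spec, sim_config, panel=panel, n_permutations=200)[0]
        assert r1.detections.shape == (2, 2)
        assert np.array_equal(r1.detections, r2.detections)
        assert r1.lod_fraction == r2.lod_fraction


class TestConfigValidation:
    def test_descending_fraction_ladder_enforced(self):
        with pytest.raises(ValidationError):
            SpikeInSpec(abcn_by_gene={"A": 60.0}, fractions=(0.01, 0.05))

    def test_fraction_bounds(self):
        with pytest.raises(ValidationError):
            SpikeInSpec(abcn_by_gene={"A": 60.0}, fractions=(1.5,))

    def test_minimum_normals(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_normals=1)
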