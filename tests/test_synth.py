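"""Synthetic-data generator: HWE, determinism, LD, median-split recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from stratgwas import stratify, synth
from stratgwas.firth import scan_stratum
from stratgwas.regions import compute_r2


class TestConfigValidation:
    @pytest.mark.parametrize("maf_range", [(0.0, 0.3), (-0.1, 0.2), (0.3, 0.6), (0.4, 0.2)])
    def test_invalid_maf_range_rejected(self, maf_range):
        with pytest.raises(ValueError, match="maf_range"):
            synth.SimConfig(n_variants=10, maf_range=maf_range)

    def test_causal_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            synth.SimConfig(n_variants=10, causal_effects=[(10, 0.5, 0.5)])

    def test_nonpositive_group_size_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            synth.SimConfig(n_variants=10, samples_per_group=(10, 0, 10, 10))


class TestGenotypes:
    def test_same_seed_reproduces_identical_dataset(self):
        cfg = synth.SimConfig(n_variants=50, samples_per_group=(50, 50, 50, 50),
                              causal_effects=[(0, 0.4, 0.1)], seed=99)
        d1 = synth.simulate_dataset(cfg)
        d2 = synth.simulate_dataset(cfg)
        assert np.array_equal(d1.dosages, d2.dosages)
        pd.testing.assert_frame_equal(d1.samples, d2.samples)
        pd.testing.assert_frame_equal(d1.variants, d2.variants)

    def test_hwe_class_proportions_at_half(self):
        cfg = synth.SimConfig(n_variants=5, maf_range=(0.5, 0.5),
                              samples_per_group=(5000, 5000, 5000, 5000), seed=1)
        g, _ = synth.simulate_genotypes(cfg)
        counts = np.array([(g == k).mean() for k in (0.0, 1.0, 2.0)])
        assert counts == pytest.approx([0.25, 0.5, 0.25], abs=0.01)

    def test_sample_frequency_tracks_binomial_error(self):
        # at maf 0.5 the sample allele frequency is mean of 2n Bernoulli draws
        n_samp = 400
        cfg = synth.SimConfig(n_variants=100, maf_range=(0.5, 0.5),
                              samples_per_group=(100, 100, 100, 100), seed=2)
        g, _ = synth.simulate_genotypes(cfg)
        af = g.mean(axis=1) / 2
        se = math.sqrt(0.5 * 0.5 / (2 * n_samp))
        within = np.abs(af - 0.5) <= 3 * se
        assert within.mean() >= 0.95

    def test_dosages_bounded_with_jitter(self):
        cfg = synth.SimConfig(n_variants=20, samples_per_group=(200, 200, 200, 200),
                              dosage_jitter_sd=0.3, seed=3)
        ds = synth.simulate_dataset(cfg)
        assert ds.dosages.min() >= 0.0 and ds.dosages.max() <= 2.0
        # jitter produces non-integer dosages
        assert np.abs(ds.dosages - np.round(ds.dosages)).max() > 0

    def test_block_ld_decay_gives_expected_r2(self):
        cfg = synth.SimConfig(
            n_variants=10, maf_range=(0.3, 0.3),
            samples_per_group=(5000, 5000, 5000, 5000),
            ld=synth.LDConfig(block_size=10, decay=0.9), seed=4,
        )
        g, _ = synth.simulate_genotypes(cfg)
        r2_adjacent = [compute_r2(g[i], g[i + 1]) for i in range(5)]
        assert np.mean(r2_adjacent) == pytest.approx(0.81, abs=0.03)
        # decay over distance: lag-2 correlation ~ decay^2 -> r2 ~ decay^4
        assert compute_r2(g[0], g[2]) == pytest.approx(0.9**4, abs=0.06)


class TestPhenotypes:
    def test_null_model_leaves_eafs_equal(self, null_dataset):
        ds = null_dataset
        case = ds.samples["status"].to_numpy() == 1
        eaf_case = ds.dosages[:, case].mean(axis=1) / 2
        eaf_ctrl = ds.dosages[:, ~case].mean(axis=1) / 2
        assert np.abs(eaf_case - eaf_ctrl).mean() < 0.02

    def test_null_scan_z_standard_normal(self, null_dataset):
        ds = null_dataset
        out = scan_stratum(ds.dosages, ds.variants, ds.samples)
        z = out["z"].to_numpy()
        assert abs(z.mean()) < 0.15
        assert z.std() == pytest.approx(1.0, abs=0.15)

    def test_causal_variant_enriched_in_cases(self, cfh_like_dataset):
        ds = cfh_like_dataset
        idx = ds.truth[0][0]
        case = ds.samples["status"].to_numpy() == 1
        eaf_case = ds.dosages[idx, case].mean() / 2
        eaf_ctrl = ds.dosages[idx, ~case].mean() / 2
        assert eaf_case > eaf_ctrl + 0.03

    def test_swapping_stratum_labels_swaps_fitted_effects(self):
        base = dict(n_variants=10, maf_range=(0.3, 0.5),
                    samples_per_group=(800, 800, 800, 800), seed=31)
        b_y, b_o = math.log(2.0), math.log(1.2)
        ds = synth.simulate_dataset(
            synth.SimConfig(causal_effects=[(0, b_y, b_o)], **base))
        ds_sw = synth.simulate_dataset(
            synth.SimConfig(causal_effects=[(0, b_o, b_y)], **base))

        def stratum_betas(ds):
            ya, yo, _ = stratify.median_split(ds.samples)
            scans = stratify.scan_strata(ds.dosages, ds.variants, ds.samples, (ya, yo))
            return (scans["younger"]["beta"].iloc[0], scans["older"]["beta"].iloc[0])

        by1, bo1 = stratum_betas(ds)
        by2, bo2 = stratum_betas(ds_sw)
        assert by1 > bo1 and bo2 > by2
        assert by1 == pytest.approx(bo2, abs=0.15)
        assert bo1 == pytest.approx(by2, abs=0.15)

    def test_median_split_recovers_template_group_sizes(self):
        # group-size template of the motivating study design
        cfg = synth.SimConfig(n_variants=1,
                              samples_per_group=(7959, 9072, 7934, 8653), seed=5)
        ds = synth.simulate_dataset(cfg)
        _, _, labels = stratify.median_split(ds.samples)
        case = ds.samples["status"] == 1
        assert ((labels == "younger") & case).sum() == 7959
        assert ((labels == "younger") & ~case).sum() == 9072
        assert ((labels == "older") & case).sum() == 7934
        assert ((labels == "older") & ~case).sum() == 8653

    def test_unattainable_split_rejected(self):
        # the younger side must hold the pooled median
        cfg = synth.SimConfig(n_variants=1, samples_per_group=(10, 50, 90, 50), seed=6)
        with pytest.raises(ValueError, match="median split"):
            synth.simulate_dataset(cfg)

    def test_unattainable_quota_fails_explicitly(self):
        # overwhelming protective effect makes cases vanishingly rare
        cfg = synth.SimConfig(n_variants=1, maf_range=(0.5, 0.5),
                              samples_per_group=(200, 50, 200, 50),
                              causal_effects=[(0, -15.0, -15.0)],
                              prevalence=0.01, seed=7)
        with pytest.raises(RuntimeError, match="quota"):
            synth.simulate_phenotypes(
                np.zeros((1, cfg.n_samples)),
                pd.DataFrame({"variant_id": ["v1"], "maf": [0.5]}),
                cfg, max_batches=3)

    def test_sex_axis_assigns_groups_to_sexes(self):
        cfg = synth.SimConfig(n_variants=5, axis="sex",
                              samples_per_group=(300, 300, 200, 200), seed=8)
        ds = synth.simulate_dataset(cfg)
        _, _, labels = stratify.sex_split(ds.samples)
        assert (labels == "female").sum() == 600
        assert (labels == "male").sum() == 400
        assert (ds.samples.loc[labels == "female", "sex"] == "F").all()
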