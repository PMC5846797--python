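"""Clumping, LD r^2, conditional analysis and locus definition."""

import math

import numpy as np
import pandas as pd
import pytest

from stratgwas import regions, stratify, synth


def sig_frame(rows):
    return pd.DataFrame(rows, columns=["variant_id", "chr", "pos", "p"])


class TestClump:
    def test_within_window_forms_one_cluster(self):
        clusters = regions.clump(sig_frame([
            ("a", "1", 1_000_000, 1e-10), ("b", "1", 5_000_000, 1e-9)]))
        assert len(clusters) == 1
        assert clusters[0].lead == "a"
        assert set(clusters[0].members) == {"a", "b"}

    def test_beyond_window_splits(self):
        clusters = regions.clump(sig_frame([
            ("a", "1", 1_000_000, 1e-10), ("b", "1", 26_000_000, 1e-9)]))
        assert [c.lead for c in clusters] == ["a", "b"]

    def test_greedy_absorption_order(self):
        # 0/8/16 Mb with P 1e-12 / 1e-9 / 1e-11: best lead absorbs the middle,
        # the far variant seeds its own cluster
        clusters = regions.clump(sig_frame([
            ("a", "1", 1, 1e-12), ("b", "1", 8_000_001, 1e-9),
            ("c", "1", 16_000_001, 1e-11)]))
        leads = {c.lead: set(c.members) for c in clusters}
        assert set(leads) == {"a", "c"}
        assert leads["a"] == {"a", "b"}
        assert leads["c"] == {"c"}

    def test_chromosomes_never_merge(self):
        clusters = regions.clump(sig_frame([
            ("a", "1", 1_000_000, 1e-10), ("b", "2", 1_000_000, 1e-9)]))
        assert len(clusters) == 2

    def test_empty_input_empty_output(self):
        assert regions.clump(sig_frame([])) == []

    def test_members_within_window_and_no_smaller_p_than_lead(self):
        rng = np.random.default_rng(0)
        n = 200
        df = sig_frame(list(zip(
            [f"v{i}" for i in range(n)],
            rng.choice(["1", "2"], size=n),
            rng.integers(1, 60_000_000, size=n),
            10.0 ** rng.uniform(-30, -8, size=n),
        )))
        clusters = regions.clump(df)
        by_id = df.set_index("variant_id")
        for c in clusters:
            lead_p = by_id.loc[c.lead, "p"]
            lead_pos = by_id.loc[c.lead, "pos"]
            for m in c.members:
                assert by_id.loc[m, "p"] >= lead_p
                assert abs(by_id.loc[m, "pos"] - lead_pos) <= 10_000_000
                assert by_id.loc[m, "chr"] == by_id.loc[c.lead, "chr"]


class TestComputeR2:
    def test_identical_vectors(self):
        g = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        assert regions.compute_r2(g, g) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        a = np.array([1.0, -1.0, 1.0, -1.0]) + 1.0
        b = np.array([1.0, 1.0, -1.0, -1.0]) + 1.0
        assert regions.compute_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_reported_zero_with_warning(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            assert regions.compute_r2(np.zeros(5), np.arange(5.0)) == 0.0


def _ld_dataset(causal, seed, n_variants=12, decay=0.9):
    cfg = synth.SimConfig(
        n_variants=n_variants, maf_range=(0.3, 0.3),
        samples_per_group=(1500, 1500, 1500, 1500),
        causal_effects=causal,
        ld=synth.LDConfig(block_size=n_variants, decay=decay),
        seed=seed,
    )
    return synth.simulate_dataset(cfg)


class TestConditionalScan:
    def _masks(self, ds):
        ya, yo, labels = stratify.median_split(ds.samples)
        return {"younger": (labels == "younger").to_numpy(),
                "older": (labels == "older").to_numpy()}

    def test_single_causal_yields_no_secondary_signal(self):
        b = math.log(2.3)
        ds = _ld_dataset([(5, b, b)], seed=41)
        leads, res = regions.conditional_scan(
            ds.variants, ds.dosages, ds.samples, self._masks(ds), "v000006")
        assert leads == ["v000006"]
        if len(res):
            assert res["p_joint"].min() >= 5e-8

    def test_two_independent_causals_recovered(self):
        b1, b2 = math.log(2.5), math.log(2.2)
        # causals at block ends: r ~ 0.9^11, effectively independent
        ds = _ld_dataset([(0, b1, b1), (11, b2, b2)], seed=42)
        leads, _ = regions.conditional_scan(
            ds.variants, ds.dosages, ds.samples, self._masks(ds), "v000001")
        assert leads[0] == "v000001"
        assert len(leads) == 2
        # second signal found near the other causal
        assert int(leads[1][1:]) >= 9

    def test_lead_itself_skipped_as_collinear(self):
        ds = _ld_dataset([], seed=43, n_variants=6)
        leads, res = regions.conditional_scan(
            ds.variants, ds.dosages, ds.samples, self._masks(ds), "v000003")
        assert leads == ["v000003"]
        assert "v000003" not in set(res.get("variant_id", []))

    def test_unknown_lead_rejected(self):
        ds = _ld_dataset([], seed=44, n_variants=4)
        with pytest.raises(ValueError, match="not among region variants"):
            regions.conditional_scan(
                ds.variants, ds.dosages, ds.samples, self._masks(ds), "nope")


class TestDefineLocus:
    def _singleton(self, lead_pos, chrom, gene_table):
        variants = pd.DataFrame({
            "variant_id": ["lead"], "chr": chrom, "pos": [lead_pos],
            "ea": "A", "oa": "G",
        })
        dosages = np.array([[0.0, 1.0, 2.0, 1.0]])
        return regions.define_locus("lead", variants, dosages, gene_table)

    def test_no_correlated_partner_gives_lead_pm_500kb(self):
        locus = self._singleton(2_000_000, "7", None)
        assert locus.boundaries == (1_500_000, 2_500_000)
        assert locus.correlated == ["lead"]

    def test_boundaries_floored_at_one(self):
        locus = self._singleton(100, "7", None)
        assert locus.boundaries[0] == 1

    def test_correlated_partners_extend_boundaries(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, size=500).astype(float)
        variants = pd.DataFrame({
            "variant_id": ["left", "lead", "right", "far"],
            "chr": "7",
            "pos": [1_800_000, 2_000_000, 2_200_000, 3_000_000],
            "ea": "A", "oa": "G",
        })
        noise = rng.binomial(2, 0.4, size=500).astype(float)
        dosages = np.vstack([g, g, g, noise])
        locus = regions.define_locus("lead", variants, dosages, None)
        assert set(locus.correlated) == {"left", "lead", "right"}
        assert locus.boundaries == (1_300_000, 2_700_000)

    def test_published_locus_gene_counts(self, gene_table):
        # follow-up loci on chr15 and chr18 overlap 5 and 6 annotated genes
        chr15 = self._singleton(89_760_997, "15", gene_table)
        chr18 = self._singleton(597_950, "18", gene_table)
        assert len(chr15.genes) == 5
        assert len(chr18.genes) == 6
        assert "RLBP1" in chr15.genes and "CLUL1" in chr18.genes
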