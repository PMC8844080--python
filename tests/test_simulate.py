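"""Generator determinism, truth-layer structure, and the observation model."""

import numpy as np
import pandas as pd
import pytest

from methcross.epivariation import classify_pairs
from methcross.simulate import (
    FeedbackParams,
    GenomeSpec,
    apply_genotype,
    assign_wildtype_truth,
    build_genome,
    draw_epi_loss,
    draw_met1_retention,
    emit_reads,
    establishment_efficiency,
    genome_mean_mcg,
    global_gain,
    Lineage,
    simulate_scenario,
    write_scenario,
)
from .conftest import TINY_SPEC


class TestBuildGenome:
    def test_deterministic_for_fixed_seed(self, tmp_path):
        r1 = simulate_scenario("met1_f1", 5, genome_spec=GenomeSpec(n_genes=40, n_te_genes=20))
        r2 = simulate_scenario("met1_f1", 5, genome_spec=GenomeSpec(n_genes=40, n_te_genes=20))
        pd.testing.assert_frame_equal(r1.genome.annotations, r2.genome.annotations)
        pd.testing.assert_frame_equal(r1.samples["WT"], r2.samples["WT"])
        # byte-identical on disk too
        p1, p2 = write_scenario(r1, tmp_path / "a"), write_scenario(r2, tmp_path / "b")
        assert (tmp_path / "a" / "annotations.bed").read_bytes() == (
            tmp_path / "b" / "annotations.bed"
        ).read_bytes()

    def test_te_gene_free_genome(self):
        g = build_genome(GenomeSpec(n_genes=30, n_te_genes=0), 1)
        assert (g.annotations["region_class"] == "gene").all()

    def test_short_te_fraction_present(self):
        g = build_genome(GenomeSpec(n_genes=10, n_te_genes=200, te_short_fraction=0.2), 2)
        te_len = g.annotations.loc[g.annotations["region_class"] == "te_gene", "length"]
        assert (te_len < 1000).mean() == pytest.approx(0.2, abs=0.05)

    def test_site_density_law_of_large_numbers(self):
        spec = GenomeSpec(n_chrom=1, n_genes=400, n_te_genes=100)
        g = build_genome(spec, 3)
        span = g.sites["pos"].max()  # ~1.4 Mb of tiled regions+gaps
        assert span > 1_000_000
        for ctx, dens in spec.densities().items():
            realized = (g.sites["context"] == ctx).sum() / span
            assert realized == pytest.approx(dens, rel=0.05)

    def test_regions_do_not_overlap(self):
        g = build_genome(TINY_SPEC, 4)
        for _, sub in g.annotations.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


class TestTruthLayers:
    @pytest.fixture(scope="class")
    def genome(self):
        return build_genome(GenomeSpec(n_genes=400, n_te_genes=150), 7)

    def test_te_mcg_exceeds_gene_mcg_across_seeds(self):
        spec = GenomeSpec(n_genes=150, n_te_genes=80)
        for seed in range(20):
            g = build_genome(spec, seed)
            wt = assign_wildtype_truth(g, seed)
            te = g.attrs.loc[g.attrs["region_class"] == "te_gene", "region_id"]
            gene = g.attrs.loc[g.attrs["region_class"] == "gene", "region_id"]
            assert wt.loc[te, "CG"].mean() > wt.loc[gene, "CG"].mean()

    def test_gbm_fraction_zero_leaves_genes_unmethylated(self):
        g = build_genome(GenomeSpec(n_genes=200, n_te_genes=0, gbm_fraction=0.0, misannotated_fraction=0.0), 8)
        wt = assign_wildtype_truth(g, 8)
        assert wt["CG"].mean() < 0.05

    def test_misannotated_fraction_planted(self):
        g = build_genome(GenomeSpec(n_genes=2000, n_te_genes=0, misannotated_fraction=0.05), 9)
        wt = assign_wildtype_truth(g, 9)
        assert (wt["CHG"] > 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_truth_proportions_bounded_after_every_composition(self, genome):
        wt = assign_wildtype_truth(genome, 7)
        params = FeedbackParams()
        lineage = Lineage(retention=draw_met1_retention(genome, params, 7))
        lineage.epi_retention["Mi_1"] = draw_epi_loss(genome, params, 7, "Mi_1")
        params2 = FeedbackParams(m_ref=genome_mean_mcg(wt, genome.attrs))
        for g, kw in [
            ("WT", {}), ("met1", {}), ("cc", {}), ("mcc", {}), ("F1", {}), ("mF1", {}),
            ("ibm1", {"generation": 3}), ("mi", {}), ("Mi_1", {}), ("ddm1", {}), ("ddm1_ibm1", {}),
        ]:
            t = apply_genotype(wt, g, genome, params2, 7, lineage=lineage, **kw)
            assert ((t[["CG", "CHG", "CHH"]] >= 0) & (t[["CG", "CHG", "CHH"]] <= 1)).all().all()

    def test_gate_zeroes_establishment_exactly(self, genome):
        wt = assign_wildtype_truth(genome, 7)
        params = FeedbackParams(m_ref=genome_mean_mcg(wt, genome.attrs))
        lineage = Lineage(retention=draw_met1_retention(genome, params, 7))
        mf1 = apply_genotype(wt, "mF1", genome, params, 7, lineage=lineage)
        te = genome.attrs.loc[genome.attrs["region_class"] == "te_gene", "region_id"]
        gated = te[(mf1.loc[te, "CG"] < params.c_min).to_numpy()]
        assert len(gated) > 0
        assert (mf1.loc[gated, ["CHG", "CHH"]] == 0).all().all()

    def test_gain_closed_form(self):
        params = FeedbackParams(gamma=1.0, m_ref=0.2)
        assert global_gain(0.1, params) == pytest.approx(2.0)
        assert global_gain(0.2, FeedbackParams(gamma=0.0, m_ref=0.2)) == pytest.approx(1.0)

    def test_efficiency_monotone_and_gated(self):
        params = FeedbackParams()
        m = np.linspace(0, 1, 101)
        e = establishment_efficiency(m, params)
        assert (np.diff(e) >= 0).all()
        assert (e[m < params.c_min] == 0).all()
        assert e[-1] == 1.0
        assert (establishment_efficiency(m, FeedbackParams(feedback="none")) == 1).all()

    def test_unknown_genotype_rejected(self, genome):
        wt = assign_wildtype_truth(genome, 7)
        with pytest.raises(ValueError, match="unknown genotype"):
            apply_genotype(wt, "xyz", genome, FeedbackParams(m_ref=0.3), 7)


class TestEmitReads:
    @pytest.fixture(scope="class")
    def genome(self):
        return build_genome(GenomeSpec(n_genes=60, n_te_genes=30), 13)

    def _flat_truth(self, genome, p):
        ids = genome.attrs["region_id"].to_numpy()
        return pd.DataFrame({"CG": p, "CHG": p, "CHH": p}, index=ids)

    def test_fully_unmethylated_without_nonconversion(self, genome):
        reads = emit_reads(genome, self._flat_truth(genome, 0.0), "s", 1,
                           epsilon_nonconv=0.0, background=0.0)
        assert reads["n_meth"].sum() == 0

    def test_fully_methylated_without_overconversion(self, genome):
        reads = emit_reads(genome, self._flat_truth(genome, 1.0), "s", 1,
                           epsilon_overconv=0.0, background=1.0)
        assert reads["n_unmeth"].sum() == 0

    def test_region_level_tracks_observed_proportion(self, met1_f1_small):
        """Estimated weighted level within 3 binomial SEs of p_obs."""
        res = met1_f1_small
        truth = res.truth["WT"]
        counts = res.region_counts("WT")
        eps_n, eps_o = 0.005, 0.002
        sub = counts[(counts["context"] == "CHG") & (counts["n_total"] > 500)]
        for row in sub.itertuples(index=False):
            p_true = truth.loc[row.region_id, "CHG"]
            p_obs = p_true * (1 - eps_o) + (1 - p_true) * eps_n
            se = np.sqrt(max(p_obs * (1 - p_obs), 1e-6) / row.n_total)
            assert abs(row.level - p_obs) < 3.5 * se + 1e-3

    def test_invalid_coverage_rejected(self, genome):
        with pytest.raises(ValueError):
            emit_reads(genome, self._flat_truth(genome, 0.5), "s", 1, coverage_lambda=0)


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            simulate_scenario("nope", 1)

    def test_replicates_share_truth_but_differ_in_reads(self, met1_f1_small):
        res = met1_f1_small
        assert res.sample_genotype["mF1_rep1"] == res.sample_genotype["mF1_rep2"] == "mF1"
        r1, r2 = res.samples["mF1_rep1"], res.samples["mF1_rep2"]
        assert not r1["n_meth"].equals(r2["n_meth"])

    def test_no_feedback_decouples_recovery_from_mcg(self):
        res = simulate_scenario("no_feedback", 3, genome_spec=TINY_SPEC)
        te = res.te_set()
        mf1 = res.truth["mF1"]
        wt = res.truth["WT"]
        # truth recovery ratio is mCG-independent: correlation with mCG ~ 0
        ratio = (mf1.loc[te, "CHG"] / wt.loc[te, "CHG"]).to_numpy()
        mcg = mf1.loc[te, "CG"].to_numpy()
        assert abs(np.corrcoef(ratio, mcg)[0, 1]) < 0.25

    def test_global_scale_pair_shares_reference(self):
        res = simulate_scenario("global_scale_pair", 4, genome_spec=TINY_SPEC)
        assert res.truth["ibm1_scaled"].attrs["gain"] > 1.5
        assert res.truth["ibm1_ref"].attrs["gain"] == pytest.approx(1.0)

    def test_sibling_classification_accuracy_rises_with_coverage(self):
        spec = GenomeSpec(n_genes=150, n_te_genes=20)
        acc = []
        for cov in (0.5, 2.0, 10.0):  # sparse coverage so estimation error matters
            per_seed = []
            for seed in (6, 7, 8):
                res = simulate_scenario("mi_siblings", seed, genome_spec=spec, coverage=cov)
                genes = res.gene_set()
                mcg_a = res.levels("Mi_1", "CG").reindex(genes)
                mcg_b = res.levels("Mi_2", "CG").reindex(genes)
                classes, _ = classify_pairs(mcg_a, mcg_b)
                ta = res.truth["Mi_1"]["CG"].reindex(classes.index)
                tb = res.truth["Mi_2"]["CG"].reindex(classes.index)
                truth_label = np.select(
                    [(ta > 0.05) & (tb > 0.05), (ta <= 0.05) & (tb <= 0.05), (ta > 0.05) & (tb <= 0.05)],
                    ["common_methylated", "common_hypomethylated", "specific_A"],
                    "specific_B",
                )
                per_seed.append((classes["label"] == truth_label).mean())
            acc.append(np.mean(per_seed))
        assert acc[0] <= acc[1] <= acc[2]
        assert acc[2] > acc[0]

    def test_expression_silencing_direction(self, met1_f1_small):
        """Restored methylation silences TE genes in the expression model."""
        res = met1_f1_small
        expr = res.expression
        te = res.te_set()
        by_geno = expr[expr["region_id"].isin(te)].groupby("genotype")["rpkm"].median()
        assert by_geno["mcc"] > by_geno["WT"]  # demethylated TEs derepressed
        assert by_geno["mF1"] < by_geno["mcc"]  # recovery re-silences
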