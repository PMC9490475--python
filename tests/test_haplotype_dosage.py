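"""Promoter classification, enhancer conditioning and risk-dosage tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haploloop.haplotype_dosage import (
    PromoterClass,
    classify_promoter,
    composite_haplotypes,
    condition_enhancer_labels,
    haplotype_frequencies,
    multilocus_genotypes,
    promoter_classes,
    relabel_a_as_n,
    risk_dosage_analysis,
)
from haploloop.synthetic_data import (
    ExpressionSpec,
    PanelSpec,
    simulate_expression,
    simulate_panel,
)

RISK = "CCCCTTAAACA"
NONRISK = "TGTACCGGGTG"


class TestClassifyPromoter:
    @pytest.mark.parametrize(
        "haplotype,expected",
        [
            (RISK, PromoterClass.RISK),
            (NONRISK, PromoterClass.NONRISK),
            ("TGTACCGGGTA", PromoterClass.IDIOSYNCRATIC),
        ],
    )
    def test_exact_match_classification(self, blk_cs11, haplotype, expected):
        assert classify_promoter(haplotype, blk_cs11) is expected

    def test_length_mismatch_is_error(self, blk_cs11):
        with pytest.raises(ValueError):
            classify_promoter("ACGT", blk_cs11)


class TestHaplotypeFrequencies:
    def test_reference_cohort_counts_round_to_printed_percentages(
        self, frequency_panel, blk_cs11
    ):
        freqs = haplotype_frequencies(frequency_panel, blk_cs11).set_index("class")
        assert freqs.loc["NonRisk", "count"] == 725
        assert freqs.loc["Risk", "count"] == 243
        assert freqs.loc["Idiosyncratic", "count"] == 38
        assert freqs.loc["NonRisk", "percent"] == 72
        assert freqs.loc["Risk", "percent"] == 24
        assert freqs.loc["NonRisk", "fraction"] + freqs.loc[
            "Risk", "fraction"
        ] == pytest.approx(968 / 1006)

    def test_counts_sum_to_two_per_sample(self, frequency_panel, blk_cs11):
        freqs = haplotype_frequencies(frequency_panel, blk_cs11)
        assert freqs["count"].sum() == 2 * frequency_panel.n_samples
        assert abs(freqs["percent"].sum() - 100) <= 1

    def test_simulated_counts_match_truth_table_exactly(self, blk_cs11):
        panel, truth = simulate_panel(PanelSpec(seed=31, n_individuals=150))
        freqs = haplotype_frequencies(panel, blk_cs11).set_index("class")
        prom = truth[truth.region == "P"].label.value_counts()
        assert freqs.loc["NonRisk", "count"] == prom.get("N", 0)
        assert freqs.loc["Risk", "count"] == prom.get("R", 0)
        assert freqs.loc["Idiosyncratic", "count"] == prom.get("A", 0)

    def test_sample_permutation_invariance(self, blk_cs11):
        panel, _ = simulate_panel(PanelSpec(seed=32, n_individuals=60))
        from haploloop.core_io import HaplotypePanel

        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n_samples)
        shuffled = HaplotypePanel(
            panel.variants,
            [panel.samples[i] for i in perm],
            panel.alleles[perm],
        )
        a = haplotype_frequencies(panel, blk_cs11)
        b = haplotype_frequencies(shuffled, blk_cs11)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_snp_is_error(self, frequency_panel, blk_cs11):
        smaller = frequency_panel.subset(variant_ids=list(blk_cs11.snps[:-1]))
        with pytest.raises(ValueError, match="cs11_11"):
            haplotype_frequencies(smaller, blk_cs11)


class TestConditioning:
    def test_uniform_enhancer_string_defines_risk_haplotype(self, blk_cs11):
        panel, _ = simulate_panel(
            PanelSpec(seed=33, n_individuals=80, ld_coupling=1.0)
        )
        from haploloop.haplotype_dosage import load_blk_regions

        regions = load_blk_regions()
        pclasses = promoter_classes(panel, blk_cs11)
        labels, defs = condition_enhancer_labels(
            panel, pclasses, regions.by_role("enhancer")
        )
        # full coupling: every prom-R chromosome carries the enhancer R string
        risk_chroms = {
            ch for ch, c in pclasses.items() if c is PromoterClass.RISK
        }
        for region in ("E1", "E2", "E3"):
            sub = labels[labels.region == region]
            lab = {(r["sample"], r["hap"]): r["label"] for _, r in sub.iterrows()}
            assert all(lab[ch] == "R" for ch in risk_chroms)
            assert defs[region]["R"] != defs[region]["N"]

    def test_conditional_frequency_tracks_ld_coupling(self, blk_cs11):
        spec = PanelSpec(seed=34, n_individuals=400, ld_coupling=0.7)
        panel, truth = simulate_panel(spec)
        from haploloop.haplotype_dosage import load_blk_regions

        pclasses = promoter_classes(panel, blk_cs11)
        labels, _ = condition_enhancer_labels(
            panel, pclasses, load_blk_regions().by_role("enhancer")
        )
        # P(E3-R | prom-R) = coupling + (1 - coupling) * marginal R freq
        c = spec.ld_coupling
        expected = c + (1 - c) * spec.main_haplotype_freqs["E3"]["R"]
        risk = {ch for ch, v in pclasses.items() if v is PromoterClass.RISK}
        e3 = labels[labels.region == "E3"]
        on_risk = e3[[(s, h) in risk for s, h in zip(e3["sample"], e3["hap"])]]
        observed = (on_risk.label == "R").mean()
        n = len(on_risk)
        assert abs(observed - expected) <= 3 * np.sqrt(expected * (1 - expected) / n)

    def test_labels_agree_with_generator_truth_without_idiosyncrasy(self, blk_cs11):
        # no idiosyncratic haplotypes: every label must match the truth table
        spec = PanelSpec(
            seed=35,
            n_individuals=120,
            main_haplotype_freqs={
                "P": {"N": 0.72, "R": 0.28},
                "E1": {"N": 0.6, "R": 0.4},
                "E2": {"N": 0.6, "R": 0.4},
                "E3": {"N": 0.6, "R": 0.4},
            },
        )
        panel, truth = simulate_panel(spec)
        from haploloop.haplotype_dosage import load_blk_regions

        pclasses = promoter_classes(panel, blk_cs11)
        labels, _ = condition_enhancer_labels(
            panel, pclasses, load_blk_regions().by_role("enhancer")
        )
        merged = labels.merge(
            truth, on=["sample", "hap", "region"], suffixes=("", "_truth")
        )
        assert (merged.label == merged.label_truth).all()

    def test_empty_conditioning_class_is_error(self, blk_cs11):
        spec = PanelSpec(
            seed=36,
            n_individuals=30,
            main_haplotype_freqs={
                "P": {"N": 1.0, "R": 0.0},  # no prom-R chromosomes at all
                "E1": {"N": 0.6, "R": 0.4},
                "E2": {"N": 0.6, "R": 0.4},
                "E3": {"N": 0.6, "R": 0.4},
            },
        )
        panel, _ = simulate_panel(spec)
        from haploloop.haplotype_dosage import load_blk_regions

        pclasses = promoter_classes(panel, blk_cs11)
        with pytest.raises(ValueError):
            condition_enhancer_labels(
                panel, pclasses, load_blk_regions().by_role("enhancer")
            )


class TestMultilocusGenotypes:
    def test_canonical_sorting(self):
        comp = {(0, 0): "RNRN", (0, 1): "NNNN"}
        assert multilocus_genotypes(comp, 1) == {0: "NNNN/RNRN"}

    def test_homozygous_genotype(self):
        comp = {(0, 0): "NNNN", (0, 1): "NNNN"}
        assert multilocus_genotypes(comp, 1) == {0: "NNNN/NNNN"}

    def test_promoter_e3_projection(self):
        comp = {(0, 0): "RXXR".replace("X", "N"), (0, 1): "NAAN"}
        out = multilocus_genotypes(comp, 1, projection=(0, 3))
        assert out == {0: "NN/RR"}

    def test_samples_with_excluded_chromosome_omitted(self):
        comp = {(0, 0): "NNNN"}  # hap 1 excluded upstream
        assert multilocus_genotypes(comp, 1) == {}


class TestRiskDosage:
    def test_welch_t_matches_closed_form(self):
        a = [10.1, 9.8, 10.5, 10.0, 10.3]
        b = [9.2, 9.5, 9.1, 9.6, 9.0]
        genotypes = {f"a{i}": "NN/NN" for i in range(5)}
        genotypes.update({f"b{i}": "RR/RR" for i in range(5)})
        expr = pd.Series(
            dict(zip([f"a{i}" for i in range(5)], a))
            | dict(zip([f"b{i}" for i in range(5)], b))
        )
        res = risk_dosage_analysis(genotypes, expr, contrasts=[("NN/NN", "RR/RR")])
        row = res.contrasts.iloc[0]
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / 5, np.var(b, ddof=1) / 5
        t = (ma - mb) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        p = stats.t.sf(t, df)
        assert row.t == pytest.approx(t, abs=1e-10)
        assert row.p_one_sided == pytest.approx(p, abs=1e-10)

    def test_identical_groups_give_t_zero_p_half(self):
        vals = [10.0, 11.0, 9.0, 10.5]
        genotypes = {f"a{i}": "NN/NN" for i in range(4)}
        genotypes.update({f"b{i}": "NR/NR" for i in range(4)})
        expr = pd.Series(
            dict(zip([f"a{i}" for i in range(4)], vals))
            | dict(zip([f"b{i}" for i in range(4)], vals))
        )
        res = risk_dosage_analysis(genotypes, expr, contrasts=[("NN/NN", "NR/NR")])
        assert res.contrasts.iloc[0].t == pytest.approx(0.0, abs=1e-12)
        assert res.contrasts.iloc[0].p_one_sided == pytest.approx(0.5)

    def test_small_group_contrast_skipped(self):
        genotypes = {"a": "NN/NN", "b": "RR/RR", "c": "RR/RR"}
        expr = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        res = risk_dosage_analysis(genotypes, expr, contrasts=[("NN/NN", "RR/RR")])
        assert res.contrasts.empty

    def test_risk_dosage_counts_r_labels(self):
        genotypes = {"x": "RNRN/NNNN", "y": "RRRR/RRRR"}
        expr = pd.Series({"x": 1.0, "y": 2.0})
        res = risk_dosage_analysis(genotypes, expr)
        assert res.risk_dosage["x"] == 2
        assert res.risk_dosage["y"] == 8

    def test_dosage_trend_follows_negative_beta(self, blk_cs11):
        spec = PanelSpec(seed=44, n_individuals=344, ld_coupling=0.8)
        panel, truth = simulate_panel(spec)
        beta = {"P": -0.5, "E1": -0.5, "E2": -0.5, "E3": -0.5}
        expr = simulate_expression(
            truth, ExpressionSpec(seed=45, mu=10.0, beta=beta, sigma=0.1)
        ).set_index("sample")["expression"]
        from haploloop.haplotype_dosage import load_blk_regions

        pclasses = promoter_classes(panel, blk_cs11)
        labels, _ = condition_enhancer_labels(
            panel, pclasses, load_blk_regions().by_role("enhancer")
        )
        comp = composite_haplotypes(pclasses, labels, ["P", "E1", "E2", "E3"])
        genos = {
            panel.samples[s]: g
            for s, g in multilocus_genotypes(comp, panel.n_samples).items()
        }
        res = risk_dosage_analysis(genos, expr)
        trend = res.dosage_groups[res.dosage_groups.n >= 3]
        assert len(trend) >= 5
        assert (np.diff(trend["mean"].values) < 0).all()

    def test_relabeling_a_as_n_changes_only_a_carriers(self):
        genotypes = {"x": "NNNN/RARN", "y": "NNNN/RNRN"}
        relabeled = relabel_a_as_n(genotypes)
        assert relabeled["y"] == genotypes["y"]
        assert relabeled["x"] == "NNNN/RNRN"
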