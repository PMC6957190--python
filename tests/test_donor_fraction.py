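"""Donor-fraction estimator tests: exactness, QC gates, inference."""

import numpy as np
import pandas as pd
import pytest

import allofrac as af
from allofrac import (
    DfResult,
    GenotypeCall,
    McConfig,
    QcThresholds,
    QgtSample,
    SnpPanel,
    SnpTarget,
    classify_risk,
    compute_rcv,
    compute_skew,
    estimate_df_method1,
    estimate_df_method2,
    per_target_minor_fraction,
)
from allofrac.donor_fraction import apply_qc, read_genotypes_csv, read_sample_csv

from conftest import genotype_maps, make_noiseless_sample

HOM_REF = GenotypeCall.HOM_REF
HET = GenotypeCall.HET
HOM_VAR = GenotypeCall.HOM_VAR


def sample_from_fractions(fractions, total=100.0):
    """QgtSample with HOM_REF recipient and the given alt fractions."""
    records = pd.DataFrame({
        "target_id": [f"S{i}" for i in range(len(fractions))],
        "replicate": 1,
        "ref_quantity": [total * (1 - f) for f in fractions],
        "alt_quantity": [total * f for f in fractions],
    })
    return QgtSample(sample_id="x", records=records, rnasep_log_value=9.0)


def make_panel(n):
    return SnpPanel([SnpTarget(f"S{i}", "A", "C", 0.5) for i in range(n)])


class TestPerTargetMinorFraction:
    def test_hom_ref_recipient(self):
        assert per_target_minor_fraction(99.5, 0.5, HOM_REF) == pytest.approx(0.005)

    def test_hom_var_recipient_symmetric(self):
        assert per_target_minor_fraction(0.5, 99.5, HOM_VAR) == pytest.approx(0.005)

    def test_het_recipient_uninformative(self):
        assert per_target_minor_fraction(50.0, 50.0, HET) is None

    def test_zero_total_excluded(self):
        assert per_target_minor_fraction(0.0, 0.0, HOM_REF) is None


class TestRobustCv:
    def test_constant_estimates(self):
        assert compute_rcv([0.01, 0.01, 0.01]) == 0.0

    def test_single_outlier_ignored(self):
        assert compute_rcv([1.0, 1.0, 1.0, 100.0]) == 0.0

    def test_dispersed_estimates(self):
        # median 0.015, MAD 0.0095 -> 100 * 1.4826 * 0.0095 / 0.015
        assert compute_rcv([0.001, 0.01, 0.02, 0.04]) == pytest.approx(
            93.898, abs=1e-3)

    def test_requires_two_estimates(self):
        with pytest.raises(ValueError):
            compute_rcv([0.01])

    def test_zero_median_undefined(self):
        with pytest.raises(ValueError):
            compute_rcv([0.0, 0.0, 0.0])


class TestSkew:
    def test_symmetric_estimates(self):
        assert compute_skew([0.009, 0.010, 0.011]) == pytest.approx(1.0)

    def test_upper_tail_raises_ratio(self):
        assert compute_skew([0.01, 0.01, 0.01, 0.05]) > 1.01

    def test_single_estimate_errors(self):
        with pytest.raises(ValueError):
            compute_skew([0.01])

    def test_zeros_trimmed(self):
        with_zeros = compute_skew([0.0, 0.009, 0.010, 0.011])
        assert with_zeros == compute_skew([0.009, 0.010, 0.011])

    def test_related_cohort_scores_higher(self, panel):
        """Relatedness distorts the per-target estimates, raising mean skew."""
        def mean_skew(relatedness, seed):
            cfg = af.SimConfig(seed=seed, df_true=0.05, relatedness=relatedness)
            samples, truths = af.simulate_cohort(
                12, [0.05] * 12, cfg, panel, seed=seed)
            skews = []
            for s, t in zip(samples, truths):
                rec, don = genotype_maps(panel, t.recipient, t.donor)
                r = estimate_df_method1(s, rec, don, panel)
                if r.skew is not None:
                    skews.append(r.skew)
            return float(np.mean(skews))

        assert mean_skew(0.5, 61) > mean_skew(0.0, 61)


class TestRiskClassification:
    def test_low_probability(self):
        call = classify_risk(0.0012)
        assert call.classification == "low_probability"

    def test_increased_probability(self):
        assert classify_risk(0.0104).classification == "increased_probability"

    def test_boundary_is_positive(self):
        assert classify_risk(0.0032).classification == "increased_probability"

    def test_below_loq_annotation(self):
        assert classify_risk(0.0010).below_loq
        assert not classify_risk(0.0030).below_loq

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(-0.001)


class TestQcGates:
    def make_result(self, **over):
        base = dict(sample_id="x", method="with_donor", df=0.01,
                    n_informative=30, n_quantifiable=72, n_calibrator_pass=80,
                    rcv=40.0, skew=1.0)
        base.update(over)
        return DfResult(**base)

    def make_sample(self, rnasep=9.0):
        return QgtSample(
            sample_id="x",
            records=pd.DataFrame({
                "target_id": ["S0"], "replicate": [1],
                "ref_quantity": [99.0], "alt_quantity": [1.0]}),
            rnasep_log_value=rnasep)

    def test_all_gates_pass(self):
        result = apply_qc(self.make_sample(), self.make_result())
        assert result.qc_pass and result.qc_reasons == []

    def test_rnasep_out_of_range(self):
        result = apply_qc(self.make_sample(rnasep=7.5), self.make_result())
        assert not result.qc_pass
        assert result.qc_reasons == ["rnasep_range"]

    def test_excess_skew(self):
        result = apply_qc(self.make_sample(), self.make_result(skew=1.05))
        assert result.qc_reasons == ["skew"]

    def test_too_few_informative(self):
        result = apply_qc(self.make_sample(), self.make_result(n_informative=10))
        assert result.qc_reasons == ["informative_targets"]

    def test_every_gate_recorded(self):
        result = apply_qc(self.make_sample(), self.make_result())
        assert set(result.qc_details) == {
            "calibrators", "rnasep_range", "quantifiable_targets",
            "informative_targets", "rcv", "skew"}
        for gate in result.qc_details.values():
            assert {"observed", "threshold", "pass"} <= set(gate)


class TestMethod1:
    def test_noiseless_exactness(self, panel, genotype_pair):
        rec, don = genotype_pair
        rec_map, don_map = genotype_maps(panel, rec, don)
        for df_true in (0.001, 0.002, 0.01, 0.05, 0.10):
            sample = make_noiseless_sample(panel, rec, don, df_true)
            result = estimate_df_method1(sample, rec_map, don_map, panel)
            assert abs(result.df - df_true) <= 1e-12
            assert result.n_informative >= 27

    def test_median_of_explicit_estimates(self):
        panel = make_panel(3)
        # HET donor everywhere: estimate = 2 x alt fraction
        ests = [0.0085, 0.0104, 0.0313]
        sample = sample_from_fractions([e / 2 for e in ests])
        rec = {f"S{i}": HOM_REF for i in range(3)}
        don = {f"S{i}": HET for i in range(3)}
        result = estimate_df_method1(sample, rec, don, panel)
        assert result.df == pytest.approx(0.0104, abs=1e-15)

    def test_even_count_median_is_midpoint(self):
        panel = make_panel(4)
        ests = [0.008, 0.010, 0.014, 0.030]
        sample = sample_from_fractions([e / 2 for e in ests])
        rec = {f"S{i}": HOM_REF for i in range(4)}
        don = {f"S{i}": HET for i in range(4)}
        result = estimate_df_method1(sample, rec, don, panel)
        assert result.df == pytest.approx(0.012, abs=1e-15)

    def test_scale_invariance(self, panel, genotype_pair):
        """Multiplying every quantity by a constant changes nothing."""
        rec, don = genotype_pair
        rec_map, don_map = genotype_maps(panel, rec, don)
        sample = af.simulate_qgt_sample(
            af.SimConfig(seed=8, df_true=0.01), panel, rec, don)
        scaled = QgtSample(
            sample_id="x",
            records=sample.records.assign(
                ref_quantity=sample.records["ref_quantity"] * 7.3,
                alt_quantity=sample.records["alt_quantity"] * 7.3),
            rnasep_log_value=sample.rnasep_log_value)
        a = estimate_df_method1(sample, rec_map, don_map, panel)
        b = estimate_df_method1(scaled, rec_map, don_map, panel)
        assert a.df == pytest.approx(b.df, rel=1e-12)
        assert a.rcv == pytest.approx(b.rcv, rel=1e-12)
        assert a.skew == pytest.approx(b.skew, rel=1e-12)

    def test_estimates_above_ceiling_excluded(self):
        panel = make_panel(3)
        sample = sample_from_fractions([0.005, 0.005, 0.40])  # 0.80 > ceiling
        rec = {f"S{i}": HOM_REF for i in range(3)}
        don = {f"S{i}": HET for i in range(3)}
        result = estimate_df_method1(sample, rec, don, panel)
        assert result.n_informative == 2
        assert result.df == pytest.approx(0.01)

    def test_no_informative_targets(self):
        panel = make_panel(2)
        sample = sample_from_fractions([0.005, 0.005])
        rec = {f"S{i}": HOM_REF for i in range(2)}
        don = {f"S{i}": HOM_REF for i in range(2)}
        result = estimate_df_method1(sample, rec, don, panel)
        assert result.df is None
        assert not result.qc_pass


class TestMethod2:
    MC = McConfig(n_stage1=3000, n_stage2=6000, seed=7)

    def test_noiseless_recovery(self, panel, genotype_pair):
        rec, don = genotype_pair
        rec_map, _ = genotype_maps(panel, rec, don)
        sample = make_noiseless_sample(panel, rec, don, 0.01)
        result = estimate_df_method2(sample, rec_map, panel, mc=self.MC)
        assert abs(result.df - 0.0100) <= 5e-4

    def test_deterministic_for_fixed_seed(self, panel, genotype_pair):
        rec, don = genotype_pair
        rec_map, _ = genotype_maps(panel, rec, don)
        sample = af.simulate_qgt_sample(
            af.SimConfig(seed=9, df_true=0.02), panel, rec, don)
        a = estimate_df_method2(sample, rec_map, panel, mc=self.MC)
        b = estimate_df_method2(sample, rec_map, panel, mc=self.MC)
        assert a.df == b.df
        assert a.candidate_percentiles == b.candidate_percentiles

    def test_blank_sample_below_detection(self, panel, genotype_pair):
        """Single-genome samples report DF below the 0.110% blank limit."""
        rec, don = genotype_pair
        rec_map, _ = genotype_maps(panel, rec, don)
        rng = np.random.default_rng(71)
        dfs = []
        for _ in range(5):
            sample = af.simulate_qgt_sample(
                af.SimConfig(seed=int(rng.integers(2**31)), df_true=0.0),
                panel, rec, don)
            mc = McConfig(n_stage1=3000, n_stage2=6000,
                          seed=int(rng.integers(2**31)))
            dfs.append(estimate_df_method2(sample, rec_map, panel, mc=mc).df)
        assert np.median(dfs) < 0.00110

    def test_point_mass_calibration_identity(self):
        """With exact data the candidate distribution collapses and the
        identity calibration returns that point."""
        panel = make_panel(40)
        sample = sample_from_fractions([0.01] * 40)
        rec = {f"S{i}": HOM_REF for i in range(40)}
        mc = McConfig(n_stage1=2000, n_stage2=4000, seed=3,
                      calibration=(1.0, 0.0))
        result = estimate_df_method2(sample, rec, panel, mc=mc)
        assert result.df == pytest.approx(0.02, rel=1e-9)
        pct = result.candidate_percentiles
        assert pct["p5"] == pytest.approx(pct["p95"], rel=1e-9)

    def test_degenerate_all_zero_fractions(self):
        panel = make_panel(30)
        sample = sample_from_fractions([0.0] * 30)
        rec = {f"S{i}": HOM_REF for i in range(30)}
        result = estimate_df_method2(sample, rec, panel, mc=self.MC)
        assert result.df == 0.0
        assert result.below_lob

    def test_insufficient_homozygous_targets(self):
        panel = make_panel(3)
        sample = sample_from_fractions([0.01, 0.01, 0.01])
        rec = {"S0": HET, "S1": HET, "S2": HOM_REF}
        with pytest.raises(ValueError, match="recipient-homozygous"):
            estimate_df_method2(sample, rec, panel, mc=self.MC)

    def test_agrees_with_method1_on_noisy_sample(self, panel, genotype_pair):
        rec, don = genotype_pair
        rec_map, don_map = genotype_maps(panel, rec, don)
        sample = af.simulate_qgt_sample(
            af.SimConfig(seed=12, df_true=0.05), panel, rec, don)
        r1 = estimate_df_method1(sample, rec_map, don_map, panel)
        r2 = estimate_df_method2(sample, rec_map, panel, mc=self.MC)
        assert r2.df == pytest.approx(r1.df, rel=0.10)


class TestReaders:
    def test_genotype_csv_round_trip(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("sample_id,target_id,genotype\n"
                        "p1,S0,HOM_REF\np1,S1,HET\np1,S2,NO_CALL\n")
        calls = read_genotypes_csv(path)
        assert calls == {"S0": HOM_REF, "S1": HET, "S2": GenotypeCall.NO_CALL}

    def test_genotype_csv_invalid_value(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("sample_id,target_id,genotype\np1,S0,WILD\n")
        with pytest.raises(ValueError, match="WILD"):
            read_genotypes_csv(path)

    def test_genotype_csv_multi_sample_needs_id(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("sample_id,target_id,genotype\n"
                        "p1,S0,HOM_REF\np2,S0,HET\n")
        with pytest.raises(ValueError, match="multiple samples"):
            read_genotypes_csv(path)
        assert read_genotypes_csv(path, sample_id="p2") == {"S0": HET}

    def test_sample_csv_long_form(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "sample_id,target_id,allele,replicate,quantity\n"
            "p1,S0,ref,1,99.0\np1,S0,alt,1,1.0\n"
            "p1,S0,ref,2,98.0\np1,S0,alt,2,2.0\n")
        sample = read_sample_csv(path)
        avg = sample.averaged()
        assert avg.loc["S0", "ref_quantity"] == pytest.approx(98.5)
        assert avg.loc["S0", "alt_quantity"] == pytest.approx(1.5)

    def test_genotype_vcf(self, tmp_path):
        path = tmp_path / "g.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tp1\n"
            "1\t100\tS0\tA\tG\t.\t.\t.\tGT\t0/0\n"
            "1\t200\tS1\tC\tT\t.\t.\t.\tGT\t0/1\n"
            "1\t300\tS2\tG\tA\t.\t.\t.\tGT\t1/1\n"
            "1\t400\tS3\tG\tA\t.\t.\t.\tGT\t./.\n")
        panel = SnpPanel([
            SnpTarget("S0", "A", "G", 0.3), SnpTarget("S1", "C", "T", 0.3),
            SnpTarget("S2", "G", "A", 0.3), SnpTarget("S3", "G", "A", 0.3)])
        calls = af.read_genotypes_vcf(path, panel)
        assert calls == {"S0": HOM_REF, "S1": HET, "S2": HOM_VAR,
                         "S3": GenotypeCall.NO_CALL}

    def test_negative_quantity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            QgtSample("x", pd.DataFrame({
                "target_id": ["S0"], "replicate": [1],
                "ref_quantity": [-1.0], "alt_quantity": [1.0]}))
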