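"""Statistical and determinism properties of the trio/ADS simulator."""

import numpy as np
import pytest

from lcmvar.calling import call_trio
from lcmvar.io_formats import CallerConfig, VariantRecord
from lcmvar.synthetic import SimulationConfig, simulate_ads, simulate_trio, write_truth_vcf


def small_config(**overrides):
    base = dict(
        n_patients=1,
        n_germline_per_patient=5,
        n_somatic_ect=2,
        n_somatic_eu=2,
        n_somatic_shared=1,
        n_null_per_patient=5,
        rng_seed=42,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_same_output(self):
        cfg = small_config()
        out1 = simulate_trio(cfg, 0)
        out2 = simulate_trio(cfg, 0)
        assert out1 == out2

    def test_different_patients_differ(self):
        cfg = small_config()
        _, counts0, truth0 = simulate_trio(cfg, 0)
        _, counts1, truth1 = simulate_trio(cfg, 1)
        assert truth0.somatic != truth1.somatic
        assert counts0 != counts1


class TestNoiseFreeLimit:
    def test_blood_is_clean_and_tissue_binomial(self):
        cfg = small_config(
            seq_error_rate=0.0,
            wga_artifact_rate=0.0,
            wga_dropout_prob=0.0,
            coverage_mean=1000.0,
            coverage_dispersion=500.0,
            somatic_vaf_range=(0.05, 0.05),
        )
        trio, counts, truth = simulate_trio(cfg, 0)
        somatic_loci = truth.somatic_loci
        blood = [c for c in counts if c.sample_id == trio.blood and c.locus in somatic_loci]
        assert blood and all(c.alt_reads == 0 for c in blood)
        # tissue alt reads scatter around vaf * depth
        for locus, vaf, comp in truth.somatic:
            reps = trio.ectopic_replicates if comp == "ECT" else trio.eutopic_replicates
            if comp == "BOTH":
                reps = trio.ectopic_replicates + trio.eutopic_replicates
            for c in counts:
                if c.locus == locus and c.sample_id in reps:
                    mean = vaf * c.depth
                    assert abs(c.alt_reads - mean) < 6 * np.sqrt(mean * (1 - vaf) + 1)


class TestTruthProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_categories_disjoint_across_seeds(self, seed):
        cfg = small_config(rng_seed=seed, wga_artifact_rate=1.0)
        _, _, truth = simulate_trio(cfg, 0)
        # TruthSet validates disjointness in __post_init__; check non-trivial
        assert truth.germline and truth.somatic and truth.artifacts

    def test_too_many_sites_rejected(self, panel):
        tiny = type(panel)(panel.entries[:1])
        cfg = small_config(panel=tiny, n_germline_per_patient=20_000)
        with pytest.raises(ValueError, match="panel positions"):
            simulate_trio(cfg, 0)


class TestStatisticalCalibration:
    def test_mean_vaf_converges_to_truth(self):
        """Law of large numbers: observed VAF averages to the configured
        true VAF within three standard errors."""
        v = 0.06
        cfg = small_config(
            n_germline_per_patient=0,
            n_somatic_ect=1500,
            n_somatic_eu=0,
            n_somatic_shared=0,
            n_null_per_patient=0,
            somatic_vaf_range=(v, v),
            wga_dropout_prob=0.0,
            wga_artifact_rate=0.0,
            n_replicates_per_tissue=1,
        )
        trio, counts, truth = simulate_trio(cfg, 0)
        (ect_rep,) = trio.ectopic_replicates
        vafs = np.array(
            [c.alt_reads / c.depth for c in counts if c.sample_id == ect_rep and c.depth > 0]
        )
        se = vafs.std(ddof=1) / np.sqrt(len(vafs))
        assert abs(vafs.mean() - v) <= 3 * se

    def test_coverage_fraction_at_20x(self):
        """The calibrated negative-binomial coverage model puts ~82% of
        sites at >=20x when the mean is 159x."""
        cfg = small_config(
            n_germline_per_patient=0,
            n_somatic_ect=0,
            n_somatic_eu=0,
            n_somatic_shared=0,
            n_null_per_patient=2000,
            wga_artifact_rate=0.0,
        )
        _, counts, _ = simulate_trio(cfg, 0)
        depths = np.array([c.depth for c in counts])
        assert len(depths) >= 10_000
        frac = (depths >= 20).mean()
        assert abs(frac - 0.82) <= 0.03
        assert abs(depths.mean() - 159) < 10


class TestAds:
    def _variants(self, truth):
        return [
            VariantRecord(locus, gene="G1", compartment=comp, patient_id=truth.patient_id)
            for locus, _, comp in truth.somatic
        ]

    def test_true_variant_mean_alt_reads(self):
        """alt reads in ADS replicates of the carrying compartment follow
        Binomial(depth, vaf): mean vaf*depth over many replicate draws."""
        v = 0.05
        cfg = small_config(
            somatic_vaf_range=(v, v),
            n_somatic_ect=50,
            n_somatic_eu=0,
            n_somatic_shared=0,
            ads_coverage_mean=2500.0,
            seq_error_rate=0.0,
        )
        _, _, truth = simulate_trio(cfg, 0)
        ads = simulate_ads(truth, self._variants(truth), cfg)
        ect = [c for c in ads if "_ECT_" in c.sample_id]
        ratios = np.array([c.alt_reads / c.depth for c in ect])
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - v) <= 4 * se
        eu = [c for c in ads if "_EU_" in c.sample_id]
        assert all(c.alt_reads == 0 for c in eu)  # error rate zero

    def test_artifact_clean_limit(self):
        cfg = small_config(seq_error_rate=0.0, wga_artifact_rate=1.0)
        _, _, truth = simulate_trio(cfg, 0)
        artifact_recs = [
            VariantRecord(locus, gene="G1", patient_id=truth.patient_id)
            for locus, _ in truth.artifacts
        ]
        ads = simulate_ads(truth, artifact_recs, cfg)
        assert ads and all(c.alt_reads == 0 for c in ads)

    def test_empty_selection_empty_output(self):
        cfg = small_config()
        _, _, truth = simulate_trio(cfg, 0)
        assert simulate_ads(truth, [], cfg) == []


class TestTruthVcf:
    def test_written_truth_is_readable(self, tmp_path):
        import pysam

        cfg = small_config(wga_artifact_rate=1.0)
        _, _, truth = simulate_trio(cfg, 0)
        path = tmp_path / "truth.vcf"
        write_truth_vcf([truth], path)
        kinds = [rec.info["TRUTH"] for rec in pysam.VariantFile(str(path))]
        assert {"germline", "somatic", "artifact"} <= set(kinds)
        n_expected = (
            len(truth.germline)
            + len(truth.somatic)
            + len(truth.artifacts)
            + len(truth.null_sites)
        )
        assert len(kinds) == n_expected


class TestRecoveryByCaller:
    def test_zero_noise_recovers_planted_set(self):
        """With all noise off and ample coverage the caller returns exactly
        the planted somatic loci with their planted compartments."""
        cfg = small_config(
            seq_error_rate=0.0,
            wga_artifact_rate=0.0,
            wga_dropout_prob=0.0,
            coverage_mean=1000.0,
            coverage_dispersion=300.0,
            somatic_vaf_range=(0.05, 0.10),
        )
        trio, counts, truth = simulate_trio(cfg, 0)
        compartments, _ = call_trio(counts, trio, CallerConfig())
        planted = {locus: comp for locus, _, comp in truth.somatic}
        assert compartments == planted
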