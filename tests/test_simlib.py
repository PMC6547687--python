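"""Generative-model behavior of the screen simulator."""

import numpy as np
import pandas as pd
import pytest

from staract import activity, counts as cm, difftest, simlib


class TestSimulateCounts:
    def test_identical_seeds_identical_outputs(self):
        cfg = simlib.SimulationConfig(n_snps=20, seed=9)
        a, ta = simlib.simulate_counts(cfg)
        b, tb = simlib.simulate_counts(simlib.SimulationConfig(n_snps=20, seed=9))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seeds_differ(self):
        a, _ = simlib.simulate_counts(simlib.SimulationConfig(n_snps=20, seed=1))
        b, _ = simlib.simulate_counts(simlib.SimulationConfig(n_snps=20, seed=2))
        assert set(a["barcode"]) != set(b["barcode"])

    def test_full_dropout_gives_empty_table(self):
        cfg = simlib.SimulationConfig(n_snps=10, seed=3, dropout_prob=1.0)
        counts, truth = simlib.simulate_counts(cfg)
        assert len(counts) == 0
        assert len(truth) == 10

    def test_truth_effect_structure(self):
        cfg = simlib.SimulationConfig(n_snps=300, seed=5, frac_differential=0.25)
        truth = simlib.simulate_truth(cfg)
        shift = truth["a_minor"] - truth["a_major"]
        assert np.allclose(shift[truth.is_differential], cfg.effect_log2)
        assert np.allclose(shift[~truth.is_differential], 0.0)

    def test_null_symmetry_between_alleles(self):
        # no allelic effect, no RNA noise, deep sequencing: mean allele
        # score difference vanishes within Monte-Carlo error
        cfg = simlib.SimulationConfig(
            n_snps=100,
            seed=7,
            frac_differential=0.0,
            rna_noise_sd=0.0,
            activity_sd=0.5,
            dna_depth=2_000_000,
            rna_depth=2_000_000,
        )
        counts, _ = simlib.simulate_counts(cfg)
        meas = activity.score_measurements(counts)
        alleles, _ = activity.aggregate_alleles(meas)
        wide = alleles.pivot(index="snp_id", columns="allele", values="mean_score")
        diff = (wide["minor"] - wide["major"]).dropna()
        assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(len(diff))

    def test_invalid_config_rejected(self):
        with pytest.raises(simlib.SimulationError):
            simlib.SimulationConfig(dropout_prob=1.5)
        with pytest.raises(simlib.SimulationError):
            simlib.SimulationConfig(n_replicates=0)


class TestSimulateReads:
    def test_unknown_variant_raises(self, toy_designs, tmp_path):
        cfg = simlib.SimulationConfig(n_snps=2, seed=1)
        counts = pd.DataFrame(
            {
                "snp_id": ["nope"],
                "allele": ["major"],
                "barcode": ["AAAAA"],
                "replicate": ["rep1"],
                "dna_reads": [5],
                "rna_reads": [5],
            }
        )
        with pytest.raises(simlib.SimulationError):
            simlib.simulate_reads(counts, toy_designs, cfg, tmp_path)

    def test_single_substitution_read_assigned_nowhere(self, toy_designs, toy_index):
        d = toy_designs[0]
        read = list(d.insert + "GCCGGTCAGAATGATGG" + "ACGTA")
        read[100] = "A" if read[100] != "A" else "G"
        assert cm.assign_read("".join(read), toy_index) is None

    def test_error_rate_reduces_retention_toward_binomial_survival(
        self, toy_designs, toy_index, tmp_path
    ):
        rate = 0.01
        cfg = simlib.SimulationConfig(
            n_snps=12, seed=13, dna_depth=8000, rna_depth=8000, read_error_rate=rate
        )
        counts, _ = simlib.simulate_counts(cfg)
        paths = simlib.simulate_reads(counts, toy_designs, cfg, tmp_path)
        n_reads = 0
        n_pass_insert = 0
        for rep in paths.values():
            for path in rep.values():
                res = cm.tabulate(path, [], "r", toy_index)
                n_reads += res.input_reads["dna"]
                n_pass_insert += res.input_reads["dna"] - res.rejects["dna"][
                    cm.REJECT_UNASSIGNED
                ]
        expected = (1 - rate) ** 196
        frac = n_pass_insert / n_reads
        se = np.sqrt(expected * (1 - expected) / n_reads)
        assert n_pass_insert < n_reads  # strictly fewer survive the filter
        assert abs(frac - expected) < 3 * se + 5e-4  # + slack for SNP-site flips


class TestSimulatePeaks:
    def _regions(self, n, rng):
        starts = np.arange(n) * 1000
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + 196,
                "activity": rng.normal(size=n),
                "snp_id": [f"s{i}" for i in range(n)],
            }
        )

    def test_flat_model_overlaps_half(self, rng):
        regions = self._regions(4000, rng)
        peaks = simlib.simulate_peaks(regions, slope=0.0, intercept=0.0, seed=1)
        frac = len(peaks) / len(regions)
        assert abs(frac - 0.5) < 0.03

    def test_positive_slope_enriches_active_regions(self, rng):
        from staract import enrich

        regions = self._regions(1000, rng)
        regions["mean_score"] = regions["activity"]
        peaks = simlib.simulate_peaks(regions, slope=3.0, intercept=0.0, seed=2)
        quint = enrich.assign_quintiles(regions)
        flags = enrich.overlap_flags(regions, {"sim": peaks})
        res = enrich.top_vs_bottom(flags, quint, dataset="sim")
        assert res.fold > 1.0
        top_rate = res.a / (res.a + res.b)
        bottom_rate = res.c / (res.c + res.d)
        assert top_rate > bottom_rate

    def test_emitted_peaks_intersect_their_region(self, rng):
        regions = self._regions(500, rng)
        peaks = simlib.simulate_peaks(regions, slope=0.0, intercept=30.0, seed=3)
        assert len(peaks) == len(regions)  # p = 1 to machine precision
        for (_, peak), (_, reg) in zip(peaks.iterrows(), regions.iterrows()):
            assert peak.Start < reg.end and peak.End > reg.start


class TestSimulateFeatures:
    def test_causal_count_validation(self):
        with pytest.raises(simlib.SimulationError):
            simlib.simulate_features(50, 10, 11, seed=1)

    def test_shapes_and_sparsity(self):
        X, y, beta, flags = simlib.simulate_features(80, 25, 4, seed=6)
        assert X.shape == (80, 25)
        assert (beta != 0).sum() == 4
        assert flags.sum() == round(0.3 * 25)
        # flagged features were exponentiated: strictly positive
        assert (X.loc[:, flags] > 0).all().all()


class TestSimulateAei:
    def test_zero_depth_flagged_not_crashing(self):
        counts, _ = simlib.simulate_aei(n_patients=3, dna_depth=0, seed=1)
        assert (counts["dna_major"] + counts["dna_minor"] == 0).all()

    def test_true_fold_shifts_rna_fraction(self):
        counts, truth = simlib.simulate_aei(
            n_patients=9, true_fold=1.5, dna_depth=50_000, rna_depth=50_000, seed=2
        )
        dna_frac = counts["dna_minor"] / (counts["dna_minor"] + counts["dna_major"])
        rna_frac = counts["rna_minor"] / (counts["rna_minor"] + counts["rna_major"])
        assert rna_frac.mean() > dna_frac.mean()
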