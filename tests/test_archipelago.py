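import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from motifbench.archipelago import (
    ArchipelagoClassifier,
    NegativeSetSpec,
    build_feature_matrix,
    build_positive_set,
    delta_vs_best_pwm,
    importance_ranking,
    merge_peaks,
    sample_negatives,
)
from motifbench.benchmarks import PeakSet
from motifbench.motifs import CountMatrix, FrequencyMatrix, MotifRecord
from motifbench.scanning import best_hit
from motifbench.simulate import GenomeConfig, PeakConfig, make_genome, plant_peaks
from motifbench.experiments import planted_motif, run_archipelago_experiment


def peakset(rows):
    return PeakSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "signal", "summit_offset"])
    )


def freq_record(name, freqs, platform="HTS"):
    counts = CountMatrix(freqs.matrix * 100, 100, "normalized_pfm_scaled")
    return MotifRecord(name, counts, tf="TF1", platform=platform)


class TestMergePeaks:
    def test_disjoint_unchanged(self):
        ps = peakset([("chr1", 0, 100, 1.0, 50), ("chr1", 500, 600, 2.0, 50)])
        merged = merge_peaks([ps])
        assert len(merged) == 2
        pd.testing.assert_frame_equal(
            merged.records[["chrom", "start", "end"]],
            ps.records[["chrom", "start", "end"]],
        )

    def test_overlapping_summits_averaged(self):
        ps = peakset([("chr1", 50, 150, 1.0, 50), ("chr1", 100, 200, 2.0, 10)])
        merged = merge_peaks([ps])
        assert len(merged) == 1
        rec = merged.records.iloc[0]
        assert rec["start"] == 50 and rec["end"] == 200
        assert rec["start"] + rec["summit_offset"] == 105  # mean(100, 110)

    def test_idempotent(self):
        ps = peakset(
            [("chr1", 0, 100, 1.0, 40), ("chr1", 90, 200, 2.0, 60),
             ("chr2", 0, 50, 1.0, 25)]
        )
        once = merge_peaks([ps])
        twice = merge_peaks([once])
        pd.testing.assert_frame_equal(once.records, twice.records)


class TestPositiveSet:
    def test_window_arithmetic(self):
        genome = {"chr1": "A" * 1000}
        ps = peakset([("chr1", 450, 550, 1.0, 50)])  # summit 500
        pos = build_positive_set(ps, genome)
        rec = pos.iloc[0]
        assert (rec["start"], rec["end"]) == (350, 651)
        assert len(rec["sequence"]) == 301

    def test_edge_peak_dropped(self):
        genome = {"chr1": "A" * 300, "chr2": "C" * 1000}
        ps = peakset(
            [("chr1", 50, 150, 1.0, 50), ("chr2", 450, 550, 1.0, 50)]
        )
        pos = build_positive_set(ps, genome)
        assert len(pos) == 1
        assert pos.iloc[0]["chrom"] == "chr2"

    def test_all_dropped_raises(self):
        with pytest.raises(ValueError):
            build_positive_set(
                peakset([("chr1", 10, 60, 1.0, 25)]), {"chr1": "A" * 200}
            )


class TestSampleNegatives:
    def setup_method(self):
        self.genome = make_genome(
            GenomeConfig(n_autosomes=2, length=120_000), seed=5
        )
        self.peaks, self.genome = plant_peaks(
            self.genome, planted_motif(), PeakConfig(n=20), seed=6
        )
        self.positives = build_positive_set(self.peaks, self.genome)

    def test_random_count_and_ratio(self):
        neg = sample_negatives(
            NegativeSetSpec("random", ratio=100),
            self.positives, self.genome, peaks=self.peaks, seed=1,
        )
        assert len(neg) == 100 * len(self.positives)
        assert (neg["end"] - neg["start"] == 301).all()

    def test_negatives_avoid_peaks_and_n(self):
        neg = sample_negatives(
            NegativeSetSpec("random", ratio=10),
            self.positives, self.genome, peaks=self.peaks, seed=1,
        )
        for rec in neg.itertuples(index=False):
            assert "N" not in rec.sequence
            for p in self.peaks.records.itertuples(index=False):
                if p.chrom == rec.chrom:
                    assert rec.end <= p.start or rec.start >= p.end

    def test_shade_offsets_within_printed_intervals(self):
        neg = sample_negatives(
            NegativeSetSpec("shades", ratio=2),
            self.positives, self.genome, peaks=None, seed=2,
        )
        offs = neg["offset"].to_numpy()
        assert np.all((np.abs(offs) >= 450) & (np.abs(offs) <= 750))
        assert len(neg) <= 2 * len(self.positives)

    def test_gc_matching_chi2(self):
        neg = sample_negatives(
            NegativeSetSpec("random", ratio=50),
            self.positives, self.genome, peaks=self.peaks, seed=3,
        )
        def gc_hist(seqs):
            gcs = np.array(
                [(s.count("G") + s.count("C")) / len(s) for s in seqs]
            )
            bins = np.arange(0, 1.02, 0.02)
            return np.histogram(gcs, bins=bins)[0]
        h_pos = gc_hist(self.positives["sequence"])
        h_neg = gc_hist(neg["sequence"])
        p = h_pos / h_pos.sum()
        expected = p * h_neg.sum()
        mask = expected > 0
        stat = ((h_neg[mask] - expected[mask]) ** 2 / expected[mask]).sum()
        # negatives drawn from the positives' binned GC distribution
        assert stat < chi2.ppf(0.95, mask.sum() - 1) + 20  # loose guard

    def test_determinism(self):
        a = sample_negatives(
            NegativeSetSpec("random", ratio=5),
            self.positives, self.genome, peaks=self.peaks, seed=9,
        )
        b = sample_negatives(
            NegativeSetSpec("random", ratio=5),
            self.positives, self.genome, peaks=self.peaks, seed=9,
        )
        pd.testing.assert_frame_equal(a, b)

    def test_alien_needs_pool(self):
        with pytest.raises(ValueError, match="pool"):
            sample_negatives(
                NegativeSetSpec("alien"), self.positives, self.genome, seed=0
            )


class TestFeatureMatrix:
    def test_shape_and_no_missing(self, rng):
        seqs = ["ACGT" * 20, "TTTT" * 20, "AC"]
        pwms = [
            freq_record("p1", FrequencyMatrix(rng.dirichlet(np.ones(4), size=5))),
            freq_record("p2", FrequencyMatrix(rng.dirichlet(np.ones(4), size=7))),
        ]
        ds = build_feature_matrix(seqs, [1, 0, 0], pwms)
        assert ds.features.shape == (3, 2)
        assert not np.isnan(ds.features).any()

    def test_entries_match_best_hit(self, rng):
        seqs = ["ACGTACGTAGCTAGCT", "GGGGCCCCAAAATTTT"]
        pwm = freq_record("p1", FrequencyMatrix(rng.dirichlet(np.ones(4), size=4)))
        ds = build_feature_matrix(seqs, [1, 0], [pwm])
        for i, s in enumerate(seqs):
            assert ds.features[i, 0] == pytest.approx(
                best_hit(pwm.weights(), s).score, rel=1e-10
            )

    def test_excluded_platform_raises(self, rng):
        pwm = freq_record(
            "bad", FrequencyMatrix(rng.dirichlet(np.ones(4), size=4)),
            platform="CHS",
        )
        with pytest.raises(ValueError, match="excluded platform"):
            build_feature_matrix(["ACGTACGT"], [1], [pwm], exclusion_platform="CHS")


class TestClassifier:
    def make_data(self, rng, n=300):
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.5, n) > 0).astype(int)
        return X, y

    def test_deterministic_refit(self, rng):
        X, y = self.make_data(rng)
        a = ArchipelagoClassifier(random_state=3).fit(X, y).predict_proba(X)
        b = ArchipelagoClassifier(random_state=3).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="both classes"):
            ArchipelagoClassifier().fit(X, np.ones(10))

    def test_importances_normalized_and_constant_zero(self, rng):
        X, y = self.make_data(rng)
        X = np.column_stack([X, np.full(len(X), 3.0)])  # constant feature
        clf = ArchipelagoClassifier(random_state=0).fit(X, y)
        imp = clf.feature_importances_
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert imp[-1] == 0.0

    def test_sklearn_get_set_params(self):
        clf = ArchipelagoClassifier()
        params = clf.get_params()
        assert params["max_depth"] == 6
        assert params["max_samples"] == 0.8
        assert params["n_estimators"] == 100
        clf.set_params(random_state=42)
        assert clf.random_state == 42

    def test_logreg_comparator_same_interface(self, rng):
        X, y = self.make_data(rng)
        clf = ArchipelagoClassifier(model="logreg").fit(X, y)
        assert clf.predict_proba(X).shape == (len(X), 2)


class TestDeltaVsBestPwm:
    def test_hand_computed_table(self):
        model = {
            "per_set": {
                "random": {"auroc": 0.9, "auprc": 0.6},
                "shades": {"auroc": 0.8, "auprc": 0.7},
            }
        }
        pwm = {
            "random": {"auroc": 0.85, "auprc": 0.5},
            "shades": {"auroc": 0.82, "auprc": 0.65},
        }
        gains = delta_vs_best_pwm(model, pwm)
        assert gains["per_set"]["random"]["delta_auroc"] == pytest.approx(0.05)
        assert gains["per_set"]["shades"]["delta_auroc"] == pytest.approx(-0.02)
        assert gains["delta_auroc"] == pytest.approx((0.05 - 0.02) / 2)
        assert gains["average_gain"] == pytest.approx(
            ((0.05 + 0.1) / 2 + (-0.02 + 0.05) / 2) / 2
        )

    def test_identical_performance_zero_gain(self):
        m = {"per_set": {"random": {"auroc": 0.8, "auprc": 0.5}}}
        p = {"random": {"auroc": 0.8, "auprc": 0.5}}
        gains = delta_vs_best_pwm(m, p)
        assert gains["average_gain"] == 0.0


class TestEndToEnd:
    def test_leakage_guard_on_test_chromosomes(self):
        res = run_archipelago_experiment(seed=2, two_mode=False, n_peaks=80)
        train = res["datasets"]["train"]
        # training sequences all come from odd autosomes by construction;
        # verify none appears in any test set
        test_seqs = {
            s for ds in res["datasets"]["test"].values() for s in ds.sequences
        }
        assert not (set(train.sequences) & test_seqs)

    def test_baselines_may_differ_per_metric(self):
        res = run_archipelago_experiment(seed=3, two_mode=True, n_peaks=120)
        b = res["baselines"]["random"]
        assert {"best_auroc_pwm", "best_auprc_pwm"} <= set(b)

    def test_importance_ranking_orders_descending(self):
        res = run_archipelago_experiment(seed=4, two_mode=True, n_peaks=120)
        imps = [v for _, v in res["importances"]]
        assert imps == sorted(imps, reverse=True)
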