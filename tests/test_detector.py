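"""Detector training, calibration, scanning and library serialization."""

import numpy as np
import pytest

import sigmer.detector as det_mod
from sigmer.detector import (
    THRESHOLD_GRID,
    CalibrationError,
    DataError,
    DetectorModel,
    LibraryFormatError,
    ModelLibrary,
    calibrate_read_fraction,
    extract_examples,
    grid_search_threshold,
    load_library,
    merge_libraries,
    model_objective,
    save_library,
    scan_read,
    train_detector,
)
from sigmer.nn import TinyConvNet
from sigmer.seqio import InputError
from sigmer.sim import Squiggle, random_sequence, simulate_squiggle


class TestModelObjective:
    @pytest.mark.parametrize(
        "f1,p_c,p_max,lam,expected",
        [
            (1.0, 0, 1000, 0.01, 0.0),
            (1.0, 1000, 1000, 0.01, 0.01),
            (0.0, 0, 1000, 0.01, 1.0),
            (0.5, 500, 1000, 0.02, 0.51),
        ],
    )
    def test_printed_formula(self, f1, p_c, p_max, lam, expected):
        assert model_objective(f1, p_c, p_max, lam) == pytest.approx(expected)

    def test_monotone(self):
        assert model_objective(0.9, 100, 1000) < model_objective(0.8, 100, 1000)
        assert model_objective(0.9, 200, 1000) > model_objective(0.9, 100, 1000)

    def test_validation(self):
        with pytest.raises(InputError):
            model_objective(1.1, 0, 10)
        with pytest.raises(InputError):
            model_objective(0.5, 11, 10)


class TestThresholdGrid:
    def test_grid_shape(self):
        assert THRESHOLD_GRID.size == 250
        assert THRESHOLD_GRID[0] == 0.75
        assert THRESHOLD_GRID[-1] == 0.999
        assert np.allclose(np.diff(THRESHOLD_GRID), 0.001, atol=1e-9)

    def test_perfectly_separated_posteriors_tie_break_low(self):
        post = np.array([0.9995] * 5 + [0.6] * 5)
        y = np.array([1] * 5 + [0] * 5)
        assert grid_search_threshold(post, y) == 0.75

    def test_informative_threshold_found(self):
        post = np.array([0.98, 0.97, 0.96, 0.90, 0.85, 0.80])
        y = np.array([1, 1, 1, 0, 0, 0])
        t = grid_search_threshold(post, y)
        assert 0.90 < t <= 0.96

    def test_degenerate_posteriors_warn_and_return_minimum(self):
        with pytest.warns(UserWarning):
            t = grid_search_threshold(np.full(6, 0.9), np.array([1, 0, 1, 0, 1, 0]))
        assert t == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            grid_search_threshold(np.array([0.9, 0.8]), np.array([1, 1]))


@pytest.fixture(scope="module")
def labeled_squiggles(pore4):
    """Noise-light reads with a known embedded 8-mer (4-mer contexts)."""
    kmer = "ACGTGGTA"
    rng = np.random.default_rng(42)
    sqs = []
    for i in range(60):
        seq = list(random_sequence(150, 1000 + i))
        pos = int(rng.integers(20, 120))
        seq[pos : pos + 8] = kmer
        sqs.append(simulate_squiggle("".join(seq), pore4, seed=2000 + i, read_id=f"r{i}"))
    return kmer, sqs


class TestExtractExamples:
    def test_positive_windows_found(self, labeled_squiggles):
        kmer, sqs = labeled_squiggles
        pos, neg = extract_examples(sqs, kmer, window=100, seed=0)
        assert len(pos) >= len(sqs)  # at least one jittered window per read
        assert len(neg) == pytest.approx(len(pos), rel=0.1)
        assert pos.shape[1] == neg.shape[1] == 100

    def test_absent_kmer_is_data_error(self, labeled_squiggles):
        _, sqs = labeled_squiggles
        with pytest.raises(DataError, match="CCCCCCCC"):
            extract_examples(sqs, "CCCCCCCC", window=100, seed=0)

    def test_neg_ratio(self, labeled_squiggles):
        kmer, sqs = labeled_squiggles
        pos, neg = extract_examples(sqs, kmer, window=100, neg_ratio=2.0, seed=0)
        assert len(neg) == pytest.approx(2 * len(pos), rel=0.1)


@pytest.fixture(scope="module")
def trained_detector(labeled_squiggles):
    kmer, sqs = labeled_squiggles
    pos, neg = extract_examples(
        sqs, kmer, window=100, neg_ratio=1.5, seed=1, jitter_per_occurrence=3
    )
    return kmer, train_detector(
        (pos, neg), arch_config={"target_kmer": kmer}, seed=3, epochs=150
    )


class TestTrainAndScan:
    def test_training_learns_the_kmer(self, trained_detector):
        _, det = trained_detector
        assert det.training_f1 >= 0.8
        assert det.parameter_count <= det_mod.DEFAULT_P_MAX
        assert 0.75 <= det.posterior_threshold <= 0.999

    def test_training_deterministic(self, labeled_squiggles):
        kmer, sqs = labeled_squiggles
        pos, neg = extract_examples(sqs, kmer, window=100, seed=1)
        digests = set()
        for _ in range(2):
            det = train_detector((pos, neg), {"target_kmer": kmer}, seed=9, epochs=15)
            digests.add(det.net.weights_digest())
        assert len(digests) == 1

    def test_empty_class_rejected(self):
        with pytest.raises(DataError):
            train_detector((np.empty((0, 50)), np.zeros((3, 50))), seed=0)

    def test_scan_finds_embedded_kmer(self, trained_detector, pore4):
        kmer, det = trained_detector
        hits = 0
        for i in range(10):
            seq = list(random_sequence(400, 7000 + i))
            if kmer in "".join(seq):
                continue
            seq[200:208] = kmer
            sq = simulate_squiggle("".join(seq), pore4, seed=500 + i)
            hits += scan_read(det, sq).count >= 1
        assert hits >= 8

    def test_short_read_flagged(self, trained_detector, pore4):
        _, det = trained_detector
        sq = simulate_squiggle("ACGTACGT", pore4, seed=1, fixed_dwell=2)
        res = scan_read(det, sq)
        assert res.short_read and res.count == 0

    def test_window_length_read_yields_at_most_one_occurrence(self, trained_detector, pore4):
        kmer, det = trained_detector
        seq = "ACG" + kmer + "TACGTACGTACG"
        sq = simulate_squiggle(seq, pore4, seed=3, fixed_dwell=6)
        sq.samples = sq.samples[: det.input_window]
        assert scan_read(det, sq).count <= 1


class TestArchitectureSearch:
    def test_search_minimizes_objective(self, labeled_squiggles):
        from sigmer.detector import random_architecture_search

        kmer, sqs = labeled_squiggles
        pos, neg = extract_examples(sqs, kmer, window=100, seed=2)
        best, trials = random_architecture_search((pos, neg), n_trials=2, seed=4, epochs=15)
        assert len(trials) == 2
        scores = [t["objective"] for t in trials]
        assert model_objective(best.training_f1, best.parameter_count, det_mod.DEFAULT_P_MAX) == min(scores)
        for t in trials:
            assert t["objective"] == pytest.approx((1 - t["f1"]) + 0.01 * t["p_c"] / det_mod.DEFAULT_P_MAX)


class TestLibraryIO:
    def _library(self, trained_detector):
        kmer, det = trained_detector
        return ModelLibrary(
            detectors=[det],
            mode="read_detection",
            read_fraction_threshold=0.5,
            sample_fraction_threshold=0.2,
        )

    def test_round_trip_posteriors(self, trained_detector, tmp_path, rng):
        lib = self._library(trained_detector)
        save_library(lib, tmp_path / "lib")
        back = load_library(tmp_path / "lib")
        probe = rng.normal(size=(4, lib.detectors[0].input_window)).astype(np.float32)
        a = lib.detectors[0].net.predict_proba(probe)
        b = back.detectors[0].net.predict_proba(probe)
        assert np.array_equal(a, b)
        assert back.mode == "read_detection"
        assert back.read_fraction_threshold == 0.5
        assert back.detectors[0].posterior_threshold == lib.detectors[0].posterior_threshold

    def test_missing_weights_blob(self, trained_detector, tmp_path):
        lib = self._library(trained_detector)
        save_library(lib, tmp_path / "lib")
        (tmp_path / "lib" / "weights_0000.npz").unlink()
        with pytest.raises(LibraryFormatError):
            load_library(tmp_path / "lib")

    def test_version_mismatch(self, trained_detector, tmp_path):
        import json

        lib = self._library(trained_detector)
        save_library(lib, tmp_path / "lib")
        mf = tmp_path / "lib" / "manifest.json"
        manifest = json.loads(mf.read_text())
        manifest["version"] = "something-else"
        mf.write_text(json.dumps(manifest))
        with pytest.raises(LibraryFormatError):
            load_library(tmp_path / "lib")

    def test_merge_without_retraining(self, trained_detector, rng):
        kmer, det = trained_detector
        other = DetectorModel(target_kmer="TTTTAAAA", net=det.net, posterior_threshold=0.9)
        lib_a = ModelLibrary([det], mode="read_detection", read_fraction_threshold=0.5)
        lib_b = ModelLibrary([other], mode="read_detection", read_fraction_threshold=0.5)
        merged = merge_libraries(
            [(lib_a, [kmer]), (lib_b, ["TTTTAAAA"])],
            mode="read_detection",
            read_fraction_threshold=0.5,
        )
        assert merged.kmers == [kmer, "TTTTAAAA"]
        # interchangeability: the detector's posteriors are unchanged by merging
        probe = rng.normal(size=(3, det.input_window)).astype(np.float32)
        assert np.array_equal(det.net.predict_proba(probe), merged.detectors[0].net.predict_proba(probe))

    def test_duplicate_kmers_rejected(self, trained_detector):
        kmer, det = trained_detector
        with pytest.raises(InputError):
            ModelLibrary([det, det], mode="read_detection")


class TestReadFractionCalibration:
    def _fake_reads(self, n):
        return [Squiggle(read_id=f"r{i}", samples=np.zeros(10, np.float32)) for i in range(n)]

    def test_joint_calibration_recovers_separating_pair(self, trained_detector, monkeypatch):
        kmer, det = trained_detector
        lib = ModelLibrary(
            [det, DetectorModel("AACCGGTT", det.net), DetectorModel("GGTTAACC", det.net)],
            mode="read_detection",
        )
        reads = self._fake_reads(40)
        labels = np.array([i < 20 for i in range(40)])
        rng = np.random.default_rng(0)
        M = np.where(labels[:, None], rng.uniform(0.97, 1.0, (40, 3)), rng.uniform(0.0, 0.8, (40, 3)))
        monkeypatch.setattr(det_mod, "max_posterior_matrix", lambda dets, rds: M)
        t, f, best = calibrate_read_fraction(lib, reads, labels)
        assert best == 1.0
        assert 0 < f <= 1
        assert lib.read_fraction_threshold == f
        assert all(0.75 <= d.posterior_threshold <= 0.999 for d in lib.detectors)
        assert t == pytest.approx(np.mean([d.posterior_threshold for d in lib.detectors]))

    def test_uninformative_detectors_warn(self, trained_detector, monkeypatch):
        kmer, det = trained_detector
        lib = ModelLibrary([det], mode="read_detection")
        reads = self._fake_reads(60)
        labels = np.array([i < 30 for i in range(60)])
        rng = np.random.default_rng(1)
        M = rng.uniform(0.74, 1.0, (60, 1))  # fires at random, label-independent
        monkeypatch.setattr(det_mod, "max_posterior_matrix", lambda dets, rds: M)
        with pytest.warns(UserWarning, match="uninformative"):
            calibrate_read_fraction(lib, reads, labels)

    def test_single_class_rejected(self, trained_detector):
        kmer, det = trained_detector
        lib = ModelLibrary([det], mode="read_detection")
        with pytest.raises(CalibrationError):
            calibrate_read_fraction(lib, self._fake_reads(4), np.ones(4, bool))
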