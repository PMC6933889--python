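"""Sliding-window scanning, binary filters and call export."""

from dataclasses import replace

import numpy as np
import pytest

from splicescan import ModelSpec, SpliceCNN, TrainConfig
from splicescan.cnn_model import count_parameters
from splicescan.dataset import LabeledWindow, encode_batch
from splicescan.errors import CapacityError, ConfigError
from splicescan.scanner import (
    SiteCall,
    candidate_boundaries,
    filter_calls,
    non_maximum_suppression,
    read_calls_tsv,
    scan_sequence,
    train_binary_filters,
    write_calls_bed,
    write_calls_tsv,
)
from splicescan.sequence_io import Region


class TestScanEquivalence:
    def test_scan_equals_per_window_classification(self, small_sim):
        """Brute-force oracle: classify every window independently."""
        genome, _, _ = small_sim
        L = 30
        region = Region(genome.name, 500, 2500)
        model = SpliceCNN(ModelSpec(L=L, kernels=6, fc_units=12)).initialize(3)
        calls = scan_sequence(model, genome, region, L=L)

        positions = [
            p
            for p in range(region.start, region.end + 1)
            if p - L // 2 + 1 >= 1 and p + L // 2 <= genome.length
        ]
        windows = [genome.seq[p - L // 2 : p + L // 2] for p in positions]
        probs = model.predict_proba(encode_batch(windows))
        expected = []
        for p, row in zip(positions, probs):
            label = model.label_order[int(np.argmax(row))]
            if label in ("donor", "acceptor"):
                expected.append(SiteCall(genome.name, p, label, float(row.max())))
        assert calls == expected

    def test_step_strided_scan_subset_of_full_scan(self, small_sim):
        genome, _, _ = small_sim
        model = SpliceCNN(ModelSpec(L=30, kernels=6, fc_units=12)).initialize(3)
        region = Region(genome.name, 500, 1500)
        full = {c.boundary: c for c in scan_sequence(model, genome, region, L=30)}
        strided = scan_sequence(model, genome, region, L=30, step=5)
        assert all(c == full[c.boundary] for c in strided)
        assert all((c.boundary - region.start) % 5 == 0 for c in strided)


class TestScanContracts:
    def test_constant_non_splice_model_gives_no_calls(
        self, small_sim, stub_model_factory
    ):
        genome, _, _ = small_sim
        model = stub_model_factory(L=20, constant=(0.0, 0.0, 1.0))
        assert scan_sequence(model, genome, Region(genome.name, 100, 400)) == []

    def test_min_score_one_excludes_sub_one_probabilities(
        self, small_sim, stub_model_factory
    ):
        genome, _, _ = small_sim
        model = stub_model_factory(L=20, constant=(0.2, 0.7, 0.1))
        calls = scan_sequence(
            model, genome, Region(genome.name, 100, 400), min_score=1.0
        )
        assert calls == []

    def test_invalid_step_rejected(self, small_sim, stub_model_factory):
        genome, _, _ = small_sim
        with pytest.raises(ConfigError):
            scan_sequence(
                stub_model_factory(), genome, Region(genome.name, 100, 400), step=0
            )

    def test_region_shorter_than_window_rejected(self, small_sim, stub_model_factory):
        genome, _, _ = small_sim
        with pytest.raises(ConfigError):
            scan_sequence(
                stub_model_factory(L=20), genome, Region(genome.name, 100, 110)
            )

    def test_every_fitting_position_evaluated_once_at_step_one(self, small_sim):
        genome, _, _ = small_sim
        region = Region(genome.name, 5, 300)
        positions = candidate_boundaries(genome, region, L=40)
        assert positions[0] == 20  # first boundary with full left context
        assert positions[-1] == 300
        assert len(positions) == len(set(positions.tolist())) == 281


class TestBinaryFilters:
    def _toy_windows(self, L=20):
        """Linearly separable: sites carry GT at the junction, FPs are A-runs."""
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        positives, fps = [], []
        for i in range(40):
            s = bases[rng.integers(4, size=L)]
            s[L // 2 : L // 2 + 2] = list("GT")
            positives.append(
                LabeledWindow("c", 100 + i, "".join(s), "donor", True)
            )
            fps.append(
                LabeledWindow("c", 500 + i, "A" * L, "non_splice", None,
                              predicted_as="donor")
            )
        acceptors = [
            LabeledWindow("c", 900 + i, w.sequence[::-1], "acceptor", True)
            for i, w in enumerate(positives)
        ]
        fps_acc = [
            LabeledWindow("c", 1500 + i, "C" * L, "non_splice", None,
                          predicted_as="acceptor")
            for i in range(40)
        ]
        return positives + acceptors, fps + fps_acc

    def test_filters_have_two_output_units_and_expected_param_count(self):
        positives, fps = self._toy_windows()
        spec = ModelSpec(L=20, kernels=4, fc_units=8)
        donor_f, acceptor_f = train_binary_filters(
            positives, fps, spec, TrainConfig(epochs=1, seed=0)
        )
        for f in (donor_f, acceptor_f):
            assert f.params["fc2_W"].shape[1] == 2
            assert f.n_parameters == count_parameters(replace(spec, n_classes=2))

    def test_filters_learn_separable_toy_data(self):
        positives, fps = self._toy_windows()
        spec = ModelSpec(L=20, kernels=4, fc_units=8)
        donor_f, _ = train_binary_filters(
            positives, fps, spec, TrainConfig(epochs=25, seed=0, learning_rate=1e-3)
        )
        donors = [w for w in positives if w.label == "donor"]
        d_fps = [w for w in fps if w.predicted_as == "donor"]
        x = encode_batch([w.sequence for w in donors + d_fps])
        pred = donor_f.predict_proba(x).argmax(axis=1)
        truth = np.array([1] * len(donors) + [0] * len(d_fps))
        assert (pred == truth).mean() == 1.0

    def test_empty_class_raises(self):
        positives, fps = self._toy_windows()
        donors_only = [w for w in positives if w.label == "donor"]
        with pytest.raises(CapacityError):
            train_binary_filters(
                donors_only, fps, ModelSpec(L=20, kernels=4, fc_units=8),
                TrainConfig(epochs=1, seed=0),
            )


class _ScoreStub:
    """A filter stub returning a fixed site-probability per boundary."""

    def __init__(self, site_type, scores):
        self.label_order = ("false_positive", site_type)
        self.scores = scores

    def predict_proba(self, x):
        score = self.scores.pop(0)
        return np.array([[1 - score, score]])


class TestFilterCalls:
    def _calls(self):
        return [
            SiteCall("chr1", 100, "donor", 0.8),
            SiteCall("chr1", 200, "donor", 0.7),
        ]

    def test_accept_all_filters_keep_everything(self, small_sim):
        genome, _, _ = small_sim
        calls = self._calls()
        out = filter_calls(
            calls,
            _ScoreStub("donor", [1.0, 1.0]),
            _ScoreStub("acceptor", []),
            genome,
            L=20,
        )
        assert [(c.boundary, c.site_type, c.score) for c in out] == [
            (c.boundary, c.site_type, c.score) for c in calls
        ]
        assert all(c.passed_filter for c in out)

    def test_reject_all_filters_empty_output(self, small_sim):
        genome, _, _ = small_sim
        out = filter_calls(
            self._calls(),
            _ScoreStub("donor", [0.0, 0.0]),
            _ScoreStub("acceptor", []),
            genome,
            L=20,
        )
        assert out == []

    def test_threshold_keeps_only_passing_scores(self, small_sim):
        genome, _, _ = small_sim
        out = filter_calls(
            self._calls(),
            _ScoreStub("donor", [0.9, 0.4]),
            _ScoreStub("acceptor", []),
            genome,
            L=20,
            min_filter_score=0.5,
        )
        assert [c.boundary for c in out] == [100]
        assert out[0].filter_score == pytest.approx(0.9)

    def test_filtering_is_a_contraction(self, small_sim):
        genome, _, _ = small_sim
        rng = np.random.default_rng(1)
        calls = self._calls()
        out = filter_calls(
            calls,
            _ScoreStub("donor", list(rng.random(2))),
            _ScoreStub("acceptor", []),
            genome,
            L=20,
        )
        assert len(out) <= len(calls)
        kept = {(c.boundary, c.site_type) for c in out}
        assert kept <= {(c.boundary, c.site_type) for c in calls}

    def test_missing_filter_for_called_type_raises(self, small_sim):
        genome, _, _ = small_sim
        with pytest.raises(ConfigError):
            filter_calls(
                [SiteCall("chr1", 100, "acceptor", 0.8)],
                _ScoreStub("donor", [1.0]),
                None,
                genome,
                L=20,
            )


class TestCallExport:
    def test_tsv_round_trip(self, tmp_path):
        calls = [
            SiteCall("chr1", 100, "donor", 0.8, passed_filter=True),
            SiteCall("chr1", 250, "acceptor", 0.55),
        ]
        path = tmp_path / "calls.tsv"
        write_calls_tsv(calls, path)
        loaded = read_calls_tsv(path)
        assert [(c.seq_name, c.boundary, c.site_type, c.passed_filter)
                for c in loaded] == [
            ("chr1", 100, "donor", True),
            ("chr1", 250, "acceptor", None),
        ]

    def test_bed_is_zero_based_half_open(self, tmp_path):
        path = tmp_path / "calls.bed"
        write_calls_bed([SiteCall("chr1", 100, "donor", 0.8)], path)
        fields = path.read_text().strip().split("\t")
        assert fields[:4] == ["chr1", "99", "100", "donor"]
        assert fields[4] == "800"

    def test_nms_keeps_best_within_radius(self):
        calls = [
            SiteCall("chr1", 100, "donor", 0.6),
            SiteCall("chr1", 101, "donor", 0.9),
            SiteCall("chr1", 130, "donor", 0.5),
            SiteCall("chr1", 101, "acceptor", 0.3),
        ]
        out = non_maximum_suppression(calls, radius=5)
        assert {(c.boundary, c.site_type) for c in out} == {
            (101, "donor"),
            (130, "donor"),
            (101, "acceptor"),
        }
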